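"""Group-exclusive upregulated gene signatures from a labeled reference cohort.

For each molecular group, per-gene differential expression against all other
samples is computed on log2(x+1) values with a two-sided unequal-variance
t-test. A group's signature is the top ``n`` genes (ascending p) that pass
the p-value and log2 fold-change cuts in that group and in no other group —
the exclusivity rule that makes the downstream enrichment classifier's
signatures non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSignature",
    "SignatureBuildConfig",
    "EmptySignatureError",
    "per_group_de",
    "build_signature",
    "build_all_signatures",
]


class EmptySignatureError(ValueError):
    """No gene passes the exclusive-upregulation thresholds for a group."""


@dataclass(frozen=True)
class SignatureBuildConfig:
    n: int = 50
    p_threshold: float = 0.01
    log2fc_threshold: float = 2.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.log2fc_threshold < 0:
            raise ValueError("log2fc_threshold must be >= 0")


@dataclass(frozen=True)
class GeneSignature:
    """A group's exclusive upregulated gene set; ``shortfall`` is True when
    fewer than the requested ``n`` genes qualified."""

    group: str
    genes: tuple[str, ...]
    n: int
    shortfall: bool = False

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if len(self.genes) != self.n:
            raise ValueError("n must equal the number of genes")


def per_group_de(
    reference: pd.DataFrame, labels: pd.Series, group: str,
) -> pd.DataFrame:
    """Per-gene two-group test of ``group`` samples vs the rest.

    Expression is log2(x+1)-transformed; log2fc is the difference of group
    means on that scale and p comes from a two-sided Welch t-test. Genes
    with zero variance in both groups get p = 1 by convention.

    Returns a frame indexed by gene with columns ``p`` and ``log2fc``.
    """
    labels = labels.reindex(reference.columns)
    in_group = (labels == group).to_numpy()
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("need >= 2 samples inside and outside the group")

    log_expr = np.log2(reference.to_numpy(dtype=float) + 1.0)
    a, b = log_expr[:, in_group], log_expr[:, ~in_group]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, 1.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"p": p, "log2fc": log2fc}, index=reference.index)


def _passes(de: pd.DataFrame, config: SignatureBuildConfig) -> pd.Series:
    return (de["p"] < config.p_threshold) & (de["log2fc"] > config.log2fc_threshold)


def build_signature(
    reference: pd.DataFrame, labels: pd.Series, group: str,
    config: SignatureBuildConfig = SignatureBuildConfig(),
    _de_by_group: dict[str, pd.DataFrame] | None = None,
) -> GeneSignature:
    """Exclusive upregulated signature for one group.

    A gene qualifies when it passes the (p, log2fc) cuts in ``group`` and in
    no other group; qualifying genes are ranked by ascending p in ``group``
    and truncated to ``config.n``. A shortfall below ``n`` is flagged on the
    returned signature, not fatal; zero qualifying genes raise
    :class:`EmptySignatureError`.
    """
    config.validate()
    groups = labels.unique().tolist()
    if group not in groups:
        raise ValueError(f"group {group!r} not present in labels")
    de_by_group = _de_by_group or {
        g: per_group_de(reference, labels, g) for g in groups}

    passing = _passes(de_by_group[group], config)
    for other in groups:
        if other != group:
            passing &= ~_passes(de_by_group[other], config)
    if not passing.any():
        raise EmptySignatureError(
            f"no gene is exclusively upregulated in group {group!r}")

    qualified = de_by_group[group].loc[passing].sort_values(
        ["p", "log2fc"], ascending=[True, False], kind="mergesort")
    genes = tuple(qualified.index[: config.n])
    return GeneSignature(group=group, genes=genes, n=len(genes),
                         shortfall=len(genes) < config.n)


def build_all_signatures(
    reference: pd.DataFrame, labels: pd.Series,
    config: SignatureBuildConfig = SignatureBuildConfig(),
) -> dict[str, GeneSignature]:
    """Signatures for every group in ``labels`` (one DE pass per group)."""
    groups = labels.unique().tolist()
    de_by_group = {g: per_group_de(reference, labels, g) for g in groups}
    return {
        g: build_signature(reference, labels, g, config, _de_by_group=de_by_group)
        for g in groups
    }
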