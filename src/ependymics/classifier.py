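"""Molecular-group classification by a running-sum enrichment statistic.

A query expression profile is ranked by decreasing expression; walking down
the ranked list L (length m), the running sum increases by 1/n at each of
the n signature genes and decreases by 1/(m-n) otherwise, so the curve ends
exactly at 0 and its maximum is the enrichment score (ES). Significance is
estimated by randomizing the signature: uniform random n-subsets of L give
a permutation null, with the add-one estimator p = (1 + #{ES_b >= ES_obs})
/ (B + 1).

Decision rules: a dedicated low-power group (PFB in the posterior fossa
setting) is assigned first whenever its p-value falls below its own
threshold (default 0.34); otherwise the minimum-p signature is assigned if
its p is at most the unassignment threshold (default 0.35); else the sample
is left UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "UNASSIGNED",
    "ClassifierConfig",
    "EnrichmentResult",
    "ClassificationResult",
    "rank_genes",
    "running_sum_es",
    "permutation_p",
    "normalized_es",
    "classify",
    "evaluate_classifier",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ClassifierConfig:
    unassigned_threshold: float = 0.35
    pfb_threshold: float = 0.34
    pfb_group: str | None = None
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.unassigned_threshold < 1 and 0 < self.pfb_threshold < 1):
            raise ValueError("thresholds must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class EnrichmentResult:
    es: float
    p: float | None = None
    n_perm: int = 0
    curve: np.ndarray | None = None


@dataclass
class ClassificationResult:
    assigned_group: str
    per_signature: dict[str, EnrichmentResult] = field(default_factory=dict)


def rank_genes(profile: pd.Series) -> list[str]:
    """Genes of a profile ordered by decreasing expression.

    Ties are broken lexicographically by gene identifier so the ranking is
    deterministic across platforms; duplicate identifiers are rejected.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    if profile.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in profile")
    order = sorted(profile.index, key=lambda g: (-profile[g], g))
    return order


def _hit_ranks(ranked: list[str], signature_genes) -> np.ndarray:
    pos = {g: i for i, g in enumerate(ranked)}
    try:
        ranks = np.array(sorted(pos[g] for g in signature_genes))
    except KeyError as exc:
        raise ValueError(
            f"signature gene {exc.args[0]!r} absent from ranked list; "
            "intersect the signature with the profile first") from None
    return ranks


def _es_from_hit_ranks(ranks: np.ndarray, n: int, m: int) -> float:
    # curve rises only at hits, so its maximum is attained at a hit position:
    # after the k-th hit (0-based rank r_k) the curve is (k+1)/n - (r_k - k)/(m-n)
    k = np.arange(1, n + 1)
    return float(np.max(k / n - (ranks + 1 - k) / (m - n)))


def running_sum_es(
    ranked: list[str], signature: GeneSignature | None = None,
    genes=None, keep_curve: bool = True,
) -> EnrichmentResult:
    """Enrichment score (max of the running sum) of a signature on a ranked list.

    ``genes`` may be passed instead of a :class:`GeneSignature`. The full
    curve is returned unless ``keep_curve=False``; its final value is 0 up
    to rounding of the two step sizes.
    """
    sig_genes = list(signature.genes) if signature is not None else list(genes)
    m, n = len(ranked), len(sig_genes)
    if not 0 < n < m:
        raise ValueError("need 0 < signature size < ranked-list length")
    ranks = _hit_ranks(ranked, sig_genes)
    es = _es_from_hit_ranks(ranks, n, m)
    curve = None
    if keep_curve:
        steps = np.full(m, -1.0 / (m - n))
        steps[ranks] = 1.0 / n
        curve = np.cumsum(steps)
    return EnrichmentResult(es=es, curve=curve)


def permutation_p(
    ranked: list[str], signature: GeneSignature | None = None,
    config: ClassifierConfig = ClassifierConfig(), genes=None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation p-value for the enrichment score.

    Null scores come from uniform random n-subsets of the ranked list
    (gene randomization); p = (1 + #{ES_b >= ES_obs}) / (n_perm + 1), so
    p is never 0 and is deterministic given the config seed.
    """
    config.validate()
    sig_genes = list(signature.genes) if signature is not None else list(genes)
    m, n = len(ranked), len(sig_genes)
    result = running_sum_es(ranked, genes=sig_genes, keep_curve=False)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    null = _null_scores(rng, m, n, config.n_perm)
    result.p = (1.0 + int(np.sum(null >= result.es))) / (config.n_perm + 1.0)
    result.n_perm = config.n_perm
    return result


def _null_scores(rng: np.random.Generator, m: int, n: int, n_perm: int) -> np.ndarray:
    k = np.arange(1, n + 1)
    # rank matrix of n_perm random n-subsets of {0..m-1}, rows sorted
    ranks = np.sort(
        rng.random((n_perm, m)).argpartition(n - 1, axis=1)[:, :n], axis=1)
    return np.max(k[None, :] / n - (ranks + 1 - k[None, :]) / (m - n), axis=1)


def normalized_es(
    ranked: list[str], signature: GeneSignature | None = None,
    config: ClassifierConfig = ClassifierConfig(), genes=None,
) -> float:
    """NES: observed ES divided by the mean of the positive permuted scores.

    Values above 1 indicate enrichment, below 1 depletion, of the signature
    near the top of the ranked list.
    """
    config.validate()
    if config.n_perm < 10:
        raise ValueError("n_perm must be >= 10 for NES")
    sig_genes = list(signature.genes) if signature is not None else list(genes)
    m, n = len(ranked), len(sig_genes)
    es = running_sum_es(ranked, genes=sig_genes, keep_curve=False).es
    rng = np.random.default_rng(config.seed)
    null = _null_scores(rng, m, n, config.n_perm)
    positive = null[null > 0]
    if positive.size == 0:
        raise ValueError("no positive permuted scores; NES undefined")
    return es / float(positive.mean())


def classify(
    profile: pd.Series, signatures: list[GeneSignature],
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassificationResult:
    """Assign a molecular group to one query profile.

    Signature genes absent from the profile are dropped before scoring
    (the post-intersection size is used in the step sizes). The PFB-style
    carve-out (step 2) precedes the minimum-p assignment (step 3); ties on
    p go to the larger ES, then lexicographically.
    """
    config.validate()
    if not signatures:
        raise ValueError("empty signature list")
    ranked = rank_genes(profile)
    present = set(ranked)
    rng = np.random.default_rng(config.seed)
    per_signature: dict[str, EnrichmentResult] = {}
    for sig in sorted(signatures, key=lambda s: s.group):
        genes = [g for g in sig.genes if g in present]
        if not genes:
            raise ValueError(f"signature {sig.group!r} shares no genes with profile")
        per_signature[sig.group] = permutation_p(
            ranked, genes=genes, config=config, rng=rng)

    if config.pfb_group is not None and config.pfb_group in per_signature:
        if per_signature[config.pfb_group].p < config.pfb_threshold:
            return ClassificationResult(config.pfb_group, per_signature)
    best = min(per_signature,
               key=lambda g: (per_signature[g].p, -per_signature[g].es, g))
    if per_signature[best].p <= config.unassigned_threshold:
        return ClassificationResult(best, per_signature)
    return ClassificationResult(UNASSIGNED, per_signature)


def evaluate_classifier(
    predictions, truth_labels,
) -> tuple[float, pd.DataFrame]:
    """Misclassification rate and confusion table.

    UNASSIGNED predictions count as misclassified. The confusion table has
    true groups as rows and predicted groups (plus UNASSIGNED) as columns.
    """
    predictions = list(predictions)
    truth_labels = list(truth_labels)
    if len(predictions) != len(truth_labels):
        raise ValueError("predictions and truth labels differ in length")
    groups = sorted(set(truth_labels) | (set(predictions) - {UNASSIGNED}))
    cols = groups + [UNASSIGNED]
    table = pd.DataFrame(0, index=groups, columns=cols)
    errors = 0
    for pred, true in zip(predictions, truth_labels):
        table.loc[true, pred] += 1
        errors += pred != true
    return errors / len(truth_labels), table
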