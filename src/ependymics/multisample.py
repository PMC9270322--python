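"""Per-sample population-vs-rest testing with Fisher combination across samples.

The framework: within each sample, every feature is tested between one cell
population and all other cells; samples where the population is too rare
(below a fraction threshold — 3% for expression, 4% for accessibility and
motif scores) are excluded; per-sample p-values of features observed in at
least ``min_samples_for_combination`` included samples are combined with
Fisher's method (-2 * sum(ln p) ~ chi-square with 2k df); features seen in
exactly one included sample are reported with that p-value and flagged
uncombined. Benjamini-Hochberg FDR is computed over the reported batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEConfig",
    "CombinedTestResult",
    "per_sample_de",
    "sample_inclusion",
    "fisher_combine",
    "combine_across_samples",
    "bh_fdr",
    "run_population_de",
]

P_FLOOR = 1e-300  # floor before log to keep Fisher's statistic finite


@dataclass(frozen=True)
class DEConfig:
    min_cluster_expr_frac: float = 0.05
    min_cluster_sample_frac: float = 0.03
    min_samples_for_combination: int = 2
    fdr_threshold: float = 0.1

    def validate(self) -> None:
        if not 0 < self.min_cluster_expr_frac < 1:
            raise ValueError("min_cluster_expr_frac must be in (0, 1)")
        if not 0 < self.min_cluster_sample_frac < 1:
            raise ValueError("min_cluster_sample_frac must be in (0, 1)")
        if self.min_samples_for_combination < 1:
            raise ValueError("min_samples_for_combination must be >= 1")


@dataclass
class CombinedTestResult:
    feature: str
    per_sample_p: dict[str, float] = field(default_factory=dict)
    per_sample_log2fc: dict[str, float] = field(default_factory=dict)
    included_samples: set[str] = field(default_factory=set)
    combined_p: float = np.nan
    fdr: float = np.nan
    uncombined: bool = False


class PopulationAbsentError(ValueError):
    """The target population has no cells in the sample (distinct from a
    feature being excluded by the expression filter)."""


def per_sample_de(
    counts: pd.DataFrame, cell_labels: pd.Series, target_population: str,
    config: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Population-vs-rest differential expression within one sample.

    Genes expressed (count > 0) in fewer than ``min_cluster_expr_frac`` of
    the population's cells are dropped before testing. The test is a
    two-sided Mann-Whitney rank-sum on the raw counts (tie-corrected normal
    approximation); log2fc is computed on per-cell library-size-normalized
    means with a pseudocount of 1.

    Returns a frame indexed by gene with columns ``p`` and ``log2fc``.
    """
    config.validate()
    cell_labels = cell_labels.reindex(counts.columns)
    in_pop = (cell_labels == target_population).to_numpy()
    if in_pop.sum() == 0:
        raise PopulationAbsentError(
            f"population {target_population!r} absent from sample")
    if (~in_pop).sum() == 0:
        raise ValueError("population comprises the whole sample; no rest to test")

    x = counts.to_numpy(dtype=float)
    expr_frac = (x[:, in_pop] > 0).mean(axis=1)
    keep = expr_frac >= config.min_cluster_expr_frac
    x = x[keep]

    # library-size normalization to the mean cell total (guard empty cells)
    totals = counts.to_numpy(dtype=float).sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    norm = x / totals[None, :] * totals.mean()
    mean_in = norm[:, in_pop].mean(axis=1)
    mean_out = norm[:, ~in_pop].mean(axis=1)
    log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-tied genes emit a zero-variance warning
        res = stats.mannwhitneyu(
            x[:, in_pop], x[:, ~in_pop], axis=1, method="asymptotic",
            use_continuity=False, alternative="two-sided")
    p = np.clip(np.nan_to_num(res.pvalue, nan=1.0), P_FLOOR, 1.0)
    return pd.DataFrame({"p": p, "log2fc": log2fc}, index=counts.index[keep])


def sample_inclusion(
    labels_by_sample: Mapping[str, pd.Series], target_population: str,
    min_frac: float = 0.03,
) -> set[str]:
    """Samples whose fraction of the target population is >= ``min_frac``."""
    included = set()
    for sample, labels in labels_by_sample.items():
        if len(labels) == 0:
            raise ValueError(f"empty labels for sample {sample!r}")
        if (labels == target_population).mean() >= min_frac:
            included.add(sample)
    return included


def fisher_combine(p_values) -> float:
    """Fisher's method: combined p from -2 * sum(ln p) ~ chi-square(2k)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]; floor zeros first")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def combine_across_samples(
    per_sample: Mapping[str, pd.DataFrame], included_samples: set[str],
    config: DEConfig = DEConfig(),
) -> list[CombinedTestResult]:
    """Fisher-combine per-sample results for features seen in enough samples.

    A feature with per-sample p-values in >= ``min_samples_for_combination``
    included samples gets a combined p; a feature observed in exactly one
    included sample is reported with that p-value and ``uncombined=True``
    (mirroring populations present in a single sample); features absent
    from all included samples are dropped. FDR is Benjamini-Hochberg over
    all reported combined p-values.
    """
    config.validate()
    usable = {s: df for s, df in per_sample.items() if s in included_samples}
    if not usable:
        warnings.warn("no included samples; returning empty result list")
        return []

    features: dict[str, CombinedTestResult] = {}
    for sample, df in sorted(usable.items()):
        for feature, row in df.iterrows():
            res = features.setdefault(feature, CombinedTestResult(feature=feature))
            res.per_sample_p[sample] = float(row["p"])
            if "log2fc" in df.columns:
                res.per_sample_log2fc[sample] = float(row["log2fc"])
            res.included_samples.add(sample)

    results = []
    for feature in sorted(features):
        res = features[feature]
        ps = np.clip(list(res.per_sample_p.values()), P_FLOOR, 1.0)
        if len(ps) >= config.min_samples_for_combination:
            res.combined_p = fisher_combine(ps)
        elif len(ps) == 1:
            res.combined_p = float(ps[0])
            res.uncombined = True
        else:
            continue
        results.append(res)

    qs = bh_fdr(np.array([r.combined_p for r in results]))
    for res, q in zip(results, qs):
        res.fdr = float(q)
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def run_population_de(
    counts_by_sample: Mapping[str, pd.DataFrame],
    labels_by_sample: Mapping[str, pd.Series],
    target_population: str,
    config: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Full per-population pipeline: per-sample DE, 3% inclusion, combination.

    Returns a frame indexed by gene with combined_p, fdr, uncombined flag,
    number of contributing samples, and the mean per-sample log2fc.
    """
    included = sample_inclusion(
        labels_by_sample, target_population, config.min_cluster_sample_frac)
    per_sample = {
        s: per_sample_de(counts_by_sample[s], labels_by_sample[s],
                         target_population, config)
        for s in sorted(included)
    }
    results = combine_across_samples(per_sample, included, config)
    return results_to_frame(results)


def results_to_frame(results: list[CombinedTestResult]) -> pd.DataFrame:
    rows = {
        r.feature: {
            "combined_p": r.combined_p,
            "fdr": r.fdr,
            "uncombined": r.uncombined,
            "n_samples": len(r.included_samples),
            "mean_log2fc": (np.mean(list(r.per_sample_log2fc.values()))
                            if r.per_sample_log2fc else np.nan),
        }
        for r in results
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "feature"
    return frame
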