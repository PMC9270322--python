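"""Chromatin-accessibility statistics and TF regulatory-network construction.

Covers the ATAC-side procedures: merging per-sample peak sets into a union
set (maximal unions of overlapping half-open intervals), removing
outlier-wide peaks (width > mean + 3 SD), gene-activity scoring (fragments
overlapping gene body or the strand-aware 2 kb promoter), per-sample Fisher
exact differential accessibility with a 30% in-population accessibility
filter and Fisher-method combination across samples (4% population-fraction
inclusion rule), enhancer/DEG concordance, rank-sum testing of per-cell TF
motif deviation scores, a joint expression-correlation + motif screen, and
the directed TF-to-TF network built from significant differentially
accessible binding sites within +/-10 kbp of a target gene's locus.

All coordinates are 0-based half-open (BED convention): abutting intervals
do not overlap, and a window's left edge is inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .multisample import (
    DEConfig, P_FLOOR, bh_fdr, combine_across_samples, sample_inclusion,
)

__all__ = [
    "DAConfig",
    "MotifTestConfig",
    "merge_peak_sets",
    "filter_peak_widths",
    "gene_activity",
    "fisher_exact_two_sided",
    "differential_accessibility",
    "enhancer_concordance",
    "motif_deviation_test",
    "joint_emt_screen",
    "build_tf_network",
]


@dataclass(frozen=True)
class DAConfig:
    """Differential-accessibility knobs: 30% in-population accessibility
    pre-filter, 4% sample-inclusion rule, >=2-sample combination."""

    min_cluster_access_frac: float = 0.30
    min_cluster_sample_frac: float = 0.04
    min_samples_for_combination: int = 2
    fdr_threshold: float = 0.1


@dataclass(frozen=True)
class MotifTestConfig:
    delta_z_min: float = 1.0
    fdr_threshold: float = 0.01
    sample_min_frac: float = 0.04
    min_samples_for_combination: int = 2
    alternative: str = "greater"  # upregulation in the population

    def validate(self) -> None:
        if self.delta_z_min < 0:
            raise ValueError("delta_z_min must be >= 0")


# ---------------------------------------------------------------- intervals

def _validate_intervals(df: pd.DataFrame) -> None:
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    bad = np.flatnonzero(~((starts >= 0) & (starts < ends)))
    if bad.size:
        raise ValueError(f"malformed interval at record index {int(bad[0])}: "
                         f"start={starts[bad[0]]}, end={ends[bad[0]]}")


def merge_peak_sets(peak_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union peak set: maximal unions of overlapping intervals across samples.

    Half-open convention: [10,20) and [20,30) abut but do not intersect and
    stay separate. Output is disjoint and sorted by (chrom, start).
    """
    frames = [df[["chrom", "start", "end"]] for df in peak_sets]
    for df in frames:
        _validate_intervals(df)
    allpeaks = pd.concat(frames, ignore_index=True)
    merged = []
    for chrom, grp in allpeaks.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        cur_start = cur_end = None
        for start, end in zip(grp["start"], grp["end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start < cur_end:  # strict: abutment does not merge
                cur_end = max(cur_end, end)
            else:
                merged.append((chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end))
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    out["name"] = [f"union_peak{i:05d}" for i in range(len(out))]
    return out


def filter_peak_widths(peaks: pd.DataFrame) -> pd.DataFrame:
    """Drop peaks wider than mean + 3 SD of the input widths (order kept)."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to estimate the width cutoff")
    widths = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    cutoff = widths.mean() + 3.0 * widths.std(ddof=1)
    return peaks.loc[widths <= cutoff]


def _gene_regions(row) -> list[tuple[int, int]]:
    """Gene body plus strand-aware 2 kb promoter upstream of the TSS."""
    strand = row.get("strand")
    if strand not in ("+", "-"):
        raise ValueError(f"gene {row['gene']!r} has no strand; promoter undefined")
    tss = int(row["tss"])
    body = (int(row["start"]), int(row["end"]))
    if strand == "+":
        promoter = (max(0, tss - 2000), tss)
    else:
        promoter = (tss, tss + 2000)
    # merge body and promoter where they touch or overlap
    regions = sorted([body, promoter])
    if regions[0][1] >= regions[1][0]:
        return [(regions[0][0], max(regions[0][1], regions[1][1]))]
    return regions


def gene_activity(
    fragments: pd.DataFrame, gene_loci: pd.DataFrame,
) -> pd.DataFrame:
    """Gene x cell activity: fragments overlapping gene body or promoter.

    ``fragments`` needs columns chrom, start, end, cell. A fragment is
    counted once per gene when it has nonzero overlap with the union of the
    gene body and its 2 kb promoter (half-open; a fragment ending exactly
    at a region start does not overlap).
    """
    _validate_intervals(fragments)
    cells = pd.unique(fragments["cell"])
    cell_idx = {c: i for i, c in enumerate(cells)}
    out = np.zeros((len(gene_loci), len(cells)), dtype=int)
    by_chrom = dict(tuple(fragments.groupby("chrom")))
    for gi, (_, row) in enumerate(gene_loci.iterrows()):
        frags = by_chrom.get(row["chrom"])
        if frags is None:
            continue
        fs = frags["start"].to_numpy()
        fe = frags["end"].to_numpy()
        hit = np.zeros(len(frags), dtype=bool)
        for rs, re_ in _gene_regions(row):
            hit |= (fs < re_) & (fe > rs)
        for cell in frags.loc[hit, "cell"]:
            out[gi, cell_idx[cell]] += 1
    return pd.DataFrame(out, index=gene_loci["gene"].to_numpy(), columns=cells)


# ------------------------------------------------------------ exact testing

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Computed by summing, over the conditional (hypergeometric) support,
    the probabilities of all tables at most as likely as the observed one
    (with the customary 1 + 1e-7 relative guard against float noise).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n1, total, k = a + b, a + b + c + d, a + c
    if total == 0:
        return 1.0
    n2 = total - n1
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    # log C(n1,x) + log C(n2,k-x) - log C(N,k) over the conditional support
    lg = gammaln
    log_pmf = (lg(n1 + 1) - lg(support + 1) - lg(n1 - support + 1)
               + lg(n2 + 1) - lg(k - support + 1) - lg(n2 - k + support + 1)
               - (lg(total + 1) - lg(k + 1) - lg(total - k + 1)))
    pmf = np.exp(log_pmf)
    p_obs = pmf[a - support[0]]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def differential_accessibility(
    matrices_by_sample: Mapping[str, pd.DataFrame],
    labels_by_sample: Mapping[str, pd.Series],
    population: str,
    config: DAConfig = DAConfig(),
) -> pd.DataFrame:
    """Per-population differentially accessible peaks across samples.

    In each sample, peaks accessible (nonzero) in fewer than 30% of the
    population's cells are removed; remaining peaks are tested with a
    two-sided Fisher exact test on (accessible x in-population) counts.
    Samples where the population is below ``min_cluster_sample_frac`` are
    excluded; per-sample p-values are Fisher-combined (>=2 samples, single
    -sample peaks flagged uncombined) and BH-adjusted. Direction comes from
    the majority sign of the per-sample log odds (ties -> 'ambiguous').
    """
    if not any((labels == population).any()
               for labels in labels_by_sample.values()):
        raise ValueError(f"population {population!r} absent from all samples")
    included = sample_inclusion(
        labels_by_sample, population, config.min_cluster_sample_frac)
    per_sample: dict[str, pd.DataFrame] = {}
    direction_votes: dict[str, list[int]] = {}
    for sample in sorted(included):
        mat = matrices_by_sample[sample]
        labels = labels_by_sample[sample].reindex(mat.columns)
        in_pop = (labels == population).to_numpy()
        acc = (mat.to_numpy() > 0)
        frac_in = acc[:, in_pop].mean(axis=1)
        keep = frac_in >= config.min_cluster_access_frac
        a = acc[keep][:, in_pop].sum(axis=1)
        c = acc[keep][:, ~in_pop].sum(axis=1)
        n_in, n_out = int(in_pop.sum()), int((~in_pop).sum())
        ps = np.array([
            fisher_exact_two_sided(ai, n_in - ai, ci, n_out - ci)
            for ai, ci in zip(a, c)
        ])
        # log odds sign (0.5 Haldane correction) for the direction vote
        lo = np.log(((a + 0.5) / (n_in - a + 0.5)) / ((c + 0.5) / (n_out - c + 0.5)))
        names = mat.index[keep]
        per_sample[sample] = pd.DataFrame({"p": ps, "log2fc": lo / np.log(2)},
                                          index=names)
        for name, sign in zip(names, np.sign(lo)):
            direction_votes.setdefault(name, []).append(int(sign))

    de_cfg = DEConfig(
        min_cluster_expr_frac=config.min_cluster_access_frac,
        min_cluster_sample_frac=config.min_cluster_sample_frac,
        min_samples_for_combination=config.min_samples_for_combination,
        fdr_threshold=config.fdr_threshold)
    results = combine_across_samples(per_sample, included, de_cfg)
    rows = {}
    for res in results:
        votes = sum(direction_votes.get(res.feature, []))
        direction = "up" if votes > 0 else "down" if votes < 0 else "ambiguous"
        rows[res.feature] = {
            "combined_p": res.combined_p, "fdr": res.fdr,
            "uncombined": res.uncombined,
            "n_samples": len(res.included_samples), "direction": direction,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "peak"
    return frame


def _overlaps(s1, e1, s2, e2) -> bool:
    return s1 < e2 and e1 > s2


def enhancer_concordance(
    da_peaks: pd.DataFrame, enhancer_map: pd.DataFrame,
    deg_genes: set[str], gene_universe: set[str],
) -> tuple[dict[str, int], float]:
    """Overlap between DA-enhancer target genes and differentially expressed genes.

    DA peak intervals are intersected with enhancer records to obtain the
    set of genes whose enhancer is differentially accessible; a two-sided
    Fisher exact test over ``gene_universe`` then asks whether DA-enhancer
    targets are enriched among the DEGs.
    """
    if not gene_universe:
        raise ValueError("empty gene universe")
    da_targets: set[str] = set()
    if len(da_peaks):
        _validate_intervals(da_peaks)
        for _, enh in enhancer_map.iterrows():
            same = da_peaks[da_peaks["chrom"] == enh["chrom"]]
            hit = (same["start"].to_numpy() < enh["end"]) & \
                  (same["end"].to_numpy() > enh["start"])
            if hit.any():
                da_targets.add(enh["gene"])
    da_targets &= gene_universe
    degs = deg_genes & gene_universe
    overlap = len(da_targets & degs)
    counts = {
        "both": overlap,
        "da_only": len(da_targets) - overlap,
        "deg_only": len(degs) - overlap,
        "neither": len(gene_universe) - len(da_targets) - len(degs) + overlap,
    }
    p = fisher_exact_two_sided(
        counts["both"], counts["da_only"], counts["deg_only"], counts["neither"])
    return counts, p


def motif_deviation_test(
    scores_by_sample: Mapping[str, pd.DataFrame],
    labels_by_sample: Mapping[str, pd.Series],
    population: str,
    config: MotifTestConfig = MotifTestConfig(),
) -> pd.DataFrame:
    """Per-TF test of motif deviation-score upregulation in a population.

    One-sided (by default) Mann-Whitney rank-sum per sample on the per-cell
    deviation scores, Fisher combination with the 4% sample-inclusion rule,
    BH FDR, and the display statistic delta_z = mean score in the population
    minus mean in the rest (pooled over included samples). A TF is flagged
    when FDR < ``fdr_threshold`` AND delta_z >= ``delta_z_min``.
    """
    config.validate()
    if not any((labels == population).any()
               for labels in labels_by_sample.values()):
        raise ValueError(f"population {population!r} absent from all samples")
    included = sample_inclusion(
        labels_by_sample, population, config.sample_min_frac)
    per_sample: dict[str, pd.DataFrame] = {}
    pooled_in, pooled_out = [], []
    for sample in sorted(included):
        mat = scores_by_sample[sample]
        labels = labels_by_sample[sample].reindex(mat.columns)
        in_pop = (labels == population).to_numpy()
        x = mat.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                x[:, in_pop], x[:, ~in_pop], axis=1, method="asymptotic",
                use_continuity=False, alternative=config.alternative)
        p = np.clip(np.nan_to_num(res.pvalue, nan=1.0), P_FLOOR, 1.0)
        per_sample[sample] = pd.DataFrame({"p": p}, index=mat.index)
        pooled_in.append(x[:, in_pop])
        pooled_out.append(x[:, ~in_pop])

    de_cfg = DEConfig(min_cluster_sample_frac=config.sample_min_frac,
                      min_samples_for_combination=config.min_samples_for_combination)
    results = combine_across_samples(per_sample, included, de_cfg)
    if pooled_in:
        tfs = next(iter(per_sample.values())).index
        delta_z = pd.Series(
            np.hstack(pooled_in).mean(axis=1) - np.hstack(pooled_out).mean(axis=1),
            index=tfs)
    else:
        delta_z = pd.Series(dtype=float)
    rows = {}
    for res in results:
        dz = float(delta_z.get(res.feature, np.nan))
        rows[res.feature] = {
            "combined_p": res.combined_p, "fdr": res.fdr, "delta_z": dz,
            "flagged": bool(res.fdr < config.fdr_threshold
                            and dz >= config.delta_z_min),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "tf"
    return frame


def joint_emt_screen(
    tf_expression: pd.DataFrame, mlc_abundance: pd.Series,
    motif_fdr: pd.Series,
    correlation_p: float = 0.05, motif_fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Joint screen: TF expression correlated with mesenchymal-like abundance
    AND differentially accessible binding motif.

    Spearman correlation of each TF's bulk expression against the supplied
    per-sample population abundances (abundances come from upstream
    deconvolution and are inputs here). A TF is selected when the
    correlation p-value is below ``correlation_p`` and its motif FDR is
    below ``motif_fdr_threshold``; the correlation sign is reported as a
    direction label, not interpreted.
    """
    shared = [s for s in tf_expression.columns if s in mlc_abundance.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 paired samples for a useful correlation")
    abundance = mlc_abundance[shared].to_numpy(dtype=float)
    rows = {}
    for tf, expr in tf_expression[shared].iterrows():
        r, p = stats.spearmanr(expr.to_numpy(dtype=float), abundance)
        fdr = float(motif_fdr.get(tf, np.nan))
        selected = bool(p < correlation_p and fdr < motif_fdr_threshold)
        rows[tf] = {
            "spearman_r": r, "spearman_p": p, "motif_fdr": fdr,
            "selected": selected,
            "direction": "positive" if r > 0 else "negative" if r < 0 else "zero",
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "tf"
    return frame


def build_tf_network(
    sites: pd.DataFrame, tf_loci: pd.DataFrame,
    window: int = 10_000, p_threshold: float = 0.05,
) -> nx.DiGraph:
    """Directed TF-to-TF network from significant DA binding sites.

    Edge A -> B exists when at least one binding site of A with
    p < ``p_threshold`` overlaps the half-open window
    [B.start - window, B.end + window), clipped at 0. Nodes are all TFs in
    ``tf_loci``; edges carry the supporting sites and their minimum p.

    ``sites`` needs columns tf, chrom, start, end, p.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    _validate_intervals(sites)
    graph = nx.DiGraph()
    graph.add_nodes_from(tf_loci["gene"])
    sig = sites[sites["p"] < p_threshold]
    for _, locus in tf_loci.iterrows():
        win_start = max(0, int(locus["start"]) - window)
        win_end = int(locus["end"]) + window
        same = sig[sig["chrom"] == locus["chrom"]]
        hit = same[(same["start"].to_numpy() < win_end) &
                   (same["end"].to_numpy() > win_start)]
        for tf, grp in hit.groupby("tf"):
            support = list(zip(grp["start"], grp["end"], grp["p"]))
            graph.add_edge(tf, locus["gene"], n_sites=len(support),
                           min_p=float(grp["p"].min()), sites=support)
    return graph
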