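"""Synthetic multi-omic cohorts with planted ground truth.

Generates every input the analysis stages consume: a labeled bulk
expression cohort for signature construction and classification, per-sample
single-nucleus count matrices with cell-population labels, binary
peak-accessibility matrices with BED coordinates, and a genome annotation
(gene loci, enhancer-to-gene map, TF binding sites) carrying a planted
TF-to-TF regulatory network.

Every simulator derives its own random substream deterministically from the
single config seed, so one seed fixes the entire cohort. Planted effects
(group markers, population markers, differentially accessible peaks,
regulatory edges) are recorded in a :class:`GroundTruth` object that
downstream recovery tests compare against.

Model choices: bulk expression is log-normal per gene (heavy-tailed
positive baseline) with additive shifts on the log2 scale for planted group
markers and multiplicative log-normal noise; single-nucleus counts are
gamma-Poisson (negative binomial) with rate multipliers for population
markers; accessibility is Bernoulli per peak-cell with a probability margin
for planted DA peaks. One designated cell population follows a fixed
per-sample abundance schedule that straddles the 3% and 4% sample-inclusion
thresholds, so the inclusion rules are exercised on every cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_bulk_cohort",
    "simulate_sc_cohort",
    "simulate_accessibility",
    "simulate_annotation",
]

# substream tags (mixed with the seed so simulators are independent)
_BULK, _SC, _ATAC, _ANNOT = 11, 22, 33, 44

# per-sample abundance schedule of the first population; cycles so every
# cohort has samples below 3%, between 3% and 4%, and above 4%
_RARE_POP_SCHEDULE = (0.02, 0.035, 0.08, 0.15)


@dataclass(frozen=True)
class SimulationConfig:
    """All dials for the cohort simulators; ``seed`` fully determines output."""

    seed: int = 0
    n_groups: int = 8
    n_genes: int = 2000
    n_samples_per_group: int = 10
    n_planted_markers_per_group: int = 60
    marker_log2fc: float = 3.0
    baseline_dispersion: float = 0.5
    n_cells_per_sample: int = 400
    n_populations: int = 5
    n_peaks: int = 300
    genome_length: int = 10_000_000
    n_tfs: int = 12
    # single-cell / accessibility extras
    n_sc_samples: int = 4
    n_markers_per_population: int = 20
    marker_rate_fold: float = 8.0
    base_rate: float = 0.3
    n_da_peaks_per_population: int = 10
    baseline_accessibility: tuple[float, float] = (0.35, 0.60)
    accessibility_margin: float = 0.35

    def validate(self) -> None:
        positive = [
            "n_groups", "n_genes", "n_samples_per_group",
            "n_planted_markers_per_group", "n_cells_per_sample",
            "n_populations", "n_peaks", "genome_length", "n_tfs",
            "n_sc_samples", "n_markers_per_population",
        ]
        for name in positive:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_markers_per_group * self.n_groups > self.n_genes:
            raise ValueError(
                "n_planted_markers_per_group * n_groups exceeds n_genes")
        if self.n_markers_per_population * self.n_populations > self.n_genes:
            raise ValueError(
                "n_markers_per_population * n_populations exceeds n_genes")
        if self.baseline_dispersion < 0 or self.marker_rate_fold <= 0:
            raise ValueError("dispersion must be >= 0 and rate fold > 0")


@dataclass
class GroundTruth:
    """Planted effects, keyed by the identifiers used in the simulated data."""

    group_markers: dict[str, list[str]] = field(default_factory=dict)
    population_markers: dict[str, list[str]] = field(default_factory=dict)
    da_peaks: dict[str, list[str]] = field(default_factory=dict)
    planted_edges: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        return d


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def _gene_names(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def simulate_bulk_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Labeled bulk expression cohort with group-exclusive planted markers.

    Returns ``(expression, labels, truth)`` where ``expression`` is a
    genes x samples frame of non-negative values, ``labels`` maps sample to
    molecular group, and ``truth.group_markers`` lists each group's planted
    marker genes (disjoint blocks, so markers are group-exclusive).
    """
    config.validate()
    rng = _rng(config, _BULK)
    genes = _gene_names(config.n_genes)
    groups = [f"G{g + 1}" for g in range(config.n_groups)]
    samples = [f"{g}_s{i + 1}" for g in groups
               for i in range(config.n_samples_per_group)]
    labels = pd.Series(
        np.repeat(groups, config.n_samples_per_group), index=samples, name="label")

    # log2 baseline per gene at TPM/microarray scale, where the +1
    # pseudocount used downstream is negligible for expressed genes
    mu = rng.normal(6.0, 2.0, size=config.n_genes)
    log2_expr = np.tile(mu[:, None], (1, len(samples)))

    truth = GroundTruth()
    k = config.n_planted_markers_per_group
    for g_idx, group in enumerate(groups):
        marker_idx = np.arange(g_idx * k, (g_idx + 1) * k)
        cols = np.flatnonzero(labels.to_numpy() == group)
        log2_expr[np.ix_(marker_idx, cols)] += config.marker_log2fc
        truth.group_markers[group] = [genes[i] for i in marker_idx]

    log2_expr += rng.normal(0.0, config.baseline_dispersion, size=log2_expr.shape)
    expression = pd.DataFrame(
        np.exp2(log2_expr), index=genes, columns=samples)
    return expression, labels, truth


def _population_fractions(
    config: SimulationConfig, rng: np.random.Generator, sample_idx: int,
) -> np.ndarray:
    """Per-sample population proportions; population 1 straddles 3%/4%."""
    rare = _RARE_POP_SCHEDULE[sample_idx % len(_RARE_POP_SCHEDULE)]
    rest = rng.dirichlet(np.full(config.n_populations - 1, 5.0))
    return np.concatenate([[rare], rest * (1.0 - rare)])


def _cell_labels(
    config: SimulationConfig, rng: np.random.Generator, sample_idx: int,
    populations: list[str],
) -> pd.Series:
    fracs = _population_fractions(config, rng, sample_idx)
    n = config.n_cells_per_sample
    counts = np.round(fracs * n).astype(int)
    counts[0] = max(1, int(round(fracs[0] * n)))  # rare population never empty
    counts[-1] = max(1, n - counts[:-1].sum())
    counts[counts < 0] = 0
    # trim/pad to exactly n cells using the largest population
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    labels = np.repeat(populations, counts)
    rng.shuffle(labels)
    barcodes = [f"s{sample_idx + 1}_c{i + 1}" for i in range(len(labels))]
    return pd.Series(labels, index=barcodes, name="population")


def simulate_sc_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.Series], GroundTruth]:
    """Per-sample single-nucleus count matrices with planted population markers.

    Counts are gamma-Poisson: gene rates are log-normal, a per-entry gamma
    factor with variance ``baseline_dispersion`` adds overdispersion, and
    planted markers get their rate multiplied by ``marker_rate_fold`` in
    their own population only.
    """
    config.validate()
    if config.n_populations < 2:
        raise ValueError("n_populations must be >= 2")
    rng = _rng(config, _SC)
    genes = _gene_names(config.n_genes)
    populations = [f"P{p + 1}" for p in range(config.n_populations)]

    base_rate = rng.lognormal(np.log(config.base_rate), 1.0, size=config.n_genes)

    truth = GroundTruth()
    k = config.n_markers_per_population
    marker_rows = {}
    for p_idx, pop in enumerate(populations):
        idx = np.arange(p_idx * k, (p_idx + 1) * k)
        marker_rows[pop] = idx
        truth.population_markers[pop] = [genes[i] for i in idx]

    counts_by_sample: dict[str, pd.DataFrame] = {}
    labels_by_sample: dict[str, pd.Series] = {}
    phi = max(config.baseline_dispersion, 1e-6)
    for s in range(config.n_sc_samples):
        sample = f"sample{s + 1}"
        labels = _cell_labels(config, rng, s, populations)
        rate = np.tile(base_rate[:, None], (1, len(labels)))
        for pop, rows in marker_rows.items():
            cols = np.flatnonzero(labels.to_numpy() == pop)
            if cols.size:
                rate[np.ix_(rows, cols)] *= config.marker_rate_fold
        gamma = rng.gamma(1.0 / phi, phi, size=rate.shape)
        counts = rng.poisson(rate * gamma)
        counts_by_sample[sample] = pd.DataFrame(
            counts, index=genes, columns=labels.index)
        labels_by_sample[sample] = labels
    return counts_by_sample, labels_by_sample, truth


def _peak_template(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Reference peak intervals; a few wide outliers exercise the width filter."""
    margin = 6000
    starts = np.sort(rng.integers(
        margin, config.genome_length - margin, size=config.n_peaks))
    widths = rng.integers(200, 501, size=config.n_peaks)
    n_wide = max(1, config.n_peaks // 50)
    wide_idx = rng.choice(config.n_peaks, size=n_wide, replace=False)
    widths[wide_idx] = 5000
    names = [f"peak{i:05d}" for i in range(config.n_peaks)]
    return pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": starts + widths, "name": names})


def simulate_accessibility(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.Series],
           dict[str, pd.DataFrame], GroundTruth]:
    """Binary peak x cell accessibility per sample, with planted DA peaks.

    Returns ``(matrices, labels, peak_beds, truth)``. Peak coordinates are
    jittered per sample (within +/-50 bp) so that cross-sample union/merge
    is exercised; planted DA peaks have their accessible-cell probability
    raised by ``accessibility_margin`` in their target population.
    """
    config.validate()
    rng = _rng(config, _ATAC)
    template = _peak_template(config, rng)
    populations = [f"P{p + 1}" for p in range(config.n_populations)]

    lo, hi = config.baseline_accessibility
    base_prob = rng.uniform(lo, hi, size=config.n_peaks)

    truth = GroundTruth()
    da_rows: dict[str, np.ndarray] = {}
    k = config.n_da_peaks_per_population
    if k * config.n_populations > config.n_peaks:
        raise ValueError("n_da_peaks_per_population * n_populations exceeds n_peaks")
    for p_idx, pop in enumerate(populations):
        rows = np.arange(p_idx * k, (p_idx + 1) * k)
        da_rows[pop] = rows
        truth.da_peaks[pop] = template["name"].iloc[rows].tolist()

    matrices: dict[str, pd.DataFrame] = {}
    labels_by_sample: dict[str, pd.Series] = {}
    beds: dict[str, pd.DataFrame] = {}
    for s in range(config.n_sc_samples):
        sample = f"sample{s + 1}"
        labels = _cell_labels(config, rng, s, populations)
        jitter = rng.integers(-50, 51, size=config.n_peaks)
        bed = template.copy()
        bed["start"] = np.clip(bed["start"] + jitter, 0, config.genome_length - 1)
        bed["end"] = np.clip(bed["end"] + jitter, bed["start"] + 1,
                             config.genome_length)
        beds[sample] = bed

        prob = np.tile(base_prob[:, None], (1, len(labels)))
        for pop, rows in da_rows.items():
            cols = np.flatnonzero(labels.to_numpy() == pop)
            if cols.size:
                prob[np.ix_(rows, cols)] = np.minimum(
                    prob[np.ix_(rows, cols)] + config.accessibility_margin, 0.95)
        acc = (rng.random(prob.shape) < prob).astype(np.int8)
        matrices[sample] = pd.DataFrame(
            acc, index=template["name"].to_numpy(), columns=labels.index)
        labels_by_sample[sample] = labels
    return matrices, labels_by_sample, beds, truth


def simulate_annotation(
    config: SimulationConfig, window: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Gene loci, enhancer map and TF binding sites with a planted TF network.

    For every planted edge (A, B) one binding site of A is placed inside
    the +/-``window`` bp extension of B's gene locus; the site doubles as a
    planted differentially accessible peak and carries a small synthetic
    DA p-value (< 0.05). Decoy sites are placed in the gaps between loci,
    outside every window, with non-significant p-values.

    Returns ``(gene_loci, enhancer_map, motif_sites, truth)`` where
    ``motif_sites`` has columns tf, chrom, start, end, p, planted.
    """
    config.validate()
    rng = _rng(config, _ANNOT)
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]

    spacing = config.genome_length // config.n_tfs
    locus_width = 2000
    if spacing < 6 * window + 2 * locus_width + 1:
        raise ValueError("genome_length too small for non-overlapping TF windows")
    starts = np.array([i * spacing + 2 * window for i in range(config.n_tfs)])
    strands = np.where(np.arange(config.n_tfs) % 2 == 0, "+", "-")
    loci = pd.DataFrame({
        "gene": tfs, "chrom": "chr1", "start": starts,
        "end": starts + locus_width, "strand": strands,
        "tss": np.where(strands == "+", starts, starts + locus_width),
    })

    # planted directed edges (distinct pairs, self-loops excluded)
    edges: list[tuple[str, str]] = []
    while len(edges) < config.n_tfs:
        a, b = rng.integers(0, config.n_tfs, size=2)
        if a != b and (tfs[a], tfs[b]) not in edges:
            edges.append((tfs[a], tfs[b]))
    truth = GroundTruth(planted_edges=edges)

    site_len = 10
    records = []
    for a, b in edges:
        row = loci.loc[loci["gene"] == b].iloc[0]
        lo = row["start"] - window
        hi = row["end"] + window - site_len
        s = int(rng.integers(lo, hi + 1))
        records.append((a, "chr1", s, s + site_len,
                        float(rng.uniform(0.001, 0.04)), True))
    # decoys at gap midpoints, far outside every +/-window extension
    for i in range(config.n_tfs):
        tf = tfs[int(rng.integers(0, config.n_tfs))]
        mid = i * spacing + 2 * window + locus_width + 2 * window + \
            int(rng.integers(0, spacing - 6 * window - 2 * locus_width))
        records.append((tf, "chr1", mid, mid + site_len,
                        float(rng.uniform(0.1, 0.9)), False))
    sites = pd.DataFrame(
        records, columns=["tf", "chrom", "start", "end", "p", "planted"])

    # GeneHancer-style enhancer records: one interval near each TF locus
    enh = pd.DataFrame({
        "chrom": "chr1",
        "start": loci["start"] - 5000,
        "end": loci["start"] - 4000,
        "gene": loci["gene"],
    })
    return loci, enh, sites, truth
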