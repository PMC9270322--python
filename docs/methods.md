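# Methods

This note documents the statistical procedures implemented in
`ependymics`, the modelling assumptions behind the synthetic-data
generator, and the numerical and design choices that were genuinely open.

## Running-sum enrichment classifier

A query profile's genes are ranked by decreasing expression; ties are
broken lexicographically by gene identifier so results are
platform-independent. For a signature of size *n* in a list of length *m*,
the walk gains 1/*n* at signature genes and loses 1/(*m*−*n*) elsewhere;
the telescoping identity guarantees the curve ends at 0, and because the
curve rises only at signature genes its maximum is always attained at a
hit position — the implementation exploits this to score a permutation in
O(*n*) after sampling.

The enrichment score is the **maximum** of the running sum (one-sided,
upregulation). Signatures are built from upregulated genes, so depletion
is not scored; the maximum-deviation variant would change nothing for
enriched signatures and is not exposed.

Significance uses gene randomization: B uniform random *n*-subsets of the
ranked list, with the add-one estimator *p* = (1 + #{ES_b ≥ ES_obs})/(B+1),
which is never 0 and is uniform under the null up to discreteness (the
test suite verifies this with a Kolmogorov–Smirnov check at B = 200).
The default B = 1000 gives a Monte-Carlo standard error of about 0.015
near p ≈ 0.35, enough to resolve the decision thresholds below.

Decision procedure, in order:

1. compute the permutation p-value of every signature (signature genes
   absent from the query are dropped first; the post-intersection size is
   the *n* used in the step sizes);
2. if a dedicated low-power group is configured (PFB in the posterior
   fossa setting) and its p < 0.34, assign it — the carve-out precedes the
   minimum-p rule, reading the threshold as an override for a group whose
   signature is too weak to win the argmin;
3. otherwise assign the minimum-p group if its p ≤ 0.35 (ties: larger ES,
   then lexicographic);
4. otherwise leave the sample UNASSIGNED.

Whether the assignment score should be the raw ES or the normalized ES
was open; raw ES is used, since the decision operates on p-values and the
NES (ES divided by the mean positive permuted ES) is provided separately
as a reporting statistic.

Misclassification counts UNASSIGNED as an error, so the reported error
rate is conservative.

## Signature construction

Per-gene differential expression is a two-sided Welch *t*-test on
log2(x+1) values (pseudocount 1, since TPM/microarray-scale inputs
contain zeros); log2FC is the difference of group means on that scale.
Genes with zero variance in both groups get p = 1 by convention. The
upstream tools' empirical-Bayes variance moderation is deliberately not
reproduced: the classifier consumes only the ranked exclusive gene lists,
and moderation affects borderline genes, not the strong markers that
drive them.

Exclusivity is enforced at the **threshold** level: a gene passing
p < 0.01 and log2FC > 2 in any other group is disqualified, whichever
group it is being built for. (The alternative — exclusivity against other
groups' top-n lists — was considered and rejected as a weaker reading of
"exclusively upregulated".) Built signatures are therefore pairwise
disjoint by construction. If fewer than *n* genes qualify the signature
is returned short with a flag rather than failing, since small cohorts
legitimately yield short signatures; zero qualifying genes raise an
explicit error.

## Multi-sample population-vs-rest framework

The contribution here is the framework — filters, inclusion rules,
combination — not the base test. Per sample, each feature is tested
between the population of interest and all other cells:

- **expression**: genes with count > 0 in fewer than 5% of the
  population's cells are dropped ("expressed" means a nonzero UMI count,
  the only unambiguous reading); the base test is a two-sided
  Mann-Whitney rank-sum on raw counts with tie-corrected asymptotic
  p-values and no continuity correction. A rank-sum base test was chosen
  over an overdispersed-count likelihood-ratio fit because it is exactly
  calibrated under the null at the cell numbers involved, assumption-free
  about the count law, and fast enough to test thousands of genes in
  seconds; the framework's behaviour (filters + combination) is identical
  under either base test. log2FC is computed on library-size-normalized
  per-cell means with a pseudocount of 1.
- **accessibility**: peaks accessible (nonzero) in fewer than 30% of the
  population's cells are dropped; the base test is a two-sided Fisher
  exact test on the 2×2 accessible × in-population table.
- **motif deviation scores**: consumed as input (their computation is an
  established published method); the base test is a one-sided rank-sum
  for upregulation — the reported direction of the screen — with the
  two-sided variant available.

Samples where the population is below 3% (expression) or 4%
(accessibility, motifs) of cells are excluded. Features with per-sample
p-values in ≥ 2 included samples are combined with Fisher's method,
X = −2Σln p ~ χ²(2k); p-values are floored at 1e−300 first so the
statistic stays finite. Features observed in exactly one included sample
are reported with that p-value and flagged uncombined — populations
present in a single sample would otherwise be silently lost. BH FDR is
computed over the whole reported batch; FDR cutoffs (0.1 for reporting,
0.01/0.05 in stricter screens) are parameters, never hard-coded.

The two-sided Fisher exact p is computed directly from the conditional
hypergeometric distribution (sum of support probabilities ≤ the observed
one, with a 1+1e−7 relative guard), via log-gamma, because the scipy
routine's per-call overhead dominates genome-scale peak loops; the test
suite checks it exhaustively against exact rational enumeration for all
tables with N ≤ 40 and against `scipy.stats.fisher_exact` on random
tables.

## Regulatory genomics

All coordinates are 0-based half-open; abutting intervals do not overlap.
Merging is a sweep line per chromosome with a **strict** overlap predicate,
so [10,20) and [20,30) remain separate. The peak-width filter removes
widths above mean + 3 SD (sample SD, ddof = 1) of the input widths.
Gene-activity scores count fragments with nonzero overlap of the union of
the gene body and the 2 kb promoter upstream of the TSS — strand-aware,
and unstranded genes are rejected rather than silently defaulted; a
fragment spanning both body and promoter counts once.

The TF network adds a directed edge A→B when at least one binding site of
A with p < 0.05 (raw, as the screen defines significance; an FDR variant
is a parameter) overlaps the half-open window
[B.start − 10000, B.end + 10000), clipped at 0. The ±10 kbp window is
anchored on the **gene body**, not the TSS — "gene locus" extended both
ways — which was the more natural reading of the rule; self-loops are
permitted and edges carry their supporting sites and minimum p.

DA direction (up/down) is the majority sign of the per-sample log odds
(Haldane 0.5 correction); a tie is flagged ambiguous rather than forced.

## Synthetic-data generator

One integer seed fixes the entire cohort; each simulator draws from its
own deterministically derived substream, so e.g. regenerating only the
annotation reproduces it bit-for-bit.

- **Bulk expression**: per-gene log2 baselines ~ N(6, 2) — a heavy-tailed
  positive expression scale on which the +1 pseudocount used downstream is
  negligible for expressed genes — with additive shifts of
  `marker_log2fc` (default 3) for each group's planted marker block and
  multiplicative log-normal noise (σ = 0.5 in log2 units). Marker blocks
  are disjoint, so planted markers are group-exclusive by construction.
  Defaults: 8 groups × 10 samples, 2000 genes, 60 planted markers per
  group (enough to fill 50-gene signatures).
- **Single-nucleus counts**: gamma-Poisson (negative binomial) counts with
  log-normal gene rates around 0.3 counts/cell; population markers get an
  8-fold rate multiplier in their own population. Four samples of 400
  cells by default.
- **Accessibility**: Bernoulli peak × cell entries with per-peak baseline
  probabilities uniform on [0.35, 0.60] — deliberately high enough that
  typical peaks pass the 30% in-population filter, mirroring the fact
  that the filter restricts real analyses to well-covered peaks — and a
  +0.35 probability margin (capped at 0.95) for planted DA peaks. Peak
  coordinates are jittered ±50 bp per sample so cross-sample merging is
  exercised; ~2% of peaks are 5 kb outliers so the width filter has work.
- **Population abundances**: the first population follows a fixed
  per-sample schedule (2%, 3.5%, 8%, 15%, cycling) so the 3% and 4%
  inclusion thresholds are straddled on every cohort; the remaining mass
  is Dirichlet-split (concentration 5) among the other populations. The
  schedule is deterministic where the Dirichlet draw alone could not
  guarantee the straddle.
- **Annotation**: TF gene loci (2 kb, alternating strands) spaced ~800 kb
  apart so their ±10 kb windows never overlap; for each planted edge
  (A, B), one 10 bp binding site of A is placed uniformly inside B's
  window and doubles as a planted DA site carrying a synthetic p-value
  < 0.05; decoy sites are placed in the gaps, provably outside every
  window, with p-values ≥ 0.1. The synthetic per-site p-values stand in
  for the upstream differential-accessibility overlay so the network
  builder can be tested in isolation.

What the generator does **not** emulate: sequencing-read noise, doublets,
batch effects, fragment-level ATAC structure, correlated gene programs,
or realistic gene-length/GC biases. Passing recovery tests therefore
demonstrates the correctness of the statistics and decision rules under
their own assumptions, not robustness to the artefacts of real droplet
data.

## Problem sizes and numerics

The shipped tests and the acceptance script run the classifier benchmark
at 8 groups × 10 samples with 2000 genes and 500 permutations, the
permutation-calibration check at 500 draws × 200 permutations, and the
type-I checks at ≥ 2000 null features with 1000 cells per sample — a
down-scaled version of the study design (which averaged ~2660 nuclei per
sample), chosen so the whole suite completes in well under a minute while
keeping the exact test's discreteness negligible. Degenerate inputs are
handled explicitly: zero-variance genes (p = 1), empty signatures
(error), populations absent from a sample (a distinct error from filter
exclusion), p = 0 into Fisher's method (error; callers floor at 1e−300),
windows clipped at coordinate 0.

## Known limitations

- The rank-sum base test ignores library-size differences between cells;
  with strongly varying depth between populations it can pick up depth
  rather than expression (the log2FC column is depth-normalized and can
  be used to screen such calls).
- Fisher's method assumes independent per-sample p-values; shared
  upstream processing across samples violates this mildly in real data.
- The classifier's permutation null randomizes genes, not phenotypes, so
  correlated gene sets inflate significance exactly as in standard
  gene-randomization GSEA.
- `gene_activity` is a plain interval-overlap counter intended for
  peak/fragment tables that fit in memory, not a scalable fragment-file
  processor.
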