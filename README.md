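# ependymics

Reusable implementations of the bespoke statistical procedures used in
single-nucleus multi-omic studies of posterior fossa ependymoma — and of
similar tumor cohorts where bulk expression, single-nucleus RNA and
single-nucleus ATAC data are analysed jointly:

- **Gene-signature molecular-group classification.** A query expression
  profile is ranked by decreasing expression into a list *L* of *m* genes.
  For a signature *s* of *n* group-exclusive upregulated genes, a running
  sum is walked down *L*: it rises by 1/*n* at each signature gene and
  falls by 1/(*m*−*n*) otherwise, so the curve ends exactly at 0; its
  maximum is the enrichment score (ES). Significance comes from gene
  randomization (uniform random *n*-subsets of *L*), with the add-one
  estimator *p* = (1 + #{ES<sub>b</sub> ≥ ES<sub>obs</sub>})/(B + 1).
  If every signature's *p* exceeds 0.35 the sample is left unassigned; a
  designated low-power group (PFB) is assigned whenever its own *p* falls
  below 0.34.
- **Signature construction.** Per-group differential expression on
  log2(x+1) values (two-sided Welch test); a group's signature is the top
  *n* = 50 genes (ascending *p*) passing *p* < 0.01 and log2FC > 2 in that
  group and in no other group.
- **Multi-sample population-vs-rest testing.** Within each sample, each
  cell population is tested against all other cells (genes expressed in
  < 5% of the population's cells are dropped); samples where the
  population is below 3% (expression) or 4% (accessibility, motifs) are
  excluded; per-sample p-values are combined with Fisher's method
  (−2Σln p ~ χ²(2k)) for features seen in ≥ 2 included samples, then
  BH-adjusted.
- **Regulatory genomics.** Union peak sets by merging intersecting
  half-open intervals; peak-width outlier removal at mean + 3 SD;
  gene-activity scores over gene body + strand-aware 2 kb promoter;
  per-sample Fisher exact differential accessibility with a 30%
  in-population accessibility filter; enhancer/DEG concordance; rank-sum
  tests on per-cell TF motif deviation scores with a Δz ≥ 1 display
  filter; a joint Spearman-correlation + motif screen; and a directed
  TF→TF network with an edge A→B whenever a significant (*p* < 0.05)
  differentially accessible binding site of A lies within ±10 kbp of B's
  gene locus.
- **Synthetic cohorts.** `ependymics.simulate` generates every input with
  planted ground truth (group markers, population markers, DA peaks,
  TF→TF edges), so the full pipeline is testable without controlled-access
  data.

## Worked example

```python
from ependymics.simulate import SimulationConfig, simulate_bulk_cohort
from ependymics.signatures import build_all_signatures
from ependymics.classifier import ClassifierConfig, classify, evaluate_classifier

cfg = SimulationConfig(seed=1, n_groups=8, n_genes=2000,
                       n_samples_per_group=10, n_planted_markers_per_group=60,
                       marker_log2fc=3.0)
expr, labels, truth = simulate_bulk_cohort(cfg)
sigs = build_all_signatures(expr, labels)          # eight 50-gene signatures
ccfg = ClassifierConfig(n_perm=500, seed=7)
preds = [classify(expr[s], list(sigs.values()), ccfg).assigned_group
         for s in expr.columns]
error, confusion = evaluate_classifier(preds, labels.tolist())
print(f"classification error: {error:.1%}")
```

prints

```
classification error: 0.0%
```

i.e. on an 8-group synthetic cohort with 3-log2-unit planted markers, the
signature classifier recovers every sample's molecular group (80/80); the
unassignment rule fires only when no signature is enriched. The same
pattern works from the shell:

```bash
ependymics simulate --outdir cohort/
ependymics build-signatures --expr cohort/bulk_expression.tsv \
    --labels cohort/bulk_labels.tsv --out sigs.gmt
ependymics classify --expr cohort/bulk_expression.tsv \
    --signatures sigs.gmt --n-perm 500 --seed 7 --out calls.tsv
```

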