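# prediagtx

Analysis of paired blood transcriptomes sampled **years before a lung-cancer
diagnosis**. The package implements, as a tested and reusable pipeline, the
statistics used to ask whether matched case–control expression differences
in prospective cohort blood samples carry signal, and whether that signal
depends on the time remaining until the case's diagnosis:

- **Preprocessing** of bead-array probe intensities: negative-control
  detection filtering, background correction, quantile normalization, log2
  transform and probe→gene collapsing.
- **Comprehensive smoking index (CSI)**: the exposure scalar
  `(1 − 0.5^(dur*/τ)) · 0.5^(tsc*/τ) · ln(int + 1)` with
  `tsc* = max(tsc − δ, 0)` and `dur* = max(dur + tsc − δ, 0) − tsc*`, where
  `dur` is years smoked, `int` cigarettes/day and `tsc` years since
  cessation; half-life τ and lag δ are estimated by a profile grid search
  on a logistic likelihood of case status.
- **Immune-cell deconvolution** of bulk expression against a signature
  matrix (nonnegative least squares, fractions normalized to 1), the
  neutrophil-to-lymphocyte ratio (NLR), nonparametric case–control and
  smoking-group tests, and spline trend tests of fractions over time.
- **Curve groups**: genes whose three-window mean profile of
  case-minus-control differences exceeds its own sign-flip permutation
  null are sorted into the six orderings of the windows ('123' … '231';
  '123' = difference largest nearest diagnosis); per-group occupancy is
  tested against the permutation null.
- **Local-in-time statistics (LITS)**: sliding windows of 30 pairs
  consecutive in time-to-diagnosis; per window the mean squared one-sample
  t over genes, with raw and family-wise (max-statistic) sign-flip
  permutation p-values.
- **Gene-wise moderated tests**: empirical-Bayes variance shrinkage
  (limma-style moment matching of d₀ and s₀² on log sample variances) for
  paired t-tests and natural-spline (3 df) moderated F trend tests,
  Benjamini–Hochberg FDR, cumulative-by-year analyses and Top-N overlaps.
- **Overrepresentation analysis** of gene lists against GMT gene-set
  collections (upper-tail hypergeometric, BH-adjusted, gene ratios).

Because the motivating cohort data are not publicly deposited, the package
ships a first-class **synthetic-cohort generator** that reproduces the
study's structure — 128 matched pairs (100 metastatic), sampling times
spanning ~0.2–7.2 years before diagnosis, cell-composition-driven
expression with a neutrophil shift in cases, planted time-trend genes,
negative-control probes, and smoking covariates whose link to case status
runs through the CSI — so every stage is testable end to end.

## Worked example

```python
import prediagtx as px

cfg = px.SyntheticConfig(n_pairs=128, n_genes=1000, seed=42, exact_counts=True,
                         planted_trends=(("123", 60, 0.5),))
raw, meta, signature, truth = px.generate_cohort(cfg)
expr = px.run_preprocess(raw)                      # genes x samples, log2
D, pairs = px.make_differences(expr, meta)         # genes x pairs
meta_ids = px.subset_pairs(pairs, "metastatic")
res = px.CurveGroupModel(D[meta_ids], pairs.loc[meta_ids, "days_to_diagnosis"]).fit(
    n_permutations=999, seed=1)
print(res.summary())
```

```
Curve-group time-trend test (sign-flip permutation null)
windows (pairs): [37, 33, 30]   alpha0 = 0.2   B = 999   seed = 1

             observed  expected  p_overall  p_period1  p_period2  p_period3
curve_group
123              78.0   33.2032      0.001      0.001      0.001      1.000
132              26.0   32.5956      0.844      0.038      0.032      0.013
312              44.0   33.6066      0.070      0.623      0.391      0.839
321              67.0   33.5546      0.001      0.018      0.432      0.765
213              33.0   33.7437      0.557      0.215      0.948      0.041
231              33.0   32.4955      0.470      0.157      0.744      0.878
global          281.0  199.1992      0.002        NaN        NaN        NaN
```

The 60 genes planted with a '123' trajectory (case–control difference
growing toward diagnosis) drive the '123' group far above its permutation
expectation (78 observed vs ~33 expected, p = 0.001), with the period-1
(nearest-diagnosis) magnitude carrying the signal. The mirror-image '321'
excess arises from quantile normalization redistributing the planted shift
across the remaining genes — a coupling worth remembering when reading
real-data curve-group tables. The global row counts all designated genes.

The same differences feed the sliding-window test:

```python
lits = px.LITSModel(D[meta_ids], pairs.loc[meta_ids, "days_to_diagnosis"], k=30).fit(
    n_permutations=999, seed=1)
print(lits.summary())
```

```
Local-in-time statistics (sliding-window sign-flip test)
71 windows of 30 pairs   statistic = mean_t2   B = 999   seed = 1
minimum adjusted p: 0.0010
best window: #1 days [133, 907] p_raw = 0.0010
```

100 metastatic pairs in windows of 30 give the expected 71 overlapping
periods, and the planted near-diagnosis signal pulls the minimum p-value
into the earliest window.

A command-line interface mirrors the stages
(`prediagtx simulate | preprocess | csi | deconv | curvegroups | lits |
genewise | enrich | run-all`); `run-all` executes the whole DAG from one
YAML config and writes seed-stamped TSV tables.

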