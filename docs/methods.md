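# Methods

## Setting and data model

The package analyses a nested matched case–control design: for each cancer
case a cancer-free control matched on birth year and assay batch, with
whole-blood expression measured once, `t` days before the case's
diagnosis. The unit of every time-to-diagnosis analysis is the **pair
difference** `d_gp = (case log2 expression) − (control log2 expression)`
for gene `g` and pair `p`. Under the null hypothesis of no case–control
difference the two members of a pair are exchangeable, so `d_gp` is
symmetric about zero and multiplying any pair's differences by −1 leaves
the joint distribution invariant. All permutation tests exploit exactly
this: one ±1 flip per pair, shared across genes (and windows), which
preserves the inter-gene correlation structure of the data.

The design is prospective but **not longitudinal**: each pair contributes
one time point, and "trajectories" are trends across pairs sampled at
different times to diagnosis. Everything the methods detect is therefore a
between-pair trend, as in the motivating study.

## Preprocessing

1. **Detection filter.** A probe is detected in a sample when its
   intensity exceeds the 0.95 quantile of that array's negative controls
   (the analogue of a detection-p < 0.05 call). Probes detected in fewer
   than 10% of samples (boundary inclusive), lacking a gene annotation, or
   quality-flagged are removed. Detection calls are invariant to per-array
   monotone shifts, so running the filter before background correction is
   equivalent to running it after.
2. **Background correction.** Per array, the median negative-control
   intensity is subtracted and the result floored at `offset` (default 1).
   This deliberately replaces a maximum-likelihood convolution model
   (normexp): the downstream statistics only need positive, monotonically
   transformed intensities, and the median-subtract-and-floor rule is
   exact to test.
3. **Quantile normalization.** Every column is mapped onto the mean of the
   order statistics across columns; ties within a column receive the mean
   of the reference values at their tied ranks, so a constant column maps
   to the grand reference mean. The operation is idempotent.
4. **log2 and collapse.** Probes mapping to the same gene are collapsed by
   keeping the probe with the highest mean intensity (`max_mean`); the
   collapse rule is configurable in name but only this rule is
   implemented, since nothing downstream depends on the choice.

Note one systemic coupling: quantile normalization redistributes a planted
(or real) one-sided shift in a subset of genes across the remaining genes
with opposite sign. Synthetic experiments show this as a mirror-image
curve-group excess ('321' accompanying a planted '123'); the same caution
applies to real data.

## Comprehensive smoking index

`CSI = (1 − 0.5^(dur*/τ)) · 0.5^(tsc*/τ) · ln(int + 1)` with
`tsc* = max(tsc − δ, 0)` and `dur* = max(dur + tsc − δ, 0) − tsc*`
(the inner `max` is read with a zero floor; without it the expression is
ill-formed). τ > 0 (years) is a half-life governing both accumulation with
duration and decay after cessation; δ ≥ 0 (years) is a lag during which
recent abstinence does not yet count. Two properties matter for testing:
the index is bounded by `ln(int + 1)` and is nondecreasing in duration and
intensity, but it is **only nonincreasing in time since cessation once
tsc ≥ δ** — below the lag, increasing tsc trades into effective duration
and can raise the index. That is a property of the published formula, not
a bug, and the property tests respect it.

The study this package reproduces does not report its fitted (τ, δ) or its
estimation criterion. We fix the criterion as a profile grid search
maximizing the log-likelihood of a logistic regression of case status on
the index (the standard approach for this index family), with ties broken
toward the smallest τ then smallest δ. Complete separation degrades to a
warning, not an error. The synthetic generator links case status to the
index through a conditional-logistic role assignment within pairs at
(τ = 2, δ = 1, β = 1.5 by default); recovery tests fit the marginal
logistic model to 2000 pairs and demand the maximizing grid point lie
within one grid step (per coordinate) of the truth — the slight
misspecification between the conditional generative model and the marginal
fit leaves the likelihood surface shallow along a (τ, δ) trade-off ridge,
which is why adjacent-cell recovery, not exact recovery, is the honest
criterion.

## Deconvolution and NLR

Bulk linear-scale expression over the marker genes shared with a signature
matrix is modelled as a nonnegative mixture of cell-type reference
profiles; coefficients are estimated per sample by nonnegative least
squares and normalized to sum to one. This is a deterministic,
dependency-light stand-in for ν-support-vector-regression deconvolution;
its acceptance surface is recovery on synthetic mixtures (per-type RMSE
< 0.05 at 5% multiplicative noise with 200 markers and 6 types), not
agreement with any particular external tool.

Populations with mean relative fraction strictly > 5% enter the group
comparisons; fractions are not renormalized after filtering. The NLR is
computed on the **unfiltered** table as neutrophil fraction over the sum
of lymphocyte fractions (default: all T-, B-, NK- and plasma-cell types;
configurable, since the membership used in the original supplementary
material is not available); a zero lymphocyte sum yields a missing value
with a warning. Case–control comparisons use the paired Wilcoxon
signed-rank test (zero differences dropped; all-zero vectors report p = 1
by convention); smoking-status comparisons pool all samples in a
Kruskal–Wallis test; nonlinear trends of fractions over years to diagnosis
in cases use an ordinary F-test of a natural-spline basis (3 df).

## Curve groups

Time to diagnosis is cut at 1093 and 1783 days into three windows of
near-equal occupancy (window 1 nearest diagnosis; boundary days go to the
upper window). Per gene, the between-window sum of squares
`T_g = Σ_w n_w (m_gw − m̄_g)²` measures how much the window means deviate
from the pooled mean. A gene is **designated** when `T_g` exceeds the
(1 − α₀) quantile (order statistic, "higher" rule) of its own sign-flip
null; α₀ defaults to 0.2. Designated genes are labelled by the descending
order of their window means (ties to the lower period, making the
labelling total and deterministic). The original designation statistic is
published only in an earlier methods paper that is not part of this
package's sources; `T_g` with a permutation quantile is our surrogate, so
published designation *rates* are not comparable, while the occupancy
*test* logic is.

Each of the B permutations (default 999) reuses one shared flip vector and
recomputes designation, labels and counts; expected counts are permutation
means, and all p-values use the add-one estimator
`(1 + #{null ≥ observed}) / (B + 1)`, which is never zero and is exact
under exchangeability. Per-period p-values compare the mean |window mean|
of the designated genes in a group against the same quantity recomputed in
each permutation (magnitude rather than a signed contrast — the choice is
flagged as ours). Sum identities (label counts add to the global count,
for observed and expected alike) hold exactly because the same
permutations are reused throughout.

## Local-in-time statistics

Pairs sorted by days to diagnosis (ties by pair id) are grouped into all
`n − k + 1` overlapping windows of `k` consecutive pairs (k = 30; with the
study's 100 metastatic pairs this gives the 71 windows the design
predicts). Per window the statistic is the mean over genes of the squared
one-sample t of the k differences (zero-variance genes contribute 0);
`max |t|` is available as an alternative. The mean-t² choice — again a
surrogate for an unpublished original — is sensitive to many small
coordinated shifts and is scale-free per gene. Raw p-values are add-one
tail probabilities per window; the family-wise adjusted p-value compares
each window's statistic against the permutation distribution of the
max-over-windows statistic, which is valid because the same flips are
reused across windows, and guarantees `p_adjusted ≥ p_raw`.

## Gene-wise moderated tests

Per gene a linear model is fitted to the pair differences by QR
factorization (shared design across genes). Residual variances are shrunk
by empirical Bayes: with residual df `d`,
`e_g = log s_g² − ψ(d/2) + log(d/2)` has moments
`E[e] = log s₀² + ψ(d₀/2) − log(d₀/2)` and
`Var[e] = ψ′(d/2) + ψ′(d₀/2)` under a scaled-F marginal, so d₀ follows by
inverting the trigamma function (Brent bracketing on [1e−8, 1e8]) and s₀²
from the mean; a non-positive variance excess yields d₀ = ∞ (complete
pooling). The posterior variance is `(d₀ s₀² + d s²)/(d₀ + d)` and
moderated statistics gain d₀ degrees of freedom; the infinite-df limits
use the normal and χ² distributions explicitly. The implementation matches
both a scalar step-by-step recomputation (to 1e−10) and the reference R
implementation of the same shrinkage on a shared fixture (to 1e−8).

The paired test reports the intercept (mean pair difference), optionally
adjusting for the pair's case-minus-control smoking-index difference — our
coding of a covariate whose original parameterization is unstated; a
constant covariate is dropped with a warning. The spline trend test
regresses differences on an intercept plus a natural cubic spline basis of
days (3 df; boundary knots at min/max, interior knots at terciles; the
truncated-power construction is standardized onto [0, 1] internally purely
for conditioning) and forms a moderated F on the spline coefficients
jointly, so a pure offset is absorbed by the intercept and only time
*shape* is tested; testing spline terms only (not the full model) is our
reading of the underspecified original. Duplicate days that collapse the
basis reduce the tested df with a warning; constant genes report p = 1.

BH step-up q-values are used throughout. The cumulative-by-year table
reruns the paired test on pairs accumulated up to each whole year
(cutoff y·365.25 days), marking slices with fewer than 3 pairs as not run.
Top-N lists are ordered by raw p with gene-id tie-breaks; the "< 3 years"
subgroup cutoff is 1095.75 days (configurable — the original windows only
approximately align with whole years).

## Overrepresentation

Upper-tail hypergeometric tests of a gene list against GMT collections,
with sets intersected with the analysis universe (the genes surviving
preprocessing — not the whole genome) before testing; BH across sets;
gene ratio k/n for dot plots. The closed-form tail is verified against
exhaustive subset enumeration for small universes. Live ontology retrieval
is out of scope; GMT files are the only interface.

## Synthetic cohort generator

The generator emulates the study conditions: 128 pairs with a 100/128
metastatic fraction (binomial by default, exact with `exact_counts`),
days to diagnosis uniform on 75–2630 (the design table's year bins are
roughly flat), per-sample cell fractions from a Dirichlet (concentration
150) around a realistic blood composition with the case neutrophil mean
shifted by +0.02 and recentred, expression built as
(reference profiles × fractions) on the linear scale with marker blocks
(8× specificity) forming the signature matrix, planted case-only trend
effects added on the log2 scale as piecewise-linear curves through the
three window centers ordered by the requested curve label (maximum effect
0.5 log2 — the study calls its signals "subtle" without quantifying them,
so this default is a choice), log2-normal noise (σ = 0.3), negative-control
probes carrying background only (mean 80), a handful of unannotated and
quality-flagged probes, and a per-array scale factor that quantile
normalization removes. Smoking histories are drawn per member and the case
role assigned by a conditional logistic draw on the true smoking index.

What the generator does **not** emulate: bead-level noise, probe
cross-hybridization, batch structure beyond a scalar array factor,
histology subtypes, or realistic gene–gene correlation beyond what the
shared cell-composition mixture induces. Passing calibration and power
tests on these cohorts therefore validates the statistical machinery — the
exchangeability logic, the permutation estimators, the shrinkage closed
forms — not the biological sensitivity of the pipeline on real arrays.

## Problem sizes and numerical conventions

Calibration experiments use 200 replicates (100 in the acceptance script)
of 500-gene, 100-pair null cohorts at B = 199 permutations; power
experiments use 50 (script: 25) planted cohorts; these sizes put
binomial/Monte-Carlo error well below the margins being asserted while
keeping a full run in minutes on one CPU. Add-one p-values live in
[1/(B+1), 1]. Degenerate inputs follow explicit conventions: all-zero
difference matrices give p = 1 everywhere; zero-variance genes contribute
0 to LITS statistics; empty curve-group cells give per-period p = 1.
Everything stochastic is driven by explicit integer seeds, and results are
bit-reproducible for a fixed seed.

## Known limitations

- The designation statistic (curve groups) and window statistic (LITS) are
  surrogates for unpublished originals; published gene counts and
  designation rates from the motivating study are not reproducible targets.
- The deconvolution stand-in shares the contract but not the estimator of
  ν-SVR-based tools; absolute-scale deconvolution and empirical
  deconvolution p-values are out of scope.
- The marginal logistic criterion for (τ, δ) is shallow along a trade-off
  ridge; grid-step, not point, recovery is the supported guarantee.
- Quantile normalization couples genes; strong one-sided signals bleed
  into mirror-image trends (see Preprocessing).
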