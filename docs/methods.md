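# Methods

This note records the statistical models implemented in `crticc`, the
choices made where the published record was ambiguous, and what the test
suite's synthetic experiments do and do not demonstrate.

## The data and their two representations

The package analyses two-arm cluster randomized trial (CRT) data — here a
trial randomizing 14 community hospitals (7 care-pathway, CP; 7 usual-care,
UC; 429 heart-failure patients in clusters of 30–32) — in either of two
forms:

* individual-level long format (`CRTDataset`): one row per patient with
  cluster id, arm and outcome columns;
* per-cluster sufficient statistics (`ClusterSummarySet`): `(n, mean, SD)`
  for continuous outcomes, `(n, events)` for binary, per-category counts
  for ordinal.

All estimators consume summaries. Fitting from individual data is *defined*
as summarize-then-fit, so the two routes are bit-identical by construction;
the test suite additionally checks agreement with an independent pandas
aggregation to float precision. This design makes published summary tables
first-class inputs: the trial's own tables ship as packaged CSVs
(`crticc/tables/`), transcribed as printed, including their defects (see
"Fixture caveats").

## Continuous and ordinal outcomes: one-way ANOVA ICC

Model: y_ij = μ + b_i + e_ij with b_i ~ N(0, σ²_b), e_ij ~ N(0, σ²_w);
ICC ρ = σ²_b/(σ²_b+σ²_w). The moment (Donner–Klar) estimator uses
MSB = Σnᵢ(ȳᵢ−ȳ)²/(k−1), MSW = Σ(nᵢ−1)sᵢ²/(N−k) and the adjusted average
cluster size m₀ = (N − Σnᵢ²/N)/(k−1), giving σ̂²_b = (MSB−MSW)/m₀ and
σ̂²_w = MSW. The raw estimate can be negative; the reported point estimate
is truncated at zero (negative ICCs must not enter sample-size
calculations). Data with zero variance everywhere raise a distinct
degeneracy error rather than returning 0 or 1.

The 95% CI is the Wald interval ρ̂ ± 1.96·SE with the Swiger large-sample
variance

    Var(ρ̂) = 2(N−1)(1−ρ)² [1+(m₀−1)ρ]² / [m₀²(N−k)(k−1)],

clipped to [0, 1], with m₀ substituting for the common cluster size under
unbalance. Two numerical conventions, fixed here once: the SE is evaluated
at the *truncated* estimate (so published-style CIs never extend below 0),
and clipping happens after the ± construction. The Swiger variance is an
approximation: averaged over replicate simulated trials it tracks a
jackknife-over-clusters SE to within a few percent (measured ≈3% at k=50),
but on any single dataset a jackknife SE carries ~10% Monte-Carlo noise of
its own, so single-dataset agreement should not be over-read. Coverage of
the interval at the trial-relevant design (k=50, m=30, ρ=0.05) measures
≈0.93 in the suite's 500-replicate experiment; at ρ=0 the truncated
interval over-covers (≥0.95), which is the conservative direction for
planning.

Ordinal outcomes (NYHA class II–IV) are scored on their integer category
codes (2, 3, 4) and passed through the same estimator. This is the
convention that reproduces the published NYHA ICCs; it treats adjacent
classes as equidistant.

## Binary outcomes: latent-scale logit-normal model

Model: y_i | b_i ~ Binomial(n_i, logit⁻¹(β₀+b_i)), b_i ~ N(0, σ²_b). The
marginal likelihood is integrated by Gauss–Hermite quadrature (default 50
nodes; estimates on study-sized data change by <1e-6 between 50 and 200
nodes) and maximized by bounded L-BFGS-B from three σ starts
(0.01, 0.5, 1.5) around the pooled log-odds, with an explicit profile of
the σ_b = 0 boundary so boundary solutions are exact rather than
numerically small. The ICC is defined on the latent logistic scale,
ρ = σ²_b/(σ²_b+π²/3); since σ_b ≥ 0 is enforced, no separate truncation is
needed.

Confidence intervals use a nonparametric cluster bootstrap (default 500
replicates): resample k clusters with replacement, refit, take the 2.5/97.5
percentiles. Replicates whose resample is fully degenerate contribute ICC 0
(the boundary fit). A parametric scheme (redrawing event counts from the
fitted model) is available behind a flag. Runs are reproducible from the
seed; more than 20% non-converged refits raises an error rather than
silently narrowing the interval.

Boundary behaviour worth knowing: at small true ICC and very few clusters
most fits land on σ̂_b = 0 and their percentile intervals collapse toward
[0, ε]. One consequence is that average CI width does *not* decrease
monotonically in k near the boundary (measured: k=7 intervals are
*narrower* than k=28 at true ρ=0.05); away from the boundary (ρ=0.2) the
expected ordering holds. Coverage of the percentile interval at the
trial's own size (k=14, m=30, ρ=0.05) is well below nominal — ≈0.8 in the
suite's seeded scaled-down experiment — as expected for a percentile
bootstrap with only 14 clusters; the suite documents that undercoverage
with a frozen band rather than pretending 95%. Intervals from designs with
few clusters should be read as rough precision indicators, not calibrated
95% statements.

`icc_anova_binary` applies the ANOVA moment estimator to the 0/1
indicators. It serves two roles: an independent cross-check of the GLMM
(at small σ_b the two agree to ≈0.002 on average in the suite's
simulations), and the estimator that in fact reproduces the published
binary ICCs (next section).

## Reproducing the published tables

`reproduce_tables()` recomputes every printed ICC cell from the fixture
tables and pairs it with its printed value, with per-route tolerances
declared once:

| route | tolerance | noise sources |
|---|---|---|
| ANOVA from printed (n, mean, SD) | ±0.005 | rounding of printed summaries |
| ordinal (counts from percentages) | ±0.01 | + count reconstruction |
| ordinal with inferred denominators | ±0.05 | + unprinted denominators |
| binary | ±0.02 | + under-specified published method |

Binary route: the published methods text names the logit-normal model, but
the printed point estimates coincide to printed precision with the
indicator-ANOVA estimator in every unambiguous cell (e.g. appropriateness
of stay: UC 0.203, CP 0.069 — the latent MLEs are 0.194 and 0.115), and a
500-replicate cluster bootstrap of that estimator reproduces the printed
CIs to a few thousandths for readmission. The reproduction pipeline
therefore pairs printed binary values with the indicator-ANOVA estimate
(plus its cluster-bootstrap CI) and reports the latent-scale estimate in a
separate column. For fresh analyses the latent model remains the
recommended estimator: its ICC has a clean model-based definition and is
the quantity the synthetic generator controls exactly.

Counts are reconstructed from printed percentages by nearest-integer
rounding (ties to even) with a deterministic largest-remainder repair when
an exhaustive partition must sum to its denominator; reconstruction is
exact whenever the percentages came from integer counts, which the
exhaustive small-case property test confirms.

Median/IQR summaries of the printed ICC lists use the Weibull plotting
position (quantile p at position p·(n+1), linear interpolation, clamped) —
the one standard convention that reproduces all three printed triples —
evaluated in exact rational arithmetic with half-up presentation rounding,
because one printed quartile (0.0645 → 0.065) sits exactly on a rounding
boundary that binary floats resolve the wrong way.

Design effects are DE = 1+(m−1)ρ with ρ ∈ [0,1] enforced (truncation
upstream) and m ≥ 1 (m = 1 degenerates to an unclustered design, DE = 1).
Sample-size inflation is ceil(n·DE) with a 1-ulp guard so that products
that are integers up to binary rounding are not pushed up a whole subject.

### Fixture caveats

* The first CP cluster's baseline row is incomplete in the source (only its
  NYHA percentages are printed; its size, 30, follows from the arm total).
  Baseline age — a continuous variable needing the unprinted mean/SD — is
  therefore declared **not reproducible**, as is the admission-source ICC
  (no per-cluster column is printed at all). Hypertension and
  co-morbidities are reproduced from the 13 printed clusters and flagged
  as partial; both land within the binary tolerance.
* NYHA-at-discharge denominators are unprinted and smaller than the
  admitted n (deaths were not graded). Each cluster's denominator is
  inferred as the integer in [n − deaths − 3, n] minimizing the total
  rounding residual of its percentage triple (ties to the larger value);
  this reconstruction is approximate, hence the widened ±0.05 tolerance
  for that one variable.
* The source text states a mean age of 81.66 where its table's total row
  prints 80.66; the fixtures carry the table values and the discrepancy is
  recorded, not resolved.
* Sample SDs (n−1 denominator) are assumed throughout, the standard
  convention for "mean (SD)" clinical reporting.
* The source names hypertension among the two highest baseline ICCs in one
  place and disease severity in another; the pipeline reproduces both
  values and does not adjudicate the ranking sentence.

## Synthetic-data generator

`simulate()` draws CRT data from random-intercept models in which the
target ICC is exact by construction: normal (σ²_b = ρ·scale²,
σ²_w = (1−ρ)·scale²), binary logit (σ²_b = ρ·(π²/3)/(1−ρ) on the latent
scale, with the conditional intercept solved numerically so the *marginal*
event rate matches the requested value — a Gaussian intercept attenuates
marginal rates), and ordinal latent-logistic (a latent b_i + logistic
residual cut at thresholds solved to match requested marginal category
probabilities). The latent-scale construction for binary/ordinal makes
parameter recovery well-posed: the generator's ρ is exactly the quantity
the latent estimator targets.

`simulate_study_like()` instantiates the trial's design — 7+7 clusters,
sizes drawn from {30, 31, 32} and nudged to the arm totals 214/215, six
outcomes at the arm-specific means, SDs, rates and ICCs the study reports.
Lengths of stay and costs are generated as normals truncated at zero
(logged when truncation occurs), matching the normal-theory estimator
applied to them rather than clinical skewness. What these simulations do
**not** emulate: the joint correlation between outcomes (e.g. mortality
vs. length of stay), informative cluster size, and real-data skewness —
so passing recovery tests shows estimator correctness under the assumed
models, not robustness to their violation.

`recovery_experiment()` chains seeds as base_seed + replicate index
(recorded in the report) and returns bias, RMSE and CI coverage. Problem
sizes used in the shipped experiments: 500 replicates at k=50, m=30 for
ANOVA bias/coverage; 500 replicates at the study's own k=14 for the
mean-recovery check; 300 replicate synthetic trials for the study-like
UC length-of-stay recovery (compared on the untruncated scale, since at
ρ=0.02 and k=7 truncation is frequent and one-sided); scaled-down
bootstrap-coverage runs for the binary model. These sizes are the
package's choices for routine testing; all experiments accept larger
`n_reps`.

## Known limitations

* No REML/ML variance components for continuous outcomes, no
  covariate-adjusted ICCs, no beta-binomial or Rao–Scott binary
  estimators, and no manifest-scale (proportion-scale) transformation of
  the latent binary ICC.
* The Swiger interval is a large-sample Wald construction; with very few
  clusters it under-covers slightly and the published-style truncation
  makes it conservative only near ρ=0.
* Unequal-cluster-size corrections beyond m₀ (coefficient-of-variation
  adjustments) and fixed-cluster-number sample-size formulae are out of
  scope; the design-effect module intentionally implements only
  1+(m−1)ρ.
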