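# crticc

Intraclass correlation coefficients (ICCs) and design effects for **cluster
randomized trials** (CRTs), with a complete, runnable reproduction of the
ICC tables of a 14-hospital heart-failure care-pathway trial.

## Why

In a CRT, intact groups (here: hospitals) are randomized while outcomes are
measured on individuals. Patients treated in the same hospital resemble each
other, and that within-cluster dependence — quantified by the ICC,
ρ = σ²_b / (σ²_b + σ²_w) — inflates the variance of every treatment-effect
estimate by the design effect

```
DE = 1 + (m − 1)·ρ        (m = average cluster size)
```

so a trial powered for *n* individually randomized patients needs
`ceil(n·DE)` patients under cluster randomization. Planning a CRT therefore
requires an ICC estimate for the planned outcome *before* the trial runs,
and published per-outcome ICCs are the usual source. This package is for
trialists and biostatisticians who need to (a) estimate ICCs from their own
clustered data **or from published per-cluster summary tables**, (b) turn
them into design effects and inflated sample sizes, and (c) check the
estimators' behaviour against simulated trials with known ground truth.

## Estimators

* **Continuous and ordinal outcomes** — one-way random-effects ANOVA
  (Donner–Klar moment estimator). From per-cluster sizes nᵢ, means ȳᵢ and
  SDs sᵢ: MSB = Σnᵢ(ȳᵢ−ȳ)²/(k−1), MSW = Σ(nᵢ−1)sᵢ²/(N−k),
  m₀ = (N − Σnᵢ²/N)/(k−1), σ̂²_b = (MSB−MSW)/m₀, ρ̂ = σ̂²_b/(σ̂²_b+MSW),
  truncated at 0. Standard errors by the Swiger large-sample formula
  Var(ρ̂) = 2(N−1)(1−ρ)²[1+(m₀−1)ρ]² / [m₀²(N−k)(k−1)].
  Ordinal outcomes (e.g. NYHA class II–IV) are scored on their integer
  codes and fed through the same machinery.
* **Binary outcomes** — a logit-normal binomial random-intercept model
  (binomial GLMM) fitted by Gauss–Hermite quadrature, with the latent-scale
  ICC ρ = σ²_b/(σ²_b + π²/3) and a nonparametric cluster-bootstrap
  percentile CI; plus the ANOVA estimator applied to the 0/1 indicators as
  an independent cross-check.

Everything is organised as model objects: build an `AnovaICC` or
`LogitNormalICC` from data, call `.fit()`, and read estimates, SEs, CIs and
a `summary()` table off the results object.

## Worked example

```python
import crticc

# the embedded per-cluster summaries of the 14-hospital trial
study = crticc.load_study_fixture()

# ICC of length of stay in the usual-care arm, from (n, mean, SD) rows
res = crticc.AnovaICC(study.table2["los"].subset_arm("UC")).fit()
print(res.summary())
```

```
One-way random-effects ANOVA ICC
==============================================
Outcome:            los
Clusters (k):       7
Individuals (N):    215
Adj. mean size m0:  30.7101
----------------------------------------------
MSB:                71.712
MSW:                44.0258
sigma_b^2:          0.901535
sigma_w^2:          44.0258
----------------------------------------------
ICC (raw):          0.020067
ICC (truncated):    0.020067
SE (Swiger):        0.029827
95% CI:             [0.000000, 0.078527]
```

The seven usual-care hospitals explain about 2% of the variance in length
of stay (the trial reports 0.020): patients in the same hospital stay only
slightly more similarly long than patients in different hospitals. Turning
an ICC into a planning number:

```python
de = crticc.design_effect(0.058, m=30)   # admission-source baseline ICC
print(round(de.value, 2), crticc.inflate_n(100, de))
# 2.68 269  -> a 100-patient individually randomized design needs 269 patients
```

Binary outcomes use the latent-scale model with a cluster bootstrap:

```python
res = crticc.icc_binary(study.table2["aos"].subset_arm("UC"),
                        crticc.BootstrapConfig(n_reps=500, seed=11))
print(round(res.icc, 3), tuple(round(x, 3) for x in res.conf_int()))
# 0.194 (0.0, 0.343)
```

A command-line interface mirrors these uses
(`crticc estimate | simulate | reproduce | design`); e.g.
`crticc reproduce` regenerates the full printed-vs-recomputed table and
exits nonzero if any cell misses its declared tolerance.

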