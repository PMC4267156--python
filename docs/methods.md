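# Methods

This note records the statistical model behind `factbmap`, the numerical
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Instrument scoring

FACT-B items are scored 0–4; negatively worded items are reversed as
`4 − raw`, the unique involution consistent with the 0–4 FACIT convention.
The half-rule is implemented with a *strict* "more than half answered"
threshold: a 7-item subscale needs ≥ 4 answers, the 6-item EWB needs ≥ 4,
the 10-item BCS needs ≥ 6. Prorated scores are kept at full float precision
(`sum(answered) × n_items / n_answered`); rounding would bias downstream
regressions. A composite (FACT-G, TOI, FACT-B total) is undefined whenever
any of its components is undefined, and subjects missing a covariate needed
by the chosen model are dropped from the design matrix with a logged count.

Item identities and polarity are supplied by a manifest CSV because the
licensed FACIT item list cannot be redistributed; the shipped default uses
placeholder IDs (`PWB1`…`BCS10`) with a reverse-scoring pattern resembling
the FACIT convention. Real analyses must load the official manifest.

## Utilities and the bounded-outcome transform

A value set is a pure lookup from the 3125 EQ-5D-5L states to utilities,
anchored at exactly 1 for state 11111. The crosswalk tariffs are licensed,
so the package ships *synthetic* stubs: additive, monotone in every
dimension, with floors pinned to the crosswalk ranges (−0.111 "Japanese",
−0.594 "UK"). They exercise every code path (anchors, ordering, floor/
ceiling logic) but carry no tariff information; user tables load from CSV
in either full-table or additive-decrement form.

Logistic quantile regression uses `h(y) = log((y − y_min)/(y_max − y))` on
the open interval `(y_min, y_max)`. Bounds come either from data
(`observed_min − smallest_increment/2`, `y_max = 1.001`) or from presets
storing the constants used with the crosswalk value sets (`y_min = 0.17885`
"Japanese", `−0.28265` "UK"). The UK preset is knowingly slightly *above*
a rounded display value of −0.283 sometimes quoted as the UK minimum; the
data-driven `derive_bounds` enforces `y_min < observed_min`, the presets
store their constants verbatim and are not validated against data. The
inverse transform's codomain is the open interval; because a float result
would round onto a bound for |h| ≳ 36, outputs are clamped to the nearest
representable interior values, preserving the strict-interior guarantee in
floating point.

## Estimators

* **OLS** is delegated to statsmodels (classical standard errors). Mean
  preservation on the training sample (`mean(ŷ) = mean(y)`) holds to 1e−10
  and is asserted in tests.
* **Tobit** is an upper-censored normal MLE written in-house (no installed
  package provides the upper-censored case): parameters `(β, log σ)`,
  analytic gradient with `log Φ` evaluated via `log_ndtr`, BFGS on the
  *mean* log-likelihood (making the 1e−8 gradient tolerance sample-size
  free), started at OLS. Standard errors come from the inverse observed
  information, obtained by central differences of the analytic gradient.
  Predictions use the latent linear index, which may exceed 1 — the index,
  not the censored expectation, is the quantity a mapping user wants.
* **Quantile/median regression** solves the check-loss LP exactly with
  HiGHS (`scipy.optimize.linprog`); the LAD optimum interpolates p+1
  observations, which the tests exploit via a brute-force subset oracle.
  On degenerate data the minimizer may be non-unique; the solver's fixed
  settings pick one deterministically and the (unique) objective value is
  the primary test surface.
* **CLAD** iterates: fit LAD on the kept set, drop *kept* rows whose fitted
  value is ≥ the censor point, refit, stop when the kept set is stable
  (max 50 iterations). Restricting drops to the current kept set makes the
  kept set monotone non-increasing, guaranteeing termination; the classic
  full-sample re-screening variant does not have this property, so
  coefficient-level agreement with other software on heavily censored data
  is not claimed. When trimming never activates, CLAD equals median
  regression exactly.
* **Logistic quantile regression** is median regression of `h(y)`; fitted
  mappings store their bounds so predictions back-transform automatically
  and always stay strictly inside `(y_min, y_max)` — 0% of predictions at
  the ceiling, by construction.
* Standard errors for CLAD/quantile/logistic-quantile use a seeded
  nonparametric bootstrap (default 200 resamples) since their sampling
  distributions have no convenient closed form.

The published registry is a 4-decimal CSV transcription of all 25
method × model coefficient sets (development n = 238) plus their fit
statistics; no attempt is made to recover full-precision values, since the
development data are not deposited. The CLAD and quantile entries are
identical coefficient vectors, as published for the primary value set.

## Goodness of fit and validation

`r²` is the squared *Pearson* correlation of observed and predicted (the
only definition that coincides with OLS R², which the registry reproduction
confirms), adjusted as `1 − (n−1)/(n−p−1)(1−r²)` with `p` counting
covariates excluding the intercept — the registry's 25 adjusted values
reproduce at 4-decimal rounding only under this convention. MSE and MAD are
moments of observed − predicted.

The signed-rank test drops zero differences (Wilcoxon convention, chosen
over Pratt as the common default), uses an exact sign-flip null for ≤ 25
nonzero pairs — computed by dynamic programming over doubled midranks, so
ties are handled exactly, with two-sided p defined as
`P(|W⁺ − S/2| ≥ |w − S/2|)` — and a tie-corrected normal approximation with
continuity correction beyond. All-zero differences return p = 1 by
convention.

Cuzick's trend test standardizes `T = Σ score·rank` by its exact
permutation moments computed from the observed (mid)ranks; this
tie-corrects the variance and makes the two-group case agree with the
rank-sum test to machine precision. The asymptotic normal p is the default
(the test's usual form); a seeded Monte-Carlo permutation null is available
for very small groups, where the normal tail is poor. In the validation
battery, statuses 3 and 4 are merged ("3 or 4") and the merged group is
scored 3; group scores are 0,1,2,3.

MID thresholds are stored as named constants (UK 0.08, US 0.06); a
group-mean discrepancy is "within MID" when `|Δ| < threshold`.

## Synthetic cohorts

The generator emulates the baseline study conditions: subscale means
(21.1, 22.2, 18.0, 20.0, 21.7) and SDs (6.0, 6.1, 4.74, 6.70, 6.15),
exchangeable latent correlation 0.4 (no published correlation matrix
exists; this is a configurable, realistic default for HRQoL subscales),
integer rounding half-up with clamping to instrument ranges, a true mapping
defaulting to the published OLS Model 4 coefficients, Gaussian utility
noise of SD 0.08 (chosen so observed-vs-predicted r² lands near the 0.5
regime at n = 238), and a performance-status mix of 40.8/48.3/7.1/3.8%
obtained by cutting the latent utility at matching quantiles (the "3 or 4"
group is split half/half by latent health).

**Ceiling mechanism.** Under the default coefficients the latent utility has
mean ≈ 0.776 and SD ≈ 0.137, so plain censoring at 1 would put only ~5% of
subjects at the ceiling — far below the ~25% ceiling mass characteristic of
EQ-5D-5L data. Real EQ-5D-5L utilities have a *gap* below full health: the
best attainable state short of 11111 sits well below 1. The default
`latent-censor` rule reproduces exactly this: the top
`target_ceiling_fraction` (24.8%) of latent utilities is mapped to exactly
1, censoring at the empirical quantile (≈ 0.87 under defaults). This hits
the ceiling target by construction and keeps the mean utility within 0.01
of 0.777. The alternative `clip` rule is plain top-coding at 1 — the
textbook Tobit mechanism — and is the right choice for censoring-bias
experiments. Cohorts carry both `utility` and the uncensored
`latent_utility`; estimators consistent for the latent scale (OLS, LAD)
are recovery-tested there, while Tobit/CLAD are tested on top-coded data.

The follow-up generator retains subjects with probability 1 − attrition
(default 7%, giving ≈ 221 of 238) and drifts each retained subject's latent
utility by N(0, drift_sd), reflecting the drift into subscales at one
subscale SD per latent-utility SD, re-rounding, re-censoring at the
baseline threshold and re-deriving status from the baseline cutpoints.
With attrition 0 and drift 0 the wave equals the baseline exactly.

**What passing tests do not show.** The generator matches *marginals* only:
it makes no attempt at realistic inter-item structure (items are generated
conditional on a target subscale score for scoring tests only), real
subscale covariance, the discreteness of value-set utilities below the
ceiling, or any language/ethnicity structure. Agreement of estimates on
synthetic data therefore validates the estimators' internal consistency,
not their field behavior on clinical data.

## Problem sizes

Distributional calibration and large-sample recovery use n = 10⁴ cohorts;
censoring-bias comparisons use n = 2000 with the intercept raised to 0.4156
so that roughly a quarter of top-coded observations sit at the ceiling
(matching the ceiling mass the estimators are meant to confront); bootstrap
standard errors in tests use 40–100 resamples. These sizes give stable
assertions at the 3-standard-error tolerances used throughout.

## Known limitations

* The shipped value sets are synthetic stubs; published tariffs must be
  supplied by the user.
* Tobit assumes homoscedastic Gaussian errors; no robust variants are
  provided (CLAD is the in-package answer to heteroscedasticity).
* CLAD's trimming scheme is deliberately conservative (monotone kept set);
  on data where the censor point is active for many observations its point
  estimates can differ from re-screening implementations.
* The published registry stores rounded coefficients, so registry-based
  predictions carry ~5e−5 rounding error on the utility scale.
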