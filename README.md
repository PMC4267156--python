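# factbmap

Mapping FACT-B quality-of-life scores to the EQ-5D-5L health-utility index.

Cost-utility analysis needs a preference-based utility index, but oncology
trials usually collect profile instruments such as the FACT-B (Functional
Assessment of Cancer Therapy – Breast, 37 items, five subscales). `factbmap`
implements the complete workflow for *mapping* (cross-walking) FACT-B
subscale scores to the EQ-5D-5L utility index: instrument scoring, value-set
utility computation, the published mapping coefficients, the five-estimator
fitting framework they came from, and the goodness-of-fit / validation
battery — plus a seeded synthetic-cohort generator so the whole pipeline is
testable without patient data. It is written for health-economics and
outcomes researchers working in Python.

## The model

A patient's EQ-5D-5L utility \(y \le 1\) is predicted from FACT-B subscale
scores (PWB, SWB, EWB, FWB, BCS) through five model presets (Model 1 = all
five subscales … Model 4 = PWB, EWB, FWB, BCS — the recommended one), fitted
with five estimators chosen for how they treat the ceiling at 1:

| estimator | treatment of the bound |
|---|---|
| OLS | ignores it; minimizes squared error |
| Tobit | upper-censored latent normal MLE, \(y^* = x'\beta + \varepsilon\), observed \(y=\min(y^*,1)\) |
| median (quantile) regression | minimizes absolute deviations; bound-agnostic |
| CLAD | Powell's censored LAD via iterative trimming of fits at the bound |
| logistic quantile regression | median regression of \(h(y)=\log\frac{y-y_{min}}{y_{max}-y}\); predictions stay inside \((y_{min},y_{max})\) |

Fit is summarized by the squared Pearson correlation between observed and
predicted values and its complexity-adjusted version
\( \text{adj } r^2 = 1-\frac{n-1}{n-p-1}(1-r^2) \), MSE and MAD; validation
compares group means by self-assessed performance status with signed-rank
tests, Cuzick's trend test and the EQ-5D minimally important difference
(0.08 UK / 0.06 US).

FACT-B scoring follows the FACIT conventions: 0–4 Likert items, reverse
scoring of negatively worded items (`4 - raw`), and the half-rule (a
subscale is prorated from its answered items only when strictly more than
half were answered). Note the official FACT-B item manifest and the
licensed EQ-5D-5L crosswalk value sets are **not** bundled; the package
ships placeholder/stub versions (clearly labelled synthetic) and loads real
ones from CSV.

## Worked example

```python
import factbmap as fm

mapping = fm.published_mapping("ols", 4)   # the recommended published mapping
prof = fm.SubscaleProfile(pwb=21.1, swb=22.2, ewb=18.0, fwb=20.0, bcs=21.7)
print(fm.predict(mapping, prof))
```

prints `0.77549` — the utility predicted for a patient at the development
sample's mean subscale profile (close to, but not exactly, that sample's
observed mean utility 0.777 because the published coefficients are rounded
to four decimals). Fitting the five estimators on a synthetic
development-sized cohort (`python examples/fit_estimators.py`) prints, for
seed 1:

```
cohort: n=238, ceiling=24.8%, mean utility=0.775

method       const      PWB      EWB      FWB      BCS      r2  adj r2     mse     mad
ols         0.2084   0.0129   0.0067   0.0042   0.0051  0.5420  0.5341  0.0109  0.0832
tobit       0.1063   0.0150   0.0085   0.0049   0.0068  0.5412  0.5334  0.0120  0.0881
quantile    0.1782   0.0129   0.0058   0.0049   0.0062  0.5402  0.5323  0.0111  0.0825
clad        0.1764   0.0129   0.0062   0.0047   0.0060  0.5410  0.5331  0.0111  0.0825
lqr        -5.7103   0.1391   0.0910   0.0334   0.0612  0.5252  0.5170  0.0120  0.0877
```

Tobit slopes are steeper than OLS (it models the latent, uncensored
utility), the logistic-quantile coefficients live on the logit scale, and
OLS reproduces the observed mean exactly. The other `examples/*.py` scripts
walk through scoring, value sets, and follow-up validation; a thin CLI
(`factbmap score|utility|map|fit|evaluate|simulate|validate`) wraps the same
functions for shell use.

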