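# predcurve

Predictiveness curves and summary measures for binary risk models.

Clinicians and epidemiologists who fit a risk model — "what is this
patient's probability of in-hospital death?" — need more than an odds ratio
to judge how much a marker matters.  `predcurve` takes the per-subject
predicted risks `p_i = P(D | X_i)` (optionally with the observed 0/1
outcomes) and computes the *predictiveness curve* `R(q)`, the risk plotted
against the quantiles `q` of its own distribution, together with the family
of summary measures that live in that plot:

* **q₀** — the quantile where `R(q)` crosses the prevalence `P(D)`; it splits
  the population into a *protective* range (risk below prevalence) and a
  *harmful* range (risk above).
* **A_N, A_S** — the areas between the curve and the prevalence line below
  and above it; equal under global calibration.
* **Degrees of necessity and sufficiency** — generalized attributable risks

      DN₂ = E[(P(D) − p)/P(D) | p < P(D)]      DS₂ = E[(p − P(D))/(1 − P(D)) | p > P(D)]

  with root-mean-square variants DN₁ ≥ DN₂ and DS₁ ≥ DS₂.  They are exactly
  the relative areas in the plot: `DN₂ = A_N / (P(D)·q₀)` and
  `DS₂ = A_S / ((1 − P(D))(1 − q₀))`.
* **Explained variation** `EV = Var(p) / (P(D)(1 − P(D)))`, **Tjur's
  coefficient of discrimination** `C_D = P¹(D) − P⁰(D)`, **total gain**
  `TG = A_N + A_S`, its standardization `STG = TG / (2P(D)(1 − P(D)))`, and
  the **above-average risk difference** `AARD = q₀⁰ − q₀¹` (Youden's index at
  the prevalence threshold).

For calibrated risks these obey the chain `DN₂·DS₂ ≤ EV ≤ STG`, with
equality on the left for a dichotomous marker — all of which the test suite
verifies to machine precision.

## Worked example

A dichotomous marker assigns risk 10.7% to 45% of a population and 18.0% to
the remaining 55% — a two-point predictiveness curve stepping at q = 0.45:

```python
import numpy as np
from predcurve import PredictivenessModel

risks   = np.array([0.107, 0.180])   # risk without / with the marker
weights = np.array([0.45, 0.55])     # population shares

res = PredictivenessModel(risks, weights=weights).fit()
print(res.summary())
```

```
          Predictiveness analysis
============================================
                       estimate bootstrap CI
--------------------------------------------
Prevalence P(D)            0.15
q0                         0.45
Explained variation EV     0.01
Necessity DN1              0.27
Necessity DN2              0.27
Sufficiency DS1            0.04
Sufficiency DS2            0.04
Total gain TG              0.04
Standardized TG            0.14
Area A_N                   0.02
Area A_S                   0.02
--------------------------------------------
```

The prevalence is the mixture mean 0.147; the marker's protective range
(45% of subjects) sits 27% below the average risk (`DN₂ = 0.27`), the
harmful range only 4% of the way toward certainty (`DS₂ = 0.04`), so the
marker is moderately necessary but hardly sufficient, and it explains about
1% of outcome variation.  The area identity is exact:

```python
print(f"A_N = {res.a_n:.4f}, A_N/(P(D) q0) = {res.a_n/(res.prevalence*res.q0):.4f}")
# A_N = 0.0181, A_N/(P(D) q0) = 0.2729
```

With outcomes available, `res.c_d`, `res.aard` and `res.plot_stratified(...)`
add the discrimination view; `res.bootstrap(b=1000, seed=...)` attaches
percentile confidence intervals (with optimism correction when the model is
refit per replicate via `PredictivenessModel.from_formula("y ~ x1 + x2", df)`);
`res.plot("curve.svg", show_denominators=True)` renders the curve with the
hatched areas A_N, A_S and their denominator rectangles.

A command line mirrors the library: `predcurve compute` (table → summary +
plots), `predcurve simulate` (synthetic populations), `predcurve compare`
(paired bootstrap test of two markers), `predcurve plot`.

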