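# Methods

## The model

`predcurve` operates on the distribution of conditional event probabilities
`p = P(D | X)` produced by an arbitrary risk model for a binary event `D`.
All quantities are functionals of that distribution (and, for the
discrimination measures, of the joint law of `(p, D)`); nothing depends on
the model type that produced the risks.  Two assumptions matter:

* **Representative sample** — the empirical risk distribution stands in for
  the population one; weights are frequency weights and can encode an exact
  population mixture.
* **Global calibration** — the conditional risks average to the
  unconditional prevalence.  The area symmetry `A_N = A_S`, the bound chain
  `DN₂·DS₂ ≤ EV ≤ STG`, and the STG = AARD equality hold under this
  assumption.  The package never silently enforces it: the prevalence source
  is explicit (`outcomes` vs `risks` mode), and `calibration_check` /
  `Results.calibration()` flag a discrepancy |mean risk − event rate| >
  0.005 (a pragmatic threshold an analyst would notice on a risk scale; it
  only gates a warning, never a computation).

## Estimators

The predictiveness curve is the left-continuous empirical quantile function
of the risks: `R(q)` = the smallest sorted risk whose cumulative weight
share reaches `q`, with `q ∈ {0, 1}` mapped to the extreme risks.  This
convention makes `risk_at_quantile`, `compute_q0` and the area integrals
mutually consistent, and because `R` is a step function every integral
reduces to an exact weighted sum — there is no quadrature error anywhere in
the estimators, which is why the identity tests can demand 1e−12.

Ties at the prevalence (risk exactly equal to `P(D)`) belong to neither the
protective nor the harmful range, mirroring the strict inequalities in the
defining conditional expectations; their mass is reported as `frac_tied` and
`q0` is the strictly-below fraction.  Tied points contribute zero area, so
the area identities remain exact.  Classification at a threshold `t` is
positive iff `risk > t` (ties negative), which makes the AARD–Youden
identity hold on tie-free samples.

Degenerate ranges score zero rather than NaN: an uninformative marker has
empty protective and harmful sets and `DN = DS = 0`.  A prevalence of
exactly 0 or 1 is an error, since every denominator vanishes.

`dichotomize_at_risk` replaces each risk by the weighted mean of its side of
a threshold (ties to the low side) — the locally calibrated two-group model.
At the mean-risk threshold this preserves DN₂, DS₂ and STG exactly and can
only decrease EV, DN₁ and DS₁ (the within-group variance is discarded);
both facts are verified as properties.

## Synthetic populations

The `synthetic` module provides the study conditions for every test:

* `two_point(w, a, b)` — a dichotomous marker; the canonical instance
  (w = 0.45, a = 0.107, b = 0.180) is the package's worked example, with
  mixture prevalence 0.14715.
* `beta(alpha, beta)` — Beta-distributed risks; EV has the closed form
  1/(α+β+1), used as an analytic anchor (Beta(2,8) → 1/11).
* `logistic_gaussian(intercept, slope)` — expit(intercept + slope·X) with
  X ~ N(0,1); the default acceptance instance (−2, 1) gives a smooth,
  right-skewed curve with prevalence ≈ 0.155, typical of a moderately
  informative clinical marker.
* `uninformative(π)` / `perfect(π)` — the two boundary cases.

Exact-weights mode encodes the law itself: two-point families exactly, and
continuous laws on an equal-probability midpoint quantile grid (default
10,001 atoms) so that every atom carries the same weight and step
integration stays exact; the grid bias is O(1/m) and the default grid
recovers the Beta EV closed form to ~1e−5.  With `include_outcomes=True`
each atom is split into event/non-event rows with Bernoulli(risk) mass, so
outcome-dependent measures are exact too.  Sampled mode draws risks from the
law and outcomes as Bernoulli(risk) — calibrated in expectation,
reproducible bit-for-bit under the spec's seed.

What the generator does **not** emulate: covariate structure, model
misspecification, measurement error, or case-mix shift.  Passing tests show
the estimators and identities are correct for calibrated risk distributions;
they say nothing about whether a particular fitted model is calibrated on
real data — that must be checked per dataset (hence the calibration
diagnostic).

`population_oracle` integrates the *defining* expectations of every measure
by adaptive quadrature over the risk law (scipy `quad`, domain split at the
risk-equals-prevalence point), or by finite sums for discrete families.  It
shares no code path with the sample estimators and is used only as an
independent reference in tests.

## Inference

Bootstrap CIs are percentile intervals (the simplest defensible default; no
BCa or studentization in this version), with subject-level resampling.
Replicates that lose an outcome class are redrawn, capped at 10·B attempts.
When a model formula is supplied the logistic model is refit on each
replicate and the optimism — mean of (apparent performance on the replicate
− replicate model's performance on the original data) — is subtracted from
the apparent estimate.  On exact-weights population fixtures the optimism is
≈ 0, as there is no sampling noise to overfit.  The two-marker comparison is
a paired percentile bootstrap (identical resample indices for both markers)
with a continuity-adjusted two-sided p-value; it is a generic substitute for
more specialized comparison tests, not a reconstruction of any particular
one.

The logistic adapter delegates to statsmodels' maximum-likelihood `Logit`
with an always-included intercept and no regularization; separation or
non-convergence raises.  The intercept's score equation forces the mean
fitted risk to equal the event rate, which the adapter asserts to 1e−8 as a
self-check.

## Numerical choices and problem sizes

* "Exact" identities are asserted at 1e−12 absolute — step-function sums
  accumulate only rounding error, orders of magnitude below this.
* Table-style reports round half-up to 2 decimals.
* Display smoothing of the curve (moving average on a fine grid, forced
  monotone) is cosmetic only and never feeds back into any measure, since
  any smoother would introduce an arbitrary bandwidth into the estimators.
* Figures render deterministically (fixed SVG hash salt, no embedded dates),
  so golden-file comparisons are byte-exact; the committed goldens are
  regression anchors for this package's styling, not replicas of any
  external figure.
* Test problem sizes: 1,000 randomized samples for the identity/inequality
  suites; 6 replicates of n = 200,000 for oracle-equivalence Monte-Carlo
  bands; 8 fitted models of n = 5,000 for the Tjur and STG–AARD asymptotics;
  200 simulations of n = 2,000 with B = 200 for bootstrap coverage.  These
  sizes put Monte-Carlo error well below the tolerances being checked while
  keeping the whole suite in tens of seconds.

## Known limitations

* Binary outcomes only; no survival or competing-risks extensions.
* The logistic adapter fits additive main effects without shrinkage or
  variable selection; risks from any richer model can be supplied directly.
* Percentile bootstrap intervals can undercover for measures near their
  boundary (e.g. EV ≈ 0); the coverage test targets a mid-range setting.
* Weighted samples treat weights as frequencies; survey-design (probability)
  weights with finite-population corrections are out of scope.
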