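# Methods

## Model

The illness-death model for an irreversible ("chronic") disease has
three states — nondiseased, diseased, dead — and three age-specific
transition hazards: incidence `i(a)`, mortality of the nondiseased
`m0(a)` and mortality of the diseased `m1(a)`.  The population is
closed (no migration) and the rates depend on age only (time
homogeneity); under these assumptions one age variable suffices and
the susceptible/case counts `S, C` in a cohort obey the linear system

    dS/da = -(i + m0) S,        dC/da = i S - m1 C.

Writing `N = S + C` and `p = C/N` (with `p := 0` where `N = 0`), the
prevalence solves the scalar Riccati-type ODE

    dp/da = (1 - p) { i - p (m1 - m0) },    p(a0) = C0/(S0 + C0),

and stays in [0, 1] whenever the rates are nonnegative.  For chronic
diseases the excess mortality `Δm = m1 - m0` is normally nonnegative;
inputs with `Δm < 0` are accepted (the ODE is still integrable) but the
[0, 1]-bound enforcement then downgrades from an error to a warning,
since a protective "disease" genuinely can push reconstructed counts
outside the chronic-disease regime.

Six combinations of mortality information determine the right-hand
side: with the general mortality `m = p m1 + (1-p) m0` and the relative
risk `R = m1/m0`, the pairs `(m, m0)` and `(m, m1)` give linear ODEs,
`(m0, m1)`, `(m0, R)`, `(m1, R)` Riccati ODEs, and `(m, R)` an Abelian
ODE through the population attributable fraction
`PAF(p, R) = p(R-1)/(p(R-1)+1)`.  The `(m, m1)` variant is implemented
in the algebraically simplified form `dp/da = (1-p) i - p (m1 - m)`,
which removes the 0/0 at `p → 1` present in the textbook display.
`consistent_mortality_family` constructs all six inputs from one
`(m0, m1)` pair by solving the ODE once with dense output and deriving
`m` and `R` as age functions; this underlies the cross-variant
consistency tests.

## Numerics

- **Integrator.** `scipy.integrate.solve_ivp` with adaptive RK45,
  `rtol = 1e-10`, `atol = 1e-12`, sampled on the uniform grid.  These
  tolerances make the numerical ODE solution and the nondifferential
  closed form agree to ~1e-10 in sup norm at desk scale (at
  `rtol = 1e-8` the discrepancy is ~1e-8, too close to the accuracy the
  package promises); the cost difference is negligible.
- **Quadratures.** Cumulative hazards and the nested integral of the
  closed-form cohort solution use composite Simpson
  (`scipy.integrate.cumulative_simpson`) on the solver grid, keeping
  the nested integral O(n).
- **Bounds.** Prevalence excursions beyond [0, 1] up to 1e-9 are
  treated as roundoff and clamped; larger excursions raise when the
  inputs certify `Δm ≥ 0` (they then indicate inconsistent inputs)
  and warn+clamp otherwise.  Cohort counts may undershoot zero by at
  most `1e-12 · N0` before the solver errors.
- **Peak localisation.** The interior maximum of a prevalence curve is
  the grid maximiser refined by a quadratic fit through its two grid
  neighbours.
- **Differentiation.** Default is second-order central differences
  (one-sided second-order at the two boundary points, which are
  retained but listed in the estimate's metadata).  For noisy empirical
  curves a cubic smoothing spline is available
  (`scipy.interpolate.make_smoothing_spline`); its penalty is chosen by
  generalized cross-validation when not supplied.  Noise amplification
  is the core hazard of this inversion, so the smoothing route is the
  recommended one for real data.
- **Inverse diagnostics.** `1 - p ≤ 1e-9` raises (the formula is
  singular there, and the offending age is named); `1 - p < 1e-3` only
  sets a `near_singular_denominator` flag.  Negative incidence
  estimates are flagged, not silently clipped — they diagnose
  inconsistent mortality assumptions (e.g. an extreme protective
  scenario `R = 0.5`); `clip_nonnegative` exists for presentation.

## Ill-posedness experiment

Perturbing a prevalence curve by `ε sin(na)` moves it by at most `ε`,
but the recovered incidence moves by a term dominated by
`ε n cos(na)/(1 - p)`.  With the coupled amplitude `ε_n = n^(-1/2)` the
curve perturbation vanishes while the incidence error grows like `√n`
— the inversion map is discontinuous (ill-posed in the Hadamard
sense).  The default frequency ladder 10, 40, 160, 640 (ratio 4)
therefore predicts an error ratio of 2 per step; the experiment's
default `analytic_perturbation` mode adds the sine's derivative
`ε n cos(na)` in closed form, because a finite grid aliases
high-frequency sines and the numeric mode would otherwise measure
finite-difference artefacts instead of the operator-level mechanism
(the numeric mode is retained to show exactly that practical
manifestation).  The sup norm is restricted to ages with `p ≤ 0.99`,
where the `1/(1-p)` factor is under control.  The measured ratios on
the worked example are ≈ 1.79, 1.96, 1.99: the first step still feels
the finite amplitude `ε_10 ≈ 0.32` interacting with the base curve,
the later steps sit on the asymptotic law.

## Stochastic simulator

Each individual starts nondiseased at `a0`.  The nondiseased sojourn
ends at the first event of the combined hazard `i + m0`, sampled by
inverting its cumulative hazard (tabulated by the trapezoid rule on a
0.01-year grid with linear interpolation — deterministic cost, no
rejection loops for steep Gompertz tails); at the event age the
competing risks split with probability `i/(i + m0)`, exact for the
combined-hazard construction.  Diseased individuals draw a residual
lifetime from `m1` the same way; anyone alive at `omega` is censored.
All uniforms come from one seeded PCG64 generator as a single
`(N0, 3)` block, so individual k is identical for every cohort size
≥ k and reruns are bit-identical.  Empirical prevalence is the
diseased fraction among the living at each grid age (0 where nobody is
alive), with Wilson 95% binomial intervals.

Against the deterministic theory: at `N0 = 1e5` on the worked example
the empirical prevalence deviates from the ODE solution by < 0.01 in
sup norm over ages 30–90, shrinking like `N0^(-1/2)`.

## Synthetic prevalence fixture

Claims-data prevalence of an early-onset chronic disease (the
motivating case is type 1 diabetes in young women) is emulated by a
synthetic template: a monotone PCHIP interpolant through knots rising
steeply from 0 at birth to ~2.2 per 1000 at age 15, a plateau to 20, a
second rise to ~3.2 per 1000 at 30 and a plateau to 35.  Per-age
Gaussian noise of binomial scale `sqrt(p(1-p)/n_eff)` with
`n_eff = 5e5` (the order of a single-year female age class covered by
a large claims dataset) is added, scaled by `noise_sd_scale`, and
clamped to [0, 1].  The template is synthetic — knot values are
qualitative, not published numbers — so fixture-based tests show that
the inversion machinery behaves on realistically shaped and
realistically noisy curves (and that spline differentiation beats raw
central differences there); they do not reproduce any published
incidence estimate.  Real claims data additionally carry age-grouping,
diagnostic-code misclassification and calendar-time trends that the
fixture does not model.

## Problem sizes and defaults

Defaults are desk-scale: grid step 0.1 years, domains of ~70 years
(e.g. ages 30–100; `omega` must be finite and user-supplied — the
theory admits `omega = ∞` but the solvers need a bound, and no
canonical upper age exists), cohorts of 1e3–1e5 individuals, 20–100
randomized configurations in the property suites.  All complete in
seconds on one CPU.

## Limitations

- Age-only rates: no calendar-time (period/cohort) dependence, no
  duration-dependent `m1`, no migration, no remission.
- The inverse problem gets no formal regularization theory and no
  confidence intervals; the scenario sweep plus the sandwich principle
  is the supported way to express mortality-assumption uncertainty.
- Tabulated rates interpolate linearly between knots and refuse to
  extrapolate — constant extension at the tails silently corrupts
  Gompertz-like hazards.
- CSV output carries 12 significant digits; round trips are lossless
  at the accuracy the solvers deliver, not to machine precision for
  arbitrary magnitudes.
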