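# illdeath

Tools for the **illness-death model** of chronic-disease epidemiology:
the three-state compartment model *nondiseased → diseased → dead* with
age-specific incidence rate `i(a)`, mortality `m0(a)` of the
nondiseased and mortality `m1(a)` of the diseased (ages in years,
hazards per person-year).

The package is aimed at epidemiologists and biostatisticians who want
to move between the three equivalent descriptions of an irreversible
disease in a closed cohort:

- the **cohort system** for susceptible and case counts,
  `dS/da = -(i + m0) S`, `dC/da = i S - m1 C`, with `N = S + C` alive;
- the scalar **prevalence ODE** for `p = C/N`,

      dp/da = (1 - p) { i - p (m1 - m0) },

  a Riccati-type equation whose right-hand side can be rewritten for
  any of six combinations of available mortality information — `(m, m0)`
  or `(m, m1)` (linear), `(m0, m1)`, `(m0, R)` or `(m1, R)` (Riccati),
  `(m, R)` (Abelian, via the population attributable fraction
  `PAF(p, R) = p(R-1)/(p(R-1)+1)`), where `m = p m1 + (1-p) m0` is the
  general mortality and `R = m1/m0` the relative risk;
- the **inverse problem**: given a cross-sectional prevalence curve and
  mortality information, recover the incidence,

      i(a) = (dp/da) / (1 - p) + m · PAF(p, R)

  (and the analogous closed forms for the other five variants).  This
  inversion is useful — prevalence comes from cheap cross-sectional
  studies, incidence normally needs follow-up — but it is **ill-posed**:
  a prevalence perturbation `ε sin(na)` of vanishing size `ε_n = n^(-1/2)`
  drives the incidence error to infinity like `√n`.  The package both
  demonstrates this and mitigates it (smoothing-spline differentiation).

A stochastic individual-level simulator (competing-risks sampling by
cumulative-hazard inversion) validates the deterministic theory and
generates synthetic noisy prevalence curves.

## Worked example

Gompertz mortalities `m_j(a) = exp(β0_j + β1_j a)` with
`β0 = -10.7 / -10.0` (nondiseased / diseased) and common slope
`β1 = 0.1` per year, ramp incidence `i(a) = max(0, a - 30)/2000`,
starting disease-free at age 30:

```python
import numpy as np
from illdeath import (AgeDomain, MortalityInput, MortalityTag, RateFunction,
                      solve_prevalence_ode, find_local_maximum,
                      estimate_incidence, illposedness_experiment)

domain = AgeDomain(a0=30, omega=100, step=0.1)
m0 = RateFunction.gompertz(-10.7, 0.1, domain)
m1 = RateFunction.gompertz(-10.0, 0.1, domain)
i = RateFunction.from_callable(lambda a: np.maximum(0.0, a - 30.0) / 2000.0, domain)
mort = MortalityInput(MortalityTag.M0_M1, m0, m1)

curve = solve_prevalence_ode(i, mort, p0=0.0, domain=domain)
age, value = find_local_maximum(curve)
print(f"ODE type: {curve.meta['classification']}")
print(f"prevalence peaks at age {age:.1f} years (p = {value:.3f})")

est = estimate_incidence(curve, mort)          # invert the curve back
tab = illposedness_experiment(curve, mort)     # coupled perturbations
print(tab.to_string(index=False))
```

prints

```
ODE type: riccati
prevalence peaks at age 80.6 years (p = 0.350)
    n  epsilon_n  sup_error
 10.0   0.316228   5.574540
 40.0   0.158114   9.997705
160.0   0.079057  19.583584
640.0   0.039528  38.886218
```

The prevalence rises, peaks at about age 80 (35% of the survivors are
diseased there) and falls again as the excess mortality of the diseased
thins out the cases — the hump shape typical of dementia, diabetes or
rheumatic diseases.  The inversion of the same curve recovers the ramp
incidence to about 1e-6 per person-year.  The perturbation table shows
the ill-posedness: each quadrupling of the frequency *halves* the size
of the prevalence perturbation (`epsilon_n`) yet *doubles* the sup-norm
error of the recovered incidence.

The same runs from the shell:

```bash
idm forward --incidence ramp.csv --mortality-tag m0_m1 \
    --m0 gompertz:-10.7,0.1 --m1 gompertz:-10.0,0.1 \
    --p0 0 --a0 30 --omega 100 --step 0.1 --out prevalence.csv
idm invert --prevalence prevalence.csv --mortality-tag m0_m1 \
    --m0 gompertz:-10.7,0.1 --m1 gompertz:-10.0,0.1 --out incidence.csv
idm perturb --prevalence prevalence.csv --mortality-tag m0_m1 \
    --m0 gompertz:-10.7,0.1 --m1 gompertz:-10.0,0.1 --out illposed.csv
idm simulate --incidence ramp.csv --m0 gompertz:-10.7,0.1 \
    --m1 gompertz:-10.0,0.1 --n0 100000 --seed 42 --a0 30 --omega 100 \
    --out events.csv --prevalence-out prev_hat.csv
idm fixture --template t1d_like --seed 1 --out noisy_prev.csv
```

Relative-risk scenario sweeps for the inverse problem (`--mortality-tag
m_r --relative-risk 0.5,1,5`) write one incidence file per scenario;
bracketing the unknown true relative risk with a low and a high
scenario brackets the true incidence (sandwich principle).

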