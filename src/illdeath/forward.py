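"""The direct problem: from rates to cohort counts and prevalence.

Given the incidence ``i`` and the two mortalities ``m0``/``m1``, the
numbers of susceptible (``S``) and diseased (``C``) individuals in a
closed cohort obey the linear system

    dS/da = -(i + m0) S,
    dC/da =  i S - m1 C,

with ``N = S + C`` alive overall.  The age-specific prevalence
``p = C / N`` satisfies the scalar ODE

    dp/da = (1 - p) { i - p (m1 - m0) },

whose right-hand side can be rewritten in six equivalent forms
depending on which two pieces of mortality information are available
(see :class:`~illdeath.rates.MortalityTag`).  Under nondifferential
mortality (``m0 = m1``) the prevalence has the closed form
``p(a) = 1 - (1 - p0) exp(-\\int i)``.

This module provides the closed-form quadrature solution of the cohort
system, adaptive ODE solutions of both the system and the scalar
prevalence equation, the nondifferential closed form, and the survival
curve ``N(a) = N0 exp(-\\int m)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, solve_ivp

from .errors import NumericError, ValidationError
from .rates import AgeDomain, MortalityInput, MortalityTag, RateFunction

__all__ = [
    "CohortTrajectory",
    "PrevalenceCurve",
    "SurvivalCurve",
    "solve_cohort_closed_form",
    "solve_cohort_ode",
    "prevalence_of",
    "solve_prevalence_ode",
    "closed_form_nondifferential",
    "survival_curve",
    "consistent_mortality_family",
    "find_local_maximum",
]

#: default integrator tolerances; tight enough that the numerical ODE
#: solution and the closed-form quadratures agree to ~1e-10
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12

#: prevalence excursions beyond [0, 1] up to this size are treated as
#: roundoff and clamped; anything larger signals inconsistent inputs
CLAMP_TOL = 1e-9


@dataclass
class CohortTrajectory:
    """Cohort counts ``S`` (susceptible), ``C`` (diseased), ``N = S + C``
    on a uniform age grid."""

    ages: np.ndarray
    S: np.ndarray
    C: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ages", "S", "C", "N"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.ages.shape == self.S.shape == self.C.shape == self.N.shape):
            raise ValidationError("trajectory arrays must share one shape")
        if np.any(self.S < 0) or np.any(self.C < 0):
            raise ValidationError("cohort counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "S": self.S, "C": self.C, "N": self.N}
        )


@dataclass
class PrevalenceCurve:
    """Age-specific prevalence ``p(a) = C(a)/N(a)`` on an age grid.

    The prevalence of an irreversible disease always lies in [0, 1];
    the constructor enforces this (after absorbing roundoff-sized
    excursions up to ``CLAMP_TOL``).
    """

    ages: np.ndarray
    p: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.ages.shape != self.p.shape or self.ages.ndim != 1:
            raise ValidationError("ages and p must be 1-D arrays of equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValidationError("ages must be strictly increasing")
        excursion = max(float(np.max(-self.p, initial=0.0)),
                        float(np.max(self.p - 1.0, initial=0.0)))
        if excursion > CLAMP_TOL:
            raise ValidationError(
                f"prevalence leaves [0, 1] by {excursion:.3e}"
            )
        self.p = np.clip(self.p, 0.0, 1.0)

    @property
    def step(self) -> float:
        return float(self.ages[1] - self.ages[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "p": self.p})


@dataclass
class SurvivalCurve:
    """Alive counts ``N(a)`` on an age grid (nonincreasing)."""

    ages: np.ndarray
    N: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "N": self.N})


# ---------------------------------------------------------------------------
# cohort system
# ---------------------------------------------------------------------------


def _check_initial_counts(S0: float, C0: float) -> None:
    if S0 < 0 or C0 < 0:
        raise ValidationError("initial counts must be nonnegative")
    if S0 + C0 <= 0:
        raise ValidationError("need S0 + C0 > 0 to start a cohort")


def solve_cohort_closed_form(
    i: RateFunction,
    m0: RateFunction,
    m1: RateFunction,
    S0: float,
    C0: float,
    domain: AgeDomain,
) -> CohortTrajectory:
    """Quadrature solution of the cohort system.

    ``S(a) = S0 exp(-\\int (i + m0))`` and
    ``C(a) = exp(-\\int m1) [C0 + \\int i S exp(\\int m1)]``, with all
    integrals taken from ``a0`` and evaluated by composite Simpson on
    the domain grid.  ``N = S + C``.
    """
    _check_initial_counts(S0, C0)
    grid = domain.grid()
    iv, m0v, m1v = i(grid), m0(grid), m1(grid)

    H0 = cumulative_simpson(iv + m0v, x=grid, initial=0.0)
    S = S0 * np.exp(-H0)
    M1 = cumulative_simpson(m1v, x=grid, initial=0.0)
    # the nested integral in C shares the grid; exp(M1) can be large for
    # steep Gompertz tails but the product i*S*exp(M1) stays moderate
    inner = cumulative_simpson(iv * S * np.exp(M1), x=grid, initial=0.0)
    if not np.all(np.isfinite(inner)):
        raise NumericError("cohort quadrature overflowed; shrink the domain")
    C = np.exp(-M1) * (C0 + inner)
    return CohortTrajectory(ages=grid, S=S, C=C, N=S + C)


def solve_cohort_ode(
    i: RateFunction,
    m0: RateFunction,
    m1: RateFunction,
    S0: float,
    C0: float,
    domain: AgeDomain,
    rtol: float = DEFAULT_RTOL,
    atol: Optional[float] = None,
) -> CohortTrajectory:
    """Adaptive Runge-Kutta solution of the 2-D linear cohort system."""
    _check_initial_counts(S0, C0)
    grid = domain.grid()
    scale = max(1.0, S0 + C0)
    if atol is None:
        atol = DEFAULT_ATOL * scale

    def rhs(a, y):
        S, C = y
        ia, m0a, m1a = i(a), m0(a), m1(a)
        return [-(ia + m0a) * S, ia * S - m1a * C]

    sol = solve_ivp(
        rhs,
        (domain.a0, domain.omega),
        [float(S0), float(C0)],
        t_eval=grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericError(
            f"cohort integration failed near age {sol.t[-1]:.3f}: {sol.message}"
        )
    S, C = sol.y
    floor = 1e-12 * scale
    if np.any(S < -floor) or np.any(C < -floor):
        raise NumericError("cohort solution went significantly negative")
    return CohortTrajectory(
        ages=grid, S=np.maximum(S, 0.0), C=np.maximum(C, 0.0),
        N=np.maximum(S, 0.0) + np.maximum(C, 0.0),
    )


def prevalence_of(traj: CohortTrajectory) -> PrevalenceCurve:
    """Prevalence ``p = C/N`` with the convention ``p = 0`` where ``N = 0``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(traj.N > 0, traj.C / np.where(traj.N > 0, traj.N, 1.0), 0.0)
    return PrevalenceCurve(ages=traj.ages.copy(), p=np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# scalar prevalence ODE
# ---------------------------------------------------------------------------


def _paf_raw(p, R):
    # PAF without [0,1] validation: the ODE right-hand side may probe
    # slightly outside the band during adaptive stepping
    return p * (R - 1.0) / (p * (R - 1.0) + 1.0)


def prevalence_rhs(
    i: RateFunction, mort: MortalityInput
) -> Callable[[float, float], float]:
    """Right-hand side ``f(a, p)`` of the prevalence ODE for the given
    mortality information.

    All six variants are algebraically equivalent when the inputs are
    mutually consistent; the (m, m1) form uses the simplified expression
    ``(1-p) i - p (m1 - m)`` to avoid the removable 0/0 at p -> 1.
    """
    tag = mort.tag
    c = mort.component

    if tag is MortalityTag.M_M0:
        m, m0 = c("m"), c("m0")
        return lambda a, p: (1.0 - p) * (i(a) - (m(a) - m0(a)))
    if tag is MortalityTag.M_M1:
        m, m1 = c("m"), c("m1")
        return lambda a, p: (1.0 - p) * i(a) - p * (m1(a) - m(a))
    if tag is MortalityTag.M0_M1:
        m0, m1 = c("m0"), c("m1")
        return lambda a, p: (1.0 - p) * (i(a) - p * (m1(a) - m0(a)))
    if tag is MortalityTag.M0_R:
        m0, R = c("m0"), c("R")
        return lambda a, p: (1.0 - p) * (i(a) - p * m0(a) * (R(a) - 1.0))
    if tag is MortalityTag.M1_R:
        m1, R = c("m1"), c("R")
        return lambda a, p: (1.0 - p) * (i(a) - p * m1(a) * (R(a) - 1.0) / R(a))
    # M_R, Abelian: cubic in p through the PAF
    m, R = c("m"), c("R")
    return lambda a, p: (1.0 - p) * (i(a) - m(a) * _paf_raw(p, R(a)))


def solve_prevalence_ode(
    i: RateFunction,
    mort: MortalityInput,
    p0: float,
    domain: AgeDomain,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dense: bool = False,
) -> PrevalenceCurve:
    """Integrate the scalar prevalence ODE on the domain grid.

    Returns a :class:`PrevalenceCurve` whose ``meta`` records the ODE
    classification for the chosen mortality tag and, when ``dense`` is
    set, a callable interpolant of the solution under ``"dense"``.

    Solutions drifting outside [0, 1] by more than roundoff indicate
    inconsistent inputs (typically negative excess mortality); this
    raises unless the mortality input itself admits m1 < m0, in which
    case the bound check downgrades to a warning and the curve is
    clamped.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValidationError(f"p0 must lie in [0, 1], got {p0}")
    grid = domain.grid()
    rhs = prevalence_rhs(i, mort)
    sol = solve_ivp(
        lambda a, y: [rhs(a, y[0])],
        (domain.a0, domain.omega),
        [float(p0)],
        t_eval=grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=dense,
    )
    if not sol.success:
        raise NumericError(
            f"prevalence integration failed near age {sol.t[-1]:.3f}: {sol.message}"
        )
    p = sol.y[0]
    excursion = max(float(np.max(-p, initial=0.0)), float(np.max(p - 1.0, initial=0.0)))
    if excursion > CLAMP_TOL:
        if mort.implies_nonneg_excess(grid) is True:
            raise NumericError(
                f"prevalence left [0, 1] by {excursion:.3e} despite "
                "nonnegative excess mortality; inputs are inconsistent"
            )
        warnings.warn(
            f"prevalence left [0, 1] by {excursion:.3e} (negative excess "
            "mortality admitted); clamping",
            stacklevel=2,
        )
        p = np.clip(p, 0.0, 1.0)
    meta = {"classification": mort.classification, "tag": mort.tag.value}
    if dense:
        meta["dense"] = sol.sol
    return PrevalenceCurve(ages=grid, p=p, meta=meta)


def closed_form_nondifferential(
    i: RateFunction, p0: float, domain: AgeDomain
) -> PrevalenceCurve:
    """Closed-form prevalence under nondifferential mortality (m0 = m1):
    ``p(a) = 1 - (1 - p0) exp(-\\int_{a0}^{a} i)``."""
    if not (0.0 <= p0 <= 1.0):
        raise ValidationError(f"p0 must lie in [0, 1], got {p0}")
    grid = domain.grid()
    cum_inc = cumulative_simpson(i(grid), x=grid, initial=0.0)
    if not np.all(np.isfinite(cum_inc)):
        raise NumericError("cumulative incidence quadrature is non-finite")
    p = 1.0 - (1.0 - p0) * np.exp(-cum_inc)
    return PrevalenceCurve(
        ages=grid, p=p, meta={"classification": "closed_form_nondifferential"}
    )


def survival_curve(m: RateFunction, N0: float, domain: AgeDomain) -> SurvivalCurve:
    """Alive counts ``N(a) = N0 exp(-\\int m)`` for general mortality ``m``."""
    if not (N0 > 0):
        raise ValidationError(f"N0 must be positive, got {N0}")
    grid = domain.grid()
    H = cumulative_simpson(m(grid), x=grid, initial=0.0)
    return SurvivalCurve(ages=grid, N=float(N0) * np.exp(-H))


def consistent_mortality_family(
    i: RateFunction,
    m0: RateFunction,
    m1: RateFunction,
    p0: float,
    domain: AgeDomain,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> dict:
    """All six mortality-information variants consistent with (m0, m1).

    Solves the prevalence ODE once for the (m0, m1) pair with dense
    output, then derives the general mortality ``m = p m1 + (1-p) m0``
    and the relative risk ``R = m1/m0`` as age functions.  Feeding any
    of the returned inputs to :func:`solve_prevalence_ode` (same ``i``
    and ``p0``) reproduces the same prevalence; this is the package's
    consistency check across the six ODE variants.

    Requires ``m0 > 0`` on the grid (the relative risk is undefined
    otherwise).  Returns a dict mapping :class:`MortalityTag` to
    :class:`MortalityInput`.
    """
    grid = domain.grid()
    if np.any(m0(grid) <= 0):
        raise ValidationError("m0 must be strictly positive to derive R = m1/m0")
    base = MortalityInput(MortalityTag.M0_M1, m0, m1)
    sol = solve_prevalence_ode(i, base, p0, domain, rtol=rtol, atol=atol, dense=True)
    dense = sol.meta["dense"]

    def p_of(a):
        return np.clip(dense(np.asarray(a, dtype=float))[0], 0.0, 1.0)

    m = RateFunction.from_callable(
        lambda a: p_of(a) * m1._fn(np.asarray(a, dtype=float))
        + (1.0 - p_of(a)) * m0._fn(np.asarray(a, dtype=float)),
        domain,
        name="general_mortality",
    )
    R = RateFunction.from_callable(
        lambda a: m1._fn(np.asarray(a, dtype=float))
        / m0._fn(np.asarray(a, dtype=float)),
        domain,
        name="relative_risk",
    )
    return {
        MortalityTag.M_M0: MortalityInput(MortalityTag.M_M0, m, m0),
        MortalityTag.M_M1: MortalityInput(MortalityTag.M_M1, m, m1),
        MortalityTag.M0_M1: base,
        MortalityTag.M0_R: MortalityInput(MortalityTag.M0_R, m0, R),
        MortalityTag.M1_R: MortalityInput(MortalityTag.M1_R, m1, R),
        MortalityTag.M_R: MortalityInput(MortalityTag.M_R, m, R),
    }


def find_local_maximum(curve: PrevalenceCurve) -> tuple:
    """Interior local maximum of a prevalence curve.

    Takes the grid maximiser and refines the age by a quadratic fit
    through its two neighbours.  Returns ``(age, value)``.  Raises if
    the maximum sits on the boundary (no interior maximum).
    """
    k = int(np.argmax(curve.p))
    if k == 0 or k == curve.p.size - 1:
        raise ValidationError("prevalence maximum lies on the grid boundary")
    y0, y1, y2 = curve.p[k - 1], curve.p[k], curve.p[k + 1]
    denom = y0 - 2.0 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    h = curve.ages[k] - curve.ages[k - 1]
    age = float(curve.ages[k] + offset * h)
    value = float(y1 - 0.25 * (y0 - y2) * offset)
    return age, value
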