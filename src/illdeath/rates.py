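"""Age-dependent hazard functions and the algebraic mortality relations.

The illness-death model is parameterised by nonnegative age-specific
hazards: the incidence rate ``i(a)`` of disease onset, the mortality
``m0(a)`` of the nondiseased, the mortality ``m1(a)`` of the diseased,
the general (population) mortality ``m(a) = p*m1 + (1-p)*m0`` and the
relative risk ``R(a) = m1(a)/m0(a)``.  Ages are in years, hazards in
events per person-year.

A :class:`RateFunction` wraps one such hazard — Gompertz-parameterised,
tabulated with linear interpolation, or an arbitrary callable — together
with the closed age interval on which it is defined.  A
:class:`MortalityInput` bundles the two pieces of mortality information
that, next to the incidence, determine the prevalence ODE; the six
admissible combinations each give the ODE a different classification
(linear, Riccati or Abelian).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "AgeDomain",
    "RateFunction",
    "MortalityTag",
    "MortalityInput",
    "evaluate_rate",
    "general_mortality",
    "eaf",
    "paf",
]

#: tolerance for "age inside the closed domain" checks (years)
_AGE_TOL = 1e-9


@dataclass(frozen=True)
class AgeDomain:
    """Closed age interval ``[a0, omega]`` with a uniform grid spacing.

    Parameters
    ----------
    a0 : float
        Lower age bound in years, ``>= 0``.
    omega : float
        Upper age bound in years.  The model interprets ``omega`` as the
        age by which the whole cohort is deceased; it must be finite.
    step : float, default 0.1
        Grid spacing in years for the uniform partition of
        ``[a0, omega]`` used by solvers and validators.
    """

    a0: float
    omega: float
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (self.a0 >= 0):
            raise ValidationError(f"a0 must be >= 0, got {self.a0}")
        if not (self.omega > self.a0):
            raise ValidationError(
                f"omega must exceed a0, got omega={self.omega}, a0={self.a0}"
            )
        if not (self.step > 0):
            raise ValidationError(f"step must be positive, got {self.step}")

    @property
    def n_intervals(self) -> int:
        return max(1, int(round((self.omega - self.a0) / self.step)))

    def grid(self) -> np.ndarray:
        """Uniform closed partition of ``[a0, omega]`` (endpoints included)."""
        return np.linspace(self.a0, self.omega, self.n_intervals + 1)

    def contains(self, a) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return (a >= self.a0 - _AGE_TOL) & (a <= self.omega + _AGE_TOL)

    def require(self, a) -> np.ndarray:
        """Return ``a`` as an array, raising :class:`DomainError` if any
        age lies outside ``[a0, omega]``."""
        a = np.asarray(a, dtype=float)
        ok = self.contains(a)
        if not np.all(ok):
            bad = np.atleast_1d(a)[~np.atleast_1d(ok)][0]
            raise DomainError(
                f"age {bad} outside domain [{self.a0}, {self.omega}]"
            )
        return a


class RateFunction:
    """A nonnegative age-dependent hazard on a finite age domain.

    Construct through one of the classmethods:

    - :meth:`gompertz` — ``rate(a) = exp(beta0 + beta1 * a)``,
    - :meth:`from_table` — piecewise-linear interpolation between
      ``(age, rate)`` knots; extrapolation beyond the knots is an error,
    - :meth:`constant` — an age-independent value (used e.g. for a
      constant relative risk),
    - :meth:`from_callable` — any vectorised callable.

    Nonnegativity is validated at construction by sampling the function
    on the domain grid; a single negative sample fails construction.
    Evaluating outside the domain raises :class:`DomainError`.
    """

    def __init__(
        self,
        kind: str,
        fn: Callable[[np.ndarray], np.ndarray],
        domain: AgeDomain,
        params: Optional[dict] = None,
        *,
        validate: bool = True,
    ) -> None:
        self.kind = kind
        self._fn = fn
        self.domain = domain
        self.params = dict(params or {})
        if validate:
            sample = np.asarray(fn(domain.grid()), dtype=float)
            if not np.all(np.isfinite(sample)):
                raise ValidationError(
                    f"{kind} rate is non-finite on the domain grid"
                )
            if np.any(sample < 0):
                a_bad = domain.grid()[np.argmax(sample < 0)]
                raise ValidationError(
                    f"{kind} rate is negative at age {a_bad}"
                )

    # -- constructors -----------------------------------------------------

    @classmethod
    def gompertz(cls, beta0: float, beta1: float, domain: AgeDomain) -> "RateFunction":
        """Gompertz hazard ``exp(beta0 + beta1 * a)``.

        ``beta0`` is the dimensionless log-hazard intercept, ``beta1``
        the per-year log-hazard slope.
        """
        b0, b1 = float(beta0), float(beta1)

        def fn(a: np.ndarray) -> np.ndarray:
            return np.exp(b0 + b1 * np.asarray(a, dtype=float))

        return cls("gompertz", fn, domain, {"beta0": b0, "beta1": b1})

    @classmethod
    def from_table(
        cls,
        ages: Sequence[float],
        values: Sequence[float],
        step: float = 0.1,
    ) -> "RateFunction":
        """Piecewise-linear hazard through ``(age, value)`` knots.

        The domain is the knot span ``[ages[0], ages[-1]]``; evaluation
        beyond it raises rather than extrapolating.
        """
        ages = np.asarray(ages, dtype=float)
        values = np.asarray(values, dtype=float)
        if ages.ndim != 1 or ages.shape != values.shape or ages.size < 2:
            raise ValidationError("need >= 2 (age, value) knots of equal length")
        if np.any(np.diff(ages) <= 0):
            raise ValidationError("knot ages must be strictly increasing")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("tabulated rates must be finite and >= 0")
        domain = AgeDomain(float(ages[0]), float(ages[-1]), step)

        def fn(a: np.ndarray) -> np.ndarray:
            return np.interp(np.asarray(a, dtype=float), ages, values)

        return cls(
            "tabulated", fn, domain, {"ages": ages, "values": values}
        )

    @classmethod
    def constant(cls, value: float, domain: AgeDomain) -> "RateFunction":
        """Age-independent hazard (degenerate rate; also used for constant R)."""
        v = float(value)
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"constant rate must be finite and >= 0, got {v}")

        def fn(a: np.ndarray) -> np.ndarray:
            return np.full_like(np.asarray(a, dtype=float), v)

        return cls("expression", fn, domain, {"value": v}, validate=False)

    @classmethod
    def from_callable(
        cls,
        fn: Callable[[np.ndarray], np.ndarray],
        domain: AgeDomain,
        name: str = "expression",
    ) -> "RateFunction":
        return cls("expression", fn, domain, {"name": name})

    # -- evaluation -------------------------------------------------------

    def __call__(self, a):
        a_arr = self.domain.require(a)
        out = np.asarray(self._fn(a_arr), dtype=float)
        if np.isscalar(a) or np.ndim(a) == 0:
            return float(out)
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RateFunction(kind={self.kind!r}, domain=[{self.domain.a0}, "
            f"{self.domain.omega}], params={self.params})"
        )


def evaluate_rate(rate: RateFunction, a):
    """Evaluate a hazard at age(s) ``a`` (per person-year)."""
    return rate(a)


class MortalityTag(str, Enum):
    """Which two pieces of mortality information accompany the incidence.

    The tag fixes the right-hand side of the prevalence ODE and with it
    the ODE's classification.
    """

    M_M0 = "m_m0"    # general mortality m and m0        -> linear
    M_M1 = "m_m1"    # general mortality m and m1        -> linear
    M0_M1 = "m0_m1"  # m0 and m1                         -> Riccati
    M0_R = "m0_r"    # m0 and relative risk R            -> Riccati
    M1_R = "m1_r"    # m1 and relative risk R            -> Riccati
    M_R = "m_r"      # general mortality m and R         -> Abelian

    @property
    def classification(self) -> str:
        if self in (MortalityTag.M_M0, MortalityTag.M_M1):
            return "linear"
        if self is MortalityTag.M_R:
            return "abelian"
        return "riccati"

    @property
    def component_names(self) -> tuple:
        return {
            MortalityTag.M_M0: ("m", "m0"),
            MortalityTag.M_M1: ("m", "m1"),
            MortalityTag.M0_M1: ("m0", "m1"),
            MortalityTag.M0_R: ("m0", "R"),
            MortalityTag.M1_R: ("m1", "R"),
            MortalityTag.M_R: ("m", "R"),
        }[self]


@dataclass
class MortalityInput:
    """Tagged pair of mortality information for the prevalence ODE.

    ``first`` and ``second`` are interpreted according to
    ``tag.component_names``; a relative risk in second position must be
    strictly positive on the domain grid.
    """

    tag: MortalityTag
    first: RateFunction
    second: RateFunction
    _components: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.tag = MortalityTag(self.tag)
        names = self.tag.component_names
        self._components = {names[0]: self.first, names[1]: self.second}
        if "R" in self._components:
            R = self._components["R"]
            sample = np.asarray(R._fn(R.domain.grid()), dtype=float)
            if np.any(sample <= 0):
                raise ValidationError("relative risk R must be > 0 everywhere")

    def component(self, name: str) -> RateFunction:
        try:
            return self._components[name]
        except KeyError:
            raise KeyError(
                f"tag {self.tag.value!r} carries {tuple(self._components)}, "
                f"not {name!r}"
            ) from None

    @property
    def classification(self) -> str:
        """ODE classification implied by the tag (linear/riccati/abelian)."""
        return self.tag.classification

    def implies_nonneg_excess(self, grid: np.ndarray):
        """Whether the input certifies the excess mortality m1 - m0 >= 0.

        Returns True/False where decidable from the components alone
        (m0&m1, or an R-bearing tag), None where it is not (m-bearing
        tags without R, since m already mixes in the unknown prevalence).
        """
        c = self._components
        if "m0" in c and "m1" in c:
            return bool(np.all(c["m1"](grid) >= c["m0"](grid) - 1e-15))
        if "R" in c:
            return bool(np.all(c["R"](grid) >= 1.0 - 1e-12))
        return None


def general_mortality(p, m0, m1):
    """General (population) mortality ``m = p*m1 + (1-p)*m0``.

    The convex combination of the mortalities of the diseased and the
    nondiseased, weighted by the prevalence ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValidationError("prevalence p must lie in [0, 1]")
    m0 = np.asarray(m0, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    if np.any(m0 < 0) or np.any(m1 < 0):
        raise ValidationError("mortality rates must be nonnegative")
    out = p * m1 + (1.0 - p) * m0
    if out.ndim == 0:
        return float(out)
    return out


def eaf(R):
    """Exposition attributable fraction ``(R - 1) / R``.

    Negative for protective factors (R < 1); always < 1.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValidationError("relative risk R must be > 0")
    out = (R - 1.0) / R
    if out.ndim == 0:
        return float(out)
    return out


def paf(p, R):
    """Population attributable fraction ``p(R-1) / (p(R-1) + 1)``.

    Zero when nobody is exposed (p = 0) or the exposure carries no
    excess risk (R = 1); equals the EAF at p = 1.
    """
    p = np.asarray(p, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValidationError("relative risk R must be > 0")
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValidationError("prevalence p must lie in [0, 1]")
    denom = p * (R - 1.0) + 1.0
    if np.any(denom <= 0):
        raise ValidationError("PAF denominator p(R-1)+1 must be positive")
    out = p * (R - 1.0) / denom
    if out.ndim == 0:
        return float(out)
    return out
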