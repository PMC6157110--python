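"""The inverse problem: incidence from prevalence plus mortality.

Solving the prevalence ODE for the incidence gives, for each of the
six mortality-information variants, an explicit estimator of the form

    i(a) = (dp/da) / (1 - p) + <mortality term>,

e.g. ``i = p'/(1-p) + p (m1 - m0)`` given both mortalities, or
``i = p'/(1-p) + m * PAF(p, R)`` given the general mortality and the
relative risk.  The derivative ``dp/da`` must be estimated from the
(possibly noisy) prevalence curve, which is exactly where the
inversion's ill-conditioning bites; both plain central differences and
a generalized-cross-validated smoothing spline are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .errors import SingularityError, ValidationError
from .rates import MortalityInput, MortalityTag, RateFunction

__all__ = [
    "DerivativeOptions",
    "IncidenceEstimate",
    "differentiate",
    "differentiate_arrays",
    "invert_arrays",
    "estimate_incidence",
    "scenario_sweep",
]

#: 1 - p below this raises (formula singular); below NEAR_SINGULAR_TOL
#: only a diagnostic flag is set
SINGULAR_TOL = 1e-9
NEAR_SINGULAR_TOL = 1e-3


@dataclass(frozen=True)
class DerivativeOptions:
    """How to differentiate a prevalence curve.

    method : "central_difference" (second-order central differences,
        one-sided second-order at the boundaries) or "smoothing_spline"
        (cubic smoothing spline; ``smoothing`` is the penalty ``lam``,
        chosen by generalized cross-validation when None).
    """

    method: str = "central_difference"
    smoothing: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in ("central_difference", "smoothing_spline"):
            raise ValidationError(f"unknown derivative method {self.method!r}")
        if self.smoothing is not None and self.smoothing < 0:
            raise ValidationError("smoothing parameter must be >= 0")


@dataclass
class IncidenceEstimate:
    """Estimated age-specific incidence with per-age diagnostics.

    flags: boolean arrays ``negative_estimate`` (formula produced a
    negative rate — usually a sign the assumed mortality information is
    inconsistent with the curve) and ``near_singular_denominator``
    (1 - p < 1e-3, estimate numerically delicate).  ``meta`` records
    the derivative settings, the mortality tag, and which boundary
    grid points used one-sided differences.
    """

    ages: np.ndarray
    i_hat: np.ndarray
    flags: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "i_hat": self.i_hat,
                "flag_negative": self.flags["negative_estimate"].astype(int),
                "flag_near_singular": self.flags["near_singular_denominator"].astype(int),
            }
        )


def differentiate_arrays(
    ages: np.ndarray, p: np.ndarray, opts: Optional[DerivativeOptions] = None
) -> np.ndarray:
    """Derivative estimate on raw arrays (no curve validation)."""
    opts = opts or DerivativeOptions()
    ages = np.asarray(ages, dtype=float)
    p = np.asarray(p, dtype=float)
    if ages.size < 3:
        raise ValidationError("need >= 3 grid points to differentiate")
    if opts.method == "central_difference":
        return np.gradient(p, ages, edge_order=2)
    spline = make_smoothing_spline(ages, p, lam=opts.smoothing)
    return spline.derivative()(ages)


def differentiate(curve, opts: Optional[DerivativeOptions] = None) -> np.ndarray:
    """Estimate dp/da on the curve's own grid (per year)."""
    return differentiate_arrays(curve.ages, curve.p, opts)


def _mortality_term(
    tag: MortalityTag, mort: MortalityInput, ages: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """The additive mortality correction of the incidence formula."""
    c = mort.component
    if tag is MortalityTag.M_M0:
        return c("m")(ages) - c("m0")(ages)
    if tag is MortalityTag.M_M1:
        # from dp/da = (1-p) i - p (m1 - m):  i = [p' + p(m1-m)]/(1-p)
        return p * (c("m1")(ages) - c("m")(ages)) / (1.0 - p)
    if tag is MortalityTag.M0_M1:
        return p * (c("m1")(ages) - c("m0")(ages))
    if tag is MortalityTag.M0_R:
        return p * c("m0")(ages) * (c("R")(ages) - 1.0)
    if tag is MortalityTag.M1_R:
        R = c("R")(ages)
        return p * c("m1")(ages) * (R - 1.0) / R
    # M_R: PAF term, computed raw so perturbation studies may probe
    # prevalence values outside [0, 1]
    R = c("R")(ages)
    return c("m")(ages) * p * (R - 1.0) / (p * (R - 1.0) + 1.0)


def invert_arrays(
    ages: np.ndarray, p: np.ndarray, dpda: np.ndarray, mort: MortalityInput
) -> np.ndarray:
    """Incidence formula applied to raw arrays (no curve validation).

    Used both by :func:`estimate_incidence` and by the ill-posedness
    experiment, whose perturbed curves may leave [0, 1].
    """
    one_minus_p = 1.0 - p
    if np.any(one_minus_p <= SINGULAR_TOL):
        a_bad = ages[np.argmax(one_minus_p <= SINGULAR_TOL)]
        raise SingularityError(
            f"prevalence reaches 1 at age {a_bad}: incidence formula singular"
        )
    return dpda / one_minus_p + _mortality_term(mort.tag, mort, ages, p)


def estimate_incidence(
    curve,
    mort: MortalityInput,
    opts: Optional[DerivativeOptions] = None,
    clip_nonnegative: bool = False,
) -> IncidenceEstimate:
    """Estimate the age-specific incidence from a prevalence curve.

    Negative estimates are retained and flagged unless
    ``clip_nonnegative`` is set (flags are computed before clipping).
    """
    opts = opts or DerivativeOptions()
    ages = np.asarray(curve.ages, dtype=float)
    p = np.asarray(curve.p, dtype=float)
    dpda = differentiate(curve, opts)
    i_hat = invert_arrays(ages, p, dpda, mort)
    flags = {
        "negative_estimate": i_hat < 0.0,
        "near_singular_denominator": (1.0 - p) < NEAR_SINGULAR_TOL,
    }
    if clip_nonnegative:
        i_hat = np.maximum(i_hat, 0.0)
    boundary = []
    if opts.method == "central_difference":
        boundary = [0, int(ages.size - 1)]
    meta = {
        "tag": mort.tag.value,
        "derivative_method": opts.method,
        "smoothing": opts.smoothing,
        "one_sided_boundary_indices": boundary,
        "clipped_nonnegative": clip_nonnegative,
    }
    return IncidenceEstimate(ages=ages, i_hat=i_hat, flags=flags, meta=meta)


def scenario_sweep(
    curve,
    m: RateFunction,
    R_values: Sequence[float],
    opts: Optional[DerivativeOptions] = None,
    clip_nonnegative: bool = False,
) -> List[IncidenceEstimate]:
    """Relative-risk scenario sweep under the general-mortality tag.

    One estimate per R, in input order.  Bracketing the unknown true
    relative risk with a low and a high scenario brackets the true
    incidence pointwise wherever p > 0 (sandwich principle).
    """
    if any(R <= 0 for R in R_values):
        raise ValidationError("all relative risks must be > 0")
    out = []
    for R in R_values:
        mort = MortalityInput(
            MortalityTag.M_R, m, RateFunction.constant(float(R), m.domain)
        )
        est = estimate_incidence(curve, mort, opts, clip_nonnegative)
        est.meta["R"] = float(R)
        out.append(est)
    return out
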