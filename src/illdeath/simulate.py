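"""Individual-level stochastic illness-death simulator.

Each of ``N0`` individuals starts nondiseased at age ``a0``.  The
sojourn in the nondiseased state ends at the first event of the
combined hazard ``i + m0``, sampled by inverting the tabulated
cumulative hazard; at the event age the competing risks are split with
probability ``i / (i + m0)`` for disease onset versus death.  Diseased
individuals then live out a residual lifetime under the hazard ``m1``.
Anyone still alive at ``omega`` is censored there.

Averaged over many individuals, the alive/diseased counts reproduce
the deterministic cohort system, and the fraction of diseased among
the living converges to the prevalence ODE solution — the simulator is
the empirical check on the deterministic theory, and doubles as a
generator of noisy synthetic prevalence curves shaped like claims-data
prevalence of an early-onset chronic disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.proportion import proportion_confint

from .errors import NumericError, ValidationError
from .forward import PrevalenceCurve
from .rates import AgeDomain, RateFunction

__all__ = [
    "IndividualRecord",
    "EmpiricalPrevalence",
    "simulate_cohort",
    "empirical_prevalence",
    "make_noisy_prevalence_fixture",
    "FINAL_STATES",
]

FINAL_STATES = ("nondiseased", "diseased", "dead_nondiseased", "dead_diseased")

#: spacing (years) of the fine grid used to tabulate cumulative hazards
HAZARD_TABLE_STEP = 0.01


@dataclass(frozen=True)
class IndividualRecord:
    """One simulated life course.

    ``onset_age``/``death_age`` are None when the event never happened
    before censoring at omega; ``final_state`` is one of
    ``FINAL_STATES``.
    """

    onset_age: Optional[float]
    death_age: Optional[float]
    final_state: str


def _cumulative_hazard(rate_values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate_values[1:] + rate_values[:-1]) * np.diff(grid))]
    )
    if not np.all(np.isfinite(cum)):
        raise NumericError("cumulative hazard is non-finite on the domain")
    return cum


def simulate_cohort(
    i: RateFunction,
    m0: RateFunction,
    m1: RateFunction,
    N0: int,
    domain: AgeDomain,
    seed: int,
) -> pd.DataFrame:
    """Simulate ``N0`` individual life courses.

    Returns a DataFrame with one row per individual and columns
    ``onset_age``, ``death_age`` (NaN when the event did not occur
    before omega) and ``final_state``.  The uniform variates are drawn
    as one ``(N0, 3)`` block from a single seeded generator, so the
    first k individuals are identical for any cohort size >= k and
    identical seeds give bit-identical output.
    """
    if N0 < 1:
        raise ValidationError("N0 must be >= 1")
    fine = AgeDomain(domain.a0, domain.omega, HAZARD_TABLE_STEP).grid()
    iv, m0v, m1v = i(fine), m0(fine), m1(fine)
    total = iv + m0v
    Lam0 = _cumulative_hazard(total, fine)
    Lam1 = _cumulative_hazard(m1v, fine)

    rng = np.random.default_rng(seed)
    U = rng.random((int(N0), 3))
    E1 = -np.log1p(-U[:, 0])

    # invert the combined cumulative hazard; E1 beyond its range means
    # the individual survives the nondiseased state to omega
    survived = E1 > Lam0[-1]
    T1 = np.interp(E1, Lam0, fine)
    T1[survived] = np.nan

    hazard_at = np.interp(T1[~survived], fine, total)
    inc_at = np.interp(T1[~survived], fine, iv)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_onset = np.where(hazard_at > 0, inc_at / np.where(hazard_at > 0, hazard_at, 1.0), 0.0)
    onset_event = np.zeros(U.shape[0], dtype=bool)
    onset_event[~survived] = U[~survived, 1] < p_onset

    onset_age = np.full(U.shape[0], np.nan)
    death_age = np.full(U.shape[0], np.nan)
    final_state = np.full(U.shape[0], "nondiseased", dtype=object)

    died_susceptible = ~survived & ~onset_event
    death_age[died_susceptible] = T1[died_susceptible]
    final_state[died_susceptible] = "dead_nondiseased"

    onset_age[onset_event] = T1[onset_event]
    E2 = -np.log1p(-U[onset_event, 2])
    target = np.interp(T1[onset_event], fine, Lam1) + E2
    beyond = target > Lam1[-1]
    T2 = np.interp(target, Lam1, fine)
    T2[beyond] = np.nan
    death_age[onset_event] = T2
    states1 = np.where(beyond, "diseased", "dead_diseased")
    final_state[onset_event] = states1

    return pd.DataFrame(
        {"onset_age": onset_age, "death_age": death_age, "final_state": final_state}
    )


@dataclass
class EmpiricalPrevalence:
    """Simulated prevalence: diseased fraction among the living, with
    Wilson 95% binomial intervals; 0 by convention where nobody is
    alive."""

    ages: np.ndarray
    p_hat: np.ndarray
    n_alive: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "p": self.p_hat,
                "n_alive": self.n_alive,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_curve(self) -> PrevalenceCurve:
        return PrevalenceCurve(ages=self.ages.copy(), p=self.p_hat.copy())


def empirical_prevalence(records: pd.DataFrame, age_grid) -> EmpiricalPrevalence:
    """Cross-sectional prevalence of the simulated cohort at each grid age."""
    if len(records) == 0:
        raise ValidationError("no records")
    age_grid = np.asarray(age_grid, dtype=float)
    onset = records["onset_age"].to_numpy(dtype=float)
    death = records["death_age"].to_numpy(dtype=float)

    alive_mat = ~(death[None, :] <= age_grid[:, None])  # NaN death -> alive
    diseased_mat = onset[None, :] <= age_grid[:, None]
    n_alive = alive_mat.sum(axis=1)
    n_dis = (alive_mat & diseased_mat).sum(axis=1)

    p_hat = np.zeros_like(age_grid)
    ci_low = np.zeros_like(age_grid)
    ci_high = np.zeros_like(age_grid)
    pos = n_alive > 0
    p_hat[pos] = n_dis[pos] / n_alive[pos]
    if np.any(pos):
        lo, hi = proportion_confint(n_dis[pos], n_alive[pos], method="wilson")
        ci_low[pos] = lo
        ci_high[pos] = hi
    return EmpiricalPrevalence(
        ages=age_grid, p_hat=p_hat, n_alive=n_alive, ci_low=ci_low, ci_high=ci_high
    )


# ---------------------------------------------------------------------------
# synthetic prevalence fixture
# ---------------------------------------------------------------------------

#: knots of the synthetic early-onset ("type-1-diabetes-like") prevalence
#: template: steep rise from birth to ~15, plateau near 20, second rise
#: to 30, plateau at 35, peak a few per 1000
_T1D_KNOTS = (
    (0.0, 0.0),
    (5.0, 0.0008),
    (10.0, 0.0016),
    (15.0, 0.0022),
    (17.5, 0.00228),
    (20.0, 0.0023),
    (25.0, 0.0028),
    (30.0, 0.0032),
    (32.5, 0.00328),
    (35.0, 0.0033),
)

#: effective per-age denominator behind the binomial-style noise
#: (claims data cover populations of this order per single year of age)
_FIXTURE_N_EFF = 500_000.0


def make_noisy_prevalence_fixture(
    template: str = "t1d_like",
    noise_sd_scale: float = 1.0,
    seed: Optional[int] = None,
    knots: Optional[Sequence] = None,
    domain: Optional[AgeDomain] = None,
) -> PrevalenceCurve:
    """Synthetic noisy prevalence curve for inverse-problem exercises.

    ``t1d_like`` is a monotone shape-preserving (PCHIP) interpolant of
    a synthetic template emulating the qualitative age profile of an
    early-onset chronic disease on ages 0-35; ``custom`` interpolates
    user-supplied ``(age, prevalence)`` knots.  Per-age Gaussian noise
    with binomial scale ``noise_sd_scale * sqrt(p(1-p)/n_eff)``
    (``n_eff`` = 5e5) is added and the result clamped to [0, 1].
    ``noise_sd_scale = 0`` returns the deterministic template.
    """
    if noise_sd_scale < 0:
        raise ValidationError("noise_sd_scale must be >= 0")
    if template == "t1d_like":
        pts = np.asarray(_T1D_KNOTS)
        domain = domain or AgeDomain(0.0, 35.0, 0.25)
    elif template == "custom":
        if knots is None:
            raise ValidationError("custom template needs knots")
        pts = np.asarray(knots, dtype=float)
        domain = domain or AgeDomain(float(pts[0, 0]), float(pts[-1, 0]), 0.25)
    else:
        raise ValidationError(f"unknown template {template!r}")
    interp = PchipInterpolator(pts[:, 0], pts[:, 1])
    grid = domain.grid()
    p = np.clip(interp(grid), 0.0, 1.0)
    if noise_sd_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd_scale * np.sqrt(np.maximum(p * (1.0 - p), 0.0) / _FIXTURE_N_EFF)
        p = np.clip(p + rng.normal(0.0, 1.0, grid.size) * sd, 0.0, 1.0)
    return PrevalenceCurve(
        ages=grid, p=p, meta={"template": template, "noise_sd_scale": noise_sd_scale}
    )
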