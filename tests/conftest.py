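import numpy as np
import pytest

from illdeath import AgeDomain, MortalityInput, MortalityTag, RateFunction
from illdeath.forward import solve_prevalence_ode


def ramp_incidence(domain, onset=30.0, slope=1.0 / 2000.0):
    """Piecewise-linear incidence i(a) = max(0, a - onset) * slope."""
    return RateFunction.from_callable(
        lambda a: np.maximum(0.0, np.asarray(a, dtype=float) - onset) * slope,
        domain,
        name="ramp",
    )


@pytest.fixture(scope="session")
def domain_ex1():
    return AgeDomain(30.0, 100.0, 0.1)


@pytest.fixture(scope="session")
def gompertz_mortalities(domain_ex1):
    """The worked-example Gompertz pair: log-hazard intercepts -10.7
    (nondiseased) and -10.0 (diseased), common slope 0.1/yr."""
    m0 = RateFunction.gompertz(-10.7, 0.1, domain_ex1)
    m1 = RateFunction.gompertz(-10.0, 0.1, domain_ex1)
    return m0, m1


@pytest.fixture(scope="session")
def example1_incidence(domain_ex1):
    return ramp_incidence(domain_ex1)


@pytest.fixture(scope="session")
def example1_mortality(gompertz_mortalities):
    m0, m1 = gompertz_mortalities
    return MortalityInput(MortalityTag.M0_M1, m0, m1)


@pytest.fixture(scope="session")
def example1_curve(example1_incidence, example1_mortality, domain_ex1):
    return solve_prevalence_ode(example1_incidence, example1_mortality, 0.0, domain_ex1)


def random_smooth_config(rng, domain):
    """A random smooth nonnegative (i, m0, m1) triple with m1 >= m0.

    Gompertz mortalities with moderate coefficients plus a smooth
    sinusoid-modulated incidence; scales chosen so cohorts neither die
    out immediately nor saturate at p = 1.
    """
    b0 = rng.uniform(-11.5, -9.5)
    slope = rng.uniform(0.05, 0.11)
    delta = rng.uniform(0.0, 1.2)
    m0 = RateFunction.gompertz(b0, slope, domain)
    m1 = RateFunction.gompertz(b0 + delta, slope, domain)
    amp = rng.uniform(0.0005, 0.02)
    freq = rng.uniform(0.02, 0.15)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    i = RateFunction.from_callable(
        lambda a, amp=amp, freq=freq, phase=phase: amp
        * (1.0 + 0.8 * np.sin(freq * np.asarray(a, dtype=float) + phase)),
        domain,
        name="random_smooth",
    )
    return i, m0, m1
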