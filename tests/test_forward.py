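import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from illdeath import (
    AgeDomain,
    MortalityInput,
    MortalityTag,
    RateFunction,
    closed_form_nondifferential,
    find_local_maximum,
    prevalence_of,
    solve_cohort_closed_form,
    solve_cohort_ode,
    solve_prevalence_ode,
    survival_curve,
)
from illdeath.errors import ValidationError
from illdeath.forward import CohortTrajectory, PrevalenceCurve, consistent_mortality_family

from conftest import ramp_incidence, random_smooth_config


def nondiff_mortality(mu, domain):
    m = RateFunction.constant(mu, domain)
    return MortalityInput(MortalityTag.M0_M1, m, m)


class TestCohortSolvers:
    def test_zero_rates_freeze_the_cohort(self):
        d = AgeDomain(0.0, 50.0, 0.5)
        zero = RateFunction.constant(0.0, d)
        for solver in (solve_cohort_closed_form, solve_cohort_ode):
            traj = solver(zero, zero, zero, 1000.0, 10.0, d)
            assert np.allclose(traj.S, 1000.0, atol=1e-8)
            assert np.allclose(traj.C, 10.0, atol=1e-10)

    def test_constant_incidence_exponential_susceptible_decay(self):
        d = AgeDomain(0.0, 10.0, 0.1)
        i = RateFunction.constant(0.02, d)
        zero = RateFunction.constant(0.0, d)
        for solver in (solve_cohort_closed_form, solve_cohort_ode):
            traj = solver(i, zero, zero, 1000.0, 0.0, d)
            assert traj.S[-1] == pytest.approx(1000.0 * math.exp(-0.2), rel=1e-8)

    def test_equal_mortalities_give_exponential_alive_decay(self):
        d = AgeDomain(0.0, 20.0, 0.1)
        mu = RateFunction.constant(0.05, d)
        zero = RateFunction.constant(0.0, d)
        traj = solve_cohort_ode(zero, mu, mu, 800.0, 200.0, d)
        expected = 1000.0 * np.exp(-0.05 * d.grid())
        assert np.allclose(traj.N, expected, rtol=1e-8)

    def test_closed_form_matches_ode_on_gompertz_example(
        self, example1_incidence, gompertz_mortalities, domain_ex1
    ):
        m0, m1 = gompertz_mortalities
        cf = solve_cohort_closed_form(example1_incidence, m0, m1, 1e5, 0.0, domain_ex1)
        ode = solve_cohort_ode(example1_incidence, m0, m1, 1e5, 0.0, domain_ex1)
        scale = np.maximum(np.abs(ode.S), 1.0)
        assert np.max(np.abs(cf.S - ode.S) / scale) < 1e-6
        scale_c = np.maximum(np.abs(ode.C), 1.0)
        assert np.max(np.abs(cf.C - ode.C) / scale_c) < 1e-6

    def test_counts_stay_nonnegative_and_n_is_sum(self, domain_ex1, gompertz_mortalities):
        m0, m1 = gompertz_mortalities
        i = ramp_incidence(domain_ex1)
        traj = solve_cohort_ode(i, m0, m1, 1000.0, 5.0, domain_ex1)
        assert np.all(traj.S >= 0) and np.all(traj.C >= 0)
        assert np.allclose(traj.N, traj.S + traj.C, rtol=1e-9)
        assert np.all(np.diff(traj.N) <= 1e-9)  # nonincreasing

    def test_empty_cohort_rejected(self):
        d = AgeDomain(0.0, 10.0, 0.1)
        zero = RateFunction.constant(0.0, d)
        with pytest.raises(ValidationError):
            solve_cohort_ode(zero, zero, zero, 0.0, 0.0, d)


class TestPrevalenceOf:
    def test_no_cases_gives_zero_prevalence(self):
        ages = np.linspace(0, 10, 11)
        traj = CohortTrajectory(ages, np.full(11, 5.0), np.zeros(11), np.full(11, 5.0))
        assert np.all(prevalence_of(traj).p == 0.0)

    def test_all_cases_gives_unit_prevalence(self):
        ages = np.linspace(0, 10, 11)
        traj = CohortTrajectory(ages, np.zeros(11), np.full(11, 3.0), np.full(11, 3.0))
        assert np.all(prevalence_of(traj).p == 1.0)

    def test_extinct_ages_use_zero_convention(self):
        ages = np.linspace(0, 10, 11)
        S = np.where(ages < 5, 2.0, 0.0)
        C = np.where(ages < 5, 2.0, 0.0)
        traj = CohortTrajectory(ages, S, C, S + C)
        p = prevalence_of(traj).p
        assert np.all(p[ages < 5] == 0.5)
        assert np.all(p[ages >= 5] == 0.0)


class TestPrevalenceODE:
    def test_zero_incidence_nondifferential_stays_zero(self):
        d = AgeDomain(0.0, 50.0, 0.5)
        zero = RateFunction.constant(0.0, d)
        curve = solve_prevalence_ode(zero, nondiff_mortality(0.01, d), 0.0, d)
        assert np.allclose(curve.p, 0.0, atol=1e-12)

    def test_constant_incidence_nondifferential_closed_form(self):
        d = AgeDomain(0.0, 10.0, 0.1)
        i = RateFunction.constant(0.01, d)
        curve = solve_prevalence_ode(i, nondiff_mortality(0.02, d), 0.0, d)
        assert curve.p[-1] == pytest.approx(1.0 - math.exp(-0.1), rel=1e-8)

    def test_worked_example_peaks_near_eighty(self, example1_curve):
        age, value = find_local_maximum(example1_curve)
        assert age == pytest.approx(80.0, abs=5.0)
        assert 0.0 < value < 1.0

    def test_classification_reported(self, example1_curve):
        assert example1_curve.meta["classification"] == "riccati"

    def test_invalid_initial_prevalence_rejected(self, example1_incidence, example1_mortality, domain_ex1):
        with pytest.raises(ValidationError):
            solve_prevalence_ode(example1_incidence, example1_mortality, 1.5, domain_ex1)

    def test_negative_excess_mortality_warns_not_raises(self):
        d = AgeDomain(0.0, 60.0, 0.2)
        i = RateFunction.constant(0.03, d)
        m0 = RateFunction.constant(0.05, d)
        m1 = RateFunction.constant(0.01, d)  # protective disease: delta_m < 0
        mort = MortalityInput(MortalityTag.M0_M1, m0, m1)
        curve = solve_prevalence_ode(i, mort, 0.0, d)
        assert np.all((curve.p >= 0) & (curve.p <= 1))

    def test_closed_form_nondifferential_agreement(self):
        d = AgeDomain(0.0, 100.0, 0.1)
        i = RateFunction.gompertz(-6.0, 0.03, d)
        cf = closed_form_nondifferential(i, 0.0, d)
        ode = solve_prevalence_ode(i, nondiff_mortality(0.0, d), 0.0, d)
        assert np.max(np.abs(cf.p - ode.p)) < 1e-8

    def test_closed_form_trivial_cases(self):
        d = AgeDomain(0.0, 30.0, 0.5)
        zero = RateFunction.constant(0.0, d)
        assert np.allclose(closed_form_nondifferential(zero, 0.2, d).p, 0.2)
        i = RateFunction.constant(0.05, d)
        assert np.allclose(closed_form_nondifferential(i, 1.0, d).p, 1.0)

    def test_pointwise_larger_incidence_gives_larger_prevalence(self):
        d = AgeDomain(0.0, 60.0, 0.2)
        lo = RateFunction.constant(0.005, d)
        hi = RateFunction.gompertz(math.log(0.005) + 0.3, 0.01, d)
        p_lo = closed_form_nondifferential(lo, 0.0, d).p
        p_hi = closed_form_nondifferential(hi, 0.0, d).p
        assert np.all(p_hi >= p_lo - 1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_prevalence_bounded_for_random_nonnegative_rates(self, seed):
        """Solutions of the prevalence ODE stay in [0, 1] whenever the
        rates are nonnegative with nonnegative excess mortality."""
        rng = np.random.default_rng(seed)
        d = AgeDomain(20.0, 90.0, 0.5)
        i, m0, m1 = random_smooth_config(rng, d)
        p0 = float(rng.uniform(0.0, 0.5))
        curve = solve_prevalence_ode(
            i, MortalityInput(MortalityTag.M0_M1, m0, m1), p0, d
        )
        assert np.all(curve.p >= -1e-9) and np.all(curve.p <= 1 + 1e-9)


class TestSurvivalCurve:
    def test_zero_mortality_keeps_cohort(self):
        d = AgeDomain(0.0, 40.0, 0.5)
        N = survival_curve(RateFunction.constant(0.0, d), 500.0, d).N
        assert np.allclose(N, 500.0)

    def test_constant_hazard_exponential_decay(self):
        d = AgeDomain(0.0, 10.0, 0.1)
        N = survival_curve(RateFunction.constant(0.1, d), 100.0, d).N
        assert N[-1] == pytest.approx(100.0 * math.exp(-1.0), rel=1e-10)

    def test_gompertz_hazard_matches_ode_oracle(self):
        from scipy.integrate import solve_ivp

        d = AgeDomain(0.0, 100.0, 0.1)
        m = RateFunction.gompertz(-10.0, 0.1, d)
        N = survival_curve(m, 1.0, d).N
        sol = solve_ivp(
            lambda a, y: [-m(a) * y[0]],
            (0.0, 100.0),
            [1.0],
            t_eval=d.grid(),
            rtol=1e-11,
            atol=1e-14,
        )
        assert np.max(np.abs(N - sol.y[0]) / np.abs(sol.y[0])) < 1e-8

    def test_nonincreasing(self, domain_ex1):
        m = RateFunction.gompertz(-10.5, 0.1, domain_ex1)
        N = survival_curve(m, 1e5, domain_ex1).N
        assert np.all(np.diff(N) <= 0)

    def test_nonpositive_n0_rejected(self, domain_ex1):
        m = RateFunction.constant(0.01, domain_ex1)
        with pytest.raises(ValidationError):
            survival_curve(m, 0.0, domain_ex1)


class TestCorrespondence:
    """The cohort system, the scalar prevalence ODE and the survival
    ODE describe one and the same model, in both directions."""

    def test_system_to_scalar(self, example1_incidence, gompertz_mortalities, domain_ex1):
        m0, m1 = gompertz_mortalities
        S0, C0 = 9.0e4, 1.0e4
        traj = solve_cohort_ode(example1_incidence, m0, m1, S0, C0, domain_ex1)
        p_sys = prevalence_of(traj).p
        mort = MortalityInput(MortalityTag.M0_M1, m0, m1)
        p_scalar = solve_prevalence_ode(
            example1_incidence, mort, C0 / (S0 + C0), domain_ex1
        ).p
        assert np.max(np.abs(p_sys - p_scalar)) < 1e-6

    def test_scalar_to_system(self, example1_incidence, gompertz_mortalities, domain_ex1):
        m0, m1 = gompertz_mortalities
        p0, N0 = 0.1, 1.0e5
        fam = consistent_mortality_family(
            example1_incidence, m0, m1, p0, domain_ex1
        )
        p = solve_prevalence_ode(
            example1_incidence, fam[MortalityTag.M0_M1], p0, domain_ex1
        ).p
        N = survival_curve(fam[MortalityTag.M_M0].component("m"), N0, domain_ex1).N
        traj = solve_cohort_ode(
            example1_incidence, m0, m1, (1 - p0) * N0, p0 * N0, domain_ex1
        )
        scale = np.maximum(traj.N, 1e-6 * N0)
        assert np.max(np.abs((1 - p) * N - traj.S) / scale) < 1e-5
        assert np.max(np.abs(p * N - traj.C) / scale) < 1e-5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_for_random_smooth_rates(self, seed):
        rng = np.random.default_rng(seed)
        d = AgeDomain(20.0, 90.0, 0.25)
        i, m0, m1 = random_smooth_config(rng, d)
        S0, C0 = 1000.0 * rng.uniform(0.5, 1.0), 1000.0 * rng.uniform(0.0, 0.3)
        traj = solve_cohort_ode(i, m0, m1, S0, C0, d)
        mort = MortalityInput(MortalityTag.M0_M1, m0, m1)
        p_scalar = solve_prevalence_ode(i, mort, C0 / (S0 + C0), d).p
        assert np.max(np.abs(prevalence_of(traj).p - p_scalar)) < 1e-6


class TestTagConsistency:
    def test_all_six_variants_agree(
        self, example1_incidence, gompertz_mortalities, domain_ex1
    ):
        m0, m1 = gompertz_mortalities
        fam = consistent_mortality_family(example1_incidence, m0, m1, 0.0, domain_ex1)
        reference = solve_prevalence_ode(
            example1_incidence, fam[MortalityTag.M0_M1], 0.0, domain_ex1
        ).p
        for tag, mort in fam.items():
            p = solve_prevalence_ode(example1_incidence, mort, 0.0, domain_ex1).p
            assert np.max(np.abs(p - reference)) < 1e-6, tag
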