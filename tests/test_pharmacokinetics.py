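"""Release kernels, normalization, uptake, and free-drug reaction terms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, special

from nanocell import (
    AdministrationSchedule,
    DrugFields,
    ReleaseProfile,
    gamma_kernel,
    normalization_constant,
    release_rate,
    rhs_c,
    rhs_d,
    single_window_normalization,
    uptake_rate,
    vessel_concentration,
)
from nanocell.pharmacokinetics import profile_table


class TestSchedule:
    def test_defaults_match_protocol(self, schedule):
        assert schedule.dose_times == (8.0, 10.0, 12.0, 14.0, 16.0)
        assert schedule.horizon == 17.0

    @pytest.mark.parametrize("times,horizon", [
        ((), 17.0), ((8.0, 8.0), 17.0), ((10.0, 8.0), 17.0), ((8.0, 18.0), 17.0),
    ])
    def test_invalid_schedules_rejected(self, times, horizon):
        with pytest.raises(ValueError):
            AdministrationSchedule(times, horizon)


class TestGammaKernel:
    def test_zero_before_and_at_dose(self):
        assert gamma_kernel(7.9, 8.0, 0.3, 15.0) == 0.0
        assert gamma_kernel(8.0, 8.0, 0.3, 15.0) == 0.0  # power-law prefactor

    @pytest.mark.parametrize("p,tau", [(0.3, 15.0), (0.1, 2.0), (0.8, 15.0)])
    def test_argmax_at_p_tau_after_dose(self, p, tau):
        t = np.linspace(8.0, 8.0 + 10 * p * tau + 1.0, 200001)
        tmax = t[np.argmax(gamma_kernel(t, 8.0, p, tau))]
        assert tmax - 8.0 == pytest.approx(p * tau, abs=5e-3)

    @given(st.floats(0.05, 2.0), st.floats(0.5, 20.0), st.floats(0.0, 30.0))
    def test_nonnegative_and_causal(self, p, tau, t):
        v = gamma_kernel(t, 10.0, p, tau)
        assert v >= 0.0
        if t < 10.0:
            assert v == 0.0


class TestNormalization:
    def test_single_dose_untruncated_matches_complete_gamma(self):
        # closed-form oracle: tau^(p+1) Gamma(p+1) for one infinite window
        for p, tau in ((0.3, 15.0), (0.1, 2.0), (0.8, 15.0)):
            sched = AdministrationSchedule((0.0,), tau * 60.0)
            n = normalization_constant(sched, p, tau)
            assert n == pytest.approx(tau ** (p + 1) * special.gamma(p + 1), rel=1e-8)

    def test_truncated_window_matches_incomplete_gamma(self, schedule):
        total = sum(
            single_window_normalization(0.3, 15.0, schedule.horizon - t_i)
            for t_i in schedule.dose_times
        )
        assert normalization_constant(schedule, 0.3, 15.0) == pytest.approx(total, rel=1e-10)

    def test_identical_windows_add_linearly(self):
        one = normalization_constant(AdministrationSchedule((0.0,), 400.0), 0.5, 2.0)
        three = normalization_constant(
            AdministrationSchedule((0.0, 500.0, 1000.0), 1400.0), 0.5, 2.0)
        assert three == pytest.approx(3.0 * one, rel=1e-8)

    @pytest.mark.parametrize("p,tau", [(0.3, 15.0), (0.1, 2.0), (0.8, 15.0)])
    def test_normalized_release_integrates_to_one(self, schedule, p, tau):
        # the defining condition: sum_i int_0^tf RP dt = 1, checked by an
        # independent quadrature of the normalized profile
        prof = ReleaseProfile(p=p, tau=tau).normalize(schedule)
        total = 0.0
        for t_i in schedule.dose_times:
            val, _ = integrate.quad(lambda t: prof(t, t_i), t_i, schedule.horizon,
                                    limit=200)
            total += val
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_time_unit_invariance(self, schedule):
        # profiles are densities: converting t and tau by rho and
        # renormalizing rescales values by exactly 1/rho
        rho = 0.35
        prof_days = ReleaseProfile(p=0.3, tau=15.0).normalize(schedule)
        sched_dimless = AdministrationSchedule(
            tuple(rho * t for t in schedule.dose_times), rho * schedule.horizon)
        prof_dimless = ReleaseProfile(p=0.3, tau=rho * 15.0).normalize(sched_dimless)
        for t in (8.5, 11.0, 16.9):
            assert prof_dimless(rho * t, rho * 8.0) == pytest.approx(
                prof_days(t, 8.0) / rho, rel=1e-10)

    def test_unnormalized_profile_refuses_evaluation(self):
        with pytest.raises(ValueError, match="not normalized"):
            ReleaseProfile(p=0.3, tau=15.0)(9.0, 8.0)


class TestVesselConcentration:
    def test_step_and_decay(self):
        assert vessel_concentration(7.0, 8.0, 15.0) == 0.0
        assert vessel_concentration(8.0, 8.0, 15.0) == 1.0
        assert vessel_concentration(23.0, 8.0, 15.0) == pytest.approx(np.exp(-1.0), rel=1e-12)


class TestUptake:
    def test_no_vessels_no_delivery(self, lung):
        m = np.zeros((3, 3, 3))
        assert np.all(uptake_rate(m, 1.0, lung) == 0.0)

    def test_table_value_product(self, lung):
        # delta * Gamma * kernel at m = 1, m_lim = 2
        val = uptake_rate(np.array(1.0), 1.0, lung)
        assert val == pytest.approx(0.8 * np.exp(-0.25), rel=1e-12)

    def test_uptake_below_peak_at_tumor_vessel_density(self, lung):
        assert uptake_rate(np.array(1.97), 1.0, lung) < uptake_rate(np.array(1.0), 1.0, lung)


class TestReleaseRate:
    def test_absent_profile_contributes_nothing(self, schedule):
        fields = DrugFields()
        fields.add_administration((2, 2, 2), 8.0)
        assert release_rate(12.0, fields, None, schedule) == 0.0

    def test_unit_carrier_recovers_profile(self, schedule):
        prof = ReleaseProfile(p=0.3, tau=15.0).normalize(schedule)
        fields = DrugFields()
        fields.add_administration((2, 2, 2), 8.0)
        fields.carriers[0][:] = 1.0
        out = release_rate(12.0, fields, prof, schedule)
        np.testing.assert_allclose(out, prof(12.0, 8.0))

    def test_before_first_dose_zero(self, schedule):
        prof = ReleaseProfile(p=0.3, tau=15.0).normalize(schedule)
        fields = DrugFields()
        fields.add_administration((2, 2, 2), 8.0)
        fields.carriers[0][:] = 1.0
        assert np.all(np.asarray(release_rate(5.0, fields, prof, schedule)) == 0.0)

    def test_two_doses_sum_term_by_term(self, schedule):
        prof = ReleaseProfile(p=0.3, tau=15.0).normalize(schedule)
        fields = DrugFields()
        for t_i in (8.0, 10.0):
            fields.add_administration((2, 2, 2), t_i)
            fields.carriers[-1][:] = 1.0
        out = release_rate(12.0, fields, prof, schedule)
        by_hand = prof(12.0, 8.0) + prof(12.0, 10.0)  # brute-force sum
        np.testing.assert_allclose(out, by_hand, rtol=1e-12)

    def test_carrier_bookkeeping_mismatch_rejected(self, schedule):
        prof = ReleaseProfile(p=0.3, tau=15.0).normalize(schedule)
        fields = DrugFields()
        fields.add_administration((2, 2, 2), 8.0)
        fields.carrier_times.append(10.0)
        with pytest.raises(ValueError, match="out of sync"):
            release_rate(12.0, fields, prof, schedule)


class TestFreeDrugReactions:
    def test_pure_decay_without_source(self, lung):
        c = np.full((2, 2, 2), 0.7)
        np.testing.assert_allclose(rhs_c(c, 0.0, lung), -lung.nuC_t * c)
        d = np.full((2, 2, 2), 0.3)
        np.testing.assert_allclose(rhs_d(d, 0.0, np.zeros_like(d), lung), -lung.nuD_t * d)

    def test_homogeneous_steady_states(self, lung):
        R = 0.4
        c_star = lung.lambdaC_t * R / lung.nuC_t
        assert rhs_c(np.array(c_star), R, lung) == pytest.approx(0.0, abs=1e-9)
        m = 1.3
        d_star = lung.lambdaD_t * R / (lung.mu_t * m + lung.nuD_t)
        assert rhs_d(np.array(d_star), R, np.array(m), lung) == pytest.approx(0.0, abs=1e-9)

    def test_source_amplitude(self, lung):
        assert rhs_c(np.array(0.0), 1.0, lung) == pytest.approx(1300.0)

    def test_trapping_ratio_between_collapsed_and_intact_vasculature(self, lung):
        # equal source: steady free chemo at the tumor vessel density is
        # about half that at normalized density - collapse traps the drug
        def d_star(m):
            return lung.lambdaD_t / (lung.mu_t * m + lung.nuD_t)
        assert d_star(1.97) / d_star(1.0) == pytest.approx(8.1 / 15.86, abs=1e-3)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_steady_state_monotone_decreasing_in_vessel_density(self, m1, m2):
        from nanocell import default_parameters

        p = default_parameters("lung")
        R = 1.0

        def d_star(m):
            return float(p.lambdaD_t * R / (p.mu_t * m + p.nuD_t))

        if m1 < m2:
            assert d_star(m1) > d_star(m2)


def test_profile_table_schema(schedule):
    prof = ReleaseProfile(p=0.1, tau=2.0, label="liposome").normalize(schedule)
    df = profile_table({"L_C/C": prof}, schedule, tau_D=15.0)
    assert set(df.columns) == {"day", "value", "agent", "arm"}
    assert set(df["agent"]) == {"C", "Gamma"}
    assert (df["value"] >= 0).all()
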