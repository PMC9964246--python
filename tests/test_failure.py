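"""Weibull damage/repair model: closed-form anchors, CDF/pdf consistency,
repair dominance, quadrature convergence and monotonicity properties."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from tibiofem.failure import (
    FailureParams,
    failure_curve,
    failure_pdf,
    failure_probability,
    failure_with_repair,
    repair_probability,
    sensitivity_analysis,
    time_to_failure,
)

P = FailureParams()

# frozen from a 25-digit symbolic evaluation of
# (1.0 * 1.61 / 6000) * (1.03 * 0.23)^(-12.9) days / 365.25
T_FAIL_023_161 = 85.93995416416645


class TestCharacteristicLife:
    def test_frozen_high_precision_value(self):
        assert time_to_failure(0.23, 1.61, P) == pytest.approx(
            T_FAIL_023_161, rel=1e-12
        )

    def test_unit_cycle_case(self):
        """B*eps = 1 collapses the power law to one cycle, so the life is one
        stride's share of a day."""
        eps = 1.0 / P.weibull_coefficient
        t = time_to_failure(eps, 1.5, P)
        assert t == pytest.approx(1.5 / 6000.0 / 365.25, rel=1e-12)

    def test_strictly_decreasing_in_strain(self):
        assert time_to_failure(0.25, 1.61, P) < time_to_failure(0.19, 1.61, P)

    def test_shorter_stride_shortens_life(self):
        # more daily cycles for the same distance
        assert time_to_failure(0.23, 1.40, P) < time_to_failure(0.23, 1.80, P)

    def test_zero_strain_sentinel(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert time_to_failure(0.0, 1.61, P) == np.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            time_to_failure(0.2, 0.0, P)
        with pytest.raises(ValueError):
            time_to_failure(-0.1, 1.6, P)


class TestFailureProbability:
    def test_characteristic_point_is_63_2_percent(self):
        assert failure_probability(10.0, P.v_ref, 10.0, P) == pytest.approx(
            1.0 - np.exp(-1.0), rel=1e-12
        )

    def test_zero_time(self):
        assert failure_probability(0.0, P.v_ref, 10.0, P) == 0.0

    def test_doubled_volume_closed_form(self):
        assert failure_probability(10.0, 2 * P.v_ref, 10.0, P) == pytest.approx(
            1.0 - np.exp(-2.0), rel=1e-12
        )

    def test_volume_scale_property(self):
        """Doubling V/V_ref maps P -> 1 - (1-P)^2 at fixed t/t_fail."""
        t, tf, v = 17.0, 40.0, 120.0
        p1 = failure_probability(t, v, tf, P)
        p2 = failure_probability(t, 2 * v, tf, P)
        assert p2 == pytest.approx(1.0 - (1.0 - p1) ** 2, rel=1e-12)

    @given(
        t=st.floats(0.0, 200.0),
        v=st.floats(0.0, 5000.0),
        tf=st.floats(0.1, 2000.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bounds_property(self, t, v, tf):
        p = failure_probability(t, v, tf, P)
        assert 0.0 <= p <= 1.0

    def test_nondecreasing_in_time_and_volume(self):
        ts = np.linspace(0, 80, 50)
        p = failure_probability(ts, 150.0, 30.0, P)
        assert (np.diff(p) >= 0).all()
        vs = np.linspace(0, 1000, 50)
        pv = [failure_probability(20.0, v, 30.0, P) for v in vs]
        assert (np.diff(pv) >= 0).all()


class TestRepairProbability:
    def test_characteristic_point_is_63_2_percent(self):
        assert repair_probability(P.t_rep, P) == pytest.approx(
            1.0 - np.exp(-1.0), rel=1e-12
        )

    def test_half_time_direct_evaluation(self):
        assert repair_probability(2.5, P) == pytest.approx(
            1.0 - np.exp(-(0.5**5.2)), rel=1e-12
        )

    def test_zero_time(self):
        assert repair_probability(0.0, P) == 0.0

    def test_nondecreasing(self):
        p = repair_probability(np.linspace(0, 42, 200), P)
        assert (np.diff(p) >= 0).all()


class TestDensity:
    def test_zero_at_origin(self):
        # shape k/m > 1, so the density vanishes at t = 0
        assert failure_pdf(0.0, 100.0, 30.0, P) == 0.0

    def test_quadrature_matches_cdf(self):
        """Integral of the density over [0, 10 t_fail] equals the CDF there."""
        tf, v = 12.0, P.v_ref
        integral, _ = quad(
            lambda t: failure_pdf(t, v, tf, P), 0.0, 10.0 * tf, limit=400
        )
        assert integral == pytest.approx(
            failure_probability(10.0 * tf, v, tf, P), abs=1e-6
        )

    def test_central_difference_matches_density(self):
        tf, v = 12.0, 150.0
        h = 1e-6
        num = (
            failure_probability(tf + h, v, tf, P)
            - failure_probability(tf - h, v, tf, P)
        ) / (2 * h)
        assert num == pytest.approx(failure_pdf(tf, v, tf, P), rel=1e-6)


class TestRepairIntegral:
    times = np.linspace(0.0, 42.0, 505)

    def test_dominance_everywhere(self):
        for tf, v in [(5.0, 400.0), (30.0, 150.0), (300.0, 78.5), (1000.0, 500.0)]:
            p = failure_probability(self.times, v, tf, P)
            pr = failure_with_repair(self.times, v, tf, P)
            assert (pr <= p + 1e-12).all()
            assert (pr >= 0).all() and (np.diff(pr) >= -1e-15).all()

    @given(
        tf=st.floats(0.5, 2000.0),
        v=st.floats(1.0, 3000.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_dominance_property(self, tf, v):
        p = failure_probability(self.times, v, tf, P)
        pr = failure_with_repair(self.times, v, tf, P, check_convergence=False)
        assert (pr <= p + 1e-12).all()
        assert (pr <= 1.0).all() and (pr >= 0.0).all()

    def test_repair_disabled_limit(self):
        """t_rep -> infinity reduces the integral to the no-repair CDF."""
        params = dataclasses.replace(P, t_rep=1e9)
        tf, v = 25.0, 200.0
        pr = failure_with_repair(self.times, v, tf, params)
        p = failure_probability(self.times, v, tf, params)
        assert pr[-1] == pytest.approx(p[-1], abs=5e-4)

    def test_instant_repair_limit(self):
        params = dataclasses.replace(P, t_rep=1e-3, dt=1e-4)
        times = np.linspace(0.0, 42.0, 2001)
        pr = failure_with_repair(times, 200.0, 25.0, params, check_convergence=False)
        assert pr[-1] < 0.01

    def test_richardson_convergence(self):
        """Halving dt moves the horizon value by < 1e-4."""
        tf, v = 28.0, 500.0  # obese-scale inputs, the harder case
        coarse = failure_with_repair(self.times, v, tf, P, check_convergence=False)
        fine_grid = np.linspace(0.0, 42.0, 2 * (self.times.size - 1) + 1)
        fine = failure_with_repair(fine_grid, v, tf, P, check_convergence=False)
        assert abs(fine[-1] - coarse[-1]) < 1e-4


class TestCurve:
    def test_grid_and_invariants(self):
        curve = failure_curve(300.0, 50.0, P)
        assert curve.times[0] == 0.0 and curve.times[-1] == P.horizon
        assert curve.p_fail[0] == 0.0 and curve.p_fail_repair[0] == 0.0
        assert (np.diff(curve.p_fail) >= 0).all()
        assert (curve.p_fail_repair <= curve.p_fail + 1e-12).all()

    def test_infinite_life_gives_zero_curves(self):
        curve = failure_curve(300.0, np.inf, P)
        assert not curve.p_fail.any() and not curve.p_fail_repair.any()

    def test_participant_wiring_monotone_in_stride(self, default_grid, default_geometry):
        """Identical mechanics, shorter stride -> more daily cycles -> higher
        probability at the horizon."""
        from tibiofem.cohort import ParticipantProfile, synth_stance_waveform
        from tibiofem.contact import solve_contact
        from tibiofem.failure import participant_failure

        sol = solve_contact(default_grid, default_geometry, 1800.0, 15.0)

        def profile(stride):
            return ParticipantProfile(
                id="x", group="healthy_weight", mass=70.0, stature=1.65,
                velocity=1.4, stride_length=stride, peak_force_n=1800.0,
                flexion_at_peak=15.0, vasti_peaks_bw=(0.5, 0.45, 0.4),
                stance_waveform=synth_stance_waveform(1800.0),
            )

        short = participant_failure(profile(1.40), sol, P)
        long = participant_failure(profile(1.80), sol, P)
        assert short.t_fail < long.t_fail
        assert short.p_fail[-1] > long.p_fail[-1]

    def test_zero_strain_participant(self, coarse_grid, coarse_geometry):
        from tibiofem.cohort import ParticipantProfile, synth_stance_waveform
        from tibiofem.contact import solve_contact
        from tibiofem.failure import participant_failure

        sol = solve_contact(coarse_grid, coarse_geometry, 0.0)
        prof = ParticipantProfile(
            id="x", group="healthy_weight", mass=70.0, stature=1.65,
            velocity=1.4, stride_length=1.6, peak_force_n=0.0,
            flexion_at_peak=15.0, vasti_peaks_bw=(0.0, 0.0, 0.0),
            stance_waveform=synth_stance_waveform(0.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = participant_failure(prof, sol, P)
        assert not curve.p_fail.any()


class TestSensitivity:
    def test_zero_width_range(self, coarse_geometry):
        table = sensitivity_analysis(
            coarse_geometry, 1500.0, 10.0, {"cartilage_height": np.array([5.0, 5.0])}
        )
        assert table["peak_strain"].nunique() == 1

    def test_modulus_sweep_monotone(self, coarse_geometry):
        table = sensitivity_analysis(
            coarse_geometry, 1500.0, 10.0,
            {"moduli.femoral": np.linspace(5.0, 14.0, 4)},
        )
        strains = table["peak_strain"].to_numpy()
        assert (np.diff(strains) <= 1e-12).all()

    def test_sweep_matches_direct_rerun(self, coarse_geometry):
        """Sweep rows equal an independent re-run of the contact solve."""
        from tibiofem.contact import build_element_grid, solve_contact

        values = np.array([4.0, 5.0, 6.5])
        table = sensitivity_analysis(
            coarse_geometry, 1500.0, 10.0, {"cartilage_height": values}
        )
        for value, row_strain in zip(values, table["peak_strain"]):
            geo = dataclasses.replace(coarse_geometry, cartilage_height=float(value))
            sol = solve_contact(build_element_grid(geo), geo, 1500.0, 10.0)
            assert row_strain == sol.peak_strain

    def test_failures_reported_not_fatal(self, coarse_geometry):
        # absurd force saturates the solver at some sweep points
        table = sensitivity_analysis(
            coarse_geometry, 1500.0, 10.0, {},
            force_range=np.array([1500.0, 1e9]),
        )
        assert np.isnan(table["peak_strain"].iloc[-1])
        assert not np.isnan(table["peak_strain"].iloc[0])
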