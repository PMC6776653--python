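"""SRTM forward model, basis/NLS fitters and SUV utilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal
from scipy.integrate import solve_ivp

from morpet.kinetics import (
    BasisFitter,
    FrameSchedule,
    SRTMParams,
    TimeActivityCurve,
    default_schedule,
    fit_srtm_basis,
    fit_srtm_nls,
    srtm_forward,
    suv_auc,
)


class TestFrameSchedule:
    def test_packaged_26_frame_schedule(self):
        sched = default_schedule()
        assert sched.n_frames == 26
        assert sched.total_duration == 5400.0
        durs = sched.frame_durations
        assert [(d, list(durs).count(d)) for d in (15, 60, 120, 300, 600)] == [
            (15, 8), (60, 3), (120, 5), (300, 5), (600, 5)]
        assert np.allclose(sched.frame_starts[1:],
                           sched.frame_starts[:-1] + sched.frame_durations[:-1])

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            FrameSchedule(np.array([0.0, 20.0]), np.array([15.0, 15.0]))
        with pytest.raises(ValueError, match="positive"):
            FrameSchedule(np.array([0.0, 15.0]), np.array([15.0, 0.0]))

    def test_roundtrip_json(self, tmp_path, schedule):
        path = tmp_path / "sched.json"
        schedule.to_json(path)
        back = FrameSchedule.from_json(path)
        assert np.allclose(back.frame_starts, schedule.frame_starts)
        assert np.allclose(back.frame_durations, schedule.frame_durations)


class TestForwardModel:
    def test_identity_when_r1_one_and_bp_zero(self, ref_tac):
        # coefficient of the convolution term vanishes and R1 = 1
        out = srtm_forward(SRTMParams(r1=1.0, k2=0.37, bp_nd=0.0), ref_tac)
        np.testing.assert_allclose(out.values, ref_tac.values, atol=1e-10)

    def test_domain_errors(self, ref_tac):
        with pytest.raises(ValueError, match="BP_ND"):
            srtm_forward(SRTMParams(1.0, 0.1, -1.0), ref_tac)
        with pytest.raises(ValueError, match="k2"):
            srtm_forward(SRTMParams(1.0, 0.0, 1.0), ref_tac)
        with pytest.raises(ValueError, match="R1"):
            srtm_forward(SRTMParams(0.0, 0.1, 1.0), ref_tac)

    def test_matches_ode_oracle(self, ref_tac, schedule):
        """Frame-averaged solution of dC_T/dt = R1 dC_R/dt + k2 C_R - k2a C_T.

        The oracle reconstructs the same mean-preserving piecewise-linear
        reference curve and integrates the two-parameter differential form of
        the model with an independent ODE solver; agreement is required to
        0.1% per frame.
        """
        r1, k2, bp = 1.0, 0.1, 1.7
        k2a = k2 / (1.0 + bp)
        v = ref_tac.values
        b = np.concatenate([[0.0], signal.lfilter([2.0], [1.0, 1.0], v)])
        bt = np.concatenate([schedule.frame_starts, [schedule.frame_ends[-1]]]) / 60.0

        def cr(t):
            return np.interp(t, bt, b)

        def dcr(t):
            i = np.clip(np.searchsorted(bt, t, side="right") - 1, 0, len(bt) - 2)
            return (b[i + 1] - b[i]) / (bt[i + 1] - bt[i])

        sol = solve_ivp(lambda t, y: r1 * dcr(t) + k2 * cr(t) - k2a * y,
                        (0.0, 90.0), [0.0], rtol=1e-10, atol=1e-12,
                        max_step=0.25, dense_output=True)
        tgrid = np.linspace(0.0, 90.0, 5401)
        ct = sol.sol(tgrid)[0]
        cum = np.concatenate([[0.0], np.cumsum((ct[1:] + ct[:-1]) / 2 * np.diff(tgrid))])
        lo = np.interp(schedule.frame_starts / 60.0, tgrid, cum)
        hi = np.interp(schedule.frame_ends / 60.0, tgrid, cum)
        oracle = (hi - lo) / (schedule.frame_durations / 60.0)

        mine = srtm_forward(SRTMParams(r1, k2, bp), ref_tac).values
        np.testing.assert_allclose(mine, oracle, rtol=1e-3)

    def test_linear_in_coefficients_for_fixed_k2a(self, ref_tac):
        # doubling R1 and k2 keeps k2a fixed and doubles both linear
        # coefficients, hence doubles the output
        out1 = srtm_forward(SRTMParams(0.7, 0.1, 1.5), ref_tac).values
        k2a = 0.1 / 2.5
        out2 = srtm_forward(SRTMParams(1.4, 0.2, 0.2 / k2a - 1.0), ref_tac).values
        np.testing.assert_allclose(out2, 2.0 * out1, rtol=1e-12)


class TestBasisFit:
    def test_target_equal_to_reference(self, ref_tac):
        fit = fit_srtm_basis(ref_tac, ref_tac)
        assert abs(fit.params.bp_nd) < 1e-6
        assert abs(fit.params.r1 - 1.0) < 1e-6

    @pytest.mark.parametrize("r1,k2,bp", [
        (1.0, 0.1, 1.7),    # striatal scale
        (1.0, 0.1, 2.69),   # ventral-striatum scale
        (0.8, 0.2, 0.5),
        (1.2, 0.05, 3.0),
    ])
    def test_noiseless_roundtrip(self, ref_tac, r1, k2, bp):
        target = srtm_forward(SRTMParams(r1, k2, bp), ref_tac)
        fit = fit_srtm_basis(target, ref_tac)
        assert abs(fit.params.bp_nd - bp) < 1e-2
        assert abs(fit.params.r1 - r1) < 1e-3
        assert fit.weighted_rss < 1e-8

    def test_agrees_with_nls(self, ref_tac):
        target = srtm_forward(SRTMParams(1.0, 0.1, 1.7), ref_tac)
        bp_basis = fit_srtm_basis(target, ref_tac).params.bp_nd
        bp_nls = fit_srtm_nls(target, ref_tac).params.bp_nd
        assert abs(bp_basis - bp_nls) < 1e-3

    def test_grid_boundary_flagged(self, ref_tac):
        target = srtm_forward(SRTMParams(1.0, 0.1, 1.7), ref_tac)  # true k2a ~0.037
        fit = fit_srtm_basis(target, ref_tac, k2a_grid=np.geomspace(0.1, 1.0, 16))
        assert "k2a_at_grid_boundary" in fit.flags

    def test_degenerate_reference_rejected(self, ref_tac, schedule):
        zeros = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(ValueError, match="reference"):
            fit_srtm_basis(ref_tac, zeros)
        with pytest.raises(ValueError, match="grid"):
            fit_srtm_basis(ref_tac, ref_tac, k2a_grid=np.array([]))

    def test_unit_rescaling_invariance(self, ref_tac, schedule):
        """With frame-duration weights, BP_ND/R1/k2 are unit-scale invariant."""
        target = srtm_forward(SRTMParams(0.9, 0.12, 1.2), ref_tac)
        fit1 = fit_srtm_basis(target, ref_tac)
        scaled_t = TimeActivityCurve(schedule, target.values * 1000.0)
        scaled_r = TimeActivityCurve(schedule, ref_tac.values * 1000.0)
        fit2 = fit_srtm_basis(scaled_t, scaled_r)
        assert np.allclose(
            [fit1.params.r1, fit1.params.k2, fit1.params.bp_nd],
            [fit2.params.r1, fit2.params.k2, fit2.params.bp_nd], rtol=1e-8)

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(r1=st.floats(0.6, 1.4), k2=st.floats(0.05, 0.3), bp=st.floats(0.0, 3.0))
    def test_roundtrip_property(self, ref_tac, r1, k2, bp):
        """BP_ND recovered to < 0.02 over the physiological parameter box."""
        target = srtm_forward(SRTMParams(r1, k2, bp), ref_tac)
        fit = fit_srtm_basis(target, ref_tac)
        assert abs(fit.params.bp_nd - bp) < 0.02


class TestNLSFit:
    def test_init_at_truth_converges(self, ref_tac):
        truth = SRTMParams(1.0, 0.1, 1.7)
        target = srtm_forward(truth, ref_tac)
        fit = fit_srtm_nls(target, ref_tac, init=truth)
        assert abs(fit.params.bp_nd - 1.7) < 1e-6
        assert fit.weighted_rss < 1e-10

    def test_all_zero_target_rejected(self, ref_tac, schedule):
        zeros = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(ValueError, match="degenerate"):
            fit_srtm_nls(zeros, ref_tac)


class TestSUV:
    def _constant_suv_tac(self, dose=200.0, weight=80.0):
        # 90 one-minute frames; SUV == 1 everywhere
        sched = FrameSchedule.from_durations([60.0] * 90)
        conc = np.full(90, dose / weight)
        return TimeActivityCurve(sched, conc), dose, weight

    def test_constant_window_integral(self):
        tac, dose, weight = self._constant_suv_tac()
        assert suv_auc(tac, dose, weight, window_min=(10.0, 90.0)) == pytest.approx(80.0)

    def test_triangular_ramp_integral(self):
        # SUV rising linearly 0 -> 1 between 10 and 90 min: area = 40
        sched = FrameSchedule.from_durations([60.0] * 90)
        mids_min = sched.frame_mids / 60.0
        suv = np.clip((mids_min - 10.0) / 80.0, 0.0, None)
        dose, weight = 150.0, 75.0
        tac = TimeActivityCurve(sched, suv * dose / weight)
        assert suv_auc(tac, dose, weight, (10.0, 90.0)) == pytest.approx(40.0)

    def test_partial_frames_prorated(self):
        tac, dose, weight = self._constant_suv_tac()
        assert suv_auc(tac, dose, weight, (10.5, 89.5)) == pytest.approx(79.0)

    def test_invalid_inputs(self):
        tac, dose, weight = self._constant_suv_tac()
        with pytest.raises(ValueError, match="dose"):
            suv_auc(tac, 0.0, weight)
        with pytest.raises(ValueError, match="weight"):
            suv_auc(tac, dose, 0.0)
        with pytest.raises(ValueError, match="window"):
            suv_auc(tac, dose, weight, (10.0, 120.0))


class TestBasisFitterReuse:
    def test_matches_single_shot_fit(self, ref_tac):
        fitter = BasisFitter(ref_tac)
        for bp in (0.3, 1.7):
            target = srtm_forward(SRTMParams(1.0, 0.1, bp), ref_tac)
            a = fitter.fit(target).params.bp_nd
            b = fit_srtm_basis(target, ref_tac).params.bp_nd
            assert a == pytest.approx(b, abs=1e-12)
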