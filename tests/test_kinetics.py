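"""SRTM forward model, basis-function fit, and SUVr."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tauflow.kinetics import (
    FrameSchedule,
    SRTMParams,
    TimeActivityCurve,
    compute_suvr,
    dvr_from_bp,
    fit_rpm,
    make_basis,
    srtm_model_tac,
)
from tauflow.simulate import NoiseModel, add_noise


class TestFrameSchedule:
    def test_midpoints_and_end(self):
        s = FrameSchedule([0.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert np.allclose(s.midpoints, [0.5, 1.5, 3.0])
        assert s.total_end == 4.0

    @pytest.mark.parametrize(
        "start,dur,msg",
        [
            ([0.0, 0.5], [1.0, 1.0], "overlap"),
            ([0.0, 1.0], [1.0, -1.0], "positive"),
            ([1.0, 0.5], [0.5, 0.5], "increasing"),
        ],
    )
    def test_invalid_schedules_rejected(self, start, dur, msg):
        with pytest.raises(ValueError, match=msg):
            FrameSchedule(start, dur)

    def test_gapped_frames_allowed(self):
        FrameSchedule([0.0, 2.0], [1.0, 1.0])


class TestForwardModel:
    def test_identity_when_target_equals_reference(self, ref):
        """R1=1, BPND=0 makes the SRTM output collapse onto the reference."""
        out = srtm_model_tac(SRTMParams(R1=1.0, k2=0.05, BPND=0.0), ref)
        assert np.allclose(out.activity, ref.activity, rtol=1e-3)

    @pytest.mark.parametrize(
        "params",
        [
            SRTMParams(R1=0.85, k2=0.0425, BPND=0.6),
            SRTMParams(R1=0.71, k2=0.0355, BPND=0.05),
            SRTMParams(R1=1.1, k2=0.06, BPND=1.2),
        ],
    )
    def test_noiseless_round_trip_within_one_percent(self, ref, basis, params):
        """RPM recovers the generating (R1, k2, BPND) from noiseless data."""
        target = srtm_model_tac(params, ref)
        fit = fit_rpm(target, ref, basis)
        assert fit.R1 == pytest.approx(params.R1, rel=0.01)
        assert fit.k2 == pytest.approx(params.k2, rel=0.01)
        assert fit.BPND == pytest.approx(params.BPND, rel=0.01)
        assert not fit.converged_on_boundary

    def test_fine_grid_convergence(self, ref, canonical_params):
        """Halving the integration step changes frame values by < 0.05%."""
        coarse = srtm_model_tac(canonical_params, ref, fine_dt=0.1)
        fine = srtm_model_tac(canonical_params, ref, fine_dt=0.05)
        rel = np.abs(coarse.activity / fine.activity - 1.0)
        assert rel.max() < 5e-4

    def test_dvr_invariant_under_joint_flow_scaling(self, ref, basis, canonical_params):
        """Scaling R1 and k2 together leaves the fitted DVR unchanged:
        flow cannot masquerade as binding in the quantitative measure."""
        for f in (0.7, 0.85, 1.0, 1.15, 1.3):
            p = SRTMParams(
                R1=canonical_params.R1 * f,
                k2=canonical_params.k2 * f,
                BPND=canonical_params.BPND,
            )
            fit = fit_rpm(srtm_model_tac(p, ref), ref, basis)
            assert fit.DVR == pytest.approx(canonical_params.BPND + 1.0, rel=0.01)

    def test_invalid_inputs_rejected(self, ref):
        with pytest.raises(ValueError):
            srtm_model_tac(SRTMParams(1.0, 0.05, 0.0), ref, fine_dt=-0.1)
        short = TimeActivityCurve(FrameSchedule([0.0], [1.0]), [1.0])
        with pytest.raises(ValueError):
            srtm_model_tac(SRTMParams(1.0, 0.05, 0.0), short)


class TestBasis:
    def test_two_point_grid_hits_endpoints_exactly(self, ref):
        b = make_basis(ref, k2a_min=0.01, k2a_max=0.5, n_basis=2)
        assert np.allclose(b.k2a_grid, [0.01, 0.5])

    def test_constant_reference_converges_to_c_over_k2a(self, schedule):
        """Convolving a constant c with exp(-k t) tends to c/k."""
        c = 7.3
        const = TimeActivityCurve(schedule, np.full(schedule.n_frames, c))
        b = make_basis(const, k2a_min=0.2, k2a_max=0.4, n_basis=2)
        assert b.basis_curves[0, -1] == pytest.approx(c / 0.2, rel=5e-3)
        assert b.basis_curves[1, -1] == pytest.approx(c / 0.4, rel=5e-3)

    def test_basis_curves_decrease_with_k2a(self, ref, basis):
        """For a non-negative reference, a faster kernel gives a smaller
        convolution at every time point."""
        diffs = np.diff(basis.basis_curves, axis=0)
        assert np.all(diffs[:, 1:] <= 1e-9)

    def test_invalid_grid_rejected(self, ref):
        with pytest.raises(ValueError):
            make_basis(ref, k2a_min=0.5, k2a_max=0.1)
        with pytest.raises(ValueError):
            make_basis(ref, n_basis=1)


class TestFitRPM:
    def test_identity_target_gives_unit_r1_zero_binding(self, ref, basis):
        fit = fit_rpm(ref, ref, basis)
        assert fit.R1 == pytest.approx(1.0, abs=0.01)
        assert fit.BPND == pytest.approx(0.0, abs=0.01)

    def test_selected_grid_point_minimises_wrss(self, ref, basis, canonical_target):
        """Exhaustive oracle: closed-form selection agrees with per-point
        least squares via numpy lstsq on noisy data."""
        rng = np.random.default_rng(42)
        noisy = TimeActivityCurve(
            ref.schedule,
            canonical_target.activity * (1 + 0.05 * rng.standard_normal(ref.schedule.n_frames)),
        )
        fit = fit_rpm(noisy, ref, basis, refine=False)
        wrss_all = np.empty(basis.k2a_grid.size)
        for j in range(basis.k2a_grid.size):
            X = np.column_stack([ref.activity, basis.basis_curves[j]])
            theta, res, *_ = np.linalg.lstsq(X, noisy.activity, rcond=None)
            wrss_all[j] = np.sum((noisy.activity - X @ theta) ** 2)
        assert fit.basis_index == int(np.argmin(wrss_all))
        assert fit.wrss == pytest.approx(wrss_all[fit.basis_index], rel=1e-8)
        assert np.all(fit.wrss <= wrss_all + 1e-9)

    def test_noisy_replicates_recover_dvr_on_average(self, ref, canonical_target):
        """Monte-Carlo unbiasedness: mean fitted DVR over 100 noisy
        replicates (COV 5%) stays within 2% of the true 1.60."""
        rng = np.random.default_rng(7)
        nm = NoiseModel(cov=0.05)
        dvrs = []
        for _ in range(100):
            tgt = add_noise(canonical_target, nm, rng)
            rn = add_noise(ref, nm, rng)
            b = make_basis(rn)
            dvrs.append(fit_rpm(tgt, rn, b).DVR)
        assert np.mean(dvrs) == pytest.approx(1.60, rel=0.02)

    def test_eiv_correction_removes_r1_attenuation(self, ref, canonical_target):
        """With a noisy reference, plain WLS attenuates R1; subtracting the
        known reference-noise moments restores it."""
        rng = np.random.default_rng(3)
        nm = NoiseModel(cov=0.05)
        dur = ref.schedule.frame_duration
        sd_model = 0.05 * np.abs(ref.activity) * np.sqrt(dur.mean() / dur)
        plain, corrected = [], []
        for _ in range(150):
            tgt = add_noise(canonical_target, nm, rng)
            rn = add_noise(ref, nm, rng)
            b = make_basis(rn)
            plain.append(fit_rpm(tgt, rn, b, weights=dur).R1)
            corrected.append(
                fit_rpm(tgt, rn, b, weights=dur, ref_noise_sd=sd_model).R1
            )
        err_plain = abs(np.mean(plain) - 0.85)
        err_corr = abs(np.mean(corrected) - 0.85)
        assert err_corr < err_plain
        assert err_corr < 0.01

    def test_degenerate_inputs_rejected(self, ref, basis, canonical_target):
        with pytest.raises(ValueError, match="zero"):
            fit_rpm(canonical_target, ref, basis, weights=np.zeros(ref.schedule.n_frames))
        other = FrameSchedule([0.0, 5.0], [5.0, 5.0])
        tac2 = TimeActivityCurve(other, [1.0, 1.0])
        with pytest.raises(ValueError, match="schedule"):
            fit_rpm(tac2, ref, basis)


class TestSUVr:
    def test_identity_and_scaling(self, ref):
        assert compute_suvr(ref, ref, 80, 100) == pytest.approx(1.0)
        double = TimeActivityCurve(ref.schedule, 2.0 * ref.activity)
        assert compute_suvr(double, ref, 80, 100) == pytest.approx(2.0)

    @given(
        scale_both=st.floats(0.1, 10.0),
        scale_target=st.floats(0.1, 10.0),
    )
    def test_linearity_properties(self, ref, canonical_target, scale_both, scale_target):
        """SUVr ignores common rescaling and is linear in the target."""
        base = compute_suvr(canonical_target, ref, 80, 100)
        t2 = TimeActivityCurve(ref.schedule, canonical_target.activity * scale_both)
        r2 = TimeActivityCurve(ref.schedule, ref.activity * scale_both)
        assert compute_suvr(t2, r2, 80, 100) == pytest.approx(base, rel=1e-12)
        t3 = TimeActivityCurve(ref.schedule, canonical_target.activity * scale_target)
        assert compute_suvr(t3, ref, 80, 100) == pytest.approx(
            base * scale_target, rel=1e-12
        )

    def test_partial_frame_overlap_weighting(self):
        """Frames straddling the window edge contribute by overlap length."""
        sched = FrameSchedule([0.0, 10.0, 20.0], [10.0, 10.0, 10.0])
        target = TimeActivityCurve(sched, [1.0, 2.0, 4.0])
        refc = TimeActivityCurve(sched, [1.0, 1.0, 1.0])
        # window 15-25: 5 min of frame 1, 5 min of frame 2
        assert compute_suvr(target, refc, 15, 25) == pytest.approx(3.0)

    def test_window_outside_range_rejected(self, ref):
        with pytest.raises(ValueError):
            compute_suvr(ref, ref, 125, 140)
        with pytest.raises(ValueError):
            compute_suvr(ref, ref, 100, 80)


class TestDVRFromBP:
    def test_values_and_negative_warning(self):
        assert dvr_from_bp(0.0) == 1.0
        assert dvr_from_bp(0.6) == pytest.approx(1.6)
        with pytest.warns(UserWarning, match="negative"):
            assert dvr_from_bp(-0.01) == pytest.approx(0.99)
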