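import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pibtransfer import (
    DegenerateInputError,
    FrameSchedule,
    InsufficientDataError,
    InvalidInputError,
    KineticParams,
    PlasmaCurve,
    TimeActivityCurve,
    TissueKineticTruth,
    compute_mtga_variables,
    fit_mtga,
    model_v,
    patlak_plot_data,
    select_model,
    simulate_tissue_tac,
)
from pibtransfer.mtga import MTGAVariables


def params(**kw):
    base = dict(K=0.0, K1=0.25, Vg=2.5, Vo=0.05, se_K=0.01, se_K1=0.01,
                se_Vg=0.1, se_Vo=0.01, model_tag="full")
    base.update(kw)
    return KineticParams(**base)


class TestComputeVariables:
    def test_constant_input_theta_equals_real_time(self, constant_plasma, constant_frames):
        tac = TimeActivityCurve(constant_frames.start, constant_frames.end,
                                np.ones(constant_frames.start.size))
        mv = compute_mtga_variables(tac, constant_plasma)
        np.testing.assert_allclose(mv.theta, constant_frames.mid_times, rtol=1e-12)

    def test_pure_vascular_signal_gives_constant_v(self, pib_plasma, pib_frames):
        Vo = 0.04
        tac = simulate_tissue_tac(pib_plasma, TissueKineticTruth(0.0, 0.1, Vo), pib_frames)
        # frame-averaged m over frame-averaged... evaluated at mid-times: V = m/ca;
        # compare against Vo * (frame-average ca)/(mid ca), ~1 except at the bolus peak
        mv = compute_mtga_variables(tac, pib_plasma)
        late = mv.frame_mid_times > 2.0  # smooth part of the curve
        np.testing.assert_allclose(mv.v[late], Vo, rtol=5e-3)

    def test_exponential_input_closed_form_theta(self):
        lam = 0.3
        t = np.arange(0.0, 10.0 + 1e-9, 0.001)
        plasma = PlasmaCurve(times=t, activity=np.exp(-lam * t))
        frames = FrameSchedule.from_durations([0.5] * 20)
        tac = TimeActivityCurve(frames.start, frames.end, np.ones(20))
        mv = compute_mtga_variables(tac, plasma)
        T = frames.mid_times
        np.testing.assert_allclose(mv.theta, (np.exp(lam * T) - 1.0) / lam, rtol=1e-5)

    def test_zero_plasma_activity_is_degenerate(self):
        t = np.arange(0.0, 5.0 + 1e-9, 0.1)
        activity = np.where(t < 1.0, 0.0, 1.0)
        plasma = PlasmaCurve(times=t, activity=activity)
        frames = FrameSchedule.from_durations([0.5] * 10)
        tac = TimeActivityCurve(frames.start, frames.end, np.ones(10))
        with pytest.raises(DegenerateInputError, match="frame 0"):
            compute_mtga_variables(tac, plasma)


class TestModelEquation:
    def test_full_model_with_zero_k_equals_reversible(self):
        theta = np.linspace(0.0, 20.0, 500)
        full = model_v(theta, 0.0, 0.28, 2.0, 0.05)
        reversible = 2.0 * -np.expm1(-0.28 * theta / 2.0) + 0.05
        assert np.max(np.abs(full - reversible)) < 1e-12

    def test_early_slope_equals_k1(self):
        h = 1e-3
        K1 = 0.28
        slope = (model_v(h, 0.0, K1, 2.0, 0.05) - model_v(0.0, 0.0, K1, 2.0, 0.05)) / h
        assert slope == pytest.approx(K1, rel=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        K1=st.floats(0.05, 1.0),
        Vg=st.floats(0.2, 10.0),
        Vo=st.floats(0.0, 0.2),
    )
    def test_reversible_curve_monotone_and_bounded(self, K1, Vg, Vo):
        theta = np.linspace(0.0, 50.0, 200)
        v = model_v(theta, 0.0, K1, Vg, Vo)
        assert np.all(np.diff(v) >= -1e-12)
        assert np.all(v <= Vg + Vo + 1e-12)


class TestFitMtga:
    def test_constant_input_reversible_round_trip(self, constant_plasma, constant_frames):
        """The reversible Patlak equation is exact under constant input, so the
        fit must reproduce the generating (K1, Vg, Vo) with essentially zero
        residual."""
        truth = TissueKineticTruth(K1=0.25, k2=0.1, Vo=0.05)  # Vg = 2.5
        tac = simulate_tissue_tac(constant_plasma, truth, constant_frames)
        mv = compute_mtga_variables(tac, constant_plasma)
        fit = fit_mtga(mv, "reversible", window=(0.0, 20.0))
        assert fit.rss < 1e-10
        assert fit.K1 == pytest.approx(0.25, abs=1e-4)
        assert fit.Vg == pytest.approx(2.5, rel=1e-2)
        assert fit.Vo == pytest.approx(0.05, abs=1e-3)

    def test_linear_fit_on_exact_line(self):
        theta = np.linspace(0.1, 3.0, 12)
        mv = MTGAVariables(theta=theta, v=0.28 * theta + 0.04, frame_mid_times=theta)
        fit = fit_mtga(mv, "linear", window=(0.0, 4.0))
        assert fit.K1 == pytest.approx(0.28, abs=1e-12)
        assert fit.Vo == pytest.approx(0.04, abs=1e-12)

    def test_realistic_aif_recovery_within_documented_bias(
        self, pib_plasma, pib_input, pib_frames, pib_truth
    ):
        """Under the triphasic bolus input the reversible fit carries a known
        upward K1 bias (the apparent volume overshoots Vg + Vo once plasma
        activity collapses to the plateau); at the default kinetics it is
        ~8%, within the 10% characterized envelope."""
        tac = simulate_tissue_tac(pib_input, pib_truth, pib_frames)
        mv = compute_mtga_variables(tac, pib_plasma)
        fit = fit_mtga(mv, "reversible", window=(0.0, 4.0))
        rel = (fit.K1 - pib_truth.K1) / pib_truth.K1
        assert 0.0 < rel < 0.10

    def test_noisy_replicates_median_within_ten_percent(
        self, pib_plasma, pib_input, pib_frames, pib_truth
    ):
        est = []
        for i in range(200):
            tac = simulate_tissue_tac(
                pib_input, pib_truth, pib_frames, noise_scale=0.05, seed=1000 + i
            )
            mv = compute_mtga_variables(tac, pib_plasma)
            est.append(fit_mtga(mv, "reversible", window=(0.0, 4.0)).K1)
        med = np.median(np.abs(np.asarray(est) / pib_truth.K1 - 1.0))
        assert med < 0.10

    def test_too_few_frames_in_window(self, constant_plasma, constant_frames):
        tac = TimeActivityCurve(constant_frames.start, constant_frames.end,
                                np.ones(constant_frames.start.size))
        mv = compute_mtga_variables(tac, constant_plasma)
        with pytest.raises(InsufficientDataError):
            fit_mtga(mv, "full", window=(0.0, 1.2))  # only 2 frames

    def test_unknown_model_rejected(self, constant_plasma, constant_frames):
        tac = TimeActivityCurve(constant_frames.start, constant_frames.end,
                                np.ones(constant_frames.start.size))
        mv = compute_mtga_variables(tac, constant_plasma)
        with pytest.raises(InvalidInputError):
            fit_mtga(mv, "logan")


class TestSelectModel:
    def test_threshold_decisions(self):
        assert select_model(params(K=0.001, se_K=0.01)) == "reversible"
        assert select_model(params(K=0.05, se_K=0.01)) == "full"

    def test_missing_se_rejected(self):
        with pytest.raises(InvalidInputError):
            select_model(params(se_K=np.nan))

    def test_detects_trapping_under_constant_input(self, constant_plasma):
        """With an informative (constant) input over 30 min, a true net
        clearance K = 0.02 is detected in essentially every low-noise
        replicate, while K = 0 data select the reversible model."""
        t = np.arange(0.0, 30.0 + 1e-9, 0.05)
        plasma = PlasmaCurve(times=t, activity=np.full_like(t, 5.0))
        frames = FrameSchedule.from_durations([0.5] * 60)
        decisions = []
        for i in range(100):
            truth = TissueKineticTruth(K1=0.28, k2=0.14, Vo=0.05, K=0.02)
            tac = simulate_tissue_tac(plasma, truth, frames, noise_scale=0.01, seed=5000 + i)
            mv = compute_mtga_variables(tac, plasma)
            decisions.append(select_model(fit_mtga(mv, "full", window=(0.0, 30.0))))
        assert np.mean([d == "full" for d in decisions]) > 0.8
        null = []
        for i in range(20):
            truth = TissueKineticTruth(K1=0.28, k2=0.14, Vo=0.05)
            tac = simulate_tissue_tac(plasma, truth, frames, noise_scale=0.01, seed=6000 + i)
            mv = compute_mtga_variables(tac, plasma)
            null.append(select_model(fit_mtga(mv, "full", window=(0.0, 30.0))))
        assert np.mean([d == "reversible" for d in null]) > 0.8


class TestPatlakPlotData:
    def test_huge_vg_approaches_linear_model(self):
        theta = np.linspace(0.0, 4.0, 50)
        mv = MTGAVariables(theta=theta, v=np.zeros_like(theta), frame_mid_times=theta)
        fit = params(model_tag="reversible", K=0.0, K1=0.3, Vg=1e6, Vo=0.05)
        table = patlak_plot_data(mv, fit)
        linear = 0.3 * theta + 0.05
        np.testing.assert_allclose(table["v_fitted"], linear, rtol=1e-3)

    def test_zero_fit_gives_zero_curve(self):
        theta = np.linspace(0.0, 4.0, 10)
        mv = MTGAVariables(theta=theta, v=np.zeros_like(theta), frame_mid_times=theta)
        fit = params(K=0.0, K1=0.0, Vg=0.0, Vo=0.0)
        assert np.all(patlak_plot_data(mv, fit)["v_fitted"] == 0.0)

    def test_intercept_at_zero_theta_is_vo(self):
        mv = MTGAVariables(theta=np.array([0.0, 1.0]), v=np.zeros(2),
                           frame_mid_times=np.array([0.0, 1.0]))
        fit = params(K=0.05, K1=0.3, Vg=2.0, Vo=0.07)
        assert patlak_plot_data(mv, fit)["v_fitted"].iloc[0] == pytest.approx(0.07)
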