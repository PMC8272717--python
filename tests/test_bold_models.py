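import numpy as np
import pandas as pd
import pytest

from relmap.bold_models import (
    FIRCurve,
    ParameterMaps,
    build_design_matrix,
    canonical_regressor,
    estimate_all_parameters,
    fir_summaries,
    fit_glm,
    fit_gamma_variate,
)
from relmap.hrf import double_gamma_hrf, gamma_variate


def _events(onsets, duration=1.0):
    return pd.DataFrame({"onset": onsets, "duration": duration, "trial_type": "s"})


class TestDesignMatrix:
    def test_fir_single_event_is_shifted_deltas(self):
        X = build_design_matrix(_events([0.0]), "fir", tr=2.0, n_scans=12, fir_length=8)
        task = X.matrix[:, X.task_columns]
        expected = np.zeros((12, 8))
        expected[np.arange(8), np.arange(8)] = 1.0
        np.testing.assert_array_equal(task, expected)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="empty design"):
            build_design_matrix(_events([]), "canonical", 2.0, 10)

    def test_canonical_column_peak_normalized(self):
        X = build_design_matrix(_events([0.0]), "canonical", tr=2.0, n_scans=20)
        assert np.max(X.matrix[:, 0]) == pytest.approx(1.0)

    def test_overlapping_fir_windows_rejected(self):
        with pytest.raises(ValueError, match="FIR windows overlap"):
            build_design_matrix(_events([0.0, 6.0]), "fir", tr=2.0, n_scans=30, fir_length=8)

    def test_onsets_outside_run_rejected(self):
        with pytest.raises(ValueError, match="outside the run"):
            build_design_matrix(_events([100.0]), "canonical", 2.0, 10)


class TestGLM:
    def test_exact_recovery(self):
        X = build_design_matrix(_events([4.0]), "canonical", 2.0, 30, drift_order=1)
        series = 2.0 * X.matrix[:, 0]
        betas, resid = fit_glm(series, X)
        assert betas[0] == pytest.approx(2.0, abs=1e-10)
        assert np.max(np.abs(resid)) < 1e-10

    def test_drift_only_gives_zero_task_beta(self):
        X = build_design_matrix(_events([4.0]), "canonical", 2.0, 30, drift_order=2)
        series = 0.7 * X.matrix[:, -1] + 0.2 * X.matrix[:, -2]
        betas, _ = fit_glm(series, X)
        assert abs(betas[0]) < 1e-8

    def test_beta_within_sampling_error(self, rng):
        X = build_design_matrix(_events(12.0 * np.arange(16)), "canonical", 2.0, 200, 1)
        x = X.matrix[:, 0]
        noise_sd = 0.1
        series = 1.5 * x + rng.normal(0, noise_sd, 200)
        betas, _ = fit_glm(series, X)
        XtX_inv = np.linalg.inv(X.matrix.T @ X.matrix)
        se = noise_sd * np.sqrt(XtX_inv[0, 0])
        assert abs(betas[0] - 1.5) < 3 * se

    def test_rank_deficiency_named(self):
        X = build_design_matrix(_events([0.0]), "canonical", 2.0, 20, drift_order=1)
        X.matrix = np.column_stack([X.matrix, X.matrix[:, -1]])
        X.names = X.names + ["dup"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(np.zeros(20), X)

    def test_residuals_orthogonal_to_design(self, rng):
        X = build_design_matrix(_events(12.0 * np.arange(5)), "fir", 1.5, 60, 2, 8)
        series = rng.standard_normal(60)
        _, resid = fit_glm(series, X)
        assert np.max(np.abs(X.matrix.T @ resid)) < 1e-8

    def test_fir_recovers_canonical_shape_noiselessly(self):
        # With an FIR window long enough to span the whole response, the
        # noiseless FIR betas equal the sampled response exactly.
        tr, L = 1.5, 24
        onsets = 48.0 * np.arange(3) + 6.0
        n_scans = 130
        x = canonical_regressor(_events(onsets), tr, n_scans)
        X = build_design_matrix(_events(onsets), "fir", tr, n_scans, 0, L)
        betas, _ = fit_glm(3.0 * x, X)
        sampled = 3.0 * x[4 + np.arange(L)]  # first onset at scan 4
        assert np.max(np.abs(betas[:L] - sampled)) < 1e-6


class TestFIRSummaries:
    @pytest.mark.parametrize(
        "betas,amp,auc",
        [
            ([0, 1, 3, 2, 1, 0, 0, 0], 3.0, 7.0),
            ([0] * 8, 0.0, 0.0),
            ([-1, -2, -1, 0, 0, 0, 0, 0], -1.0, -4.0),
        ],
    )
    def test_examples(self, betas, amp, auc):
        curve = FIRCurve(np.array(betas, float), np.arange(8) * 2.0)
        a, s = fir_summaries(curve)
        assert a == amp
        assert s == auc


class TestGammaFit:
    @pytest.mark.parametrize("delta", [0.0, 2.0, 4.0])
    @pytest.mark.parametrize("r", [0.5, 1.5])
    @pytest.mark.parametrize("h", [3.0, -2.0])
    def test_noiseless_self_recovery_sweep(self, delta, r, h):
        t = np.arange(16) * 1.0
        y = gamma_variate(t, delta, r, h)
        fit = fit_gamma_variate(y, t)
        assert not fit.degenerate
        assert fit.onset_delay == pytest.approx(delta, abs=2e-3)
        assert fit.rise_decay == pytest.approx(r, rel=1e-3)
        assert fit.height == pytest.approx(h, rel=1e-3)

    def test_all_zero_curve_degenerate(self):
        fit = fit_gamma_variate(np.zeros(8), np.arange(8.0))
        assert fit.degenerate
        assert fit.height == 0.0

    def test_flat_curve_degenerate(self):
        fit = fit_gamma_variate(np.full(10, 0.8), np.arange(10.0))
        assert fit.degenerate

    def test_noisy_height_recovery(self, rng):
        t = np.arange(16) * 1.0
        y0 = gamma_variate(t, 2.0, 1.5, 3.0)
        errs = []
        for _ in range(50):
            fit = fit_gamma_variate(y0 + rng.normal(0, 0.15, 16), t)
            errs.append(abs(fit.height - 3.0) / 3.0)
        assert np.median(errs) < 0.05

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_variate(np.ones(6), np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0]))


class TestEstimateAllParameters:
    def test_noiseless_identifiability(self):
        from relmap.synthetic import AmplitudeClass, event_related_config, simulate_dataset

        cfg = event_related_config(
            n_subjects=5,
            grid_shape=(4, 4, 4),
            classes={"c": AmplitudeClass(1.0, 0.5, 0.2)},
            voxel_class_map=np.full((4, 4, 4), "c"),
            noise_sd=0.0,
            drift_coef_sd=0.0,
            seed=2,
        )
        ds, truth = simulate_dataset(cfg)
        maps = estimate_all_parameters(ds, parameters=("canonical_amplitude", "amplitude", "auc"))
        est = maps.get("canonical_amplitude").ravel()
        true = truth.subject_amplitudes.ravel()
        assert np.corrcoef(est, true)[0, 1] > 0.999
        # all four response-scale summaries are monotone in the truth
        for p in ("amplitude", "auc"):
            assert np.corrcoef(maps.get(p).ravel(), true)[0, 1] > 0.99

    def test_roundtrip(self, tmp_path, small_dataset):
        ds, _ = small_dataset
        maps = estimate_all_parameters(ds, parameters=("canonical_amplitude", "auc"))
        maps.save(tmp_path / "maps")
        back = ParameterMaps.load(tmp_path / "maps")
        np.testing.assert_array_equal(back.values, maps.values)
        assert back.parameters == maps.parameters
        assert back.tr == maps.tr
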