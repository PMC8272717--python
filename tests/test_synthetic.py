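import numpy as np
import pandas as pd
import pytest

from relmap.reliability import icc_3_1_matrix
from relmap.synthetic import (
    AmplitudeClass,
    SimulationConfig,
    amplitude_class_for_icc,
    block_config,
    embedded_subregion_class_map,
    event_related_config,
    simulate_dataset,
    slab_class_map,
    true_icc_from_variances,
)


class TestTrueICC:
    @pytest.mark.parametrize(
        "sb,sw,expected",
        [(1.0, 0.0, 1.0), (0.0, 1.0, 0.0), (np.sqrt(3.0), 1.0, 0.75)],
    )
    def test_values(self, sb, sw, expected):
        assert true_icc_from_variances(sb, sw) == pytest.approx(expected)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            true_icc_from_variances(0.0, 0.0)
        with pytest.raises(ValueError):
            true_icc_from_variances(-1.0, 1.0)


def _tiny_cfg(**kw):
    kw.setdefault("n_subjects", 3)
    kw.setdefault("grid_shape", (4, 4, 4))
    kw.setdefault("classes", {"c": amplitude_class_for_icc(0.6)})
    kw.setdefault("voxel_class_map", np.full((4, 4, 4), "c"))
    return event_related_config(**kw)


class TestSimulateDataset:
    def test_seed_reproducibility(self):
        d1, _ = simulate_dataset(_tiny_cfg(seed=7))
        d2, _ = simulate_dataset(_tiny_cfg(seed=7))
        np.testing.assert_array_equal(d1.data, d2.data)

    def test_noiseless_sessions_identical(self):
        cfg = _tiny_cfg(
            classes={"c": AmplitudeClass(2.0, 1.0, 0.0)},
            noise_sd=0.0,
            drift_coef_sd=0.0,
            seed=1,
        )
        ds, _ = simulate_dataset(cfg)
        np.testing.assert_allclose(ds.data[:, 0], ds.data[:, 1], atol=1e-12)

    def test_adding_subjects_preserves_existing(self):
        d_small, _ = simulate_dataset(_tiny_cfg(n_subjects=3, seed=5))
        d_big, _ = simulate_dataset(_tiny_cfg(n_subjects=5, seed=5))
        np.testing.assert_array_equal(d_small.data, d_big.data[:3])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            simulate_dataset(_tiny_cfg(tr=-1.0))
        with pytest.raises(ValueError):
            simulate_dataset(_tiny_cfg(ar1_coef=1.0))
        with pytest.raises(ValueError):
            simulate_dataset(_tiny_cfg(grid_shape=(3, 4, 4), voxel_class_map=None))
        with pytest.raises(ValueError, match="empty mask"):
            simulate_dataset(_tiny_cfg(voxel_class_map=np.full((4, 4, 4), "")))

    def test_variance_decomposition_recovery(self):
        # ANOVA on the generated true amplitudes recovers the variance
        # components at large n.
        cfg = _tiny_cfg(
            n_subjects=200,
            classes={"c": AmplitudeClass(1.0, 0.8, 0.6)},
            seed=3,
        )
        _, truth = simulate_dataset(cfg)
        a = truth.subject_amplitudes.reshape(200, 2, -1)
        # between/within component estimates pooled over voxels
        subj_mean = a.mean(axis=1)
        within = a - a.mean(axis=1, keepdims=True)
        var_w = (within**2).sum() / (a.shape[0] * a.shape[2])  # df n per voxel
        var_b = subj_mean.var(axis=0, ddof=1).mean() - var_w / 2
        assert var_b == pytest.approx(0.64, abs=0.08)
        assert var_w == pytest.approx(0.36, abs=0.05)
        icc = icc_3_1_matrix(np.moveaxis(a, -1, 0))
        assert np.median(icc) == pytest.approx(true_icc_from_variances(0.8, 0.6), abs=0.05)

    def test_ar1_autocorrelation_of_pure_noise(self):
        cfg = _tiny_cfg(
            classes={"null": AmplitudeClass(0.0, 0.0, 0.0)},
            voxel_class_map=np.full((4, 4, 4), "null"),
            n_subjects=2,
            ar1_coef=0.4,
            drift_coef_sd=0.0,
            smoothness_fwhm_mm=0.0,
            events=pd.DataFrame(
                {"onset": 12.0 * np.arange(35) + 6, "duration": 1.0, "trial_type": "s"}
            ),
            seed=9,
        )
        ds, _ = simulate_dataset(cfg)
        x = ds.data[0, 0].reshape(-1, ds.data.shape[-1])
        r1 = np.mean(
            [np.corrcoef(v[:-1], v[1:])[0, 1] for v in x]
        )
        assert r1 == pytest.approx(0.4, abs=0.05)

    def test_null_voxels_have_no_task_response(self):
        from relmap.bold_models import build_design_matrix, fit_glm

        cfg = _tiny_cfg(
            n_subjects=30,
            classes={"null": AmplitudeClass(0.0, 0.0, 0.0)},
            voxel_class_map=np.full((4, 4, 4), "null"),
            seed=4,
        )
        ds, _ = simulate_dataset(cfg)
        X = build_design_matrix(ds.events, "canonical", ds.tr, ds.data.shape[-1], 2)
        betas = []
        for i in range(30):
            b, _ = fit_glm(ds.data[i, 0].reshape(-1, ds.data.shape[-1]).T, X)
            betas.append(b[0].mean())
        assert abs(np.mean(betas)) < 0.05

    def test_covariate_effect_shifts_session2(self):
        cfg = _tiny_cfg(
            n_subjects=60,
            classes={"c": AmplitudeClass(1.0, 0.5, 0.1)},
            covariate_model={"bdi_pre": 1.0},
            noise_sd=0.0,
            seed=13,
        )
        _, truth = simulate_dataset(cfg)
        a = truth.subject_amplitudes.reshape(60, 2, -1).mean(axis=2)
        shift = a[:, 1] - a[:, 0]
        bdi = truth.covariates["bdi_pre"].to_numpy()
        assert np.corrcoef(shift, (bdi - bdi.mean()) / bdi.std())[0, 1] > 0.8


class TestClassMaps:
    def test_slab_covers_grid(self):
        cmap = slab_class_map((6, 6, 6))
        assert set(np.unique(cmap)) == {"reliable", "unreliable", "null"}

    def test_embedded_subregion_fraction(self):
        cmap = embedded_subregion_class_map((10, 10, 5), subregion_fraction=0.2)
        frac = np.mean(cmap == "reliable")
        assert 0.1 < frac < 0.35
        # the subregion is one contiguous block
        from scipy import ndimage

        _, n = ndimage.label(cmap == "reliable")
        assert n == 1


def test_dataset_roundtrip(tmp_path, small_dataset):
    ds, _ = small_dataset
    ds.save(tmp_path / "d")
    from relmap.synthetic import VoxelDataset

    back = VoxelDataset.load(tmp_path / "d")
    np.testing.assert_allclose(back.data, ds.data, atol=1e-6)  # float32 storage
    assert back.subjects == ds.subjects
    assert back.tr == ds.tr
    np.testing.assert_array_equal(back.mask, ds.mask)


def test_block_config_design():
    cfg = block_config(n_subjects=3, grid_shape=(4, 4, 4))
    assert cfg.fir_length == 20
    kinds = list(cfg.events["trial_type"][:3])
    assert kinds == ["rest", "regulate", "count"]
    assert (cfg.events["duration"] == 40.0).all()
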