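"""End-to-end validation experiments with known ground truth.

Each function runs one calibration or recovery experiment on synthetic
data through the package's own pipeline and returns summary metrics:
ICC recovery across a grid of true reliabilities, gamma-variate
parameter recovery, semi-partial-correlation checks, ranking power and
false-positive calibration, cluster-threshold familywise error, the
voxelwise-versus-ROI-median contrast, and the neurofeedback
training-attenuation contrast. They are used by the acceptance tests
and the acceptance script; problem sizes are chosen to finish on one
CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from .bold_models import estimate_all_parameters, fit_gamma_variate
from .cluster import estimate_acf, icc_to_p, simulate_cluster_null, _connectivity_structure
from .hrf import gamma_variate
from .ranking import ConditionGrid, rank_analysis
from .reliability import icc_3_1_matrix, semipartial_reliability, voxelwise_icc
from .synthetic import (
    _smooth_unit_noise,
    amplitude_class_for_icc,
    block_config,
    embedded_subregion_class_map,
    event_related_config,
    simulate_dataset,
)

__all__ = [
    "icc_recovery_experiment",
    "gamma_recovery_experiment",
    "semipartial_pearson_check",
    "semipartial_analytic_check",
    "ranking_power_experiment",
    "cluster_fwe_experiment",
    "subregion_experiment",
    "nf_training_experiment",
]


def _grid_300() -> tuple[int, int, int]:
    return (5, 12, 5)  # 300 voxels, all dims >= 4


def icc_recovery_experiment(
    true_iccs=(0.0, 0.25, 0.5, 0.75, 0.9),
    n_subjects: int = 100,
    seed: int = 0,
) -> dict[float, float]:
    """Full simulate -> canonical GLM -> Windsorize -> voxelwise ICC
    pipeline at each true reliability; returns mean estimated voxelwise
    ICC per truth (300 voxels)."""
    out = {}
    grid = _grid_300()
    for i, t in enumerate(true_iccs):
        cfg = event_related_config(
            n_subjects=n_subjects,
            grid_shape=grid,
            classes={"c": amplitude_class_for_icc(t)},
            voxel_class_map=np.full(grid, "c"),
            seed=seed * 1009 + i,
        )
        ds, _ = simulate_dataset(cfg)
        maps = estimate_all_parameters(ds, parameters=("canonical_amplitude",))
        m = voxelwise_icc(maps.get("canonical_amplitude"), maps.mask, windsorize=True)
        out[float(t)] = float(np.mean(m.values()))
    return out


def gamma_recovery_experiment(seed: int = 0) -> tuple[float, float]:
    """(max relative parameter error on a noiseless (delta, r, h) grid,
    median relative height error at noise SD = 5% of h over 50
    replicates)."""
    t = np.arange(16) * 1.0
    max_rel = 0.0
    for delta in (0.0, 1.0, 2.0, 4.0):
        for r in (0.5, 1.0, 2.0):
            for h in (3.0, -2.0, 0.5):
                y = gamma_variate(t, delta, r, h)
                fit = fit_gamma_variate(y, t)
                errs = [
                    abs(fit.onset_delay - delta) / max(delta, 1.0),
                    abs(fit.rise_decay - r) / r,
                    abs(fit.height - h) / abs(h),
                ]
                max_rel = max(max_rel, *errs)
    rng = np.random.default_rng(seed)
    h = 3.0
    y0 = gamma_variate(t, 2.0, 1.5, h)
    herrs = []
    for _ in range(50):
        fit = fit_gamma_variate(y0 + rng.normal(0.0, 0.05 * h, t.size), t)
        herrs.append(abs(fit.height - h) / h)
    return max_rel, float(np.median(herrs))


def semipartial_pearson_check(seed: int = 0, n_datasets: int = 100) -> float:
    """Max |sr - Pearson r| over random datasets with no covariates."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        pre = rng.standard_normal(30)
        post = 0.6 * pre + rng.standard_normal(30)
        sr = semipartial_reliability(pre, post).sr
        worst = max(worst, abs(sr - np.corrcoef(pre, post)[0, 1]))
    return worst


def semipartial_analytic_check(seed: int = 0, n_rep: int = 25, n: int = 200) -> tuple[float, float]:
    """(mean fitted sr, closed-form multivariate-normal sr) for
    post = 0.5 pre + 1.0 cov + e with unit-variance components."""
    rng = np.random.default_rng(seed)
    srs = []
    for _ in range(n_rep):
        pre = rng.standard_normal(n)
        cov = rng.standard_normal(n)
        post = 0.5 * pre + 1.0 * cov + rng.standard_normal(n)
        srs.append(semipartial_reliability(pre, post, cov[:, None]).sr)
    analytic = 0.5 / np.sqrt(0.25 + 1.0 + 1.0)
    return float(np.mean(srs)), float(analytic)


def _amplitude_icc_values(rng, true_icc, n_sub, n_vox):
    sb, sw = np.sqrt(true_icc), np.sqrt(1.0 - true_icc)
    b = sb * rng.standard_normal((n_sub, 1, n_vox))
    e = sw * rng.standard_normal((n_sub, 2, n_vox))
    return icc_3_1_matrix(np.moveaxis(b + e, -1, 0))


def ranking_power_experiment(
    n_rep: int = 100, n_subjects: int = 50, n_voxels: int = 300, seed: int = 0
) -> tuple[float, float]:
    """(detection rate, falsely-disjoint pair rate).

    Power: six parameters, one at true ICC 0.8 and five at 0.2; a hit is
    the superior parameter topping the mean ranks with a CI disjoint
    from all others. False rate: all six exchangeable at ICC 0.2;
    fraction of disjoint CI pairs.
    """
    rng = np.random.default_rng(seed)
    names = [f"p{i}" for i in range(6)]
    hits = 0
    for _ in range(n_rep):
        vals = np.stack(
            [
                _amplitude_icc_values(rng, 0.8 if i == 0 else 0.2, n_subjects, n_voxels)
                for i in range(6)
            ]
        )
        res = rank_analysis(ConditionGrid(vals, names))
        top = int(np.argmax(res.mean_ranks))
        if top == 0 and res.top_condition_is_distinct():
            hits += 1
    false_pairs = total = 0
    for _ in range(n_rep):
        vals = np.stack(
            [_amplitude_icc_values(rng, 0.2, n_subjects, n_voxels) for _ in range(6)]
        )
        res = rank_analysis(ConditionGrid(vals, names))
        iu = np.triu_indices(6, 1)
        false_pairs += int(res.nonoverlap[iu].sum())
        total += len(iu[0])
    return hits / n_rep, false_pairs / total


def cluster_fwe_experiment(
    seed: int = 0,
    n_subjects: int = 20,
    grid=(20, 20, 12),
    theta: float = 0.4,
    alpha: float = 0.05,
    n_iter: int = 2000,
    n_validation: int = 2000,
) -> tuple[float, int]:
    """Familywise error of the cluster-calibrated threshold on null data.

    One null dataset is simulated and run through the GLM to produce
    amplitude maps; the spatial ACF is fitted to the across-subject
    demeaned maps; the ICC threshold is mapped to its null p; and the
    minimum cluster extent is Monte-Carloed with the direct ICC null.
    Validation draws fresh null amplitude maps from the simulator's own
    smoothed-noise law (under the null the GLM amplitude estimate is a
    linear functional of the noise, so this is its exact distribution),
    computes real voxelwise ICC maps, and measures how often a
    supra-threshold cluster of at least the minimum extent appears.
    Returns (FWE, min cluster size).
    """
    from scipy import ndimage

    from .synthetic import AmplitudeClass

    grid = tuple(grid)
    cfg = event_related_config(
        n_subjects=n_subjects,
        grid_shape=grid,
        classes={"null": AmplitudeClass(0.0, 0.0, 0.0)},  # no response anywhere
        voxel_class_map=np.full(grid, "null"),
        seed=seed * 2003 + 17,
    )
    ds, _ = simulate_dataset(cfg)
    maps = estimate_all_parameters(ds, parameters=("canonical_amplitude",))
    vox = float(cfg.voxel_size_mm)
    vols = maps.get("canonical_amplitude").reshape(-1, *grid)
    vols = vols - vols.mean(axis=0, keepdims=True)
    acf = estimate_acf(vols, maps.mask, vox)
    p_thr = icc_to_p(theta, n_subjects)
    min_size = simulate_cluster_null(
        acf,
        maps.mask,
        p_thr,
        vox,
        n_iter=n_iter,
        alpha=alpha,
        seed=seed * 4001 + 5,
        null="icc",
        n_subjects=n_subjects,
    )
    rng = np.random.default_rng(seed * 5003 + 29)
    struct = _connectivity_structure(6)
    hits = 0
    for _ in range(n_validation):
        white = rng.standard_normal(grid + (2 * n_subjects,))
        a = np.moveaxis(_smooth_unit_noise(white, cfg.smoothness_fwhm_mm, vox), -1, 0)
        a = a.reshape(n_subjects, 2, -1)
        icc = icc_3_1_matrix(np.moveaxis(a, -1, 0)).reshape(grid)
        labels, n_lab = ndimage.label(icc >= theta, structure=struct)
        if n_lab and np.bincount(labels.ravel())[1:].max() >= min_size:
            hits += 1
    return hits / n_validation, int(min_size)


def subregion_experiment(
    n_subjects: int = 60, seed: int = 0
) -> tuple[float, float]:
    """Voxelwise-beats-ROI-median demonstration.

    An ROI whose voxels are 20% truly reliable (ICC 0.8) inside
    unreliable tissue (ICC 0.1). Returns (ROI median estimated ICC,
    fraction of truly-reliable voxels with estimated ICC > 0.6).
    """
    grid = (10, 10, 5)
    cmap = embedded_subregion_class_map(grid, 0.2, "reliable", "unreliable")
    cfg = event_related_config(
        n_subjects=n_subjects,
        grid_shape=grid,
        classes={
            "reliable": amplitude_class_for_icc(0.8),
            "unreliable": amplitude_class_for_icc(0.1),
        },
        voxel_class_map=cmap,
        seed=seed * 3001 + 7,
    )
    ds, truth = simulate_dataset(cfg)
    maps = estimate_all_parameters(ds, parameters=("canonical_amplitude",))
    m = voxelwise_icc(maps.get("canonical_amplitude"), maps.mask, windsorize=True)
    roi_median = float(np.median(m.values()))
    rel = truth.voxel_class_map == "reliable"
    frac_good = float(np.mean(m.icc[rel] > 0.6))
    return roi_median, frac_good


def nf_training_experiment(
    n_rep: int = 100,
    n_untrained: int = 16,
    n_trained: int = 18,
    training_shift_sd: float = 1.5,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the untrained condition is more
    reliable (mean-summary ICC) than the trained one.

    Training is modeled as a heterogeneous per-subject shift of the
    visit-2 response amplitude (SD comparable to the between-subject
    spread), which adds within-subject variance and attenuates
    test-retest reliability.
    """
    from .nf import BlockDesign, average_blocks, feedback_signal, summarize_visit
    from .reliability import icc_3_1

    def one_icc(rep_seed, n, shift_sd):
        cfg = block_config(
            n_subjects=n,
            grid_shape=(4, 4, 4),
            classes={"roi": amplitude_class_for_icc(0.7, mean_amplitude=2.0)},
            voxel_class_map=np.full((4, 4, 4), "roi"),
            session2_shift_sd=shift_sd,
            seed=rep_seed,
        )
        ds, _ = simulate_dataset(cfg)
        design = BlockDesign.from_events(ds.events, ds.tr)
        means = np.zeros((n, 2))
        for i in range(n):
            for j in range(2):
                roi = ds.data[i, j][ds.mask].mean(axis=0)
                means[i, j] = summarize_visit(
                    average_blocks(feedback_signal(roi, design)), "mean"
                )
        return icc_3_1(means)[0]

    base = seed * 7001
    wins = 0
    for rep in range(n_rep):
        icc_u = one_icc(base + 2 * rep, n_untrained, 0.0)
        icc_t = one_icc(base + 2 * rep + 1, n_trained, training_shift_sd)
        wins += icc_u > icc_t
    return wins / n_rep
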