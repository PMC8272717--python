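"""Synthetic multi-session BOLD datasets with known true reliability.

The generator emulates the two study designs the package targets:

* a slow event-related task (30 trials, 12 s inter-stimulus interval,
  TR 1.5 s — slow enough that an 8-TR FIR window fits between trials),
  acquired in 2 sessions over a cohort of patients and controls;
* a 40-s block neurofeedback design (rest / regulate / count cycles,
  TR 2 s) acquired on 2 visits.

Every in-mask voxel belongs to one amplitude class (e.g. reliable,
unreliable, null). A subject's true response height at voxel v in
session j is

    a_ijv = mu_class + b_iv + e_ijv,   b ~ N(0, sigma_between^2),
                                       e ~ N(0, sigma_within^2),

so the population test-retest reliability of the true amplitude is the
variance ratio sigma_b^2 / (sigma_b^2 + sigma_w^2) — the ICC the
downstream pipeline should recover. The time series is the amplitude
times the canonical double-gamma response to the stimulus train, plus
random Legendre polynomial drift and spatially smoothed AR(1) Gaussian
noise. Session-2 amplitudes can additionally be shifted by covariate
effects and by a random per-subject "training" shift (which injects
extra within-subject variance, as neurofeedback training does).

Each subject consumes an independent RNG stream spawned from the master
seed, so enlarging the cohort never reshuffles existing subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .bold_models import canonical_regressor, legendre_basis

__all__ = [
    "AmplitudeClass",
    "SimulationConfig",
    "GroundTruth",
    "VoxelDataset",
    "true_icc_from_variances",
    "slab_class_map",
    "embedded_subregion_class_map",
    "event_related_config",
    "block_config",
    "make_block_events",
    "simulate_dataset",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def true_icc_from_variances(sigma_between: float, sigma_within: float) -> float:
    """Population reliability implied by the variance components:
    ``sigma_b^2 / (sigma_b^2 + sigma_w^2)``."""
    if sigma_between < 0 or sigma_within < 0:
        raise ValueError("variance components must be non-negative")
    if sigma_between == 0 and sigma_within == 0:
        raise ValueError("degenerate variance specification: both components zero")
    vb, vw = sigma_between**2, sigma_within**2
    return vb / (vb + vw)


@dataclass(frozen=True)
class AmplitudeClass:
    """Variance-component specification of one voxel class."""

    mean_amplitude: float
    sigma_between: float
    sigma_within: float

    @property
    def true_icc(self) -> float:
        if self.sigma_between == 0 and self.sigma_within == 0:
            return float("nan")  # null class: no amplitude variance at all
        return true_icc_from_variances(self.sigma_between, self.sigma_within)


def amplitude_class_for_icc(
    true_icc: float, mean_amplitude: float = 2.0, total_sd: float = 1.0
) -> AmplitudeClass:
    """Class with the given true ICC at fixed total amplitude SD."""
    if not 0.0 <= true_icc <= 1.0:
        raise ValueError("true ICC must be in [0, 1]")
    vb = true_icc * total_sd**2
    vw = (1.0 - true_icc) * total_sd**2
    return AmplitudeClass(mean_amplitude, float(np.sqrt(vb)), float(np.sqrt(vw)))


# Default classes: a reliable class at the boundary of "excellent", an
# unreliable class near the low end reported for task fMRI, and a null
# (no-response) class.
DEFAULT_CLASSES = {
    "reliable": amplitude_class_for_icc(0.75),
    "unreliable": amplitude_class_for_icc(0.10),
    "null": AmplitudeClass(0.0, 0.0, 0.0),
}


@dataclass
class SimulationConfig:
    n_subjects: int = 20
    n_sessions: int = 2
    grid_shape: tuple[int, int, int] = (12, 12, 6)
    voxel_size_mm: float = 3.0
    tr: float = 1.5
    design_kind: str = "event_related"  # or "block"
    events: pd.DataFrame | None = None  # onset, duration, trial_type
    classes: dict[str, AmplitudeClass] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    voxel_class_map: np.ndarray | None = None  # str codes, "" = out of mask
    ar1_coef: float = 0.3
    noise_sd: float = 0.5
    drift_order: int = 2
    drift_coef_sd: float = 0.5
    smoothness_fwhm_mm: float = 6.0
    covariate_model: dict[str, float] = field(default_factory=dict)
    session2_shift_mean: float = 0.0
    session2_shift_sd: float = 0.0
    patient_fraction: float = 57.0 / 92.0
    covariate_missing_rate: float = 0.0
    fir_length: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if any(d < 4 for d in self.grid_shape):
            raise ValueError("grid dimensions must be at least 4")
        for name, cls in self.classes.items():
            if cls.sigma_between < 0 or cls.sigma_within < 0:
                raise ValueError(f"negative variance component in class {name!r}")
        if self.voxel_class_map is not None:
            cmap = np.asarray(self.voxel_class_map)
            if cmap.shape != tuple(self.grid_shape):
                raise ValueError("voxel_class_map shape does not match the grid")
            in_mask = cmap != ""
            if not in_mask.any():
                raise ValueError("empty mask: no voxel assigned to any class")
            unknown = set(np.unique(cmap[in_mask])) - set(self.classes)
            if unknown:
                raise ValueError(f"voxel classes without a specification: {unknown}")


@dataclass
class GroundTruth:
    true_icc_per_class: dict[str, float]
    subject_amplitudes: np.ndarray  # (n_sub, n_sess, *grid); NaN out of mask
    voxel_class_map: np.ndarray
    covariates: pd.DataFrame
    covariate_effects: dict[str, float]


@dataclass
class VoxelDataset:
    """A subject x session collection of 4-D series over one grid."""

    data: np.ndarray  # (n_sub, n_sess, X, Y, Z, T)
    mask: np.ndarray
    tr: float
    events: pd.DataFrame
    subjects: list[str]
    affine: np.ndarray
    design_kind: str = "event_related"
    fir_length: int = 8
    covariates: pd.DataFrame | None = None

    def save(self, root) -> None:
        """BIDS-like layout: 4-D NIfTI per subject/session, mask, events
        TSV, covariates TSV."""
        import nibabel as nib

        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        for i, sub in enumerate(self.subjects):
            for j in range(self.data.shape[1]):
                d = root / f"sub-{sub}" / f"ses-{j + 1}"
                d.mkdir(parents=True, exist_ok=True)
                nib.save(
                    nib.Nifti1Image(self.data[i, j].astype(np.float32), self.affine),
                    d / f"sub-{sub}_ses-{j + 1}_bold.nii.gz",
                )
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), root / "mask.nii.gz")
        self.events.to_csv(root / "events.tsv", sep="\t", index=False)
        if self.covariates is not None:
            self.covariates.to_csv(root / "covariates.tsv", sep="\t", index=False)
        (root / "dataset.json").write_text(
            json.dumps(
                {
                    "tr": self.tr,
                    "design_kind": self.design_kind,
                    "fir_length": self.fir_length,
                    "subjects": self.subjects,
                    "n_sessions": int(self.data.shape[1]),
                }
            )
        )

    @classmethod
    def load(cls, root) -> "VoxelDataset":
        import nibabel as nib

        root = Path(root)
        meta = json.loads((root / "dataset.json").read_text())
        mask_img = nib.load(root / "mask.nii.gz")
        mask = np.asarray(mask_img.dataobj).astype(bool)
        subjects = meta["subjects"]
        n_sess = meta["n_sessions"]
        data = None
        for i, sub in enumerate(subjects):
            for j in range(n_sess):
                img = nib.load(
                    root / f"sub-{sub}" / f"ses-{j + 1}" / f"sub-{sub}_ses-{j + 1}_bold.nii.gz"
                )
                arr = np.asarray(img.dataobj, dtype=np.float64)
                if data is None:
                    data = np.zeros((len(subjects), n_sess) + arr.shape)
                data[i, j] = arr
        cov_path = root / "covariates.tsv"
        return cls(
            data=data,
            mask=mask,
            tr=float(meta["tr"]),
            events=pd.read_csv(root / "events.tsv", sep="\t"),
            subjects=subjects,
            affine=mask_img.affine,
            design_kind=meta["design_kind"],
            fir_length=int(meta["fir_length"]),
            covariates=pd.read_csv(cov_path, sep="\t") if cov_path.exists() else None,
        )


# ---------------------------------------------------------------------------
# Class-map helpers


def slab_class_map(
    grid_shape: tuple[int, int, int],
    fractions: dict[str, float] | None = None,
) -> np.ndarray:
    """Assign contiguous z-slabs of the grid to classes (whole grid in-mask)."""
    if fractions is None:
        fractions = {"reliable": 1 / 3, "unreliable": 1 / 3, "null": 1 / 3}
    cmap = np.empty(grid_shape, dtype=object)
    nz = grid_shape[2]
    bounds = np.cumsum([f / sum(fractions.values()) for f in fractions.values()]) * nz
    lo = 0
    for name, hi in zip(fractions, np.round(bounds).astype(int)):
        cmap[:, :, lo:hi] = name
        lo = hi
    cmap[:, :, lo:] = list(fractions)[-1]
    return cmap.astype(str)


def embedded_subregion_class_map(
    grid_shape: tuple[int, int, int],
    subregion_fraction: float = 0.2,
    inner: str = "reliable",
    outer: str = "unreliable",
) -> np.ndarray:
    """A compact cuboid of ``inner``-class voxels embedded in ``outer``
    tissue — e.g. a reliable subregion inside an unreliable ROI."""
    cmap = np.full(grid_shape, outer, dtype=object)
    n_total = int(np.prod(grid_shape))
    n_inner = max(1, int(round(subregion_fraction * n_total)))
    side = np.maximum(1, np.round(np.array(grid_shape) * subregion_fraction ** (1 / 3)))
    # Grow the cuboid until it holds the requested fraction.
    while np.prod(side) < n_inner:
        side[np.argmin(side / np.array(grid_shape))] += 1
    side = np.minimum(side.astype(int), grid_shape)
    start = [(g - s) // 2 for g, s in zip(grid_shape, side)]
    sl = tuple(slice(a, a + s) for a, s in zip(start, side))
    cmap[sl] = inner
    return cmap.astype(str)


# ---------------------------------------------------------------------------
# Design builders


def make_event_table(
    n_trials: int = 30, isi: float = 12.0, duration: float = 1.0, first_onset: float = 6.0
) -> pd.DataFrame:
    """Slow event-related stimulus train (negative-word valence labeling
    style): fixed inter-stimulus interval, brief events."""
    onsets = first_onset + isi * np.arange(n_trials)
    return pd.DataFrame(
        {"onset": onsets, "duration": duration, "trial_type": "stimulus"}
    )


def make_block_events(
    n_cycles: int = 4, block_s: float = 40.0, order: tuple[str, ...] = ("rest", "regulate", "count")
) -> pd.DataFrame:
    """Repeated 40-s rest -> regulate -> count neurofeedback cycles."""
    rows = []
    t = 0.0
    for _ in range(n_cycles):
        for kind in order:
            rows.append({"onset": t, "duration": block_s, "trial_type": kind})
            t += block_s
    return pd.DataFrame(rows)


def event_related_config(**kwargs) -> SimulationConfig:
    cfg = SimulationConfig(**kwargs)
    if cfg.events is None:
        cfg.events = make_event_table()
    cfg.design_kind = "event_related"
    return cfg


def block_config(**kwargs) -> SimulationConfig:
    kwargs.setdefault("tr", 2.0)
    cfg = SimulationConfig(**kwargs)
    if cfg.events is None:
        cfg.events = make_block_events()
    cfg.design_kind = "block"
    cfg.fir_length = int(round(40.0 / cfg.tr))
    return cfg


# ---------------------------------------------------------------------------
# Covariates

_COVARIATE_SPECS = {  # name: (mean, sd) for plausible clinical scales
    "bdi_pre": (22.0, 9.0),
    "bdi_post": (14.0, 10.0),
    "state_anxiety": (45.0, 11.0),
    "trait_anxiety": (48.0, 10.0),
    "rumination": (50.0, 12.0),
    "sleepiness": (3.0, 1.5),
}


def _simulate_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    n_pat = int(round(cfg.patient_fraction * n))
    df = pd.DataFrame({"subject": [f"{i + 1:03d}" for i in range(n)]})
    for name, (mu, sd) in _COVARIATE_SPECS.items():
        df[name] = rng.normal(mu, sd, size=n)
    df["scanner"] = rng.integers(0, 2, size=n)  # dummy-coded, two scanners
    df["group"] = np.r_[np.ones(n_pat, int), np.zeros(n - n_pat, int)]  # 1 = patient
    if cfg.covariate_missing_rate > 0:
        for name in _COVARIATE_SPECS:
            miss = rng.random(n) < cfg.covariate_missing_rate
            df.loc[miss, name] = np.nan
    return df


# ---------------------------------------------------------------------------
# Core generator


def _smooth_unit_noise(
    white: np.ndarray, fwhm_mm: float, voxel_mm: float
) -> np.ndarray:
    """Spatially smooth white noise and renormalize to unit variance.

    The renormalization constant is the exact l2 norm of the discrete
    smoothing kernel (computed from an impulse response), so the output
    field has unit marginal variance with the requested correlation
    structure.
    """
    if fwhm_mm <= 0:
        return white
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_mm
    sm = gaussian_filter(white, sigma=(sigma_vox,) * 3 + (0,), mode="constant")
    # Kernel l2 norm via impulse response on a sufficient grid.
    half = int(np.ceil(4 * sigma_vox)) * 2 + 1
    imp = np.zeros((half, half, half))
    imp[half // 2, half // 2, half // 2] = 1.0
    k = gaussian_filter(imp, sigma=sigma_vox, mode="constant")
    return sm / np.sqrt(np.sum(k**2))


def _ar1_filter(white: np.ndarray, rho: float) -> np.ndarray:
    """Unit-variance AR(1) process along the last axis."""
    if rho == 0:
        return white
    w = white.copy()
    # Start the recursion in its stationary distribution.
    w[..., 0] /= np.sqrt(1.0 - rho**2)
    return lfilter([np.sqrt(1.0 - rho**2)], [1.0, -rho], w, axis=-1)


def simulate_dataset(cfg: SimulationConfig) -> tuple[VoxelDataset, GroundTruth]:
    """Generate a multi-session dataset and its ground truth.

    Deterministic given ``cfg.seed``; subject i's data depend only on
    the master seed and i.
    """
    cfg.validate()
    if cfg.events is None:
        cfg.events = (
            make_event_table() if cfg.design_kind == "event_related" else make_block_events()
        )
    cmap = cfg.voxel_class_map
    if cmap is None:
        cmap = slab_class_map(cfg.grid_shape)
    cmap = np.asarray(cmap)
    mask = cmap != ""
    grid = tuple(cfg.grid_shape)

    # Task regressor: response to stimuli (event design) or to regulate
    # blocks (block design); count/rest blocks carry no response.
    if cfg.design_kind == "block":
        task_events = cfg.events[cfg.events["trial_type"] == "regulate"]
    else:
        task_events = cfg.events
    tail = cfg.fir_length * cfg.tr if cfg.design_kind == "event_related" else 0.0
    total_s = float((cfg.events["onset"] + cfg.events["duration"]).max() + tail)
    n_scans = int(np.ceil(total_s / cfg.tr))
    regressor = canonical_regressor(task_events, cfg.tr, n_scans)
    drift_basis = legendre_basis(n_scans, cfg.drift_order)[:, 1:]  # no intercept

    mu = np.zeros(grid)
    sb = np.zeros(grid)
    sw = np.zeros(grid)
    for name, cls in cfg.classes.items():
        sel = cmap == name
        mu[sel] = cls.mean_amplitude
        sb[sel] = cls.sigma_between
        sw[sel] = cls.sigma_within

    master = np.random.SeedSequence(cfg.seed)
    cov_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2**16,)))
    covariates = _simulate_covariates(cfg, cov_rng)

    # Covariate-linked session-2 amplitude shift (z-scored covariates).
    cov_shift = np.zeros(cfg.n_subjects)
    for name, effect in cfg.covariate_model.items():
        col = covariates[name].to_numpy(dtype=float)
        col = np.where(np.isnan(col), np.nanmean(col), col)
        z = (col - col.mean()) / (col.std() if col.std() > 0 else 1.0)
        cov_shift += effect * z

    n_sub, n_sess = cfg.n_subjects, cfg.n_sessions
    data = np.zeros((n_sub, n_sess, *grid, n_scans), dtype=np.float64)
    amplitudes = np.full((n_sub, n_sess, *grid), np.nan)
    V = int(mask.sum())

    for i in range(n_sub):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(i,)))
        b = rng.normal(0.0, 1.0, size=V) * sb[mask]
        shift2 = cfg.session2_shift_mean + (
            rng.normal(0.0, cfg.session2_shift_sd) if cfg.session2_shift_sd > 0 else 0.0
        )
        for j in range(n_sess):
            e = rng.normal(0.0, 1.0, size=V) * sw[mask]
            a = mu[mask] + b + e
            if j == 1:
                a = a + cov_shift[i] + shift2
            amplitudes[i, j][mask] = a
            series = np.zeros((*grid, n_scans))
            series[mask] = a[:, None] * regressor[None, :]
            if cfg.drift_order > 0 and cfg.drift_coef_sd > 0:
                coefs = rng.normal(0.0, cfg.drift_coef_sd, size=(V, cfg.drift_order))
                series[mask] += coefs @ drift_basis.T
            if cfg.noise_sd > 0:
                white = rng.standard_normal((*grid, n_scans))
                noise = _smooth_unit_noise(white, cfg.smoothness_fwhm_mm, cfg.voxel_size_mm)
                noise = _ar1_filter(noise, cfg.ar1_coef)
                series += cfg.noise_sd * noise
            data[i, j] = series

    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    dataset = VoxelDataset(
        data=data,
        mask=mask,
        tr=cfg.tr,
        events=cfg.events,
        subjects=list(covariates["subject"]),
        affine=affine,
        design_kind=cfg.design_kind,
        fir_length=cfg.fir_length,
        covariates=covariates,
    )
    truth = GroundTruth(
        true_icc_per_class={name: cls.true_icc for name, cls in cfg.classes.items()},
        subject_amplitudes=amplitudes,
        voxel_class_map=cmap,
        covariates=covariates,
        covariate_effects=dict(cfg.covariate_model),
    )
    return dataset, truth
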