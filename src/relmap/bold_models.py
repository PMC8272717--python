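"""Single-subject BOLD reactivity models.

Four modeling routes yield six reactivity parameters per voxel per
session:

1. amplitude of a canonically shaped BOLD response (one GLM beta
   against a boxcar convolved with the canonical double-gamma HRF),
2. area under the curve from an FIR (finite impulse response)
   deconvolution — the sum of the FIR betas,
3. peak amplitude from the same FIR regression — the signed maximum
   beta,
4. a gamma-variate fit to the FIR response curve, yielding onset-delay,
   rise-decay rate and height.

All models are fit per subject and session on already-preprocessed,
registered time series; per-voxel fit failures are flagged, never
fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy.optimize import least_squares

from .hrf import GAMMA_SHAPE_DEFAULT, double_gamma_hrf, gamma_variate

log = logging.getLogger(__name__)

__all__ = [
    "PARAMETERS",
    "DesignMatrix",
    "FIRCurve",
    "GammaFit",
    "ParameterMaps",
    "legendre_basis",
    "canonical_regressor",
    "build_design_matrix",
    "fit_glm",
    "fir_summaries",
    "fit_gamma_variate",
    "estimate_all_parameters",
]

#: The six reactivity parameters, in canonical order.
PARAMETERS = (
    "canonical_amplitude",
    "amplitude",
    "auc",
    "onset_delay",
    "rise_decay",
    "height",
)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_scans, p)
    names: list[str]
    tr: float
    kind: str  # "canonical" | "fir"
    task_columns: list[int]

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr


@dataclass
class FIRCurve:
    """Estimated response at each post-onset lag."""

    betas: np.ndarray
    lag_times: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        if self.betas.shape != self.lag_times.shape:
            raise ValueError("betas and lag_times must have the same length")


@dataclass
class GammaFit:
    onset_delay: float
    rise_decay: float
    height: float
    shape: float
    sse: float
    converged: bool
    degenerate: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return gamma_variate(t, self.onset_delay, self.rise_decay, self.height, self.shape)


def legendre_basis(n_scans: int, order: int) -> np.ndarray:
    """Legendre polynomials of degree 0..order evaluated on [-1, 1].

    Degree 0 is the constant (intercept) column. The Legendre basis is
    numerically well-conditioned compared to raw powers of time.
    """
    x = np.linspace(-1.0, 1.0, n_scans)
    cols = [legendre.legval(x, np.eye(order + 1)[d]) for d in range(order + 1)]
    return np.column_stack(cols)


def canonical_regressor(
    events: pd.DataFrame, tr: float, n_scans: int, oversample: int = 10
) -> np.ndarray:
    """Boxcar event train convolved with the canonical HRF, sampled at
    scan times and peak-normalized to a maximum of 1."""
    dt = tr / oversample
    t_hi = np.arange(0, n_scans * tr, dt)
    box = np.zeros_like(t_hi)
    for onset, dur in zip(events["onset"], events["duration"]):
        box[(t_hi >= onset) & (t_hi < onset + max(dur, dt))] = 1.0
    hrf = double_gamma_hrf(np.arange(0, 32.0, dt))
    conv = np.convolve(box, hrf)[: t_hi.size] * dt
    x = conv[:: oversample][:n_scans]
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return x


def build_design_matrix(
    events: pd.DataFrame,
    kind: str,
    tr: float,
    n_scans: int,
    drift_order: int = 0,
    fir_length: int = 8,
) -> DesignMatrix:
    """Design matrix for the canonical-amplitude GLM or the FIR model.

    ``canonical``: one task column — the peak-normalized convolved
    regressor. ``fir``: ``fir_length`` delta columns, column ``l`` set
    to 1 at the scan nearest ``onset + l*TR`` for every event; requires
    a slow design (inter-onset interval >= fir_length * TR) so FIR
    windows do not overlap. Legendre drift columns (including the
    intercept) are appended.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if events is None or len(events) == 0:
        raise ValueError("empty design: no events provided")
    onsets = np.asarray(events["onset"], dtype=float)
    if np.any(onsets < 0) or np.any(onsets >= n_scans * tr):
        raise ValueError("event onsets fall outside the run duration")

    if kind == "canonical":
        task = canonical_regressor(events, tr, n_scans)[:, None]
        task_names = ["task"]
    elif kind == "fir":
        if len(onsets) > 1:
            isi = np.min(np.diff(np.sort(onsets)))
            if isi < fir_length * tr:
                raise ValueError(
                    f"FIR windows overlap: inter-onset interval {isi:.1f}s "
                    f"< {fir_length} lags x TR {tr:.1f}s; use a slow design"
                )
        task = np.zeros((n_scans, fir_length))
        for onset in onsets:
            for lag in range(fir_length):
                idx = int(round((onset + lag * tr) / tr))
                if idx < n_scans:
                    task[idx, lag] = 1.0
        task_names = [f"fir_{lag:02d}" for lag in range(fir_length)]
    else:
        raise ValueError(f"unknown design kind {kind!r}")

    drift = legendre_basis(n_scans, drift_order)
    drift_names = [f"drift_{d}" for d in range(drift_order + 1)]
    X = np.column_stack([task, drift])
    return DesignMatrix(
        matrix=X,
        names=task_names + drift_names,
        tr=tr,
        kind=kind,
        task_columns=list(range(task.shape[1])),
    )


def fit_glm(series: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares fit of a design to one or many voxel series.

    ``series`` is (n_scans,) or (n_scans, n_voxels). Returns
    ``(betas, residuals)`` with betas shaped (p,) or (p, n_voxels).
    Raises on rank deficiency, naming the collinear columns.
    """
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [design.names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    y = np.asarray(series, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("series length does not match the design")
    betas, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ betas
    return betas, resid


def fir_summaries(curve: FIRCurve) -> tuple[float, float]:
    """(peak amplitude, area under the curve) of an FIR response.

    Amplitude is the signed maximum beta; AUC is the signed sum.
    """
    b = curve.betas
    if not np.all(np.isfinite(b)):
        raise ValueError("FIR curve contains non-finite betas")
    nonzero = b[b != 0]
    # Exactly-zero betas are no-response lags, not candidate peaks, so a
    # purely negative response has a negative peak.
    amplitude = float(np.max(nonzero)) if nonzero.size else 0.0
    return amplitude, float(np.sum(b))


def _robust_noise_sd(curve: np.ndarray) -> float:
    """Noise scale from first differences: 1.4826 * MAD(diff) / sqrt(2)."""
    d = np.diff(curve)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def fit_gamma_variate(
    curve: FIRCurve | np.ndarray,
    t_grid: np.ndarray | None = None,
    shape: float = GAMMA_SHAPE_DEFAULT,
) -> GammaFit:
    """Bounded nonlinear least-squares fit of the gamma-variate model.

    Fits ``g(t) = h * (r*(t-d)/a)**a * exp(a - r*(t-d))`` (peak value
    ``h`` at ``t = d + a/r``) to a response curve — typically an FIR
    estimate or a block-averaged trace. The shape ``a`` is fixed so
    onset-delay ``d``, rise-decay rate ``r`` and height ``h`` are the
    free parameters.

    Multi-start over onset delays {0, dt, 2dt}; bounds d in
    [0, t_max/2], r in [0.05, 10]; ``h`` is unbounded, so inverted
    (negative) responses are fit with negative height. Curves with no
    significant structure (peak magnitude at or below twice a robust
    first-difference noise estimate, or no range at all) are flagged
    ``degenerate`` with all parameters zero; optimizer failure likewise
    yields a degenerate result rather than an exception.
    """
    if isinstance(curve, FIRCurve):
        y = curve.betas
        t = curve.lag_times
    else:
        y = np.asarray(curve, dtype=float)
        if t_grid is None:
            raise ValueError("t_grid required when curve is a bare array")
        t = np.asarray(t_grid, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 time points for the gamma fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    peak = float(np.max(np.abs(y)))
    rng_y = float(np.max(y) - np.min(y))
    noise = _robust_noise_sd(y)
    if peak < 1e-12 or rng_y <= 1e-12 * max(1.0, peak) or peak <= 2.0 * noise:
        return GammaFit(0.0, 0.0, 0.0, shape, float(np.sum(y**2)), False, True)

    dt = float(np.median(np.diff(t)))
    t_max = float(t[-1])
    i_pk = int(np.argmax(np.abs(y)))
    h0 = float(y[i_pk])
    t_pk = float(t[i_pk])

    def resid(p: np.ndarray) -> np.ndarray:
        return gamma_variate(t, p[0], p[1], p[2], shape) - y

    best = None
    for d0 in (0.0, dt, 2.0 * dt):
        r0 = np.clip(shape / max(t_pk - d0, dt), 0.05, 10.0)
        x0 = np.array([min(d0, t_max / 2), r0, h0])
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=([0.0, 0.05, -np.inf], [t_max / 2, 10.0, np.inf]),
                method="trf",
                max_nfev=200,
            )
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        log.warning("gamma-variate optimizer failed on all starts; flagged degenerate")
        return GammaFit(0.0, 0.0, 0.0, shape, float(np.sum(y**2)), False, True)
    sse, sol = best
    d, r, h = (float(v) for v in sol.x)
    return GammaFit(d, r, h, shape, sse, bool(sol.success), False)


# ---------------------------------------------------------------------------
# Parameter maps


@dataclass
class ParameterMaps:
    """Per subject/session/voxel values of the six reactivity parameters.

    ``values`` has shape (n_subjects, n_sessions, n_parameters, *grid);
    NaN marks voxels where a parameter was not estimated.
    """

    values: np.ndarray
    parameters: tuple[str, ...]
    mask: np.ndarray
    tr: float
    subjects: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def get(self, parameter: str) -> np.ndarray:
        """(n_subjects, n_sessions, *grid) array for one parameter."""
        return self.values[:, :, self.parameters.index(parameter)]

    def save(self, root) -> None:
        """One 3-D NIfTI per subject/session/parameter plus an index TSV."""
        import nibabel as nib
        from pathlib import Path

        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        affine = self.metadata.get("affine", np.eye(4))
        rows = []
        for i, sub in enumerate(self.subjects or range(self.values.shape[0])):
            for j in range(self.values.shape[1]):
                for p, name in enumerate(self.parameters):
                    fn = f"sub-{sub}_ses-{j + 1}_{name}.nii.gz"
                    nib.save(
                        nib.Nifti1Image(
                            self.values[i, j, p].astype(np.float64), affine
                        ),
                        root / fn,
                    )
                    rows.append(
                        {"subject": sub, "session": j + 1, "parameter": name, "file": fn}
                    )
        pd.DataFrame(rows).to_csv(root / "parameter_maps.tsv", sep="\t", index=False)
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), root / "mask.nii.gz")
        pd.Series({"tr": self.tr}).to_json(root / "parameter_maps.json")

    @classmethod
    def load(cls, root) -> "ParameterMaps":
        import nibabel as nib
        import json
        from pathlib import Path

        root = Path(root)
        index = pd.read_csv(root / "parameter_maps.tsv", sep="\t", dtype={"subject": str})
        subjects = list(dict.fromkeys(index["subject"]))
        sessions = sorted(index["session"].unique())
        parameters = tuple(dict.fromkeys(index["parameter"]))
        mask_img = nib.load(root / "mask.nii.gz")
        mask = np.asarray(mask_img.dataobj).astype(bool)
        values = np.full(
            (len(subjects), len(sessions), len(parameters)) + mask.shape, np.nan
        )
        for _, row in index.iterrows():
            i = subjects.index(row["subject"])
            j = sessions.index(row["session"])
            p = parameters.index(row["parameter"])
            values[i, j, p] = np.asarray(nib.load(root / row["file"]).dataobj)
        meta = json.loads((root / "parameter_maps.json").read_text())
        return cls(
            values=values,
            parameters=parameters,
            mask=mask,
            tr=float(meta["tr"]),
            subjects=subjects,
            metadata={"affine": mask_img.affine},
        )


def estimate_all_parameters(
    dataset,
    parameters: tuple[str, ...] = PARAMETERS,
    drift_order: int = 2,
    fir_length: int | None = None,
) -> ParameterMaps:
    """Fit all requested reactivity parameters over a dataset.

    ``dataset`` is a :class:`~relmap.synthetic.VoxelDataset` (or any
    object exposing ``data`` (n_sub, n_sess, *grid, T), ``mask``,
    ``tr`` and an events table per the same contract). The canonical
    amplitude comes from the canonical GLM; amplitude/AUC from the FIR
    betas; onset-delay/rise-decay/height from the gamma-variate fit to
    the FIR curve. Restricting ``parameters`` skips unneeded models
    (the gamma fit is by far the most expensive).
    """
    data = dataset.data
    mask = dataset.mask
    tr = dataset.tr
    n_sub, n_sess = data.shape[0], data.shape[1]
    grid = data.shape[2:-1]
    n_scans = data.shape[-1]
    if fir_length is None:
        fir_length = getattr(dataset, "fir_length", 8)

    need_canonical = "canonical_amplitude" in parameters
    need_fir = any(p in parameters for p in ("amplitude", "auc"))
    need_gamma = any(p in parameters for p in ("onset_delay", "rise_decay", "height"))

    events = dataset.events
    X_can = (
        build_design_matrix(events, "canonical", tr, n_scans, drift_order)
        if need_canonical
        else None
    )
    X_fir = (
        build_design_matrix(events, "fir", tr, n_scans, drift_order, fir_length)
        if (need_fir or need_gamma)
        else None
    )
    lag_times = np.arange(fir_length) * tr

    values = np.full((n_sub, n_sess, len(parameters)) + grid, np.nan)
    idx = {p: parameters.index(p) for p in parameters}
    mflat = mask.ravel()
    n_degenerate = 0

    for i in range(n_sub):
        for j in range(n_sess):
            Y = data[i, j].reshape(-1, n_scans).T[:, mflat]  # (T, V)
            if need_canonical:
                betas, _ = fit_glm(Y, X_can)
                vol = np.full(mflat.shape, np.nan)
                vol[mflat] = betas[0]
                values[i, j, idx["canonical_amplitude"]] = vol.reshape(grid)
            if need_fir or need_gamma:
                betas, _ = fit_glm(Y, X_fir)
                fir_betas = betas[:fir_length]  # (L, V)
                if "amplitude" in idx:
                    vol = np.full(mflat.shape, np.nan)
                    vol[mflat] = fir_betas.max(axis=0)
                    values[i, j, idx["amplitude"]] = vol.reshape(grid)
                if "auc" in idx:
                    vol = np.full(mflat.shape, np.nan)
                    vol[mflat] = fir_betas.sum(axis=0)
                    values[i, j, idx["auc"]] = vol.reshape(grid)
                if need_gamma:
                    vols = {p: np.full(mflat.shape, np.nan) for p in ("onset_delay", "rise_decay", "height")}
                    for v, flat_idx in enumerate(np.flatnonzero(mflat)):
                        fit = fit_gamma_variate(fir_betas[:, v], lag_times)
                        if fit.degenerate:
                            n_degenerate += 1
                        vols["onset_delay"][flat_idx] = fit.onset_delay
                        vols["rise_decay"][flat_idx] = fit.rise_decay
                        vols["height"][flat_idx] = fit.height
                    for p, vol in vols.items():
                        if p in idx:
                            values[i, j, idx[p]] = vol.reshape(grid)
    if need_gamma:
        log.info("gamma-variate fits flagged degenerate: %d", n_degenerate)
    return ParameterMaps(
        values=values,
        parameters=tuple(parameters),
        mask=mask,
        tr=tr,
        subjects=list(getattr(dataset, "subjects", [])),
        metadata={"drift_order": drift_order, "fir_length": fir_length,
                  "affine": getattr(dataset, "affine", np.eye(4))},
    )
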