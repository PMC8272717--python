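"""Two preprocessing streams for already-registered data.

``tbv_style`` emulates what a real-time neurofeedback package does
online: 4 mm FWHM spatial smoothing followed by a fourth-order
polynomial detrend. ``standard`` is a contemporary post-hoc stream:
4 mm smoothing plus a nuisance GLM with motion parameters and their
derivatives, white-matter and CSF series, and five polynomial drift
terms. Motion correction, despiking and slice timing are out of scope —
inputs are assumed registered (always true for the synthetic data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .bold_models import legendre_basis

log = logging.getLogger(__name__)

__all__ = [
    "PreprocSpec",
    "smooth_gaussian",
    "detrend_polynomial",
    "nuisance_glm",
    "nuisance_derivatives",
    "run_preprocessing",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PreprocSpec:
    style: str = "standard"  # "tbv_style" | "standard"
    smoothing_fwhm_mm: float = 4.0
    detrend_order: int = 4  # tbv_style drift removal
    polynomial_terms: int = 5  # standard-stream drift columns (degree 0..4)
    nuisance: pd.DataFrame | None = None  # motion/WM/CSF columns

    def __post_init__(self) -> None:
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be non-negative")
        if self.detrend_order < 0 or self.polynomial_terms < 0:
            raise ValueError("polynomial orders must be non-negative")
        if self.style not in ("tbv_style", "standard"):
            raise ValueError(f"unknown preprocessing style {self.style!r}")


def smooth_gaussian(
    series: np.ndarray, fwhm_mm: float, voxel_size_mm: float
) -> np.ndarray:
    """Isotropic spatial Gaussian smoothing of a (X, Y, Z, T) series.

    ``fwhm_mm = 0`` is the identity. The kernel is truncated at the
    volume boundary (zero padding), so the image sum is preserved only
    up to boundary loss.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(series, dtype=float).copy()
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    arr = np.asarray(series, dtype=float)
    sig = (sigma_vox,) * 3 + (0,) * (arr.ndim - 3)
    return gaussian_filter(arr, sigma=sig, mode="constant")


def detrend_polynomial(series: np.ndarray, order: int) -> np.ndarray:
    """Residuals of an OLS fit of Legendre polynomials up to ``order``.

    ``series`` has time on the last axis. Order 0 demeans. The output is
    orthogonal to every polynomial regressor.
    """
    arr = np.asarray(series, dtype=float)
    n_t = arr.shape[-1]
    if n_t <= order + 1:
        raise ValueError(f"{n_t} timepoints insufficient for order-{order} detrend")
    X = legendre_basis(n_t, order)
    flat = arr.reshape(-1, n_t).T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return resid.T.reshape(arr.shape)


def nuisance_derivatives(nuisance: pd.DataFrame) -> pd.DataFrame:
    """Backward-difference temporal derivatives (first element zero)."""
    deriv = nuisance.diff().fillna(0.0)
    deriv.columns = [f"{c}_deriv" for c in nuisance.columns]
    return deriv


def nuisance_glm(
    series: np.ndarray,
    nuisance: pd.DataFrame | np.ndarray | None,
    polynomial_terms: int = 5,
) -> np.ndarray:
    """Residualize voxel series against nuisance regressors.

    The design always includes ``polynomial_terms`` Legendre drift
    columns (degree 0 upward, so the intercept is always present).
    Collinear nuisance columns are dropped with a logged warning, never
    silently. Residuals are orthogonal to every retained column.
    """
    arr = np.asarray(series, dtype=float)
    n_t = arr.shape[-1]
    drift = legendre_basis(n_t, max(polynomial_terms - 1, 0))
    names = [f"poly_{d}" for d in range(drift.shape[1])]
    X = drift
    if nuisance is not None:
        if isinstance(nuisance, pd.DataFrame):
            N = nuisance.to_numpy(dtype=float)
            nnames = [str(c) for c in nuisance.columns]
        else:
            N = np.asarray(nuisance, dtype=float)
            if N.ndim == 1:
                N = N[:, None]
            nnames = [f"nuisance_{j}" for j in range(N.shape[1])]
        if N.shape[0] != n_t:
            raise ValueError("nuisance table length does not match the series")
        X = np.column_stack([X, N])
        names += nnames
    # Prune to full column rank, earlier columns win.
    keep: list[int] = []
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
        else:
            msg = f"dropping collinear nuisance column {names[j]!r}"
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
    X = X[:, keep]
    flat = arr.reshape(-1, n_t).T
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return resid.T.reshape(arr.shape)


def run_preprocessing(
    series: np.ndarray, spec: PreprocSpec, voxel_size_mm: float
) -> np.ndarray:
    """Apply one full stream to a (X, Y, Z, T) series."""
    out = smooth_gaussian(series, spec.smoothing_fwhm_mm, voxel_size_mm)
    if spec.style == "tbv_style":
        out = detrend_polynomial(out, spec.detrend_order)
    else:
        nuis = spec.nuisance
        if nuis is not None:
            # Derivatives are added for the motion parameters; WM/CSF
            # series enter as-is.
            motion = [c for c in nuis.columns if str(c).startswith(("motion", "trans", "rot"))]
            if motion:
                nuis = pd.concat([nuis, nuisance_derivatives(nuis[motion])], axis=1)
        out = nuisance_glm(out, nuis, spec.polynomial_terms)
    return out
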