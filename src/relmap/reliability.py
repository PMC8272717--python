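"""Core test-retest psychometrics.

Implements the reliability machinery applied voxelwise to BOLD
reactivity parameter maps:

* Tukey-hinge Windsorizing of across-subject outliers,
* ICC(3,1) — two-way mixed model, consistency, single measurement —
  with its ANOVA decomposition,
* voxelwise ICC maps and ROI summaries with the conventional category
  cutoffs (<0.4 poor, 0.4-0.59 fair, 0.60-0.74 good, >=0.75 excellent),
* covariate-adjusted reliability via semi-partial correlations in the
  regression ``post ~ intercept + covariates + pre``, with regression
  imputation of missing covariates and a Gaussian-ML AIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ICCDecomposition",
    "ICCMap",
    "ROISummary",
    "SemipartialResult",
    "tukey_hinges",
    "windsorize_tukey",
    "icc_3_1",
    "icc_3_1_matrix",
    "voxelwise_icc",
    "roi_summary",
    "reliability_category",
    "impute_covariates",
    "semipartial_reliability",
    "count_voxels_above",
    "RELIABILITY_THRESHOLDS",
]

#: Conventional reliability effect-size thresholds: fair, good, and the
#: two common cutoffs for labeling data "reliable" / clinically meaningful.
RELIABILITY_THRESHOLDS = (0.4, 0.6, 0.7, 0.75)


@dataclass(frozen=True)
class ICCDecomposition:
    """Two-way ANOVA mean squares underlying ICC(3,1)."""

    bms: float  # between-subject (rows) mean square
    jms: float  # between-session (columns) mean square
    ems: float  # residual mean square
    n: int  # subjects
    k: int  # sessions

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


@dataclass
class ICCMap:
    """Voxelwise ICC values over a mask, with bookkeeping.

    ``icc`` is a 3-D array, NaN outside the mask and at voxels where
    fewer than 3 subjects had complete data.
    """

    icc: np.ndarray
    mask: np.ndarray
    n_subjects: int
    n_sessions: int = 2
    windsorized: bool = False
    clip_counts: np.ndarray | None = None  # per-voxel Windsorize clip count
    dropped_counts: np.ndarray | None = None  # per-voxel listwise-dropped subjects
    decomposition: dict[str, np.ndarray] = field(default_factory=dict)

    def values(self) -> np.ndarray:
        """Finite in-mask ICC values as a flat array."""
        v = self.icc[self.mask]
        return v[np.isfinite(v)]


@dataclass(frozen=True)
class ROISummary:
    mean: float
    sd: float
    median: float
    n_voxels: int
    counts_above: dict[float, int]


@dataclass
class SemipartialResult:
    """Covariate-adjusted reliability of session-1 values for session 2."""

    sr: float
    betas: np.ndarray
    aic: float
    with_covariates: bool
    r2_full: float
    r2_reduced: float
    n: int


# ---------------------------------------------------------------------------
# Windsorizing


def tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Tukey's fold hinges (median-inclusive), not interpolated quartiles.

    With sorted data of size n, the median depth is (n + 1) / 2 and the
    hinge depth is (floor(median depth) + 1) / 2; a half-integer depth
    averages the two adjacent order statistics.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    depth = (np.floor((n + 1) / 2) + 1) / 2

    def _at(d: float, arr: np.ndarray) -> float:
        lo = int(np.floor(d)) - 1
        if d == np.floor(d):
            return float(arr[lo])
        return float(0.5 * (arr[lo] + arr[lo + 1]))

    return _at(depth, x), _at(depth, x[::-1])


def windsorize_tukey(values: np.ndarray) -> np.ndarray:
    """Clip values beyond 1.5 H-spreads outside the Tukey hinges.

    Values below ``H1 - 1.5*(H2 - H1)`` are set to that lower fence,
    values above ``H2 + 1.5*(H2 - H1)`` to the upper fence. Samples with
    fewer than 4 values are returned unchanged with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 values; Windsorizing skipped", stacklevel=2)
        return x.copy()
    h1, h2 = tukey_hinges(x)
    spread = h2 - h1
    lo, hi = h1 - 1.5 * spread, h2 + 1.5 * spread
    return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# ICC(3,1)


def _mean_squares(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-way ANOVA mean squares along the last two axes (..., n, k)."""
    n, k = data.shape[-2], data.shape[-1]
    grand = data.mean(axis=(-2, -1), keepdims=True)
    row_means = data.mean(axis=-1, keepdims=True)
    col_means = data.mean(axis=-2, keepdims=True)
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=(-2, -1))
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=(-2, -1))
    resid = data - row_means - col_means + grand
    ss_err = (resid**2).sum(axis=(-2, -1))
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return bms, jms, ems


def icc_3_1(data: np.ndarray) -> tuple[float, ICCDecomposition]:
    """ICC(3,1): two-way mixed model, consistency, single measurement.

    ``data`` is an (n subjects x k sessions) matrix with no missing
    cells. Returns ``(BMS - EMS) / (BMS + (k - 1) * EMS)`` (the
    Shrout-Fleiss (3,1) estimator) together with the ANOVA
    decomposition. Session (column) main effects are removed, so a
    constant offset between sessions does not reduce the ICC; negative
    estimates are returned as-is.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x sessions matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 sessions, got {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells; drop or impute subjects first")
    if np.allclose(x, x.flat[0]):
        raise ValueError("constant data: ICC undefined (zero total variance)")
    bms, jms, ems = _mean_squares(x)
    denom = bms + (k - 1) * ems
    if denom == 0:
        raise ValueError("constant data: ICC undefined (zero total variance)")
    icc = float((bms - ems) / denom)
    return icc, ICCDecomposition(float(bms), float(jms), float(ems), n, k)


def icc_3_1_matrix(data: np.ndarray) -> np.ndarray:
    """Vectorized ICC(3,1) over stacked (..., n, k) matrices.

    Degenerate (zero-variance) slices yield NaN rather than raising.
    """
    x = np.asarray(data, dtype=float)
    k = x.shape[-1]
    bms, _, ems = _mean_squares(x)
    denom = bms + (k - 1) * ems
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (bms - ems) / denom
    return np.where(denom > 0, out, np.nan)


def voxelwise_icc(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    windsorize: bool = True,
) -> ICCMap:
    """Voxelwise ICC(3,1) map from per-subject/session parameter values.

    Parameters
    ----------
    values
        Array of shape (n_subjects, n_sessions, X, Y, Z) — or
        (n_subjects, n_sessions, V) for flat voxel sets — of one
        reactivity parameter. NaN marks missing estimates.
    mask
        Boolean array over the voxel grid; defaults to all voxels.
    windsorize
        Clip across-subject outliers beyond the Tukey fences, per
        session per voxel, before computing the ICC.

    Subjects missing a voxel's value in either session are dropped
    listwise at that voxel; voxels with fewer than 3 complete subjects
    get NaN. Windsorizing is performed on complete subjects only.
    """
    vals = np.asarray(values, dtype=float)
    n_sub, n_sess = vals.shape[0], vals.shape[1]
    spatial = vals.shape[2:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    flat = vals.reshape(n_sub, n_sess, -1)[:, :, mask.ravel()]  # (n, k, V)
    complete = np.isfinite(flat).all(axis=1)  # (n, V)
    n_complete = complete.sum(axis=0)
    dropped = n_sub - n_complete

    V = flat.shape[-1]
    icc_flat = np.full(V, np.nan)
    clip_flat = np.zeros(V, dtype=int)

    all_complete = bool(complete.all())
    if all_complete and not windsorize:
        icc_flat = icc_3_1_matrix(np.moveaxis(flat, -1, 0))  # (V, n, k)
    else:
        for v in range(V):
            keep = complete[:, v]
            nv = int(keep.sum())
            if nv < 3:
                log.info("voxel %d: only %d complete subjects, ICC set NaN", v, nv)
                continue
            d = flat[keep, :, v]  # (nv, k)
            if windsorize and nv >= 4:
                for j in range(n_sess):
                    clipped = windsorize_tukey(d[:, j])
                    clip_flat[v] += int(np.sum(clipped != d[:, j]))
                    d[:, j] = clipped
            icc_flat[v] = icc_3_1_matrix(d[None])[0]

    icc = np.full(spatial, np.nan)
    icc[mask] = icc_flat
    clip_counts = np.zeros(spatial, dtype=int)
    clip_counts[mask] = clip_flat
    dropped_counts = np.zeros(spatial, dtype=int)
    dropped_counts[mask] = dropped
    return ICCMap(
        icc=icc,
        mask=mask,
        n_subjects=n_sub,
        n_sessions=n_sess,
        windsorized=windsorize,
        clip_counts=clip_counts,
        dropped_counts=dropped_counts,
    )


def reliability_category(icc: float) -> str:
    """Conventional label: poor / fair / good / excellent."""
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def roi_summary(
    icc_map: ICCMap | np.ndarray,
    roi_mask: np.ndarray | None = None,
    thresholds: tuple[float, ...] = RELIABILITY_THRESHOLDS,
) -> ROISummary:
    """Mean, SD, median of voxelwise ICCs within an ROI, plus the number
    of voxels exceeding each reliability threshold (uncorrected)."""
    icc = icc_map.icc if isinstance(icc_map, ICCMap) else np.asarray(icc_map, float)
    if roi_mask is None:
        roi_mask = np.isfinite(icc)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != icc.shape:
        raise ValueError("ROI mask shape does not match the ICC map")
    vals = icc[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI mask has no finite ICC voxels")
    counts = {float(t): int(np.sum(vals > t)) for t in thresholds}
    return ROISummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        median=float(np.median(vals)),
        n_voxels=int(vals.size),
        counts_above=counts,
    )


def count_voxels_above(
    icc_map: ICCMap | np.ndarray,
    thresholds: tuple[float, ...] = RELIABILITY_THRESHOLDS,
    min_cluster_sizes: dict[float, int] | None = None,
    connectivity: int = 6,
) -> pd.DataFrame:
    """Voxel counts above each reliability threshold, optionally cluster
    corrected.

    With ``min_cluster_sizes`` (threshold -> minimum extent from the
    cluster-simulation module), only voxels in surviving clusters are
    counted; otherwise the raw supra-threshold count is returned.
    """
    from .cluster import extract_clusters

    icc = icc_map.icc if isinstance(icc_map, ICCMap) else np.asarray(icc_map, float)
    rows = []
    for t in thresholds:
        if min_cluster_sizes is None:
            n = int(np.sum(icc[np.isfinite(icc)] > t))
            rows.append({"threshold": float(t), "n_voxels": n, "cluster_corrected": False})
        else:
            table = extract_clusters(
                icc, theta=t, min_size=min_cluster_sizes[t], connectivity=connectivity
            )
            n = int(sum(c.size for c in table.clusters if c.survives))
            rows.append({"threshold": float(t), "n_voxels": n, "cluster_corrected": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariates


def impute_covariates(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regression imputation of missing covariate cells.

    Each missing cell is replaced by the prediction of an OLS regression
    of that covariate on all the other covariates, fit on complete
    cases. Deterministic. Returns the imputed table and a boolean flag
    table marking imputed cells.
    """
    df = table.copy()
    num = df.select_dtypes(include=[np.number])
    flags = num.isna()
    if not flags.to_numpy().any():
        return df, flags
    for col in num.columns:
        frac = num[col].notna().mean()
        if frac < 0.5:
            raise ValueError(
                f"covariate {col!r} observed in {frac:.0%} of subjects (< 50%)"
            )
    complete = num.dropna()
    if complete.empty:
        raise ValueError("no complete-case rows to fit the imputation model")
    n_imputed = 0
    for col in num.columns:
        miss = flags[col]
        if not miss.any():
            continue
        # A row may be missing several covariates; each cell is predicted
        # from the covariates observed in that row, with the model fit on
        # complete cases.
        for idx in num.index[miss]:
            others = [
                c for c in num.columns if c != col and not pd.isna(num.at[idx, c])
            ]
            if not others:
                raise ValueError(
                    f"subject {idx} has no observed covariates to impute {col!r} from"
                )
            X = np.column_stack([np.ones(len(complete)), complete[others].to_numpy()])
            beta, *_ = np.linalg.lstsq(X, complete[col].to_numpy(), rcond=None)
            df.at[idx, col] = float(
                beta[0] + num.loc[idx, others].to_numpy(dtype=float) @ beta[1:]
            )
            n_imputed += 1
    log.info("imputed %d missing covariate cells", n_imputed)
    return df, flags


def _prune_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns until full rank, keeping earlier columns, with warning."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {names[j]!r}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def semipartial_reliability(
    pre: np.ndarray,
    post: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> SemipartialResult:
    """Reliability of session-1 values for predicting session 2, with
    covariate-shared variance removed.

    Fits ``post ~ intercept + covariates + pre`` by OLS and returns the
    semi-partial correlation of ``pre``:
    ``sr = sign(beta_pre) * sqrt(R2_full - R2_without_pre)``,
    together with the Gaussian-ML AIC of the full model. With no
    covariates ``sr`` reduces to the Pearson correlation of pre and
    post.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    n = pre.size
    if covariates is None:
        C = np.empty((n, 0))
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(dtype=float)
        names = [str(c) for c in covariates.columns]
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"cov{j}" for j in range(C.shape[1])]
    if C.shape[0] != n or post.size != n:
        raise ValueError("pre, post and covariates must have matching rows")

    if C.shape[1] > 0:
        Cc = C - C.mean(axis=0)
        Cc, names = _prune_collinear(Cc, names)
    else:
        Cc = C
    p = Cc.shape[1] + 1  # covariates + pre
    if n <= p + 2:
        raise ValueError(f"n={n} too small for {p} predictors")

    def _r2(X: np.ndarray) -> tuple[float, np.ndarray, float]:
        Xd = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xd, post, rcond=None)
        resid = post - Xd @ beta
        sse = float(resid @ resid)
        sst = float(((post - post.mean()) ** 2).sum())
        return 1.0 - sse / sst, beta, sse

    r2_full, betas, sse_full = _r2(np.column_stack([Cc, pre]))
    if Cc.shape[1] > 0:
        r2_red, _, _ = _r2(Cc)
    else:
        r2_red = 0.0
    beta_pre = betas[-1]
    sr = float(np.sign(beta_pre) * np.sqrt(max(r2_full - r2_red, 0.0)))

    # Gaussian AIC with ML variance: k = predictors + intercept + variance.
    sigma2 = sse_full / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k_params = p + 1 + 1
    aic = float(2 * k_params - 2 * loglik)
    return SemipartialResult(
        sr=sr,
        betas=betas,
        aic=aic,
        with_covariates=Cc.shape[1] > 0,
        r2_full=float(r2_full),
        r2_reduced=float(r2_red),
        n=n,
    )
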