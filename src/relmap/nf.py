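"""Neurofeedback feedback-signal reconstruction and reliability.

In the 40-s rest / regulate / count block protocol, the feedback value
shown to a participant at each TR of a regulate block is the ROI signal
at that TR minus the mean signal of the immediately preceding rest
block. This module reconstructs that trace from an ROI-mean time
series, averages it over regulate blocks, summarizes each visit by the
trace mean or by a gamma-variate fit, and computes across-visit
test-retest reliability (ICC(3,1), optionally covariate-adjusted
semi-partial correlations) of each summary parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bold_models import GammaFit, fit_gamma_variate
from .reliability import SemipartialResult, icc_3_1, semipartial_reliability

log = logging.getLogger(__name__)

__all__ = [
    "BlockDesign",
    "FeedbackTrace",
    "feedback_signal",
    "average_blocks",
    "summarize_visit",
    "nf_reliability",
]


@dataclass
class BlockDesign:
    """Ordered (kind, onset s, duration s) blocks of one run."""

    blocks: list[tuple[str, float, float]]
    tr: float

    @classmethod
    def from_events(cls, events: pd.DataFrame, tr: float) -> "BlockDesign":
        rows = events.sort_values("onset")
        return cls(
            blocks=[
                (str(r["trial_type"]), float(r["onset"]), float(r["duration"]))
                for _, r in rows.iterrows()
            ],
            tr=tr,
        )

    def validate(self) -> None:
        last_end = -np.inf
        prev_kind = None
        for kind, onset, dur in self.blocks:
            if onset < last_end - 1e-9:
                raise ValueError("blocks overlap")
            if kind == "regulate" and prev_kind != "rest":
                log.warning("regulate block at %.0fs not preceded by rest", onset)
            last_end = onset + dur
            prev_kind = kind

    def _scan_slice(self, onset: float, dur: float) -> slice:
        start = int(round(onset / self.tr))
        stop = int(round((onset + dur) / self.tr))
        return slice(start, stop)


@dataclass
class FeedbackTrace:
    """Per-regulate-block feedback values and their block average."""

    block_traces: np.ndarray  # (n_blocks, n_tr_per_block)
    tr: float
    percent_signal_change: bool = False

    @property
    def lag_times(self) -> np.ndarray:
        return np.arange(self.block_traces.shape[1]) * self.tr


def feedback_signal(
    roi_series: np.ndarray,
    design: BlockDesign,
    percent_signal_change: bool = False,
) -> FeedbackTrace:
    """Reconstruct the feedback trace from an ROI-mean series.

    For each regulate block the trace is the per-TR signal minus the
    mean of the preceding rest block (count blocks are not used). With
    ``percent_signal_change`` the difference is additionally divided by
    the rest mean and scaled by 100; the default is the absolute
    difference. Adding a constant to the whole series leaves the
    default trace unchanged.
    """
    series = np.asarray(roi_series, dtype=float).ravel()
    design.validate()
    total_scans = design._scan_slice(*design.blocks[-1][1:]).stop
    if series.size < total_scans:
        raise ValueError(
            f"series has {series.size} scans but the design needs {total_scans}"
        )
    traces = []
    prev: tuple[str, float, float] | None = None
    for kind, onset, dur in design.blocks:
        if kind == "regulate":
            if prev is None or prev[0] != "rest":
                log.warning("skipping regulate block at %.0fs with no preceding rest", onset)
                prev = (kind, onset, dur)
                continue
            rest_mean = float(series[design._scan_slice(prev[1], prev[2])].mean())
            vals = series[design._scan_slice(onset, dur)] - rest_mean
            if percent_signal_change:
                vals = 100.0 * vals / rest_mean
            traces.append(vals)
        prev = (kind, onset, dur)
    if not traces:
        raise ValueError("design contains no usable regulate block")
    n = min(len(t) for t in traces)
    return FeedbackTrace(
        block_traces=np.vstack([t[:n] for t in traces]),
        tr=design.tr,
        percent_signal_change=percent_signal_change,
    )


def average_blocks(trace: FeedbackTrace) -> np.ndarray:
    """Pointwise mean of the feedback trace across regulate blocks."""
    return trace.block_traces.mean(axis=0)


def summarize_visit(
    time_course: np.ndarray,
    method: str,
    tr: float | None = None,
) -> float | GammaFit:
    """Summarize a visit's block-averaged trace.

    ``mean`` returns the scalar mean; ``gamma`` fits the gamma-variate
    response model (degenerate fits carry zero parameters, per that
    model's contract).
    """
    tc = np.asarray(time_course, dtype=float).ravel()
    if method == "mean":
        return float(tc.mean())
    if method == "gamma":
        if tc.size < 5:
            raise ValueError("need at least 5 points for the gamma summary")
        if tr is None:
            raise ValueError("tr required for the gamma summary")
        return fit_gamma_variate(tc, np.arange(tc.size) * tr)
    raise ValueError(f"unknown summary method {method!r}")


@dataclass
class NFReliabilityResult:
    icc: dict[str, float]
    sr: dict[str, SemipartialResult] = field(default_factory=dict)
    n_subjects: int = 0


def nf_reliability(
    visit1: pd.DataFrame,
    visit2: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> NFReliabilityResult:
    """Across-visit reliability of feedback-signal summary parameters.

    ``visit1``/``visit2`` are indexed by subject with one column per
    summary parameter (e.g. mean, onset_delay, rise_decay, height).
    Subjects present in only one visit are dropped with a log entry.
    Returns per-parameter ICC(3,1), plus covariate-adjusted semi-partial
    correlations when a covariate table (same subject index) is given.
    """
    common = visit1.index.intersection(visit2.index)
    dropped = len(visit1.index.union(visit2.index)) - len(common)
    if dropped:
        log.info("dropping %d unpaired subjects", dropped)
    v1, v2 = visit1.loc[common], visit2.loc[common]
    icc: dict[str, float] = {}
    sr: dict[str, SemipartialResult] = {}
    for col in v1.columns:
        data = np.column_stack([v1[col].to_numpy(float), v2[col].to_numpy(float)])
        ok = np.isfinite(data).all(axis=1)
        try:
            icc[col], _ = icc_3_1(data[ok])
        except ValueError as exc:
            log.warning("ICC for %r undefined: %s", col, exc)
            icc[col] = float("nan")
        if covariates is not None:
            cov = covariates.loc[common].to_numpy(float)[ok]
            sr[col] = semipartial_reliability(data[ok, 0], data[ok, 1], cov)
    return NFReliabilityResult(icc=icc, sr=sr, n_subjects=int(len(common)))
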