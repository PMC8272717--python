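"""Hemodynamic response shapes.

Two parametric forms are used throughout the package:

* a canonical double-gamma HRF (positive lobe peaking at 5 s, an
  undershoot peaking at 15 s with 1/6 relative amplitude), used both to
  generate synthetic BOLD responses and as the "canonically shaped"
  regressor in the canonical-amplitude GLM;
* a three-parameter gamma-variate response curve parameterized by
  onset-delay, rise-decay rate and height, used as the fitted model for
  response-shape summaries.

The gamma variate is deliberately a *different* parametric family from
the double gamma (no undershoot, free onset and rate), so fitting it to
simulated data is a genuine estimation problem rather than self-recovery.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["double_gamma_hrf", "gamma_variate", "GAMMA_SHAPE_DEFAULT"]

#: Fixed shape parameter of the gamma-variate response model. With shape
#: fixed, exactly three parameters (onset-delay, rise-decay rate, height)
#: remain free, which keeps the fit identifiable from a handful of
#: post-stimulus samples.
GAMMA_SHAPE_DEFAULT = 6.0

# Double-gamma parameters: Gamma(shape=6, scale=1) peaks at t = 5 s,
# Gamma(shape=16, scale=1) peaks at t = 15 s; undershoot ratio 1/6.
_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Peak-normalized so that the maximum over a dense grid equals 1.
    Values at ``t < 0`` are zero.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, _PEAK_SHAPE) - _UNDERSHOOT_RATIO * _gamma_dist.pdf(
        t, _UNDERSHOOT_SHAPE
    )
    h = np.where(t < 0, 0.0, h)
    # Normalization constant: peak of the positive lobe on a dense grid.
    dense = np.linspace(0.0, 30.0, 3001)
    peak = np.max(
        _gamma_dist.pdf(dense, _PEAK_SHAPE)
        - _UNDERSHOOT_RATIO * _gamma_dist.pdf(dense, _UNDERSHOOT_SHAPE)
    )
    return h / peak


def gamma_variate(
    t: np.ndarray,
    onset_delay: float,
    rise_decay: float,
    height: float,
    shape: float = GAMMA_SHAPE_DEFAULT,
) -> np.ndarray:
    """Peak-normalized gamma-variate response curve.

    ``g(t) = h * (r*(t - d)/a)**a * exp(a - r*(t - d))`` for ``t >= d``
    and 0 before onset, where ``d`` is the onset delay (s), ``r`` the
    rise-decay rate (1/s), ``h`` the height and ``a`` the fixed shape.
    The curve peaks at ``t = d + a/r`` with value exactly ``h``.
    """
    t = np.asarray(t, dtype=float)
    tau = t - onset_delay
    out = np.zeros_like(t)
    pos = tau > 0
    x = rise_decay * tau[pos] / shape
    out[pos] = height * np.power(x, shape) * np.exp(shape - rise_decay * tau[pos])
    return out
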