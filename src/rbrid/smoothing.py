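"""Friedman's variable-span "super smoother" (supsmu), implemented from scratch.

The smoother runs local linear least-squares fits at three primary spans
(fractions of the data used per window), estimates each span's pointwise
quality by leave-one-out cross-validated residuals, picks the best span at
every point, smooths the span choices themselves, and interpolates between
the bracketing primary-span fits. The result adapts its bandwidth along the
curve: narrow windows where the signal has structure, wide windows where it
is flat.

Windows are nearest-neighbor windows of constant size that become one-sided
at the boundaries (no reflection). All window statistics come from prefix
sums, so a fixed-span pass is O(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

#: Friedman's canonical spans: tweeter, midrange, woofer.
DEFAULT_SPANS = (0.05, 0.2, 0.5)

_LEVERAGE_EPS = 1e-10


@dataclass(frozen=True)
class SmootherConfig:
    """Settings for :func:`supersmooth`.

    primary_spans
        Three strictly increasing fractions of n in (0, 1]; window sizes are
        ``max(min_window, round(span * n))``.
    bass
        Bass enhancement in [0, 10]: larger values pull the per-point span
        choice toward the largest span, giving a smoother result. 0 disables.
    min_window
        Smallest window size after rounding; at least 3 keeps leave-one-out
        leverages below 1.
    final_pass
        Smooth the interpolated result once more at the smallest span, as
        Friedman's original algorithm does; disable to obtain the pure
        interpolation between the primary-span fits, which is pointwise
        bounded by them.
    """

    primary_spans: tuple[float, float, float] = DEFAULT_SPANS
    bass: float = 0.0
    min_window: int = 5
    final_pass: bool = True

    def __post_init__(self) -> None:
        spans = self.primary_spans
        if len(spans) != 3 or not all(0 < s <= 1 for s in spans):
            raise ValueError("primary_spans must be three fractions in (0, 1]")
        if not (spans[0] < spans[1] < spans[2]):
            raise ValueError("primary_spans must be strictly increasing")
        if not (0 <= self.bass <= 10):
            raise ValueError("bass must be in [0, 10]")
        if self.min_window < 2:
            raise ValueError("min_window must be >= 2")


class FixedSpanFit(NamedTuple):
    fitted: np.ndarray
    loo_abs_residuals: np.ndarray


def _validate_xy(x: np.ndarray, y: np.ndarray, min_window: int) -> None:
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < min_window:
        raise ValueError(f"need at least {min_window} points, got {x.size}")
    dx = np.diff(x)
    if (dx <= 0).any():
        raise ValueError("x must be strictly increasing (no duplicates)")


def fixed_span_smooth(
    x: Sequence[float],
    y: Sequence[float],
    span: float,
    min_window: int = 5,
) -> FixedSpanFit:
    """Running local linear fit over a fixed-fraction nearest-neighbor window.

    For each point i the window holds the ``J = max(min_window,
    round(span * n))`` nearest neighbors (symmetric inside the data,
    one-sided at the edges); a straight line is fit by least squares over
    the window and evaluated at ``x[i]``.

    Returns the fitted values and the absolute leave-one-out residuals
    ``|y_i - fit_i| / (1 - h_i)`` obtained from the standard deletion
    formula, where ``h_i`` is the leverage of point i in its own window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, y, min_window)
    n = x.size
    J = min(max(min_window, int(round(span * n))), n)

    starts = np.clip(np.arange(n) - J // 2, 0, n - J)
    ends = starts + J

    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))

    sx = cx[ends] - cx[starts]
    sy = cy[ends] - cy[starts]
    sxx = cxx[ends] - cxx[starts]
    sxy = cxy[ends] - cxy[starts]

    xbar = sx / J
    ybar = sy / J
    Sxx = sxx - sx * xbar
    Sxy = sxy - sy * xbar

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(Sxx > 0, Sxy / np.where(Sxx > 0, Sxx, 1.0), 0.0)
    dev = x - xbar
    fitted = ybar + beta * dev

    leverage = 1.0 / J + np.where(Sxx > 0, dev * dev / np.where(Sxx > 0, Sxx, 1.0), 0.0)
    denom = np.maximum(1.0 - leverage, _LEVERAGE_EPS)
    loo = np.abs(y - fitted) / denom
    return FixedSpanFit(fitted=fitted, loo_abs_residuals=loo)


def supersmooth(
    x: Sequence[float],
    y: Sequence[float],
    config: SmootherConfig | None = None,
) -> np.ndarray:
    """Variable-span smooth of y on strictly increasing x.

    Stages: (1) fixed-span fits at the three primary spans; (2) the absolute
    leave-one-out residual curves of each fit are smoothed with the midrange
    span; (3) at every point the span with the smallest smoothed residual
    wins, optionally pulled toward the largest span by bass enhancement;
    (4) the chosen span values are themselves smoothed with the midrange
    span; (5) the output interpolates linearly between the two primary-span
    fits that bracket the smoothed chosen span; (6) unless
    ``config.final_pass`` is off, the interpolated values get one more
    fixed-span smooth at the smallest span.

    With ``final_pass=False`` the output at every point lies between the
    pointwise minimum and maximum of the three primary fits.
    """
    cfg = config or SmootherConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, y, cfg.min_window)
    spans = np.asarray(cfg.primary_spans, dtype=float)

    fits = []
    residual_curves = []
    for span in spans:
        fit = fixed_span_smooth(x, y, span, cfg.min_window)
        fits.append(fit.fitted)
        # stage 2: cross-validated quality of this span, smoothed at midrange
        smoothed_res = fixed_span_smooth(
            x, fit.loo_abs_residuals, spans[1], cfg.min_window
        ).fitted
        residual_curves.append(np.maximum(smoothed_res, 0.0))
    fits = np.asarray(fits)  # (3, n)
    resids = np.asarray(residual_curves)  # (3, n)

    best = np.argmin(resids, axis=0)
    chosen = spans[best]
    if cfg.bass > 0:
        r_best = resids[best, np.arange(x.size)]
        r_large = resids[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(r_large > 0, r_best / r_large, 1.0)
        ratio = np.clip(ratio, 0.0, 1.0)
        chosen = chosen + (spans[-1] - chosen) * ratio ** (10.0 - cfg.bass)

    smooth_span = fixed_span_smooth(x, chosen, spans[1], cfg.min_window).fitted
    smooth_span = np.clip(smooth_span, spans[0], spans[-1])

    # stage 5: per-point linear interpolation between bracketing primary fits
    hi = np.clip(np.searchsorted(spans, smooth_span, side="left"), 1, 2)
    lo = hi - 1
    w = (smooth_span - spans[lo]) / (spans[hi] - spans[lo])
    idx = np.arange(x.size)
    out = (1.0 - w) * fits[lo, idx] + w * fits[hi, idx]
    if cfg.final_pass:
        out = fixed_span_smooth(x, out, spans[0], cfg.min_window).fitted
    return out
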