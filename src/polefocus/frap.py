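"""Fluorescence recovery after photobleaching of the pole region.

The pole-ROI mean is ratio-corrected by the simultaneous whole-cell total
(acquisition drift), then recovery is expressed as percent of the bleached
signal: recovery(t) = (F(t) - F(0+)) / (F_pre - F(0+)) * 100 on the
ratio-corrected values.  A single-exponential A * (1 - exp(-k t)) fit is
provided for parameter-recovery work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .stack import ImageStack
from .segmentation import segment_cells


class NormalizationError(ValueError):
    """Raised when the prebleach level does not exceed the post-bleach floor."""


@dataclass
class FRAPCurve:
    times_s: np.ndarray               # from bleach; starts at 0
    pole_means: np.ndarray            # raw ROI means
    cell_totals: np.ndarray           # raw whole-cell totals
    prebleach_ratio: float            # F_pre / T_pre
    recovery_pct: np.ndarray          # normalized recovery, % of bleached signal

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")


def normalize_recovery_curve(
    pole_series: Sequence[float],
    cell_total_series: Sequence[float],
    prebleach_ratio: float,
    times_s: Optional[Sequence[float]] = None,
) -> FRAPCurve:
    """Double normalization of a post-bleach pole-intensity series.

    ``pole_series`` and ``cell_total_series`` are simultaneous raw
    measurements starting at the first post-bleach frame; ``prebleach_ratio``
    is the ratio-corrected prebleach reference (pole mean / cell total).
    Recovery at t=0 is 0 by construction.
    """
    pole = np.asarray(pole_series, dtype=float)
    total = np.asarray(cell_total_series, dtype=float)
    if pole.shape != total.shape or pole.ndim != 1:
        raise ValueError("pole and total series must be 1-D and equal length")
    if len(pole) < 2:
        raise ValueError("need >= 2 post-bleach time points")
    f_hat = pole / total
    f0 = f_hat[0]
    if prebleach_ratio <= f0:
        raise NormalizationError(
            "prebleach level does not exceed the first post-bleach value: "
            "nothing was bleached")
    rec = (f_hat - f0) / (prebleach_ratio - f0) * 100.0
    t = (np.arange(len(pole), dtype=float)
         if times_s is None else np.asarray(times_s, dtype=float))
    return FRAPCurve(times_s=t, pole_means=pole, cell_totals=total,
                     prebleach_ratio=float(prebleach_ratio), recovery_pct=rec)


def recovery_fraction_at(curve: FRAPCurve, t_s: float) -> float:
    """Linear interpolation of the normalized recovery (%) at ``t_s``."""
    t = np.asarray(curve.times_s, dtype=float)
    if not (t[0] <= t_s <= t[-1]):
        raise ValueError(f"t={t_s} s outside the measured span [{t[0]}, {t[-1]}]")
    return float(np.interp(t_s, t, curve.recovery_pct))


@dataclass
class ExponentialRecoveryFit:
    asymptote_pct: float
    rate_per_s: float
    residual_norm: float
    converged: bool
    message: str = ""


def fit_exponential_recovery(curve: FRAPCurve) -> ExponentialRecoveryFit:
    """Least-squares fit of A * (1 - exp(-k t)) to a normalized curve."""
    t = np.asarray(curve.times_s, dtype=float)
    y = np.asarray(curve.recovery_pct, dtype=float)
    if len(t) < 5:
        raise ValueError("need >= 5 points to fit the recovery model")
    if np.allclose(y, 0.0):
        return ExponentialRecoveryFit(0.0, math.nan, 0.0, False,
                                      "flat curve: rate unidentifiable")

    def model(tt, A, k):
        return A * (1.0 - np.exp(-k * tt))

    a0 = max(float(y[-1]), 1e-3)
    k0 = 1.0 / max(t[-1] / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, k0),
                            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000)
    except Exception as exc:  # pragma: no cover - pathological data
        return ExponentialRecoveryFit(math.nan, math.nan, math.nan, False, str(exc))
    resid = float(np.linalg.norm(y - model(t, *popt)))
    return ExponentialRecoveryFit(float(popt[0]), float(popt[1]), resid, True)


def analyze_frap_stack(
    stack: ImageStack,
    roi_boxes,
    bleach_frame: int,
    fluor_channel: str = "mcherry",
    phase_channel: str = "phase",
) -> list:
    """Measure per-cell recovery curves from a bleach stack.

    ``roi_boxes`` is an iterable of (r0, r1, c0, c1) pole-ROI boxes, one per
    bleached cell (the bleached region is part of the acquisition protocol,
    not something the pipeline infers).  Cells are segmented on the phase
    channel of the prebleach frame; each ROI is paired with the cell whose
    mask it overlaps most.  Returns a list of :class:`FRAPCurve`.
    """
    fluor = stack.channel(fluor_channel)
    rois = segment_cells(stack.channel(phase_channel)[max(bleach_frame - 1, 0)],
                         stack.pixel_size)
    curves = []
    for (r0, r1, c0, c1) in roi_boxes:
        best, best_ov = None, 0
        for cell in rois:
            fm = cell.full_mask(fluor.shape[1:])
            ov = int(fm[r0:r1, c0:c1].sum())
            if ov > best_ov:
                best, best_ov = cell, ov
        if best is None:
            continue
        mask = best.full_mask(fluor.shape[1:])
        pre = fluor[bleach_frame - 1]
        prebleach_ratio = float(pre[r0:r1, c0:c1].mean() / pre[mask].sum())
        post = fluor[bleach_frame:]
        pole = post[:, r0:r1, c0:c1].mean(axis=(1, 2))
        totals = post[:, mask].sum(axis=1)
        times = np.arange(post.shape[0]) * stack.frame_interval
        curves.append(normalize_recovery_curve(pole, totals, prebleach_ratio,
                                               times_s=times))
    return curves


def mean_recovery_at(curves: Sequence[FRAPCurve], t_s: float) -> tuple:
    """Mean and standard error of the recovery (%) at ``t_s`` across cells."""
    vals = np.array([recovery_fraction_at(c, t_s) for c in curves])
    se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else math.nan
    return float(vals.mean()), float(se)
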