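"""Reactive-hyperemia curve descriptors.

From an ROI-mean T2* time-curve and the cuffing-paradigm schedule this
module derives the descriptors of the reperfusion response:

* BL — baseline T2*, the mean over all frames of the pre-occlusion
  resting phase (the first 60 s under the default paradigm);
* HPV — hyperemia peak value, the maximum (optionally smoothed) T2*
  among frames at or after cuff release;
* TTP — time to peak, the delay from cuff release to the HPV frame;
* overshoot — HPV minus BL.

Smoothing is a centered moving average over an odd number of frames
(window 1 = none; edges use shrunken windows); the peak value is reported
from the same smoothed sequence whose argmax locates it, and ties go to
the earliest frame.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParadigmError
from .registration import T2StarTimeCurve

#: Tolerance (s) when comparing frame times to phase boundaries, guarding
#: against float round-off on the frame grid.
_TIME_EPS = 1e-9


@dataclass(frozen=True)
class CurveFeatures:
    """BL, HPV, TTP and overshoot for one ROI curve."""

    bl: float            # ms
    hpv: float           # ms
    ttp: float           # s, peak_time_abs - release_time
    overshoot: float     # ms, hpv - bl
    peak_time_abs: float  # s from acquisition start
    smoothing_window: int


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available frames."""
    if window < 1 or window % 2 == 0:
        raise InputError("smoothing window must be a positive odd integer")
    v = np.asarray(values, dtype=float)
    if window == 1:
        return v.copy()
    half = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        lo = max(0, i - half)
        hi = min(v.size, i + half + 1)
        out[i] = v[lo:hi].mean()
    return out


def _schedule_of(curve: T2StarTimeCurve):
    if curve.schedule is None:
        raise ParadigmError("curve carries no paradigm schedule")
    return curve.schedule


def compute_baseline(curve: T2StarTimeCurve) -> float:
    """Mean T2* over the resting-phase frames (time < occlusion start)."""
    schedule = _schedule_of(curve)
    sel = curve.times < schedule.occlusion_start - _TIME_EPS
    if not sel.any():
        raise ParadigmError("no frames before occlusion start")
    return float(curve.values[sel].mean())


def detect_peak(curve: T2StarTimeCurve,
                smoothing_window: int = 1) -> tuple[float, float]:
    """Locate the post-release maximum of the (smoothed) curve.

    Returns ``(peak_time_abs, hpv)``.  The whole curve is smoothed first,
    then the search is restricted to frames at or after cuff release; exact
    ties resolve to the earliest frame.
    """
    schedule = _schedule_of(curve)
    smoothed = moving_average(curve.values, smoothing_window)
    sel = curve.times >= schedule.release_time - _TIME_EPS
    if not sel.any():
        raise ParadigmError("no frames at or after cuff release")
    times = curve.times[sel]
    vals = smoothed[sel]
    idx = int(np.argmax(vals))  # earliest index on exact ties
    return float(times[idx]), float(vals[idx])


def extract_features(curve: T2StarTimeCurve,
                     smoothing_window: int = 1) -> CurveFeatures:
    """Compute BL, HPV, TTP and overshoot for one curve."""
    schedule = _schedule_of(curve)
    bl = compute_baseline(curve)
    peak_time_abs, hpv = detect_peak(curve, smoothing_window)
    ttp = max(0.0, peak_time_abs - schedule.release_time)
    return CurveFeatures(bl=bl, hpv=hpv, ttp=ttp, overshoot=hpv - bl,
                         peak_time_abs=peak_time_abs,
                         smoothing_window=smoothing_window)
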