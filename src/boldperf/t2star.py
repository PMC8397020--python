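"""Dynamic T2* mapping by weighted least squares.

Each pixel's multi-echo magnitudes are fit to the mono-exponential decay
``S(TE) = s0 * exp(-TE * R2*)`` by linear least squares on
``ln S_i = ln s0 - TE_i * R2*`` with weights ``w_i = S_i**2`` — the
standard variance-stabilizing weight that makes the log-domain fit
first-order equivalent to unweighted fitting in the signal domain.  One
reweighting pass replaces the observed magnitudes in the weights with the
first fit's predicted signal, removing the bias that noisy observed
weights introduce at low SNR; on noiseless data the weights are
irrelevant and the fit is exact.
T2* = 1/R2* is clamped to a physiological range; non-decaying pixels map
to the clamp maximum with a flag.  Fitting is purely pixel-wise: no
spatial regularization or smoothing is applied to the maps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .series import MultiEchoSeries

#: Clamp bounds for fitted T2* (ms): generous around muscle (~20-30 ms).
T2STAR_MIN_MS = 1.0
T2STAR_MAX_MS = 200.0

#: Echoes with magnitude <= signal_floor are discarded before fitting.
DEFAULT_SIGNAL_FLOOR = 1e-6

#: Minimum surviving echoes for a valid fit (2 points fit exactly and
#: leave no residual diagnostics).
MIN_VALID_ECHOES = 3

#: Weight passes: first with observed-signal weights, then refit with
#: weights from the predicted signal.
WEIGHT_ITERATIONS = 2


@dataclass
class DynamicT2StarMap:
    """Per-frame T2* and S0 maps with validity and clamp flags.

    ``t2star`` and ``s0`` are (row, col, frame) arrays; invalid pixels are
    NaN, never silently zero.  ``fit_residual`` is the weighted RMS of the
    log-domain residuals.
    """

    t2star: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    clamped: np.ndarray
    fit_residual: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.t2star.shape[2]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.t2star.shape[:2]

    def frame(self, k: int) -> np.ndarray:
        return self.t2star[:, :, k]

    def report(self) -> dict:
        """Fit bookkeeping: valid / invalid / clamped pixel-frame counts."""
        total = int(self.valid.size)
        n_valid = int(self.valid.sum())
        return {"total": total, "valid": n_valid,
                "invalid": total - n_valid,
                "clamped": int(self.clamped.sum())}


def _wls_loglinear(signals: np.ndarray, echo_times: np.ndarray,
                   signal_floor: float):
    """Vectorized weighted log-linear fit over the last axis (echoes).

    Returns (t2star, s0, valid, clamped, residual) with the echo axis
    reduced away.  ``signals`` may have any leading shape.
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    usable = s > signal_floor
    n_usable = usable.sum(axis=-1)
    valid = n_usable >= MIN_VALID_ECHOES

    # log of discarded echoes never enters: their weight is zero
    y = np.log(np.where(usable, s, 1.0))
    w = np.where(usable, s * s, 0.0)

    slope = intercept = None
    safe = valid
    for it in range(WEIGHT_ITERATIONS):
        sw = w.sum(axis=-1)
        swx = (w * te).sum(axis=-1)
        swy = (w * y).sum(axis=-1)
        swxx = (w * te * te).sum(axis=-1)
        swxy = (w * te * y).sum(axis=-1)
        denom = sw * swxx - swx * swx
        safe = valid & (denom > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(safe, (sw * swxy - swx * swy) / denom, np.nan)
            intercept = np.where(safe, (swy - slope * swx) / sw, np.nan)
        if it < WEIGHT_ITERATIONS - 1:
            log_pred = np.clip(intercept[..., None] + slope[..., None] * te,
                               -350.0, 350.0)
            w = np.where(usable & safe[..., None], np.exp(2.0 * log_pred), 0.0)

    r2star = -slope  # 1/ms
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(r2star > 0, 1.0 / np.where(r2star > 0, r2star, 1.0),
                      np.inf)
    clamped = safe & ((t2 < T2STAR_MIN_MS) | (t2 > T2STAR_MAX_MS))
    t2 = np.clip(t2, T2STAR_MIN_MS, T2STAR_MAX_MS)
    t2 = np.where(safe, t2, np.nan)
    s0 = np.where(safe, np.exp(intercept), np.nan)

    resid = y - (intercept[..., None] + slope[..., None] * te)
    with np.errstate(invalid="ignore"):
        residual = np.sqrt(np.where(
            safe & (sw > 0),
            (w * resid * resid).sum(axis=-1) / np.where(sw > 0, sw, 1.0),
            np.nan))
    return t2, s0, safe, clamped, residual


def fit_t2star_pixel(signal: np.ndarray, echo_times: np.ndarray,
                     signal_floor: float = DEFAULT_SIGNAL_FLOOR):
    """Fit one pixel's echo train.

    Returns ``(t2star_ms, s0, valid, clamped, residual)``.  Echoes at or
    below ``signal_floor`` are discarded; fewer than 3 surviving echoes
    invalidates the fit (t2star and s0 are NaN).  A non-decaying fit
    (slope >= 0) is clamped to the T2* maximum and flagged.
    """
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if signal.ndim != 1 or signal.size != te.size:
        raise InputError("signal and echo_times must be 1D of equal length")
    if te.size < 2 or np.any(np.diff(te) <= 0):
        raise InputError("echo_times must be >= 2 strictly increasing values")
    t2, s0, valid, clamped, residual = _wls_loglinear(signal, te, signal_floor)
    return float(t2), float(s0), bool(valid), bool(clamped), float(residual)


def fit_dynamic_maps(series: MultiEchoSeries,
                     mask: np.ndarray | None = None,
                     signal_floor: float = DEFAULT_SIGNAL_FLOOR
                     ) -> DynamicT2StarMap:
    """Fit every (pixel, frame) of a series independently.

    ``mask`` optionally restricts fitting to a pixel subset; everything
    outside is marked invalid (NaN).  Results do not depend on pixel
    ordering — each fit sees only its own echo train.
    """
    te = series.echo_times_ms
    if np.any(np.diff(te) <= 0):
        raise InputError("echo_times must be strictly increasing")
    nr, nc = series.image_shape
    n_frames = series.n_frames
    if mask is None:
        mask = np.ones((nr, nc), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (nr, nc):
            raise InputError(
                f"mask shape {mask.shape} != image shape {(nr, nc)}")

    # (P, F, E) view of the selected pixels' echo trains
    sel = series.data[mask]                       # (P, E, F)
    sel = np.moveaxis(sel, 1, 2)                  # (P, F, E)
    t2_p, s0_p, valid_p, clamped_p, resid_p = _wls_loglinear(
        sel, te, signal_floor)

    def scatter(flat: np.ndarray, fill) -> np.ndarray:
        out = np.full((nr, nc, n_frames), fill,
                      dtype=flat.dtype if flat.dtype != bool else bool)
        out[mask] = flat
        return out

    return DynamicT2StarMap(
        t2star=scatter(t2_p, np.nan),
        s0=scatter(s0_p, np.nan),
        valid=scatter(valid_p, False),
        clamped=scatter(clamped_p, False),
        fit_residual=scatter(resid_p, np.nan),
    )
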