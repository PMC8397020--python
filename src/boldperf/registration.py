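"""Motion correction and ROI time-curve extraction.

Subject motion across frames is corrected by rigid, integer-pixel
translation: each frame's first-echo image is registered to the first
frame's first-echo image by exhaustive normalized cross-correlation search
within a square window.  The resulting transforms are not applied to the
image data — they are applied to the ROI masks, which are pulled into each
frame's coordinates before averaging, mirroring the workflow of
registering first-echo frames and propagating hand-drawn ROIs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateROIError, InputError
from .imageops import normalized_cross_correlation, shift_image
from .paradigm import ParadigmSchedule
from .series import MultiEchoSeries
from .t2star import DynamicT2StarMap

#: Clinical ROI pixel-count range for the full 128 x 119 matrix.
FULL_MATRIX_SHAPE = (128, 119)
ROI_PIXELS_RANGE = (700, 1600)

#: Frames whose transformed ROI retains less than this valid fraction are
#: flagged in the extracted curve.
MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask with an anatomical label."""

    mask: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise InputError("ROI mask must be 2D")
        if not m.any():
            raise DegenerateROIError("ROI mask is empty")
        object.__setattr__(self, "mask", m)
        if m.shape == FULL_MATRIX_SHAPE:
            lo, hi = ROI_PIXELS_RANGE
            if not lo <= int(m.sum()) <= hi:
                warnings.warn(
                    f"ROI '{self.label}' has {int(m.sum())} pixels, outside "
                    f"the typical clinical range [{lo}, {hi}]",
                    stacklevel=2)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class FrameTransform:
    """Integer translation aligning one frame to the reference frame.

    ``shift`` is the (drow, dcol) to apply to the frame image so that it
    matches frame 0; the reference frame carries (0, 0).
    """

    frame_index: int
    shift: tuple[int, int]

    def inverse(self) -> "FrameTransform":
        return FrameTransform(self.frame_index,
                              (-self.shift[0], -self.shift[1]))


@dataclass
class T2StarTimeCurve:
    """ROI-mean T2* versus time for one muscle region."""

    times: np.ndarray          # s, strictly increasing
    values: np.ndarray         # ms, mean over valid ROI pixels
    roi_label: str
    n_valid_pixels: np.ndarray  # per frame
    flagged: np.ndarray         # per frame: < 50% of ROI pixels valid
    schedule: ParadigmSchedule | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise InputError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")


def register_frames(series: MultiEchoSeries,
                    search_radius: int = 5) -> list[FrameTransform]:
    """Estimate per-frame integer shifts against frame 0 (first echo).

    For each frame the shift within ``+/- search_radius`` maximizing the
    normalized cross-correlation with the reference first-echo image is
    returned; ties are broken by smallest shift magnitude, then
    lexicographically by (drow, dcol).  NCC is invariant to global
    intensity scaling of a frame.
    """
    if search_radius < 0:
        raise InputError("search_radius must be >= 0")
    if series.n_frames < 1:
        raise InputError("series has no frames")
    ref = series.first_echo_frame(0)
    # candidates ordered by the tie-break rule; a strictly better score wins
    candidates = sorted(
        ((dr, dc) for dr in range(-search_radius, search_radius + 1)
         for dc in range(-search_radius, search_radius + 1)),
        key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))
    transforms = [FrameTransform(0, (0, 0))]
    for k in range(1, series.n_frames):
        img = series.first_echo_frame(k)
        best_shift, best_score = (0, 0), -np.inf
        for shift in candidates:
            score = normalized_cross_correlation(shift_image(img, shift), ref)
            if score > best_score + 1e-12:
                best_score, best_shift = score, shift
        transforms.append(FrameTransform(k, best_shift))
    return transforms


def transform_roi(roi: ROIMask, transform: FrameTransform) -> ROIMask:
    """Translate an ROI by a frame transform's shift.

    Pixels shifted outside the image are dropped; losing the whole ROI is
    a degenerate-ROI error.
    """
    shifted = shift_image(roi.mask.astype(np.uint8), transform.shift) > 0
    if not shifted.any():
        raise DegenerateROIError(
            f"ROI '{roi.label}' shifted entirely out of bounds "
            f"(frame {transform.frame_index}, shift {transform.shift})")
    return ROIMask(mask=shifted, label=roi.label)


def extract_roi_curve(maps: DynamicT2StarMap, roi: ROIMask,
                      transforms: list[FrameTransform] | None = None,
                      frame_times: np.ndarray | None = None,
                      schedule=None) -> T2StarTimeCurve:
    """ROI-mean T2* per frame, over valid pixels of the transformed ROI.

    ``transforms`` come from :func:`register_frames`: since each transform
    aligns the frame *to* the reference, the ROI (drawn in reference
    coordinates) is carried into frame coordinates with the inverse shift.
    Frames where fewer than half the ROI pixels have valid fits are
    flagged; a frame with zero valid pixels raises
    :class:`~boldperf.errors.DegenerateROIError` naming the frame.
    """
    n_frames = maps.n_frames
    if roi.mask.shape != maps.image_shape:
        raise InputError("ROI shape does not match the map shape")
    if transforms is not None and len(transforms) != n_frames:
        raise InputError(
            f"{len(transforms)} transforms for {n_frames} frames")
    if frame_times is None:
        frame_times = np.arange(n_frames, dtype=float)
    values = np.empty(n_frames)
    n_valid = np.empty(n_frames, dtype=int)
    flagged = np.zeros(n_frames, dtype=bool)
    for k in range(n_frames):
        roi_k = roi if transforms is None \
            else transform_roi(roi, transforms[k].inverse())
        use = roi_k.mask & maps.valid[:, :, k]
        n = int(use.sum())
        if n == 0:
            raise DegenerateROIError(
                f"frame {k}: no valid pixels in ROI '{roi.label}'")
        values[k] = float(maps.t2star[:, :, k][use].mean())
        n_valid[k] = n
        flagged[k] = n < MIN_VALID_FRACTION * roi_k.pixel_count
    return T2StarTimeCurve(times=np.asarray(frame_times, dtype=float),
                           values=values, roi_label=roi.label,
                           n_valid_pixels=n_valid, flagged=flagged,
                           schedule=schedule)


def write_curve(curve: T2StarTimeCurve, path: str | Path) -> None:
    """Write a curve as TSV (time_s, t2star_ms, n_valid, flagged)."""
    df = pd.DataFrame({
        "time_s": curve.times,
        "t2star_ms": curve.values,
        "n_valid": curve.n_valid_pixels,
        "flagged": curve.flagged.astype(int),
    })
    df.to_csv(Path(path), sep="\t", index=False)


def read_curve(path: str | Path, roi_label: str = "other",
               schedule=None) -> T2StarTimeCurve:
    df = pd.read_csv(Path(path), sep="\t")
    return T2StarTimeCurve(times=df["time_s"].to_numpy(),
                           values=df["t2star_ms"].to_numpy(),
                           roi_label=roi_label,
                           n_valid_pixels=df["n_valid"].to_numpy(),
                           flagged=df["flagged"].to_numpy().astype(bool),
                           schedule=schedule)
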