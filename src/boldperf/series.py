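"""The 4D multi-echo acquisition container and its on-disk format.

A :class:`MultiEchoSeries` holds signal magnitudes indexed as
``(row, col, echo, frame)`` together with the echo times, frame timestamps
and the cuffing-paradigm schedule.  On disk a series is a 4D NIfTI-1 image
in the same dimension order plus a JSON sidecar carrying
``echo_times_ms``, ``frame_times_s``, the schedule and, for phantoms, the
exact ground-truth generating parameters.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InputError
from .paradigm import ParadigmSchedule


@dataclass
class MultiEchoSeries:
    """4D multi-echo gradient-echo magnitude series.

    Attributes
    ----------
    data
        Array of shape (row, col, echo, frame), non-negative magnitudes.
    echo_times_ms
        Echo times in ms, one per echo index.
    frame_times_s
        Frame-start timestamps in seconds, one per frame index.
    schedule
        The cuffing paradigm the acquisition followed.
    """

    data: np.ndarray
    echo_times_ms: np.ndarray
    frame_times_s: np.ndarray
    schedule: ParadigmSchedule
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 4:
            raise InputError("series data must be 4D (row, col, echo, frame)")
        if self.data.shape[2] != self.echo_times_ms.size:
            raise InputError("echo axis length does not match echo_times_ms")
        if self.data.shape[3] != self.frame_times_s.size:
            raise InputError("frame axis length does not match frame_times_s")
        if np.any(self.data < 0):
            raise InputError("signal magnitudes must be non-negative")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def first_echo_frame(self, k: int) -> np.ndarray:
        """The first-echo image of frame ``k`` (used for registration)."""
        return self.data[:, :, 0, k]


def write_series(series: MultiEchoSeries, nifti_path: str | Path,
                 sidecar_path: str | Path | None = None,
                 ground_truth: dict | None = None) -> None:
    """Write a series as 4D NIfTI-1 plus JSON sidecar.

    The sidecar records echo times, frame times, the schedule and an
    optional ground-truth block (phantom generating parameters).
    """
    nifti_path = Path(nifti_path)
    img = nib.Nifti1Image(series.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, nifti_path)
    sidecar = {
        "subject_id": series.subject_id,
        "echo_times_ms": [float(t) for t in series.echo_times_ms],
        "frame_times_s": [float(t) for t in series.frame_times_s],
        "schedule": series.schedule.to_dict(),
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix("").with_suffix(".json") \
            if nifti_path.name.endswith(".nii.gz") \
            else nifti_path.with_suffix(".json")
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_sidecar(sidecar_path: str | Path) -> dict:
    return json.loads(Path(sidecar_path).read_text())


def read_series(nifti_path: str | Path,
                sidecar_path: str | Path) -> MultiEchoSeries:
    """Load a series written by :func:`write_series`."""
    meta = read_sidecar(sidecar_path)
    data = np.asarray(nib.load(str(nifti_path)).get_fdata(), dtype=float)
    return MultiEchoSeries(
        data=data,
        echo_times_ms=np.asarray(meta["echo_times_ms"], dtype=float),
        frame_times_s=np.asarray(meta["frame_times_s"], dtype=float),
        schedule=ParadigmSchedule.from_dict(meta["schedule"]),
        subject_id=meta.get("subject_id"),
    )


def write_label_image(labels: np.ndarray, path: str | Path) -> None:
    """Write a 2D label / mask image as unsigned 8-bit NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.uint8), affine=np.eye(4))
    nib.save(img, Path(path))


def read_label_image(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()).astype(np.uint8)
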