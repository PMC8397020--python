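"""Cuff-occlusion paradigm timing and acquisition protocol.

The reperfusion BOLD-MRI examination acquires a single-slice multi-echo
gradient-echo series continuously through three phases: rest, thigh-cuff
compression (ischemia) and reperfusion after rapid cuff deflation.  The
default schedule is 60 s rest / 300 s occlusion / 300 s reperfusion at a
temporal resolution of 3.2 s (660 s total); the default acquisition reads
11 echoes between 2 and 40 ms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

#: Echo times (ms) of the 11-echo gradient-echo protocol.
DEFAULT_ECHO_TIMES_MS: tuple[float, ...] = (
    2.0, 5.8, 9.6, 13.4, 17.2, 21.0, 24.8, 28.6, 32.4, 36.2, 40.0,
)


@dataclass(frozen=True)
class ParadigmSchedule:
    """Timing of the rest / occlusion / reperfusion cuffing paradigm.

    Parameters
    ----------
    rest_duration, occlusion_duration, reperfusion_duration
        Phase durations in seconds.  Defaults: 60 / 300 / 300 s.
    frame_interval
        Temporal resolution of the dynamic acquisition in seconds
        (default 3.2 s).
    """

    rest_duration: float = 60.0
    occlusion_duration: float = 300.0
    reperfusion_duration: float = 300.0
    frame_interval: float = 3.2

    def __post_init__(self) -> None:
        for name in ("rest_duration", "occlusion_duration",
                     "reperfusion_duration", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def total_duration(self) -> float:
        """Total acquisition time in seconds."""
        return (self.rest_duration + self.occlusion_duration
                + self.reperfusion_duration)

    @property
    def occlusion_start(self) -> float:
        """Time of cuff inflation (s)."""
        return self.rest_duration

    @property
    def release_time(self) -> float:
        """Time of cuff deflation (s)."""
        return self.rest_duration + self.occlusion_duration

    @property
    def n_frames(self) -> int:
        # last frame-start time must leave a full frame inside the paradigm
        return int(math.floor(
            (self.total_duration - self.frame_interval) / self.frame_interval
            + 1e-9)) + 1

    def frame_times(self) -> np.ndarray:
        """Frame-start timestamps ``t_k = k * frame_interval`` in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def aligned_to_grid(self) -> "ParadigmSchedule":
        """Snap cuff inflation and deflation to the nearest frame timestamp.

        The total duration is preserved; rest and occlusion durations are
        adjusted so that ``occlusion_start`` and ``release_time`` are exact
        multiples of ``frame_interval``.  Exact half-frame ties round to the
        even frame index.
        """
        dt = self.frame_interval
        occ = round(self.occlusion_start / dt) * dt
        rel = round(self.release_time / dt) * dt
        if not (0 < occ < rel < self.total_duration):
            raise ConfigurationError(
                "phase boundaries collapse when snapped to the frame grid")
        return replace(self, rest_duration=occ,
                       occlusion_duration=rel - occ,
                       reperfusion_duration=self.total_duration - rel)

    def to_dict(self) -> dict:
        return {
            "rest_duration_s": self.rest_duration,
            "occlusion_duration_s": self.occlusion_duration,
            "reperfusion_duration_s": self.reperfusion_duration,
            "frame_interval_s": self.frame_interval,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmSchedule":
        return cls(rest_duration=d["rest_duration_s"],
                   occlusion_duration=d["occlusion_duration_s"],
                   reperfusion_duration=d["reperfusion_duration_s"],
                   frame_interval=d["frame_interval_s"])


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-echo gradient-echo scan parameters.

    ``echo_times_ms`` must be strictly increasing and positive; the default
    is the 11-echo readout between 2 and 40 ms.  ``matrix`` is the
    (rows, cols) acquisition matrix; phantoms may use a smaller test matrix.
    """

    echo_times_ms: tuple[float, ...] = DEFAULT_ECHO_TIMES_MS
    field_of_view_mm: tuple[float, float] = (160.0, 160.0)
    matrix: tuple[int, int] = (128, 119)
    repetition_time_ms: float = 44.0
    slice_thickness_mm: float = 10.0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ConfigurationError(
                "echo_times_ms must be >= 2 strictly increasing positive values")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    def echo_times(self) -> np.ndarray:
        return np.asarray(self.echo_times_ms, dtype=float)
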