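"""Synthetic cuff-occlusion phantoms.

This module synthesizes single-slice multi-echo gradient-echo series whose
per-region T2* follows the three-phase reactive-hyperemia paradigm:

* rest — T2* constant at the baseline value BL;
* occlusion — mono-exponential decline toward a floor, emulating the
  gradual deoxygenation of the compressed calf;
* reperfusion — a gamma-variate bolus-shaped response
  ``T2*(tau) = T2*_rel + (peak - T2*_rel) * (tau/ttp)**alpha *
  exp(alpha*(1 - tau/ttp))`` whose maximum sits exactly at ``tau = ttp``
  with value ``peak = BL + overshoot``, where ``tau`` is time since cuff
  release and ``T2*_rel`` the occlusion-phase value at release.

The analytic peak location makes time-to-peak recovery testable to machine
precision.  Signal synthesis is the mono-exponential decay
``S(TE) = s0 * exp(-TE / T2*)`` evaluated at the protocol echo times,
optionally followed by per-frame rigid translation (subject motion) and
Gaussian or Rician magnitude noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, ParadigmError
from .imageops import shift_image
from .paradigm import AcquisitionProtocol, ParadigmSchedule
from .series import MultiEchoSeries

#: Region label values in phantom geometries.
BACKGROUND, GASTROCNEMIUS, SOLEUS, BONE = 0, 1, 2, 3
LABEL_NAMES = {GASTROCNEMIUS: "gastrocnemius", SOLEUS: "soleus", BONE: "bone"}

#: T2* (ms) used for the static bone region.
BONE_T2STAR_MS = 10.0


@dataclass(frozen=True)
class PerfusionCurveParams:
    """Ground-truth parameters of one region's T2* time-course.

    Parameters
    ----------
    t2star_baseline
        Resting T2* in ms (BL ground truth).
    t2star_occlusion_floor
        Asymptotic T2* during occlusion (ms); must satisfy
        ``0 < floor < baseline``.
    occlusion_decay_tau
        Time constant of the occlusion decline (s).
    overshoot
        Peak T2* minus baseline (ms); may be any real, patients can show
        near-zero hyperemic overshoot.
    ttp
        Time from cuff release to the reperfusion peak (s).
    recovery_shape_alpha
        Gamma-variate shape parameter (dimensionless, > 0); larger values
        give a sharper peak.
    s0
        TE = 0 signal amplitude (arbitrary units).
    """

    t2star_baseline: float
    t2star_occlusion_floor: float
    occlusion_decay_tau: float = 60.0
    overshoot: float = 0.0
    ttp: float = 48.0
    recovery_shape_alpha: float = 2.0
    s0: float = 100.0

    def __post_init__(self) -> None:
        if not (self.t2star_baseline > self.t2star_occlusion_floor > 0):
            raise ConfigurationError(
                "need t2star_baseline > t2star_occlusion_floor > 0")
        if self.ttp <= 0 or self.recovery_shape_alpha <= 0 or self.s0 <= 0 \
                or self.occlusion_decay_tau <= 0:
            raise ConfigurationError(
                "ttp, recovery_shape_alpha, occlusion_decay_tau and s0 "
                "must be > 0")

    def to_dict(self) -> dict:
        return {
            "t2star_baseline_ms": self.t2star_baseline,
            "t2star_occlusion_floor_ms": self.t2star_occlusion_floor,
            "occlusion_decay_tau_s": self.occlusion_decay_tau,
            "overshoot_ms": self.overshoot,
            "ttp_s": self.ttp,
            "recovery_shape_alpha": self.recovery_shape_alpha,
            "s0": self.s0,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PerfusionCurveParams":
        return cls(t2star_baseline=d["t2star_baseline_ms"],
                   t2star_occlusion_floor=d["t2star_occlusion_floor_ms"],
                   occlusion_decay_tau=d["occlusion_decay_tau_s"],
                   overshoot=d["overshoot_ms"],
                   ttp=d["ttp_s"],
                   recovery_shape_alpha=d["recovery_shape_alpha"],
                   s0=d["s0"])


def curve_params(baseline: float, overshoot: float, ttp: float,
                 floor_drop: float = 3.0, **kw) -> PerfusionCurveParams:
    """Convenience constructor: floor defaults to ``baseline - floor_drop``."""
    return PerfusionCurveParams(
        t2star_baseline=baseline,
        t2star_occlusion_floor=baseline - floor_drop,
        overshoot=overshoot, ttp=ttp, **kw)


@dataclass(frozen=True)
class PhantomGeometry:
    """Labeled phantom anatomy: background, two muscle regions and bone."""

    region_labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.region_labels)
        if labels.ndim != 2:
            raise ConfigurationError("region_labels must be 2D")
        for lab in (GASTROCNEMIUS, SOLEUS):
            if not np.any(labels == lab):
                raise ConfigurationError(
                    f"muscle region {LABEL_NAMES[lab]} is empty")
        object.__setattr__(self, "region_labels", labels.astype(np.uint8))

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.region_labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.region_labels == label

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.region_labels != BACKGROUND


def default_phantom_geometry(shape: tuple[int, int] = (32, 32)) -> PhantomGeometry:
    """Disk-based calf cross-section stand-in.

    Two muscle disks (gastrocnemius, soleus) and one small bone disk placed
    well inside the image so that modest integer motion keeps all regions
    in-bounds.  At the default 32 x 32 test matrix each muscle region has
    roughly 60 pixels; centers and radii scale with the image size, so the
    full 128 x 119 acquisition matrix yields clinical-sized regions
    (~1000 pixels).
    """
    nr, nc = shape
    scale = min(nr, nc) / 32.0
    rr, cc = np.mgrid[0:nr, 0:nc]

    def disk(cr: float, ccol: float, radius: float) -> np.ndarray:
        return (rr - cr * scale) ** 2 + (cc - ccol * scale) ** 2 \
            <= (radius * scale) ** 2

    labels = np.zeros(shape, dtype=np.uint8)
    labels[disk(11, 12, 4.5)] = GASTROCNEMIUS
    labels[disk(22, 20, 4.5)] = SOLEUS
    labels[disk(14, 24, 2.5)] = BONE
    return PhantomGeometry(region_labels=labels)


@dataclass
class SubjectParams:
    """Per-subject simulation parameters.

    ``region_params`` maps region label names ("gastrocnemius", "soleus",
    "bone") to :class:`PerfusionCurveParams` for dynamic regions, or to a
    plain float for a time-invariant T2* (bone).  ``motion_trace`` lists
    one integer (drow, dcol) translation per frame.
    """

    subject_id: str
    group: str  # "PAOD" | "control"
    abi: float
    region_params: dict
    motion_trace: list[tuple[int, int]] | None = None
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("PAOD", "control"):
            raise ConfigurationError("group must be 'PAOD' or 'control'")
        if self.abi <= 0:
            raise ConfigurationError("abi must be > 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "abi": self.abi,
            "region_params": {
                name: (p.to_dict() if isinstance(p, PerfusionCurveParams)
                       else float(p))
                for name, p in self.region_params.items()},
            "motion_trace": ([[int(a), int(b)] for a, b in self.motion_trace]
                             if self.motion_trace is not None else None),
            "noise_sigma": self.noise_sigma,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubjectParams":
        region_params = {
            name: (PerfusionCurveParams.from_dict(p) if isinstance(p, Mapping)
                   else float(p))
            for name, p in d["region_params"].items()}
        motion = d.get("motion_trace")
        return cls(subject_id=d["subject_id"], group=d["group"],
                   abi=d["abi"], region_params=region_params,
                   motion_trace=([tuple(s) for s in motion]
                                 if motion is not None else None),
                   noise_sigma=d.get("noise_sigma", 0.0))


def t2star_timecourse(t, params: PerfusionCurveParams,
                      schedule: ParadigmSchedule):
    """Ground-truth T2* (ms) at time ``t`` seconds into the paradigm.

    Piecewise model: constant baseline at rest; exponential approach to the
    occlusion floor while the cuff is inflated; gamma-variate hyperemic
    response after release, peaking at exactly ``ttp`` seconds past release
    with value ``baseline + overshoot``.

    ``t`` may be a scalar or array; values outside ``[0, total_duration]``
    raise :class:`~boldperf.errors.ParadigmError`.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > schedule.total_duration):
        raise ParadigmError("time outside the cuffing paradigm")
    occ = schedule.occlusion_start
    rel = schedule.release_time
    bl = params.t2star_baseline
    floor = params.t2star_occlusion_floor
    tau_occ = params.occlusion_decay_tau
    alpha = params.recovery_shape_alpha

    out = np.full(t_arr.shape, bl, dtype=float)
    in_occ = (t_arr >= occ) & (t_arr < rel)
    out[in_occ] = floor + (bl - floor) * np.exp(-(t_arr[in_occ] - occ) / tau_occ)

    t2_rel = floor + (bl - floor) * np.exp(-(rel - occ) / tau_occ)
    peak = bl + params.overshoot
    in_rep = t_arr >= rel
    x = (t_arr[in_rep] - rel) / params.ttp
    out[in_rep] = t2_rel + (peak - t2_rel) * x ** alpha * np.exp(alpha * (1.0 - x))
    return out if np.ndim(t) else float(out)


def region_t2star_at(label_name: str, params, t: np.ndarray,
                     schedule: ParadigmSchedule) -> np.ndarray:
    """T2* trace for one region: dynamic curve or static value."""
    if isinstance(params, PerfusionCurveParams):
        return np.asarray(t2star_timecourse(t, params, schedule), dtype=float)
    return np.full(np.shape(t), float(params))


def generate_phantom_series(
    geometry: PhantomGeometry,
    subject: SubjectParams,
    schedule: ParadigmSchedule,
    protocol: AcquisitionProtocol | None = None,
    *,
    noise_model: str = "gaussian",
    align_release_to_grid: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[MultiEchoSeries, dict]:
    """Synthesize one subject's multi-echo series.

    For each frame time ``t_k`` and echo ``TE_i`` the in-region signal is
    ``s0 * exp(-TE_i / T2*(region, t_k))`` with background zero; the
    subject's per-frame motion shift is then applied identically to all
    echoes of the frame, and finally magnitude noise of the configured
    model ("gaussian" clipped at zero, or "rician") is added.

    When ``align_release_to_grid`` is set (the default) the cuff inflation
    and deflation times are snapped to the nearest frame timestamp before
    simulation, so a ground-truth ttp that is a multiple of the frame
    interval has its analytic peak exactly on the frame grid.

    Returns the series together with a ground-truth record holding the
    exact schedule and parameters used; the record round-trips through the
    JSON sidecar.
    """
    if protocol is None:
        protocol = AcquisitionProtocol()
    if noise_model not in ("gaussian", "rician"):
        raise ConfigurationError(f"unknown noise model {noise_model!r}")
    labels = geometry.region_labels
    if align_release_to_grid:
        schedule = schedule.aligned_to_grid()
    times = schedule.frame_times()
    n_frames = times.size
    motion = subject.motion_trace
    if motion is None:
        motion = [(0, 0)] * n_frames
    if len(motion) != n_frames:
        raise ConfigurationError(
            f"motion_trace length {len(motion)} != number of frames {n_frames}")

    te = protocol.echo_times()  # ms
    nr, nc = labels.shape
    data = np.zeros((nr, nc, te.size, n_frames), dtype=float)

    # per-region T2* trace -> signal cube, painted into the labeled pixels
    for lab, name in LABEL_NAMES.items():
        region_mask = labels == lab
        if not np.any(region_mask):
            continue
        params = subject.region_params.get(name)
        if params is None:
            if lab == BONE:
                params = BONE_T2STAR_MS
            else:
                raise ConfigurationError(f"no parameters for region {name!r}")
        t2 = region_t2star_at(name, params, times, schedule)  # (F,)
        s0 = params.s0 if isinstance(params, PerfusionCurveParams) else 100.0
        # (E, F) decay table for this region
        signal = s0 * np.exp(-te[:, None] / t2[None, :])
        data[region_mask] = signal  # broadcast over region pixels

    for k, (dr, dc) in enumerate(motion):
        if (dr, dc) != (0, 0):
            for i in range(te.size):
                data[:, :, i, k] = shift_image(data[:, :, i, k], (dr, dc))

    if subject.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        sigma = subject.noise_sigma
        if noise_model == "gaussian":
            data = np.clip(data + rng.normal(0.0, sigma, data.shape), 0.0, None)
        else:  # rician: magnitude of complex signal + iid Gaussian channels
            re = data + rng.normal(0.0, sigma, data.shape)
            im = rng.normal(0.0, sigma, data.shape)
            data = np.hypot(re, im)

    series = MultiEchoSeries(data=data, echo_times_ms=te, frame_times_s=times,
                             schedule=schedule, subject_id=subject.subject_id)
    ground_truth = {
        "schedule": schedule.to_dict(),
        "noise_model": noise_model,
        "subject": subject.to_dict(),
    }
    return series, ground_truth


def default_noise_sigma(params: PerfusionCurveParams, snr: float = 50.0,
                        first_echo_ms: float = 2.0) -> float:
    """Noise sigma giving the requested SNR at the first echo at baseline."""
    return params.s0 * float(np.exp(-first_echo_ms / params.t2star_baseline)) / snr
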