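"""Synthetic data generators with known ground truth.

Stand-ins for the study's raw recordings: two-state CCW/CW switching
speed traces (tethered-cell assays), bead centroid trajectories,
stepwise stator-resurrection traces, and noisy end-on ring images with
N-fold rotational symmetry.  Every generator draws from a single
seeded ``numpy.random.Generator`` per call, so fixtures are exactly
reproducible.

Conventions: CCW rotation is positive speed; angles are right-handed in
the x/y plane viewed from above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .trace import SpeedTrace, Trajectory

__all__ = [
    "SwitchSimParams",
    "BeadSimParams",
    "ResurrectionSimParams",
    "RingSimParams",
    "SwitchingSim",
    "ResurrectionSim",
    "RingImage",
    "simulate_switching_speed",
    "simulate_bead_positions",
    "simulate_resurrection",
    "generate_ring_image",
]

CCW, CW = "CCW", "CW"


@dataclass(frozen=True)
class SwitchSimParams:
    """Two-state Markov motor: CCW at +ccw_speed_hz, CW at -cw_speed_hz.

    ``k_ccw_to_cw`` and ``k_cw_to_ccw`` are the exponential switching
    rates (1/s).  The two rates are independent parameters: nothing
    forces detailed balance, and real motors are not symmetric.
    ``initial_state`` may be "CCW", "CW" or "stationary" (drawn from the
    chain's stationary distribution).
    """

    ccw_speed_hz: float = 7.0
    cw_speed_hz: float = 7.0
    k_ccw_to_cw: float = 0.5
    k_cw_to_ccw: float = 0.5
    duration_s: float = 30.0
    frame_rate_hz: float = 100.0
    speed_noise_sd_hz: float = 1.0
    seed: int = 0
    initial_state: str = CCW

    def __post_init__(self):
        if not (self.ccw_speed_hz > 0 and self.cw_speed_hz > 0):
            raise ValueError("speeds must be positive")
        for k in (self.k_ccw_to_cw, self.k_cw_to_ccw):
            if not np.isfinite(k) or k < 0:
                raise ValueError("switching rates must be finite and >= 0")
        if self.duration_s * self.frame_rate_hz < 2:
            raise ValueError("duration * frame_rate must give at least 2 frames")
        if self.speed_noise_sd_hz < 0:
            raise ValueError("noise SD must be >= 0")
        if self.initial_state not in (CCW, CW, "stationary"):
            raise ValueError("initial_state must be CCW, CW or stationary")


@dataclass(frozen=True)
class BeadSimParams:
    """Geometry of a bead-assay recording: rotation radius, centre, and
    camera localisation error (all micrometres)."""

    rotation_radius_um: float = 0.3
    localization_noise_um: float = 0.01
    center_xy_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (np.isfinite(self.rotation_radius_um) and self.rotation_radius_um > 0):
            raise ValueError("rotation radius must be finite and positive")
        if self.localization_noise_um < 0:
            raise ValueError("localisation noise must be >= 0")


@dataclass(frozen=True)
class ResurrectionSimParams:
    """Stepwise stator recruitment: unit count is a pure-birth process,
    each active unit adding ``unit_increment_hz`` to the speed.

    Defaults follow the high-load bead-assay picture: ~7 Hz per unit,
    at most ~11 units, 1000 frames/s.
    """

    unit_increment_hz: float = 7.0
    max_units: int = 11
    recruitment_rate_per_s: float = 0.05
    speed_noise_sd_hz: float = 0.7
    duration_s: float = 300.0
    frame_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.unit_increment_hz <= 0:
            raise ValueError("unit increment must be positive")
        if not (1 <= self.max_units <= 12):
            raise ValueError("max_units must be in 1..12")
        if self.recruitment_rate_per_s < 0:
            raise ValueError("recruitment rate must be >= 0")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration and frame rate must be positive")


@dataclass(frozen=True)
class RingSimParams:
    """End-on view of an N-fold symmetric ring: ``symmetry_n`` Gaussian
    blobs (peak amplitude 1) equally spaced on a circle, plus white
    pixel noise.  SNR is blob peak over noise SD."""

    symmetry_n: int = 34
    ring_radius_px: float = 50.0
    blob_sigma_px: float = 2.0
    image_size_px: int = 128
    pixel_size_angstrom: float = 1.69
    noise_sd: float = 0.0
    global_rotation_deg: float = 0.0
    center_offset_px: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.symmetry_n < 2:
            raise ValueError("symmetry_n must be >= 2")
        if self.ring_radius_px <= 0 or self.blob_sigma_px <= 0:
            raise ValueError("radius and blob sigma must be positive")
        if self.pixel_size_angstrom <= 0:
            raise ValueError("pixel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        reach = self.ring_radius_px + 3 * self.blob_sigma_px
        off = max(abs(self.center_offset_px[0]), abs(self.center_offset_px[1]))
        if reach + off >= self.image_size_px / 2:
            raise ValueError("ring (radius + 3 sigma + offset) exceeds the frame")


@dataclass(frozen=True)
class SwitchingSim:
    """A simulated switching trace with its ground truth."""

    trace: SpeedTrace
    state: np.ndarray  # per-frame label, "CCW"/"CW"
    dwell_states: np.ndarray  # per continuous-time dwell
    dwell_durations_s: np.ndarray
    true_cw_fraction: float  # time-weighted CW occupancy of the state path
    true_reversals: int  # reversals within the sampled window


@dataclass(frozen=True)
class ResurrectionSim:
    trace: SpeedTrace
    unit_count: np.ndarray  # per-frame ground-truth active-unit count
    recruitment_times_s: np.ndarray


@dataclass(frozen=True)
class RingImage:
    """2-D end-on ring image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_angstrom: float
    center_px: tuple[float, float] | None = None

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("pixels must be a square 2-D array")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", p)


def _gillespie_two_state(
    rng: np.random.Generator,
    k12: float,
    k21: float,
    duration: float,
    initial: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time state path: (dwell states, dwell durations).

    Dwells are exact exponential draws, so switching statistics are
    independent of the eventual frame rate.
    """
    if initial == "stationary":
        p_ccw = k21 / (k12 + k21) if (k12 + k21) > 0 else 1.0
        initial = CCW if rng.random() < p_ccw else CW
    states, durs = [], []
    t, s = 0.0, initial
    while t < duration:
        rate = k12 if s == CCW else k21
        dwell = np.inf if rate == 0 else rng.exponential(1.0 / rate)
        states.append(s)
        durs.append(min(dwell, duration - t))
        t += dwell
        s = CW if s == CCW else CCW
    return np.array(states), np.array(durs)


def simulate_switching_speed(params: SwitchSimParams) -> SwitchingSim:
    """Simulate a two-state switching motor sampled at the camera frame rate.

    The state path is generated in continuous time (Gillespie) and then
    sampled; the signed speed is +ccw_speed in CCW, -cw_speed in CW,
    plus i.i.d. Gaussian noise.  Ground-truth per-frame labels, the dwell
    sequence, the time-weighted CW occupancy and the number of reversals
    inside the recording are returned alongside the trace.
    """
    rng = np.random.default_rng(params.seed)
    dwell_states, dwell_durs = _gillespie_two_state(
        rng,
        params.k_ccw_to_cw,
        params.k_cw_to_ccw,
        params.duration_s,
        params.initial_state,
    )
    n = int(round(params.duration_s * params.frame_rate_hz))
    t = np.arange(n) / params.frame_rate_hz
    edges = np.concatenate([[0.0], np.cumsum(dwell_durs)])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(dwell_states) - 1)
    state = dwell_states[idx]
    speed = np.where(state == CCW, params.ccw_speed_hz, -params.cw_speed_hz)
    if params.speed_noise_sd_hz > 0:
        speed = speed + rng.normal(0.0, params.speed_noise_sd_hz, n)
    cw_time = dwell_durs[dwell_states == CW].sum()
    return SwitchingSim(
        trace=SpeedTrace(time_s=t, speed_hz=speed.astype(float),
                         frame_rate_hz=params.frame_rate_hz),
        state=state,
        dwell_states=dwell_states,
        dwell_durations_s=dwell_durs,
        true_cw_fraction=float(cw_time / params.duration_s),
        true_reversals=max(0, len(dwell_states) - 1),
    )


def simulate_bead_positions(
    speed: SpeedTrace, params: BeadSimParams, seed: int = 0
) -> Trajectory:
    """Turn a speed trace into a bead centroid trajectory.

    The phase angle is the cumulative integral of ``2*pi*speed``; the
    bead sits on a circle of the given radius about the centre, with
    isotropic Gaussian localisation error added per frame.
    """
    rng = np.random.default_rng(seed)
    t = speed.time_s
    theta = np.concatenate(
        [[0.0], cumulative_trapezoid(2 * np.pi * speed.speed_hz, t)]
    )
    cx, cy = params.center_xy_um
    x = cx + params.rotation_radius_um * np.cos(theta)
    y = cy + params.rotation_radius_um * np.sin(theta)
    if params.localization_noise_um > 0:
        x = x + rng.normal(0.0, params.localization_noise_um, t.size)
        y = y + rng.normal(0.0, params.localization_noise_um, t.size)
    return Trajectory(time_s=t, x_um=x, y_um=y)


def simulate_resurrection(params: ResurrectionSimParams) -> ResurrectionSim:
    """Simulate stepwise stator recruitment after induced expression.

    The active-unit count is a pure-birth process (exponential waiting
    times at ``recruitment_rate_per_s``) capped at ``max_units``; speed
    is ``count * unit_increment_hz`` plus Gaussian noise.
    """
    rng = np.random.default_rng(params.seed)
    if params.recruitment_rate_per_s > 0:
        waits = rng.exponential(1.0 / params.recruitment_rate_per_s, params.max_units)
        times = np.cumsum(waits)
        times = times[times < params.duration_s]
    else:
        times = np.array([])
    n = int(round(params.duration_s * params.frame_rate_hz))
    t = np.arange(n) / params.frame_rate_hz
    count = np.searchsorted(times, t, side="right").astype(int)
    speed = count * params.unit_increment_hz
    if params.speed_noise_sd_hz > 0:
        speed = speed + rng.normal(0.0, params.speed_noise_sd_hz, n)
    return ResurrectionSim(
        trace=SpeedTrace(time_s=t, speed_hz=speed.astype(float),
                         frame_rate_hz=params.frame_rate_hz),
        unit_count=count,
        recruitment_times_s=times,
    )


def generate_ring_image(params: RingSimParams) -> RingImage:
    """Render an N-fold symmetric ring: Gaussian blobs on a circle.

    Blobs of unit peak amplitude sit at angles ``2*pi*k/N`` (plus the
    global rotation) on a circle of ``ring_radius_px`` about the frame
    centre shifted by ``center_offset_px``; i.i.d. Gaussian pixel noise
    of SD ``noise_sd`` is added on top.
    """
    size = params.image_size_px
    c = (size - 1) / 2.0
    cx = c + params.center_offset_px[0]
    cy = c + params.center_offset_px[1]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size))
    phases = 2 * np.pi * np.arange(params.symmetry_n) / params.symmetry_n
    phases = phases + np.deg2rad(params.global_rotation_deg)
    s2 = 2 * params.blob_sigma_px**2
    for ph in phases:
        bx = cx + params.ring_radius_px * np.cos(ph)
        by = cy + params.ring_radius_px * np.sin(ph)
        img += np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / s2)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return RingImage(
        pixels=img,
        pixel_size_angstrom=params.pixel_size_angstrom,
        center_px=(cx, cy),
    )
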