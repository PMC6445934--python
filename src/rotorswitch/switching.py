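"""Switching statistics from signed speed traces.

A motor's direction record is reduced to a binary CCW/CW trace with a
dead-band (hysteresis) comparator, then summarised as CW bias — the
fraction of time spent CW over a 30-s running window — switching
frequency (reversals per second), and a rotation-class label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trace import SpeedTrace

__all__ = [
    "BinaryTrace",
    "SwitchStats",
    "PopulationSummary",
    "IndeterminateTraceError",
    "binarize",
    "estimate_hysteresis",
    "compute_switch_stats",
    "population_summary",
]

CCW, CW = "CCW", "CW"

CCW_ONLY, CW_ONLY, SWITCHING = "CCW_only", "CW_only", "switching"


class IndeterminateTraceError(ValueError):
    """The whole trace lies inside the hysteresis dead band."""


@dataclass(frozen=True)
class BinaryTrace:
    """Per-frame CCW/CW labels derived from a speed trace."""

    time_s: np.ndarray
    state: np.ndarray
    hysteresis_hz: float

    def __post_init__(self):
        if self.time_s.shape != self.state.shape:
            raise ValueError("time and state must have equal length")
        if self.hysteresis_hz < 0:
            raise ValueError("hysteresis must be >= 0")

    @property
    def reversals(self) -> int:
        return int(np.sum(self.state[1:] != self.state[:-1]))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class SwitchStats:
    """CW bias, switching frequency and rotation class of one motor."""

    cw_bias: float
    switching_frequency_per_s: float
    rotation_class: str
    window_s: float = 30.0
    bias_series: np.ndarray | None = None  # (n, 2) columns: window-centre t, bias

    def __post_init__(self):
        if not 0.0 <= self.cw_bias <= 1.0:
            raise ValueError("cw_bias must lie in [0, 1]")
        if self.switching_frequency_per_s < 0:
            raise ValueError("switching frequency must be >= 0")


@dataclass(frozen=True)
class PopulationSummary:
    mean_cw_bias: float
    sd_cw_bias: float
    mean_switching_frequency_per_s: float
    sd_switching_frequency_per_s: float
    n: int
    class_counts: dict


def estimate_hysteresis(speed: SpeedTrace, factor: float = 3.0) -> float:
    """Dead-band half-width from the trace's own noise level.

    The noise SD is estimated robustly as MAD(diff(speed))/(sqrt(2) *
    0.6745) — first differences cancel the slowly varying signal — and
    multiplied by ``factor`` (default 3) so that noise alone almost
    never crosses the band.
    """
    d = np.diff(speed.speed_hz)
    sd = np.median(np.abs(d - np.median(d))) / (np.sqrt(2) * 0.6745)
    return float(factor * sd)


def _runs(state: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (half-open) index pairs of constant-state runs."""
    change = np.flatnonzero(state[1:] != state[:-1]) + 1
    bounds = np.concatenate([[0], change, [state.size]])
    return list(zip(bounds[:-1], bounds[1:]))


def binarize(
    speed: SpeedTrace,
    hysteresis_hz: float | None = None,
    min_dwell_s: float | None = None,
) -> BinaryTrace:
    """Convert a signed speed trace to a binary CCW/CW trace.

    A Schmitt-trigger rule: CCW where speed > +h, CW where speed < -h,
    and inside the dead band |speed| <= h the previous state persists.
    Runs shorter than ``min_dwell_s`` (default 2 frames) are then merged
    into their neighbours, shortest first, so that camera noise cannot
    masquerade as reversals.

    ``hysteresis_hz=None`` uses :func:`estimate_hysteresis`.

    Raises
    ------
    IndeterminateTraceError
        If every sample lies inside the dead band.
    """
    v = speed.speed_hz
    h = estimate_hysteresis(speed) if hysteresis_hz is None else float(hysteresis_hz)
    if min_dwell_s is None:
        min_dwell_s = 2.0 / speed.frame_rate_hz
    sgn = np.zeros(v.size, dtype=int)
    sgn[v > h] = 1
    sgn[v < -h] = -1
    nz = np.flatnonzero(sgn)
    if nz.size == 0:
        raise IndeterminateTraceError(
            f"every sample lies within the dead band |speed| <= {h:g} Hz"
        )
    # dead-band samples inherit the previous decided state (first decided
    # state back-fills the leading band samples)
    sgn[: nz[0]] = sgn[nz[0]]
    idx = np.maximum.accumulate(np.where(sgn != 0, np.arange(v.size), 0))
    filled = sgn[idx]
    state = np.where(filled > 0, CCW, CW)

    # debounce: merge sub-min_dwell runs into neighbours, shortest first
    dt = 1.0 / speed.frame_rate_hz
    min_frames = max(1, int(np.ceil(min_dwell_s / dt)))
    runs = _runs(state)
    while len(runs) > 1:
        lengths = [b - a for a, b in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_frames:
            break
        a, b = runs[i]
        neighbour = state[runs[i - 1][0]] if i > 0 else state[runs[i + 1][0]]
        state[a:b] = neighbour
        runs = _runs(state)
    return BinaryTrace(time_s=speed.time_s, state=state, hysteresis_hz=h)


def compute_switch_stats(bin_trace: BinaryTrace, window_s: float = 30.0) -> SwitchStats:
    """CW bias (30-s running window), switching frequency, rotation class.

    The per-window bias is the fraction of frames in the CW state; for a
    record longer than the window the summary bias is the mean of the
    running-window series, for a record of exactly the window length the
    two definitions coincide, and for a shorter record the full-record
    fraction is used with a warning.  Switching frequency is reversals
    divided by record duration.  A motor is classed ``CCW_only`` /
    ``CW_only`` only if it never reverses over the whole record.
    """
    if bin_trace.state.size == 0:
        raise ValueError("empty binary trace")
    is_cw = (bin_trace.state == CW).astype(float)
    t = bin_trace.time_s
    duration = bin_trace.duration_s
    dt = duration / max(1, t.size - 1)
    w = int(round(window_s / dt)) if dt > 0 else t.size
    series = None
    if w < t.size and w >= 2:
        csum = np.concatenate([[0.0], np.cumsum(is_cw)])
        frac = (csum[w:] - csum[:-w]) / w
        centers = (t[w - 1 :] + t[: t.size - w + 1]) / 2
        series = np.column_stack([centers, frac])
        bias = float(frac.mean())
    else:
        if duration + dt < window_s:  # one-frame slack: a nominal 30-s
            # record spans (n-1) frame intervals
            warnings.warn(
                f"record ({duration:.1f} s) shorter than the {window_s:g}-s "
                "window; CW bias computed on the full record",
                stacklevel=2,
            )
        bias = float(is_cw.mean())
    reversals = bin_trace.reversals
    freq = reversals / duration if duration > 0 else 0.0
    if reversals == 0:
        rot_class = CW_ONLY if is_cw[0] else CCW_ONLY
    else:
        rot_class = SWITCHING
    return SwitchStats(
        cw_bias=bias,
        switching_frequency_per_s=float(freq),
        rotation_class=rot_class,
        window_s=window_s,
        bias_series=series,
    )


def population_summary(stats: list[SwitchStats]) -> PopulationSummary:
    """Arithmetic mean and population SD (divisor n) of bias and
    switching frequency over a cohort, plus rotation-class counts."""
    if len(stats) == 0:
        raise ValueError("need at least one motor")
    biases = np.array([s.cw_bias for s in stats])
    freqs = np.array([s.switching_frequency_per_s for s in stats])
    counts = {c: 0 for c in (CCW_ONLY, CW_ONLY, SWITCHING)}
    for s in stats:
        counts[s.rotation_class] += 1
    return PopulationSummary(
        mean_cw_bias=float(biases.mean()),
        sd_cw_bias=float(biases.std()),
        mean_switching_frequency_per_s=float(freqs.mean()),
        sd_switching_frequency_per_s=float(freqs.std()),
        n=len(stats),
        class_counts=counts,
    )
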