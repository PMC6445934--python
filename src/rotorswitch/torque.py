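"""Torque computation and torque-speed curve extrapolation.

In a bead assay the motor turns a polystyrene bead of radius ``a`` on a
circle of radius ``r`` through a viscous medium; at these Reynolds
numbers the motor torque equals the rotational viscous drag torque,

    T = xi * 2*pi*f,      xi = 8*pi*eta*a**3 + 6*pi*eta*a*r**2,

with ``f`` the rotation rate (Hz) and ``eta`` the medium viscosity.
The first drag term is the bead spinning about its own axis, the second
the bead translating around the rotation circle; filament-stub drag is
neglected.  Varying bead size varies load, tracing the motor's
torque-speed curve: a near-flat high-load plateau and a steep low-load
drop.  The curve's two endpoints — stall torque and zero-load speed —
are obtained by simple linear extrapolation of each regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import SpeedTrace

__all__ = [
    "BeadSpec",
    "TorqueSpeedPoint",
    "TorqueSpeedCurve",
    "WATER_VISCOSITY_PA_S",
    "drag_coefficient",
    "torque_from_speed",
    "build_curve",
    "extrapolate_limits",
]

# water at ~22 degC; the buffer is dilute so this is the default
WATER_VISCOSITY_PA_S = 9.6e-4

_PNNM_PER_NM = 1e21  # 1 N*m*s = 1e21 pN*nm*s


@dataclass(frozen=True)
class BeadSpec:
    """Bead-assay load descriptor (bead diameter, rotation radius, viscosity)."""

    bead_diameter_um: float
    rotation_radius_um: float = 0.0
    viscosity_pa_s: float = WATER_VISCOSITY_PA_S

    def __post_init__(self):
        if self.bead_diameter_um <= 0:
            raise ValueError("bead diameter must be positive")
        if self.rotation_radius_um < 0:
            raise ValueError("rotation radius must be >= 0")
        if self.viscosity_pa_s <= 0:
            raise ValueError("viscosity must be positive")


@dataclass(frozen=True)
class TorqueSpeedPoint:
    speed_hz: float
    torque_pn_nm: float
    bead_diameter_um: float
    n_motors: int = 1


@dataclass(frozen=True)
class TorqueSpeedCurve:
    """(speed, torque) points ordered by speed, with optional extrapolated
    limits filled in by :func:`extrapolate_limits`."""

    points: tuple[TorqueSpeedPoint, ...]
    stall_torque_pn_nm: float | None = None
    zero_load_speed_hz: float | None = None
    knee_speed_hz: float | None = None


def drag_coefficient(spec: BeadSpec) -> float:
    """Rotational drag coefficient xi in pN*nm*s.

    xi = 8*pi*eta*a^3 + 6*pi*eta*a*r^2 with a the bead radius and r the
    rotation radius.  Computed in SI and converted (1 N*m*s = 1e21
    pN*nm*s).
    """
    a = spec.bead_diameter_um / 2 * 1e-6  # m
    r = spec.rotation_radius_um * 1e-6
    eta = spec.viscosity_pa_s
    xi_si = 8 * np.pi * eta * a**3 + 6 * np.pi * eta * a * r**2  # N*m*s
    return float(xi_si * _PNNM_PER_NM)


def torque_from_speed(speed_hz: float, xi_pn_nm_s: float) -> float:
    """Torque (pN*nm) at rotation rate ``speed_hz`` under drag ``xi``."""
    if not (np.isfinite(speed_hz) and np.isfinite(xi_pn_nm_s)):
        raise ValueError("speed and drag must be finite")
    return float(xi_pn_nm_s * 2 * np.pi * speed_hz)


def build_curve(records: list[tuple[SpeedTrace, BeadSpec]]) -> TorqueSpeedCurve:
    """Assemble a torque-speed curve from per-motor recordings.

    Motors recorded with the same bead diameter are pooled: the point's
    speed is the mean |speed| over those motors and its torque uses the
    pooled mean drag coefficient.  Points are returned sorted by speed.
    """
    if not records:
        raise ValueError("no records")
    by_bead: dict[float, list[tuple[float, float]]] = {}
    for tr, spec in records:
        by_bead.setdefault(spec.bead_diameter_um, []).append(
            (float(np.mean(np.abs(tr.speed_hz))), drag_coefficient(spec))
        )
    points = []
    for d, entries in by_bead.items():
        speeds, xis = zip(*entries)
        f = float(np.mean(speeds))
        points.append(
            TorqueSpeedPoint(
                speed_hz=f,
                torque_pn_nm=torque_from_speed(f, float(np.mean(xis))),
                bead_diameter_um=d,
                n_motors=len(entries),
            )
        )
    points.sort(key=lambda p: p.speed_hz)
    return TorqueSpeedCurve(points=tuple(points))


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def extrapolate_limits(
    curve: TorqueSpeedCurve, knee_speed_hz: float | str = "auto"
) -> TorqueSpeedCurve:
    """Stall torque and zero-load speed by two linear extrapolations.

    Points below the knee speed (high load) are fitted with a line and
    evaluated at speed 0 -> stall torque; points at or above the knee
    (low load) are fitted and solved for torque 0 -> zero-load speed.
    ``knee_speed_hz="auto"`` chooses the two-segment split (each segment
    keeping >= 2 points) that minimises the total squared residual.

    Raises
    ------
    ValueError
        If either regime has fewer than 2 points, or the low-load line
        does not descend (no zero-torque crossing).
    """
    pts = sorted(curve.points, key=lambda p: p.speed_hz)
    f = np.array([p.speed_hz for p in pts])
    T = np.array([p.torque_pn_nm for p in pts])
    if f.size < 4:
        raise ValueError("need at least 4 points (2 per regime)")

    if knee_speed_hz == "auto":
        best, best_rss = None, np.inf
        for split in range(2, f.size - 1):
            rss = 0.0
            for xs, ys in ((f[:split], T[:split]), (f[split:], T[split:])):
                s, b = _line_fit(xs, ys)
                rss += float(np.sum((ys - (s * xs + b)) ** 2))
            if rss < best_rss:
                best, best_rss = split, rss
        split = best
        knee = float((f[split - 1] + f[split]) / 2)
    else:
        knee = float(knee_speed_hz)
        split = int(np.searchsorted(f, knee))
        if split < 2 or f.size - split < 2:
            raise ValueError("fewer than 2 points in a regime for this knee")

    hs, hb = _line_fit(f[:split], T[:split])
    stall = hb  # torque at speed 0
    ls, lb = _line_fit(f[split:], T[split:])
    if ls >= 0:
        raise ValueError("low-load segment does not descend; no zero-torque crossing")
    zero_load = -lb / ls
    return TorqueSpeedCurve(
        points=tuple(pts),
        stall_torque_pn_nm=float(stall),
        zero_load_speed_hz=float(zero_load),
        knee_speed_hz=knee,
    )
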