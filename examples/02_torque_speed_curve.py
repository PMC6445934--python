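"""Torque-speed curve and its stall/zero-load extrapolations.

Five bead sizes load a motor that follows a piecewise-linear
torque-speed law (stall 1523 pN*nm, knee at 100 Hz, zero-load 144 Hz).
For each bead the steady speed consistent with the law and the bead's
rotational drag is found, a constant-speed trace simulated, and the
curve rebuilt and extrapolated from those records alone.
"""

import numpy as np
from scipy.optimize import brentq

from rotorswitch import (
    BeadSpec,
    SpeedTrace,
    build_curve,
    drag_coefficient,
    extrapolate_limits,
)

STALL, KNEE_F, KNEE_T, ZERO = 1523.0, 100.0, 1200.0, 144.0


def motor_torque(f):
    if f < KNEE_F:
        return STALL + (KNEE_T - STALL) / KNEE_F * f
    return KNEE_T * (ZERO - f) / (ZERO - KNEE_F)


records = []
for diameter in (1.5, 1.0, 0.8, 0.6, 0.5):
    spec = BeadSpec(bead_diameter_um=diameter, rotation_radius_um=0.2)
    xi = drag_coefficient(spec)
    # steady state: motor torque equals drag torque xi*2*pi*f
    f = brentq(lambda v: motor_torque(v) - xi * 2 * np.pi * v, 1e-3, ZERO)
    t = np.arange(2000) / 1000.0
    records.append((SpeedTrace(t, np.full(t.size, f), 1000.0), spec))

curve = extrapolate_limits(build_curve(records))
for p in curve.points:
    print(f"bead {p.bead_diameter_um:4.1f} um : "
          f"{p.speed_hz:7.1f} Hz  {p.torque_pn_nm:8.1f} pN nm")
print(f"stall torque    : {curve.stall_torque_pn_nm:7.1f} pN nm (true {STALL})")
print(f"zero-load speed : {curve.zero_load_speed_hz:7.1f} Hz    (true {ZERO})")
# The high-load points extrapolate linearly to the stall torque at zero
# speed; the low-load points extrapolate to the zero-load speed at zero
# torque.  Both recover the generating law's endpoints.
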