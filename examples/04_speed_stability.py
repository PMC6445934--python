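"""Speed stability: sigma_omega / omega_av of a 300-s bead record.

A motor holding 10 stator units rotates steadily; one whose unit count
wanders fluctuates.  The ratio of the speed SD to the mean separates
the two.
"""

import numpy as np

from rotorswitch import SpeedTrace, speed_stability

rng = np.random.default_rng(0)
n = 30_000  # 300 s at 100 frames/s
t = np.arange(n) / 100.0

counts = np.empty(n)
c = 10
for i in range(n):
    if rng.random() < 1e-3:  # unit exchange roughly every 10 s
        c = int(np.clip(c + rng.choice([-1, 1]), 7, 10))
    counts[i] = c
noise = rng.normal(0, 2.0, n)

steady = SpeedTrace(t, 10 * 7.0 + noise, 100.0)
wandering = SpeedTrace(t, counts * 7.0 + noise, 100.0)

for name, trace in [("steady (10 units)", steady),
                    ("wandering (7-10 units)", wandering)]:
    st = speed_stability(trace)
    print(f"{name:24s}: omega_av {st.omega_av_hz:5.1f} Hz, "
          f"sigma {st.sigma_omega_hz:4.1f} Hz, ratio {st.ratio:.2f}")
# A higher sigma/mean ratio flags a motor that cannot hold its torque
# output constant — e.g. one that keeps losing and regaining stators.
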