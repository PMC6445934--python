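# rotorswitch

Quantitative analysis of bacterial flagellar-motor rotation and C-ring
geometry, for single-molecule biophysicists working with tethered-cell and
bead-assay recordings and with end-on cryo-EM views of the motor's
cytoplasmic switch complex.

The flagellar motor is a rotary machine: MotA/MotB stator units drive a
rotor whose cytoplasmic C ring (FliG/FliM/FliN) sets the rotation direction.
`rotorswitch` implements the standard measurements made on such motors:

- **Trace conversion** — centroid trajectories of a rotating bead or cell
  body are turned into signed rotation-rate traces (algebraic circle fit,
  phase unwrapping, windowed-regression differentiation; CCW positive).
- **Switching statistics** — a speed trace is binarized with a dead-band
  comparator; the CW bias is the fraction of time spent CW over a 30-s
  running window and the switching frequency counts reversals per second.
- **Torque–speed analysis** — at low Reynolds number the motor torque
  equals the viscous drag torque, *T* = ξ·2π*f* with
  ξ = 8πη*a*³ + 6πη*a r*² (bead radius *a*, rotation radius *r*, viscosity
  η).  Varying the bead size traces the torque–speed curve; linear
  extrapolation of the high-load and low-load branches yields the stall
  torque and zero-load speed.
- **Resurrection analysis** — after induced stator expression the speed
  rises in steps of one stator unit.  A shared-width Gaussian comb
  Σₖ Aₖ·N(offset + kΔ, σ) fitted to the speed histogram gives the per-unit
  increment Δ; mean speed over Δ counts the active units.  The speed
  stability of a motor is σ_ω/ω_av of a long record.
- **Ring symmetry and geometry** — an end-on ring image is resampled into
  polar coordinates; the circular autocorrelation of the angular intensity
  profile is Fourier-transformed and the dominant harmonic order in a
  search band (default C28–C35) is the rotational symmetry *N*.  The
  diameter *D* is twice the radius of the rotationally averaged radial
  profile's peak, and the unit repeat distance along the circumference is
  π*D*/*N*.
- **Synthetic generators** — seeded simulators for all of these inputs
  (continuous-time two-state switching motors, bead trajectories, pure-birth
  resurrection traces, N-fold symmetric ring images) with ground truth
  returned alongside every trace.

## Worked example

`examples/` holds one short script per capability.  Ring analysis
(`examples/05_ring_symmetry.py`) renders a noisy C31 ring of radius 106 px
at 1.69 Å/px and recovers its geometry:

```
detected symmetry    : C31 (confidence 4761.5x next candidate)
ring diameter        : 357.6 Å (true 358.3)
unit repeat distance : 36.2 Å
```

The symmetry is read off the harmonic spectrum of the angular
autocorrelation, the diameter from the radial profile peak (sub-pixel), and
the repeat distance is the circumferential spacing of adjacent subunits —
the quantity that distinguishes loosely from tightly packed ring states.

Torque–speed extrapolation (`examples/02_torque_speed_curve.py`) simulates
beads of 1.5–0.5 µm on a motor with a piecewise-linear torque–speed law and
recovers its endpoints from the rebuilt curve:

```
bead  1.5 um :    21.6 Hz    1453.3 pN nm
bead  1.0 um :    62.3 Hz    1321.8 pN nm
bead  0.8 um :   101.2 Hz    1166.4 pN nm
bead  0.6 um :   120.0 Hz     654.8 pN nm
bead  0.5 um :   127.6 Hz     447.3 pN nm
stall torque    :  1523.0 pN nm (true 1523.0)
zero-load speed :   144.0 Hz    (true 144.0)
```

A thin CLI mirrors the library (`rotorswitch simulate|trace|switch|torque|
resurrection|stability|ringsym|run`); `rotorswitch run --config manifest.yaml`
executes every stage named in a YAML manifest and writes a JSON report plus
TSV tables.

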