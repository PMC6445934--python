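# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `rotorswitch`.

## Trace conversion

A recording is a centroid time series (time, x, y) of a marker rotating
about a fixed centre.  The rotation circle is fitted by the algebraic
(Kåsa) method — the linear least-squares solution of
x² + y² = 2c_x·x + 2c_y·y + (r² − c_x² − c_y²) — which is closed-form,
translation- and rotation-equivariant, and has negligible bias at the
signal-to-noise of bead assays (localisation error ~10 nm on rotation radii
of hundreds of nm).  No iterative refinement is applied.  Degenerate
(collinear) input is rejected rather than producing an unstable fit.

The phase angle atan2(y − c_y, x − c_x) is unwrapped cumulatively.  A
frame-to-frame step reaching π rad is direction-ambiguous — a 300 Hz motor
filmed at 100 frames/s aliases — so it raises an explicit undersampling
error listing the offending frames instead of silently wrapping.

Rotation rate (Hz) is the slope of a linear regression of angle/(2π) on
time over a centred window: 5 frames at 100 frames/s, 11 at 1000 frames/s
and above (defaults; any odd length is accepted).  The first and last
half-windows use shrunken one-sided windows so the output keeps the input
length.  Windowed regression was chosen over plain finite differences
because it suppresses localisation noise without phase delay; the exact
differentiation filter used in the original tracking literature is not
published, so this is a documented package choice.

Sign convention everywhere: CCW rotation (right-handed x/y frame viewed
from above) is positive.

## Switching statistics

Binarization is a Schmitt trigger: CCW where speed > +h, CW where speed
< −h, previous state retained inside the dead band |speed| ≤ h.  The
default h is 3× a robust noise estimate (median absolute deviation of the
first-differenced speed divided by √2·0.6745), so noise alone essentially
never crosses the band.  Runs shorter than a minimum dwell (default 2
frames) are merged into their neighbours, shortest first; without
debouncing, camera noise inflates the switching frequency.  A trace lying
entirely inside the dead band raises an "indeterminate" error.

CW bias is the fraction of time in the CW state over a 30-s running
window.  For records longer than 30 s the summary bias is the mean of the
running-window series; for a 30-s record the two definitions coincide; for
shorter records the full-record fraction is used with a warning.  Switching
frequency is reversals divided by record duration.  A motor is classed
CCW-only or CW-only only if it never reverses over the whole record.
Population summaries use the arithmetic mean and the population SD
(divisor n); the choice of divisor is configurable in analysis code built
on these primitives but population SD is the package default.

## Torque and torque–speed curves

Rotational drag: ξ = 8πη·a³ + 6πη·a·r², the spinning-sphere term plus the
term for the bead's translation around the rotation circle.  Filament-stub
drag is neglected (dominated by the bead at these radii).  Default
viscosity is 9.6×10⁻⁴ Pa·s (water near 22 °C), configurable per record.
Computation is in SI internally and converted once
(1 N·m·s = 10²¹ pN·nm·s).  Torque is T = ξ·2πf with speeds entered as
magnitudes; direction is handled upstream.

A curve is built by pooling motors per bead size (mean |speed|, mean drag)
and sorting points by speed.  Stall torque and zero-load speed come from
two least-squares lines: the high-load points evaluated at zero speed and
the low-load points solved for zero torque.  The knee splitting the
regimes is chosen automatically as the two-segment split (≥2 points each)
minimising the total squared residual, since which points feed each
extrapolation is otherwise a judgement call.  A non-descending low-load
branch (no zero crossing) is an explicit error.

## Resurrection and stability

Speed histograms use |speed| with a 1 Hz default bin width.  The comb
model Σₖ Aₖ·exp(−(v − offset − kΔ)²/2σ²) shares σ across components and
enforces equal spacing.  Fitting is nonlinear least squares (lmfit,
Levenberg–Marquardt) over a grid of component counts (from the number of
occupied clusters up to 12 — roughly the stator-unit ceiling at high load)
and several spacing initialisations: the dominant non-zero-lag peak of the
count autocorrelation, half that lag, and the smallest gap between
occupied clusters.  Three guards make the spacing identifiable:

- amplitudes are capped at twice the histogram maximum, so an off-range
  component cannot serve as a disguised background via its far tail;
- σ is bounded by the candidate spacing, so the comb cannot degenerate
  into one broad Gaussian;
- a comb at Δ/m always fits at least as well as the true comb (extra
  components go to ~0), so after fitting, harmonics are collapsed: if the
  occupied components — those above the Poisson noise floor √(max count)
  and within the histogram range — share an index stride g > 1, the
  spacing is g·Δ.

A histogram with fewer than two occupied clusters cannot identify Δ and
raises an error recommending the raw-mean fallback.  The increment's
standard error is the fit standard error; whether a published "±" on such
an increment is fit uncertainty or across-motor spread is generally
ambiguous, and this package reports the former.

Stator count is round(mean speed / Δ).  Speed stability is σ_ω/ω_av of
|speed| (population SD); zero mean is an explicit error.

## Ring symmetry and geometry

The centre is the intensity centroid refined by a two-stage grid search
(0.5 px then 0.25 px steps) maximising the sharpness of the rotationally
averaged radial profile, which peaks hardest when rays emanate from the
true centre.  The polar transform samples the image by bilinear
interpolation on 720 angular samples (0.5°, Nyquist-safe for N ≤ 50) at
1-px radial steps.

The angular profile is averaged over a radial band of ±10 % around the
detected ring radius — the band concentrates signal where the subunits
lie — mean-subtracted, and circularly autocorrelated via FFT (ACF(0) = 1).
Band-averaging before the ACF (rather than per-radius ACFs averaged after)
is the package's choice where the original processing order is unstated.
The symmetry order is the argmax of Fourier power at integer harmonics
within a configurable search band, default 28–35, the range such C rings
span; restricting the band avoids confusing N with 2N or N/2, and the
unrestricted argmax is reported alongside.  When locating the ring-radius
peak, the radial profile is smoothed with a 3-sample moving average and
radii under 4 px are excluded: an angular mean at radius r pools only
~2πr pixels, so its noise grows as 1/√r and tiny radii otherwise produce
spurious peaks in noisy images.

Diameter is twice the radius of the radial-profile peak, refined by
three-point parabolic interpolation (the raw peak is pixel-quantised); on
noiseless synthetic rings the residual bias is under 0.05 px across radii
80–120 px.  A peak on the first or last sampled radius is flagged.  The
unit repeat distance is πD/N.  Where a ring's symmetry is genuinely
ambiguous between two orders, compute the repeat distance under each
candidate rather than forcing a choice.

Population classification assigns each image its dominant order, then
aligns class members by circular cross-correlation of their band-averaged
angular profiles (shifts are equivalent modulo 2π/N) and averages the
rotated images.  3-D reconstruction is out of scope: diameters are
measured on 2-D end-on views, with the rotationally averaged radial
profile standing in for a cylindrically symmetrised reprojection.

## Synthetic generators

The generators emulate the statistical structure of the study conditions,
not the microscopy itself:

- **Switching motor**: a continuous-time two-state Markov chain (Gillespie
  dwells, exponential by construction) sampled at the camera frame rate —
  100 frames/s for tethered-cell-like traces — with signed speed ±7 Hz by
  default and i.i.d. Gaussian speed noise.  Simulating in continuous time
  keeps switching statistics independent of the frame rate.  The two
  switching rates are independent parameters; no detailed-balance
  assumption is imposed, since rate asymmetry between states is a real
  biological possibility.
- **Bead trajectory**: angle is the cumulative integral of 2π·speed;
  positions lie on a circle (default radius 0.3 µm) plus isotropic
  Gaussian localisation error (default 0.01 µm), sampled at 1000 frames/s
  by default.
- **Resurrection**: the active-unit count is a pure-birth process capped
  at 11 units (the high-load ceiling is about 10–11), with ~7 Hz per unit
  and 0.7 Hz speed noise over 300 s.  The default recruitment rate of
  0.05 /s fills most of the cap within a 300-s record; recovery tests use
  0.02 /s so several distinct levels stay well occupied.
- **Ring image**: N Gaussian blobs of unit peak amplitude, equally spaced
  on a circle, plus white pixel noise.  SNR is defined as blob peak over
  noise SD, so "SNR 2" means noise_sd = 0.5.  Default geometry is a
  50-px-radius ring in a 128-px frame at 1.69 Å/px; diameter tests use
  larger frames so radii up to 120 px fit.

What the generators do **not** emulate: rotational Brownian motion of the
bead within a frame, CheY-P binding kinetics behind switching, load
dependence of the unit increment, CTF effects, structural heterogeneity,
or correlated background in micrographs.  Passing recovery tests therefore
demonstrates correctness of the estimators under idealised noise, not
robustness to every artefact of real recordings.

All randomness flows through one seeded `numpy.random.Generator` per call,
so every fixture is exactly reproducible.

## Problem sizes

Recovery studies use 60–300-s simulated records (100–1000 frames/s), 20
replicate torque–speed curves at 5 % multiplicative noise, 50 resurrection
seeds, and 50 rings per symmetry order across C28–C35 at SNR 2 on 128-px
frames — sizes at which every quoted recovery margin is stable from run to
run while the whole suite stays quick.

## Known limitations

- The comb fit assumes a common σ and strictly equal spacing; a
  load-dependent increment would bias Δ.
- The symmetry detector requires the true order to lie inside the search
  band; orders at the band edge lose the protection against harmonic
  confusion.
- The undersampling guard detects only steps of exactly π or more;
  moderate aliasing below that threshold is undetectable in principle from
  centroid data alone.
- Circle fitting assumes a fixed rotation centre; slow stage drift is not
  modelled or corrected.
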