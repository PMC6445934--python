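"""Rotational symmetry and geometry of end-on ring images.

The C ring of the flagellar motor is an N-fold rotationally symmetric
assembly (N around 31-35 depending on strain and state).  Given an
end-on projection image, this module estimates the ring centre,
resamples the image into polar coordinates, computes the circular
autocorrelation of the angular intensity profile over a radial band at
the ring radius, and reads the symmetry order off the Fourier power
spectrum of that autocorrelation.  The ring diameter is the radius of
the peak of the rotationally averaged radial profile (sub-pixel by
parabolic interpolation), and the unit repeat distance along the
circumference is pi*D/N.

Coordinates: ``center_px`` is (x, y) = (column, row); angles are
right-handed about the centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import RingImage

__all__ = [
    "PolarMap",
    "SymmetrySpectrum",
    "RingGeometry",
    "estimate_center",
    "polar_transform",
    "angular_autocorrelation",
    "symmetry_spectrum",
    "ring_diameter",
    "unit_repeat_distance",
    "analyze_ring",
    "classify_population",
]

DEFAULT_SEARCH_BAND = (28, 35)


@dataclass(frozen=True)
class PolarMap:
    """Image resampled on a (radius, angle) grid; the angle axis spans
    [0, 2*pi) uniformly."""

    values: np.ndarray  # shape (n_radii, n_angles)
    radii_px: np.ndarray
    n_angle_samples: int

    def __post_init__(self):
        if self.values.shape != (self.radii_px.size, self.n_angle_samples):
            raise ValueError("values shape must be (n_radii, n_angles)")


@dataclass(frozen=True)
class SymmetrySpectrum:
    """Fourier power of the angular ACF at integer harmonic orders."""

    harmonic_orders: np.ndarray
    power: np.ndarray
    dominant_n: int  # argmax within the search band
    full_spectrum_n: int  # unrestricted argmax over all orders
    confidence: float  # dominant power / next-highest power in the band

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class RingGeometry:
    """Symmetry order N, diameter D (Å) and unit repeat distance pi*D/N."""

    symmetry_n: int
    diameter_angstrom: float
    repeat_distance_angstrom: float


def estimate_center(
    img: RingImage, refine_extent_px: float = 2.0, refine_step_px: float = 0.25
) -> tuple[float, float]:
    """Ring centre (x, y in pixels): intensity centroid, then local grid
    refinement maximising the sharpness (peak height) of the rotationally
    averaged radial profile — the profile is sharpest when rays are
    measured from the true centre.
    """
    p = img.pixels
    if np.ptp(p) == 0:
        raise ValueError("flat image: centre undefined")
    w = p - p.min()
    tot = w.sum()
    yy, xx = np.mgrid[0 : p.shape[0], 0 : p.shape[1]].astype(float)
    cx = float((w * xx).sum() / tot)
    cy = float((w * yy).sum() / tot)

    def sharpness(c):
        ccx, ccy = c
        lim = min(ccx, ccy, p.shape[1] - 1 - ccx, p.shape[0] - 1 - ccy)
        if lim < 2:
            return -np.inf
        radii = np.arange(1.0, np.floor(lim))
        pm = polar_transform(img, c, n_angles=180, radii_px=radii)
        prof = pm.values.mean(axis=1)
        return float(prof.max() - prof.mean())

    best = (cx, cy)
    for step in (refine_step_px * 2, refine_step_px):
        bx, by = best
        offs = np.arange(-refine_extent_px, refine_extent_px + step / 2, step)
        score_best = -np.inf
        for dx in offs:
            for dy in offs:
                s = sharpness((bx + dx, by + dy))
                if s > score_best:
                    score_best, cand = s, (bx + dx, by + dy)
        best = cand
        refine_extent_px = step
    return best


def polar_transform(
    img: RingImage,
    center: tuple[float, float] | None = None,
    n_angles: int = 720,
    radii_px: np.ndarray | None = None,
) -> PolarMap:
    """Resample the image onto a polar (radius x angle) grid by bilinear
    interpolation; rows are radii, columns the ``n_angles`` uniform
    angle samples over [0, 2*pi).
    """
    if center is None:
        center = img.center_px if img.center_px is not None else estimate_center(img)
    cx, cy = center
    lim = min(cx, cy, img.pixels.shape[1] - 1 - cx, img.pixels.shape[0] - 1 - cy)
    if radii_px is None:
        radii_px = np.arange(1.0, np.floor(lim))
    radii_px = np.asarray(radii_px, dtype=float)
    if radii_px.max() > lim + 1e-9:
        raise ValueError("requested radii extend beyond the frame")
    ang = 2 * np.pi * np.arange(n_angles) / n_angles
    rr, aa = np.meshgrid(radii_px, ang, indexing="ij")
    x = cx + rr * np.cos(aa)
    y = cy + rr * np.sin(aa)
    vals = ndimage.map_coordinates(img.pixels, [y.ravel(), x.ravel()], order=1)
    return PolarMap(
        values=vals.reshape(rr.shape), radii_px=radii_px, n_angle_samples=n_angles
    )


def _radial_profile(pm: PolarMap) -> np.ndarray:
    return pm.values.mean(axis=1)


_MIN_PEAK_RADIUS_PX = 4.0  # below this an angular mean averages too few pixels


def _profile_peak_index(prof: np.ndarray, radii: np.ndarray) -> int:
    """Index of the ring-radius peak: a 3-sample moving average suppresses
    pixel noise and radii under ~4 px are excluded (at radius r the angular
    mean pools only ~2*pi*r pixels, so its noise grows as 1/sqrt(r))."""
    if prof.size >= 3:
        sm = np.convolve(prof, np.ones(3) / 3, mode="same")
        sm[0], sm[-1] = prof[0], prof[-1]
    else:
        sm = prof
    allowed = radii >= min(_MIN_PEAK_RADIUS_PX, radii.max())
    idx = np.flatnonzero(allowed)
    return int(idx[np.argmax(sm[idx])])


def _ring_band(pm: PolarMap, band_frac: float = 0.1) -> np.ndarray:
    """Row mask of the +/-``band_frac`` radial band about the profile peak."""
    prof = _radial_profile(pm)
    r0 = pm.radii_px[_profile_peak_index(prof, pm.radii_px)]
    return np.abs(pm.radii_px - r0) <= band_frac * r0


def angular_autocorrelation(
    pm: PolarMap, radial_band: np.ndarray | tuple[float, float] | None = None
) -> np.ndarray:
    """Circular autocorrelation of the band-averaged angular profile.

    The polar map rows inside the radial band (default: +/-10 % around
    the detected ring radius) are averaged into one angular profile,
    which is mean-subtracted and circularly autocorrelated (via FFT) and
    normalised so ACF(0) = 1.  The ACF of an N-fold ring is periodic
    with period 2*pi/N.
    """
    if radial_band is None:
        mask = _ring_band(pm)
    elif isinstance(radial_band, tuple):
        lo, hi = radial_band
        mask = (pm.radii_px >= lo) & (pm.radii_px <= hi)
    else:
        mask = np.asarray(radial_band, dtype=bool)
    if not mask.any():
        raise ValueError("empty radial band")
    prof = pm.values[mask].mean(axis=0)
    prof = prof - prof.mean()
    var = np.dot(prof, prof)
    if var == 0:
        raise ValueError("zero-variance angular profile in the band")
    f = np.fft.rfft(prof)
    acf = np.fft.irfft(np.abs(f) ** 2, n=prof.size)
    return acf / acf[0]


def symmetry_spectrum(
    acf: np.ndarray,
    n_max: int = 50,
    search_band: tuple[int, int] = DEFAULT_SEARCH_BAND,
) -> SymmetrySpectrum:
    """Fourier power of the ACF at integer harmonic orders 1..n_max.

    ``dominant_n`` is the argmax of the power inside ``search_band``
    (inclusive); the unrestricted argmax is reported as
    ``full_spectrum_n``.  The band (default 28-35, the range observed
    across these C rings) avoids confusing N with its harmonics 2N or
    N/2.  ``confidence`` is the ratio of the dominant power to the
    next-highest power in the band.
    """
    acf = np.asarray(acf, dtype=float)
    if acf.size < 2 * n_max:
        raise ValueError("ACF too short for the requested n_max")
    power = np.abs(np.fft.rfft(acf)) ** 2
    orders = np.arange(1, n_max + 1)
    p = power[1 : n_max + 1]
    lo, hi = search_band
    if not (1 <= lo <= hi <= n_max):
        raise ValueError("search band must lie within 1..n_max")
    band = slice(lo - 1, hi)
    band_p = p[band]
    dom = int(orders[band][np.argmax(band_p)])
    rest = np.sort(band_p)[::-1]
    conf = float(rest[0] / rest[1]) if rest.size > 1 and rest[1] > 0 else np.inf
    return SymmetrySpectrum(
        harmonic_orders=orders,
        power=p,
        dominant_n=dom,
        full_spectrum_n=int(orders[np.argmax(p)]),
        confidence=conf,
    )


def ring_diameter(
    pm: PolarMap,
    pixel_size_angstrom: float,
    radial_band: tuple[float, float] | None = None,
) -> float:
    """Ring diameter (Å): twice the radius of the peak of the
    rotationally averaged radial profile, refined to sub-pixel precision
    by three-point parabolic interpolation.

    ``radial_band`` restricts the search (e.g. to pick an inner ring out
    of a double-ring image).  A peak on the first or last radius is
    flagged as an error: the true maximum may lie outside the sampling.
    """
    prof = _radial_profile(pm)
    radii = pm.radii_px
    if radial_band is not None:
        lo, hi = radial_band
        sel = (radii >= lo) & (radii <= hi)
        if not sel.any():
            raise ValueError("empty radial band")
        prof, radii = prof[sel], radii[sel]
    i = _profile_peak_index(prof, radii)
    if i == 0 or i == prof.size - 1:
        raise ValueError("radial profile peaks at the boundary; widen the band")
    y0, y1, y2 = prof[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    step = radii[i + 1] - radii[i]
    r_peak = radii[i] + frac * step
    return float(2 * r_peak * pixel_size_angstrom)


def unit_repeat_distance(diameter_angstrom: float, symmetry_n: int) -> float:
    """Distance between adjacent subunits along the ring circumference,
    pi*D/N — e.g. 416 Å at C34 gives 38.4 Å."""
    if symmetry_n < 1:
        raise ValueError("symmetry must be >= 1")
    if diameter_angstrom <= 0:
        raise ValueError("diameter must be positive")
    return float(np.pi * diameter_angstrom / symmetry_n)


def analyze_ring(
    img: RingImage,
    n_angles: int = 720,
    search_band: tuple[int, int] = DEFAULT_SEARCH_BAND,
    center: tuple[float, float] | None = None,
) -> tuple[RingGeometry, SymmetrySpectrum]:
    """Full single-image pipeline: centre, polar map, ACF, symmetry,
    diameter, repeat distance."""
    if center is None:
        center = estimate_center(img)
    pm = polar_transform(img, center, n_angles=n_angles)
    acf = angular_autocorrelation(pm)
    spec = symmetry_spectrum(acf, search_band=search_band)
    D = ring_diameter(pm, img.pixel_size_angstrom)
    geo = RingGeometry(
        symmetry_n=spec.dominant_n,
        diameter_angstrom=D,
        repeat_distance_angstrom=unit_repeat_distance(D, spec.dominant_n),
    )
    return geo, spec


def _band_profile(img: RingImage, center, n_angles) -> np.ndarray:
    pm = polar_transform(img, center, n_angles=n_angles)
    mask = _ring_band(pm)
    prof = pm.values[mask].mean(axis=0)
    return prof - prof.mean()


def classify_population(
    images: list[RingImage],
    n_angles: int = 720,
    search_band: tuple[int, int] = DEFAULT_SEARCH_BAND,
) -> tuple[dict[int, int], dict[int, np.ndarray]]:
    """Assign each image its dominant symmetry, then rotationally align
    and average the members of each symmetry class.

    Alignment is in-plane rotation only: each image's band-averaged
    angular profile is circularly cross-correlated against the class
    reference (the first member) and the image rotated by the best
    shift; shifts are equivalent modulo 2*pi/N, so any global maximum
    aligns the subunit lattice.  Returns ``(counts, averages)`` keyed by
    symmetry order.
    """
    if not images:
        raise ValueError("no images")
    classes: dict[int, list[RingImage]] = {}
    for img in images:
        geo, _ = analyze_ring(img, n_angles=n_angles, search_band=search_band)
        classes.setdefault(geo.symmetry_n, []).append(img)
    counts = {n: len(v) for n, v in classes.items()}
    averages: dict[int, np.ndarray] = {}
    for n, members in classes.items():
        c0 = estimate_center(members[0])
        ref = _band_profile(members[0], c0, n_angles)
        ref_f = np.conj(np.fft.rfft(ref))
        acc = np.array(members[0].pixels, dtype=float)
        for img in members[1:]:
            c = estimate_center(img)
            prof = _band_profile(img, c, n_angles)
            xcorr = np.fft.irfft(np.fft.rfft(prof) * ref_f, n=n_angles)
            shift = int(np.argmax(xcorr))
            angle_deg = 360.0 * shift / n_angles
            # positive profile shift = image rotated by +angle vs reference
            acc += ndimage.rotate(img.pixels, angle_deg, reshape=False, order=1)
        averages[n] = acc / len(members)
    return counts, averages
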