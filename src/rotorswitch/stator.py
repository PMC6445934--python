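"""Resurrection analysis and speed stability.

When stator expression is induced in a stator-less motor, the rotation
rate climbs in discrete steps as MotA/MotB units dock one by one — a
"resurrection".  The speed histogram of such a trace is a comb of
equally spaced Gaussian peaks; fitting the comb yields the per-unit
speed increment, and dividing a motor's mean speed by that increment
counts its active stator units.  Speed stability is quantified as the
ratio of the standard deviation to the mean of the rotation rate,
sigma_omega / omega_av.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from .trace import SpeedTrace

__all__ = [
    "SpeedHistogram",
    "CombFit",
    "StatorEstimate",
    "SpeedStability",
    "CombFitError",
    "make_histogram",
    "fit_gaussian_comb",
    "estimate_stator_number",
    "speed_stability",
]


class CombFitError(ValueError):
    """The histogram does not support an increment fit (e.g. a single
    occupied cluster); the caller should fall back to the raw mean."""


@dataclass(frozen=True)
class SpeedHistogram:
    """Histogram of |speed| samples."""

    bin_edges_hz: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges_hz, dtype=float)
        counts = np.asarray(self.counts)
        if counts.size != edges.size - 1:
            raise ValueError("len(counts) must equal len(edges) - 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must increase")
        object.__setattr__(self, "bin_edges_hz", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers_hz(self) -> np.ndarray:
        return (self.bin_edges_hz[:-1] + self.bin_edges_hz[1:]) / 2


@dataclass(frozen=True)
class CombFit:
    """Fitted Gaussian comb: component k is centred at offset + k*increment
    with shared width sigma."""

    increment_hz: float
    offset_hz: float
    sigma_hz: float
    amplitudes: np.ndarray
    n_components: int
    fit_rss: float
    increment_stderr_hz: float | None = None

    def component_means_hz(self) -> np.ndarray:
        return self.offset_hz + self.increment_hz * np.arange(self.n_components)


@dataclass(frozen=True)
class StatorEstimate:
    mean_speed_hz: float
    unit_increment_hz: float
    n_units: int


@dataclass(frozen=True)
class SpeedStability:
    """Mean rotation rate omega_av, its SD sigma_omega, and their ratio."""

    omega_av_hz: float
    sigma_omega_hz: float
    ratio: float


def make_histogram(speed: SpeedTrace, bin_width_hz: float = 1.0) -> SpeedHistogram:
    """Histogram of |speed| with the given bin width, spanning the data."""
    if bin_width_hz <= 0:
        raise ValueError("bin width must be positive")
    v = np.abs(speed.speed_hz)
    if v.size == 0:
        raise ValueError("empty trace")
    lo = np.floor(v.min() / bin_width_hz) * bin_width_hz
    hi = np.ceil(v.max() / bin_width_hz) * bin_width_hz
    if hi <= lo:
        hi = lo + bin_width_hz
    edges = np.arange(lo, hi + bin_width_hz / 2, bin_width_hz)
    counts, _ = np.histogram(v, bins=edges)
    return SpeedHistogram(bin_edges_hz=edges, counts=counts)


def _occupied_clusters(hist: SpeedHistogram, rel_threshold: float = 0.05) -> list[tuple[int, int]]:
    """Contiguous groups of bins above rel_threshold * max count (gaps of
    one empty bin are bridged)."""
    thresh = max(1.0, rel_threshold * hist.counts.max())
    occ = hist.counts >= thresh
    clusters: list[tuple[int, int]] = []
    i = 0
    n = occ.size
    while i < n:
        if occ[i]:
            j = i
            while j + 1 < n and (occ[j + 1] or (j + 2 < n and occ[j + 2])):
                j += 1
            clusters.append((i, j))
            i = j + 1
        else:
            i += 1
    return clusters


def _acf_increment_init(hist: SpeedHistogram) -> float | None:
    """Initial increment guess: first dominant non-zero-lag peak of the
    count autocorrelation, in Hz."""
    c = hist.counts.astype(float) - hist.counts.mean()
    acf = np.correlate(c, c, mode="full")[c.size - 1 :]
    if acf.size < 3:
        return None
    # first local maximum after the lag-0 peak
    for lag in range(1, acf.size - 1):
        if acf[lag] > acf[lag - 1] and acf[lag] >= acf[lag + 1] and acf[lag] > 0:
            bw = float(np.median(np.diff(hist.bin_edges_hz)))
            return lag * bw
    return None


def comb_model(v: np.ndarray, offset: float, increment: float, sigma: float,
               amplitudes: np.ndarray) -> np.ndarray:
    """Evaluate the Gaussian comb sum_k A_k N(offset + k*increment, sigma)."""
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    for k, a in enumerate(np.asarray(amplitudes, dtype=float)):
        out += a * np.exp(-((v - offset - k * increment) ** 2) / (2 * sigma**2))
    return out


def fit_gaussian_comb(hist: SpeedHistogram, max_components: int = 12) -> CombFit:
    """Fit a shared-width, equal-spacing Gaussian comb to a speed histogram.

    The model is sum_k A_k exp(-(v - offset - k*Delta)^2 / 2 sigma^2)
    evaluated at bin centres, with A_k >= 0, shared sigma and spacing
    Delta enforced.  Delta is initialised from the dominant non-zero-lag
    peak of the count autocorrelation (falling back to the spacing of
    the two largest occupied clusters); a small grid of component counts
    up to ``max_components`` is tried and the fit with the lowest
    residual sum of squares wins.  The increment's standard error is
    taken from the fit covariance.

    Raises
    ------
    CombFitError
        If fewer than two occupied clusters make the spacing
        unidentifiable.
    """
    clusters = _occupied_clusters(hist)
    if len(clusters) < 2:
        raise CombFitError(
            "fewer than two occupied speed clusters: the unit increment is "
            "not identifiable; use the raw mean speed instead"
        )
    centers = hist.centers_hz
    counts = hist.counts.astype(float)
    bw = float(np.median(np.diff(hist.bin_edges_hz)))

    cluster_centers = []
    for i, j in clusters:
        seg = slice(i, j + 1)
        w = counts[seg]
        cluster_centers.append(float(np.average(centers[seg], weights=w)))
    cluster_centers = np.sort(cluster_centers)

    # candidate spacings: the ACF lag can lock onto a multiple of the true
    # increment when an intermediate level is sparsely occupied, so the
    # smallest cluster gap (and half the ACF lag) are fitted as well and the
    # lowest-residual comb wins
    min_gap = float(np.min(np.diff(cluster_centers)))
    candidates = [min_gap]
    acf_lag = _acf_increment_init(hist)
    if acf_lag is not None and acf_lag > 0:
        candidates += [acf_lag, acf_lag / 2]
    deltas = sorted({round(d, 6) for d in candidates if d >= 2 * bw})
    if not deltas:
        deltas = [max(min_gap, 2 * bw)]
    sigma0 = max(bw, float(np.median([(j - i + 1) for i, j in clusters])) * bw / 4)

    n_lo = max(2, len(clusters))
    n_hi = max(max_components, n_lo)

    def _residual(params, n_comp):
        amps = np.array([params[f"a{k}"].value for k in range(n_comp)])
        model = comb_model(centers, params["offset"].value,
                           params["increment"].value, params["sigma"].value, amps)
        return model - counts

    best = None
    for delta0 in deltas:
        offset0 = float(
            cluster_centers[0] - delta0 * round(cluster_centers[0] / delta0)
        )
        span = centers[-1] - offset0
        # components past the histogram's end have no data support: their
        # amplitudes see no gradient and just sit at the initial value
        k_cap = int(np.floor(span / delta0)) + 1
        for n_comp in range(n_lo, min(n_hi, max(n_lo, k_cap)) + 1):
            params = Parameters()
            params.add("offset", value=offset0, min=-2 * delta0, max=centers[-1])
            params.add("increment", value=delta0, min=0.2 * delta0,
                       max=3 * delta0)
            # components must stay resolvable: a sigma comparable to the
            # spacing degenerates the comb into one broad Gaussian
            params.add("sigma", value=min(sigma0, delta0 / 2), min=bw / 10,
                       max=max(delta0, 2 * sigma0))
            for k in range(n_comp):
                # start each amplitude at the histogram height where the
                # component is predicted to sit
                mean_k = offset0 + k * delta0
                j = int(np.clip(np.argmin(np.abs(centers - mean_k)), 0,
                                counts.size - 1))
                a0 = max(counts[j], 0.05 * counts.max())
                # cap: an off-range component with a huge amplitude could
                # otherwise serve as a disguised background via its far tail
                params.add(f"a{k}", value=a0, min=0.0, max=2.0 * counts.max())
            try:
                res = lm_minimize(_residual, params, args=(n_comp,),
                                  method="leastsq")
            except Exception:
                continue
            rss = float(np.sum(res.residual**2))
            if best is None or rss < best[0] * (1 - 1e-9):
                best = (rss, n_comp, res)
    if best is None:
        raise CombFitError("comb fit failed to converge for any component count")
    rss, n_comp, res = best
    p = res.params
    increment = float(p["increment"].value)
    offset = float(p["offset"].value)
    amps = np.array([p[f"a{k}"].value for k in range(n_comp)])
    stderr = p["increment"].stderr
    stderr = float(stderr) if stderr is not None else None

    # a comb at delta/m fits at least as well as the true comb (the extra
    # components just go to ~zero), so collapse harmonics: if the occupied
    # components share an index stride g > 1, the physical spacing is g*delta
    # occupied = clearly above the ghost components a harmonic comb leaves
    # at ~zero; the level-0 peak can dwarf real peaks, so the threshold is
    # the Poisson noise floor, not a large fraction of the maximum
    means = offset + increment * np.arange(n_comp)
    in_range = (means >= hist.bin_edges_hz[0] - increment / 2) & (
        means <= hist.bin_edges_hz[-1] + increment / 2
    )
    occ = np.flatnonzero(
        in_range & (amps > max(0.01 * amps.max(), np.sqrt(counts.max())))
    )
    if occ.size >= 2:
        g = int(np.gcd.reduce(np.diff(occ)))
        if g > 1:
            k0 = int(occ[0] % g)
            offset += k0 * increment
            new_n = (n_comp - 1 - k0) // g + 1
            amps = amps[k0::g][:new_n]
            increment *= g
            if stderr is not None:
                stderr *= g
            n_comp = amps.size

    return CombFit(
        increment_hz=increment,
        offset_hz=offset,
        sigma_hz=float(p["sigma"].value),
        amplitudes=amps,
        n_components=n_comp,
        fit_rss=rss,
        increment_stderr_hz=stderr,
    )


def estimate_stator_number(mean_speed_hz: float, increment_hz: float) -> StatorEstimate:
    """Active stator units = mean speed / unit increment, rounded.

    At high load each docked stator unit adds a fixed speed increment,
    so 71 Hz at 7.0 Hz/unit means about 10 active units.
    """
    if increment_hz <= 0:
        raise ValueError("increment must be positive")
    n = int(round(mean_speed_hz / increment_hz))
    return StatorEstimate(
        mean_speed_hz=float(mean_speed_hz),
        unit_increment_hz=float(increment_hz),
        n_units=n,
    )


def speed_stability(speed: SpeedTrace) -> SpeedStability:
    """sigma_omega / omega_av of |speed| (population SD, divisor n).

    Raises
    ------
    ValueError
        On fewer than 2 samples or zero mean speed.
    """
    v = np.abs(speed.speed_hz)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("mean speed is zero; stability ratio undefined")
    sd = float(v.std())
    return SpeedStability(omega_av_hz=mean, sigma_omega_hz=sd, ratio=sd / mean)
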