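"""Centre finding, polar transform, angular ACF, symmetry, diameter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rotorswitch import (
    RingImage,
    RingSimParams,
    analyze_ring,
    angular_autocorrelation,
    classify_population,
    estimate_center,
    generate_ring_image,
    polar_transform,
    ring_diameter,
    symmetry_spectrum,
    unit_repeat_distance,
)


def _ring(n=34, r=50.0, rot=0.0, noise=0.0, seed=0, size=128, offset=(0.0, 0.0),
          apix=1.69):
    return generate_ring_image(
        RingSimParams(symmetry_n=n, ring_radius_px=r, blob_sigma_px=2.0,
                      image_size_px=size, pixel_size_angstrom=apix,
                      noise_sd=noise, global_rotation_deg=rot,
                      center_offset_px=offset, seed=seed)
    )


class TestCenter:
    def test_centered_ring(self):
        img = _ring()
        cx, cy = estimate_center(img)
        c = (128 - 1) / 2
        assert abs(cx - c) < 0.5 and abs(cy - c) < 0.5

    def test_offset_recovered(self):
        img = _ring(offset=(3.0, -2.0))
        cx, cy = estimate_center(img)
        tx, ty = img.center_px
        assert abs(cx - tx) < 0.5 and abs(cy - ty) < 0.5

    def test_translation_equivariance(self):
        base = _ring(size=160)
        shifted = RingImage(pixels=np.roll(base.pixels, (4, -3), axis=(0, 1)),
                            pixel_size_angstrom=base.pixel_size_angstrom)
        cx0, cy0 = estimate_center(base)
        cx1, cy1 = estimate_center(shifted)
        assert cx1 - cx0 == pytest.approx(-3.0, abs=0.5)  # roll axis 1 = x
        assert cy1 - cy0 == pytest.approx(4.0, abs=0.5)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            estimate_center(RingImage(pixels=np.ones((64, 64)),
                                      pixel_size_angstrom=1.0))


class TestPolarTransform:
    def test_uniform_disk_rows_constant(self):
        size = 96
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        disk = (np.hypot(xx - c, yy - c) < 40).astype(float)
        img = RingImage(pixels=disk, pixel_size_angstrom=1.0)
        pm = polar_transform(img, (c, c), radii_px=np.arange(2.0, 35.0))
        assert np.all(np.ptp(pm.values, axis=1) < 1e-6)

    def test_rotation_cyclically_shifts_map(self):
        n_ang = 720
        a = _ring(rot=0.0)
        b = _ring(rot=10.0)  # 10 deg = 20 angle samples at 0.5 deg
        pa = polar_transform(a, a.center_px, n_angles=n_ang)
        pb = polar_transform(b, b.center_px, n_angles=n_ang)
        row = np.argmin(np.abs(pa.radii_px - 50.0))
        shifted = np.roll(pa.values[row], 20)
        # bilinear resampling of a sigma=2 px blob is good to a few percent
        assert np.allclose(pb.values[row], shifted, atol=0.05)

    def test_peak_count_at_ring_radius(self):
        from scipy.signal import find_peaks

        img = _ring(n=34, noise=0.0)
        pm = polar_transform(img, img.center_px)
        row = pm.values[np.argmin(np.abs(pm.radii_px - 50.0))]
        # tile to handle the circular wrap; prominence filters ties from
        # interpolation plateaus
        peaks, _ = find_peaks(np.tile(row, 2), prominence=0.05)
        n_peaks = np.sum((peaks >= row.size) & (peaks < 2 * row.size))
        assert n_peaks == 34

    def test_radii_beyond_frame_rejected(self):
        img = _ring()
        with pytest.raises(ValueError, match="beyond"):
            polar_transform(img, img.center_px, radii_px=np.array([100.0]))


class TestAutocorrelation:
    def test_normalised_and_symmetric(self):
        img = _ring(n=31, noise=0.3, seed=5)
        pm = polar_transform(img, img.center_px)
        acf = angular_autocorrelation(pm)
        assert acf[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(acf[1:], acf[1:][::-1], atol=1e-10)

    def test_period_of_perfect_ring(self):
        img = _ring(n=30, noise=0.0)
        pm = polar_transform(img, img.center_px, n_angles=720)
        acf = angular_autocorrelation(pm)
        lag = 720 // 30
        assert acf[lag] == pytest.approx(1.0, abs=0.01)

    def test_white_noise_acf_small(self):
        # at 720 samples the angular step (~0.4 px of arc at this radius) is
        # finer than a pixel, so bilinear interpolation correlates the first
        # couple of lags even for white noise; beyond that (and before the
        # mirrored circular tail) the ACF shows no structure.  Monte-Carlo
        # over a few fields bounds the worst lag.
        c = (128 - 1) / 2
        maxima = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            img = RingImage(pixels=rng.normal(0, 1, (128, 128)),
                            pixel_size_angstrom=1.0)
            pm = polar_transform(img, (c, c), n_angles=720)
            acf = angular_autocorrelation(pm, radial_band=(40.0, 60.0))
            maxima.append(np.max(np.abs(acf[3:-2])))
        assert np.mean(maxima) < 0.2

    def test_zero_variance_band_rejected(self):
        img = RingImage(pixels=np.zeros((64, 64)), pixel_size_angstrom=1.0)
        img2 = RingImage(pixels=img.pixels.copy(), pixel_size_angstrom=1.0)
        img2.pixels[32, 32] = 1.0  # centre spike, annulus stays flat
        pm = polar_transform(img2, (31.5, 31.5), radii_px=np.arange(10.0, 25.0))
        with pytest.raises(ValueError, match="zero-variance"):
            angular_autocorrelation(pm, radial_band=(15.0, 20.0))


class TestSymmetrySpectrum:
    @pytest.mark.parametrize("n", [31, 34])
    def test_perfect_ring_detected(self, n):
        geo, spec = analyze_ring(_ring(n=n))
        assert geo.symmetry_n == n
        assert spec.full_spectrum_n == n

    def test_acf_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            symmetry_spectrum(np.ones(60), n_max=50)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(13)
        for rot in rng.uniform(0, 360, 25):
            geo, _ = analyze_ring(_ring(n=33, rot=float(rot)))
            assert geo.symmetry_n == 33


class TestDiameter:
    def test_round_trip_358_angstrom(self):
        # radius 106 px at 1.69 A/px: diameter 2*106*1.69 = 358.3 A
        img = _ring(n=31, r=106.0, size=256, apix=1.69)
        pm = polar_transform(img, img.center_px)
        d = ring_diameter(pm, img.pixel_size_angstrom)
        assert d == pytest.approx(358.28, rel=0.01)

    def test_pixel_size_scaling(self):
        img = _ring(n=31)
        pm = polar_transform(img, img.center_px)
        d1 = ring_diameter(pm, 1.0)
        d2 = ring_diameter(pm, 2.35)
        assert d2 == pytest.approx(2.35 * d1, rel=1e-12)

    def test_unbiased_across_radii(self):
        for r in (80.0, 90.0, 100.0, 110.0, 120.0):
            img = _ring(n=34, r=r, size=288, apix=1.0)
            pm = polar_transform(img, img.center_px)
            d = ring_diameter(pm, 1.0)
            assert abs(d / 2 - r) < 0.5

    def test_double_ring_band_selection(self):
        inner = _ring(n=20, r=30.0, size=192, apix=1.0)
        outer = _ring(n=34, r=70.0, size=192, apix=1.0)
        both = RingImage(pixels=0.6 * inner.pixels + 1.0 * outer.pixels,
                         pixel_size_angstrom=1.0)
        c = both.pixels.shape[0]
        pm = polar_transform(both, ((c - 1) / 2, (c - 1) / 2))
        assert ring_diameter(pm, 1.0) == pytest.approx(140.0, abs=1.5)
        assert ring_diameter(pm, 1.0, radial_band=(15.0, 45.0)) == pytest.approx(
            60.0, abs=1.5
        )

    def test_boundary_peak_flagged(self):
        img = _ring(n=34, r=50.0)
        pm = polar_transform(img, img.center_px, radii_px=np.arange(10.0, 50.5))
        with pytest.raises(ValueError, match="boundary"):
            ring_diameter(pm, 1.0)


class TestRepeatDistance:
    @pytest.mark.parametrize(
        ("d", "n", "expect"),
        [(416.0, 34, 38.4), (407.0, 34, 37.6), (358.0, 31, 36.3), (372.0, 31, 37.7)],
    )
    def test_printed_values(self, d, n, expect):
        assert round(unit_repeat_distance(d, n), 1) == expect

    @given(d=st.floats(100.0, 600.0), n=st.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identity(self, d, n):
        assert unit_repeat_distance(d, n) * n == pytest.approx(np.pi * d, rel=1e-12)


class TestClassification:
    def test_mixed_population_counts(self):
        imgs = [_ring(n=34, rot=20.0 * i, seed=i) for i in range(4)]
        imgs += [_ring(n=31, rot=15.0 * i, seed=10 + i) for i in range(3)]
        counts, _ = classify_population(imgs)
        assert counts == {34: 4, 31: 3}

    def test_single_image_average_is_input(self):
        img = _ring(n=34)
        counts, avgs = classify_population([img])
        assert counts == {34: 1}
        assert np.allclose(avgs[34], img.pixels)

    def test_average_sharper_than_members(self):
        rng = np.random.default_rng(1)
        imgs = [_ring(n=34, rot=float(rng.uniform(0, 360)), noise=0.4, seed=i)
                for i in range(10)]
        counts, avgs = classify_population(imgs)
        assert counts == {34: 10}

        def rel_power(pixels):
            im = RingImage(pixels=pixels, pixel_size_angstrom=1.0)
            pm = polar_transform(im, estimate_center(im))
            spec = symmetry_spectrum(angular_autocorrelation(pm))
            return spec.power[33] / spec.power.sum()

        assert rel_power(avgs[34]) > max(rel_power(i.pixels) for i in imgs)
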