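"""Ground-truth behaviour of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from rotorswitch import (
    BeadSimParams,
    ResurrectionSimParams,
    RingSimParams,
    SwitchSimParams,
    fit_rotation_center,
    generate_ring_image,
    simulate_bead_positions,
    simulate_resurrection,
    simulate_switching_speed,
)


class TestSwitchingSimulator:
    def test_absorbing_ccw(self):
        sim = simulate_switching_speed(
            SwitchSimParams(k_ccw_to_cw=0.0, k_cw_to_ccw=0.5,
                            initial_state="CCW", speed_noise_sd_hz=0.0, seed=0)
        )
        assert np.all(sim.trace.speed_hz > 0)
        assert sim.true_cw_fraction == 0.0

    def test_absorbing_cw(self):
        sim = simulate_switching_speed(
            SwitchSimParams(k_cw_to_ccw=0.0, initial_state="CW",
                            speed_noise_sd_hz=0.0, seed=0)
        )
        assert np.all(sim.trace.speed_hz < 0)
        assert sim.true_cw_fraction == 1.0

    def test_stationary_cw_fraction(self):
        # symmetric rates: stationary CW occupancy is k1/(k1+k2) = 0.5;
        # SE of the time-averaged fraction over T with rate k each way is
        # roughly sqrt(2/(k_total*T))/2
        k = 0.5
        sim = simulate_switching_speed(
            SwitchSimParams(k_ccw_to_cw=k, k_cw_to_ccw=k, duration_s=300.0,
                            initial_state="stationary", seed=11)
        )
        se = 0.5 * np.sqrt(2.0 / (2 * k * 300.0))
        assert abs(sim.true_cw_fraction - 0.5) < 3 * se

    def test_dwell_times_exponential(self):
        # pooled CCW dwells against the generating exponential (KS, alpha=0.01)
        k = 2.0
        dwells = []
        seed = 0
        while len(dwells) < 10_000:
            sim = simulate_switching_speed(
                SwitchSimParams(k_ccw_to_cw=k, k_cw_to_ccw=k, duration_s=2000.0,
                                frame_rate_hz=1.0, seed=seed)
            )
            # censored final dwell excluded
            full = sim.dwell_durations_s[:-1]
            dwells.extend(full[sim.dwell_states[:-1] == "CCW"].tolist())
            seed += 1
        d = np.array(dwells[:10_000])
        p = stats.kstest(d, stats.expon(scale=1.0 / k).cdf).pvalue
        assert p > 0.01

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SwitchSimParams(k_ccw_to_cw=np.inf)
        with pytest.raises(ValueError):
            SwitchSimParams(duration_s=0.001, frame_rate_hz=100.0)


class TestBeadSimulator:
    def test_one_revolution_closes(self, constant_speed):
        trace = constant_speed(1.0, duration_s=1.0, frame_rate_hz=100.0)
        traj = simulate_bead_positions(
            trace, BeadSimParams(rotation_radius_um=1.0, localization_noise_um=0.0)
        )
        # final angle 2*pi minus one frame; the closing point is one frame shy
        th = np.arctan2(traj.y_um, traj.x_um)
        assert th[0] == pytest.approx(0.0, abs=1e-12)
        total = 2 * np.pi * (traj.time_s[-1] - traj.time_s[0])
        assert np.hypot(traj.x_um - 1.0, traj.y_um)[0] == pytest.approx(0.0, abs=1e-12)
        assert np.unwrap(th)[-1] == pytest.approx(total, abs=1e-9)

    def test_zero_speed_static(self, constant_speed):
        trace = constant_speed(0.0, duration_s=0.5, frame_rate_hz=100.0)
        traj = simulate_bead_positions(
            trace, BeadSimParams(rotation_radius_um=0.5, localization_noise_um=0.0)
        )
        assert np.ptp(traj.x_um) == 0 and np.ptp(traj.y_um) == 0

    def test_noise_free_points_on_circle(self, constant_speed):
        trace = constant_speed(3.0, duration_s=1.0, frame_rate_hz=500.0)
        traj = simulate_bead_positions(
            trace,
            BeadSimParams(rotation_radius_um=0.25, localization_noise_um=0.0,
                          center_xy_um=(1.0, -1.0)),
        )
        r = np.hypot(traj.x_um - 1.0, traj.y_um + 1.0)
        assert np.allclose(r, 0.25, atol=1e-12)

    def test_round_trip_radius_recovery(self, constant_speed):
        trace = constant_speed(5.0, duration_s=2.0, frame_rate_hz=500.0)
        traj = simulate_bead_positions(
            trace,
            BeadSimParams(rotation_radius_um=0.3, localization_noise_um=0.01),
            seed=7,
        )
        fit = fit_rotation_center(traj)
        assert fit.rotation_radius_um == pytest.approx(0.3, rel=0.02)


class TestResurrectionSimulator:
    def test_no_recruitment_zero_speed(self):
        sim = simulate_resurrection(
            ResurrectionSimParams(recruitment_rate_per_s=0.0,
                                  speed_noise_sd_hz=0.0, duration_s=10.0,
                                  frame_rate_hz=100.0)
        )
        assert np.all(sim.trace.speed_hz == 0)
        assert np.all(sim.unit_count == 0)

    def test_noiseless_terminal_speed(self):
        # drive recruitment fast enough that the cap is always reached
        sim = simulate_resurrection(
            ResurrectionSimParams(unit_increment_hz=7.0, max_units=3,
                                  recruitment_rate_per_s=5.0,
                                  speed_noise_sd_hz=0.0, duration_s=60.0,
                                  frame_rate_hz=100.0, seed=1)
        )
        assert sim.unit_count[-1] == 3
        assert sim.trace.speed_hz[-1] == pytest.approx(21.0, abs=1e-12)

    def test_unit_count_monotone_and_capped(self):
        sim = simulate_resurrection(
            ResurrectionSimParams(max_units=5, recruitment_rate_per_s=0.5,
                                  duration_s=60.0, frame_rate_hz=100.0, seed=4)
        )
        assert np.all(np.diff(sim.unit_count) >= 0)
        assert sim.unit_count.max() <= 5

    def test_max_units_cap_validated(self):
        with pytest.raises(ValueError):
            ResurrectionSimParams(max_units=20)


class TestRingGenerator:
    def test_symmetry_rotation_invariance_by_construction(self):
        base = dict(symmetry_n=34, ring_radius_px=50.0, blob_sigma_px=2.0,
                    image_size_px=128, noise_sd=0.0)
        a = generate_ring_image(RingSimParams(**base, global_rotation_deg=0.0))
        b = generate_ring_image(RingSimParams(**base,
                                              global_rotation_deg=360.0 / 34))
        assert np.allclose(a.pixels, b.pixels, atol=1e-10)

    def test_c2_two_antipodal_blobs(self):
        img = generate_ring_image(
            RingSimParams(symmetry_n=2, ring_radius_px=30.0, blob_sigma_px=2.0,
                          image_size_px=96, noise_sd=0.0)
        )
        c = (96 - 1) / 2
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert np.hypot(ix - c, iy - c) == pytest.approx(30.0, abs=1.0)
        # the antipode is equally bright
        jy, jx = int(round(2 * c - iy)), int(round(2 * c - ix))
        assert img.pixels[jy, jx] == pytest.approx(img.pixels[iy, ix], rel=0.05)

    def test_harmonic_power_dominates_at_n(self):
        from rotorswitch import angular_autocorrelation, polar_transform, symmetry_spectrum

        img = generate_ring_image(
            RingSimParams(symmetry_n=23, ring_radius_px=45.0, image_size_px=128,
                          noise_sd=0.0)
        )
        pm = polar_transform(img, img.center_px)
        spec = symmetry_spectrum(angular_autocorrelation(pm), search_band=(2, 50))
        assert spec.dominant_n == 23
        others = np.delete(spec.power, 23 - 1)
        assert spec.power[23 - 1] > others.max()

    def test_blobs_must_fit_in_frame(self):
        with pytest.raises(ValueError, match="frame"):
            RingSimParams(ring_radius_px=60.0, blob_sigma_px=3.0, image_size_px=128)
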