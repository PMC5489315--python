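import numpy as np
import pytest

from tiltframe.imu import (
    GRAVITY,
    KinematicSeries,
    band_power_fractions,
    band_fraction_of_channel,
    decompose_acceleration,
    estimate_orientation,
    kinematic_derivatives,
    rotate_to_earth_frame,
    rotation_induced_accelerations,
)


def make_kin(omega, acc, fs=250.0):
    n = len(omega)
    return KinematicSeries(t=np.arange(n) / fs, omega=np.asarray(omega, float),
                           acc=np.asarray(acc, float), sample_rate=fs)


class TestEstimateOrientation:
    def test_static_identity(self):
        n = 500
        kin = make_kin(np.zeros((n, 3)), np.tile([0.0, 0.0, 1.0], (n, 1)))
        orient = estimate_orientation(kin)
        assert np.allclose(orient.gravity_head, [0, 0, 1], atol=1e-9)
        assert np.allclose(orient.nongrav_head, 0.0, atol=1e-9)

    def test_constant_roll_90deg(self):
        # 90° roll about +x at 90°/s, noiseless gyro; gravity ends at +y
        fs = 250.0
        n = int(fs) + 1
        omega = np.zeros((n, 3))
        omega[:, 0] = 90.0
        # accelerometer follows true gravity (no lever arm)
        angles = np.deg2rad(90.0 * np.arange(n) / fs)
        acc = np.column_stack([np.zeros(n), np.sin(angles), np.cos(angles)])
        kin = make_kin(omega, acc, fs)
        orient = estimate_orientation(kin, correction_gain=0.0,
                                      q0=np.array([1.0, 0, 0, 0]))
        final = orient.gravity_head[-1]
        err = np.degrees(np.arccos(np.clip(final @ np.array([0.0, 1.0, 0.0]), -1, 1)))
        assert err < 1.0

    def test_gain_one_snaps_to_accelerometer(self):
        rng = np.random.default_rng(0)
        n = 200
        acc = rng.standard_normal((n, 3)) * 0.1 + [0, 0, 1]
        kin = make_kin(rng.standard_normal((n, 3)) * 10, acc)
        orient = estimate_orientation(kin, correction_gain=1.0)
        acc_dir = acc / np.linalg.norm(acc, axis=1, keepdims=True)
        assert np.allclose(orient.gravity_head, acc_dir, atol=1e-8)

    def test_gain_zero_is_pure_gyro(self):
        rng = np.random.default_rng(1)
        n = 300
        omega = rng.standard_normal((n, 3)) * 30
        acc = np.tile([0.0, 0.0, 1.0], (n, 1))
        kin = make_kin(omega, acc)
        q0 = np.array([1.0, 0, 0, 0])
        o0 = estimate_orientation(kin, correction_gain=0.0, q0=q0)
        from tiltframe import quaternions as qt

        q_pure = qt.integrate_body_rates(np.deg2rad(omega), 1 / 250.0, q0)
        assert np.allclose(np.abs(np.sum(o0.q_es * q_pure, axis=1)), 1.0, atol=1e-9)

    def test_synthetic_gravity_error_small(self, short_session):
        kin, truth, orient = short_session
        cosang = np.clip(np.sum(orient.gravity_head * truth.gravity_head, axis=1), -1, 1)
        err = np.degrees(np.arccos(cosang))
        assert np.median(err) < 3.0

    def test_rejects_bad_input(self):
        kin = make_kin(np.zeros((10, 3)), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            estimate_orientation(kin, correction_gain=2.0)
        with pytest.raises(ValueError):
            KinematicSeries(t=np.array([0.0, 0.1, 0.15]), omega=np.zeros((3, 3)),
                            acc=np.zeros((3, 3)), sample_rate=10.0)


class TestDecomposition:
    def test_identity_and_norms(self, short_session):
        kin, truth, orient = short_session
        a_g, a_ng = decompose_acceleration(kin, orient)
        # additive decomposition holds to machine precision (one rounding step)
        assert np.abs((a_g + a_ng) - kin.acc).max() < 1e-14
        assert np.abs(np.linalg.norm(a_g, axis=1) - 1.0).max() < 1e-9

    def test_static_nongrav_at_noise_level(self):
        rng = np.random.default_rng(2)
        n = 2000
        acc = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.standard_normal((n, 3)) * 0.01
        kin = make_kin(np.zeros((n, 3)), acc)
        orient = estimate_orientation(kin)
        rms = np.sqrt(np.mean(orient.nongrav_head ** 2))
        assert rms < 0.012

    def test_pitch_oscillation_ag_xz_covary(self):
        # pitch oscillation around a 45° nose-down posture: a^G_x and a^G_z co-vary
        fs = 250.0
        t = np.arange(int(20 * fs)) / fs
        theta = np.deg2rad(45.0 + 20.0 * np.sin(2 * np.pi * 0.5 * t))
        theta_dot = np.gradient(theta, 1 / fs)
        omega = np.column_stack([np.zeros_like(t), np.degrees(theta_dot), np.zeros_like(t)])
        acc = np.column_stack([-np.sin(theta), np.zeros_like(t), np.cos(theta)])
        kin = make_kin(omega, acc, fs)
        orient = estimate_orientation(kin)
        a_g, _ = decompose_acceleration(kin, orient)
        r = np.corrcoef(a_g[:, 0], a_g[:, 2])[0, 1]
        assert r > 0.9

    def test_low_frequency_dominance(self, short_session):
        kin, truth, orient = short_session
        summary = band_power_fractions(kin, orient, bands=[(0.0, 2.0), (2.0, 20.0)])
        df = summary.band_fractions
        low = df[df.band_lo == 0.0].iloc[0]
        high = df[df.band_lo == 2.0].iloc[0]
        assert low.gravitational > 0.9
        assert high.gravitational < 0.5


class TestRotateToEarth:
    def test_identity(self, short_session):
        kin, truth, orient = short_session
        from tiltframe.imu import OrientationSeries

        n = 100
        ident = OrientationSeries(
            q_es=np.tile([1.0, 0, 0, 0], (n, 1)),
            gravity_head=np.tile([0.0, 0, 1], (n, 1)),
            nongrav_head=np.zeros((n, 3)),
        )
        v = np.random.default_rng(3).standard_normal((n, 3))
        assert np.allclose(rotate_to_earth_frame(v, ident), v)

    def test_rolled_90deg_yaw_maps_to_minus_y(self):
        from tiltframe import quaternions as qt
        from tiltframe.imu import OrientationSeries

        q = qt.qexp(np.array([np.pi / 2, 0.0, 0.0]))  # roll +90° about x
        orient = OrientationSeries(q_es=q[None, :], gravity_head=np.array([[0.0, 1, 0]]),
                                   nongrav_head=np.zeros((1, 3)))
        out = rotate_to_earth_frame(np.array([[0.0, 0.0, 100.0]]), orient)
        assert np.allclose(out, [[0.0, -100.0, 0.0]], atol=1e-9)

    def test_norm_preserved(self, short_session):
        kin, truth, orient = short_session
        out = rotate_to_earth_frame(kin.omega, orient)
        assert np.allclose(np.linalg.norm(out, axis=1),
                           np.linalg.norm(kin.omega, axis=1), atol=1e-9)

    def test_earth_vertical_spin_constant_under_tilt_wobble(self):
        """ω_z^earth of a pure earth-vertical spin is untouched by tilt wobble."""
        from tiltframe import quaternions as qt
        from tiltframe.imu import OrientationSeries

        fs = 250.0
        n = int(10 * fs)
        dt = 1 / fs
        rng = np.random.default_rng(4)
        # earth-frame angular velocity: constant spin about earth-z + wobble in xy
        omega_earth = np.column_stack([
            30 * np.sin(2 * np.pi * 0.7 * np.arange(n) * dt),
            30 * np.cos(2 * np.pi * 1.1 * np.arange(n) * dt),
            np.full(n, 60.0),
        ])
        # integrate orientation using head-frame rates R^T omega_earth
        q = np.empty((n, 4))
        q[0] = [1.0, 0, 0, 0]
        for k in range(n - 1):
            R = qt.rotmats(q[k])[0]
            w_head = R.T @ np.deg2rad(omega_earth[k])
            q[k + 1] = qt.qmult(q[k], qt.qexp(w_head * dt))
            q[k + 1] /= np.linalg.norm(q[k + 1])
        omega_head = np.einsum("nij,nj->ni", np.transpose(qt.rotmats(q), (0, 2, 1)),
                               omega_earth)
        orient = OrientationSeries(q_es=q, gravity_head=np.zeros((n, 3)),
                                   nongrav_head=np.zeros((n, 3)))
        back = rotate_to_earth_frame(omega_head, orient)
        assert np.abs(back[:, 2] - 60.0).max() < 1e-6


class TestSpectra:
    def test_pure_sinusoid_concentration(self):
        fs = 250.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        fracs = band_fraction_of_channel(x, fs, [(0.0, 2.0), (2.0, 20.0)])
        assert fracs[1] > 0.99

    def test_white_noise_proportional_to_bandwidth(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(250 * 120)
        fracs = band_fraction_of_channel(x, 250.0, [(0.0, 25.0), (25.0, 125.0)])
        assert abs(fracs[0] / 0.2 - 1.0) < 0.1
        assert abs(fracs[1] / 0.8 - 1.0) < 0.1

    def test_dc_series_in_lowest_band(self):
        x = np.full(1000, 3.0)
        fracs = band_fraction_of_channel(x, 250.0, [(0.0, 2.0), (2.0, 20.0)])
        assert fracs[0] > 0.999

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_fraction_of_channel(np.zeros(1000), 250.0, [(0.0, 200.0)])


class TestLeverArm:
    def test_constant_spin_centripetal_closed_form(self):
        n = 1000
        omega = np.tile([0.0, 0.0, 100.0], (n, 1))
        a_lt, a_cp = rotation_induced_accelerations(omega, [0.02, 0.0, 0.0], 250.0)
        w = np.deg2rad(100.0)
        expected = w * w * 0.02 / GRAVITY
        assert np.allclose(np.linalg.norm(a_cp, axis=1), expected, rtol=1e-9)
        assert np.allclose(a_lt, 0.0, atol=1e-12)

    def test_zero_omega(self):
        a_lt, a_cp = rotation_induced_accelerations(np.zeros((100, 3)), [0.02, 0, 0], 250.0)
        assert np.allclose(a_lt, 0.0)
        assert np.allclose(a_cp, 0.0)

    def test_predicted_pattern_matches_generated_nongrav(self):
        """Cross-correlation of ω with A^nG mirrors ω with predicted lever-arm accel."""
        from tiltframe.synthetic import SimulationConfig, simulate_head_kinematics

        cfg = SimulationConfig(duration=120.0, seed=17, accel_noise_sd=0.0,
                               gyro_noise_sd=0.0)
        kin, truth = simulate_head_kinematics(cfg)
        a_ng_true = kin.acc - truth.gravity_head
        a_lt, a_cp = rotation_induced_accelerations(kin.omega, cfg.lever_arm,
                                                    kin.sample_rate)
        pred = a_lt + a_cp
        for axis_o in range(3):
            for axis_a in range(3):
                r_true = np.corrcoef(kin.omega[:, axis_o], a_ng_true[:, axis_a])[0, 1]
                r_pred = np.corrcoef(kin.omega[:, axis_o], pred[:, axis_a])[0, 1]
                assert abs(r_true - r_pred) < 0.15


class TestDerivatives:
    def test_linear_ramp(self, short_session):
        kin, truth, orient = short_session
        fs = 250.0
        n = 1000
        k = 7.5
        omega = np.zeros((n, 3))
        omega[:, 2] = k * np.arange(n) / fs
        kin2 = make_kin(omega, np.tile([0.0, 0, 1], (n, 1)), fs)
        orient2 = estimate_orientation(kin2, correction_gain=1.0)
        der = kinematic_derivatives(kin2, orient2)
        assert np.allclose(der.omega_dot[:, 2], k, atol=1e-6)

    def test_constant_gravity_zero_jerk(self):
        n = 1000
        kin2 = make_kin(np.zeros((n, 3)), np.tile([0.0, 0, 1], (n, 1)))
        orient2 = estimate_orientation(kin2)
        der = kinematic_derivatives(kin2, orient2)
        assert np.allclose(der.gravity_jerk, 0.0, atol=1e-9)

    def test_sinusoid_derivative_amplitude(self):
        fs = 250.0
        f, A = 2.0, 40.0
        t = np.arange(int(40 * fs)) / fs
        omega = np.zeros((len(t), 3))
        omega[:, 1] = A * np.sin(2 * np.pi * f * t)
        kin2 = make_kin(omega, np.tile([0.0, 0, 1], (len(t), 1)), fs)
        orient2 = estimate_orientation(kin2, correction_gain=0.0,
                                       q0=np.array([1.0, 0, 0, 0]))
        der = kinematic_derivatives(kin2, orient2)
        peak = np.abs(der.omega_dot[100:-100, 1]).max()
        assert abs(peak / (2 * np.pi * f * A) - 1.0) < 0.01

    def test_too_short_rejected(self):
        kin2 = make_kin(np.zeros((2, 3)), np.tile([0.0, 0, 1], (2, 1)))
        orient2 = estimate_orientation(kin2)
        with pytest.raises(ValueError):
            kinematic_derivatives(kin2, orient2)
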