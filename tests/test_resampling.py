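import numpy as np
import pytest

from tiltframe import resampling as rs
from tiltframe.spiking import instantaneous_rate
from tiltframe.synthetic import GateSpec, SimulationConfig, TuningSpec, planted_rate, simulate_head_kinematics, simulate_unit


def brute_force_rho(query_X, query_t, ref_X, ref_fr, ref_t, d, w, min_neighbors,
                    scale, lag=0.0, fs=250.0, same_recording=True):
    """O(n²) all-pairs oracle for the resampling estimator."""
    shift = int(round(lag * fs))
    q = np.asarray(query_X, float) / scale
    r = np.asarray(ref_X, float) / scale
    rho = np.full(len(q), np.nan)
    for i in range(len(q)):
        dist = np.linalg.norm(r - q[i], axis=1)
        mask = dist <= d
        if same_recording:
            mask &= np.abs(ref_t - query_t[i]) > w
        js = np.flatnonzero(mask)
        js = js[(js + shift >= 0) & (js + shift < len(ref_fr))]
        if len(js) >= min_neighbors:
            rho[i] = ref_fr[js + shift].mean()
    return rho


@pytest.fixture(scope="module")
def tuned_session():
    kin, truth = simulate_head_kinematics(SimulationConfig(duration=600.0, seed=21))
    spec = TuningSpec(kind="rotation_head_frame", baseline_rate=45.0, gain=0.5,
                      preferred_axis=(0.0, 0.0, 1.0), isi_cv=0.5)
    spikes = simulate_unit(kin, truth, spec, seed=5)
    fr = instantaneous_rate(spikes, kin.t)
    return kin, truth, spec, spikes, fr


class TestEstimateRate:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        n = 2000
        fs = 250.0
        t = np.arange(n) / fs
        X = rng.standard_normal((n, 3)).cumsum(axis=0)  # correlated walk
        fr = rng.gamma(2.0, 20.0, n)
        scale = X.std(axis=0)
        d = 0.3
        space = rs.ParameterSpace(channels=["omega_x", "omega_y", "omega_z"],
                                  neighbor_radius=d, exclusion_window=1.0,
                                  min_neighbors=10, normalization=scale)
        est = rs.estimate_rate(X, t, X, fr, t, space, fs)
        expected = brute_force_rho(X, t, X, fr, t, d, 1.0, 10, scale, fs=fs)
        assert np.array_equal(np.isnan(est.rho), np.isnan(expected))
        ok = np.isfinite(expected)
        assert np.allclose(est.rho[ok], expected[ok], rtol=0, atol=1e-12)

    def test_constant_rate_rho_constant_r2_zero(self):
        rng = np.random.default_rng(1)
        n = 5000
        fs = 250.0
        t = np.arange(n) / fs
        X = rng.standard_normal((n, 3))
        fr = np.full(n, 40.0)
        space = rs.ParameterSpace(channels=["a", "b", "c"], neighbor_radius=1.0,
                                  min_neighbors=5, normalization=X.std(axis=0))
        est = rs.estimate_rate(X, t, X, fr, t, space, fs, query_fr=fr)
        ok = np.isfinite(est.rho)
        assert np.allclose(est.rho[ok], 40.0)
        assert est.r2 == 0.0 or np.isnan(est.r2)

    def test_rho_is_convex_combination(self):
        rng = np.random.default_rng(2)
        n = 3000
        t = np.arange(n) / 250.0
        X = rng.standard_normal((n, 2))
        fr = rng.uniform(0, 100, n)
        space = rs.ParameterSpace(channels=["a", "b"], neighbor_radius=0.5,
                                  min_neighbors=3, normalization=X.std(axis=0))
        est = rs.estimate_rate(X, t, X, fr, t, space, 250.0)
        ok = np.isfinite(est.rho)
        assert est.rho[ok].min() >= fr.min() - 1e-12
        assert est.rho[ok].max() <= fr.max() + 1e-12

    def test_tiny_radius_zero_coverage_no_crash(self):
        rng = np.random.default_rng(3)
        n = 1000
        t = np.arange(n) / 250.0
        X = rng.standard_normal((n, 3))
        fr = rng.uniform(0, 50, n)
        space = rs.ParameterSpace(channels=["a", "b", "c"], neighbor_radius=1e-9,
                                  min_neighbors=2, normalization=np.ones(3))
        est = rs.estimate_rate(X, t, X, fr, t, space, 250.0, query_fr=fr)
        assert est.coverage == 0.0
        assert np.isnan(est.r2)

    def test_exclusion_window_blocks_self_prediction(self):
        """On a white-noise rate, w=0/d→0 degenerates toward self-prediction."""
        rng = np.random.default_rng(4)
        n = 20000
        fs = 250.0
        t = np.arange(n) / fs
        # temporally correlated parameters: temporal neighbors are spatial ones
        from scipy.ndimage import uniform_filter1d

        X = uniform_filter1d(rng.standard_normal((n, 3)), 100, axis=0)
        # movement-independent rate with temporal structure (piecewise 1/ISI)
        spikes = np.cumsum(rng.exponential(1 / 20.0, 3000))
        fr = instantaneous_rate(spikes[spikes < t[-1]], t)
        scale = X.std(axis=0)
        r2 = {}
        for w in (0.0, 1.0):
            space = rs.ParameterSpace(channels=["a", "b", "c"], neighbor_radius=0.15,
                                      exclusion_window=w, min_neighbors=1,
                                      normalization=scale)
            est = rs.estimate_rate(X, t, X, fr, t, space, fs, query_fr=fr)
            r2[w] = est.r2
        # w=0 keeps the self-sample in tiny neighborhoods -> spurious skill
        assert r2[1.0] < r2[0.0]

    def test_planted_functional_unit_noiseless(self):
        kin, truth = simulate_head_kinematics(SimulationConfig(duration=600.0, seed=22))
        spec = TuningSpec(kind="rotation_head_frame", baseline_rate=40.0, gain=0.3,
                          preferred_axis=(0.0, 0.0, 1.0))
        lam = planted_rate(kin, truth, spec)  # noiseless deterministic FR
        X = kin.omega
        scale = X.std(axis=0)
        d = rs.tune_radius(X / scale, 200)
        space = rs.ParameterSpace(channels=["ox", "oy", "oz"], neighbor_radius=d,
                                  normalization=scale)
        sel = slice(None, None, 10)
        est = rs.estimate_rate(X[sel], kin.t[sel], X, lam, kin.t, space, 250.0,
                               query_fr=lam[sel])
        assert est.r2 > 0.9


class TestIndependentEstimates:
    def test_tuned_unit_high_R(self, tuned_session):
        kin, truth, spec, spikes, fr = tuned_session
        X = kin.omega
        scale = X.std(axis=0)
        d = rs.tune_radius(X / scale, 200)
        space = rs.ParameterSpace(channels=list("xyz"), neighbor_radius=d,
                                  normalization=scale)
        R = rs.independent_estimate_correlation(X, fr, kin.t, space, 250.0,
                                                query_stride=8)
        assert R > 0.8

    def test_untuned_unit_near_zero(self):
        kin, truth = simulate_head_kinematics(SimulationConfig(duration=600.0, seed=23))
        spikes = simulate_unit(kin, truth,
                               TuningSpec(kind="untuned", baseline_rate=40.0, isi_cv=1.0),
                               seed=6)
        fr = instantaneous_rate(spikes, kin.t)
        X = kin.omega
        scale = X.std(axis=0)
        d = rs.tune_radius(X / scale, 200)
        space = rs.ParameterSpace(channels=list("xyz"), neighbor_radius=d,
                                  normalization=scale)
        R = rs.independent_estimate_correlation(X, fr, kin.t, space, 250.0,
                                                query_stride=8)
        assert abs(R) < 0.1

    def test_too_few_blocks_rejected(self):
        X = np.zeros((100, 3))
        t = np.arange(100) / 250.0
        space = rs.ParameterSpace(channels=list("xyz"), neighbor_radius=1.0)
        with pytest.raises(ValueError):
            rs.independent_estimate_correlation(X, np.zeros(100), t, space, 250.0)


class TestShuffleNull:
    def test_null_centered_and_deterministic(self, tuned_session):
        kin, truth, spec, spikes, fr = tuned_session
        X = kin.omega
        scale = X.std(axis=0)
        d = rs.tune_radius(X / scale, 200)
        space = rs.ParameterSpace(channels=list("xyz"), neighbor_radius=d,
                                  normalization=scale)
        null = rs.shuffle_null(spikes, X, kin.t, space, 250.0, n_iter=5, seed=9,
                               query_stride=16)
        assert abs(null.r_values.mean()) < 0.1
        null2 = rs.shuffle_null(spikes, X, kin.t, space, 250.0, n_iter=5, seed=9,
                                query_stride=16)
        assert np.array_equal(null.r_values, null2.r_values)
        # true R beats the null
        R = rs.independent_estimate_correlation(X, fr, kin.t, space, 250.0,
                                                query_stride=16)
        assert R > np.quantile(null.r_values, 0.975)

    def test_short_recording_rejected(self):
        space = rs.ParameterSpace(channels=list("xyz"), neighbor_radius=1.0)
        t = np.arange(1000) / 250.0  # 4 s < 2 * 10 s
        with pytest.raises(ValueError):
            rs.shuffle_null(np.array([1.0, 2.0]), np.zeros((1000, 3)), t, space,
                            250.0, n_iter=2, seed=0)


class TestTimeReversalControl:
    def test_reversed_train_loses_predictability(self, tuned_session):
        kin, truth, spec, spikes, fr = tuned_session
        T = kin.t[-1]
        rev = np.sort(T - spikes)
        fr_rev = instantaneous_rate(rev, kin.t)
        X = kin.omega
        scale = X.std(axis=0)
        d = rs.tune_radius(X / scale, 200)
        space = rs.ParameterSpace(channels=list("xyz"), neighbor_radius=d,
                                  normalization=scale)
        r2_fwd, _, _ = rs.best_lag_r2(X, fr, kin.t, space, 250.0,
                                      lag_grid=[0.0], query_stride=8)
        r2_rev, _, _ = rs.best_lag_r2(X, fr_rev, kin.t, space, 250.0,
                                      lag_grid=[0.0], query_stride=8)
        assert r2_fwd > 0.15
        assert r2_rev < 0.05


class TestSelectivityRule:
    @pytest.mark.parametrize(
        "r2_omega,r2_ag,label",
        [
            (0.40, 0.02, "omega_unit"),
            (0.05, 0.41, "ag_unit"),
            (0.20, 0.15, "mixed"),
            (0.80, 0.10, "omega_unit"),     # exactly 8x and > 0.1
            (0.10, 0.0125, "mixed"),        # 8x but preferred not > 0.1
            (0.0, 0.0, "mixed"),
        ],
    )
    def test_rule(self, r2_omega, r2_ag, label):
        assert rs.classify_inertial_selectivity(r2_omega, r2_ag) == label

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rs.classify_inertial_selectivity(-0.1, 0.2)
        with pytest.raises(ValueError):
            rs.classify_inertial_selectivity(np.nan, 0.2)


def test_tune_radius_hits_target_count():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((20000, 3))
    d = rs.tune_radius(X, target_median_neighbors=100, seed=0)
    from scipy.spatial import cKDTree

    tree = cKDTree(X)
    counts = [len(tree.query_ball_point(X[i], d)) for i in range(0, 20000, 200)]
    med = np.median(counts)
    assert 70 <= med <= 140
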