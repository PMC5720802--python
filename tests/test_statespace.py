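import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra.numpy import arrays

from trajspace import statespace as ss
from trajspace.core import default_times

from conftest import make_meta, make_recording


def rank1_recording(n_trials=4, n_sensors=6, n_samples=50, seed=0):
    rng = np.random.default_rng(seed)
    pattern = rng.standard_normal(n_sensors)
    tc = rng.standard_normal((n_trials, n_samples))
    data = pattern[None, :, None] * tc[:, None, :]
    return make_recording(n_trials=n_trials, n_sensors=n_sensors, fs=100.0,
                          t_start=-0.25, t_stop=0.25, data=data)


def random_ts(n_trials=6, k=5, n_samples=30, seed=1, meta=None):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_trials, k, n_samples))
    times = default_times(100.0, -0.15, 0.15)
    return ss.TrajectorySet(values, times, meta if meta is not None else make_meta(n_trials))


class TestFitPCA:
    def test_rank_one_concentrates_variance(self):
        model = ss.fit_pca(rank1_recording())
        assert model.var_explained[0] >= 0.999

    def test_eigenvalue_sum_equals_sensor_count(self, small_rec):
        model = ss.fit_pca(small_rec)
        assert np.isclose(model.eigenvalues.sum(), small_rec.n_sensors, rtol=1e-9)

    def test_loadings_orthonormal_and_sign_fixed(self, small_rec):
        model = ss.fit_pca(small_rec)
        gram = model.loadings.T @ model.loadings
        assert np.max(np.abs(gram - np.eye(gram.shape[0]))) < 1e-8
        peaks = model.loadings[np.argmax(np.abs(model.loadings), axis=0),
                               np.arange(model.loadings.shape[1])]
        assert (peaks > 0).all()

    def test_constant_sensor_named(self):
        rec = make_recording(n_trials=3, n_sensors=4)
        rec.data[:, 2, :] = 5.0
        with pytest.raises(ValueError, match=rec.sensor_names[2]):
            ss.fit_pca(rec)

    def test_correlation_equals_covariance_on_standardized_data(self, small_rec):
        m1 = ss.fit_pca(small_rec, method="correlation")
        x = small_rec.data
        flat = x.transpose(1, 0, 2).reshape(x.shape[1], -1)
        z = (x - flat.mean(1)[None, :, None]) / flat.std(1)[None, :, None]
        m2 = ss.fit_pca(small_rec.copy_with(data=z), method="covariance")
        assert np.allclose(np.abs(m1.loadings), np.abs(m2.loadings), atol=1e-8)

    def test_scoped_fit_recovers_shared_structure(self):
        from trajspace.simulate import SimulationConfig, generate_subject

        cfg = SimulationConfig(n_subjects=1, n_trials_per_subject=60, n_sensors=30,
                               fs=120.0, t_start=-0.5, t_stop=1.5, noise_fmax=50.0)
        rec, _ = generate_subject(cfg, 0, seed=3)
        m_all = ss.fit_pca(rec, "all_trials")
        m_seen = ss.fit_pca(rec, "seen_only")
        maps = ss.align_components([m_all, m_seen], 0, k=3)
        aligned = maps[1].apply(m_seen.loadings[:, :3])
        for j in range(3):
            r = np.corrcoef(m_all.loadings[:, j], aligned[:, j])[0, 1]
            assert abs(r) > 0.9


class TestProject:
    def test_full_backprojection_identity(self, small_rec):
        model = ss.fit_pca(small_rec)
        ts = ss.project(small_rec, model)
        recon = ss.back_project(ts, model)
        flat = small_rec.data.transpose(1, 0, 2).reshape(small_rec.n_sensors, -1)
        z = (small_rec.data - flat.mean(1)[None, :, None]) / flat.std(1)[None, :, None]
        assert np.max(np.abs(recon - z)) < 1e-8

    def test_low_rank_generator_reconstruction(self):
        from trajspace.simulate import SimulationConfig, generate_subject

        cfg = SimulationConfig(n_subjects=1, n_trials_per_subject=20, n_sensors=24,
                               fs=120.0, t_start=-0.5, t_stop=0.5, noise_sd=0.0,
                               alpha_amp=0.0, beta_amp=0.0, data_scale=1.0)
        rec, _ = generate_subject(cfg, 0, seed=2)
        model = ss.fit_pca(rec)
        ts = ss.project(rec, model, k=cfg.k_lat)
        recon = ss.back_project(ts, model)
        flat = rec.data.transpose(1, 0, 2).reshape(rec.n_sensors, -1).astype(np.float64)
        z = (rec.data - flat.mean(1)[None, :, None]) / flat.std(1)[None, :, None]
        resid = ((recon - z) ** 2).sum()
        assert resid < 0.01 * (z**2).sum()

    def test_sensor_mismatch_rejected(self, small_rec):
        model = ss.fit_pca(small_rec)
        other = make_recording(n_sensors=7)
        with pytest.raises(ValueError):
            ss.project(other, model)


class TestChooseK:
    @pytest.mark.parametrize("ve,thresh,expected", [
        ([0.5, 0.25, 0.25], 0.7, 2),
        ([0.999, 0.001], 0.999, 1),  # strictly-exceeds rule on rank-1-like data
        ([0.4, 0.3, 0.2, 0.1], 0.95, 4),
    ])
    def test_threshold_rule(self, ve, thresh, expected):
        model = ss.PCModel(np.eye(len(ve)), np.array(ve), np.array(ve),
                           np.zeros(len(ve)), np.ones(len(ve)), "scp", "all_trials")
        assert ss.choose_k(model, thresh) == expected

    def test_band_specific_dimensionality_is_monotone(self):
        from trajspace.core import BANDS
        from trajspace.preprocess import filter_epochs
        from trajspace.simulate import SimulationConfig, generate_subject

        cfg = SimulationConfig(n_subjects=1, n_trials_per_subject=40, n_sensors=36,
                               fs=200.0, t_start=-1.0, t_stop=1.0, noise_fmax=90.0)
        rec, _ = generate_subject(cfg, 0, seed=4)
        ks = {}
        for band in ("scp", "alpha"):
            filt = filter_epochs(rec, BANDS[band])
            ks[band] = ss.choose_k(ss.fit_pca(filt), 0.7)
        # latent structure lives in the slow band; higher bands are closer
        # to sensor-independent noise and need more components
        assert ks["scp"] < ks["alpha"]


class TestAlignment:
    def _model(self, loadings):
        k = loadings.shape[1]
        return ss.PCModel(loadings, np.ones(k) / k, np.ones(k),
                          np.zeros(loadings.shape[0]), np.ones(loadings.shape[0]),
                          "scp", "all_trials")

    def test_identity(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((12, 5)))
        maps = ss.align_components([self._model(q), self._model(q)], 0, k=5)
        for m in maps:
            assert m.permutation.tolist() == [0, 1, 2, 3, 4]
            assert (m.signs == 1).all()

    def test_recovers_known_scramble(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((12, 5)))
        perm = np.array([3, 0, 4, 1, 2])
        signs = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        scrambled = np.empty_like(q)
        # place reference component i at column perm[i] with sign signs[i]
        for i in range(5):
            scrambled[:, perm[i]] = signs[i] * q[:, i]
        maps = ss.align_components([self._model(q), self._model(scrambled)], 0, k=5)
        m = maps[1]
        assert m.permutation.tolist() == perm.tolist()
        assert np.allclose(m.signs, signs)
        assert np.allclose(m.apply(scrambled), q)

    def test_tie_breaks_to_lower_index(self):
        base = np.eye(6)[:, :3]
        dup = base.copy()
        dup[:, 1] = base[:, 0]  # components 0 and 1 equally correlated with ref 0
        dup[:, 0] = base[:, 0]
        maps = ss.align_components([self._model(base), self._model(dup)], 0, k=3)
        assert maps[1].permutation[0] == 0

    def test_k_too_large(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 3)))
        with pytest.raises(ValueError):
            ss.align_components([self._model(q)], 0, k=5)


class TestConditionAverage:
    def test_mean_of_identical_trials(self):
        ts = random_ts(4, meta=make_meta(4, seen=[1, 1, 1, 1]))
        ts.values[:] = ts.values[0]
        out = ss.condition_average(ts, "seen")
        assert out.n_trials == 1
        assert np.allclose(out.values[0], ts.values[0])

    def test_opposite_trials_cancel(self):
        ts = random_ts(2, meta=make_meta(2, seen=[1, 1]))
        ts.values[1] = -ts.values[0]
        out = ss.condition_average(ts, "seen")
        assert np.allclose(out.values, 0.0)

    def test_groups_from_two_columns(self):
        meta = make_meta(4, seen=[0, 0, 1, 1],
                         orientation=np.array(["left", "right", "left", "right"]))
        ts = random_ts(4, meta=meta)
        out = ss.condition_average(ts, ["seen", "orientation"])
        assert out.n_trials == 4


class TestGeometry:
    def test_distance_closed_forms(self):
        a = np.zeros((5, 10))
        assert np.allclose(ss.distance_timecourse(a, a), 0.0)
        b = a.copy()
        b[2] += 3.0
        assert np.allclose(ss.distance_timecourse(a, b), 3.0)

    def test_distance_matches_bruteforce(self, rng):
        a, b = rng.standard_normal((2, 5, 40))
        d = ss.distance_timecourse(a, b)
        brute = np.array([np.sqrt(((a[:, t] - b[:, t]) ** 2).sum()) for t in range(40)])
        assert np.max(np.abs(d - brute)) < 1e-12

    def test_velocity_constant_and_ramp(self):
        ts = random_ts(1, k=5, n_samples=30)
        ts.values[:] = 2.0
        v, t = ss.velocity_timecourse(ts, "trial_averaged", dt=1 / 600.0)
        assert np.allclose(v, 0.0)
        assert len(v) == 29 and len(t) == 29
        ramp = np.zeros((1, 5, 30))
        ramp[0, 0] = np.arange(30)
        ts2 = ss.TrajectorySet(ramp, ts.times, ts.meta.iloc[:1])
        v2, _ = ss.velocity_timecourse(ts2, "trial_averaged", dt=1 / 600.0)
        assert np.allclose(v2, 600.0)

    def test_single_trial_velocity_dominates_trial_averaged(self, rng):
        base = rng.standard_normal((1, 5, 50))
        trials = base + 0.5 * rng.standard_normal((40, 5, 50))
        ts = ss.TrajectorySet(trials, default_times(100, -0.25, 0.25), make_meta(40))
        v_single, _ = ss.velocity_timecourse(ts, "single_trial")
        v_avg, _ = ss.velocity_timecourse(ts, "trial_averaged")
        assert (v_single >= v_avg).all()

    def test_velocity_time_reversal(self, rng):
        ts = random_ts(3)
        v, _ = ss.velocity_timecourse(ts, "single_trial")
        rev = ss.TrajectorySet(ts.values[..., ::-1].copy(), ts.times, ts.meta)
        v_rev, _ = ss.velocity_timecourse(rev, "single_trial")
        assert np.allclose(v_rev, v[::-1])

    def test_norm_and_angle_closed_forms(self):
        assert ss.vector_norm(np.array([3.0, 4.0, 0, 0, 0])) == 5.0
        assert ss.vector_norm(np.zeros(5)) == 0.0
        assert np.isclose(ss.vector_norm(np.ones(5)), np.sqrt(5))
        e1 = np.eye(5)[0]
        e2 = np.eye(5)[1]
        assert ss.vector_angle(e1, e1) == 0.0
        assert np.isclose(ss.vector_angle(e1, e2), np.pi / 2)
        assert np.isclose(ss.vector_angle(e1, e1 + e2), np.pi / 4)
        assert np.isclose(ss.vector_angle(e1, -e1), np.pi)
        with pytest.raises(ValueError):
            ss.vector_angle(e1, np.zeros(5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        v=arrays(np.float64, 5, elements=hst.floats(-10, 10)),
        w=arrays(np.float64, 5, elements=hst.floats(-10, 10)),
        c=hst.floats(0.01, 50),
    )
    def test_geometry_identities(self, v, w, c):
        # homogeneity of the norm
        assert np.isclose(ss.vector_norm(c * v), c * ss.vector_norm(v), rtol=1e-9)
        if ss.vector_norm(v) > 1e-6 and ss.vector_norm(w) > 1e-6:
            # symmetry + positive scale invariance of the angle
            assert np.isclose(ss.vector_angle(v, w), ss.vector_angle(w, v))
            assert np.isclose(ss.vector_angle(c * v, w), ss.vector_angle(v, w),
                              atol=1e-6)
        # triangle inequality on distances
        u = np.zeros(5)
        d_vw = np.linalg.norm(v - w)
        assert d_vw <= np.linalg.norm(v - u) + np.linalg.norm(u - w) + 1e-9


class TestKRobustness:
    def test_velocity_contrast_sign_stable_across_k(self):
        """The seen>unseen velocity contrast keeps its sign whether the
        state space uses the top 3, 5 or 8 components."""
        from trajspace.pipeline import ANALYSIS_BANDS
        from trajspace.preprocess import filter_epochs
        from trajspace.simulate import SimulationConfig, generate_subject

        cfg = SimulationConfig(n_subjects=1, n_trials_per_subject=150,
                               n_sensors=60, fs=300.0, t_start=-0.5, t_stop=1.5,
                               noise_fmax=140.0)
        rec, _ = generate_subject(cfg, 0, seed=21)
        scp = filter_epochs(rec, ANALYSIS_BANDS["scp"])
        model = ss.fit_pca(scp)
        seen = scp.meta["seen"].astype(bool).to_numpy()
        for k in (3, 5, 8):
            ts = ss.project(scp, model, k=k)
            v_s, tv = ss.velocity_timecourse(ts.select_trials(seen))
            v_u, _ = ss.velocity_timecourse(ts.select_trials(~seen))
            window = (tv > 0.2) & (tv < 0.8)
            assert (v_s[window] - v_u[window]).mean() > 0


class TestVolume:
    def _ts_with_sd_profile(self, sd_post_factor, n=40, k=5):
        rng = np.random.default_rng(0)
        times = default_times(600.0, -1.0, 1.0)
        base = rng.standard_normal((n, k, 1))
        noise = np.repeat(base, len(times), axis=2)
        scale = np.where(times >= 0, sd_post_factor, 1.0)
        return ss.TrajectorySet(noise * scale[None, None, :], times, make_meta(n))

    def test_constant_sd_gives_zero_change(self):
        ts = self._ts_with_sd_profile(1.0)
        assert np.allclose(ss.volume_timecourse(ts), 0.0, atol=1e-9)

    def test_halved_sd_closed_form(self):
        ts = self._ts_with_sd_profile(0.5)
        vol = ss.volume_timecourse(ts)
        post = ts.times >= 0
        assert np.allclose(vol[post], 100 * (2.0**-5 - 1), atol=1e-9)
        assert np.isclose(vol[post].mean(), -96.875)

    def test_too_few_trials(self):
        ts = random_ts(2)
        with pytest.raises(ValueError):
            ss.volume_timecourse(ts, baseline=(-0.15, -0.05))


class TestDispersion:
    def test_common_direction_zero_angle_dispersion(self, rng):
        direction = rng.standard_normal(5)
        lengths = rng.uniform(0.5, 3.0, (8, 1, 20))
        ts = ss.TrajectorySet(direction[None, :, None] * lengths,
                              default_times(100, -0.1, 0.1), make_meta(8))
        assert np.allclose(ss.dispersion_timecourse(ts, "angle"), 0.0, atol=1e-7)

    def test_isotropic_directions_near_right_angle(self, rng):
        ts = ss.TrajectorySet(rng.standard_normal((300, 5, 3)),
                              default_times(100, -0.01, 0.02), make_meta(300))
        disp = ss.dispersion_timecourse(ts, "angle")
        assert np.allclose(disp, np.pi / 2, atol=0.05)

    def test_two_cluster_pair_enumeration(self):
        theta = 0.6
        v1 = np.array([1.0, 0, 0, 0, 0])
        v2 = np.array([np.cos(theta), np.sin(theta), 0, 0, 0])
        values = np.stack([v1, v1, v2, v2])[:, :, None]
        ts = ss.TrajectorySet(values, np.array([0.0]), make_meta(4))
        # 6 unordered pairs: 2 at angle 0, 4 at angle theta
        assert np.isclose(ss.dispersion_timecourse(ts, "angle")[0], 4 * theta / 6)

    def test_equal_norms_zero_norm_dispersion(self, rng):
        u = rng.standard_normal((10, 5, 4))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        ts = ss.TrajectorySet(3.0 * u, default_times(100, -0.02, 0.02), make_meta(10))
        assert np.allclose(ss.dispersion_timecourse(ts, "norm"), 0.0, atol=1e-9)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            ss.dispersion_timecourse(random_ts(), "energy")


class TestSensorSD:
    def test_identical_trials_zero(self):
        rec = make_recording(n_trials=4, data=np.tile(
            np.random.default_rng(0).standard_normal((1, 4, 100)), (4, 1, 1)))
        out = ss.sensor_sd_timecourse(rec, baseline=(-0.5, -0.1))
        assert np.allclose(out, 0.0)

    def test_post_onset_sd_doubling(self, rng):
        times = default_times(100.0, -0.5, 0.5)
        noise = rng.standard_normal((200, 3, len(times)))
        noise[:, :, times >= 0] *= 2.0
        rec = make_recording(n_trials=200, n_sensors=3, fs=100.0, data=noise)
        out = ss.sensor_sd_timecourse(rec, baseline=(-0.5, -0.1))
        assert np.allclose(out[:, times >= 0].mean(), 1.0, atol=0.1)

    def test_baseline_outside_epoch(self, small_rec):
        with pytest.raises(ValueError):
            ss.sensor_sd_timecourse(small_rec, baseline=(-10.0, -9.0))
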