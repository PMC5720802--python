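import itertools

import numpy as np
import pytest
import scipy.stats as st

from trajspace import permstats as ps


class TestSignedRankVectorized:
    def test_matches_scipy_exact(self, rng):
        x = rng.standard_normal((9, 12)) + 0.3
        w, p = ps.stat_signed_rank(x, mu=0.0, tail="greater")
        for t in range(12):
            res = st.wilcoxon(x[:, t], alternative="greater", method="exact")
            assert np.isclose(w[t], res.statistic)
            assert np.isclose(p[t], res.pvalue)

    def test_all_above_closed_form(self):
        x = np.abs(np.random.default_rng(0).standard_normal((11, 3))) + 0.5
        _, p = ps.stat_signed_rank(x + 0.5, mu=0.5, tail="greater")
        assert np.allclose(p, 2.0**-11)


class TestWilcoxonOp:
    def test_all_subjects_above_chance(self):
        x = 0.5 + np.abs(np.random.default_rng(1).standard_normal(11)) * 0.1 + 0.01
        _, p = ps.wilcoxon_signed_rank(x, mu0=0.5, tail="greater")
        assert np.isclose(p, 1 / 2**11)

    def test_symmetric_sample_not_significant(self):
        deltas = np.array([0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.4, -0.4])
        _, p = ps.wilcoxon_signed_rank(0.5 + deltas, mu0=0.5, tail="greater")
        assert p >= 0.5

    def test_all_zero_differences(self):
        _, p = ps.wilcoxon_signed_rank(np.full(6, 0.5), mu0=0.5)
        assert p == 1.0

    def test_agrees_with_sign_enumeration(self, rng):
        x = rng.standard_normal(8) + 0.4
        w_obs, p = ps.wilcoxon_signed_rank(x, mu0=0.0, tail="greater")
        ranks = st.rankdata(np.abs(x))
        count = 0
        for signs in itertools.product([1, -1], repeat=8):
            w = sum(r for r, s in zip(ranks, signs) if s > 0)
            if w >= w_obs - 1e-12:
                count += 1
        assert np.isclose(p, count / 2**8)


class TestRmAnova:
    def test_f_equals_squared_paired_t(self, rng):
        v = rng.standard_normal((9, 2, 2, 6))
        f, p = ps.stat_rm_anova_2x2(v, "A")
        contrast = v[:, 0].mean(axis=1) - v[:, 1].mean(axis=1)
        for t in range(6):
            tt = st.ttest_1samp(contrast[:, t], 0.0)
            assert abs(f[t] - tt.statistic**2) < 1e-9
            assert abs(p[t] - tt.pvalue) < 1e-9

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        v = rng.standard_normal((10, 2, 2, 1))
        rows = []
        for s in range(10):
            for a in range(2):
                for b in range(2):
                    rows.append({"subj": s, "A": a, "B": b, "y": v[s, a, b, 0]})
        df = pd.DataFrame(rows)
        aov = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subj",
                          detailed=True)
        res = ps.rm_anova_2x2_timecourse(v)
        for name, key in (("A", "A"), ("B", "B"), ("A * B", "AB")):
            row = aov[aov.Source == name].iloc[0]
            p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
            assert np.isclose(res[key][0][0], row.F, rtol=1e-6)
            assert np.isclose(res[key][1][0], row[p_col], rtol=1e-6)

    def test_pointwise_type_one_error_calibrated(self, rng):
        hits = 0
        n_sims = 400
        for _ in range(n_sims):
            v = rng.standard_normal((11, 2, 2, 1))
            _, p = ps.stat_rm_anova_2x2(v, "A")
            hits += p[0] < 0.05
        assert 0.03 <= hits / n_sims <= 0.07

    def test_degenerate_cells_flagged(self):
        v = np.ones((5, 2, 2, 3))
        f, _ = ps.stat_rm_anova_2x2(v, "A")
        assert np.isnan(f).all()

    def test_missing_cell_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.stat_rm_anova_2x2(rng.standard_normal((5, 2, 3, 4)), "A")


class TestClusterPermutation:
    @staticmethod
    def _run(data, rng_seed=0, n_perm=200, **kw):
        scheme = ps.PermScheme("condition_labels_within_subject", n_perm, rng_seed)
        return ps.cluster_permutation(
            data,
            lambda d: ps.stat_one_sample_t(d, 0.0),
            ps.permute_time_labels(np.zeros(data.shape[1], bool)),
            scheme=scheme,
            tail="two",
            signed=True,
            **kw,
        )

    def test_p_value_floor_is_one_over_nplus1(self, rng):
        data = rng.standard_normal((8, 30)) * 0.1
        data[:, 10:20] += 5.0  # overwhelming effect
        res = self._run(data, n_perm=200)
        assert res.significant_clusters
        top = max(res.clusters, key=lambda c: c.stat_sum)
        assert np.isclose(top.p_value, 1 / 201)

    def test_detects_known_window(self, rng):
        data = rng.standard_normal((10, 50))
        data[:, 20:35] += 1.5
        res = self._run(data, n_perm=200)
        sig = res.significant_clusters
        assert len(sig) >= 1
        best = max(sig, key=lambda c: c.stat_sum)
        overlap = min(best.stop_idx, 34) - max(best.start_idx, 20) + 1
        assert overlap >= 0.8 * 15

    def test_no_suprathreshold_points_is_valid(self):
        data = np.random.default_rng(3).standard_normal((8, 20)) * 1e-3
        data += np.random.default_rng(4).standard_normal((1, 20)) * 1e-3
        res = self._run(np.zeros((8, 20)) + data * 0, n_perm=50)
        assert res.clusters == []

    def test_signed_clusters_split_on_sign_change(self):
        t = np.array([3.0, 3.5, -4.0, -3.2, 3.1])
        p = np.full(5, 0.01)
        clusters = ps._find_clusters(t, p, np.arange(5.0), 0.05, signed=True)
        assert [c.sign for c in clusters] == [1, -1, 1]
        assert [(c.start_idx, c.stop_idx) for c in clusters] == [(0, 1), (2, 3), (4, 4)]

    def test_cluster_p_monotone_in_mass(self, rng):
        data = rng.standard_normal((9, 60))
        data[:, 5:10] += 1.1
        data[:, 30:45] += 1.1
        res = self._run(data, n_perm=150)
        if len(res.clusters) >= 2:
            ordered = sorted(res.clusters, key=lambda c: c.stat_sum)
            pvals = [c.p_value for c in ordered]
            assert all(pvals[i] >= pvals[i + 1] for i in range(len(pvals) - 1))

    def test_agrees_with_mne_on_one_sample_setup(self, rng):
        """Independent cross-check against mne's cluster permutation test."""
        from mne.stats import permutation_cluster_1samp_test

        data = rng.standard_normal((12, 40))
        data[:, 15:28] += 0.9
        thresh = st.t.ppf(0.975, df=11)
        t_obs, clusters, _, _ = permutation_cluster_1samp_test(
            data, threshold=thresh, n_permutations=500, tail=0, seed=1,
            out_type="indices", verbose=False,
        )
        mne_windows = [(int(np.min(c[0])), int(np.max(c[0]))) for c in clusters]
        ours = ps._find_clusters(*ps.stat_one_sample_t(data, 0.0),
                                 np.arange(40.0), 0.05, signed=True)
        our_windows = [(c.start_idx, c.stop_idx) for c in ours]
        assert set(mne_windows) == set(our_windows)


class TestCircular:
    def test_median_against_grid_bruteforce(self, rng):
        a = rng.vonmises(1.0, 2.0, 25) % (2 * np.pi)
        md = ps.circ_median(a)
        grid = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        dev = (np.pi - np.abs(np.pi - np.abs(a[None, :] - grid[:, None]))).mean(axis=1)
        best = dev.min()
        md_dev = (np.pi - np.abs(np.pi - np.abs(a - md))).mean()
        assert md_dev <= best + 1e-3

    def test_identical_samples_not_different(self, rng):
        a = rng.vonmises(0.5, 3.0, 60)
        stat, p = ps.circ_median_test(a, a.copy())
        assert stat < 1e-9 and p > 0.99

    def test_opposite_concentrations_detected(self, rng):
        a = rng.vonmises(0.0, 20.0, 100)
        b = rng.vonmises(np.pi, 20.0, 100)
        _, p = ps.circ_median_test(a, b)
        assert p < 1e-6

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            a = rng.vonmises(1.0, 2.0, 40)
            b = rng.vonmises(1.0, 2.0, 40)
            _, p = ps.circ_median_test(a, b)
            hits += p < 0.05
        assert 0.02 <= hits / n_sims <= 0.08


class TestBinomialAndFDR:
    def test_binomial_closed_forms(self):
        assert np.isclose(ps.binomial_proportion_test(10, 10, 0.5), 0.5**10)
        assert ps.binomial_proportion_test(5, 10, 0.5) > 0.5

    def test_binomial_matches_pmf_summation(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(0, n + 1))
            p = ps.binomial_proportion_test(k, n, 0.5)
            direct = sum(st.binom.pmf(j, n, 0.5) for j in range(k, n + 1))
            assert np.isclose(p, direct, atol=1e-12)

    def test_bh_all_small(self):
        reject, _ = ps.bh_fdr([0.01] * 7, q=0.05)
        assert reject.all()

    def test_bh_step_up_definition(self):
        reject, _ = ps.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()  # largest k with p_(k) <= k q / m is 4
        reject2, _ = ps.bh_fdr([0.01, 0.04, 0.3, 0.9], q=0.05)
        assert reject2.tolist() == [True, False, False, False]

    def test_bh_empty(self):
        reject, padj = ps.bh_fdr([], q=0.05)
        assert reject.size == 0 and padj.size == 0

    def test_bh_null_calibration(self, rng):
        any_rej = 0
        n_sims = 400
        for _ in range(n_sims):
            reject, _ = ps.bh_fdr(rng.random(100), q=0.05)
            any_rej += reject.any()
        # under the global null, FDR control means P(any rejection) <= q
        assert any_rej / n_sims <= 0.07


class TestWithinSubjectSEM:
    def test_pure_offsets_give_zero(self):
        profile = np.array([1.0, 2.0, 3.0])
        v = profile[None, :] + np.array([[0.0], [5.0], [-3.0], [10.0]])
        sem = ps.within_subject_sem(v)
        naive = v.std(axis=0, ddof=1) / np.sqrt(4)
        assert np.allclose(sem, 0.0, atol=1e-12)
        assert (naive > 0.1).all()

    def test_centered_data_equals_scaled_naive(self, rng):
        v = rng.standard_normal((8, 3))
        v -= v.mean(axis=1, keepdims=True)
        sem = ps.within_subject_sem(v)
        naive = v.std(axis=0, ddof=1) / np.sqrt(8)
        assert np.allclose(sem, naive * np.sqrt(3 / 2))

    def test_single_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.within_subject_sem(rng.standard_normal((5, 1)))
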