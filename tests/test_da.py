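"""Differential abundance: TMM, CPM, dispersion recovery, exact-test oracle,
BH properties, MDS geometry and DA-table summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln
from scipy.stats import nbinom

from sncrna import simulate
from sncrna.core import CountMatrix, InputError, signed_fold_change
from sncrna.da import (
    _exact_pvalue,
    bh_adjust,
    cpm,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    exact_test,
    leading_logfc_distances,
    mds_leading_logfc,
    run_da,
    summarize_da_table,
    tmm_factors,
)


def equal_lib_matrix(counts, n_case, lib=1_000_000):
    counts = np.asarray(counts)
    n = counts.shape[1]
    samples = [f"s{i}" for i in range(n)]
    group = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
    return CountMatrix(
        feature_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=samples,
        counts=counts,
        group=group,
        lib_sizes={s: lib for s in samples},
    )


class TestTMM:
    def test_identical_columns_unit_factors(self):
        m = equal_lib_matrix(np.tile([[100], [50], [10]], (1, 4)), 2)
        f = tmm_factors(m)
        assert all(v == pytest.approx(1.0) for v in f.values())

    def test_doubled_column_absorbed_by_libsize(self):
        """A pure depth change yields all-zero M-values, hence unit factors."""
        base = np.array([[100], [50], [10], [400]])
        counts = np.hstack([base, 2 * base, base, base])
        samples = ["a", "b", "c", "d"]
        m = CountMatrix(
            [f"g{i}" for i in range(4)], samples, counts,
            group={"a": "case", "b": "case", "c": "control", "d": "control"},
            lib_sizes={"a": 1000, "b": 2000, "c": 1000, "d": 1000},
        )
        f = tmm_factors(m)
        assert f["b"] == pytest.approx(f["a"], rel=1e-9)

    def test_asymmetric_spike_compensated(self):
        """10% of features 8-fold up in one library pull its factor below 1."""
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=(400, 4))
        counts = base.copy()
        counts[:40, 0] *= 8
        m = equal_lib_matrix(counts, 2, lib=int(counts.sum(axis=0).mean()))
        m.lib_sizes = {s: int(c) for s, c in zip(m.sample_ids, counts.sum(axis=0))}
        f = tmm_factors(m)
        others = [f[s] for s in m.sample_ids[1:]]
        assert f["s0"] < min(others)

    def test_geometric_mean_one(self):
        m, _ = simulate.gen_count_matrix(300, 4, 0.2, 2, 0.3, seed=3)
        f = tmm_factors(m)
        log_mean = np.mean(np.log(list(f.values())))
        assert log_mean == pytest.approx(0.0, abs=1e-9)


class TestCPM:
    def test_basic_scaling(self, small_matrix):
        f = {s: 1.0 for s in small_matrix.sample_ids}
        mat, avg = cpm(small_matrix, f, prior_count=0)
        assert mat[0, 0] == pytest.approx(100.0)
        assert mat[2, 0] == 0.0
        assert avg[0] == pytest.approx(np.mean([100, 120, 90, 110]))

    def test_scale_invariance(self, small_matrix):
        f = {s: 1.0 for s in small_matrix.sample_ids}
        mat1, _ = cpm(small_matrix, f, prior_count=0)
        doubled = CountMatrix(
            small_matrix.feature_ids, small_matrix.sample_ids,
            small_matrix.counts * 2, small_matrix.group,
            {s: 2 * v for s, v in small_matrix.lib_sizes.items()},
        )
        mat2, _ = cpm(doubled, f, prior_count=0)
        assert np.allclose(mat1, mat2)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), 2000))
        counts = rng.poisson(mu[:, None], size=(2000, 8))
        m = equal_lib_matrix(counts, 4)
        est = estimate_common_dispersion(m, {s: 1.0 for s in m.sample_ids})
        assert est < 0.01

    @pytest.mark.parametrize("seed", range(3))
    def test_nb_dispersion_recovered(self, seed):
        m, _ = simulate.gen_count_matrix(2000, 7, 0.0, 0, dispersion=0.2, seed=100 + seed)
        f = tmm_factors(m)
        est = estimate_common_dispersion(m, f)
        assert est == pytest.approx(0.2, rel=0.2)

    def test_single_flat_feature_hits_lower_bound(self):
        m = equal_lib_matrix(np.full((1, 6), 50), 3)
        est = estimate_common_dispersion(m, {s: 1.0 for s in m.sample_ids})
        assert est < 1e-4

    def test_tagwise_shrinkage_limit(self):
        m, _ = simulate.gen_count_matrix(200, 4, 0.0, 0, 0.2, seed=5)
        f = tmm_factors(m)
        common = estimate_common_dispersion(m, f)
        tag = estimate_tagwise_dispersion(m, f, common, prior_df=1e9)
        rel = [abs(v - common) / common for v in tag.values()]
        assert max(rel) < 1e-3

    def test_tagwise_prior_zero_matches_per_feature_mle(self):
        """With no shrinkage, tagwise equals a direct per-feature 1-D MLE."""
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(2, 2 / (2 + 400), size=(30, 10))
        m = equal_lib_matrix(counts, 5)
        f = {s: 1.0 for s in m.sample_ids}
        common = estimate_common_dispersion(m, f)
        tag = estimate_tagwise_dispersion(m, f, common, prior_df=0.0)

        def cond_ll(y, masks, phi):
            r = 1.0 / phi
            total = 0.0
            for mask in masks:
                yy = y[mask]
                n = len(yy)
                total += (
                    gammaln(yy + r).sum() - n * gammaln(r)
                    + gammaln(n * r) - gammaln(yy.sum() + n * r)
                )
            return total

        masks = [m.group_mask("case"), m.group_mask("control")]
        grid = np.exp(np.linspace(np.log(1e-6), np.log(10), 4000))
        for i, fid in enumerate(m.feature_ids[:10]):
            lls = np.array([cond_ll(counts[i].astype(float), masks, p) for p in grid])
            oracle = grid[np.argmax(lls)]
            if oracle < 2e-6 or oracle > 9:  # boundary solutions compare loosely
                assert tag[fid] < 1e-5 or tag[fid] > 9
            else:
                assert tag[fid] == pytest.approx(oracle, rel=0.05)

    def test_tagwise_ordering_tracks_truth(self):
        """Heterogeneous true dispersions are recovered in rank order."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        n_feat = 500
        true_phi = np.exp(rng.uniform(np.log(0.02), np.log(1.0), n_feat))
        mu = 500.0
        r = 1.0 / true_phi
        counts = rng.negative_binomial(r[:, None], (r / (r + mu))[:, None], size=(n_feat, 12))
        m = equal_lib_matrix(counts, 6)
        f = {s: 1.0 for s in m.sample_ids}
        common = estimate_common_dispersion(m, f)
        tag = estimate_tagwise_dispersion(m, f, common, prior_df=2.0)
        est = np.array([tag[fid] for fid in m.feature_ids])
        rho = spearmanr(est, true_phi).statistic
        assert rho > 0.5


class TestExactTest:
    def test_symmetric_center_p_one(self):
        p = _exact_pvalue(10, 10, 3, 3, 0.2)
        assert p == pytest.approx(1.0)

    def test_poisson_limit_binomial_tail(self):
        # dispersion -> 0, one sample per group, counts (0, 10):
        # conditional Binomial(10, 1/2), two-sided tail = 2/1024
        p = _exact_pvalue(0, 10, 1, 1, 1e-8)
        assert p == pytest.approx(2 / 1024, abs=1e-8)

    @pytest.mark.parametrize("phi", [0.05, 0.3, 1.5])
    @pytest.mark.parametrize("n1,n2", [(1, 1), (3, 3), (7, 5)])
    def test_matches_enumeration_oracle(self, phi, n1, n2):
        """p equals brute-force enumeration over all conditional splits.

        The oracle builds the conditional law from scipy's nbinom pmf at an
        arbitrary per-sample mean (it cancels on conditioning): each group sum
        of n iid NB(mu, 1/phi) draws is NB with size n/phi and the shared
        success probability 1/(1 + phi mu).
        """
        for t in [1, 7, 23, 50]:
            mu = 3.7  # arbitrary: conditioning removes it
            r1, r2 = n1 / phi, n2 / phi
            q = 1.0 / (1.0 + phi * mu)
            s = np.arange(t + 1)
            joint = nbinom.pmf(s, r1, q) * nbinom.pmf(t - s, r2, q)
            cond = joint / joint.sum()
            for s1 in [0, t // 3, t // 2, t]:
                expected = cond[cond <= cond[s1] * (1 + 1e-9)].sum()
                got = _exact_pvalue(s1, t - s1, n1, n2, phi)
                assert got == pytest.approx(min(1.0, expected), abs=1e-9)

    def test_exact_test_log2fc_sign(self, small_matrix):
        f = {s: 1.0 for s in small_matrix.sample_ids}
        res = exact_test(small_matrix, f, {fid: 0.1 for fid in small_matrix.feature_ids})
        # fB: case mean 11, control mean 29 -> down in cases
        assert res["fB"][1] < 0

    def test_missing_dispersion_raises(self, small_matrix):
        f = {s: 1.0 for s in small_matrix.sample_ids}
        with pytest.raises(InputError):
            exact_test(small_matrix, f, {"fA": 0.1})


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == [pytest.approx(0.037)]

    def test_stepup_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_raises(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_dominance_and_monotonicity(self, pvals):
        adj = bh_adjust(pvals)
        assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))
        assert all(a <= 1 + 1e-12 for a in adj)
        order = np.argsort(pvals)
        sorted_adj = np.array(adj)[order]
        assert np.all(np.diff(sorted_adj) >= -1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance(self, pvals, rnd):
        idx = list(range(len(pvals)))
        rnd.shuffle(idx)
        adj = bh_adjust(pvals)
        adj_perm = bh_adjust([pvals[i] for i in idx])
        assert adj_perm == pytest.approx([adj[i] for i in idx])


class TestRunDA:
    def test_type_one_error_calibrated(self):
        """Raw-p rejection rate under the generator's null sits at nominal."""
        m, _ = simulate.gen_count_matrix(1000, 7, 0.0, 0, 0.2, seed=77)
        res = run_da(m)
        p = np.array([r.pvalue for r in res])
        for alpha in (0.01, 0.05):
            se = np.sqrt(alpha * (1 - alpha) / len(p))
            assert abs((p < alpha).mean() - alpha) < 3 * se

    def test_planted_effects_detected(self):
        """|log2FC|=2 at moderate abundance is found at FDR < 0.15."""
        hits = total = 0
        for seed in range(3):
            m, truth = simulate.gen_count_matrix(400, 7, 0.1, 2.0, 0.2, seed=200 + seed)
            res = run_da(m, fdr_threshold=0.15)
            cpm_ok = {r.feature_id for r in res if r.avg_cpm >= 100}
            sig = {r.feature_id for r in res if r.significant}
            eligible = truth.da_features & cpm_ok
            hits += len(eligible & sig)
            total += len(eligible)
        assert hits / total >= 0.8

    def test_signed_fc_convention(self):
        assert signed_fold_change(np.log2(3.4)) == pytest.approx(3.4)
        assert signed_fold_change(-np.log2(3.4)) == pytest.approx(-3.4)
        m, _ = simulate.gen_count_matrix(100, 3, 0.3, 2, 0.2, seed=4)
        for r in run_da(m):
            assert abs(r.fc_signed) >= 1.0
            assert np.sign(r.fc_signed) == np.sign(r.log2fc) or r.log2fc == 0
            assert r.fdr >= r.pvalue - 1e-12

    def test_all_zero_features_dropped(self, small_matrix):
        res = run_da(small_matrix)
        assert "fZero" not in {r.feature_id for r in res}
        assert len(res) == 3


class TestMDS:
    def test_identical_samples_distance_zero(self):
        counts = np.tile([[100], [40], [7]], (1, 4))
        m = equal_lib_matrix(counts, 2)
        d = leading_logfc_distances(m, {s: 1.0 for s in m.sample_ids}, top_k=3)
        assert np.allclose(d, 0)

    def test_distance_matrix_metric_properties(self):
        m, _ = simulate.gen_count_matrix(300, 4, 0.2, 2, 0.3, seed=21)
        d = leading_logfc_distances(m, tmm_factors(m), top_k=100)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert np.all(d >= 0)
        n = d.shape[0]
        coords = mds_leading_logfc(m, tmm_factors(m), top_k=100, n_dims=n - 1)
        emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert emb[i, j] <= emb[i, k] + emb[k, j] + 1e-9

    def test_group_separation_on_dimension_one(self):
        """A strong planted group effect separates cases on dim 1."""
        separated = 0
        for seed in range(5):
            m, _ = simulate.gen_count_matrix(300, 7, 0.2, 3.0, 0.2, seed=300 + seed)
            coords = mds_leading_logfc(m, tmm_factors(m), top_k=150)
            case = coords[m.group_mask("case"), 0]
            ctrl = coords[m.group_mask("control"), 0]
            if case.min() > ctrl.max() or case.max() < ctrl.min():
                separated += 1
        assert separated >= 4

    def test_too_few_samples_raises(self):
        m = equal_lib_matrix(np.array([[1, 2]]), 1)
        with pytest.raises(InputError):
            mds_leading_logfc(m, {s: 1.0 for s in m.sample_ids})


class TestSummarize:
    def test_missing_column_raises(self):
        import pandas as pd

        with pytest.raises(InputError):
            summarize_da_table(pd.DataFrame({"fc": [1.2]}))

    def test_counts_and_ids(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "fc": [2.0, -3.0, 1.5, -2.0],
                "pvalue": [0.001, 0.002, 0.2, 0.01],
                "fdr": [0.01, 0.01, 0.5, 0.1],
                "end": ["5p", "3p", "5p", "3p"],
            }
        )
        s = summarize_da_table(table, end_col="end")
        assert (s["n_up"], s["n_down"]) == (1, 2)
        assert s["up_ids"] == ["a"]
        assert s["by_end"]["3p"]["n_down"] == 2
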