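"""NMF solver, CEV rank selection, permutations and the rank-test scorer."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import hetdr as hd
from hetdr.adjacency import build_mf_adjacency
from hetdr.factorization import (
    NMFConfig,
    nmf_factorize,
    nmf_predict,
    nmfpdr_predict,
    permute_null,
    permute_observed,
    ranksum_z,
    select_rank_cev,
    stouffer_divisor,
)


class TestRankSelection:
    def test_rank_one_outer_product(self, rng):
        v = np.outer(rng.random(8), rng.random(6))
        for thr in (0.5, 0.9, 1.0):
            assert select_rank_cev(v, thr).selected_rank == 1

    def test_diagonal_closed_form(self):
        # singular values (3, 1): CEV_1 = 9/10 = 0.90 exactly
        assert select_rank_cev(np.diag([3.0, 1.0]), 0.90).selected_rank == 1
        # singular values (1, 1): CEV_1 = 0.5 < 0.90
        assert select_rank_cev(np.diag([1.0, 1.0]), 0.90).selected_rank == 2

    def test_curve_nondecreasing_terminal_one(self, rng):
        rep = select_rank_cev(rng.random((10, 7)))
        assert np.all(np.diff(rep.cev_curve) >= -1e-15)
        assert rep.cev_curve[-1] == pytest.approx(1.0, abs=1e-12)
        assert rep.selected_rank == np.argmax(
            rep.cev_curve >= rep.threshold - 1e-12
        ) + 1

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            select_rank_cev(np.zeros((3, 3)))


class TestNMF:
    def test_planted_factor_recovery(self):
        """Exactly factorizable rank-3 input: relative reconstruction error
        below 1e-3 for every seed."""
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            v = r.random((20, 3)) @ r.random((3, 15))
            w, h, _ = nmf_factorize(
                v, NMFConfig(rank=3, max_iter=5000, tol=1e-12, seed=seed)
            )
            err = np.linalg.norm(v - w @ h) / np.linalg.norm(v)
            assert err < 1e-3

    def test_objective_trace_monotone(self, rng):
        v = rng.random((15, 12))
        _, _, trace = nmf_factorize(
            v, NMFConfig(rank=4, max_iter=300, tol=0.0, seed=0)
        )
        assert np.all(np.diff(trace) <= 1e-10)

    def test_factors_nonnegative_and_reproducible(self, rng):
        v = rng.random((10, 8))
        cfg = NMFConfig(rank=3, max_iter=100, seed=42)
        w1, h1, _ = nmf_factorize(v, cfg)
        w2, h2, _ = nmf_factorize(v, cfg)
        assert np.all(w1 >= 0) and np.all(h1 >= 0)
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(h1, h2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            nmf_factorize(np.zeros((3, 3)), NMFConfig(rank=1))
        with pytest.raises(ValueError, match="nonnegative"):
            nmf_factorize(-np.ones((2, 2)), NMFConfig(rank=1))
        with pytest.raises(ValueError, match="rank"):
            nmf_factorize(np.ones((3, 2)), NMFConfig(rank=5))

    def test_comparable_fit_to_sklearn_mu_solver(self, rng):
        """Independent cross-check: our multiplicative-update solver reaches
        a reconstruction error comparable to scikit-learn's 'mu' NMF."""
        from sklearn.decomposition import NMF as SkNMF

        v = rng.random((25, 18))
        w, h, _ = nmf_factorize(
            v, NMFConfig(rank=5, max_iter=2000, tol=1e-10, seed=0)
        )
        ours = np.linalg.norm(v - w @ h)
        sk = SkNMF(
            n_components=5,
            solver="mu",
            init="random",
            max_iter=2000,
            tol=1e-10,
            random_state=0,
        )
        wk = sk.fit_transform(v)
        theirs = np.linalg.norm(v - wk @ sk.components_)
        assert ours <= 1.05 * theirs

    def test_predict_shape_and_score_separation(self, planted_network):
        """Known positives receive higher mean NMF score than negatives."""
        for seed in range(5):
            p = nmf_predict(
                planted_network,
                NMFConfig(max_iter=300, tol=1e-5, seed=seed),
            ).P_rd
            assert p.shape == planted_network.M_rd.shape
            assert np.all(p >= 0)
            pos = p[planted_network.M_rd == 1].mean()
            neg = p[planted_network.M_rd == 0].mean()
            assert pos > neg


class TestPermutations:
    def test_observed_permutation_conserves_positive_values(self, rng):
        m = rng.random((8, 6))
        mask = rng.random((8, 6)) < 0.4
        mask.ravel()[:2] = True
        out = permute_observed(m, mask, seed=0)
        assert sorted(out[mask]) == pytest.approx(sorted(m[mask]))
        np.testing.assert_array_equal(out[~mask], m[~mask])
        np.testing.assert_array_equal(
            permute_observed(m, mask, seed=0), out
        )

    def test_observed_permutation_uniform_over_arrangements(self):
        """3 distinct positive values: each of the 6 arrangements appears
        with frequency 1/6 +- 0.04 over 1000 draws."""
        m = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        mask = m > 0
        counts: dict = {}
        for seed in range(1000):
            out = permute_observed(m, mask, seed=seed)
            key = tuple(out[mask])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        for c in counts.values():
            assert abs(c / 1000 - 1 / 6) < 0.04

    def test_vacuous_permutation_warns(self):
        m = np.array([[1.0, 0.0]])
        with pytest.warns(UserWarning, match="vacuous"):
            out = permute_observed(m, m > 0, seed=0)
        np.testing.assert_array_equal(out, m)

    @pytest.mark.parametrize("mode", ["rows", "columns", "both"])
    def test_null_permutation_conserves_multiset(self, rng, mode):
        m = rng.random((7, 5))
        out = permute_null(m, mode, seed=3)
        assert sorted(out.ravel()) == pytest.approx(sorted(m.ravel()))

    def test_row_mode_preserves_row_contents(self, rng):
        m = rng.random((6, 4))
        out = permute_null(m, "rows", seed=1)
        orig = {tuple(row) for row in m}
        assert {tuple(row) for row in out} == orig

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mat=hnp.arrays(
            float,
            (5, 4),
            elements=st.floats(0.0, 1.0, allow_nan=False),
        ),
        mode=st.sampled_from(["rows", "columns", "both"]),
        seed=st.integers(0, 2**16),
    )
    def test_null_permutation_conserves_multiset_property(
        self, mat, mode, seed
    ):
        out = permute_null(mat, mode, seed=seed)
        np.testing.assert_allclose(
            np.sort(out.ravel()), np.sort(mat.ravel()), atol=0
        )

    def test_both_mode_enumerates_two_by_two_outputs(self):
        """2x2: row/column permutations generate exactly the 4 arrangements
        reachable by brute force."""
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        brute = set()
        for ri in ([0, 1], [1, 0]):
            for ci in ([0, 1], [1, 0]):
                brute.add(tuple(m[ri][:, ci].ravel()))
        seen = {
            tuple(permute_null(m, "both", seed=s).ravel()) for s in range(200)
        }
        assert seen == brute


class TestRankSumZ:
    def test_matches_scipy_mannwhitneyu(self, rng):
        """Exact agreement with the one-sided asymptotic Mann-Whitney z,
        with and without ties."""
        for trial in range(20):
            if trial % 2:
                o = rng.integers(0, 5, size=10).astype(float)
                n = rng.integers(0, 5, size=14).astype(float)
            else:
                o = rng.random(12)
                n = rng.random(9)
            z = ranksum_z(o[None, :], n[None, :])[0]
            _, p = scipy.stats.mannwhitneyu(
                o, n, alternative="greater", method="asymptotic"
            )
            np.testing.assert_allclose(z, scipy.stats.norm.isf(p), atol=1e-10)

    def test_complete_separation_and_degeneracy(self):
        o = np.arange(10.0) + 100
        n = np.arange(10.0)
        z_max = ranksum_z(o[None, :], n[None, :])[0]
        assert z_max > 0
        # partial overlap scores strictly below the maximum
        o2 = np.arange(10.0) + 2.0
        z_less = ranksum_z(o2[None, :], n[None, :])[0]
        assert 0 < z_less < z_max
        # all-tied collections have zero variance -> z = 0
        assert ranksum_z(np.ones((1, 5)), np.ones((1, 5)))[0] == 0.0


class TestNmfPdr:
    def test_combined_z_standard_normal_under_null(self, rng):
        """Monte-Carlo calibration: i.i.d. score collections for 500 pairs
        give an approximately standard normal combined z."""
        K = 25
        o = rng.random((500, K))
        z = (
            ranksum_z(o, rng.random((500, K)))
            + ranksum_z(o, rng.random((500, K)))
            + ranksum_z(o, rng.random((500, K)))
        ) / stouffer_divisor(K)
        assert -0.15 < z.mean() < 0.15
        assert 0.85 < z.std() < 1.15

    def test_deterministic_and_finite(self, planted_network):
        cfg = NMFConfig(max_iter=150, tol=1e-4)
        a = nmfpdr_predict(planted_network, K=4, nmf_config=cfg, seed=9)
        b = nmfpdr_predict(planted_network, K=4, nmf_config=cfg, seed=9)
        np.testing.assert_array_equal(a.combined_Z, b.combined_Z)
        assert np.all(np.isfinite(a.combined_Z))
        assert a.rank_used >= 1

    def test_ensemble_shapes_and_rank_reuse(self, planted_network):
        cfg = NMFConfig(max_iter=100, tol=1e-4)
        res = nmfpdr_predict(
            planted_network, K=3, nmf_config=cfg, seed=0, keep_ensemble=True
        )
        n, m = planted_network.M_rd.shape
        assert res.ensemble.observed.shape == (n, m, 3)
        assert res.ensemble.null_both.shape == (n, m, 3)
        adj = build_mf_adjacency(planted_network)
        assert res.rank_used == select_rank_cev(adj.M_MF).selected_rank

    def test_positive_pairs_score_above_negative_pairs(self, planted_network):
        res = nmfpdr_predict(
            planted_network,
            K=10,
            nmf_config=NMFConfig(max_iter=200, tol=1e-5),
            seed=1,
        )
        pos = res.combined_Z[planted_network.M_rd == 1].mean()
        neg = res.combined_Z[planted_network.M_rd == 0].mean()
        assert pos > neg

    def test_k_below_two_rejected(self, planted_network):
        with pytest.raises(ValueError, match="K"):
            nmfpdr_predict(planted_network, K=1)
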