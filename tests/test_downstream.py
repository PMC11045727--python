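"""Correlation summaries, smoothing, clustering, ARI, and the gene network."""

import numpy as np
import pytest

import jobsbayes as jb
from jobsbayes.ordering import build_order


class TestSummarizeCorrelations:
    def test_unit_diagonal_and_symmetry(self, short_fit):
        _, _, res = short_fit
        summ = jb.summarize_correlations(res)
        np.testing.assert_array_equal(np.diag(summ.gene_corr), 1.0)
        np.testing.assert_array_equal(summ.gene_corr, summ.gene_corr.T)
        sc = summ.spatial_corr[0]
        np.testing.assert_array_equal(np.diag(sc), 1.0)
        assert np.linalg.eigvalsh(sc).min() > -1e-8

    def test_scaled_identity_lambda(self, short_fit):
        _, _, res = short_fit
        import dataclasses
        mod = dataclasses.replace(
            res, lam_trace=np.stack([2.0 * np.eye(res.p)] * 3)
        )
        summ = jb.summarize_correlations(mod, materialize_spatial=False)
        np.testing.assert_allclose(summ.gene_corr, np.eye(res.p))

    def test_posterior_beats_raw_correlation_under_strong_dependence(self):
        """Joint estimation outperforms the naive sample correlation of raw
        columns in most replicates when spatial dependence is strong (the
        naive estimator treats spatially dependent cells as independent
        replicates)."""
        wins = 0
        for seed in range(6):
            rng = np.random.default_rng(30 + seed)
            p, n = 4, 200
            coords = rng.uniform(size=(n, 2))
            sigma = jb.matern_cov(coords, 1.0, 0.5, 0.5)  # long-range
            lam = jb.gen_gene_cov(p, "ar1", 0.7)
            y = jb.gen_matrix_normal(lam, sigma, rng)
            sx = jb.SpatialExpression(y, [f"g{i}" for i in range(p)], coords)
            res = jb.SpatialCovarianceModel(sx).fit(
                n_iter=300, n_burn=150, thin=3, seed=1
            )
            # unit-diagonal AR(1) truth is already a correlation matrix
            e_joint = jb.rel_frobenius(lam, res.gene_correlation())
            e_naive = jb.rel_frobenius(lam, np.corrcoef(y))
            wins += e_joint < e_naive
        assert wins >= 5


class TestSmoothExpression:
    def test_zero_coefficients_zero_smooth(self, short_fit):
        sx, _, res = short_fit
        import dataclasses
        mod = dataclasses.replace(res, u_trace=[np.zeros_like(res.u_trace[0])])
        from jobsbayes.data import center_genes
        sm = jb.smooth_expression(center_genes(sx), mod)
        np.testing.assert_array_equal(sm.fitted, 0.0)

    def test_full_conditioning_matches_kriging(self):
        """m = n-1 with exact conditional factors reproduces the Gaussian
        conditional mean E[y_i | y_(-i)] computed densely."""
        rng = np.random.default_rng(8)
        n, p = 20, 3
        coords = rng.uniform(size=(n, 2))
        sigma = jb.matern_cov(coords, 1.0, 0.4, 0.5)
        order = build_order(coords, n - 1)
        sigma_perm = sigma[np.ix_(order.perm, order.perm)]
        cf = jb.factors_from_covariance(sigma_perm, order)
        y = jb.gen_matrix_normal(np.eye(p), sigma, rng)
        sx = jb.SpatialExpression(y, [f"g{i}" for i in range(p)], coords)
        # wrap exact factors in a single-draw results object
        from jobsbayes.data import RunConfig
        from jobsbayes.model import PosteriorDraws
        u_pad = np.zeros((1, n, n - 1))
        for i, g in enumerate(order.neighbors):
            u_pad[0, i, : g.size] = cf.u[i]
        draws = PosteriorDraws(
            lam_trace=np.eye(p)[None], theta_trace=np.ones((1, 3)),
            u_trace=[u_pad], d_trace=[cf.d[None]], orders=[order],
            config=RunConfig(m=n - 1, n_iter=2, n_burn=1, thin=1, seed=0),
            seed=0, acceptance_rate=1.0,
            samples_meta=[{"sample_id": "s", "n": n, "m": n - 1}],
        )
        sm_full = jb.smooth_expression(sx, draws, method="full")
        prec = np.linalg.inv(sigma)
        expected = np.empty_like(y)
        for i in range(n):
            rest = [j for j in range(n) if j != i]
            w = np.linalg.solve(sigma[np.ix_(rest, rest)], sigma[rest, i])
            expected[:, i] = y[:, rest] @ w
        np.testing.assert_allclose(sm_full.fitted, expected, atol=1e-8)

    def test_smoothing_denoises(self):
        """Smoothed expression correlates better with the noiseless field
        than the noisy observation does."""
        rng = np.random.default_rng(12)
        p, n = 3, 150
        coords = rng.uniform(size=(n, 2))
        sigma = jb.matern_cov(coords, 1.0, 0.5, 1.5)
        lam = jb.gen_gene_cov(p, "ar1", 0.5)
        clean = jb.gen_matrix_normal(lam, sigma, rng)
        noisy = clean + 0.7 * rng.standard_normal((p, n))
        sx = jb.SpatialExpression(noisy, [f"g{i}" for i in range(p)], coords)
        res = jb.SpatialCovarianceModel(sx, center=False).fit(
            n_iter=300, n_burn=150, thin=3, seed=2
        )
        sm = jb.smooth_expression(sx, res)
        corr_sm = np.mean([np.corrcoef(clean[g], sm.fitted[g])[0, 1]
                           for g in range(p)])
        corr_obs = np.mean([np.corrcoef(clean[g], noisy[g])[0, 1]
                            for g in range(p)])
        assert corr_sm > corr_obs

    def test_linear_in_data(self, short_fit):
        sx, _, res = short_fit
        from jobsbayes.data import center_genes
        sxc = center_genes(sx)
        sm1 = jb.smooth_expression(sxc, res)
        doubled = jb.SpatialExpression(2 * sxc.expr, sxc.genes, sxc.coords)
        sm2 = jb.smooth_expression(doubled, res)
        np.testing.assert_allclose(sm2.fitted, 2 * sm1.fitted, atol=1e-10)


class TestClusterCells:
    def test_two_blobs_k2_perfect_ari(self, rng):
        a = rng.standard_normal((60, 2)) * 0.3 + np.array([0, 0])
        b = rng.standard_normal((60, 2)) * 0.3 + np.array([8, 8])
        x = np.vstack([a, b])
        truth = np.array([0] * 60 + [1] * 60)
        cl = jb.cluster_cells(x, range(1, 6))
        assert cl.k == 2
        assert jb.adjusted_rand_index(cl.labels, truth) == pytest.approx(1.0)
        assert cl.k == min(cl.bic_trace, key=cl.bic_trace.get)

    def test_single_cloud_k1(self, rng):
        x = rng.standard_normal((150, 2))
        cl = jb.cluster_cells(x, range(1, 5))
        assert cl.k == 1

    def test_deterministic_under_duplication(self, rng):
        x = rng.standard_normal((40, 3))
        c1 = jb.cluster_cells(x, range(1, 4))
        c2 = jb.cluster_cells(x, range(1, 4))
        np.testing.assert_array_equal(c1.labels, c2.labels)

    def test_empty_k_range_raises(self, rng):
        with pytest.raises(ValueError):
            jb.cluster_cells(rng.standard_normal((10, 2)), [])


class TestAdjustedRandIndex:
    def test_identical_and_relabeled(self):
        a = [1, 1, 2, 2, 3]
        assert jb.adjusted_rand_index(a, a) == 1.0
        assert jb.adjusted_rand_index(a, [5, 5, 9, 9, 7]) == 1.0

    def test_hand_computed_contingency(self):
        """{1,1,2,2} vs {1,2,1,2} by hand: all contingency cells are 1 so
        the raw index is 0; the expectation term is (2*2)/C(4,2) = 2/3 and
        the maximum is 2, giving ARI = (0 - 2/3)/(2 - 2/3) = -1/2."""
        assert jb.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_symmetry_and_permutation_invariance(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 4, 30)
        assert jb.adjusted_rand_index(a, b) == pytest.approx(
            jb.adjusted_rand_index(b, a)
        )
        relabel = {0: 7, 1: 5, 2: 6, 3: 9}
        b2 = np.array([relabel[x] for x in b])
        assert jb.adjusted_rand_index(a, b) == pytest.approx(
            jb.adjusted_rand_index(a, b2)
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            jb.adjusted_rand_index([1, 2], [1, 2, 3])


class TestDecorrelate:
    def test_identity_factors_no_op(self, rng):
        order = build_order(rng.uniform(size=(8, 2)), 3)
        cf = jb.CholeskyFactors(
            u=[np.zeros(g.size) for g in order.neighbors], d=np.ones(8),
            order=order,
        )
        y = rng.standard_normal((3, 8))
        np.testing.assert_allclose(jb.decorrelate(y, cf), y)

    def test_exact_factors_whiten_columns(self):
        """With the true factors, whitened columns are i.i.d. N(0, Lambda):
        their sample covariance approaches Lambda."""
        rng = np.random.default_rng(3)
        p, n = 3, 400
        coords = rng.uniform(size=(n, 2))
        sigma = jb.matern_cov(coords, 1.0, 0.3, 0.5)
        lam = jb.gen_gene_cov(p, "ar1", 0.6)
        order = build_order(coords, n - 1)
        sigma_perm = sigma[np.ix_(order.perm, order.perm)]
        cf = jb.factors_from_covariance(sigma_perm, order)
        y = jb.gen_matrix_normal(lam, sigma_perm, rng)
        y_dec = jb.decorrelate(y, cf)
        s = (y_dec @ y_dec.T) / n
        assert jb.rel_frobenius(lam, s) < 0.2
        # column-wise precision of the whitened data is near identity
        col_cov = (y_dec.T @ y_dec) / p
        off = col_cov - np.diag(np.diag(col_cov))
        assert np.abs(off).mean() < np.abs(np.diag(col_cov)).mean()


class TestGeneNetwork:
    def test_strong_penalty_empty_graph(self, rng):
        y = rng.standard_normal((4, 100))
        net = jb.gene_network(y, penalty_grid=[5.0])
        assert net.adjacency.sum() == 0

    def test_unpenalized_limit_p2(self, rng):
        y = rng.standard_normal((2, 300))
        y[1] += 0.5 * y[0]
        net = jb.gene_network(y, penalty_grid=[1e-8])
        s = (y @ y.T) / y.shape[1]
        np.testing.assert_allclose(net.precision, np.linalg.inv(s), rtol=1e-2)

    def test_chain_precision_recovered(self):
        """Path-graph conditional independence (1-2, 2-3, no 1-3) is
        recovered in most replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            prec = jb.chain_precision(3, off=-0.9, diag=2.0)
            lam = np.linalg.inv(prec)
            y = np.linalg.cholesky(lam) @ rng.standard_normal((3, 400))
            net = jb.gene_network(y)
            want = np.array([[False, True, False],
                             [True, False, True],
                             [False, True, False]])
            hits += bool(np.array_equal(net.adjacency, want))
        assert hits >= 8

    def test_degenerate_input_raises(self, rng):
        with pytest.raises(ValueError):
            jb.gene_network(rng.standard_normal((3, 1)))
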