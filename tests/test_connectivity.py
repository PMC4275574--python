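import numpy as np
import pytest

import _oracles as oracles
from sparseconn.connectivity import (ConnectivityMatrix, bic_score,
                                     devectorize_lower, full_inverse_covariance,
                                     glasso_objective, graphical_lasso,
                                     lower_index_map, partial_correlation,
                                     pearson_correlation, sample_covariance,
                                     select_lambda, vectorize_lower,
                                     _snap_to_grid)
from sparseconn.preprocess import RegionalTimeSeries
from sparseconn.synthdata import random_sparse_precision, simulate_subject


def _cov(mat):
    return ConnectivityMatrix(mat, "covariance")


class TestSampleCovariance:
    def test_identical_columns_share_variance(self, rng):
        x = rng.normal(size=100)
        S = sample_covariance(np.column_stack([x, x])).data
        assert S[0, 1] == pytest.approx(S[0, 0])

    def test_three_by_two_hand_computation(self):
        X = np.array([[0.0, 2.0], [3.0, 4.0], [6.0, 0.0]])
        # columns centered: [-3,0,3], [0,2,-2]; MLE scaling 1/3
        S = sample_covariance(X).data
        np.testing.assert_allclose(S, [[6.0, -2.0], [-2.0, 8.0 / 3.0]])

    def test_unbiased_flag_rescales(self, rng):
        X = rng.normal(size=(50, 3))
        mle = sample_covariance(X).data
        unb = sample_covariance(X, unbiased=True).data
        np.testing.assert_allclose(unb * 49 / 50, mle, atol=1e-12)

    def test_standardized_white_noise_offdiagonals_small(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10_000, 5))
        S = sample_covariance(X).data
        off = S[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_zero_variance_column_names_region(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="(region|variance)"):
            sample_covariance(X, region_labels=["a", "b"])


class TestCorrelationAndPartials:
    def test_self_and_negated_correlation(self, rng):
        x = rng.normal(size=60)
        C = pearson_correlation(np.column_stack([x, -x, rng.normal(size=60)]))
        assert C.data[0, 0] == pytest.approx(1.0)
        assert C.data[0, 1] == pytest.approx(-1.0)

    def test_matches_numpy_corrcoef(self, rng):
        X = rng.normal(size=(50, 4))
        np.testing.assert_allclose(pearson_correlation(X).data,
                                   np.corrcoef(X, rowvar=False), atol=1e-12)

    def test_inverse_of_diagonal(self):
        P = full_inverse_covariance(_cov(np.diag([2.0, 4.0])))
        np.testing.assert_allclose(P.data, np.diag([0.5, 0.25]))

    def test_inverse_solves_identity(self, rng):
        S = oracles.random_pd_covariance(6, rng)
        P = full_inverse_covariance(_cov(S))
        np.testing.assert_allclose(P.data @ S, np.eye(6), atol=1e-8)

    def test_singular_covariance_advises_glasso(self):
        with pytest.raises(np.linalg.LinAlgError, match="graphical_lasso"):
            full_inverse_covariance(_cov(np.ones((3, 3))))

    def test_partial_correlation_formula(self):
        prec = ConnectivityMatrix(np.array([[2.0, -1.0], [-1.0, 2.0]]),
                                  "inverse_covariance")
        theta = partial_correlation(prec)
        assert theta.data[0, 1] == pytest.approx(0.5)
        assert theta.data[0, 0] == 1.0

    def test_diagonal_precision_gives_zero_partials(self):
        prec = ConnectivityMatrix(np.diag([1.0, 2.0, 3.0]),
                                  "inverse_covariance")
        theta = partial_correlation(prec).data
        assert np.abs(theta[~np.eye(3, dtype=bool)]).max() == 0.0

    def test_chain_model_zero_stays_zero(self):
        prec = np.array([[2.0, -0.8, 0.0], [-0.8, 2.0, -0.8],
                         [0.0, -0.8, 2.0]])
        theta = partial_correlation(
            ConnectivityMatrix(prec, "inverse_covariance")).data
        assert theta[0, 2] == 0.0

    def test_partials_bounded_and_symmetric(self, rng):
        S = oracles.random_pd_covariance(7, rng)
        theta = partial_correlation(full_inverse_covariance(_cov(S))).data
        assert np.abs(theta - theta.T).max() < 1e-12
        assert np.abs(theta).max() <= 1.0 + 1e-12

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(ConnectivityMatrix(
                np.array([[1.0, 0.0], [0.0, -1.0]]), "inverse_covariance"))


class TestGraphicalLasso:
    def test_unpenalized_recovers_plain_inverse(self, rng):
        S = oracles.random_pd_covariance(5, rng) + 0.5 * np.eye(5)
        om = graphical_lasso(_cov(S), 0.0)
        np.testing.assert_allclose(om.data, np.linalg.inv(S), atol=1e-6)

    def test_two_by_two_soft_threshold_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        om = graphical_lasso(_cov(S), 0.6, tol=1e-10, max_iter=500)
        np.testing.assert_allclose(om.data, np.diag([0.625, 0.625]),
                                   atol=1e-8)

    def test_objective_matches_admm_oracle(self, rng):
        for _ in range(5):
            S = oracles.random_pd_covariance(5, rng)
            lam = 0.1
            om = graphical_lasso(_cov(S), lam, tol=1e-10, max_iter=1000)
            _, Z = oracles.admm_graphical_lasso(S, lam)
            ours = glasso_objective(om.data, S, lam)
            ref = oracles.glasso_objective(Z, S, lam)
            assert ours >= ref - 1e-6

    def test_stationarity_subgradient(self, rng):
        S = oracles.random_pd_covariance(6, rng)
        lam = 0.05
        om = graphical_lasso(_cov(S), lam, tol=1e-10, max_iter=1000).data
        W = np.linalg.inv(om)
        resid = W - S
        nz = om != 0
        # where omega_ij != 0: W - S = lam * sign(omega); else |W - S| <= lam
        assert np.abs(resid[nz] - lam * np.sign(om[nz])).max() < 1e-4
        assert np.abs(resid[~nz]).max() <= lam + 1e-8

    def test_support_monotone_in_lambda(self, rng):
        S = oracles.random_pd_covariance(8, rng)
        sizes = []
        for lam in (0.001, 0.01, 0.1):
            om = graphical_lasso(_cov(S), lam)
            sizes.append(int(np.count_nonzero(
                om.data[np.tril_indices(8, -1)])))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_exact_zeros_not_thresholded(self, rng):
        S = oracles.random_pd_covariance(6, rng)
        om = graphical_lasso(_cov(S), 0.3).data
        off = om[np.tril_indices(6, -1)]
        # entries are either exactly zero or clearly nonzero
        assert np.all((off == 0.0) | (np.abs(off) > 1e-10))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso(_cov(np.eye(2)), -0.1)


class TestBic:
    def test_identity_worked_example(self):
        om = ConnectivityMatrix(np.eye(2), "sparse_inverse_covariance",
                                lambda_=0.1)
        rec = bic_score(om, _cov(np.eye(2)), n_t=100)
        assert rec.log_likelihood == pytest.approx(-2.0)
        assert rec.n_nonzero == 2
        assert rec.degrees_of_freedom == 1
        assert rec.bic == pytest.approx(4.0 + np.log(100))

    def test_denser_estimate_pays_larger_penalty(self):
        sparse = ConnectivityMatrix(np.eye(3), "sparse_inverse_covariance",
                                    lambda_=0.1)
        dense_m = np.eye(3)
        dense_m[0, 1] = dense_m[1, 0] = 1e-9  # same L to first order
        dense = ConnectivityMatrix(dense_m, "sparse_inverse_covariance",
                                   lambda_=0.1)
        cov = _cov(np.eye(3))
        assert bic_score(dense, cov, 50).bic > bic_score(sparse, cov, 50).bic

    def test_matches_independent_recomputation(self, rng):
        S = oracles.random_pd_covariance(5, rng)
        om = graphical_lasso(_cov(S), 0.05)
        rec = bic_score(om, _cov(S), n_t=123)
        L = np.linalg.slogdet(om.data)[1] - np.trace(om.data @ S)
        m = sum(1 for i in range(5) for j in range(i + 1)
                if om.data[i, j] != 0)
        d = m * (m - 1) / 2
        assert rec.bic == pytest.approx(-2 * L + d * np.log(123))

    def test_symmetric_duplicate_counting_flag(self, rng):
        S = oracles.random_pd_covariance(4, rng)
        om = graphical_lasso(_cov(S), 0.01)
        once = bic_score(om, _cov(S), 100)
        twice = bic_score(om, _cov(S), 100, count_symmetric_pairs_once=False)
        off = int(np.count_nonzero(om.data[np.tril_indices(4, -1)]))
        assert twice.n_nonzero == once.n_nonzero + off


class TestSelectLambda:
    def test_snap_rule_reproduces_grid_examples(self):
        grid = [0.1, 0.01, 0.001]
        assert _snap_to_grid(0.01, grid) == 0.01
        # mean of 0.1 and 0.001 snaps to 0.1 on the log scale
        assert _snap_to_grid(np.mean([0.1, 0.001]), grid) == 0.1
        assert _snap_to_grid(np.sqrt(0.1 * 0.01), grid) == 0.1  # tie -> sparser

    def test_agreeing_groups_keep_modal_lambda(self, rng):
        # data from a clearly sparse model: both groups should agree
        P, _ = random_sparse_precision(6, 0.2, rng)
        ts = {g: [RegionalTimeSeries(
            simulate_subject(P, 300, seed=rng)[0].data, 2.0, group=g)
            for _ in range(3)] for g in (-1, 1)}
        sel = select_lambda(ts, grid=(0.1, 0.01, 0.001))
        assert sel.pooled_lambda in (0.1, 0.01, 0.001)
        assert set(sel.lambda_per_group) == {-1, 1}

    def test_dense_strong_precision_prefers_small_lambda(self, rng):
        # every partial correlation strong, n_t large -> BIC favors dense fit
        P = np.full((5, 5), -0.15)
        np.fill_diagonal(P, 1.0)
        ts = {g: [RegionalTimeSeries(
            simulate_subject(P, 2000, seed=rng)[0].data, 2.0, group=g)
            for _ in range(2)] for g in (-1, 1)}
        sel = select_lambda(ts, grid=(0.1, 0.001))
        assert sel.pooled_lambda == 0.001


class TestVectorization:
    def test_canonical_order_for_three_regions(self):
        M = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        fv = vectorize_lower(ConnectivityMatrix(M, "covariance"))
        assert fv.index_map == [(1, 0), (2, 0), (2, 1)]
        np.testing.assert_allclose(fv.values, [1.0, 2.0, 3.0])

    def test_feature_count_for_137_regions(self):
        assert len(lower_index_map(137)) == 9316

    def test_roundtrip_restores_offdiagonals(self, rng):
        A = rng.normal(size=(6, 6))
        M = (A + A.T) / 2
        fv = vectorize_lower(ConnectivityMatrix(M, "covariance"))
        back = devectorize_lower(fv.values, 6)
        np.testing.assert_allclose(back - np.diag(np.diag(back)),
                                   M - np.diag(np.diag(M)))
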