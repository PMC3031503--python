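import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifreg.data import LabeledMatrix, RegulatoryDataset
from motifreg.errors import ParameterError, SingularSystemError
from motifreg.estimators import (
    center_dataset,
    fit_centered_least_squares,
    fit_centered_ridge,
    fit_correlation,
    fit_least_squares,
    fit_ridge,
    fit_sparse,
    get_estimator,
    goodness_of_fit,
    lambda_max,
    predict,
    soft_threshold,
    sparse_path,
)

from helpers import (
    consistency_dataset,
    dataset_from_arrays,
    random_dataset,
    vectorized_design,
)


def scalar_dataset(g=1.0):
    return dataset_from_arrays([[g]], [[1.0]], [[1.0]])


class TestPredict:
    def test_zero_coefficients_predict_zero(self, rng):
        D = random_dataset(rng)
        A = LabeledMatrix(np.zeros((D.n_motifs, D.n_tfs)), D.motifs, D.tfs)
        assert predict(D, A).values.sum() == 0

    def test_identity_designs_return_coefficients(self):
        D = dataset_from_arrays(np.eye(2), np.eye(2), np.eye(2))
        A = D.G.__class__([[1.0, 2.0], [3.0, 4.0]], D.motifs, D.tfs)
        np.testing.assert_array_equal(predict(D, A).values, A.values)

    def test_matches_scalar_loop_oracle(self, rng):
        n, p, m, t = 5, 4, 3, 2
        D = random_dataset(rng, n, p, m, t)
        A = D.G.__class__(rng.standard_normal((m, t)), D.motifs, D.tfs)
        got = predict(D, A).values
        for i in range(n):
            for j in range(p):
                expected = sum(
                    D.M.values[i, k] * A.values[k, l] * D.T.values[l, j]
                    for k in range(m)
                    for l in range(t)
                )
                assert got[i, j] == pytest.approx(expected, rel=1e-12)


class TestGoodnessOfFit:
    def test_exact_coefficients_give_zero_rss(self, rng):
        D = random_dataset(rng, 6, 5, 2, 2)
        A_true = rng.standard_normal((2, 2))
        D = dataset_from_arrays(
            D.M.values @ A_true @ D.T.values, D.M.values, D.T.values
        )
        A = D.G.__class__(A_true, D.motifs, D.tfs)
        assert goodness_of_fit(D, A).rss == pytest.approx(0, abs=1e-18)

    def test_zero_fit_on_grand_mean_centered_data(self, rng):
        G = rng.standard_normal((4, 3))
        G -= G.mean()
        D = dataset_from_arrays(G, rng.standard_normal((4, 2)),
                                rng.standard_normal((2, 3)))
        A = D.G.__class__(np.zeros((2, 2)), D.motifs, D.tfs)
        stats = goodness_of_fit(D, A)
        assert stats.rss == pytest.approx(stats.total_ss)
        assert stats.explained_ss == pytest.approx(0, abs=1e-9)

    def test_matches_elementwise_loop_oracle(self, rng):
        D = random_dataset(rng, 4, 3, 2, 2)
        A = D.G.__class__(rng.standard_normal((2, 2)), D.motifs, D.tfs)
        G_hat = D.M.values @ A.values @ D.T.values
        rss = sum(
            (D.G.values[i, j] - G_hat[i, j]) ** 2
            for i in range(4) for j in range(3)
        )
        assert goodness_of_fit(D, A).rss == pytest.approx(rss, rel=1e-12)


class TestLeastSquares:
    def test_identity_designs_recover_expression(self):
        D = dataset_from_arrays([[1.0, 2.0], [3.0, 4.0]], np.eye(2), np.eye(2))
        np.testing.assert_allclose(
            fit_least_squares(D).values, [[1.0, 2.0], [3.0, 4.0]]
        )

    def test_zero_expression_gives_zero_minimum_norm_solution(self, rng):
        D = random_dataset(rng, 5, 4, 3, 2, rank_deficient=True)
        D = D.replace(G=D.G.with_values(np.zeros((5, 4))))
        assert np.abs(fit_least_squares(D).values).max() == 0

    @pytest.mark.parametrize("rank_deficient", [False, True])
    def test_matches_kronecker_vectorization_oracle(self, rng, rank_deficient):
        for _ in range(5):
            D = random_dataset(rng, 6, 5, 3, 2, rank_deficient=rank_deficient)
            A = fit_least_squares(D).values
            X = vectorized_design(D)
            a_vec = np.linalg.pinv(X) @ D.G.values.ravel(order="F")
            np.testing.assert_allclose(
                A, a_vec.reshape(D.n_motifs, D.n_tfs, order="F"), atol=1e-8
            )

    def test_full_rank_closed_form_equals_pseudoinverse_route(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        M, G, T = D.M.values, D.G.values, D.T.values
        closed = (
            np.linalg.inv(M.T @ M) @ M.T @ G @ T.T @ np.linalg.inv(T @ T.T)
        )
        np.testing.assert_allclose(fit_least_squares(D).values, closed, atol=1e-8)

    def test_solution_family_preserves_residual_and_min_norm(self, rng):
        """Adding (I - M+M)Z1 + Z2(I - TT+) never changes the residual and
        never shrinks the Frobenius norm below the minimum-norm solution."""
        D = random_dataset(rng, 6, 5, 3, 3, rank_deficient=True)
        coef = fit_least_squares(D)
        A_hat = coef.values
        rss_hat = coef.diagnostics["rss"]
        M, T = D.M.values, D.T.values
        P_m = np.eye(D.n_motifs) - np.linalg.pinv(M) @ M
        P_t = np.eye(D.n_tfs) - T @ np.linalg.pinv(T)
        norm_hat = np.linalg.norm(A_hat)
        for _ in range(100):
            Z1 = rng.standard_normal(A_hat.shape)
            Z2 = rng.standard_normal(A_hat.shape)
            A_alt = A_hat + P_m @ Z1 + Z2 @ P_t
            rss_alt = goodness_of_fit(D, D.G.__class__(A_alt, D.motifs, D.tfs)).rss
            assert rss_alt == pytest.approx(rss_hat, rel=1e-9, abs=1e-9)
            assert np.linalg.norm(A_alt) >= norm_hat - 1e-10


class TestCentering:
    def test_centered_means_vanish(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        Dc = center_dataset(D)
        np.testing.assert_allclose(Dc.M.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Dc.T.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(Dc.G.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Dc.G.values.mean(axis=1), 0, atol=1e-12)

    def test_centering_is_idempotent(self, rng):
        D = random_dataset(rng)
        once = center_dataset(D)
        twice = center_dataset(once)
        for a, b in ((once.G, twice.G), (once.M, twice.M), (once.T, twice.T)):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_double_centering_annihilates_rank_one_plus_constant(self):
        # [[1,2],[3,4]] = grand structure only: double centering zeroes it
        D = dataset_from_arrays([[1.0, 2.0], [3.0, 4.0]],
                                [[1.0], [0.0]], [[1.0, 0.0]])
        np.testing.assert_allclose(
            center_dataset(D).G.values, np.zeros((2, 2)), atol=1e-12
        )

    def test_row_and_column_modes(self, rng):
        D = random_dataset(rng)
        np.testing.assert_allclose(
            center_dataset(D, g_mode="row").G.values.mean(axis=1), 0, atol=1e-12
        )
        np.testing.assert_allclose(
            center_dataset(D, g_mode="column").G.values.mean(axis=0), 0, atol=1e-12
        )
        with pytest.raises(ParameterError):
            center_dataset(D, g_mode="grand")


class TestCenteredLeastSquares:
    def test_equals_plain_fit_on_pre_centered_data(self, rng):
        D = center_dataset(random_dataset(rng))
        np.testing.assert_allclose(
            fit_centered_least_squares(D).values,
            fit_least_squares(D).values,
            atol=1e-10,
        )

    def test_invariant_to_constant_expression_shift(self, rng):
        D = random_dataset(rng)
        shifted = D.replace(G=D.G.with_values(D.G.values + 7.5))
        np.testing.assert_allclose(
            fit_centered_least_squares(D).values,
            fit_centered_least_squares(shifted).values,
            atol=1e-10,
        )

    def test_invariant_to_per_gene_offsets(self, rng):
        D = random_dataset(rng)
        offsets = rng.standard_normal((D.n_genes, 1))
        shifted = D.replace(G=D.G.with_values(D.G.values + offsets))
        np.testing.assert_allclose(
            fit_centered_least_squares(D).values,
            fit_centered_least_squares(shifted).values,
            atol=1e-10,
        )


class TestRidge:
    def test_scalar_closed_form(self):
        coef = fit_ridge(scalar_dataset(2.0), lam1=1.0, lam2=1.0)
        assert coef.values[0, 0] == pytest.approx(0.5)

    def test_zero_penalty_equals_least_squares_on_full_rank(self, rng):
        D = random_dataset(rng, 8, 6, 3, 2)
        np.testing.assert_allclose(
            fit_ridge(D, 0.0, 0.0).values, fit_least_squares(D).values, atol=1e-8
        )

    def test_matches_direct_inversion_oracle(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        lam1, lam2 = 0.7, 1.3
        M, G, T = D.M.values, D.G.values, D.T.values
        oracle = (
            np.linalg.inv(M.T @ M + lam1 * np.eye(3))
            @ M.T @ G @ T.T
            @ np.linalg.inv(T @ T.T + lam2 * np.eye(2))
        )
        np.testing.assert_allclose(
            fit_ridge(D, lam1, lam2).values, oracle, atol=1e-10
        )

    def test_norm_shrinks_along_penalty_grid(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        norms = [
            np.linalg.norm(fit_ridge(D, lam, lam).values)
            for lam in np.geomspace(1e-3, 1e3, 10)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_singular_unpenalised_system_rejected(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2, rank_deficient=True)
        with pytest.raises(SingularSystemError):
            fit_ridge(D, 0.0, 0.0)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ParameterError):
            fit_ridge(random_dataset(rng), -1.0, 0.0)


class TestCenteredRidge:
    def test_equals_composition_of_center_then_ridge(self, rng):
        D = random_dataset(rng)
        np.testing.assert_allclose(
            fit_centered_ridge(D, 0.5, 0.5).values,
            fit_ridge(center_dataset(D), 0.5, 0.5).values,
            atol=1e-12,
        )

    def test_invariant_to_constant_expression_shift(self, rng):
        D = random_dataset(rng)
        shifted = D.replace(G=D.G.with_values(D.G.values - 3.0))
        np.testing.assert_allclose(
            fit_centered_ridge(D).values, fit_centered_ridge(shifted).values,
            atol=1e-10,
        )


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,tau,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)]
    )
    def test_examples(self, x, tau, expected):
        assert soft_threshold(x, tau) == expected

    @given(st.floats(-1e6, 1e6))
    def test_zero_threshold_is_identity(self, x):
        assert soft_threshold(x, 0.0) == x

    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_towards_zero_and_is_odd(self, x, tau):
        y = soft_threshold(x, tau)
        assert abs(y) <= abs(x)
        assert soft_threshold(-x, tau) == -y

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            soft_threshold(1.0, -0.1)


class TestSparse:
    @pytest.mark.parametrize("lam,expected", [(0.0, 1.0), (1.0, 0.5), (2.0, 0.0)])
    def test_scalar_lasso_closed_form(self, lam, expected):
        coef = fit_sparse(scalar_dataset(1.0), lam=lam, tol=1e-12, max_iter=100000)
        assert coef.values[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_unpenalised_fit_reaches_least_squares_rss(self, rng):
        D = random_dataset(rng, 8, 6, 3, 2)
        sparse_rss = fit_sparse(D, lam=0.0, tol=1e-12, max_iter=200000).diagnostics["rss"]
        ls_rss = fit_least_squares(D).diagnostics["rss"]
        assert sparse_rss == pytest.approx(ls_rss, abs=1e-6)

    def test_matches_coordinate_descent_lasso_oracle(self, rng):
        Lasso = pytest.importorskip("sklearn.linear_model").Lasso
        for _ in range(10):
            D = random_dataset(rng, 4, 3, 2, 3)
            lam = 0.3
            coef = fit_sparse(D, lam=lam, tol=1e-12, max_iter=200000)
            X = vectorized_design(D)
            y = D.G.values.ravel(order="F")
            oracle = Lasso(
                alpha=lam / (2 * len(y)), fit_intercept=False,
                tol=1e-14, max_iter=1_000_000,
            ).fit(X, y)
            np.testing.assert_allclose(
                coef.values,
                oracle.coef_.reshape(D.n_motifs, D.n_tfs, order="F"),
                atol=1e-6,
            )

    def test_objective_never_increases(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        coef = fit_sparse(D, lam=0.5)
        path = np.array(coef.diagnostics["objective_path"])
        assert (np.diff(path) <= 1e-9).all()

    def test_all_zero_at_lambda_max(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        coef = fit_sparse(D, lam=lambda_max(D))
        assert np.abs(coef.values).max() == 0

    def test_nonconvergence_warns_but_returns(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        with pytest.warns(UserWarning, match="did not converge"):
            coef = fit_sparse(D, lam=0.01, max_iter=2, tol=1e-14)
        assert coef.diagnostics["converged"] is False


class TestSparsePath:
    def test_zero_solution_at_path_start(self, rng):
        path = sparse_path(random_dataset(rng, 6, 5, 3, 2), n_lambdas=5)
        assert np.abs(path.estimates[0].values).max() == 0
        assert (np.diff(path.lambdas) < 0).all()

    def test_support_grows_towards_small_penalties(self, rng):
        path = sparse_path(random_dataset(rng, 8, 6, 3, 3), n_lambdas=8)
        first = np.count_nonzero(path.estimates[0].values)
        last = np.count_nonzero(path.estimates[-1].values)
        assert last >= first

    def test_dominant_coefficient_enters_first(self, rng):
        D = random_dataset(rng, 40, 20, 3, 3)
        A_true = np.full((3, 3), 0.1)
        A_true[1, 2] = 10.0
        G = D.M.values @ A_true @ D.T.values
        D = D.replace(G=D.G.with_values(G))
        path = sparse_path(D, n_lambdas=30)
        # lambda_max-ordering oracle: the first active pair maximises |M'GT'|
        corr = np.abs(D.M.values.T @ G @ D.T.values.T)
        k, l = np.unravel_index(np.argmax(corr), corr.shape)
        assert path.entry_order[0] == (D.motifs[k], D.tfs[l])
        assert path.entry_order[0] == ("mo2", "tf3")


class TestCorrelation:
    def test_constant_expression_yields_zero(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        D = D.replace(G=D.G.with_values(np.full((6, 5), 4.0)))
        assert np.abs(fit_correlation(D).values).max() == 0

    def test_matches_triple_sum_oracle(self, rng):
        n, p, m, t = 3, 2, 2, 2
        D = random_dataset(rng, n, p, m, t)
        G, M, T = D.G.values, D.M.values, D.T.values
        got = fit_correlation(D).values
        g_bar = G.mean()
        for k in range(m):
            for l in range(t):
                num = sum(
                    (G[i, j] - g_bar)
                    * (M[i, k] - M[:, k].mean())
                    * (T[l, j] - T[l].mean())
                    for i in range(n) for j in range(p)
                ) / (n * p)
                expected = num / (M[:, k].var() * T[l].var())
                assert got[k, l] == pytest.approx(expected, rel=1e-10)

    def test_recovers_single_true_coefficient(self):
        D, _ = consistency_dataset(seed=0)
        A = fit_correlation(D).values
        assert 0.9 <= A[0, 0] <= 1.1
        assert np.abs(A).ravel()[1:].max() < 0.1

    def test_unrelated_predictors_do_not_move_the_coefficient(self):
        D, _ = consistency_dataset(seed=0, m=4, t=4)
        full = fit_correlation(D).values[0, 0]
        reduced = RegulatoryDataset(
            G=D.G,
            M=D.M.select(None, ["mo1", "mo3"]),
            T=D.T.select(["tf1", "tf4"], None),
        )
        assert fit_correlation(reduced).values[0, 0] == full

    def test_centered_ls_approximates_correlation_under_independence(self):
        D, _ = consistency_dataset(seed=0)
        diff = np.abs(
            fit_correlation(D).values - fit_centered_least_squares(D).values
        )
        assert diff.max() < 0.15

    def test_constant_column_reported_as_degenerate(self, rng):
        D = random_dataset(rng, 6, 5, 3, 2)
        M = D.M.values.copy()
        M[:, 1] = 2.0
        D = D.replace(M=D.M.with_values(M))
        with pytest.warns(UserWarning, match="constant"):
            coef = fit_correlation(D)
        degenerate = coef.diagnostics["degenerate_pairs"]
        assert {pair[0] for pair in degenerate} == {"mo2"}
        assert np.abs(coef.values[1]).max() == 0


class TestEstimatorInvariances:
    @pytest.mark.parametrize(
        "name,kwargs",
        [
            ("ls", {}),
            ("centered-ls", {}),
            ("ridge", {"lam1": 0.5, "lam2": 0.5}),
            ("centered-ridge", {}),
            ("sparse", {"lam": 0.2}),
            ("correlation", {}),
        ],
    )
    def test_invariant_to_consistent_reordering(self, rng, name, kwargs):
        """Permuting gene order in (G, M) and experiment order in (G, T)
        together must not change any estimate."""
        D = random_dataset(rng, 7, 6, 3, 2)
        gene_perm = rng.permutation(7)
        exp_perm = rng.permutation(6)
        genes = [D.genes[i] for i in gene_perm]
        exps = [D.experiments[j] for j in exp_perm]
        D_perm = RegulatoryDataset(
            G=D.G.select(genes, exps),
            M=D.M.select(genes, None),
            T=D.T.select(None, exps),
        )
        fit = get_estimator(name, **kwargs)
        np.testing.assert_allclose(
            fit(D).values, fit(D_perm).values, atol=1e-8
        )

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ParameterError):
            get_estimator("pls")
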