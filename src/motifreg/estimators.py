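"""Estimators for the coefficient matrix A in G = M A T + E.

The model is the classical growth-curve (GMANOVA) form: expression G
(genes x experiments) is explained by a motif design M on the left and a
TF-expression design T on the right, linked by the unknown motif x TF
coefficient matrix A.  Large |a_kl| flags a putative association between
motif k and transcription factor l.

Implemented estimators
----------------------
``fit_least_squares``
    Minimum-norm least squares, A = M+ G T+ with Moore-Penrose
    pseudoinverses; reduces to (M'M)^-1 M' G T' (TT')^-1 when M has full
    column rank and T full row rank.
``fit_centered_least_squares``
    Least squares after centering: motif columns centered over genes, TF
    rows centered over experiments, G double-centered.  Centering removes
    additive per-gene / per-experiment effects and decorrelates the
    bilinear predictors.
``fit_ridge`` / ``fit_centered_ridge``
    Two-sided Tikhonov shrinkage (M'M + l1 I)^-1 M' G T' (TT' + l2 I)^-1.
``fit_sparse``
    Entry-wise L1-penalised fit, objective ||G - MAT||_F^2 + lam*||A||_1,
    minimised by iterative soft-thresholding (proximal gradient) from
    A = 0.
``sparse_path``
    Warm-started geometric lambda grid from lambda_max down, recording the
    order in which coefficients first become nonzero.
``fit_correlation``
    Per-coefficient moment estimator a_kl = E[g~ m~_k t~_l] /
    (Var m_k * Var t_l); consistent under pairwise independence of the
    predictors and touches only motif k, TF l and G, so it is unaffected
    by motifs/TFs missing from the data.

Objective scaling for the sparse fit is fixed so that the scalar problem
(n = p = m = t = 1, M = T = [1]) has the closed form a = S_{lam/2}(g) and
the smallest all-zero penalty is lambda_max = 2 * max|M' G T'|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import LabeledMatrix, RegulatoryDataset
from .errors import ParameterError, SingularSystemError, ValidationError


@dataclass
class CoefficientMatrix:
    """An estimate of A together with how it was obtained.

    ``A`` is a motifs x TFs :class:`LabeledMatrix`; ``diagnostics`` carries
    at least ``rss`` and, for iterative fits, ``iterations`` and
    ``converged``.
    """

    A: LabeledMatrix
    method: str
    hyperparameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.A.values


def _coef_values(A: "CoefficientMatrix | LabeledMatrix") -> LabeledMatrix:
    return A.A if isinstance(A, CoefficientMatrix) else A


def _check_labels(D: RegulatoryDataset, A: LabeledMatrix) -> None:
    if A.row_ids != D.motifs or A.col_ids != D.tfs:
        raise ValidationError(
            "coefficient labels do not match the dataset's motifs x TFs"
        )


def predict(
    D: RegulatoryDataset, A: "CoefficientMatrix | LabeledMatrix"
) -> LabeledMatrix:
    """Model prediction G_hat = M A T, labeled like G."""
    A = _coef_values(A)
    _check_labels(D, A)
    return D.G.with_values(D.M.values @ A.values @ D.T.values)


@dataclass(frozen=True)
class FitStatistics:
    rss: float
    total_ss: float
    explained_ss: float


def goodness_of_fit(
    D: RegulatoryDataset, A: "CoefficientMatrix | LabeledMatrix"
) -> FitStatistics:
    """Residual, total (around the grand mean) and explained sums of squares."""
    G_hat = predict(D, A)
    rss = float(((D.G.values - G_hat.values) ** 2).sum())
    total = float(((D.G.values - D.G.values.mean()) ** 2).sum())
    return FitStatistics(rss=rss, total_ss=total, explained_ss=total - rss)


def _pinv(X: np.ndarray) -> np.ndarray:
    # numerical rank cutoff: singular values below max(dim)*eps*sigma_1
    return np.linalg.pinv(X, rcond=max(X.shape) * np.finfo(float).eps)


def _labeled_A(D: RegulatoryDataset, values: np.ndarray) -> LabeledMatrix:
    return LabeledMatrix(values, D.motifs, D.tfs)


def _with_rss(D: RegulatoryDataset, coef: CoefficientMatrix) -> CoefficientMatrix:
    coef.diagnostics["rss"] = goodness_of_fit(D, coef).rss
    return coef


def fit_least_squares(D: RegulatoryDataset) -> CoefficientMatrix:
    """Minimum-norm least squares, A = M+ G T+.

    Always defined: with rank-deficient designs it returns the minimizer of
    the residual with smallest Frobenius norm.
    """
    A = _pinv(D.M.values) @ D.G.values @ _pinv(D.T.values)
    return _with_rss(D, CoefficientMatrix(_labeled_A(D, A), "ls"))


def center_dataset(D: RegulatoryDataset, g_mode: str = "double") -> RegulatoryDataset:
    """Center the dataset: M column-wise, T row-wise, G per ``g_mode``.

    ``g_mode`` is one of ``row``, ``column`` or ``double`` (default):
    double centering subtracts row and column means and adds back the
    grand mean, removing additive per-gene and per-experiment effects.
    """
    if D.n_genes < 2 or D.n_experiments < 2:
        raise ParameterError("centering needs at least 2 genes and 2 experiments")
    if g_mode not in {"row", "column", "double"}:
        raise ParameterError(f"unknown centering mode {g_mode!r}")
    G = D.G.values
    if g_mode == "row":
        Gc = G - G.mean(axis=1, keepdims=True)
    elif g_mode == "column":
        Gc = G - G.mean(axis=0, keepdims=True)
    else:
        Gc = (
            G
            - G.mean(axis=1, keepdims=True)
            - G.mean(axis=0, keepdims=True)
            + G.mean()
        )
    Mc = D.M.values - D.M.values.mean(axis=0, keepdims=True)
    Tc = D.T.values - D.T.values.mean(axis=1, keepdims=True)
    return RegulatoryDataset(
        G=D.G.with_values(Gc), M=D.M.with_values(Mc), T=D.T.with_values(Tc)
    )


def fit_centered_least_squares(
    D: RegulatoryDataset, g_mode: str = "double"
) -> CoefficientMatrix:
    """Least squares on the centered dataset (rss reported on centered data)."""
    Dc = center_dataset(D, g_mode=g_mode)
    coef = fit_least_squares(Dc)
    coef.method = "centered-ls"
    coef.hyperparameters["g_mode"] = g_mode
    return coef


def _check_ridge_rank(D: RegulatoryDataset, lam1: float, lam2: float) -> None:
    if lam1 == 0 and np.linalg.matrix_rank(D.M.values) < D.n_motifs:
        raise SingularSystemError(
            "lam1 = 0 with rank-deficient M: the Gram matrix is singular; "
            "use fit_least_squares for the minimum-norm solution"
        )
    if lam2 == 0 and np.linalg.matrix_rank(D.T.values) < D.n_tfs:
        raise SingularSystemError(
            "lam2 = 0 with rank-deficient T: the Gram matrix is singular; "
            "use fit_least_squares for the minimum-norm solution"
        )


def fit_ridge(
    D: RegulatoryDataset, lam1: float = 1.0, lam2: float = 1.0
) -> CoefficientMatrix:
    """Two-sided ridge: A = (M'M + lam1 I)^-1 M' G T' (TT' + lam2 I)^-1.

    Computed with linear solves, never explicit inverses.
    """
    if lam1 < 0 or lam2 < 0:
        raise ParameterError("ridge penalties must be >= 0")
    _check_ridge_rank(D, lam1, lam2)
    M, G, T = D.M.values, D.G.values, D.T.values
    left = M.T @ M + lam1 * np.eye(D.n_motifs)
    right = T @ T.T + lam2 * np.eye(D.n_tfs)
    X = np.linalg.solve(left, M.T @ G @ T.T)
    A = np.linalg.solve(right, X.T).T  # right side is symmetric
    coef = CoefficientMatrix(
        _labeled_A(D, A), "ridge", {"lam1": lam1, "lam2": lam2}
    )
    return _with_rss(D, coef)


def fit_centered_ridge(
    D: RegulatoryDataset, lam1: float = 1.0, lam2: float = 1.0, g_mode: str = "double"
) -> CoefficientMatrix:
    """Ridge on the centered dataset."""
    Dc = center_dataset(D, g_mode=g_mode)
    coef = fit_ridge(Dc, lam1=lam1, lam2=lam2)
    coef.method = "centered-ridge"
    coef.hyperparameters["g_mode"] = g_mode
    return coef


def soft_threshold(x, tau):
    """S_tau(x) = sign(x) * max(|x| - tau, 0), elementwise."""
    if np.any(np.asarray(tau) < 0):
        raise ParameterError("soft-threshold level must be >= 0")
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def lambda_max(D: RegulatoryDataset) -> float:
    """Smallest L1 penalty at which the sparse fit is exactly zero."""
    return 2.0 * float(np.abs(D.M.values.T @ D.G.values @ D.T.values.T).max())


def fit_sparse(
    D: RegulatoryDataset,
    lam: float,
    mu: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
    A0: np.ndarray | None = None,
) -> CoefficientMatrix:
    """L1-penalised fit by iterative soft-thresholding.

    Minimises ||G - M A T||_F^2 + lam * ||A||_1 with the proximal-gradient
    iteration A <- S_{mu*lam/2}(A + mu * M'(G - M A T)T'), starting from
    A = 0 (or ``A0`` for warm starts).  The automatic step size
    mu = 0.9 / (s1(M)^2 * s1(T)^2) (s1 = largest singular value) keeps the
    iteration a descent method, since the smooth part has Lipschitz
    gradient constant 2 s1(M)^2 s1(T)^2.  Coefficients with magnitude
    below ``tol`` are snapped to exact zero so the support is well
    defined.  Non-convergence yields ``converged=False`` and a warning,
    not an exception.
    """
    if lam < 0:
        raise ParameterError("lam must be >= 0")
    if tol <= 0 or max_iter < 1:
        raise ParameterError("tol must be > 0 and max_iter >= 1")
    M, G, T = D.M.values, D.G.values, D.T.values
    if mu is None:
        s1m = np.linalg.norm(M, 2)
        s1t = np.linalg.norm(T, 2)
        if s1m == 0 or s1t == 0:
            raise ParameterError("cannot derive a step size: M or T is zero")
        mu = 0.9 / (s1m**2 * s1t**2)
    elif mu <= 0:
        raise ParameterError("mu must be > 0")

    A = np.zeros((D.n_motifs, D.n_tfs)) if A0 is None else np.array(A0, dtype=float)
    MtG_Tt = M.T @ G @ T.T
    MtM = M.T @ M
    TTt = T @ T.T

    def objective(A_):
        resid = G - M @ A_ @ T
        return float((resid**2).sum() + lam * np.abs(A_).sum())

    objective_path = [objective(A)]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        grad_half = MtG_Tt - MtM @ A @ TTt  # = M'(G - MAT)T'
        A_next = soft_threshold(A + mu * grad_half, mu * lam / 2.0)
        delta = float(np.abs(A_next - A).max())
        A = A_next
        objective_path.append(objective(A))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sparse fit did not converge in {max_iter} iterations "
            f"(last step {delta:.3g} >= tol {tol:.3g})",
            stacklevel=2,
        )
    A[np.abs(A) < tol] = 0.0
    coef = CoefficientMatrix(
        _labeled_A(D, A),
        "sparse",
        {"lam": lam, "mu": mu, "tol": tol, "max_iter": max_iter},
        {
            "iterations": iterations,
            "converged": converged,
            "objective_path": objective_path,
        },
    )
    return _with_rss(D, coef)


@dataclass
class PathResult:
    """Sparse fits along a decreasing lambda grid with entry bookkeeping."""

    lambdas: np.ndarray
    estimates: list[CoefficientMatrix]
    entry_order: list[tuple[str, str]]


def sparse_path(
    D: RegulatoryDataset,
    n_lambdas: int = 20,
    lambda_min_ratio: float = 0.01,
    **sparse_kwargs,
) -> PathResult:
    """Warm-started sparse fits on a geometric lambda grid.

    The grid runs from lambda_max (all-zero solution) down to
    lambda_max * lambda_min_ratio.  ``entry_order`` lists (motif, TF)
    pairs by the first grid index at which they are nonzero, ties broken
    by magnitude at that index (larger first), then lexicographically.
    """
    if n_lambdas < 2:
        raise ParameterError("n_lambdas must be >= 2")
    if not 0 < lambda_min_ratio < 1:
        raise ParameterError("lambda_min_ratio must be in (0, 1)")
    lmax = lambda_max(D)
    if lmax == 0:
        lambdas = np.zeros(n_lambdas)
    else:
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    estimates: list[CoefficientMatrix] = []
    A_warm: np.ndarray | None = None
    first_index: dict[tuple[str, str], tuple[int, float]] = {}
    for idx, lam in enumerate(lambdas):
        coef = fit_sparse(D, lam=float(lam), A0=A_warm, **sparse_kwargs)
        A_warm = coef.values.copy()
        estimates.append(coef)
        nz = np.argwhere(coef.values != 0)
        for k, l in nz:
            pair = (D.motifs[k], D.tfs[l])
            if pair not in first_index:
                first_index[pair] = (idx, abs(float(coef.values[k, l])))
    entry_order = sorted(
        first_index,
        key=lambda pair: (first_index[pair][0], -first_index[pair][1], pair),
    )
    return PathResult(lambdas=lambdas, estimates=estimates, entry_order=entry_order)


def fit_correlation(D: RegulatoryDataset) -> CoefficientMatrix:
    """Per-coefficient third-moment estimator.

    a_kl = mean over all (i, j) of (g_ij - gbar)(m_ik - mbar_k)(t_lj - tbar_l)
    divided by Var(m_k) * Var(t_l), with population (divide-by-count)
    moments.  Each coefficient depends only on G, motif column k and TF
    row l, so removing unrelated motifs/TFs cannot change it.  Pairs with
    a constant motif column or TF row get coefficient 0 and are listed in
    ``diagnostics["degenerate_pairs"]``.
    """
    M, G, T = D.M.values, D.G.values, D.T.values
    n, p = G.shape
    Gc = G - G.mean()
    Mc = M - M.mean(axis=0, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    numerator = (Mc.T @ Gc @ Tc.T) / (n * p)
    var_m = M.var(axis=0)
    var_t = T.var(axis=1)
    denom = np.outer(var_m, var_t)
    degenerate_mask = denom == 0
    A = np.zeros_like(numerator)
    np.divide(numerator, denom, out=A, where=~degenerate_mask)
    degenerate = [
        (D.motifs[k], D.tfs[l]) for k, l in np.argwhere(degenerate_mask)
    ]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} coefficient(s) involve a constant motif column "
            "or TF row; set to 0",
            stacklevel=2,
        )
    coef = CoefficientMatrix(
        _labeled_A(D, A), "correlation", {}, {"degenerate_pairs": degenerate}
    )
    return _with_rss(D, coef)


# ---------------------------------------------------------------------------
# Estimator registry
# ---------------------------------------------------------------------------

Estimator = Callable[[RegulatoryDataset], CoefficientMatrix]

ESTIMATORS: dict[str, Callable[..., CoefficientMatrix]] = {
    "ls": fit_least_squares,
    "centered-ls": fit_centered_least_squares,
    "ridge": fit_ridge,
    "centered-ridge": fit_centered_ridge,
    "sparse": fit_sparse,
    "correlation": fit_correlation,
}


def get_estimator(name: str, **hyperparameters) -> Estimator:
    """Resolve an estimator name (+ hyperparameters) to a dataset callable.

    For ``sparse``, ``lam_ratio`` may be given instead of ``lam``; the
    penalty is then ``lam_ratio * lambda_max(D)``, resolved per dataset.
    """
    if name not in ESTIMATORS:
        raise ParameterError(
            f"unknown estimator {name!r}; choose from {sorted(ESTIMATORS)}"
        )
    fn = ESTIMATORS[name]
    if name == "sparse" and "lam_ratio" in hyperparameters:
        ratio = hyperparameters.pop("lam_ratio")
        if "lam" in hyperparameters:
            raise ParameterError("give either lam or lam_ratio, not both")
        if not 0 <= ratio <= 1:
            raise ParameterError("lam_ratio must be in [0, 1]")

        def estimator(D: RegulatoryDataset) -> CoefficientMatrix:
            return fn(D, lam=ratio * lambda_max(D), **hyperparameters)

        return estimator
    return lambda D: fn(D, **hyperparameters)
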