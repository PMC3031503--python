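"""Significance and reporting for fitted coefficient matrices.

* permutation z-scores against the null obtained by shuffling the rows and
  columns of G (which decouples expression from both designs),
* an F-test of overall model significance,
* ranking of (motif, TF) pairs by score, and
* split-set stability: fit on two disjoint halves of the experiments and
  test the top-k overlap against a hypergeometric null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy import stats

from .data import LabeledMatrix, RegulatoryDataset
from .errors import MotifregError, ParameterError
from .estimators import CoefficientMatrix, get_estimator, goodness_of_fit

EstimatorSpec = Union[str, Callable[[RegulatoryDataset], CoefficientMatrix]]


def _resolve_estimator(estimator: EstimatorSpec, **hyper):
    if callable(estimator):
        if hyper:
            raise ParameterError("hyperparameters only apply to named estimators")
        return estimator
    return get_estimator(estimator, **hyper)


def permute_expression(G: LabeledMatrix, seed: int) -> LabeledMatrix:
    """Shuffle G's rows and columns with two independent permutations.

    Labels stay attached to their original positions, so the permuted
    matrix is decoupled from M and T — which is the point of the null.
    """
    rng = np.random.default_rng(seed)
    row_perm = rng.permutation(G.shape[0])
    col_perm = rng.permutation(G.shape[1])
    return G.with_values(G.values[row_perm][:, col_perm])


@dataclass
class ZScoreMatrix:
    """Coefficient z-scores against the permutation null.

    z_kl = (a_kl - mean of permuted a_kl) / population sd of permuted
    a_kl.  Pairs whose permuted estimates have zero spread get z = 0 and
    are listed in ``degenerate_pairs``.
    """

    Z: LabeledMatrix
    permutations: int
    seed: int
    degenerate_pairs: list[tuple[str, str]]


def zscores(
    D: RegulatoryDataset,
    estimator: EstimatorSpec,
    r: int = 30,
    seed: int = 0,
    **hyperparameters,
) -> ZScoreMatrix:
    """Randomization z-scores for every coefficient.

    The estimator is fitted once on the real data and ``r`` times on
    datasets whose G was row/column-shuffled (seeds ``seed+1 .. seed+r``).
    """
    if r < 2:
        raise ParameterError(f"need at least 2 permutations, got {r}")
    fit = _resolve_estimator(estimator, **hyperparameters)
    observed = fit(D).values
    permuted = np.empty((r, *observed.shape))
    for i in range(1, r + 1):
        G_null = permute_expression(D.G, seed + i)
        try:
            permuted[i - 1] = fit(D.replace(G=G_null)).values
        except Exception as exc:
            raise MotifregError(f"estimator failed on permutation {i}: {exc}") from exc
    mean = permuted.mean(axis=0)
    sd = permuted.std(axis=0)  # population sd
    degenerate_mask = sd == 0
    Z = np.zeros_like(observed)
    np.divide(observed - mean, sd, out=Z, where=~degenerate_mask)
    degenerate = [(D.motifs[k], D.tfs[l]) for k, l in np.argwhere(degenerate_mask)]
    return ZScoreMatrix(
        Z=LabeledMatrix(Z, D.motifs, D.tfs),
        permutations=r,
        seed=seed,
        degenerate_pairs=degenerate,
    )


@dataclass(frozen=True)
class FTestResult:
    F: float
    df1: int
    df2: int
    p: float


def f_test(D: RegulatoryDataset, A: CoefficientMatrix | LabeledMatrix) -> FTestResult:
    """Overall model significance.

    F = (ess/df1) / (rss/df2) with df1 = rank(M)*rank(T) identifiable
    parameters and df2 = n*p - df1 - 1 (grand mean absorbed); p is the
    upper tail of F(df1, df2).  A perfect fit (rss = 0) gets p = 0 by
    convention.  A model fitting worse than the grand mean has its F
    clamped at 0 (p = 1).
    """
    stats_ = goodness_of_fit(D, A)
    df1 = int(np.linalg.matrix_rank(D.M.values) * np.linalg.matrix_rank(D.T.values))
    df2 = D.n_genes * D.n_experiments - df1 - 1
    if df2 <= 0:
        raise ParameterError(f"model saturated: df2 = {df2} <= 0")
    if stats_.rss == 0:
        return FTestResult(F=math.inf, df1=df1, df2=df2, p=0.0)
    F = max((stats_.explained_ss / df1) / (stats_.rss / df2), 0.0)
    p = float(stats.f.sf(F, df1, df2))
    return FTestResult(F=F, df1=df1, df2=df2, p=p)


@dataclass
class RankedPairs:
    """Ordered (motif, TF, score) triples."""

    entries: list[tuple[str, str, float]]

    def pairs(self) -> list[tuple[str, str]]:
        return [(m, t) for m, t, _ in self.entries]


def rank_pairs(
    S: LabeledMatrix, direction: str = "largest", top: int = 10
) -> RankedPairs:
    """Flatten a score matrix and return the top pairs.

    ``direction`` is ``largest`` (most positive first), ``smallest`` (most
    negative first) or ``absolute`` (largest magnitude first).  Ties are
    broken by motif id then TF id, lexicographically.
    """
    if top < 1:
        raise ParameterError(f"top must be >= 1, got {top}")
    if direction not in {"largest", "smallest", "absolute"}:
        raise ParameterError(f"unknown direction {direction!r}")
    triples = [
        (m, t, float(S.values[k, l]))
        for k, m in enumerate(S.row_ids)
        for l, t in enumerate(S.col_ids)
    ]
    if direction == "largest":
        key = lambda e: (-e[2], e[0], e[1])
    elif direction == "smallest":
        key = lambda e: (e[2], e[0], e[1])
    else:
        key = lambda e: (-abs(e[2]), e[0], e[1])
    triples.sort(key=key)
    return RankedPairs(entries=triples[: min(top, len(triples))])


def write_ranked_pairs(ranked: RankedPairs, path) -> None:
    """Three-column TSV with header motif/tf/score."""
    from pathlib import Path

    lines = ["motif\ttf\tscore"]
    lines += [f"{m}\t{t}\t{format(s, '.17g')}" for m, t, s in ranked.entries]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class StabilityResult:
    """Top-k overlap between rankings fitted on two halves of the data."""

    top_k: int
    overlap: int
    p_value: float
    split_sizes: tuple[int, int]
    seed: int


def hypergeom_overlap_pvalue(N: int, top_k: int, overlap: int) -> float:
    """Upper-tail P(X >= overlap) when two size-top_k draws from N pairs
    are independent and uniform."""
    return float(stats.hypergeom.sf(overlap - 1, N, top_k, top_k))


def split_set_stability(
    D: RegulatoryDataset,
    estimator: EstimatorSpec,
    top_k: int = 10,
    seed: int = 0,
    direction: str = "absolute",
    **hyperparameters,
) -> StabilityResult:
    """Fit on two disjoint random halves of the experiments and measure
    the overlap of their top-k (motif, TF) rankings.

    The p-value is the hypergeometric upper tail over the universe of all
    m*t pairs (both halves ranking the same universe).
    """
    p = D.n_experiments
    if p < 4:
        raise ParameterError(f"need at least 4 experiments, got {p}")
    if top_k > D.n_motifs * D.n_tfs:
        raise ParameterError("top_k exceeds the number of (motif, TF) pairs")
    fit = _resolve_estimator(estimator, **hyperparameters)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(p)
    half1 = sorted(perm[: (p + 1) // 2])
    half2 = sorted(perm[(p + 1) // 2 :])
    tops = []
    for index, half in enumerate((half1, half2), start=1):
        exps = [D.experiments[j] for j in half]
        D_half = RegulatoryDataset(
            G=D.G.select(None, exps), M=D.M, T=D.T.select(None, exps)
        )
        try:
            coef = fit(D_half)
        except Exception as exc:
            raise MotifregError(f"estimator failed on half {index}: {exc}") from exc
        tops.append(set(rank_pairs(coef.A, direction=direction, top=top_k).pairs()))
    overlap = len(tops[0] & tops[1])
    p_value = hypergeom_overlap_pvalue(D.n_motifs * D.n_tfs, top_k, overlap)
    return StabilityResult(
        top_k=top_k,
        overlap=overlap,
        p_value=p_value,
        split_sizes=(len(half1), len(half2)),
        seed=seed,
    )
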