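"""Synthetic datasets from the generative model and the recovery benchmark.

Data are drawn from the model itself: motif counts M ~ Poisson(motif_rate)
i.i.d., TF expression T ~ Normal(0, tf_sd^2) i.i.d., a sparse coefficient
matrix A with a uniformly random support of round(density*m*t) cells whose
values are Normal(0, coef_sd^2), and G = M A T + E with i.i.d. Gaussian
noise E.  Estimators are scored by how well ranking cells by |a_hat|
recovers the true nonzero support (ROC AUC).

Default dimensions mimic a yeast compendium at desk scale: thousands of
genes, tens of experiments, motifs and TFs, sparse true coupling.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import LabeledMatrix, RegulatoryDataset, write_matrix_tsv
from .errors import ParameterError, ValidationError
from .estimators import CoefficientMatrix, get_estimator
from .inference import EstimatorSpec


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters (all unitless).

    density is the fraction of nonzero cells of A; motif_rate the Poisson
    mean of motif counts; tf_sd / coef_sd / noise_sd the standard
    deviations of TF expression, nonzero coefficients and additive noise.
    """

    n: int = 1000
    p: int = 80
    m: int = 40
    t: int = 50
    density: float = 0.05
    coef_sd: float = 1.0
    motif_rate: float = 0.3
    tf_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.p, self.m, self.t) < 1:
            raise ParameterError("all dimensions must be >= 1")
        if not 0 < self.density <= 1:
            raise ParameterError("density must be in (0, 1]")
        if min(self.coef_sd, self.tf_sd, self.noise_sd) < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.motif_rate < 0:
            raise ParameterError("motif_rate must be >= 0")

    def replace(self, **kwargs) -> "SimulationSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated dataset together with its ground-truth A."""

    data: RegulatoryDataset
    A_true: LabeledMatrix
    spec: SimulationSpec


def _ids(prefix: str, count: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(count))


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one dataset; bit-reproducible from ``spec.seed``.

    The draw order is fixed (M, T, support, coefficients, noise) so that
    datasets sharing a seed but differing only in ``noise_sd`` share the
    same M, T and A.
    """
    rng = np.random.default_rng(spec.seed)
    M = rng.poisson(spec.motif_rate, size=(spec.n, spec.m)).astype(float)
    T = rng.normal(0.0, spec.tf_sd, size=(spec.t, spec.p))
    n_nonzero = int(round(spec.density * spec.m * spec.t))
    A = np.zeros((spec.m, spec.t))
    support = rng.choice(spec.m * spec.t, size=n_nonzero, replace=False)
    A.ravel()[support] = rng.normal(0.0, spec.coef_sd, size=n_nonzero)
    # scale-after-draw keeps the rng stream identical across noise levels
    E = rng.standard_normal((spec.n, spec.p)) * spec.noise_sd
    G = M @ A @ T + E
    genes, exps = _ids("g", spec.n), _ids("e", spec.p)
    motifs, tfs = _ids("mo", spec.m), _ids("tf", spec.t)
    return SimulatedDataset(
        data=RegulatoryDataset(
            G=LabeledMatrix(G, genes, exps),
            M=LabeledMatrix(M, genes, motifs),
            T=LabeledMatrix(T, tfs, exps),
        ),
        A_true=LabeledMatrix(A, motifs, tfs),
        spec=spec,
    )


def perturb_missing(
    sim: SimulatedDataset,
    drop_motifs: float = 0.0,
    drop_tfs: float = 0.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Remove a random subset of motif columns and TF rows.

    G is untouched: it was generated with the full model, so the removed
    regulators become unmodeled influence — the realistic situation where
    the motif/TF catalogue is incomplete.  A_true is restricted to the
    survivors for scoring.
    """
    for name, frac in (("drop_motifs", drop_motifs), ("drop_tfs", drop_tfs)):
        if not 0 <= frac < 1:
            raise ParameterError(f"{name} must be in [0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    D = sim.data
    n_drop_m = int(round(drop_motifs * D.n_motifs))
    n_drop_t = int(round(drop_tfs * D.n_tfs))
    if n_drop_m >= D.n_motifs or n_drop_t >= D.n_tfs:
        raise ParameterError("dropping would leave zero motifs or TFs")
    drop_m = set(rng.choice(D.n_motifs, size=n_drop_m, replace=False).tolist())
    drop_t = set(rng.choice(D.n_tfs, size=n_drop_t, replace=False).tolist())
    motifs = [m for k, m in enumerate(D.motifs) if k not in drop_m]
    tfs = [t for l, t in enumerate(D.tfs) if l not in drop_t]
    return SimulatedDataset(
        data=RegulatoryDataset(
            G=D.G, M=D.M.select(None, motifs), T=D.T.select(tfs, None)
        ),
        A_true=sim.A_true.select(motifs, tfs),
        spec=sim.spec,
    )


def recovery_auc(
    A_hat: LabeledMatrix | CoefficientMatrix, A_true: LabeledMatrix
) -> float:
    """ROC AUC of ranking cells by |a_hat| against the nonzero support.

    Computed as the tie-corrected Mann-Whitney statistic (tied scores
    contribute 1/2).  Requires at least one zero and one nonzero cell in
    A_true and identical labels.
    """
    if isinstance(A_hat, CoefficientMatrix):
        A_hat = A_hat.A
    if A_hat.row_ids != A_true.row_ids or A_hat.col_ids != A_true.col_ids:
        raise ValidationError("estimate and truth must carry identical labels")
    positives = (A_true.values != 0).ravel()
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("degenerate truth: need both zero and nonzero cells")
    scores = np.abs(A_hat.values).ravel()
    ranks = rankdata(scores)  # average ranks -> ties contribute 1/2
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def run_benchmark(
    spec: SimulationSpec,
    estimators: Sequence[EstimatorSpec | tuple[str, dict]],
    runs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and sd of recovery AUC per estimator across simulated runs.

    Run ``r`` simulates with seed ``seed + r``; every estimator sees the
    same datasets.  An estimator failure on a run is recorded with a
    warning and excluded from that estimator's mean.  Returns a DataFrame
    indexed by estimator name with columns mean_auc, sd_auc, runs_used.
    """
    if runs < 1:
        raise ParameterError("runs must be >= 1")
    resolved = []
    for est in estimators:
        if isinstance(est, tuple):
            name, params = est
            label = name if not params else f"{name}({_fmt_params(params)})"
            resolved.append((label, get_estimator(name, **params)))
        elif isinstance(est, str):
            resolved.append((est, get_estimator(est)))
        else:
            resolved.append((getattr(est, "__name__", "custom"), est))
    aucs: dict[str, list[float]] = {label: [] for label, _ in resolved}
    for run in range(runs):
        sim = simulate_dataset(spec.replace(seed=seed + run))
        for label, fit in resolved:
            try:
                aucs[label].append(recovery_auc(fit(sim.data), sim.A_true))
            except Exception as exc:
                warnings.warn(
                    f"estimator {label!r} failed on run {run}: {exc}", stacklevel=2
                )
    rows = {
        label: {
            "mean_auc": float(np.mean(vals)) if vals else float("nan"),
            "sd_auc": float(np.std(vals)) if vals else float("nan"),
            "runs_used": len(vals),
        }
        for label, vals in aucs.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _fmt_params(params: dict) -> str:
    return ",".join(f"{k}={v}" for k, v in sorted(params.items()))


def signal_sd(spec: SimulationSpec) -> float:
    """Empirical sd of the noise-free signal M A T for this spec.

    Uses the same seed, so the returned value describes exactly the
    signal component of ``simulate_dataset(spec)``.
    """
    noiseless = simulate_dataset(spec.replace(noise_sd=0.0))
    return float(noiseless.data.G.values.std())


def write_dataset_bundle(sim: SimulatedDataset, directory: str | Path) -> None:
    """Write G/M/T and A_true as the standard TSV bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(sim.data.G, directory / "G.tsv")
    write_matrix_tsv(sim.data.M, directory / "M.tsv")
    write_matrix_tsv(sim.data.T, directory / "T.tsv")
    write_matrix_tsv(sim.A_true, directory / "A_true.tsv")
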