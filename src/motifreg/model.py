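"""Model/Results interface over the growth-curve estimators.

``GrowthCurveModel`` wraps an aligned (G, M, T) dataset; ``fit`` returns a
``GrowthCurveResults`` carrying the coefficient estimate, its diagnostics
and the usual post-estimation tools (prediction, F-test, permutation
z-scores, pair ranking, a text summary).

Example
-------
>>> from motifreg import GrowthCurveModel, SimulationSpec, simulate_dataset
>>> sim = simulate_dataset(SimulationSpec(n=300, p=30, m=8, t=8, seed=1))
>>> res = GrowthCurveModel(sim.data).fit("centered-ls")
>>> res.params.shape
(8, 8)
>>> top = res.rank_pairs(direction="absolute", top=3)
"""

from __future__ import annotations

from pathlib import Path

from .data import LabeledMatrix, RegulatoryDataset, align_dataset, write_matrix_tsv
from . import estimators as _est
from . import inference as _inf


class GrowthCurveModel:
    """The bilinear model G = M A T + E on an aligned dataset."""

    def __init__(self, data: RegulatoryDataset):
        self.data = data

    @classmethod
    def from_matrices(
        cls, G: LabeledMatrix, M: LabeledMatrix, T: LabeledMatrix
    ) -> "GrowthCurveModel":
        """Build a model from unaligned matrices (ids intersected, G's
        ordering kept)."""
        return cls(align_dataset(G, M, T))

    # -- estimation ---------------------------------------------------------

    def fit(self, method: str = "ls", **hyperparameters) -> "GrowthCurveResults":
        """Fit A with a named estimator.

        ``method`` is one of ``ls``, ``centered-ls``, ``ridge``,
        ``centered-ridge``, ``sparse`` (requires ``lam`` or ``lam_ratio``)
        or ``correlation``.
        """
        coef = _est.get_estimator(method, **hyperparameters)(self.data)
        return GrowthCurveResults(self, coef)

    def fit_path(
        self, n_lambdas: int = 20, lambda_min_ratio: float = 0.01, **sparse_kwargs
    ) -> _est.PathResult:
        """Sparse fits along a decreasing lambda grid (see ``sparse_path``)."""
        return _est.sparse_path(
            self.data, n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio,
            **sparse_kwargs,
        )

    # -- significance -------------------------------------------------------

    def zscores(
        self, method: str = "ls", r: int = 30, seed: int = 0, **hyperparameters
    ) -> _inf.ZScoreMatrix:
        """Permutation z-scores for every coefficient (see ``inference.zscores``)."""
        return _inf.zscores(self.data, method, r=r, seed=seed, **hyperparameters)

    def split_stability(
        self,
        method: str = "ls",
        top_k: int = 10,
        seed: int = 0,
        direction: str = "absolute",
        **hyperparameters,
    ) -> _inf.StabilityResult:
        """Top-k overlap between fits on two random halves of the experiments."""
        return _inf.split_set_stability(
            self.data, method, top_k=top_k, seed=seed, direction=direction,
            **hyperparameters,
        )


class GrowthCurveResults:
    """A fitted coefficient matrix with diagnostics and reporting."""

    def __init__(self, model: GrowthCurveModel, coef: _est.CoefficientMatrix):
        self.model = model
        self.coef = coef

    @property
    def params(self) -> LabeledMatrix:
        """The motifs x TFs coefficient estimate."""
        return self.coef.A

    @property
    def method(self) -> str:
        return self.coef.method

    @property
    def hyperparameters(self) -> dict:
        return self.coef.hyperparameters

    @property
    def diagnostics(self) -> dict:
        return self.coef.diagnostics

    def predict(self) -> LabeledMatrix:
        """Fitted values G_hat = M A T on the training data."""
        return _est.predict(self.model.data, self.coef)

    def goodness_of_fit(self) -> _est.FitStatistics:
        return _est.goodness_of_fit(self.model.data, self.coef)

    def f_test(self) -> _inf.FTestResult:
        return _inf.f_test(self.model.data, self.coef)

    def rank_pairs(self, direction: str = "largest", top: int = 10) -> _inf.RankedPairs:
        return _inf.rank_pairs(self.params, direction=direction, top=top)

    def save(self, path: str | Path, diagnostics_path: str | Path | None = None):
        """Write A as labeled TSV plus a side-car diagnostics text file."""
        path = Path(path)
        write_matrix_tsv(self.params, path)
        side = Path(diagnostics_path) if diagnostics_path else path.with_suffix(
            path.suffix + ".info.txt"
        )
        lines = [f"method={self.method}"]
        lines += [f"{k}={v}" for k, v in sorted(self.hyperparameters.items())]
        for key in ("rss", "iterations", "converged"):
            if key in self.diagnostics:
                lines.append(f"{key}={self.diagnostics[key]}")
        side.write_text("\n".join(lines) + "\n", encoding="utf-8")

    def summary(self, top: int = 5) -> str:
        """Human-readable fit summary with the strongest associations."""
        D = self.model.data
        fit = self.goodness_of_fit()
        frac = fit.explained_ss / fit.total_ss if fit.total_ss > 0 else float("nan")
        lines = [
            "Growth-curve model  G = M A T + E",
            f"  genes: {D.n_genes}   experiments: {D.n_experiments}   "
            f"motifs: {D.n_motifs}   TFs: {D.n_tfs}",
            f"  method: {self.method}"
            + (f"   hyperparameters: {self.hyperparameters}"
               if self.hyperparameters else ""),
            f"  rss: {fit.rss:.6g}   total_ss: {fit.total_ss:.6g}   "
            f"explained fraction: {frac:.4f}",
        ]
        try:
            ft = self.f_test()
            lines.append(
                f"  F({ft.df1}, {ft.df2}) = {ft.F:.4g}   p = {ft.p:.3g}"
            )
        except Exception:
            pass
        lines.append(f"  top {top} pairs by |coefficient|:")
        for m, t, s in self.rank_pairs(direction="absolute", top=top).entries:
            lines.append(f"    {m:<12s} {t:<12s} {s:+.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        k, l = self.params.shape
        return f"<GrowthCurveResults method={self.method!r} A={k}x{l}>"
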