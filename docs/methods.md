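# Methods

## Model

Expression of n target genes in p experiments is modelled as

    G = M · A · T + E,            G ∈ R^{n×p}, M ∈ R^{n×m}, A ∈ R^{m×t}, T ∈ R^{t×p}

the classical growth-curve (GMANOVA) form with design matrices on both
sides of the parameter matrix.  Element-wise, g_ij ≈ Σ_k Σ_l m_ik a_kl
t_lj: gene i's expression in experiment j is a linear function of the
pairwise products of its promoter's motif counts and the TF expression
levels in that experiment.  The modelling assumptions are (1) target-gene
expression is driven by TF expression in the same experiment, (2) a TF's
effect enters through, and proportionally to, motif occurrences in the
promoter, and (3) the combined effect is linear.  All three are crude for
real cells (protein abundance ≠ mRNA, chromatin state, combinatorial
control, regulatory lag), which is why the model is used descriptively:
coefficients a_kl rank putative motif–TF associations; prediction of G is
not the goal and is typically poor.  If the unmodeled influence is
additive and independent of the modelled TFs, coefficient estimates
remain consistent even when the residual error is large; the
missing-regulator simulations below exercise exactly this regime.

## Estimators

All estimators consume an aligned dataset (shared gene axis for G and M,
shared experiment axis for G and T) and return a labeled motifs × TFs
coefficient matrix with diagnostics.

**Minimum-norm least squares.**  Â = M⁺ G T⁺ with Moore–Penrose
pseudoinverses.  The full solution set of the least-squares problem is
Â + (I − M⁺M)Z₁ + Z₂(I − TT⁺) for arbitrary Z₁, Z₂; every member attains
the same residual and Â has the smallest Frobenius norm (both properties
are verified numerically in the tests).  With full column rank M and full
row rank T the solution is unique and equals (MᵀM)⁻¹MᵀG Tᵀ(TTᵀ)⁻¹.
Numerical rank: singular values below max(dim)·ε·σ₁ are treated as zero
(the standard reproducible cutoff).

**Centering.**  The centered variants first column-center M over genes,
row-center T over experiments, and double-center G (subtract row and
column means, add back the grand mean).  Because row-centering T is
right-multiplication by the centering projector and column-centering M is
left-multiplication, the centered model is exact: C_n G C_p =
(C_n M) A (T C_p) + C_n E C_p.  Double centering removes additive
per-gene and per-experiment effects (array scaling, probe affinity) and
decorrelates the bilinear predictors from the constant direction.  The
mode of centering G is configurable (`row`, `column`, `double`); `double`
is the default since it is the transformation induced jointly by the two
predictor centerings.

**Ridge.**  Â = (MᵀM + λ₁I)⁻¹ Mᵀ G Tᵀ (TTᵀ + λ₂I)⁻¹, computed with two
linear solves.  This is a two-sided surrogate for the vectorized Tikhonov
problem (whose exact minimiser has no closed form in matrix operations on
M and T); it shrinks each side's Gram spectrum independently.  Defaults
λ₁ = λ₂ = 1 are intended for roughly standardized inputs and are always
user-settable.  When a penalty is exactly 0 and the corresponding Gram
matrix is singular the solve cannot proceed; the estimator raises and
points the caller at the pseudoinverse route (this generalises the
degenerate λ₁ = λ₂ = 0 case to either side being unpenalised and
rank-deficient).  Ridge applied after centering gives the centered-ridge
estimator; the penalty acts on the centered Gram matrices.

**Sparse regression.**  Objective F(A) = ‖G − MAT‖²_F + λ‖A‖₁
(entry-wise L1), minimised by iterative soft-thresholding (proximal
gradient):

    A ← S_{μλ/2}( A + μ Mᵀ(G − MAT)Tᵀ ),      S_τ(x) = sign(x)·max(|x|−τ, 0)

from A = 0.  The smooth part has Lipschitz gradient constant
2σ₁(M)²σ₁(T)², so the automatic step μ = 0.9/(σ₁(M)²σ₁(T)²) guarantees
monotone descent (asserted per-iteration in tests via the recorded
objective trajectory).  Convergence is declared when the largest
coefficient change drops below `tol` (default 1e-8, max_iter 10000);
non-convergence returns the current iterate with `converged=False` and a
warning.  Coefficients with magnitude below `tol` are snapped to exact
zero so supports and entry orders are well defined.  The objective
scaling is fixed so that the scalar problem has the closed form
a = S_{λ/2}(g) and the smallest all-zero penalty is
λ_max = 2·max|MᵀGTᵀ|; the implementation is verified element-wise against
an independent coordinate-descent LASSO on the vectorized design
(Tᵀ ⊗ M).  The λ-path is a warm-started geometric grid from λ_max down to
λ_max·lambda_min_ratio; the exact piecewise-linear homotopy (a LARS-style
path exploiting the matrix structure) is a possible extension — the grid
recovers the entry order approximately, with ties at a grid point broken
by magnitude, then lexicographically.

**Correlation estimator.**  For each pair independently,

    â_kl = [ (1/np) Σ_ij (g_ij − ḡ)(m_ik − m̄_k)(t_lj − t̄_l) ] / [ Var(m_k) · Var(t_l) ]

with population (divide-by-count) moments and ḡ the grand mean of G.
Under the generative reading of the model, if m_k and t_l are
non-constant and pairwise independent of the other predictors this
plug-in ratio is consistent for a_kl, and it only touches G, motif
column k and TF row l — deleting any other motif or TF changes it by
exactly zero.  Constant columns/rows make a pair undefined; such
coefficients are set to 0 and reported in the diagnostics rather than
raising.  Centered least squares approximates this estimator when M and
T are sampled independently, which is the basis for its own
missing-regulator robustness.  Note the estimator's finite-sample noise:
pairs sharing the motif (or TF) of a true association pick up spurious
signal of order 1/√p (or 1/√n) through empirical covariances between TF
rows (or motif columns), so spurious coefficients shrink slowly with the
number of experiments.

## Significance

**Permutation z-scores.**  The null is generated by shuffling G's rows
and columns with two uniform permutations (labels stay in place), which
decouples expression from both designs while preserving the value
distribution.  With r permuted refits (default r = 30),
z_kl = (â_kl − mean)/sd with the population sd of the permuted
estimates.  Pairs with zero permuted spread get z = 0 and are listed as
degenerate (conservative; avoids infinities).  z-scores are invariant to
positive rescaling of the estimator's output.

**F-test.**  F = (ess/df₁)/(rss/df₂) with ess/rss taken around the grand
mean, df₁ = rank(M)·rank(T) (the identifiable parameter count — correct
under collinear predictors, where m·t would overstate it) and
df₂ = np − df₁ − 1.  A perfect fit returns p = 0 by convention; a fit
worse than the grand mean is clamped to F = 0 (p = 1).

**Split-set stability.**  Experiments are split at random (seeded) into
halves of ⌈p/2⌉ and ⌊p/2⌋; the estimator is refitted on each half and the
top-k (motif, TF) sets are intersected.  The default ranking direction is
`absolute`, since activation and repression are symmetric in the model.
The p-value is the hypergeometric upper tail P(X ≥ overlap) with
population m·t and two draws of size k — this assumes both halves rank
the same universe of pairs and that a null ranking is uniform; it is a
reference null for "better than random agreement", not an exact
permutation test.

No multiple-testing correction is applied across the m·t pairs; that is
deliberately left to the user.

## Synthetic data

`simulate_dataset` draws M ~ i.i.d. Poisson(motif_rate) (count
semantics), T ~ i.i.d. N(0, tf_sd²), a uniformly random support of
round(density·m·t) coefficients with N(0, coef_sd²) values, and
G = MAT + E with E ~ i.i.d. N(0, noise_sd²).  Defaults (n = 1000, p = 80,
m = 40, t = 50, density 0.05, motif_rate 0.3, tf_sd = coef_sd = noise_sd
= 1) mimic the aspect ratios of a yeast expression compendium at desk
scale: many more genes than experiments, sparse motif counts, sparse true
coupling.  The draw order is fixed (M, T, support, coefficients, noise)
and the noise is scaled after drawing, so datasets sharing a seed differ
only in E across noise levels.

`perturb_missing` deletes random motif columns and TF rows while leaving
G untouched: the removed regulators' contribution becomes unmodeled
influence, emulating an incomplete motif/TF catalogue.

What the generator does **not** emulate: additive per-gene and
per-experiment effects, heteroskedastic or heavy-tailed microarray noise,
correlated motif co-occurrence, TF co-regulation, time-series structure,
or dependence between M and T.  Passing recovery benchmarks on this
generator therefore demonstrates correctness of the estimators under the
model's own assumptions, not performance on real arrays.  Two specific
consequences: (i) because T is zero-mean and the noise is i.i.d., the
clean generative draw gives plain and centered least squares essentially
identical (near-ceiling) recovery — the variance advantage of centering
appears when additive row/column effects exist, which the generator
deliberately omits; (ii) recovery AUCs here are optimistic relative to
biological data.

**Recovery scoring.**  Cells are ranked by |â| against the true support;
the AUC is the tie-corrected Mann–Whitney statistic (ties count ½).
Ranking by magnitude treats activation and repression symmetrically.

## Problem sizes used by the tests and the acceptance script

The recovery benchmark uses n = 500, p = 60, m = 20, t = 20, density 0.1,
noise sd set equal to the empirical sd of the noise-free signal, averaged
over 20 seeded runs — small enough to run in seconds, large enough that
the least-squares estimates are in their well-conditioned regime.  The
sparse fit in the benchmark uses λ = 0.01·λ_max, a penalty small enough
to rank the full support while still thresholding noise.  Null z-score
calibration uses a 200×20 expression matrix with 10 motifs and 10 TFs,
r = 50 permutations, and averages the pooled z mean/sd over 15
independent pre-permuted replicates: the pooled statistics of a single
replicate are strongly cross-correlated across pairs (they share one
observed fit) and have replicate-to-replicate sd ≈ 0.22, so averaging is
required to measure the calibration itself rather than one replicate's
luck.  The correlation-consistency check uses n = 2000, p = 50 with
Bernoulli(0.5) motif indicators, two motifs and two TFs — the smallest
configuration containing every type of "uninvolved" pair.

## Numerical conventions and tie-breaks

* Pseudoinverse rank cutoff: max(dim)·ε·σ₁.
* Sparse: tol 1e-8 on the max coefficient change; sub-tol coefficients
  snapped to 0; objective recorded every iteration.
* Frequency filtering keeps ⌊fraction·m⌋ motifs by presence count and
  excludes every motif tying exactly at the selection boundary (interior
  ties are kept), making the survivor set reproducible without an
  arbitrary ordering.
* GO term selection breaks boundary ties lexicographically by term id.
* Pair ranking breaks score ties by motif id, then TF id.
* TSV floats are written with 17 significant digits (bit-exact round
  trip); missing cells are rejected unless row-mean imputation is
  explicitly requested.
* All randomness flows through numpy Generators seeded explicitly;
  benchmark run r uses seed + r, permutation i uses seed + i.

## Known limitations

* The exact LARS-style λ-homotopy is not implemented; the grid path can
  merge entry events that occur between grid points.
* The two-sided ridge is a surrogate, not the minimiser of the vectorized
  Tikhonov objective.
* Latent (unobserved) motifs or TFs are not estimated; their only
  treatment is the robustness of the observed coefficients to their
  presence.
* The hypergeometric stability null ignores correlation between the two
  half-rankings induced by the shared M.
* GO matrices use direct annotations only; no ontology-graph propagation.
* k-mer counting is single-strand by default; reverse-complement counting
  is a flag, and palindromic windows then count twice.
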