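# Methods

## Model

Given K numeric blocks `X_k` (I × J_k) measured on the same I units, the
regularized simultaneous component model estimates an orthonormal score
matrix `T` (I × R, `T'T = I_R`) shared by all blocks and block loadings
`P_k` (J_k × R) by minimizing

```
L(T, P) = Σ_k ||X_k − T P_k'||²_F
        + λ_L Σ_k ||P_k||_1
        + λ_G Σ_k √J_k Σ_r ||p_r^k||_2 .
```

The Lasso term makes individual loadings exactly zero; the Group Lasso term
removes whole per-block loading vectors `p_r^k`, encoding whether a
component is common (present in every block) or distinctive (absent from
some blocks). The √J_k weight keeps the group penalty comparable across
blocks of different width.

The group structure we penalize is the per-block loading *column*: each
(block, component) vector is one group. With this structure both
subproblems are exact. Given `T`, the optimal column is

```
p_r^k = [ 1/2 − λ_G √J_k / (2 ||S(2 X_k' t_r, λ_L)||_2) ]_+ · S(2 X_k' t_r, λ_L)
```

with `S` the soft-thresholding operator — the Lasso proximal map followed
by multiplicative group shrinkage, collapsing to the exact zero vector when
the group penalty dominates. Given `P`, the optimal `T` is the orthogonal
Procrustes solution `V U'` from the SVD `U Σ V' = P_C' X_C'`. Alternating
these exact updates makes the objective monotone non-increasing, which the
test suite checks on every fit. An alternative reading treats the whole
block matrix `P_k` as a single group; under that reading the closed-form
column update is no longer the exact subproblem solution and monotonicity
fails, so the per-column grouping is the one this package implements and
reports in its objective.

## Fitting: parameters and numerical choices

- `tol = 1e-8` (relative change of the penalized objective) and
  `max_iter = 1000`. The objective flattens within tens of iterations on
  the simulated designs; non-convergence returns a flagged model with a
  warning rather than an exception.
- Initialization: `T` starts at the top-R left singular vectors of the
  concatenation (deterministic); a seeded Haar-random start is available.
  The penalized objective is nonconvex — different starts can end in
  different local optima with objective gaps around 1e-2 on small random
  instances — so all pipelines use the deterministic SVD start.
- Zeros are literal: the thresholding update writes exact 0.0, and all
  sparsity counts, degrees of freedom and recovery scores compare against
  exact zero. No tolerance-based rounding is applied anywhere.
- A component whose loading column vanishes during iteration is kept and
  may re-enter later; components are never pruned.
- `lambda_max` (the smallest penalty making all loadings zero, the upper
  grid endpoint) is found by bracketing and bisection on full fits to 1%
  relative tolerance, with the other penalty held at 1e-7. A closed form at
  the initial `T` would be wrong because `T` itself changes with the
  penalty.
- Degenerate inputs: constant columns are rejected when a scaling mode is
  requested; exactly low-rank data are rejected by the BIC (its reference
  residual is zero); an all-false support pattern returns the zero model
  with a warning.

## Preprocessing

Columns are mean-centered and scaled, per block, in three modes: `center`,
`center+norm1` (default; every variable gets equal weight) and
`center+blockscale` (column squared norm 1/J_k, every block gets equal
total weight). The default matches how both the simulated and the empirical
multi-block datasets in this literature are prepared. Note that the Group
Lasso term already carries a √J_k weight, so block scaling on top of it
tilts the fit towards narrow blocks; both modes are exposed.

## Variable selection

Tuning grids are `n_points` equally spaced values per axis from a floor of
1e-7 up to `lambda_max` (default 50 points, 10 in scaled-down runs).
Tie-breaks throughout favor the sparser model: larger λ_L first, then
larger λ_G.

- **CV with the one-standard-error rule.** Cells (not rows) of `X_C` are
  partitioned into folds, matching a prediction notion for an unsupervised
  decomposition; held-out cells are replaced by their column mean over the
  retained cells, the model is fitted on the completed table once, and
  squared error is accumulated over held-out cells only. The same fold
  partition is shared across the whole grid. The selected pair has MSPE
  closest to but not above `MSPE* + SE*`; a `closest` variant (nearest the
  bound from either side) is what the simulation comparisons use. The
  single-pass imputation means completion is not exact even on noiseless
  low-rank data — CV error measures structure exploitation, not exact
  recovery.
- **rdCV.** Outer loop: rows split into T = 2 near-equal segments,
  repeated (default 50 repetitions; 10 in the scaled-down study); the inner
  one-SE CV runs on each calibration set. The most frequent λ_L and most
  frequent λ_G over all repetitions are chosen separately (the joint pair
  frequency is sparser and noisier); frequency ties go to the larger value.
- **BIC.** `BIC = Ṽ/V + df·log(I)/I` with `V` the unpenalized-model
  residual, `Ṽ` the penalized one, `df` the exact non-zero count; the
  equivalent variant `I·Ṽ/V + df·log(I)` is exposed and tested to equal
  I times the former. Note the structural consequence: with I small and
  many loadings (e.g. I = 20, 150 loadings) the df term dominates any
  achievable fit improvement and the criterion selects near-empty models —
  the over-conservatism the simulation studies exhibit.
- **Index of Sparseness.** `IS = (V_a·V_s/V_o²)·(#zeros/total)` with `V_o`
  the total sum of squares, `V_s` the unpenalized explained sum of squares,
  `V_a` the penalized one; maximized over the grid. Zero for fully dense
  and for all-zero solutions by construction.
- **Bolasso.** Bootstrap the rows (I draws with replacement, redrawing if a
  column becomes constant), select a pair by one-SE CV per replicate, fit
  on the replicate, align to the first replicate's estimate, and keep only
  loadings non-zero in all replicates (a relaxed consensus fraction is
  available but off by default). The surviving support is refitted with
  zeros fixed.
- **Stability selection.** Walk a decreasing Lasso path from `lambda_max`;
  at each value fit 100 half-samples of the rows (drawn without
  replacement) with λ_G = 0, align each to the full-data fit at that value
  (a sample-independent anchor), and record per-loading selection
  probabilities. Stop at the first value where at least Q loadings reach
  π_thr = 0.6; keep the top Q by maximum probability over the visited
  values and refit. If the path is exhausted first, the top-Q fallback is
  applied with a warning flag. Q must be supplied; `q_bound` returns the
  error-control lower bound `ceil(sqrt((2π_thr − 1)·EV·total))`, rounding
  up so the bound is conservative.

Component alignment (needed because the decomposition is invariant to
permutation and sign of components) maximizes the summed per-column
|Tucker congruence|, exhaustively for R ≤ 5 and by optimal assignment up
to R = 8; sign flips make each matched congruence non-negative. Zero
columns contribute congruence 0 with a warning.

## Simulation engine

Each dataset is built in five steps: (1) i.i.d. N(0,1) blocks; (2) the
concatenation is column-centered, scaled to norm one, and truncated at
R = 3 by SVD — the left singular vectors are the true scores `T_true` and
`V Σ` the dense true loadings; (3) whole per-block loading vectors are
zeroed by the design's structure mask (two-block design: component 2 absent
from block 1, component 3 absent from block 2; four-block design:
component 1 common, components 2 and 3 distinctive); (4) a fraction (30% or
50%, count = round(fraction × length), half-even) of the entries of each
remaining vector is zeroed uniformly at random; (5) i.i.d. Gaussian noise
is added with scale `α = sqrt(e/(1−e)·||X_true||²/||E||²)` so that exactly
a fraction `e` (0.5% or 30%) of the generated total sum of squares is
noise, under the norm-ratio bookkeeping that ignores the near-zero random
cross term. Generated blocks are returned centered and norm-1 scaled.

Centering the Gaussian draw *before* the truncated SVD is a deliberate
design choice: it makes `1'T_true = 0` exactly, so the truth lives in the
same column-centered geometry the analysis pipeline sees. With an
uncentered truth, the centering step of preprocessing clips each true score
vector's mean component and caps the achievable Tucker congruence around
0.975 at I = 20 even when the true zero pattern is supplied; with the
centered truth, the same refit reaches a median congruence above 0.998 at
0.5% noise.

What the generator does *not* emulate: correlated or heteroscedastic noise,
blocks with unequal row sets, non-Gaussian measurement scales, and
variables whose true loadings are small but non-zero. One consequence of
the design worth knowing: variables zeroed in every component carry pure
noise, and the norm-one scaling inflates those columns to the same scale as
signal columns, so half-sample refits (stability selection's raw material)
are substantially noisier than full-sample fits at I = 20. Passing
recovery tests on these data therefore demonstrate correctness of the
machinery and the methods' relative behavior under the stated conditions,
not performance guarantees on real multi-omics data.

Study layouts: study 1 crosses three two-block size situations
(20×40 + 20×10, 20×120 + 20×30, 80×40 + 80×10) with two sparsity and two
noise levels (12 cells, 20 replicates each = 240 datasets at full scale);
study 2 uses one four-block situation (20×120 + 20×30 + 20×40 + 20×10)
crossed the same way (4 cells, 80 datasets). Per-replicate seeds derive
deterministically from (master seed, cell index, replicate index), so any
cell is independently reproducible and full runs are bit-for-bit
repeatable.

Recovery scores: `PL`, `PL_non0`, `PL_0` are the proportions of all / true
non-zero / true zero loadings whose exact-zero status is correctly
recovered after alignment, and satisfy the exact count identity
`PL·total = PL_non0·n_nonzero + PL_0·n_zero`; φ is the whole-matrix Tucker
congruence of the aligned score matrices.

## Scaled-down study sizes

The test suite runs the method comparison at reduced scale chosen once as
part of the study design: the first-situation cells only, 5 replicates per
cell, 10×10 grids, rdCV at 10 repetitions, Bolasso at its full 50
repetitions (the strict-intersection behavior under test depends on the
repetition count), stability selection at its full 100 subsamples. Full
paper-scale runs (20 replicates, 50-point grids, all cells) are available
through `run_study` / `rsca simulate` flags. At the reduced scale the
coarse grid quantizes the CV-selected penalties, which makes Bolasso's
bootstrap supports more repeatable (hence its intersection less aggressive)
than at full scale; the BIC's near-empty selections at I = 20 follow from
the criterion's own df pricing, as noted above.

## Known limitations

- The alternating fit guarantees monotone descent, not global optimality.
- Element-wise CV with single-pass mean imputation under-uses the low-rank
  structure; an iterative completion would predict held-out cells better
  but is not what the selection procedures under study prescribe.
- Exhaustive alignment is limited to R ≤ 8 (assignment path above R = 5).
- Stability selection requires Q; no automatic choice is provided, and the
  error-control bound is far below the true non-zero count in the simulated
  designs.
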