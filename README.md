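# rsca — regularized simultaneous component analysis for multi-block data

`rsca` jointly decomposes K data blocks `X_k` (I × J_k) that share the same
rows — subjects, samples, families, food specimens — into one orthonormal
component score matrix `T` (I × R) and sparse block loadings `P_k`, by
minimizing

```
sum_k ||X_k - T P_k'||²_F  +  λ_L Σ_k ||P_k||_1  +  λ_G Σ_k √J_k Σ_r ||p_r^k||_2
subject to  T'T = I_R
```

The Lasso term (λ_L) zeroes individual loadings; the Group Lasso term (λ_G)
zeroes whole per-block loading vectors `p_r^k`, which is what distinguishes
*common* components (non-zero loadings in every block) from *distinctive*
ones (all-zero in some blocks). Both subproblems have exact closed-form
updates — soft-thresholding with multiplicative group shrinkage for each
loading column, an orthogonal-Procrustes SVD for the scores — so the
alternating fit decreases the objective monotonically and produces exact
zeros.

Because the usefulness of the decomposition hinges on picking the right
sparsity, the package implements six variable-selection strategies:

| method | selects | idea |
|---|---|---|
| `cv` | (λ_L, λ_G) | element-wise K-fold CV + one-standard-error rule |
| `rdcv` | (λ_L, λ_G) | repeated double CV; most frequent tuning wins |
| `bic` | (λ_L, λ_G) | SCA-adjusted BIC: relative residual + df·log(I)/I |
| `is` | (λ_L, λ_G) | Index of Sparseness: explained-variance product × zero fraction |
| `bolasso` | support | bootstrap the rows; keep loadings non-zero in *every* replicate |
| `stability` | support | subsample selection probabilities along a Lasso path, top-Q |

Pattern-based methods (`bolasso`, `stability`) end with an unpenalized refit
in which the discarded loadings are pinned to exact zero. Stability
selection needs a target count `Q` of non-zero loadings; `q_bound` computes
the error-control lower bound `Q = ceil(sqrt((2π_thr − 1)·EV·total))`.

A simulation engine generates ground-truth multi-block data (low-rank truth
from a truncated SVD, common/distinctive structure, 30%/50% within-vector
sparsity, noise at 0.5% or 30% of total variance) and scores recovery by
the proportions of correctly classified loadings (`PL`, `PL_non0`, `PL_0`)
and the Tucker congruence φ of the score matrices after permutation/sign
alignment.

## Worked example

Generate one dataset of the smallest simulated design (two blocks, 20×40
and 20×10, 30% sparsity, 0.5% noise), pick the penalties with the Index of
Sparseness on a 10×10 grid, refit, and score against the truth:

```python
from rsca.simulation import study_cells, generate_dataset, \
    score_pattern_recovery, score_congruence
from rsca.selection import make_grid, is_select, align_components
from rsca.estimator import fit_rsca

design = study_cells(1)[0]
data, truth = generate_dataset(design, 7)
grid = make_grid(data, R=3, n_points=10)
res = is_select(data, R=3, grid=grid)
model = fit_rsca(data, R=3, lambda_L=res.chosen_lambda_L,
                 lambda_G=res.chosen_lambda_G)
perm, signs, P_aligned = align_components(truth.P_C_true, model.P_C)
PL, PL_non0, PL_0 = score_pattern_recovery(truth.P_C_true, P_aligned)
phi = score_congruence(truth.T_true, model.T[:, perm] * signs)
```

This prints:

```
chosen lambda_L = 0.2228, lambda_G = 0.0000
non-zero loadings: 77 of 150 (truth: 70)
PL = 0.860, PL_non0 = 0.900, PL_0 = 0.825, phi = 0.998
```

Read: the chosen Lasso penalty keeps 77 loadings (the truth has 70); 86% of
all loadings get the correct zero status, 90% of the truly non-zero ones
are kept, 82.5% of the true zeros are recognized, and the estimated score
matrix is nearly indistinguishable from the truth (φ = 0.998).

The same run from a shell, on your own CSV blocks (one file per block,
header row = variable names, one row per subject):

```bash
rsca select --method is --R 3 --grid-points 50 \
     --block mothers.csv --block fathers.csv --block children.csv \
     --out results/
rsca simulate --study 1 --replicates 5 --grid-points 10 --out sim/
```

`select` writes `scores.csv`, `loadings.csv` (labeled by block and
variable), the selection surfaces, and a JSON report with everything needed
to reproduce the run.

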