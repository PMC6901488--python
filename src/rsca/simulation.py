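"""Ground-truth simulation of multi-block data and recovery scoring.

Datasets are built in five steps: (1) draw i.i.d. standard-normal blocks;
(2) truncate the SVD of their concatenation at R = 3 components, taking the
left singular vectors as the true scores T_true and V*Sigma as dense true
loadings; (3) zero whole per-block loading vectors to impose the
common/distinctive component structure; (4) zero a fixed fraction of the
entries within each remaining loading vector, drawn uniformly at random;
(5) add scaled i.i.d. Gaussian noise so that a prescribed fraction of the
total sum of squares of the generated data is noise.  The resulting blocks
are column-centered and scaled to norm one before analysis, mirroring how
real multi-block data are preprocessed.

Recovery is scored against the truth by the proportions of loadings whose
zero status is correctly recovered (overall, among true non-zeros, among
true zeros) and by the Tucker congruence of the score matrices after
permutation/sign alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MultiBlockData, ValidationError, preprocess
from .estimator import FitConfig, ZeroPattern, fit_rsca, fit_with_fixed_pattern
from .selection import (
    align_components,
    bic_select,
    bolasso,
    cv_one_se,
    is_select,
    make_grid,
    rdcv,
    stability_selection,
    tucker_congruence,
)

__all__ = [
    "SimulationDesign",
    "TrueModel",
    "PerformanceReport",
    "generate_dataset",
    "noise_alpha",
    "score_pattern_recovery",
    "score_congruence",
    "study_cells",
    "run_study",
    "METHODS",
]

# structure masks: rows = blocks, columns = components; True keeps the
# block's loading vector, False zeroes it wholesale (distinctive structure)
_STRUCTURE_TWO_BLOCK = np.array(
    [
        [True, False, True],
        [True, True, False],
    ]
)
_STRUCTURE_FOUR_BLOCK = np.array(
    [
        [True, True, False],
        [True, True, True],
        [True, False, True],
        [True, False, False],
    ]
)


@dataclass(frozen=True)
class SimulationDesign:
    """One design cell of the simulation studies.

    block_dims lists (I, J_k) per block (all sharing I); structure_mask is
    a K x R boolean matrix, False marking loading vectors zeroed wholesale;
    sparsity is the fraction of entries zeroed inside each retained vector;
    noise_fraction the proportion of the generated data's sum of squares
    attributable to noise.
    """

    block_dims: tuple[tuple[int, int], ...]
    structure_mask: np.ndarray
    sparsity: float
    noise_fraction: float
    R: int = 3
    n_replicates: int = 20
    cell_id: str = ""

    def __post_init__(self):
        dims = tuple((int(i), int(j)) for i, j in self.block_dims)
        object.__setattr__(self, "block_dims", dims)
        rows = {i for i, _ in dims}
        if len(rows) != 1:
            raise ValidationError("all blocks must share the same row count")
        mask = np.asarray(self.structure_mask, dtype=bool)
        if mask.shape != (len(dims), self.R):
            raise ValidationError(
                f"structure_mask shape {mask.shape} != {(len(dims), self.R)}"
            )
        object.__setattr__(self, "structure_mask", mask)
        if not (0 <= self.sparsity < 1):
            raise ValidationError("sparsity must lie in [0, 1)")
        if not (0 <= self.noise_fraction < 1):
            raise ValidationError("noise_fraction must lie in [0, 1)")
        if not self.cell_id:
            dims_s = "+".join(f"{i}x{j}" for i, j in dims)
            object.__setattr__(
                self,
                "cell_id",
                f"dims={dims_s}|sparsity={self.sparsity}|noise={self.noise_fraction}",
            )

    @property
    def I(self) -> int:  # noqa: E743
        return self.block_dims[0][0]

    @property
    def J(self) -> tuple[int, ...]:
        return tuple(j for _, j in self.block_dims)

    @property
    def total_columns(self) -> int:
        return int(sum(self.J))


@dataclass
class TrueModel:
    """Simulated ground truth accompanying one generated dataset."""

    T_true: np.ndarray
    P_C_true: np.ndarray
    X_true: np.ndarray
    zero_positions: ZeroPattern  # True where the true loading is non-zero
    alpha: float
    noise_fraction: float

    @property
    def n_nonzero(self) -> int:
        return self.zero_positions.n_nonzero


@dataclass(frozen=True)
class PerformanceReport:
    """Recovery scores of one method on one replicate of one design cell."""

    study: int
    cell_id: str
    replicate: int
    method: str
    PL: float
    PL_non0: float
    PL_0: float
    phi: float
    failed: bool = False
    message: str = ""


def noise_alpha(X_true: np.ndarray, E: np.ndarray, e: float) -> float:
    """Noise scale making a fraction *e* of the total sum of squares noise.

    alpha = sqrt( e/(1-e) * ||X_true||_F^2 / ||E||_F^2 ), so that
    ||alpha*E||^2 / (||X_true||^2 + ||alpha*E||^2) = e exactly under the
    norm-ratio reading (the random cross term is not part of the
    bookkeeping).
    """
    if not (0 <= e < 1):
        raise ValidationError("noise fraction must lie in [0, 1)")
    nE = float(np.sum(np.asarray(E) ** 2))
    if nE == 0:
        raise ValidationError("noise matrix is identically zero")
    if e == 0:
        return 0.0
    nX = float(np.sum(np.asarray(X_true) ** 2))
    return float(np.sqrt(e / (1.0 - e) * nX / nE))


def generate_dataset(
    design: SimulationDesign, replicate_seed
) -> tuple[MultiBlockData, TrueModel]:
    """Generate one dataset (preprocessed) plus its ground truth."""
    rng = np.random.default_rng(replicate_seed)
    I = design.I
    J = design.J
    R = design.R
    # step 1: i.i.d. N(0,1) blocks, column-centered and scaled to norm one so
    # the truth lives in the same geometry the (centered, scaled) analysis
    # sees; an uncentered truth would cap score congruence below 1 at small I
    raw = rng.standard_normal((I, design.total_columns))
    raw -= raw.mean(axis=0, keepdims=True)
    raw /= np.linalg.norm(raw, axis=0, keepdims=True)
    # step 2: truncated SVD of the concatenation
    U, s, Vt = np.linalg.svd(raw, full_matrices=False)
    T_true = U[:, :R]
    P = (Vt[:R].T * s[:R])  # V~ Sigma~, (sum J_k) x R
    # step 3: zero whole block loading vectors per the structure mask
    starts = np.concatenate([[0], np.cumsum(J)[:-1]]).astype(int)
    for k, (start, j) in enumerate(zip(starts, J)):
        for r in range(R):
            if not design.structure_mask[k, r]:
                P[start : start + j, r] = 0.0
    # step 4: sparsify the remaining vectors, round-half-even counts
    for k, (start, j) in enumerate(zip(starts, J)):
        for r in range(R):
            if not design.structure_mask[k, r]:
                continue
            n_zero = int(np.round(design.sparsity * j))
            if n_zero:
                pos = rng.choice(j, size=n_zero, replace=False)
                P[start + pos, r] = 0.0
    # step 5: noise scaled to the prescribed fraction of total variance
    X_true = T_true @ P.T
    E = rng.standard_normal(X_true.shape)
    alpha = noise_alpha(X_true, E, design.noise_fraction)
    X_gen = X_true + alpha * E
    blocks = [X_gen[:, start : start + j] for start, j in zip(starts, J)]
    data = preprocess(MultiBlockData(blocks), "center+norm1")
    truth = TrueModel(
        T_true=T_true,
        P_C_true=P,
        X_true=X_true,
        zero_positions=ZeroPattern(P != 0),
        alpha=alpha,
        noise_fraction=design.noise_fraction,
    )
    return data, truth


def score_pattern_recovery(
    P_true: np.ndarray, P_est: np.ndarray
) -> tuple[float, float, float]:
    """Proportions of loadings whose zero status is correctly recovered.

    Returns (PL, PL_non0, PL_0): over all loadings, over the true
    non-zeros, and over the true zeros.  "Zero" means exact zero on both
    sides (the estimator produces literal zeros).  P_est must already be
    aligned to P_true.
    """
    P_true = np.asarray(P_true)
    P_est = np.asarray(P_est)
    if P_true.shape != P_est.shape:
        raise ValidationError("shape mismatch between true and estimated loadings")
    true_nz = P_true != 0
    est_nz = P_est != 0
    n_nz = int(true_nz.sum())
    n_z = true_nz.size - n_nz
    correct_nz = int((true_nz & est_nz).sum())
    correct_z = int((~true_nz & ~est_nz).sum())
    PL = (correct_nz + correct_z) / true_nz.size
    PL_non0 = correct_nz / n_nz if n_nz else float("nan")
    PL_0 = correct_z / n_z if n_z else float("nan")
    return PL, PL_non0, PL_0


def score_congruence(T_true: np.ndarray, T_est: np.ndarray) -> float:
    """Whole-matrix Tucker congruence of aligned score matrices."""
    return tucker_congruence(T_true, T_est)


def study_cells(study: int, n_replicates: int = 20) -> list[SimulationDesign]:
    """The fully crossed design cells of simulation study 1 or 2.

    Study 1 crosses three two-block size situations (20x40+20x10,
    20x120+20x30, 80x40+80x10) with sparsity {0.3, 0.5} and noise
    {0.005, 0.30}: 12 cells.  Study 2 uses one four-block situation
    (20x120+20x30+20x40+20x10) crossed with the same sparsity and noise
    levels: 4 cells.
    """
    sparsities = (0.3, 0.5)
    noises = (0.005, 0.30)
    cells = []
    if study == 1:
        situations = [
            ((20, 40), (20, 10)),
            ((20, 120), (20, 30)),
            ((80, 40), (80, 10)),
        ]
        for dims in situations:
            for sp in sparsities:
                for nz in noises:
                    cells.append(
                        SimulationDesign(
                            block_dims=dims,
                            structure_mask=_STRUCTURE_TWO_BLOCK,
                            sparsity=sp,
                            noise_fraction=nz,
                            n_replicates=n_replicates,
                        )
                    )
    elif study == 2:
        dims = ((20, 120), (20, 30), (20, 40), (20, 10))
        for sp in sparsities:
            for nz in noises:
                cells.append(
                    SimulationDesign(
                        block_dims=dims,
                        structure_mask=_STRUCTURE_FOUR_BLOCK,
                        sparsity=sp,
                        noise_fraction=nz,
                        n_replicates=n_replicates,
                    )
                )
    else:
        raise ValidationError("study must be 1 or 2")
    return cells


METHODS = ("cv", "rdcv", "bic", "is", "bolasso", "stability")

_DEFAULT_METHOD_PARAMS: dict[str, dict] = {
    "cv": {"n_folds": 5, "mode": "closest"},
    "rdcv": {"n_segments": 2, "n_repetitions": 50, "inner_folds": 5, "mode": "closest"},
    "bic": {},
    "is": {},
    "bolasso": {"n_repetitions": 50, "inner_folds": 5, "mode": "closest"},
    "stability": {"pi_thr": 0.6, "n_subsamples": 100},
}


def _run_method(
    method: str,
    data: MultiBlockData,
    truth: TrueModel,
    R: int,
    grid,
    params: dict,
    seed: int,
    cfg: FitConfig | None,
):
    """Run one selection method end to end and return the final model."""
    if method == "cv":
        res = cv_one_se(data, R, grid, seed=seed, cfg=cfg, **params)
        return fit_rsca(data, R, res.chosen_lambda_L, res.chosen_lambda_G, cfg)
    if method == "rdcv":
        res = rdcv(data, R, grid, seed=seed, cfg=cfg, **params)
        return fit_rsca(data, R, res.chosen_lambda_L, res.chosen_lambda_G, cfg)
    if method == "bic":
        res = bic_select(data, R, grid, cfg=cfg, **params)
        return fit_rsca(data, R, res.chosen_lambda_L, res.chosen_lambda_G, cfg)
    if method == "is":
        res = is_select(data, R, grid, cfg=cfg, **params)
        return fit_rsca(data, R, res.chosen_lambda_L, res.chosen_lambda_G, cfg)
    if method == "bolasso":
        res = bolasso(data, R, grid, seed=seed, cfg=cfg, **params)
        return res.model
    if method == "stability":
        params = dict(params)
        Q = params.pop("Q", None) or truth.n_nonzero
        res = stability_selection(
            data,
            R,
            grid.lasso_values[::-1],
            Q=Q,
            seed=seed,
            cfg=cfg,
            **params,
        )
        return res.model
    raise ValidationError(f"unknown method {method!r}; valid: {METHODS}")


def run_study(
    study: int,
    methods=METHODS,
    n_replicates: int = 20,
    grid_points: int = 50,
    seed: int = 0,
    method_params: dict[str, dict] | None = None,
    cfg: FitConfig | None = None,
    cells: list[SimulationDesign] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a full (or scaled-down) simulation study.

    Crosses the study's design cells with *n_replicates* datasets per cell
    (per-replicate seeds are derived deterministically from the master
    seed, the cell index, and the replicate index), runs every requested
    method, aligns each estimate to the truth, and scores recovery.

    Returns (reports, medians): one tidy row per (cell, replicate, method)
    and the per-cell, per-method medians of the four measures.  A method
    failure on a replicate is recorded as a flagged row, and the run
    continues.
    """
    methods = list(methods)
    if not methods:
        raise ValidationError("methods must be non-empty")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValidationError(f"unknown methods {unknown}; valid: {METHODS}")
    if cells is None:
        cells = study_cells(study, n_replicates)
    rows = []
    for cell_idx, design in enumerate(cells):
        for rep in range(n_replicates):
            ss = np.random.SeedSequence([seed, cell_idx, rep])
            gen_seed, method_entropy = ss.spawn(2)
            data, truth = generate_dataset(design, gen_seed)
            grid = make_grid(data, design.R, grid_points, cfg=cfg)
            method_seeds = method_entropy.spawn(len(methods))
            for method, m_ss in zip(methods, method_seeds):
                params = dict(_DEFAULT_METHOD_PARAMS[method])
                params.update((method_params or {}).get(method, {}))
                m_seed = int(m_ss.generate_state(1)[0] % (2**31))
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model = _run_method(
                            method, data, truth, design.R, grid, params, m_seed, cfg
                        )
                        perm, signs, P_aligned = align_components(
                            truth.P_C_true, model.P_C
                        )
                    T_aligned = model.T[:, perm] * signs
                    PL, PL_non0, PL_0 = score_pattern_recovery(
                        truth.P_C_true, P_aligned
                    )
                    phi = score_congruence(truth.T_true, T_aligned)
                    rows.append(
                        PerformanceReport(
                            study, design.cell_id, rep, method, PL, PL_non0, PL_0, phi
                        )
                    )
                except Exception as exc:  # failures are data, not fatal
                    rows.append(
                        PerformanceReport(
                            study,
                            design.cell_id,
                            rep,
                            method,
                            float("nan"),
                            float("nan"),
                            float("nan"),
                            float("nan"),
                            failed=True,
                            message=str(exc),
                        )
                    )
    reports = pd.DataFrame([r.__dict__ for r in rows])
    ok = reports[~reports["failed"]]
    medians = (
        ok.groupby(["cell_id", "method"])[["PL", "PL_non0", "PL_0", "phi"]]
        .median()
        .reset_index()
    )
    return reports, medians
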