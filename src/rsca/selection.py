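"""Variable selection for regularized SCA.

Two families of methods are implemented.  Tuning-based methods search a
grid of (lambda_L, lambda_G) pairs and return an optimal pair: CV with the
one-standard-error rule, repeated double CV (rdCV), an SCA-adjusted BIC,
and the Index of Sparseness (IS).  Pattern-based methods resample the rows
and return a zero/non-zero support over the loadings: Bolasso (strict
intersection of bootstrap supports) and an adapted stability selection
(subsample selection probabilities with a threshold pi_thr and a target
count Q of non-zero loadings).  Because the SCA solution is invariant
under permutation and sign flips of components, resampled loading matrices
are aligned to a reference by maximizing Tucker congruence before supports
are compared.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import ceil, sqrt

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data_model import MultiBlockData, ValidationError, concatenate
from .estimator import (
    FitConfig,
    ScaModel,
    ZeroPattern,
    fit_rsca,
    fit_with_fixed_pattern,
    lambda_max,
)

__all__ = [
    "TuningGrid",
    "SelectionResult",
    "make_grid",
    "mspe_cv",
    "cv_one_se",
    "rdcv",
    "bic_score",
    "bic_select",
    "index_of_sparseness",
    "is_select",
    "bolasso",
    "stability_selection",
    "q_bound",
    "tucker_congruence",
    "align_components",
]


@dataclass(frozen=True)
class TuningGrid:
    """Equally spaced penalty values per axis, ending at the all-zero value."""

    lasso_values: np.ndarray
    group_values: np.ndarray

    def __post_init__(self):
        for name in ("lasso_values", "group_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size < 1:
                raise ValidationError(f"{name} must be a non-empty 1-d array")
            if v[0] <= 0:
                raise ValidationError(f"{name} must start above 0")
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, v)

    @property
    def n_points(self) -> tuple[int, int]:
        return (len(self.lasso_values), len(self.group_values))

    def pairs(self) -> list[tuple[float, float]]:
        return [
            (float(l), float(g))
            for l in self.lasso_values
            for g in self.group_values
        ]


@dataclass
class SelectionResult:
    """Outcome of one variable-selection method.

    Tuning-based methods populate the chosen lambda pair; pattern-based
    methods populate ``pattern``.  ``diagnostics`` holds the method's
    surfaces / frequency tables / probabilities, and ``model`` the final
    refitted SCA model.
    """

    method: str
    chosen_lambda_L: float | None = None
    chosen_lambda_G: float | None = None
    pattern: ZeroPattern | None = None
    diagnostics: dict = field(default_factory=dict)
    model: ScaModel | None = None

    def __post_init__(self):
        tuned = self.chosen_lambda_L is not None and self.chosen_lambda_G is not None
        if tuned == (self.pattern is not None):
            raise ValidationError(
                "exactly one of (lambda pair, pattern) must be present"
            )


def make_grid(
    data: MultiBlockData,
    R: int,
    n_points: int = 50,
    floor_value: float = 1e-7,
    cfg: FitConfig | None = None,
) -> TuningGrid:
    """Equally spaced grid from a small floor up to the all-zero penalty."""
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    lam_l = lambda_max(data, R, "lasso", cfg)
    lam_g = lambda_max(data, R, "group", cfg)
    return TuningGrid(
        lasso_values=np.linspace(floor_value, lam_l, n_points),
        group_values=np.linspace(floor_value, lam_g, n_points),
    )


# --- cross-validation ------------------------------------------------


def _data_like(data: MultiBlockData, X_C: np.ndarray) -> MultiBlockData:
    """Wrap a concatenated matrix back into *data*'s block partition."""
    return MultiBlockData(
        [X_C[:, s] for s in data.block_slices()],
        block_names=data.block_names,
        column_labels=data.column_labels,
        preprocessing=data.preprocessing,
    )


def _row_subset(data: MultiBlockData, rows: np.ndarray) -> MultiBlockData:
    return MultiBlockData(
        [b[rows] for b in data.blocks],
        block_names=data.block_names,
        column_labels=data.column_labels,
        preprocessing=data.preprocessing,
    )


def _cell_folds(I: int, J: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition the I*J cell indices into folds, none emptying a column."""
    for _ in range(100):
        perm = rng.permutation(I * J)
        folds = np.array_split(perm, n_folds)
        ok = True
        for f in folds:
            cols, counts = np.unique(f % J, return_counts=True)
            if np.any(counts >= I):
                ok = False
                break
        if ok:
            return folds
    raise ValidationError("could not partition cells without emptying a column")


def _imputed_fold_matrices(
    X: np.ndarray, folds: list[np.ndarray]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per fold: the column-mean-completed matrix and the held-out flat indices."""
    I, J = X.shape
    out = []
    for f in folds:
        Xw = X.copy()
        flat = Xw.reshape(-1)
        flat[f] = np.nan
        col_means = np.nanmean(Xw, axis=0)
        rows, cols = np.unravel_index(f, (I, J))
        Xw[rows, cols] = col_means[cols]
        out.append((Xw, f))
    return out


def mspe_cv(
    data: MultiBlockData,
    R: int,
    lambda_L: float,
    lambda_G: float,
    n_folds: int = 5,
    seed: int | None = None,
    cfg: FitConfig | None = None,
) -> tuple[float, float]:
    """Element-wise K-fold CV estimate of the mean squared prediction error.

    Cells of X_C are partitioned at random into folds; held-out cells are
    replaced by their column mean over retained cells, the model is fitted
    on the completed table, and squared error is accumulated over the
    held-out cells only.  Returns (MSPE, SE) where MSPE is the mean
    per-fold error and SE the standard deviation of the per-fold errors
    over sqrt(n_folds).
    """
    X = concatenate(data)
    rng = np.random.default_rng(seed)
    folds = _cell_folds(data.I, data.total_columns, n_folds, rng)
    errors = _fold_errors(data, X, folds, R, lambda_L, lambda_G, cfg)
    return float(np.mean(errors)), float(np.std(errors, ddof=1) / np.sqrt(n_folds))


def _fold_errors(data, X, folds, R, lambda_L, lambda_G, cfg) -> np.ndarray:
    flat_true = X.reshape(-1)
    errs = []
    for Xw, held in _imputed_fold_matrices(X, folds):
        model = fit_rsca(_data_like(data, Xw), R, lambda_L, lambda_G, cfg)
        pred = model.reconstruction().reshape(-1)
        errs.append(float(np.sum((flat_true[held] - pred[held]) ** 2)))
    return np.asarray(errs)


def _tie_key(lam_l: float, lam_g: float) -> tuple[float, float]:
    # ties favor the sparser model: larger lambda_L first, then larger lambda_G
    return (lam_l, lam_g)


def cv_one_se(
    data: MultiBlockData,
    R: int,
    grid: TuningGrid,
    n_folds: int = 5,
    seed: int | None = None,
    mode: str = "not_larger",
    cfg: FitConfig | None = None,
) -> SelectionResult:
    """CV with the one-standard-error rule over the penalty grid.

    Finds the MSPE-minimizing pair (lambda_L*, lambda_G*), then returns the
    pair whose MSPE is closest to but not above MSPE* + SE* (mode
    ``"not_larger"``), or nearest that bound in absolute value (mode
    ``"closest"``, the variant used in simulation studies).  The same fold
    partition is shared by every grid pair.
    """
    if mode not in ("not_larger", "closest"):
        raise ValidationError("mode must be 'not_larger' or 'closest'")
    pairs = grid.pairs()
    if not pairs:
        raise ValidationError("empty grid")
    X = concatenate(data)
    rng = np.random.default_rng(seed)
    folds = _cell_folds(data.I, data.total_columns, n_folds, rng)
    fold_mats = _imputed_fold_matrices(X, folds)
    flat_true = X.reshape(-1)
    rows = []
    for lam_l, lam_g in pairs:
        errs = []
        for Xw, held in fold_mats:
            model = fit_rsca(_data_like(data, Xw), R, lam_l, lam_g, cfg)
            pred = model.reconstruction().reshape(-1)
            errs.append(float(np.sum((flat_true[held] - pred[held]) ** 2)))
        errs = np.asarray(errs)
        rows.append(
            {
                "lambda_L": lam_l,
                "lambda_G": lam_g,
                "mspe": float(np.mean(errs)),
                "se": float(np.std(errs, ddof=1) / np.sqrt(n_folds)),
            }
        )
    surface = pd.DataFrame(rows)
    best = surface.loc[surface["mspe"].idxmin()]
    # break exact MSPE ties towards the sparser pair
    minimal = surface[surface["mspe"] == best["mspe"]]
    best = minimal.sort_values(["lambda_L", "lambda_G"], ascending=False).iloc[0]
    bound = best["mspe"] + best["se"]
    if mode == "not_larger":
        eligible = surface[surface["mspe"] <= bound]
        gap = bound - eligible["mspe"]
    else:
        eligible = surface
        gap = (eligible["mspe"] - bound).abs()
    eligible = eligible.assign(gap=gap)
    chosen = eligible.sort_values(
        ["gap", "lambda_L", "lambda_G"], ascending=[True, False, False]
    ).iloc[0]
    return SelectionResult(
        method="cv_one_se",
        chosen_lambda_L=float(chosen["lambda_L"]),
        chosen_lambda_G=float(chosen["lambda_G"]),
        diagnostics={
            "mspe_surface": surface,
            "minimizer": (float(best["lambda_L"]), float(best["lambda_G"])),
            "bound": float(bound),
            "mode": mode,
        },
    )


def rdcv(
    data: MultiBlockData,
    R: int,
    grid: TuningGrid,
    n_segments: int = 2,
    n_repetitions: int = 50,
    inner_folds: int = 5,
    seed: int | None = None,
    mode: str = "not_larger",
    cfg: FitConfig | None = None,
) -> SelectionResult:
    """Repeated double CV: outer row segments, inner one-SE CV.

    Per repetition the rows are split into *n_segments* near-equal
    segments; each segment in turn is set aside and the one-SE CV runs on
    the remaining calibration rows, producing one (lambda_L, lambda_G)
    pair.  Over all repetitions the most frequent lambda_L and the most
    frequent lambda_G are chosen separately; frequency ties go to the
    larger (sparser) value.
    """
    if data.I < 2 * n_segments:
        raise ValidationError("need at least 2 rows per segment")
    seg_size = data.I // n_segments
    if seg_size < R:
        raise ValidationError(f"segments of {seg_size} rows cannot support R={R}")
    ss = np.random.SeedSequence(seed)
    chosen_l, chosen_g = [], []
    for rep_ss in ss.spawn(n_repetitions):
        rng = np.random.default_rng(rep_ss)
        perm = rng.permutation(data.I)
        segments = np.array_split(perm, n_segments)
        for tau in range(n_segments):
            calib_rows = np.sort(
                np.concatenate([segments[t] for t in range(n_segments) if t != tau])
            )
            sub = _row_subset(data, calib_rows)
            inner_seed = int(rng.integers(2**31))
            res = cv_one_se(sub, R, grid, inner_folds, inner_seed, mode, cfg)
            chosen_l.append(res.chosen_lambda_L)
            chosen_g.append(res.chosen_lambda_G)
    freq_l = pd.Series(chosen_l).value_counts()
    freq_g = pd.Series(chosen_g).value_counts()

    def most_frequent(freq: pd.Series) -> float:
        top = freq[freq == freq.max()]
        return float(max(top.index))

    return SelectionResult(
        method="rdcv",
        chosen_lambda_L=most_frequent(freq_l),
        chosen_lambda_G=most_frequent(freq_g),
        diagnostics={
            "frequency_lambda_L": freq_l,
            "frequency_lambda_G": freq_g,
            "pairs": list(zip(chosen_l, chosen_g)),
        },
    )


# --- information criteria --------------------------------------------


def _baseline_residual(data: MultiBlockData, baseline: ScaModel) -> float:
    X = concatenate(data)
    return float(np.sum((X - baseline.reconstruction()) ** 2))


def bic_score(
    data: MultiBlockData,
    R: int,
    lambda_L: float,
    lambda_G: float,
    baseline: ScaModel,
    cfg: FitConfig | None = None,
    variant: str = "croux",
    model: ScaModel | None = None,
) -> float:
    """SCA-adjusted BIC of a penalized fit.

    With V the residual sum of squares of the unpenalized ("baseline")
    SCA fit, Vt the penalized-model residual, and df the number of
    non-zero loadings,

        variant "croux":  BIC = Vt/V + df * log(I)/I
        variant "guo":    BIC = I*Vt/V + df * log(I)   (exactly I times the former)

    Exact rank-R data (V = 0) make the criterion undefined.
    """
    if variant not in ("croux", "guo"):
        raise ValidationError("variant must be 'croux' or 'guo'")
    V = _baseline_residual(data, baseline)
    X = concatenate(data)
    if V <= 1e-12 * float(np.sum(X * X)):
        raise ValidationError(
            "baseline residual is zero (exact rank-R data); "
            "add noise or reduce R before using the BIC"
        )
    if model is None:
        model = fit_rsca(data, R, lambda_L, lambda_G, cfg)
    Vt = _baseline_residual(data, model)
    df = model.n_nonzero
    I = data.I
    if variant == "croux":
        return Vt / V + df * np.log(I) / I
    return I * Vt / V + df * np.log(I)


def index_of_sparseness(
    data: MultiBlockData,
    R: int,
    lambda_L: float,
    lambda_G: float,
    baseline: ScaModel,
    cfg: FitConfig | None = None,
    model: ScaModel | None = None,
) -> float:
    """Index of Sparseness of a penalized fit.

    IS = (V_a * V_s / V_o^2) * (#zeros / total loadings) with V_o the total
    sum of squares of X_C, V_s the explained sum of squares of the
    unpenalized fit, and V_a that of the penalized fit.  Larger is better:
    the index rewards explained variance retained under sparsity.
    """
    X = concatenate(data)
    V_o = float(np.sum(X * X))
    if V_o == 0:
        raise ValidationError("data are identically zero")
    V_s = float(np.sum(baseline.reconstruction() ** 2))
    if model is None:
        model = fit_rsca(data, R, lambda_L, lambda_G, cfg)
    V_a = float(np.sum(model.reconstruction() ** 2))
    n_zero = model.P_C.size - model.n_nonzero
    return (V_a * V_s / V_o**2) * (n_zero / model.P_C.size)


def _criterion_select(
    data: MultiBlockData,
    R: int,
    grid: TuningGrid,
    cfg: FitConfig | None,
    score_fn,
    minimize: bool,
    method: str,
    surface_name: str,
) -> SelectionResult:
    baseline = fit_rsca(data, R, 0.0, 0.0, cfg)
    rows = []
    for lam_l, lam_g in grid.pairs():
        model = fit_rsca(data, R, lam_l, lam_g, cfg)
        rows.append(
            {
                "lambda_L": lam_l,
                "lambda_G": lam_g,
                "score": score_fn(lam_l, lam_g, baseline, model),
                "df": model.n_nonzero,
            }
        )
    surface = pd.DataFrame(rows)
    best_val = surface["score"].min() if minimize else surface["score"].max()
    top = surface[surface["score"] == best_val]
    chosen = top.sort_values(["lambda_L", "lambda_G"], ascending=False).iloc[0]
    return SelectionResult(
        method=method,
        chosen_lambda_L=float(chosen["lambda_L"]),
        chosen_lambda_G=float(chosen["lambda_G"]),
        diagnostics={surface_name: surface, "baseline": baseline},
    )


def bic_select(
    data: MultiBlockData,
    R: int,
    grid: TuningGrid,
    cfg: FitConfig | None = None,
    variant: str = "croux",
) -> SelectionResult:
    """Pair minimizing the SCA-adjusted BIC over the grid."""
    return _criterion_select(
        data,
        R,
        grid,
        cfg,
        lambda l, g, base, model: bic_score(
            data, R, l, g, base, cfg, variant, model=model
        ),
        minimize=True,
        method="bic",
        surface_name="bic_surface",
    )


def is_select(
    data: MultiBlockData,
    R: int,
    grid: TuningGrid,
    cfg: FitConfig | None = None,
) -> SelectionResult:
    """Pair maximizing the Index of Sparseness over the grid."""
    return _criterion_select(
        data,
        R,
        grid,
        cfg,
        lambda l, g, base, model: index_of_sparseness(
            data, R, l, g, base, cfg, model=model
        ),
        minimize=False,
        method="is",
        surface_name="is_surface",
    )


# --- component alignment ---------------------------------------------


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> float:
    """Cosine of the vectorized matrices: vec(A)'vec(B) / (||A|| ||B||)."""
    a = np.asarray(A, dtype=float).ravel()
    b = np.asarray(B, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("tucker_congruence requires equal shapes")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("tucker_congruence undefined for all-zero input")
    return float(a @ b / (na * nb))


def _congruence_matrix(reference: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    R = reference.shape[1]
    C = np.zeros((R, R))
    ref_norms = np.linalg.norm(reference, axis=0)
    est_norms = np.linalg.norm(estimate, axis=0)
    zero_cols = (ref_norms == 0).any() or (est_norms == 0).any()
    if zero_cols:
        warnings.warn(
            "zero column(s) during alignment; their congruence is taken as 0",
            UserWarning,
            stacklevel=3,
        )
    for i in range(R):
        for j in range(R):
            if ref_norms[i] == 0 or est_norms[j] == 0:
                continue
            C[i, j] = reference[:, i] @ estimate[:, j] / (ref_norms[i] * est_norms[j])
    return C


def align_components(
    reference: np.ndarray, estimate: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permute and sign-flip *estimate*'s columns to best match *reference*.

    Chooses the permutation maximizing the summed per-column |Tucker
    congruence| (exhaustively for R <= 5, by optimal assignment otherwise)
    and then flips signs so each matched congruence is non-negative.
    Returns (permutation, signs, aligned) with
    ``aligned[:, i] = signs[i] * estimate[:, permutation[i]]``.
    """
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if reference.shape != estimate.shape:
        raise ValidationError("alignment requires equal shapes")
    R = reference.shape[1]
    C = _congruence_matrix(reference, estimate)
    absC = np.abs(C)
    if R <= 5:
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(R)):
            score = sum(absC[i, perm[i]] for i in range(R))
            if score > best_score + 1e-15:
                best_score, best_perm = score, perm
        perm = np.asarray(best_perm, dtype=int)
    else:
        if R > 8:
            raise ValidationError("alignment supports at most R = 8 components")
        rows, cols = linear_sum_assignment(-absC)
        perm = cols[np.argsort(rows)]
    signs = np.where(C[np.arange(R), perm] < 0, -1.0, 1.0)
    aligned = estimate[:, perm] * signs
    return perm, signs, aligned


# --- resampling-based methods ----------------------------------------


def bolasso(
    data: MultiBlockData,
    R: int,
    grid: TuningGrid,
    n_repetitions: int = 50,
    inner_folds: int = 5,
    seed: int | None = None,
    mode: str = "not_larger",
    consensus: float = 1.0,
    cfg: FitConfig | None = None,
) -> SelectionResult:
    """Bolasso with CV: strict intersection of bootstrap supports.

    Each repetition draws I rows with replacement, selects a penalty pair
    by one-SE CV on the bootstrap sample, fits on the sample, and records
    the support of the aligned loading estimate (reference: the first
    repetition).  A loading survives only if non-zero in at least
    *consensus* (default: all) of the repetitions; the surviving support is
    refitted on the full data with the zeros fixed.
    """
    if not (0 < consensus <= 1):
        raise ValidationError("consensus must be in (0, 1]")
    ss = np.random.SeedSequence(seed)
    supports = []
    reference = None
    for rep_ss in ss.spawn(n_repetitions):
        rng = np.random.default_rng(rep_ss)
        sub = None
        for _ in range(100):
            rows = rng.integers(0, data.I, size=data.I)
            cand = _row_subset(data, np.sort(rows))
            Xc = concatenate(cand)
            if np.all(Xc.max(axis=0) > Xc.min(axis=0)):
                sub = cand
                break
        if sub is None:
            raise ValidationError("bootstrap kept producing constant columns")
        inner_seed = int(rng.integers(2**31))
        res = cv_one_se(sub, R, grid, inner_folds, inner_seed, mode, cfg)
        model = fit_rsca(sub, R, res.chosen_lambda_L, res.chosen_lambda_G, cfg)
        P = model.P_C
        if reference is None:
            reference = P
            aligned = P
        else:
            _, _, aligned = align_components(reference, P)
        supports.append(aligned != 0)
    counts = np.sum(supports, axis=0)
    mask = counts >= ceil(consensus * n_repetitions)
    pattern = ZeroPattern(mask)
    model = fit_with_fixed_pattern(data, R, pattern, cfg)
    return SelectionResult(
        method="bolasso",
        pattern=pattern,
        model=model,
        diagnostics={"bootstrap_supports": np.asarray(supports), "counts": counts},
    )


def stability_selection(
    data: MultiBlockData,
    R: int,
    lasso_values_desc: np.ndarray,
    Q: int,
    pi_thr: float = 0.6,
    n_subsamples: int = 100,
    seed: int | None = None,
    cfg: FitConfig | None = None,
) -> SelectionResult:
    """Stability selection adapted to regularized SCA.

    Walks a decreasing Lasso path starting at the all-zero value.  At each
    lambda, *n_subsamples* half-samples of the rows (drawn without
    replacement) are fitted with lambda_G = 0; the per-loading selection
    probability is the fraction of subsamples in which the loading is
    non-zero after alignment to the full-data fit at that lambda.  The walk
    stops once at least Q loadings reach probability >= pi_thr; the final
    support is the top-Q loadings by their maximum probability over the
    lambdas visited, refitted with the zeros fixed.  Q itself must be
    supplied (see ``q_bound`` for the error-control lower bound).
    """
    lasso_values_desc = np.asarray(lasso_values_desc, dtype=float)
    total = data.total_columns * R
    if not (0.5 < pi_thr <= 1):
        raise ValidationError("pi_thr must lie in (0.5, 1]")
    if not (1 <= Q <= total):
        raise ValidationError(f"Q must lie in [1, {total}]")
    if lasso_values_desc.ndim != 1 or lasso_values_desc.size < 1:
        raise ValidationError("lasso_values_desc must be a non-empty 1-d array")
    if lasso_values_desc.size > 1 and not np.all(np.diff(lasso_values_desc) < 0):
        raise ValidationError("lasso values must be strictly decreasing")
    half = data.I // 2
    if half < 1:
        raise ValidationError("need at least 2 rows to subsample")
    ss = np.random.SeedSequence(seed)
    max_probs = np.zeros((data.total_columns, R))
    prob_history = []
    reached = False
    visited = 0
    for s, lam in enumerate(lasso_values_desc):
        reference = fit_rsca(data, R, float(lam), 0.0, cfg).P_C
        counts = np.zeros((data.total_columns, R))
        lam_ss = ss.spawn(1)[0]
        rng = np.random.default_rng(lam_ss)
        for _ in range(n_subsamples):
            rows = rng.choice(data.I, size=half, replace=False)
            sub = _row_subset(data, np.sort(rows))
            P = fit_rsca(sub, R, float(lam), 0.0, cfg).P_C
            if np.any(P != 0) and np.any(reference != 0):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    _, _, P = align_components(reference, P)
            counts += P != 0
        probs = counts / n_subsamples
        prob_history.append(probs)
        max_probs = np.maximum(max_probs, probs)
        visited = s + 1
        if int(np.sum(probs >= pi_thr)) >= Q:
            reached = True
            break
    if not reached:
        warnings.warn(
            "lasso path exhausted before Q loadings reached pi_thr; "
            "returning the top-Q by maximum selection probability",
            UserWarning,
            stacklevel=2,
        )
    flat = max_probs.ravel()
    order = np.argsort(-flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:Q]] = True
    pattern = ZeroPattern(mask.reshape(max_probs.shape))
    model = fit_with_fixed_pattern(data, R, pattern, cfg)
    return SelectionResult(
        method="stability_selection",
        pattern=pattern,
        model=model,
        diagnostics={
            "selection_probabilities": max_probs,
            "probability_history": prob_history,
            "lambdas_visited": lasso_values_desc[:visited],
            "reached_Q": reached,
            "pi_thr": pi_thr,
            "Q": Q,
        },
    )


def q_bound(EV: float, pi_thr: float, total_loadings: int) -> int:
    """Error-control lower bound on the expected non-zero count Q.

    Solving EV = Q^2 / ((2*pi_thr - 1) * total_loadings) at equality gives
    Q = sqrt((2*pi_thr - 1) * EV * total_loadings); the smallest integer at
    or above the root is returned.  EV is the tolerated expected number of
    falsely selected loadings.
    """
    if EV <= 0:
        raise ValidationError("EV must be > 0")
    if not (0.5 < pi_thr <= 1):
        raise ValidationError("pi_thr must lie in (0.5, 1]")
    if total_loadings < 1:
        raise ValidationError("total_loadings must be >= 1")
    return int(ceil(sqrt((2 * pi_thr - 1) * EV * total_loadings)))
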