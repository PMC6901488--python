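"""Alternating estimation of the regularized SCA model.

The model minimizes, over an orthonormal score matrix T (I x R, T'T = I_R)
and concatenated block loadings P_C,

    sum_k ||X_k - T P_k'||_F^2
        + lambda_L * sum_k ||P_k||_1
        + lambda_G * sum_k sqrt(J_k) * sum_r ||p_r^k||_2 ,

where p_r^k is the r-th loading column of block k.  The Lasso term produces
elementwise zeros; the Group Lasso term zeroes whole per-block loading
vectors, which is what encodes common versus distinctive components.  Both
subproblems have exact solutions: given T, each column p_r^k has the
closed-form soft-threshold / group-shrinkage update; given P_C, the optimal
T is the orthogonal Procrustes solution obtained from an SVD.  Alternating
these exact updates makes the objective monotone non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import MultiBlockData, ValidationError, concatenate

__all__ = [
    "FitConfig",
    "ScaModel",
    "ZeroPattern",
    "soft_threshold",
    "update_loading_vector",
    "update_scores",
    "fit_rsca",
    "fit_with_fixed_pattern",
    "lambda_max",
    "sca_objective",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Convergence and initialization settings for the alternating fit.

    tol is the relative change of the penalized objective below which the
    loop stops; max_iter caps the number of alternating sweeps.  init "svd"
    starts T at the top-R left singular vectors of X_C (deterministic);
    "random" draws a Haar-orthonormal start from *seed*.
    """

    tol: float = 1e-8
    max_iter: int = 1000
    init: str = "svd"
    seed: int | None = None

    def __post_init__(self):
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.init not in ("svd", "random"):
            raise ValidationError("init must be 'svd' or 'random'")


@dataclass(frozen=True)
class ZeroPattern:
    """Boolean support mask over the concatenated loading matrix.

    True marks a loading free to be non-zero; False constrains it to zero.
    This is the currency passed between the resampling-based selection
    methods and the fixed-pattern refit.
    """

    mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValidationError("pattern mask must be 2-d")
        object.__setattr__(self, "mask", mask)

    @property
    def n_nonzero(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @classmethod
    def from_loadings(cls, P_C: np.ndarray) -> "ZeroPattern":
        return cls(np.asarray(P_C) != 0)


@dataclass
class ScaModel:
    """Fitted regularized SCA model.

    T is I x R with orthonormal columns; P_C is (sum_k J_k) x R.  Zeros in
    P_C are exact (produced by thresholding, not rounded), so sparsity
    counts compare against literal 0.
    """

    T: np.ndarray
    P_C: np.ndarray
    R: int
    lambda_L: float
    lambda_G: float
    loss_trajectory: np.ndarray
    converged: bool
    n_iter: int
    block_slices: list[slice] = field(default_factory=list)

    @property
    def loss(self) -> float:
        return float(self.loss_trajectory[-1])

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.P_C))

    def block_loadings(self, k: int) -> np.ndarray:
        return self.P_C[self.block_slices[k]]

    def pattern(self) -> ZeroPattern:
        return ZeroPattern.from_loadings(self.P_C)

    def reconstruction(self) -> np.ndarray:
        return self.T @ self.P_C.T


def soft_threshold(x, lam: float):
    """Elementwise soft-thresholding S(x, lam) = sign(x) * max(|x| - lam, 0)."""
    if lam < 0:
        raise ValidationError("soft_threshold requires lam >= 0")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def update_loading_vector(
    Xk: np.ndarray, t_r: np.ndarray, lambda_L: float, lambda_G: float, J_k: int | None = None
) -> np.ndarray:
    """Closed-form minimizer of one block-column loading subproblem.

    With T orthonormal and every other loading column fixed, the optimal
    p_r^k is

        [1/2 - lambda_G*sqrt(J_k) / (2*||S(2 Xk' t_r, lambda_L)||_2)]_+
            * S(2 Xk' t_r, lambda_L),

    the composition of the Lasso proximal map with multiplicative group
    shrinkage.  The whole vector collapses to exactly zero when the group
    penalty dominates or the thresholded vector vanishes.
    """
    Xk = np.asarray(Xk, dtype=float)
    t_r = np.asarray(t_r, dtype=float).ravel()
    if Xk.shape[0] != t_r.shape[0]:
        raise ValidationError(
            f"Xk has {Xk.shape[0]} rows but t_r has length {t_r.shape[0]}"
        )
    if lambda_L < 0 or lambda_G < 0:
        raise ValidationError("penalties must be >= 0")
    if J_k is None:
        J_k = Xk.shape[1]
    s = soft_threshold(2.0 * (Xk.T @ t_r), lambda_L)
    norm = np.linalg.norm(s)
    if norm == 0.0:
        return np.zeros(Xk.shape[1])
    factor = 0.5 - (lambda_G * np.sqrt(J_k)) / (2.0 * norm)
    if factor <= 0.0:
        return np.zeros(Xk.shape[1])
    return factor * s


def update_scores(X_C: np.ndarray, P_C: np.ndarray) -> np.ndarray:
    """Optimal orthonormal T given loadings: Procrustes via SVD.

    Writing U S V' for the SVD of P_C' X_C', the minimizer of
    sum_k ||X_k - T P_k'||^2 over T with T'T = I is T = V U'.
    """
    X_C = np.asarray(X_C, dtype=float)
    P_C = np.asarray(P_C, dtype=float)
    U, s, Vt = np.linalg.svd(P_C.T @ X_C.T, full_matrices=False)
    if s.size and np.any(s <= s.max(initial=0.0) * 1e-14):
        warnings.warn(
            "numerically zero singular values in the score update; "
            "the optimal T is not unique",
            ConvergenceWarning,
            stacklevel=2,
        )
    return Vt.T @ U.T


def _expand_per_block(values: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Repeat a (K, R) per-block array down to (sum J_k, R) rows."""
    return np.repeat(values, J, axis=0)


def sca_objective(
    X_C: np.ndarray,
    T: np.ndarray,
    P_C: np.ndarray,
    lambda_L: float,
    lambda_G: float,
    starts: np.ndarray,
    J: np.ndarray,
) -> float:
    """Penalized objective value at (T, P_C).

    Uses the orthonormality of T to evaluate the residual term as
    ||X_C||^2 - 2 tr(T' X_C P_C) + ||P_C||^2.
    """
    fit = (
        float(np.sum(X_C * X_C))
        - 2.0 * float(np.sum((X_C @ P_C) * T))
        + float(np.sum(P_C * P_C))
    )
    pen = 0.0
    if lambda_L > 0:
        pen += lambda_L * float(np.abs(P_C).sum())
    if lambda_G > 0:
        group_norms = np.sqrt(np.add.reduceat(P_C * P_C, starts, axis=0))
        pen += lambda_G * float((np.sqrt(J)[:, None] * group_norms).sum())
    return fit + pen


def _init_T(X_C: np.ndarray, R: int, cfg: FitConfig) -> np.ndarray:
    if cfg.init == "svd":
        U, _, _ = np.linalg.svd(X_C, full_matrices=False)
        return U[:, :R]
    rng = np.random.default_rng(cfg.seed)
    A = rng.standard_normal((X_C.shape[0], R))
    Q, _ = np.linalg.qr(A)
    return Q[:, :R]


def _alternate(
    X_C: np.ndarray,
    R: int,
    lambda_L: float,
    lambda_G: float,
    starts: np.ndarray,
    J: np.ndarray,
    cfg: FitConfig,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Shared alternating loop for penalized and fixed-pattern fits.

    One sweep updates every loading column (r-major over blocks, all given
    the current T, which makes the block updates independent and
    vectorizable), then refreshes T.  When *mask* is given the penalties
    are ignored and masked-out loadings are pinned to zero.
    """
    sqrtJ = np.sqrt(J)
    T = _init_T(X_C, R, cfg)
    losses = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        C = X_C.T @ T  # (sum J_k, R)
        if mask is not None:
            P = np.where(mask, C, 0.0)
        else:
            S = soft_threshold(2.0 * C, lambda_L)
            if lambda_G > 0:
                norms = np.sqrt(np.add.reduceat(S * S, starts, axis=0))  # (K, R)
                with np.errstate(divide="ignore", invalid="ignore"):
                    factor = 0.5 - (lambda_G * sqrtJ[:, None]) / (2.0 * norms)
                factor = np.where(norms > 0, np.maximum(factor, 0.0), 0.0)
                P = _expand_per_block(factor, J) * S
            else:
                P = 0.5 * S
        T = update_scores(X_C, P)
        loss = sca_objective(
            X_C, T, P, 0.0 if mask is not None else lambda_L,
            0.0 if mask is not None else lambda_G, starts, J,
        )
        losses.append(loss)
        if prev < np.inf and abs(prev - loss) <= cfg.tol * max(abs(prev), 1e-300):
            converged = True
            break
        prev = loss
    return T, P, np.asarray(losses), converged, it


def _prepare(data: MultiBlockData, R: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X_C = concatenate(data)
    if R > min(data.I, data.total_columns):
        raise ValidationError(
            f"R={R} exceeds min(I, sum J_k) = {min(data.I, data.total_columns)}"
        )
    return X_C, data.block_starts, np.asarray(data.J, dtype=int)


def fit_rsca(
    data: MultiBlockData,
    R: int,
    lambda_L: float,
    lambda_G: float,
    cfg: FitConfig | None = None,
) -> ScaModel:
    """Fit regularized SCA by alternating exact updates.

    Returns a model with orthonormal T, exactly-sparse P_C, and the
    per-iteration objective trajectory.  Non-convergence at max_iter yields
    a warning and ``converged=False``, never an exception.
    """
    if lambda_L < 0 or lambda_G < 0:
        raise ValidationError("penalties must be >= 0")
    cfg = cfg or FitConfig()
    X_C, starts, J = _prepare(data, R)
    T, P, losses, converged, n_iter = _alternate(
        X_C, R, lambda_L, lambda_G, starts, J, cfg
    )
    if not converged:
        warnings.warn(
            f"regularized SCA did not converge in {cfg.max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    return ScaModel(
        T=T,
        P_C=P,
        R=R,
        lambda_L=lambda_L,
        lambda_G=lambda_G,
        loss_trajectory=losses,
        converged=converged,
        n_iter=n_iter,
        block_slices=data.block_slices(),
    )


def fit_with_fixed_pattern(
    data: MultiBlockData,
    R: int,
    pattern: ZeroPattern,
    cfg: FitConfig | None = None,
) -> ScaModel:
    """Unpenalized refit with masked-out loadings pinned to exact zero.

    Used after a support has been chosen (Bolasso, stability selection):
    free loadings get the unpenalized update restricted to the support,
    zeros stay zero on every iteration.
    """
    cfg = cfg or FitConfig()
    X_C, starts, J = _prepare(data, R)
    if pattern.shape != (data.total_columns, R):
        raise ValidationError(
            f"pattern shape {pattern.shape} != {(data.total_columns, R)}"
        )
    if pattern.n_nonzero == 0:
        warnings.warn(
            "all-zero pattern: loadings are identically zero", ConvergenceWarning,
            stacklevel=2,
        )
        U, _, _ = np.linalg.svd(X_C, full_matrices=False)
        T = U[:, :R]
        P = np.zeros((data.total_columns, R))
        loss = sca_objective(X_C, T, P, 0.0, 0.0, starts, J)
        return ScaModel(
            T=T, P_C=P, R=R, lambda_L=0.0, lambda_G=0.0,
            loss_trajectory=np.array([loss]), converged=True, n_iter=0,
            block_slices=data.block_slices(),
        )
    T, P, losses, converged, n_iter = _alternate(
        X_C, R, 0.0, 0.0, starts, J, cfg, mask=pattern.mask
    )
    if not converged:
        warnings.warn(
            f"fixed-pattern refit did not converge in {cfg.max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    return ScaModel(
        T=T, P_C=P, R=R, lambda_L=0.0, lambda_G=0.0,
        loss_trajectory=losses, converged=converged, n_iter=n_iter,
        block_slices=data.block_slices(),
    )


def lambda_max(
    data: MultiBlockData,
    R: int,
    which: str = "lasso",
    cfg: FitConfig | None = None,
    rel_tol: float = 0.01,
    other_penalty: float = 1e-7,
) -> float:
    """Smallest penalty value (up to *rel_tol*) that zeroes all loadings.

    Bracketing + bisection on full fits with the other penalty held at a
    floor value.  Model-based rather than closed-form because T itself
    changes with the penalty.
    """
    if which not in ("lasso", "group"):
        raise ValidationError("which must be 'lasso' or 'group'")
    cfg = cfg or FitConfig()

    def n_nonzero(lam: float) -> int:
        if which == "lasso":
            m = fit_rsca(data, R, lam, other_penalty, cfg)
        else:
            m = fit_rsca(data, R, other_penalty, lam, cfg)
        return m.n_nonzero

    # initial scale from the data: 2*max|X_C' u| bounds the lasso threshold
    X_C = concatenate(data)
    hi = 2.0 * float(np.abs(X_C).sum(axis=0).max())
    if hi == 0.0:
        raise ValidationError("data are identically zero")
    lo = 0.0
    for _ in range(60):
        if n_nonzero(hi) == 0:
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise ValidationError("failed to bracket the all-zero penalty value")
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if n_nonzero(mid) == 0:
            hi = mid
        else:
            lo = mid
    return hi
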