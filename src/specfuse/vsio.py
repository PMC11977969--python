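"""HSIC-driven variable-space iterative optimization (wavelength selection).

The selector combines two signals about each spectral channel:

* an *importance* score ``WI_m = HSIC(y, eps_m) / HSIC(y, eps_full)``, where
  ``eps_full`` are prediction residuals of the full-spectrum PLSR model and
  ``eps_m`` the residuals with channel m removed — if dropping a channel makes
  the residuals more dependent on the response, that channel carried real
  information.  Residuals are cross-validated by default (out-of-fold
  predictions): with far fewer samples than channels a PLSR's training
  residuals are dominated by overfitting and carry no predictive signal,
  so dependence must be measured on held-out predictions;
* a *frequency* score from weighted binary matrix sampling (WBMS): an M × p
  0/1 matrix whose column i contains round(M * w_i) ones defines M candidate
  channel subsets; each subset is fitted by PLSR and ranked by k-fold RMSECV,
  and f_i is the fraction of the top sigma-share of models containing
  channel i.

Channel weights start at 0.5, are updated as W = 0.5 T' + 0.5 Q each
iteration, and the loop runs while the iteration-best RMSECV keeps improving.
The K channels with the largest final weights are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    InstabilityError,
    ParameterError,
    ShapeError,
)
from .hsic import KernelSpec, empirical_hsic
from .plsr import kfold_rmsecv, make_folds, plsr_fit, plsr_predict

__all__ = [
    "VSIOConfig",
    "VSIOResult",
    "wbms_sample",
    "wavelength_importance",
    "normalize_importance",
    "top_model_frequencies",
    "update_weights",
    "run_hsic_vsio",
]


@dataclass
class VSIOConfig:
    """Tuning knobs of the selector.

    Defaults follow the study conditions: M = 1000 sampled subsets per
    iteration, sigma = 10% top-model share, K = 20 selected channels,
    10 latent variables, 5 CV folds.
    """

    M: int = 1000
    sigma: float = 0.10
    K: int = 20
    n_lv: int = 10
    cv_folds: int = 5
    kernel: KernelSpec = field(default_factory=KernelSpec)
    max_outer_iter: int = 50
    seed: int = 0
    recompute_importance_each_iter: bool = False
    residual_mode: str = "cv"  # "cv" | "training"
    n_repeats: int = 2  # fold partitions averaged in importance and scoring

    def validate(self, p: int | None = None) -> None:
        if self.M < 10:
            raise ParameterError("VSIOConfig: M must be >= 10")
        if not 0 < self.sigma <= 1:
            raise ParameterError("VSIOConfig: sigma must be in (0, 1]")
        if round(self.M * self.sigma) < 1:
            raise ParameterError("VSIOConfig: round(M * sigma) must be >= 1")
        if self.K < 1:
            raise ParameterError("VSIOConfig: K must be >= 1")
        if p is not None and self.K > p:
            raise ParameterError(f"VSIOConfig: K={self.K} exceeds channel count p={p}")
        if self.residual_mode not in ("cv", "training"):
            raise ParameterError(f"VSIOConfig: unknown residual_mode {self.residual_mode!r}")
        if self.n_repeats < 1:
            raise ParameterError("VSIOConfig: n_repeats must be >= 1")


@dataclass
class VSIOResult:
    importance_raw: np.ndarray  # T
    importance_norm: np.ndarray  # T'
    frequencies: np.ndarray  # Q from the final iteration
    weights: np.ndarray  # final W
    rmsecv_trace: np.ndarray  # per-iteration minRMSECV
    selected: np.ndarray  # sorted channel indices, length K
    best_model_channels: np.ndarray  # channel subset of the overall-best sampled model
    seed_used: int


def wbms_sample(weights: np.ndarray, M: int, seed: int | np.random.Generator) -> np.ndarray:
    """Weighted binary matrix sampling: an M × p 0/1 matrix whose column i holds
    exactly round(M * w_i) ones at uniformly random rows.

    Draws with any all-zero row (a model must contain at least one channel)
    are redrawn, up to 100 attempts.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ParameterError("wbms_sample: weights must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = w.size
    counts = np.rint(M * w).astype(int)
    mat = np.zeros((M, p), dtype=np.int8)
    # rank a uniform draw per column: the first counts[i] rows get a one
    order = np.argsort(rng.random((M, p)), axis=0)
    for i in range(p):
        if counts[i] > 0:
            mat[order[:counts[i], i], i] = 1
    # repair all-zero rows by moving a one from a donor row with >= 2
    # channels; this keeps every column count exact
    for r in np.flatnonzero(~mat.any(axis=1)):
        for _ in range(100):
            donors = np.flatnonzero(mat.sum(axis=1) >= 2)
            if donors.size == 0:
                break
            r2 = int(rng.choice(donors))
            cols = np.flatnonzero(mat[r2])
            i = int(rng.choice(cols))
            mat[r2, i] = 0
            mat[r, i] = 1
            break
        if not mat[r].any():
            raise ParameterError(
                "wbms_sample: cannot build a sampling matrix without all-zero rows "
                "(weights too small?)"
            )
    return mat


def _residuals(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    folds: list[np.ndarray] | None,
) -> np.ndarray:
    """Model residuals: out-of-fold predictions when folds are given,
    otherwise the model's own training predictions."""
    n, p = X.shape
    if folds is None:
        model = plsr_fit(X, y, min(n_lv, n - 1, p))
        return y - plsr_predict(model, X)
    eps = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        lv = min(n_lv, int(mask.sum()) - 1, p)
        model = plsr_fit(X[mask], y[mask], lv)
        eps[fold] = y[fold] - plsr_predict(model, X[fold])
    return eps


def wavelength_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    kernel: KernelSpec = KernelSpec(),
    fold_lists: list[list[np.ndarray]] | None = None,
    residual_mode: str = "cv",
    cv_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-channel-out HSIC importance T = (WI_1 .. WI_p).

    WI_m = HSIC(y, eps_m) / HSIC(y, eps_full).  In ``"cv"`` mode (default)
    the residuals are out-of-fold predictions under the given fold
    partitions (one ratio per partition, averaged); ``"training"`` mode uses
    the model's own training residuals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ParameterError("wavelength_importance needs p >= 2 channels")
    if residual_mode == "training":
        fold_lists = [None]  # type: ignore[list-item]
    elif fold_lists is None:
        rng = np.random.default_rng(seed)
        fold_lists = [make_folds(n, cv_folds, rng)]
    t = np.zeros(p)
    cols = np.arange(p)
    for folds in fold_lists:
        eps_full = _residuals(X, y, n_lv, folds)
        h_full = empirical_hsic(y, eps_full, kernel, kernel)
        if h_full == 0.0:
            raise DegenerateInputError(
                "wavelength_importance: HSIC(y, eps_full) is zero (perfect "
                "full-spectrum fit); add noise or reduce n_lv"
            )
        for m in range(p):
            sub = X[:, cols != m]
            eps_m = _residuals(sub, y, n_lv, folds)
            t[m] += empirical_hsic(y, eps_m, kernel, kernel) / h_full
    return t / len(fold_lists)


def normalize_importance(t: np.ndarray) -> np.ndarray:
    """T' = T / max(T); requires a non-negative vector with a positive maximum."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("normalize_importance: negative importance values")
    m = t.max(initial=0.0)
    if m == 0.0:
        raise DegenerateInputError("normalize_importance: all-zero importance vector")
    return t / m


def top_model_frequencies(
    binary_matrix: np.ndarray, rmsecv_values: np.ndarray, sigma: float
) -> np.ndarray:
    """Channel frequencies Q over the top sigma-share of sampled models.

    Models are ranked by RMSECV ascending (ties at the cutoff broken by row
    index); f_i = N_i / round(M * sigma) with N_i the number of kept models
    containing channel i.
    """
    b = np.asarray(binary_matrix)
    r = np.asarray(rmsecv_values, dtype=float)
    if b.ndim != 2 or r.shape != (b.shape[0],):
        raise ShapeError("top_model_frequencies: matrix rows and RMSECV lengths differ")
    m = b.shape[0]
    n_keep = int(round(m * sigma))
    if n_keep < 1:
        raise ParameterError("top_model_frequencies: round(M * sigma) must be >= 1")
    order = np.argsort(r, kind="stable")
    kept = b[order[:n_keep]]
    return kept.sum(axis=0) / n_keep


def update_weights(t_norm: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Elementwise W = 0.5 * T' + 0.5 * Q."""
    t_norm = np.asarray(t_norm, dtype=float)
    q = np.asarray(q, dtype=float)
    if t_norm.shape != q.shape:
        raise ShapeError("update_weights: T' and Q lengths differ")
    if np.any((t_norm < 0) | (t_norm > 1)) or np.any((q < 0) | (q > 1)):
        raise ParameterError("update_weights: inputs must lie in [0, 1]")
    return 0.5 * t_norm + 0.5 * q


def _score_subsets(
    X: np.ndarray,
    y: np.ndarray,
    mat: np.ndarray,
    n_lv: int,
    fold_lists: list[list[np.ndarray]],
) -> np.ndarray:
    """Best RMSECV (min over the 1..n_lv curve, averaged over the fold
    partitions) for each sampled channel subset."""
    n = X.shape[0]
    scores = np.zeros(mat.shape[0])
    for folds in fold_lists:
        min_train = min(n - f.size for f in folds)
        for j, row in enumerate(mat):
            cols = np.flatnonzero(row)
            lv = min(n_lv, min_train - 1, cols.size)
            try:
                cv = kfold_rmsecv(X[:, cols], y, lv, folds=folds)
                scores[j] += float(np.min(cv.rmsecv_per_lv))
            except (DegenerateInputError, ParameterError, np.linalg.LinAlgError):
                scores[j] = np.nan
    return scores / len(fold_lists)


def run_hsic_vsio(X: np.ndarray, y: np.ndarray, cfg: VSIOConfig) -> VSIOResult:
    """Full selector: importance once, then WBMS/RMSECV iterations until the
    iteration-best RMSECV stops improving; output the top-K channels by weight."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    cfg.validate(p)
    if n < cfg.cv_folds:
        raise ParameterError(f"need n >= cv_folds, got n={n}, k={cfg.cv_folds}")

    master = np.random.SeedSequence(cfg.seed)
    ss_folds, ss_loop = master.spawn(2)
    rng_folds = np.random.default_rng(ss_folds)
    # one set of fold partitions for the whole run: every subset in every
    # iteration is scored on identical splits, so the trace and the model
    # ranking are not perturbed by partition noise
    fold_lists = [make_folds(n, cfg.cv_folds, rng_folds) for _ in range(cfg.n_repeats)]
    ss_iter = ss_loop.spawn(cfg.max_outer_iter)

    t_raw = wavelength_importance(
        X, y, cfg.n_lv, cfg.kernel, fold_lists=fold_lists, residual_mode=cfg.residual_mode
    )
    t_norm = normalize_importance(t_raw)

    weights = np.full(p, 0.5)
    trace: list[float] = []
    q = np.zeros(p)
    best_rmsecv = np.inf
    best_channels = np.arange(p)
    prev = np.inf
    for it in range(cfg.max_outer_iter):
        rng_sample = np.random.default_rng(ss_iter[it])
        mat = wbms_sample(weights, cfg.M, rng_sample)
        if cfg.recompute_importance_each_iter and it > 0:
            t_raw = wavelength_importance(
                X, y, cfg.n_lv, cfg.kernel,
                fold_lists=fold_lists, residual_mode=cfg.residual_mode,
            )
            t_norm = normalize_importance(t_raw)
        scores = _score_subsets(X, y, mat, cfg.n_lv, fold_lists)
        n_bad = int(np.sum(~np.isfinite(scores)))
        if n_bad > 0.5 * cfg.M:
            raise InstabilityError(
                f"run_hsic_vsio: {n_bad}/{cfg.M} sampled models had non-finite RMSECV"
            )
        finite = np.where(np.isfinite(scores), scores, np.inf)
        cur = float(finite.min())
        trace.append(cur)
        if cur < best_rmsecv:
            best_rmsecv = cur
            best_channels = np.flatnonzero(mat[int(np.argmin(finite))])
        q = top_model_frequencies(mat, finite, cfg.sigma)
        weights = update_weights(t_norm, q)
        if cur >= prev:
            break
        prev = cur

    # top-K by weight, ties resolved toward the lower channel index
    order = np.argsort(-weights, kind="stable")
    selected = np.sort(order[: cfg.K])
    return VSIOResult(
        importance_raw=t_raw,
        importance_norm=t_norm,
        frequencies=q,
        weights=weights,
        rmsecv_trace=np.asarray(trace),
        selected=selected,
        best_model_channels=best_channels,
        seed_used=cfg.seed,
    )
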