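"""NIPALS partial least squares regression (PLS1), k-fold RMSECV and metrics.

For a univariate response the NIPALS algorithm is deterministic: each
component's weight vector is the (normalized) covariance between the deflated
spectra and the deflated response.  Models store enough state to predict with
any number of components up to the fitted rank, which makes the RMSECV curve
over 1..L components a single fit per fold.

Evaluation follows chemometrics convention: RMSE on the raw response scale,
R^2 = 1 - SS_res/SS_tot, and RPD = sd(y)/RMSE (ratio of performance to
deviation; the closed form 1/sqrt(1 - R^2) is available as an option).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError, ShapeError

__all__ = [
    "PLSRModel",
    "Metrics",
    "CVResult",
    "plsr_fit",
    "plsr_predict",
    "kfold_rmsecv",
    "make_folds",
    "evaluate",
]


@dataclass
class PLSRModel:
    """Fitted centered PLS1 state.

    ``weights`` (p × L), ``x_loadings`` (p × L) and ``y_loadings`` (L,) are
    per-component vectors; ``coefficients`` is the equivalent regression
    vector in the original X space for the full component count.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    scores: np.ndarray | None = None  # training scores, kept for diagnostics

    def coefficients_for(self, n_components: int) -> np.ndarray:
        """Regression vector using only the first ``n_components`` components."""
        if not 1 <= n_components <= self.n_lv:
            raise ParameterError(
                f"n_components must be in [1, {self.n_lv}], got {n_components}"
            )
        w = self.weights[:, :n_components]
        p = self.x_loadings[:, :n_components]
        q = self.y_loadings[:n_components]
        return w @ np.linalg.solve(p.T @ w, q)

    def to_json(self) -> str:
        doc = {
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PLSRModel":
        doc = json.loads(text)
        return cls(
            n_lv=int(doc["n_lv"]),
            x_mean=np.asarray(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            weights=np.asarray(doc["weights"], dtype=float),
            x_loadings=np.asarray(doc["x_loadings"], dtype=float),
            y_loadings=np.asarray(doc["y_loadings"], dtype=float),
            coefficients=np.asarray(doc["coefficients"], dtype=float),
        )


@dataclass
class Metrics:
    """RMSE / R^2 / RPD evaluation record (RPD is math.inf for perfect fits)."""

    rmse: float
    r2: float
    rpd: float
    n: int


@dataclass
class CVResult:
    rmsecv_per_lv: np.ndarray  # index l-1 -> RMSECV with l components
    best_lv: int
    fold_assignment_seed: int | None = None
    folds: list[np.ndarray] = field(default_factory=list)


def plsr_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """Fit a centered PLS1 model with ``n_lv`` latent variables.

    Components are extracted by NIPALS: w = X'y / ||X'y||, scores t = Xw,
    loadings p = X't/t't, q = y't/t't, then rank-one deflation of X and y.
    Extraction stops early (with a reduced component count) if the residual
    covariance vanishes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape != (n,):
        raise ShapeError(f"y must have length {n}, got {y.shape}")
    if n < 2:
        raise ParameterError("plsr_fit needs at least 2 samples")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ParameterError(
            f"n_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {n_lv}"
        )
    if np.ptp(y) == 0:
        raise DegenerateInputError("plsr_fit: zero-variance response")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    e = X - x_mean
    f = y - y_mean
    ws, ps, qs, ts = [], [], [], []
    for _ in range(n_lv):
        w = e.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = e @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        pl = e.T @ t / tt
        q = float(f @ t) / tt
        e -= np.outer(t, pl)
        f -= q * t
        ws.append(w)
        ps.append(pl)
        qs.append(q)
        ts.append(t)
    if not ws:
        raise DegenerateInputError("plsr_fit: no extractable component (X'y = 0)")
    weights = np.column_stack(ws)
    loadings = np.column_stack(ps)
    yload = np.asarray(qs)
    model = PLSRModel(
        n_lv=len(ws),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=weights,
        x_loadings=loadings,
        y_loadings=yload,
        coefficients=np.zeros(p),
        scores=np.column_stack(ts),
    )
    model.coefficients = model.coefficients_for(model.n_lv)
    return model


def plsr_predict(
    model: PLSRModel, X: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Predict: y_hat = (X - x_mean) @ coefficients + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ShapeError(
            f"X has {X.shape[1]} columns, model was trained on {model.x_mean.size}"
        )
    beta = (
        model.coefficients
        if n_components is None or n_components == model.n_lv
        else model.coefficients_for(n_components)
    )
    return (X - model.x_mean) @ beta + model.y_mean


def make_folds(n: int, k: int, seed: int | np.random.Generator) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k folds with sizes differing by <= 1."""
    if not 2 <= k <= n:
        raise ParameterError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def kfold_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    k: int = 5,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> CVResult:
    """RMSECV curve for 1..n_lv components under a seeded random k-fold partition.

    Squared held-out errors are pooled over folds before the root is taken.
    ``best_lv`` minimizes the curve, ties broken toward fewer components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds is None:
        folds = make_folds(n, k, seed)
    min_train = min(n - f.size for f in folds)
    if n_lv >= min_train:
        raise ParameterError(
            f"n_lv={n_lv} must be < smallest fold-training size ({min_train})"
        )
    if n_lv > p:
        raise ParameterError(f"n_lv={n_lv} exceeds channel count {p}")
    sse = np.zeros(n_lv)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = plsr_fit(X[mask], y[mask], n_lv)
        xc = X[fold] - model.x_mean
        for l in range(1, n_lv + 1):
            beta = model.coefficients_for(min(l, model.n_lv))
            pred = xc @ beta + model.y_mean
            sse[l - 1] += float(np.sum((y[fold] - pred) ** 2))
    curve = np.sqrt(sse / n)
    best = int(np.argmin(curve)) + 1  # argmin returns the first (smallest L) minimum
    return CVResult(
        rmsecv_per_lv=curve,
        best_lv=best,
        fold_assignment_seed=seed if isinstance(seed, int) else None,
        folds=folds,
    )


def evaluate(y_true: np.ndarray, y_pred: np.ndarray, rpd_mode: str = "sd_ratio") -> Metrics:
    """Compute RMSE, R^2 and RPD for a prediction vector.

    ``rpd_mode="sd_ratio"`` (default) uses sample sd(y_true)/RMSE;
    ``"closed_form"`` uses 1/sqrt(1 - R^2).  A perfect fit reports
    ``rpd = math.inf`` rather than raising.
    """
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.shape != yp.shape:
        raise ShapeError("evaluate: length mismatch")
    if yt.size < 2:
        raise ParameterError("evaluate needs at least 2 observations")
    if rpd_mode not in ("sd_ratio", "closed_form"):
        raise ParameterError(f"unknown rpd_mode {rpd_mode!r}")
    resid = yt - yp
    rmse = float(np.sqrt(np.mean(resid**2)))
    sstot = float(np.sum((yt - yt.mean()) ** 2))
    if sstot == 0:
        raise DegenerateInputError("evaluate: zero variance in y_true; R^2/RPD undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    if rmse == 0.0:
        rpd = math.inf
    elif rpd_mode == "sd_ratio":
        rpd = float(np.std(yt, ddof=1)) / rmse
    else:
        rpd = math.inf if r2 >= 1.0 else 1.0 / math.sqrt(1.0 - r2)
    return Metrics(rmse=rmse, r2=r2, rpd=rpd, n=yt.size)
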