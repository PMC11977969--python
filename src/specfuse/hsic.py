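"""Kernels and the empirical Hilbert–Schmidt Independence Criterion.

The empirical HSIC between paired samples ``x_1..x_n`` and ``y_1..y_n`` is

    HSIC = (n - 1)^-2 * tr(K H L H)

with ``K_ij = k(x_i, x_j)``, ``L_ij = l(y_i, y_j)`` and the centering matrix
``H = I - n^-1 e e^T``.  For characteristic kernels (e.g. Gaussian RBF) the
population quantity is zero iff the variables are independent, which makes
the statistic usable as a dependence score between a response and model
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, NumericError, ParameterError, ShapeError

__all__ = ["KernelSpec", "median_heuristic", "kernel_matrix", "empirical_hsic"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and bandwidth rule.

    ``rbf`` uses k(x, x') = exp(-||x - x'||^2 / (2 s^2)) with s either fixed
    or the median of pairwise distances; ``linear`` uses plain inner products.
    """

    kind: str = "rbf"  # "rbf" | "linear"
    bandwidth_rule: str = "median"  # "median" | "fixed"
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ParameterError(f"unknown kernel kind {self.kind!r}")
        if self.bandwidth_rule not in ("median", "fixed"):
            raise ParameterError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.bandwidth_rule == "fixed" and (
            self.bandwidth is None or self.bandwidth <= 0
        ):
            raise ParameterError("fixed bandwidth must be a positive number")


def _as_2d(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.ndim != 2:
        raise ShapeError("observations must be a vector or a 2-D array")
    return v


def median_heuristic(values: np.ndarray) -> float:
    """Median of pairwise Euclidean distances over distinct observation pairs."""
    v = _as_2d(values)
    if v.shape[0] < 2:
        raise ParameterError("median_heuristic needs at least 2 observations")
    dists = pdist(v)
    med = float(np.median(dists))
    if med == 0.0:
        raise DegenerateInputError("median_heuristic: all observations identical")
    return med


def kernel_matrix(values: np.ndarray, spec: KernelSpec = KernelSpec()) -> np.ndarray:
    """Gram matrix of the observations under ``spec`` (symmetric; RBF has unit diagonal)."""
    v = _as_2d(values)
    if not np.all(np.isfinite(v)):
        raise NumericError("kernel_matrix: non-finite observations")
    if v.shape[0] < 2:
        raise ParameterError("kernel_matrix needs at least 2 observations")
    if spec.kind == "linear":
        return v @ v.T
    if spec.bandwidth_rule == "fixed":
        s = float(spec.bandwidth)  # type: ignore[arg-type]
    else:
        s = median_heuristic(v)
    d2 = squareform(pdist(v, "sqeuclidean"))
    return np.exp(-d2 / (2.0 * s * s))


def empirical_hsic(
    x: np.ndarray,
    y: np.ndarray,
    kx: KernelSpec = KernelSpec(),
    ky: KernelSpec = KernelSpec(),
) -> float:
    """Biased empirical HSIC estimate (n-1)^-2 tr(KHLH), clamped at zero.

    Symmetric in its arguments; exactly zero when either variable is constant
    (centering annihilates constant Gram matrices).
    """
    xv, yv = _as_2d(x), _as_2d(y)
    if xv.shape[0] != yv.shape[0]:
        raise ShapeError("empirical_hsic: x and y must have the same number of observations")
    n = xv.shape[0]
    if n < 2:
        raise ParameterError("empirical_hsic needs n >= 2")
    k = _gram_or_zero(xv, kx)
    l = _gram_or_zero(yv, ky)
    if k is None or l is None:
        return 0.0
    kc = k - k.mean(axis=0, keepdims=True)
    kc -= kc.mean(axis=1, keepdims=True)
    val = float(np.sum(kc * l)) / (n - 1) ** 2  # tr(HKH L) = <HKH, L>
    if val < -1e-10:
        raise NumericError(f"empirical_hsic: trace unexpectedly negative ({val:.3e})")
    return max(val, 0.0)


def _gram_or_zero(v: np.ndarray, spec: KernelSpec) -> np.ndarray | None:
    """Gram matrix, or None when the variable is constant (HSIC is then 0)."""
    try:
        return kernel_matrix(v, spec)
    except DegenerateInputError:
        return None
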