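"""Spectral preprocessing operators and leak-free composable pipelines.

Implements the operators commonly chained before multivariate calibration of
vibrational/NIR spectra:

* AirPLS — adaptive iteratively reweighted penalized least squares baseline
  estimation (Whittaker smoother with a second-difference penalty; weights of
  points above the running baseline are suppressed exponentially).
* MSC — multiplicative scatter correction against a reference spectrum.
* SNV — per-spectrum standardization (mean 0, sd 1).
* Savitzky–Golay smoothing / differentiation.
* Min–max scaling to [0, 1], per spectrum or per set.

Stateful steps (the MSC reference, per-set min–max bounds) are fitted on the
calibration set only and then applied unchanged to prediction data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import (
    CompatibilityError,
    DegenerateInputError,
    NumericError,
    ParameterError,
)
from .spectra_io import SpectrumSet

__all__ = [
    "StepKind",
    "PreprocessStep",
    "PreprocessPipeline",
    "PRESETS",
    "airpls_baseline",
    "msc",
    "snv",
    "savgol",
    "minmax_scale",
    "apply_pipeline",
    "make_preset",
]


class StepKind(str, Enum):
    AIRPLS = "AIRPLS"
    MSC = "MSC"
    SNV = "SNV"
    SAVGOL = "SAVGOL"
    MINMAX = "MINMAX"


@dataclass
class PreprocessStep:
    kind: StepKind
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = StepKind(self.kind)
        p = self.params
        if self.kind is StepKind.AIRPLS and p.get("lam", 1e5) <= 0:
            raise ParameterError("AirPLS smoothness penalty lam must be > 0")
        if self.kind is StepKind.SAVGOL:
            window = p.get("window", 11)
            order = p.get("order", 2)
            if window % 2 == 0 or window <= order:
                raise ParameterError("SAVGOL window must be odd and > polynomial order")


def airpls_baseline(
    spectrum: np.ndarray,
    lam: float = 1e5,
    max_iter: int = 30,
    ratio: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate a smooth baseline under ``spectrum`` and return (baseline, corrected).

    Iteratively reweighted Whittaker smoothing: points above the running
    baseline (peaks) get exponentially vanishing weight, points below keep
    pulling the fit down.  Stops when the residual mass below the baseline
    falls under ``ratio`` of the total signal mass, or at ``max_iter``.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ParameterError("airpls_baseline needs a 1-D spectrum of length >= 5")
    if not np.all(np.isfinite(x)):
        raise NumericError("airpls_baseline: non-finite values in spectrum")
    if lam <= 0:
        raise ParameterError("airpls_baseline: lam must be > 0")
    n = x.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = x.copy()
    for it in range(1, max_iter + 1):
        wmat = sparse.diags(w, 0, shape=(n, n), format="csc")
        z = spsolve(wmat + penalty, w * x)
        resid = x - z
        neg = resid < 0
        dssn = float(np.abs(resid[neg]).sum())
        if dssn < ratio * float(np.abs(x).sum()) or it == max_iter:
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(resid[neg]) / dssn)
        # anchor the endpoints so the baseline cannot drift free there
        w[0] = np.exp(it * float(resid[neg].max()) / dssn) if neg.any() else 1.0
        w[-1] = w[0]
    return z, x - z


def msc(data: SpectrumSet, reference="mean") -> SpectrumSet:
    """Multiplicative scatter correction: regress each spectrum on the
    reference (x ~ a + b*ref, OLS) and return (x - a)/b."""
    ref = (
        data.intensities.mean(axis=0)
        if isinstance(reference, str) and reference == "mean"
        else np.asarray(reference, dtype=float)
    )
    if ref.shape != (data.n_channels,):
        raise CompatibilityError("MSC reference length does not match channel count")
    corrected = np.empty_like(data.intensities)
    for i, x in enumerate(data.intensities):
        b, a = np.polyfit(ref, x, 1)
        if abs(b) < 1e-12:
            raise DegenerateInputError(
                f"MSC: degenerate fit (|b| < 1e-12) for sample {data.sample_ids[i]!r}"
            )
        corrected[i] = (x - a) / b
    return data.with_intensities(corrected, history="msc")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale one spectrum to mean 0, sd 1."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("SNV needs more than one channel")
    sd = x.std(ddof=1)
    if np.ptp(x) == 0 or sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("SNV: zero-variance spectrum")
    return (x - x.mean()) / sd


def savgol(
    spectrum: np.ndarray, window: int = 11, order: int = 2, deriv: int = 0
) -> np.ndarray:
    """Savitzky–Golay least-squares polynomial smoothing (edges by polynomial
    fit on the truncated window)."""
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window <= order or order < deriv:
        raise ParameterError("savgol requires odd window > order >= deriv")
    if window >= x.size:
        raise ParameterError("savgol window must be smaller than the spectrum")
    return savgol_filter(x, window_length=window, polyorder=order, deriv=deriv, mode="interp")


def minmax_scale(
    data: SpectrumSet,
    mode: str = "per-spectrum",
    bounds: tuple[float, float] | None = None,
) -> SpectrumSet:
    """Scale intensities into [0, 1].

    ``per-spectrum`` rescales each row independently; ``per-set`` uses one
    (min, max) pair for the whole matrix (pass ``bounds`` to reuse bounds
    fitted on calibration data).
    """
    x = data.intensities
    if mode == "per-spectrum":
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        if np.any(hi - lo == 0):
            raise DegenerateInputError("minmax_scale: constant spectrum")
        out = (x - lo) / (hi - lo)
    elif mode == "per-set":
        lo, hi = bounds if bounds is not None else (float(x.min()), float(x.max()))
        if hi - lo == 0:
            raise DegenerateInputError("minmax_scale: constant spectrum set")
        out = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    else:
        raise ParameterError(f"unknown minmax mode {mode!r}")
    return data.with_intensities(out, history=f"minmax:{mode}")


@dataclass
class PreprocessPipeline:
    """Ordered preprocessing steps plus the state captured on calibration data."""

    steps: list[PreprocessStep]
    fitted_state: dict = field(default_factory=dict)

    @property
    def description(self) -> str:
        return "+".join(s.kind.value.lower() for s in self.steps)


PRESETS: dict[str, list[tuple[str, dict]]] = {
    # baseline-first chain: AirPLS -> MSC -> SG -> min-max
    "airpls-msc-sg": [
        ("AIRPLS", {}),
        ("MSC", {}),
        ("SAVGOL", {}),
        ("MINMAX", {"mode": "per-set"}),
    ],
    # smoothing-first chain (default): SG -> SNV -> MSC -> min-max
    "sg-snv-msc": [
        ("SAVGOL", {}),
        ("SNV", {}),
        ("MSC", {}),
        ("MINMAX", {"mode": "per-set"}),
    ],
    "sg": [("SAVGOL", {}), ("MINMAX", {"mode": "per-set"})],
    "sg-snv": [("SAVGOL", {}), ("SNV", {}), ("MINMAX", {"mode": "per-set"})],
}

DEFAULT_PRESET = "sg-snv-msc"


def make_preset(name: str = DEFAULT_PRESET) -> PreprocessPipeline:
    if name not in PRESETS:
        raise ParameterError(f"unknown preprocessing preset {name!r}; have {sorted(PRESETS)}")
    return PreprocessPipeline([PreprocessStep(k, dict(p)) for k, p in PRESETS[name]])


def _apply_step(
    step: PreprocessStep, data: SpectrumSet, state: dict, fitting: bool
) -> SpectrumSet:
    p = step.params
    if step.kind is StepKind.AIRPLS:
        lam = p.get("lam", 1e5)
        max_iter = p.get("max_iter", 30)
        out = np.vstack(
            [airpls_baseline(row, lam=lam, max_iter=max_iter)[1] for row in data.intensities]
        )
        return data.with_intensities(out, history=f"airpls:lam={lam:g}")
    if step.kind is StepKind.SAVGOL:
        window = p.get("window", 11)
        order = p.get("order", 2)
        deriv = p.get("deriv", 0)
        out = np.vstack([savgol(row, window, order, deriv) for row in data.intensities])
        return data.with_intensities(out, history=f"savgol:w={window},o={order},d={deriv}")
    if step.kind is StepKind.SNV:
        out = np.vstack([snv(row) for row in data.intensities])
        return data.with_intensities(out, history="snv")
    if step.kind is StepKind.MSC:
        key = f"msc_ref_{id(step)}"
        if fitting:
            ref = p.get("reference", "mean")
            ref = data.intensities.mean(axis=0) if isinstance(ref, str) else np.asarray(ref)
            state[key] = ref
        return msc(data, reference=state[key])
    if step.kind is StepKind.MINMAX:
        mode = p.get("mode", "per-spectrum")
        if mode == "per-set":
            key = f"minmax_bounds_{id(step)}"
            if fitting:
                state[key] = (float(data.intensities.min()), float(data.intensities.max()))
            return minmax_scale(data, mode=mode, bounds=state[key])
        return minmax_scale(data, mode=mode)
    raise ParameterError(f"unknown step kind {step.kind}")


def apply_pipeline(
    pipeline: PreprocessPipeline,
    cal: SpectrumSet,
    pred: SpectrumSet | None = None,
) -> tuple[SpectrumSet, SpectrumSet | None]:
    """Fit the pipeline's state on ``cal`` and apply the identical transform to both sets.

    The MSC reference and per-set min–max bounds come from the calibration set
    only, so no information leaks from prediction data into the transform.
    """
    if cal.n_samples == 0:
        raise DegenerateInputError("apply_pipeline: empty calibration set")
    if pred is not None and not np.array_equal(cal.axis, pred.axis):
        raise CompatibilityError("apply_pipeline: calibration/prediction axes differ")
    state = pipeline.fitted_state
    out_cal, out_pred = cal, pred
    for step in pipeline.steps:
        out_cal = _apply_step(step, out_cal, state, fitting=True)
        if out_pred is not None:
            out_pred = _apply_step(step, out_pred, state, fitting=False)
    return out_cal, out_pred
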