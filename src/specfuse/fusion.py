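"""Direct and feature-level fusion of two spectral modalities, and the
four-way method comparison (single modalities vs direct vs feature-level
fusion).

Direct fusion concatenates the full preprocessed matrices column-wise
(NIR block first, then SERS); feature-level fusion concatenates only the
channels selected per modality by the HSIC-VSIO selector.  Sample alignment
is enforced by id equality, never by positional trust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParameterError, SelectionError
from .plsr import evaluate, kfold_rmsecv, plsr_fit, plsr_predict
from .spectra_io import SpectrumSet, SplitResult
from .synthetic import response_vector
from .vsio import VSIOConfig, run_hsic_vsio

__all__ = ["FusedMatrix", "direct_fuse", "feature_fuse", "compare_methods"]


@dataclass
class FusedMatrix:
    """Column-concatenated multi-modality matrix with per-column provenance.

    ``block_map`` rows are (modality, original channel index, axis position),
    in column order; blocks are contiguous, first input block then second.
    """

    matrix: np.ndarray
    block_map: list[tuple[str, int, float]]
    mode: str  # "DIRECT" | "FEATURE"
    sample_ids: list[str]
    concentrations: np.ndarray


def _check_aligned(a: SpectrumSet, b: SpectrumSet) -> None:
    if a.sample_ids != b.sample_ids:
        raise AlignmentError("fusion: sample ids differ or are ordered differently")
    if not np.allclose(a.concentrations, b.concentrations):
        raise AlignmentError("fusion: concentration labels differ between modalities")


def _check_scaled(s: SpectrumSet, name: str) -> None:
    if not any(h.startswith("minmax") for h in s.history):
        raise ParameterError(
            f"fusion: {name} has no min-max scaling in its preprocessing history; "
            "intensities of the two modalities must be on a common scale "
            "(pass require_scaled=False to override)"
        )


def direct_fuse(a: SpectrumSet, b: SpectrumSet, require_scaled: bool = True) -> FusedMatrix:
    """Full-spectrum fusion: [A | B], width p1 + p2."""
    _check_aligned(a, b)
    if require_scaled:
        _check_scaled(a, "first input")
        _check_scaled(b, "second input")
    block_map = [(a.modality.value, i, float(x)) for i, x in enumerate(a.axis)]
    block_map += [(b.modality.value, i, float(x)) for i, x in enumerate(b.axis)]
    return FusedMatrix(
        matrix=np.hstack([a.intensities, b.intensities]),
        block_map=block_map,
        mode="DIRECT",
        sample_ids=list(a.sample_ids),
        concentrations=a.concentrations.copy(),
    )


def _check_selection(sel: np.ndarray, p: int, name: str) -> np.ndarray:
    sel = np.asarray(sel, dtype=int)
    if sel.size and (sel.min() < 0 or sel.max() >= p):
        raise SelectionError(f"feature_fuse: {name} selection index out of range [0, {p})")
    if np.unique(sel).size != sel.size:
        raise SelectionError(f"feature_fuse: duplicate indices in {name} selection")
    return sel


def feature_fuse(
    a: SpectrumSet,
    sel_a: np.ndarray,
    b: SpectrumSet,
    sel_b: np.ndarray,
    require_scaled: bool = True,
) -> FusedMatrix:
    """Selected-channel fusion: [A[:, sel_a] | B[:, sel_b]], width |sel_a| + |sel_b|."""
    _check_aligned(a, b)
    if require_scaled:
        _check_scaled(a, "first input")
        _check_scaled(b, "second input")
    sel_a = _check_selection(sel_a, a.n_channels, "first")
    sel_b = _check_selection(sel_b, b.n_channels, "second")
    if sel_a.size == 0 and sel_b.size == 0:
        raise SelectionError("feature_fuse: both selections are empty")
    block_map = [(a.modality.value, int(i), float(a.axis[i])) for i in sel_a]
    block_map += [(b.modality.value, int(i), float(b.axis[i])) for i in sel_b]
    return FusedMatrix(
        matrix=np.hstack([a.intensities[:, sel_a], b.intensities[:, sel_b]]),
        block_map=block_map,
        mode="FEATURE",
        sample_ids=list(a.sample_ids),
        concentrations=a.concentrations.copy(),
    )


def _fit_and_score(
    x_cal: np.ndarray,
    y_cal: np.ndarray,
    x_pred: np.ndarray,
    y_pred_true: np.ndarray,
    n_lv_grid,
    cv_folds: int,
    seed: int,
    rpd_mode: str,
) -> dict:
    """Pick LVs from the grid by k-fold RMSECV on calibration data, then fit
    once and report calibration-fit and prediction metrics."""
    n = x_cal.shape[0]
    grid = [
        l for l in sorted(set(int(g) for g in n_lv_grid))
        if 1 <= l <= min(n - (n // cv_folds) - 1, x_cal.shape[1])
    ]
    if not grid:
        raise ParameterError("compare_methods: no feasible latent-variable count in grid")
    cv = kfold_rmsecv(x_cal, y_cal, max(grid), k=cv_folds, seed=seed)
    curve = cv.rmsecv_per_lv
    best_lv = min(grid, key=lambda l: (curve[l - 1], l))
    model = plsr_fit(x_cal, y_cal, best_lv)
    m_cal = evaluate(y_cal, plsr_predict(model, x_cal), rpd_mode=rpd_mode)
    m_pred = evaluate(y_pred_true, plsr_predict(model, x_pred), rpd_mode=rpd_mode)
    return {
        "LVs": best_lv,
        "RMSE1": m_cal.rmse,
        "Rc2": m_cal.r2,
        "RMSE2": m_pred.rmse,
        "Rp2": m_pred.r2,
        "RPD": m_pred.rpd,
    }


def compare_methods(
    nir: SplitResult,
    sers: SplitResult,
    cfg: VSIOConfig,
    n_lv_grid=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    response_scale: str = "log10",
    rpd_mode: str = "sd_ratio",
) -> pd.DataFrame:
    """Four-way comparison: NIR-only, SERS-only, direct fusion, feature-level
    fusion (HSIC-VSIO per modality, K channels each), all with CV-chosen LVs.

    Inputs are preprocessed split results with matched sample alignment.
    Returns a tidy table with columns Method, LVs, RMSE1, Rc2, RMSE2, Rp2, RPD.
    """
    _check_aligned(nir.calibration, sers.calibration)
    _check_aligned(nir.prediction, sers.prediction)
    y_cal = response_vector(nir.calibration, response_scale)
    y_pred = response_vector(nir.prediction, response_scale)

    ss = np.random.SeedSequence(cfg.seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    rows = []
    singles = [("NIR", nir, seeds[0]), ("SERS", sers, seeds[1])]
    for name, split, seed in singles:
        res = _fit_and_score(
            split.calibration.intensities, y_cal,
            split.prediction.intensities, y_pred,
            n_lv_grid, cfg.cv_folds, seed, rpd_mode,
        )
        rows.append({"Method": name, **res})

    fused_cal = direct_fuse(nir.calibration, sers.calibration)
    fused_pred = direct_fuse(nir.prediction, sers.prediction)
    res = _fit_and_score(
        fused_cal.matrix, y_cal, fused_pred.matrix, y_pred,
        n_lv_grid, cfg.cv_folds, seeds[2], rpd_mode,
    )
    rows.append({"Method": "NIR + SERS (direct fusion)", **res})

    from dataclasses import replace as _replace

    sel_nir = run_hsic_vsio(
        nir.calibration.intensities, y_cal, _replace(cfg, seed=seeds[3])
    ).selected
    sel_sers = run_hsic_vsio(
        sers.calibration.intensities, y_cal, _replace(cfg, seed=seeds[4])
    ).selected
    feat_cal = feature_fuse(nir.calibration, sel_nir, sers.calibration, sel_sers)
    feat_pred = feature_fuse(nir.prediction, sel_nir, sers.prediction, sel_sers)
    res = _fit_and_score(
        feat_cal.matrix, y_cal, feat_pred.matrix, y_pred,
        n_lv_grid, cfg.cv_folds, seeds[5], rpd_mode,
    )
    rows.append({"Method": "NIR + SERS (feature-level fusion)", **res})

    return pd.DataFrame(rows, columns=["Method", "LVs", "RMSE1", "Rc2", "RMSE2", "Rp2", "RPD"])
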