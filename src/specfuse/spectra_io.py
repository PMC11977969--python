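"""Labelled spectral matrices: CSV/XLSX I/O and the stratified calibration split.

The central container is :class:`SpectrumSet`, a wide spectral matrix
(rows = samples, columns = channels on a monotone wavenumber or wavelength
axis) with one concentration label per sample.  The calibration/prediction
split is stratified by concentration level: a fixed number of replicates per
level goes to calibration, the rest to prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    LabelledDataError,
    StratificationError,
)

__all__ = [
    "Modality",
    "SpectrumSet",
    "SplitResult",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_supplementary_xlsx",
    "stratified_split",
]


class Modality(str, Enum):
    NIR = "NIR"
    SERS = "SERS"
    RAMAN = "RAMAN"
    FUSED = "FUSED"


@dataclass
class SpectrumSet:
    """A labelled set of spectra sharing one channel axis.

    Parameters
    ----------
    sample_ids
        Opaque per-sample labels (unique within the set).
    modality
        Which instrument family the spectra come from.
    axis
        Strictly increasing channel positions (cm^-1 for Raman/SERS, nm for
        NIR).  Units are metadata only; no conversion is ever applied.
    intensities
        ``(n_samples, n_channels)`` matrix, arbitrary units.
    concentrations
        Analyte amount per sample (mol/L), non-negative.
    meta
        Free-form annotations; the preprocessing history is kept under the
        ``"preprocessing"`` key as a list of step descriptions.
    """

    sample_ids: list[str]
    modality: Modality
    axis: np.ndarray
    intensities: np.ndarray
    concentrations: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.modality = Modality(self.modality)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.axis.ndim != 1:
            raise FormatError("axis must be one-dimensional")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise FormatError("axis must be strictly increasing")
        n, p = self.intensities.shape if self.intensities.size else (len(self.sample_ids), self.axis.size)
        if self.intensities.size == 0:
            self.intensities = self.intensities.reshape(len(self.sample_ids), self.axis.size)
            n, p = self.intensities.shape
        if p != self.axis.size:
            raise FormatError(
                f"intensity columns ({p}) do not match axis length ({self.axis.size})"
            )
        if n != len(self.sample_ids):
            raise FormatError("sample_ids length does not match intensity rows")
        if self.concentrations.shape != (n,):
            raise LabelledDataError(
                f"expected {n} concentration labels, got {self.concentrations.shape}"
            )
        if np.any(~np.isfinite(self.concentrations)) or np.any(self.concentrations < 0):
            raise LabelledDataError("concentrations must be finite and non-negative")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def subset(self, rows: Sequence[int]) -> "SpectrumSet":
        rows = np.asarray(rows, dtype=int)
        return SpectrumSet(
            sample_ids=[self.sample_ids[i] for i in rows],
            modality=self.modality,
            axis=self.axis.copy(),
            intensities=self.intensities[rows].copy(),
            concentrations=self.concentrations[rows].copy(),
            meta=dict(self.meta),
        )

    def with_intensities(self, intensities: np.ndarray, history: str | None = None) -> "SpectrumSet":
        """Copy with replaced intensity matrix, optionally appending to history."""
        meta = dict(self.meta)
        if history is not None:
            meta["preprocessing"] = list(meta.get("preprocessing", [])) + [history]
        return SpectrumSet(
            sample_ids=list(self.sample_ids),
            modality=self.modality,
            axis=self.axis.copy(),
            intensities=np.asarray(intensities, dtype=float),
            concentrations=self.concentrations.copy(),
            meta=meta,
        )

    @property
    def history(self) -> list[str]:
        return list(self.meta.get("preprocessing", []))


@dataclass
class SplitResult:
    """Outcome of a concentration-stratified calibration/prediction split."""

    calibration: SpectrumSet
    prediction: SpectrumSet
    seed: int
    per_level_counts: pd.DataFrame  # columns: level, n_cal, n_pred


def read_spectra_csv(
    path,
    modality: Modality | str = Modality.SERS,
    options: Mapping | None = None,
) -> SpectrumSet:
    """Read a wide spectral CSV (sample_id, concentration, then one column per channel).

    The axis is taken from the header names; if the file stores channels in
    descending order, columns are reordered so the returned axis is ascending.
    """
    opts = dict(options or {})
    opts.setdefault("float_precision", "round_trip")
    try:
        df = pd.read_csv(path, dtype={0: str}, **opts)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected sample_id, concentration and >=1 channel column")
    id_col, conc_col = df.columns[0], df.columns[1]
    chan_cols = list(df.columns[2:])
    try:
        axis = np.array([float(c) for c in chan_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: channel header names must be numeric: {exc}") from exc
    conc = pd.to_numeric(df[conc_col], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(conc)):
        bad = list(df.index[~np.isfinite(conc)])
        raise LabelledDataError(
            f"{path}: missing/non-numeric concentration in row(s) {bad}"
        )
    intens = df[chan_cols].to_numpy(dtype=float)
    order = np.argsort(axis, kind="stable")
    axis_sorted = axis[order]
    if axis_sorted.size > 1 and not np.all(np.diff(axis_sorted) > 0):
        raise FormatError(f"{path}: axis has duplicate channel positions; cannot sort")
    return SpectrumSet(
        sample_ids=df[id_col].astype(str).tolist(),
        modality=Modality(modality),
        axis=axis_sorted,
        intensities=intens[:, order],
        concentrations=conc,
    )


def write_spectra_csv(data: SpectrumSet, path) -> None:
    """Write the wide-CSV layout read by :func:`read_spectra_csv`.

    Floats are written with Python's shortest round-trip representation, so a
    write/read cycle preserves values bit-exactly.
    """
    cols = {"sample_id": data.sample_ids, "concentration": data.concentrations}
    df = pd.DataFrame(cols)
    chan = pd.DataFrame(
        data.intensities, columns=[repr(float(a)) for a in data.axis], index=df.index
    )
    pd.concat([df, chan], axis=1).to_csv(path, index=False)


def read_supplementary_xlsx(
    path,
    sheet: int | str = 0,
    modality: Modality | str = Modality.RAMAN,
) -> SpectrumSet:
    """Read a figure-source workbook of (axis, intensity) column series.

    The axis column is auto-detected as the strictly monotone numeric column;
    every other numeric column of the same length becomes one sample.
    Concentration labels are not present in such files and are set to zero
    with ``meta["concentrations_unknown"] = True``.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    numeric = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        vals = vals[: _trailing_valid(vals)]
        if vals.size >= 2 and np.all(np.isfinite(vals)):
            numeric[col] = vals
    axis_col = None
    for col, vals in numeric.items():
        d = np.diff(vals)
        if np.all(d > 0) or np.all(d < 0):
            axis_col = col
            break
    if axis_col is None:
        raise FormatError(f"{path}: no strictly monotone numeric column to use as axis")
    axis = numeric[axis_col]
    series = {c: v for c, v in numeric.items() if c != axis_col}
    if not series:
        raise FormatError(f"{path}: no intensity series besides the axis column")
    lengths = {v.size for v in series.values()}
    if lengths != {axis.size}:
        raise FormatError(
            f"{path}: intensity series lengths {sorted(lengths)} do not all match axis length {axis.size}"
        )
    names = list(series)
    intens = np.vstack([series[c] for c in names])
    if axis[0] > axis[-1]:
        axis = axis[::-1]
        intens = intens[:, ::-1]
    return SpectrumSet(
        sample_ids=[str(n) for n in names],
        modality=Modality(modality),
        axis=axis,
        intensities=intens,
        concentrations=np.zeros(len(names)),
        meta={"concentrations_unknown": True, "source": str(path)},
    )


def _trailing_valid(vals: np.ndarray) -> int:
    """Length of the leading finite block (tolerates trailing NaN padding)."""
    finite = np.isfinite(vals)
    if finite.all():
        return vals.size
    first_bad = int(np.argmin(finite))
    if finite[first_bad:].any():  # interior gap -> treat as non-numeric column
        return 0
    return first_bad


def stratified_split(data: SpectrumSet, n_cal_per_level: int, seed: int) -> SplitResult:
    """Per concentration level, send exactly ``n_cal_per_level`` random replicates
    to calibration and the remainder to prediction (reproducible under ``seed``)."""
    if n_cal_per_level < 1:
        raise StratificationError("n_cal_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    levels = np.unique(data.concentrations)
    cal_rows: list[int] = []
    pred_rows: list[int] = []
    counts = []
    for lv in levels:
        rows = np.flatnonzero(data.concentrations == lv)
        if rows.size < n_cal_per_level:
            raise StratificationError(
                f"concentration level {lv!r} has {rows.size} replicates, "
                f"fewer than n_cal_per_level={n_cal_per_level}"
            )
        perm = rng.permutation(rows.size)
        cal_rows.extend(rows[perm[:n_cal_per_level]].tolist())
        pred_rows.extend(rows[perm[n_cal_per_level:]].tolist())
        counts.append((lv, n_cal_per_level, rows.size - n_cal_per_level))
    cal_rows.sort()
    pred_rows.sort()
    table = pd.DataFrame(counts, columns=["level", "n_cal", "n_pred"])
    return SplitResult(
        calibration=data.subset(cal_rows),
        prediction=data.subset(pred_rows),
        seed=seed,
        per_level_counts=table,
    )
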