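"""Prominence-ranked peak detection for characteristic-band identification.

Used to read off characteristic peak positions from measured or simulated
spectra (e.g. the chlorpyrifos SERS bands at 609/990 cm^-1) and to validate
synthetic data.  Detection is plain local-maximum search with a topographic
prominence threshold expressed as a fraction of the spectrum's dynamic
range, so peak positions are invariant under positive affine intensity
transforms.  Positions are reported on the channel grid (no sub-channel
interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError
from .preprocess import airpls_baseline
from .spectra_io import SpectrumSet

__all__ = ["Peak", "PeakList", "detect_peaks"]


@dataclass(frozen=True)
class Peak:
    position: float  # axis units
    height: float
    prominence: float


@dataclass
class PeakList:
    """Detected peaks, sorted by prominence descending."""

    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    def positions(self, top: int | None = None) -> np.ndarray:
        sel = self.peaks if top is None else self.peaks[:top]
        return np.array([p.position for p in sel])


def detect_peaks(
    spectrum: SpectrumSet | np.ndarray,
    axis: np.ndarray | None = None,
    min_prominence_frac: float = 0.05,
    baseline_correct: bool = False,
    airpls_lam: float = 1e4,
) -> PeakList:
    """Find local maxima with prominence >= ``min_prominence_frac`` x dynamic range.

    Accepts a single-sample :class:`SpectrumSet` or a raw vector plus axis.
    An empty result is not an error.
    """
    if isinstance(spectrum, SpectrumSet):
        if spectrum.n_samples != 1:
            raise ParameterError("detect_peaks expects a single-sample SpectrumSet")
        x = spectrum.intensities[0]
        ax = spectrum.axis
    else:
        x = np.asarray(spectrum, dtype=float)
        if axis is None:
            ax = np.arange(x.size, dtype=float)
        else:
            ax = np.asarray(axis, dtype=float)
    if x.size < 5:
        raise ParameterError("detect_peaks needs at least 5 channels")
    if not 0 < min_prominence_frac <= 1:
        raise ParameterError("min_prominence_frac must be in (0, 1]")
    if baseline_correct:
        _, x = airpls_baseline(x, lam=airpls_lam)
    span = float(np.ptp(x))
    if span == 0.0:
        return PeakList([])
    idx, props = find_peaks(x, prominence=min_prominence_frac * span)
    order = np.argsort(-props["prominences"], kind="stable")
    return PeakList(
        [
            Peak(
                position=float(ax[idx[i]]),
                height=float(x[idx[i]]),
                prominence=float(props["prominences"][i]),
            )
            for i in order
        ]
    )
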