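"""Synthetic dual-modality spectra with planted ground truth.

Two modality styles are emulated:

* ``SERS_SHARP`` — Raman shift axis 400–1800 cm^-1 with sharp Lorentzian
  analyte peaks whose heights track concentration (chlorpyrifos-like bands at
  609 and 990 cm^-1, pymetrozine-like bands at 558 and 990 cm^-1) on top of
  fixed solvent bands (740/910/1040/1370 cm^-1), mild baseline drift and
  small multiplicative scatter.
* ``NIR_BROAD`` — wavelength axis 1000–2500 nm with broad overlapping
  Gaussian bands, a strong moisture/matrix band near 1450 nm whose height
  varies sample-to-sample, pronounced baseline drift and multiplicative
  scatter, and a log-linear analyte response (absorption-like behaviour over
  a three-decade concentration range).

Every simulation returns the ground truth needed by recovery studies: the
informative channels are those within two peak widths of an analyte peak
center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .errors import ParameterError
from .spectra_io import Modality, SpectrumSet, SplitResult, stratified_split

__all__ = [
    "PeakSpec",
    "SyntheticDesign",
    "GroundTruth",
    "default_design",
    "recovery_benchmark_design",
    "simulate",
    "benchmark_dataset",
    "response_vector",
]

CHLORPYRIFOS_SERS_PEAKS = (609.0, 990.0)
PYMETROZINE_SERS_PEAKS = (558.0, 990.0)
SOLVENT_PEAKS = (740.0, 910.0, 1040.0, 1370.0)


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: either concentration-responsive (``response``) or
    fixed-height background (``fixed_height``); exactly one must be set."""

    center: float
    width: float
    shape: str = "gaussian"  # "gaussian" | "lorentzian"
    response: float | None = None
    fixed_height: float | None = None
    jitter_sd: float | None = None  # per-peak override of the design-level jitter

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError("PeakSpec: width must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ParameterError(f"PeakSpec: unknown shape {self.shape!r}")
        if (self.response is None) == (self.fixed_height is None):
            raise ParameterError("PeakSpec: exactly one of response/fixed_height must be set")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-height line shape over the axis (width = Gaussian sd or Lorentzian HWHM)."""
        d = axis - self.center
        if self.shape == "gaussian":
            return np.exp(-(d**2) / (2.0 * self.width**2))
        return self.width**2 / (d**2 + self.width**2)


@dataclass
class SyntheticDesign:
    axis_start: float
    axis_end: float
    n_channels: int
    analyte_peaks: dict[str, list[PeakSpec]]
    background_peaks: list[PeakSpec]
    baseline_coeffs: tuple[float, ...]  # polynomial in scaled axis u in [0, 1]
    baseline_amplitude: float
    scatter: tuple[float, float]  # (multiplicative sd, additive sd)
    background_jitter_sd: float  # per-sample fractional jitter of fixed bands
    analyte_jitter_sd: float  # per-sample fractional jitter of analyte response
    drift_jitter_sd: float  # per-sample random quadratic baseline drift amplitude
    noise_sd: float
    concentration_levels: np.ndarray
    replicates_per_level: int
    modality_style: str  # "SERS_SHARP" | "NIR_BROAD"
    response_scale: str = "linear"  # "linear" | "log10"
    response_ref: float = 1e-7  # log10 response: height ~ response * log10(c / ref)
    seed: int = 0
    # high-rank matrix clutter: many minor bands at fixed random positions
    # (drawn once from the design seed) whose amplitudes vary independently
    # per sample — the un-orthogonalizable spectral variability of a real
    # sample matrix
    clutter_n: int = 0
    clutter_width: float = 10.0
    clutter_amp_sd: float = 0.0

    def __post_init__(self) -> None:
        self.concentration_levels = np.asarray(self.concentration_levels, dtype=float)
        if self.n_channels < 10:
            raise ParameterError("SyntheticDesign: n_channels must be >= 10")
        if self.replicates_per_level < 1:
            raise ParameterError("SyntheticDesign: replicates_per_level must be >= 1")
        lv = self.concentration_levels
        if np.any(lv < 0) or np.unique(lv).size != lv.size:
            raise ParameterError("SyntheticDesign: levels must be distinct and non-negative")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_start, self.axis_end, self.n_channels)

    def informative_channels(self) -> np.ndarray:
        """Channels within +/- 2 widths of any analyte peak center (sorted, unique)."""
        axis = self.axis
        hit = np.zeros(self.n_channels, dtype=bool)
        for peaks in self.analyte_peaks.values():
            for pk in peaks:
                hit |= np.abs(axis - pk.center) <= 2.0 * pk.width
        return np.flatnonzero(hit)


class GroundTruth(NamedTuple):
    informative_channels: np.ndarray
    multiplicative_draws: np.ndarray
    additive_draws: np.ndarray


def default_design(modality_style: str) -> SyntheticDesign:
    """The benchmark designs: sharp SERS-like or broad NIR-like spectra,
    6 log-spaced concentration levels (1e-6 to 1e-3 M) x 10 replicates.

    Both modalities respond log-linearly in concentration over the three
    usable decades (SERS peak heights saturate with surface coverage; NIR
    band absorbances of a trace analyte in a fixed matrix vary weakly), and
    each carries its characteristic error structure: SERS spectra have sharp,
    well-separated analyte bands but sample-to-sample enhancement-factor
    variability (10%); NIR spectra have broad overlapping bands, a dominant
    moisture/matrix band with strong per-sample variability (15%), and
    pronounced per-sample baseline drift and scatter.
    """
    levels = np.logspace(-6, -3, 6)
    if modality_style == "SERS_SHARP":
        lor = "lorentzian"
        return SyntheticDesign(
            axis_start=400.0,
            axis_end=1800.0,
            n_channels=700,
            analyte_peaks={
                "chlorpyrifos": [
                    PeakSpec(CHLORPYRIFOS_SERS_PEAKS[0], 8.0, lor, response=0.20),
                    PeakSpec(CHLORPYRIFOS_SERS_PEAKS[1], 8.0, lor, response=0.16),
                ],
                "pymetrozine": [
                    PeakSpec(PYMETROZINE_SERS_PEAKS[0], 8.0, lor, response=0.18),
                    PeakSpec(PYMETROZINE_SERS_PEAKS[1], 8.0, lor, response=0.14),
                ],
            },
            background_peaks=[
                PeakSpec(SOLVENT_PEAKS[0], 10.0, lor, fixed_height=0.90),
                PeakSpec(SOLVENT_PEAKS[1], 10.0, lor, fixed_height=0.60),
                PeakSpec(SOLVENT_PEAKS[2], 10.0, lor, fixed_height=0.75),
                PeakSpec(SOLVENT_PEAKS[3], 10.0, lor, fixed_height=0.45),
            ],
            baseline_coeffs=(0.2, 0.6, -0.4),
            baseline_amplitude=0.10,
            scatter=(0.05, 0.01),
            background_jitter_sd=0.05,
            analyte_jitter_sd=0.10,
            drift_jitter_sd=0.02,
            noise_sd=0.005,
            concentration_levels=levels,
            replicates_per_level=10,
            modality_style=modality_style,
            response_scale="log10",
            clutter_n=38,
            clutter_width=12.0,
            clutter_amp_sd=0.055,
        )
    if modality_style == "NIR_BROAD":
        return SyntheticDesign(
            axis_start=1000.0,
            axis_end=2500.0,
            n_channels=500,
            analyte_peaks={
                "combined": [
                    PeakSpec(1210.0, 60.0, "gaussian", response=0.064),
                    PeakSpec(1690.0, 80.0, "gaussian", response=0.080),
                    PeakSpec(2120.0, 70.0, "gaussian", response=0.048),
                ],
            },
            background_peaks=[
                PeakSpec(1450.0, 100.0, "gaussian", fixed_height=1.00),  # moisture band
                PeakSpec(1940.0, 90.0, "gaussian", fixed_height=0.80),
                # matrix bands overlapping the analyte regions, with strong
                # per-sample variability: the analyte signal is never clean
                PeakSpec(1230.0, 80.0, "gaussian", fixed_height=0.35, jitter_sd=0.15),
                PeakSpec(1670.0, 90.0, "gaussian", fixed_height=0.45, jitter_sd=0.15),
                PeakSpec(2100.0, 100.0, "gaussian", fixed_height=0.40, jitter_sd=0.15),
            ],
            baseline_coeffs=(0.5, 1.0, -0.3),
            baseline_amplitude=0.30,
            scatter=(0.10, 0.05),
            background_jitter_sd=0.08,
            analyte_jitter_sd=0.05,
            drift_jitter_sd=0.06,
            noise_sd=0.010,
            concentration_levels=levels,
            replicates_per_level=10,
            modality_style=modality_style,
            response_scale="log10",
            clutter_n=15,
            clutter_width=100.0,
            clutter_amp_sd=0.02,
        )
    raise ParameterError(f"unknown modality style {modality_style!r}")


def recovery_benchmark_design(n_channels: int = 200) -> SyntheticDesign:
    """Planted-signal benchmark for selector-recovery studies.

    Eight analyte bands at characteristic Raman-shift positions of the two
    pesticides (SERS and solid-state: 558/609/627/673/990/1095/1166/1294
    cm^-1), each so narrow (Gaussian, 1/4 of the channel spacing, centered on
    a grid point) that exactly one channel per band is informative.  Band
    heights are log-linear in concentration — i.e. proportional to the
    log-scale response the calibration models — and the channel noise is
    large enough (sd 0.15) that every additional recovered channel improves
    prediction measurably.  This makes "which channels does the selector
    find" a well-posed question: the informative set is identifiable, yet no
    single channel suffices.
    """
    base = default_design("SERS_SHARP")
    axis = np.linspace(base.axis_start, base.axis_end, n_channels)
    spacing = float(axis[1] - axis[0])
    width = 0.25 * spacing

    def snap(target: float) -> float:
        i = int(round((target - axis[0]) / spacing))
        return float(axis[min(max(i, 0), n_channels - 1)])

    centers = (558.0, 609.0, 627.0, 673.0, 990.0, 1095.0, 1166.0, 1294.0)
    responses = (0.40, 0.35, 0.30, 0.25, 0.35, 0.30, 0.25, 0.20)
    peaks = [
        PeakSpec(snap(c), width, "gaussian", response=r)
        for c, r in zip(centers, responses)
    ]
    return replace(
        base,
        n_channels=n_channels,
        analyte_peaks={"pesticide_mix": peaks},
        response_scale="log10",
        analyte_jitter_sd=0.0,
        drift_jitter_sd=0.0,
        noise_sd=0.15,
        clutter_n=0,
        clutter_amp_sd=0.0,
    )


def _peak_height(pk: PeakSpec, conc: float, design: SyntheticDesign) -> float:
    if pk.fixed_height is not None:
        return pk.fixed_height
    assert pk.response is not None
    if design.response_scale == "linear":
        return pk.response * conc
    if conc <= design.response_ref:
        return 0.0
    return pk.response * float(np.log10(conc / design.response_ref))


def simulate(design: SyntheticDesign, seed: int | None = None) -> tuple[SpectrumSet, GroundTruth]:
    """Draw one replicate set from the design.

    Per sample: analyte peaks (height set by the concentration response, with
    per-analyte enhancement jitter) plus fixed background bands (with
    per-sample height jitter) plus polynomial baseline drift (fixed shape
    plus a per-sample random quadratic), all scaled by a multiplicative
    scatter draw, shifted by an additive offset draw, plus channelwise white
    noise.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    axis = design.axis
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = design.baseline_amplitude * np.polyval(design.baseline_coeffs[::-1], u)
    bg_profiles = [pk.profile(axis) for pk in design.background_peaks]
    bg_heights = np.array(
        [pk.fixed_height if pk.fixed_height is not None else 0.0 for pk in design.background_peaks]
    )
    analyte_profiles = [
        (group, pk, pk.profile(axis))
        for group, peaks in design.analyte_peaks.items()
        for pk in peaks
    ]
    groups = list(design.analyte_peaks)
    if design.clutter_n > 0:
        rng_struct = np.random.default_rng(np.random.SeedSequence([design.seed, 0xC1]))
        centers = rng_struct.uniform(axis[0], axis[-1], design.clutter_n)
        shape = "lorentzian" if design.modality_style == "SERS_SHARP" else "gaussian"
        clutter = np.vstack([
            PeakSpec(c, design.clutter_width, shape, fixed_height=1.0).profile(axis)
            for c in centers
        ])
    else:
        clutter = None

    concs = np.repeat(design.concentration_levels, design.replicates_per_level)
    n = concs.size
    intens = np.empty((n, axis.size))
    mult_draws = np.empty(n)
    add_draws = np.empty(n)
    mult_sd, add_sd = design.scatter
    for s in range(n):
        spec = baseline.copy()
        for pk, h, prof in zip(design.background_peaks, bg_heights, bg_profiles):
            sd = pk.jitter_sd if pk.jitter_sd is not None else design.background_jitter_sd
            j = 1.0 + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            spec += h * j * prof
        gain = {
            g: 1.0 + (rng.normal(0.0, design.analyte_jitter_sd)
                      if design.analyte_jitter_sd > 0 else 0.0)
            for g in groups
        }
        for group, pk, prof in analyte_profiles:
            spec += gain[group] * _peak_height(pk, float(concs[s]), design) * prof
        if clutter is not None:
            amps = rng.normal(0.0, design.clutter_amp_sd, design.clutter_n)
            spec += amps @ clutter
        if design.drift_jitter_sd > 0:
            coeffs = rng.normal(0.0, design.drift_jitter_sd, 3)
            spec += np.polyval(coeffs, u)
        mult = 1.0 + (rng.normal(0.0, mult_sd) if mult_sd > 0 else 0.0)
        add = rng.normal(0.0, add_sd) if add_sd > 0 else 0.0
        noise = rng.normal(0.0, design.noise_sd, axis.size) if design.noise_sd > 0 else 0.0
        intens[s] = spec * mult + add + noise
        mult_draws[s] = mult
        add_draws[s] = add

    modality = Modality.SERS if design.modality_style == "SERS_SHARP" else Modality.NIR
    sset = SpectrumSet(
        sample_ids=[f"sample-{s:03d}" for s in range(n)],
        modality=modality,
        axis=axis,
        intensities=intens,
        concentrations=concs,
        meta={"synthetic": True, "modality_style": design.modality_style},
    )
    truth = GroundTruth(
        informative_channels=design.informative_channels(),
        multiplicative_draws=mult_draws,
        additive_draws=add_draws,
    )
    return sset, truth


class BenchmarkData(NamedTuple):
    nir: SpectrumSet
    sers: SpectrumSet
    nir_split: SplitResult
    sers_split: SplitResult
    truth: dict[str, GroundTruth]


def benchmark_dataset(seed: int, n_cal_per_level: int = 6) -> BenchmarkData:
    """Paired NIR + SERS benchmark over identical samples and concentrations
    with the stratified 6-per-level calibration split."""
    ss = np.random.SeedSequence(seed).spawn(3)
    sim_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    nir, truth_nir = simulate(default_design("NIR_BROAD"), seed=sim_seeds[0])
    sers, truth_sers = simulate(default_design("SERS_SHARP"), seed=sim_seeds[1])
    split_seed = sim_seeds[2]
    nir_split = stratified_split(nir, n_cal_per_level, seed=split_seed)
    sers_split = stratified_split(sers, n_cal_per_level, seed=split_seed)
    return BenchmarkData(
        nir=nir,
        sers=sers,
        nir_split=nir_split,
        sers_split=sers_split,
        truth={"NIR": truth_nir, "SERS": truth_sers},
    )


def response_vector(data: SpectrumSet, scale: str = "log10") -> np.ndarray:
    """Model response from concentration labels: log10(mol/L) by default
    (levels span three decades), or the raw linear concentrations."""
    c = data.concentrations
    if scale == "linear":
        return c.copy()
    if scale == "log10":
        if np.any(c <= 0):
            raise ParameterError("response_vector: log10 scale needs positive concentrations")
        return np.log10(c)
    raise ParameterError(f"unknown response scale {scale!r}")
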