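"""Shared fixtures: small labelled spectrum sets and seeded RNGs."""

import numpy as np
import pytest

from specfuse import Modality, SpectrumSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_set():
    """3 samples x 5 channels with simple values."""
    return SpectrumSet(
        sample_ids=["a", "b", "c"],
        modality=Modality.SERS,
        axis=np.array([400.0, 500.0, 600.0, 700.0, 800.0]),
        intensities=np.array(
            [
                [0.1, 0.2, 0.3, 0.4, 0.5],
                [1.0, 0.9, 0.8, 0.7, 0.6],
                [0.25, 0.5, 0.75, 1.0, 1.25],
            ]
        ),
        concentrations=np.array([1e-6, 1e-5, 1e-4]),
    )


def make_levels_set(n_levels=6, replicates=10, n_channels=12, seed=0):
    """Random labelled set with a clean level/replicate structure."""
    rng = np.random.default_rng(seed)
    levels = np.logspace(-6, -3, n_levels)
    conc = np.repeat(levels, replicates)
    n = conc.size
    return SpectrumSet(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        modality=Modality.SERS,
        axis=np.linspace(400, 1800, n_channels),
        intensities=rng.normal(size=(n, n_channels)),
        concentrations=conc,
    )
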