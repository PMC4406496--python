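"""Shared fixtures: small analysis windows and the heavy end-to-end datasets.

The three labeled datasets (null, default, strong effect) are session-scoped
because generating a 100-events-per-class recording and running the full
measurement pipeline over it takes on the order of a minute each.
"""

from __future__ import annotations

import numpy as np
import pytest

import nocieeg as ng

#: the four-measure combination used for the end-to-end Pk checks
REFERENCE_SUBSET = ("m(Re_50)_θ", "P_β", "P_VHF", "FD(Re_05)_VHF")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _make_window(x: np.ndarray, fs: float, band_name: str = "α"):
    band = ng.band_by_name(band_name)
    event = ng.EventAnnotation(100.0, "RSS", 5)
    return ng.AnalysisWindow(x, fs, band, event)


@pytest.fixture()
def sinusoid_window():
    """60 s of a unit-amplitude 10 Hz sinusoid at 128 Hz."""
    t = np.arange(60 * 128) / 128.0
    return _make_window(np.sin(2 * np.pi * 10.0 * t), 128.0)


@pytest.fixture()
def noise_window():
    """60 s of white noise at 128 Hz (fixed seed)."""
    x = np.random.default_rng(7).standard_normal(60 * 128)
    return _make_window(x, 128.0)


def _dataset(effect_size: float, seed: int) -> ng.LabeledDataset:
    cfg = ng.GeneratorConfig(n_events_per_class=100, effect_size=effect_size,
                             seed=seed)
    return ng.generate_labeled_dataset(cfg, trial="trial2")


@pytest.fixture(scope="session")
def dataset_null():
    """Full-pipeline dataset with statistically identical classes."""
    return _dataset(0.0, seed=11)


@pytest.fixture(scope="session")
def dataset_default():
    """Full-pipeline dataset at the default effect size."""
    return _dataset(1.0, seed=12)


@pytest.fixture(scope="session")
def dataset_strong():
    """Full-pipeline dataset with a strong (near-separable) effect."""
    return _dataset(2.0, seed=13)
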