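"""Shared fixtures: seeded synthetic records and whitened mixtures."""

import numpy as np
import pytest

from fetalica import center, whiten
from fetalica.synthetic import SynthConfig, synth_abdominal


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless 4-channel mixture (no sensor noise, no baseline)."""
    return synth_abdominal(
        SynthConfig(duration_s=20.0, noise_std=0.0, baseline_amp=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def default_record():
    """A 60 s record under the default study conditions."""
    return synth_abdominal(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def clean_whitened(clean_record):
    """Whitened clean mixture with its whitening model."""
    xc, _ = center(clean_record.recording)
    z, model = whiten(xc)
    return z, model


@pytest.fixture(scope="session")
def uniform_mixture():
    """Whitened 2-source mixture of uniform (sub-Gaussian) sources.

    Returns (Z, true_directions) where the columns of true_directions are
    the unit vectors recovering each source from Z.
    """
    rng = np.random.default_rng(42)
    s = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(2, 200_000))
    a = np.array([[1.0, 0.6], [-0.4, 1.2]])
    x = a @ s
    xc, _ = center(x)
    z, model = whiten(xc)
    directions = model.transform @ a
    directions /= np.linalg.norm(directions, axis=0)
    return z, directions
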