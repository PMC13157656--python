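"""Shared fixtures.

The expensive session fixtures (phantoms, trained estimators) are built once
and reused across test modules; everything is generated programmatically
from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from freewater.phantom import generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless 3-shell phantom with the default interface f-field."""
    return generate_phantom(shape=(8, 8, 8), snr=np.inf, seed=21)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small SNR-30 phantom for feature/training smoke tests."""
    return generate_phantom(shape=(12, 12, 12), snr=30.0, seed=22)


@pytest.fixture(scope="session")
def recovery_phantom():
    """Noiseless phantom for silver-standard recovery: >= 1000 voxels with
    f uniform on [0, 0.9] plus a pure-free-water slab (f = 1) so the
    MD-threshold path is exercised."""
    shape = (12, 12, 8)
    rng = np.random.default_rng(23)
    f = rng.uniform(0.0, 0.9, size=shape)
    f[:, :, -1] = 1.0
    return generate_phantom(shape=shape, snr=np.inf, seed=23, f_field=f)


@pytest.fixture(scope="session")
def trained():
    """The scaled-down study condition: spherical net + ANN trained on a
    ~50k-voxel SNR-30 phantom with uniform shell-code dropout.  Expensive;
    shared by the learned-estimator acceptance tests."""
    from freewater.experiments import train_estimators

    return train_estimators(seed=7)
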