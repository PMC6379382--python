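from __future__ import annotations

import numpy as np
import pytest

from pannen.imaging_io import CTVolume, Mask3D
from pannen.phantom import GridSpec, default_profiles, generate_lesion


def make_volume(data, spacing=(1.0, 1.0, 1.0), phase="pancreatic", origin=(0.0, 0.0, 0.0)):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return CTVolume(np.asarray(data, dtype=float), aff, phase)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return Mask3D(np.asarray(data), aff)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_grid():
    # small but still hosts lesion + vessels; z native at 5 mm
    return GridSpec(shape=(96, 96, 16), spacing=(1.0, 1.0, 5.0))


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def g3_study(profiles, small_grid):
    return generate_lesion(profiles["G3"], small_grid, seed=11, patient_id="P011")


@pytest.fixture(scope="session")
def g1_study(profiles, small_grid):
    return generate_lesion(profiles["G1"], small_grid, seed=12, patient_id="P012")
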