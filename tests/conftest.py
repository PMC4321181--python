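"""Shared fixtures: small deterministic phantoms used across the suite."""

import numpy as np
import pytest

from fibgold.detectability import DetectionGeometry
from fibgold.stack_io import LabelVolume
from fibgold.synth import SimulationConfig, build_phantom


@pytest.fixture(scope="session")
def clean_config():
    """Small noiseless, jitter-free phantom configuration (dz = 25 nm)."""
    return SimulationConfig(
        shape=(60, 128, 128),
        voxel_size=(25.0, 5.0, 5.0),
        cell_semiaxes=(1600.0, 300.0, 300.0),
        nucleus_diameter=440.0,
        nucleolus_diameter=160.0,
        nucleolus_offset=(0.0, 50.0, 50.0),
        heterochromatin_thickness=50.0,
        noise_sigma=0.0,
        gain_drift=0.0,
        offset_drift=0.0,
        jitter_max_px=0,
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_config):
    return build_phantom(clean_config)


@pytest.fixture(scope="session")
def fine_config():
    """Finely sectioned (dz = 5 nm) noiseless, jitter-free phantom: content
    changes negligibly between consecutive surfaces, so slice registration
    has a well-defined truth."""
    return SimulationConfig(
        shape=(60, 128, 128),
        voxel_size=(5.0, 5.0, 5.0),
        cell_semiaxes=(1000.0, 300.0, 300.0),
        nucleus_diameter=260.0,
        nucleolus_diameter=80.0,
        nucleolus_offset=(0.0, 30.0, 30.0),
        heterochromatin_thickness=30.0,
        noise_sigma=0.0,
        gain_drift=0.0,
        offset_drift=0.0,
        jitter_max_px=0,
        seed=0,
    )


@pytest.fixture(scope="session")
def slab_labels():
    """Uniform euchromatin slab for placement / detection statistics."""
    return LabelVolume(np.full((40, 60, 60), 2, dtype=np.int32), (25.0, 5.0, 5.0))


@pytest.fixture
def geometry():
    return DetectionGeometry(d=20.0, t=25.0, p=0.0)
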