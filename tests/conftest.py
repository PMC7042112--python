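import dataclasses

import numpy as np
import pytest

from endoca.presets import ArmSpec, preset
from endoca.synthetic import NoiseModel, generate_cell_map


@pytest.fixture(scope="session")
def tiny_cell_map():
    """Small field with a handful of cells, reused across tests."""
    return generate_cell_map(128, 128, 4, pixel_size_um=0.4, seed=11)


@pytest.fixture(scope="session")
def ip3_control_arm() -> ArmSpec:
    return preset("ip3_fk506").arm("control")


@pytest.fixture()
def small_arm(ip3_control_arm) -> ArmSpec:
    """The control IP3 arm scaled down for fast unit tests (the study-scale
    presets themselves are exercised in the acceptance suite)."""
    return dataclasses.replace(
        ip3_control_arm, n_animals=2, n_tech_reps=1, n_cells=5, n_frames=400)


@pytest.fixture(scope="session")
def zero_noise() -> NoiseModel:
    return NoiseModel(baseline_counts=500.0, read_noise_sd=0.0,
                      bleach_rate_per_frame=0.0, shot_noise=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
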