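"""Shared fixtures: small rendered scenes reused across test modules."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from npreflect import RCM, RSIM
from npreflect.simulate import (
    NoiseParams,
    SceneParams,
    generate_ground_truth,
    render_scene,
)

# The generator warns that 60 nm pixels slightly undersample the R-SIM
# lateral PSF; that is a property of the study conditions, not a test
# failure.
warnings.filterwarnings(
    "ignore", message=".*sampling is inadequate.*", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def small_scene_params() -> SceneParams:
    return SceneParams(
        shape=(12, 96, 96),
        voxel_size_nm=(200.0, 60.0, 60.0),
        n_clusters=8,
        amplitude_range=(800.0, 1200.0),
        radius_range=(5.0, 10.0),
        min_separation_nm=1500.0,
        background_level=15.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_scene_params):
    return generate_ground_truth(small_scene_params, seed=7)


@pytest.fixture(scope="session")
def small_control(small_scene_params):
    return generate_ground_truth(
        replace(small_scene_params, control_flag=True), seed=8
    )


@pytest.fixture(scope="session")
def rcm_stacks(small_truth, small_control):
    treated = render_scene(small_truth, RCM, NoiseParams(seed=9))
    control = render_scene(small_control, RCM, NoiseParams(seed=10))
    return treated, control


@pytest.fixture(scope="session")
def rsim_stacks(small_truth, small_control):
    treated = render_scene(small_truth, RSIM, NoiseParams(seed=11))
    control = render_scene(small_control, RSIM, NoiseParams(seed=12))
    return treated, control


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
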