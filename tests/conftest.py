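import dataclasses
import warnings

import numpy as np
import pytest

from cortivasc import PhantomConfig, build_geometry, calibrate_orientation_gain, generate_phantom


def small_phantom_config(**overrides) -> PhantomConfig:
    """A quick sphere-shell phantom (~2.5k native ribbon voxels)."""
    base = dict(
        seed=101,
        voxel_size_mm=0.8,
        outer_radius_mm=8.0,
        inner_radius_mm=6.0,
        n_frames=100,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def small_gre_bundle():
    """Small GRE-like phantom calibrated to +50% relative CV at theta~0."""
    cfg = small_phantom_config()
    geo = build_geometry(cfg)
    gain = calibrate_orientation_gain(cfg, geo, 50.0)
    cfg = dataclasses.replace(cfg, orientation_gain=gain)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_slab_config():
    return PhantomConfig(
        seed=202,
        geometry="flat_slab",
        slab_width_mm=8.0,
        slab_gm_thickness_mm=2.5,
        voxel_size_mm=0.5,
        n_frames=50,
    )
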