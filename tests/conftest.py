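"""Shared fixtures: small, fast phantom configurations.

The "small" configuration (16 x 96 x 96 voxels, 2 spheroids x 3 cells,
400 keratinocytes) keeps unit tests fast while exercising every code path;
module-scoped fixtures cache generated phantoms so the suite does not
regenerate them per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from sccpipe.io import AcquisitionMetadata, Channel, ImageStack, Modality, Timepoint
from sccpipe.synthetic import PhantomConfig, generate_phantom

SMALL_KWARGS = dict(
    volume_shape=(16, 96, 96),
    n_spheroids=2,
    spheroid_radius_um=18.0,
    cells_per_spheroid=3,
    n_keratinocytes=400,
)


def small_config(**overrides) -> PhantomConfig:
    kwargs = dict(SMALL_KWARGS)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, unshifted, unit-gain small phantom with a 50% tumor kill."""
    cfg = small_config(noise=None, kill_fraction_tumor=0.5, rng_seed=11)
    pre, post, truth = generate_phantom(cfg)
    return cfg, pre, post, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small phantom with default sensor noise and a 50% tumor kill."""
    cfg = small_config(kill_fraction_tumor=0.5, rng_seed=12)
    pre, post, truth = generate_phantom(cfg)
    return cfg, pre, post, truth


def make_stack(
    voxels,
    channel=Channel.GFP_488,
    modality=Modality.fluorescence,
    timepoint=Timepoint.pre,
    laser_power=1.0,
    detector_gain=1.0,
) -> ImageStack:
    meta = AcquisitionMetadata(
        channel=channel,
        modality=modality,
        timepoint=timepoint,
        laser_power=laser_power,
        detector_gain=detector_gain,
    )
    return ImageStack(np.asarray(voxels, dtype=np.float64), meta)
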