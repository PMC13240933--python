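import numpy as np
import pytest
from dataclasses import replace

import octseg as o


def micro_spec(seed=0, **overrides):
    """64x64 phantom spec for fast unit tests."""
    base = replace(o.quick_spec(seed=seed), height=64, width=64,
                   surface_depth_mean=12.0, surface_roughness_amplitude=3.0,
                   epidermis_thickness_mean=10.0,
                   epidermis_thickness_amplitude=3.0,
                   hyperkeratosis_extra_thickness=5.0)
    return replace(base, **overrides) if overrides else base


def noisefree_spec(seed=0, **overrides):
    merged = dict(speckle_contrast=0.0, hyperkeratosis_probability=0.0,
                  shadow_count_mean=0.0)
    merged.update(overrides)
    return micro_spec(seed=seed, **merged)


@pytest.fixture(scope="session")
def micro_dataset():
    """10 speckled 64x64 phantoms as (image, mask) pairs."""
    return [(p.image, p.mask)
            for p in (o.generate_phantom(micro_spec(seed=s)) for s in range(10))]


@pytest.fixture(scope="session")
def noisefree_run():
    """Train a small U-Net on noise-free 256x256 phantoms.

    Shared across tests that check learnability and the quality of
    predictions in the noise-free limit. Returns (model, dataset, split,
    history).
    """
    specs = [o.quick_spec(seed=s, speckle_contrast=0.0,
                          hyperkeratosis_probability=0.0,
                          shadow_count_mean=0.0) for s in range(14)]
    data = [(p.image, p.mask) for p in map(o.generate_phantom, specs)]
    split = o.split_dataset(range(14), test_fraction=0.15,
                            validation_fraction=0.2, seed=0)
    model = o.build_model(o.ModelConfig(base_filters=8), seed=0)
    config = o.TrainConfig(image_size=(256, 256), batch_size=2, epochs=20,
                           init_seed=0)
    history = o.train(model, data, split, config)
    return model, data, split, history
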