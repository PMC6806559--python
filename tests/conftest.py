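import numpy as np
import pytest

import ictos


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom with all texture knobs active."""
    spec = ictos.TexturePhantomSpec(seed=42)
    volumes, mask = ictos.generate_phantom(spec)
    return spec, volumes, mask


@pytest.fixture(scope="session")
def random_gray_maps():
    """Seeded single-slice 8x8 gray-level maps with an irregular ROI."""
    rng = np.random.default_rng(123)
    maps = []
    for _ in range(200):
        labels = rng.integers(1, 7, size=(8, 8)).astype(np.int32)
        roi = rng.random((8, 8)) < 0.8
        labels[~roi] = 0
        if (labels > 0).sum() < 4:
            labels[4, 4] = 1
        maps.append(labels)
    return maps


def make_gray(labels2d, n_bins):
    """Wrap a single-slice label map as a GrayLevelMap."""
    from ictos.preprocess import GrayLevelMap

    labels = np.asarray(labels2d, dtype=np.int32)[None, :, :]
    return GrayLevelMap(
        labels=labels,
        n_bins=n_bins,
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
    )


@pytest.fixture(scope="session")
def planted_study():
    """The planted-benefit study: training with confounding, randomized
    validation, model fitted end to end. Shared because it is the most
    expensive computation in the suite."""
    train = ictos.generate_cohort(
        ictos.CohortSpec(n_patients=250, confounding_strength=0.8, seed=11),
        with_images=True,
    )
    valid = ictos.generate_cohort(
        ictos.CohortSpec(n_patients=250, confounding_strength=0.0, seed=12),
        with_images=True,
    )
    config = ictos.RunConfig(seed=5)
    training = ictos.run_training(train.scans, train.table, config)
    validation = ictos.run_validation(valid.scans, valid.table, training.model, config)
    return {
        "train": train,
        "valid": valid,
        "config": config,
        "training": training,
        "validation": validation,
    }
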