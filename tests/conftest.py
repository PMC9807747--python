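"""Shared fixtures.

The trained-network fixtures are session-scoped because CPU training is the
dominant cost of the suite; every test that needs a trained detector or
masker shares the same seeded training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import toromorph as tm
from toromorph import detector as det
from toromorph import masker as msk


@pytest.fixture(scope="session")
def default_scenes():
    """Three seeded scenes with the default toroid/ellipsoid mixture."""
    return [tm.generate_scene(tm.SceneSpec(seed=i)) for i in range(3)]


@pytest.fixture(scope="session")
def fresh_scene():
    """A scene never used for training (for recall / masking checks)."""
    return tm.generate_scene(tm.SceneSpec(seed=99))


@pytest.fixture(scope="session")
def trained_detector(default_scenes):
    base = tm.generate_detection_training_set(
        default_scenes, n_pos=40, n_neg=50, seed=7
    )
    aug = det.augment_rotations(base, step=10.0)
    cfg = det.DetectorConfig(epochs=4, holdout=500, seed=3)
    net, hist = det.train_detector(aug, cfg)
    return net, hist


@pytest.fixture(scope="session")
def trained_masker(default_scenes):
    ctx, masks = tm.extract_mask_training_pairs(default_scenes, n_sources=48, seed=11)
    cfg = msk.MaskerConfig(
        per_image_samples=125, epochs=12, holdout=1000, seed=5, lr_decay_epochs=(8,)
    )
    samples = msk.build_mask_training_set(ctx, masks, cfg)
    net, hist = msk.train_masker(samples, cfg)
    return net, hist


@pytest.fixture(scope="session")
def random_detector_net():
    """An untrained (random-weight) detection network for oracle-equality tests."""
    rng = np.random.default_rng(42)
    net = det.build_network(det.DetectorConfig(), rng)
    _randomize_bn(net, rng)
    return net


@pytest.fixture(scope="session")
def random_masker_net():
    rng = np.random.default_rng(43)
    net = det.build_network(msk.MaskerConfig(), rng)
    _randomize_bn(net, rng)
    return net


def _randomize_bn(net, rng):
    from toromorph import nn

    for layer in net.layers:
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean[...] = rng.normal(0, 0.5, layer.running_mean.shape)
            layer.running_var[...] = rng.uniform(0.5, 2.0, layer.running_var.shape)


@pytest.fixture(scope="session")
def cohort_report():
    """Full detect->mask->measure run on the day-2 melanoma-line cohort.

    Twelve scenes of face-on ellipsoids whose silhouette axes are drawn from
    normal distributions with mean 519 / sd 90 nm (major) and 329 / 72 nm
    (minor); the pipeline trains its own networks on these scenes and
    returns the measurement summary.
    """
    cfg = {
        "simulate": {
            "n_scenes": 12, "n_particles": 25, "shape_mix": 0.0,
            "major_axis": [519.0, 90.0], "minor_axis": [329.0, 72.0],
        },
    }
    return tm.run_pipeline(cfg, seed=2024)
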