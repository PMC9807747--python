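"""Detection: augmentation, output map, peak picking."""

import numpy as np
import pytest

import toromorph as tm
from toromorph import detector as det
from toromorph import nn
from toromorph.synthdata import LabeledCrops


def _crops(n, rng, size=100):
    return LabeledCrops(
        images=rng.normal(size=(n, size, size)),
        labels=np.array([1, 2] * (n // 2) + [1] * (n % 2)),
    )


class TestAugmentation:
    def test_count_multiplies_by_rotations(self):
        rng = np.random.default_rng(0)
        crops = _crops(7, rng)
        out = det.augment_rotations(crops, step=10.0)
        assert len(out) == 7 * 36

    def test_full_turn_is_identity(self):
        rng = np.random.default_rng(1)
        crops = _crops(3, rng)
        out = det.augment_rotations(crops, step=360.0)
        np.testing.assert_array_equal(out.images, crops.images)
        np.testing.assert_array_equal(out.labels, crops.labels)

    def test_right_angle_rotations_are_exact(self):
        """90-degree multiples are lattice rotations: rotating a 4-fold
        symmetric crop returns pixel-identical copies."""
        rng = np.random.default_rng(2)
        q = rng.integers(0, 100, size=(100, 100)).astype(float)
        # integer-valued summands make the symmetrisation exact in floats
        sym = q + np.rot90(q, 1) + np.rot90(q, 2) + np.rot90(q, 3)
        assert np.array_equal(np.rot90(sym), sym)
        crops = LabeledCrops(images=sym[None], labels=np.array([2]))
        out = det.augment_rotations(crops, step=90.0)
        for rotated in out.images:
            np.testing.assert_array_equal(rotated, sym)

    def test_class_balance_preserved(self):
        rng = np.random.default_rng(3)
        crops = _crops(10, rng)
        out = det.augment_rotations(crops, step=30.0)
        for label in (1, 2):
            assert (out.labels == label).sum() == 12 * (crops.labels == label).sum()

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            det.augment_rotations(_crops(2, np.random.default_rng(0)), step=70.0)


class TestTraining:
    def test_single_class_rejected(self):
        rng = np.random.default_rng(4)
        crops = LabeledCrops(images=rng.normal(size=(6, 100, 100)),
                             labels=np.full(6, 2))
        with pytest.raises(ValueError, match="both classes"):
            det.train_detector(crops, det.DetectorConfig(epochs=1))

    def test_wrong_crop_size_rejected(self):
        rng = np.random.default_rng(5)
        crops = LabeledCrops(images=rng.normal(size=(6, 64, 64)),
                             labels=np.array([1, 2] * 3))
        with pytest.raises(ValueError, match="50"):
            det.train_detector(crops, det.DetectorConfig(epochs=1))

    def test_seeded_training_reproducible(self):
        rng = np.random.default_rng(6)
        crops = _crops(40, rng)
        cfg = det.DetectorConfig(epochs=2, holdout=8, seed=21)
        _, h1 = det.train_detector(crops, cfg)
        _, h2 = det.train_detector(crops, cfg)
        assert h1.loss == h2.loss and h1.accuracy == h2.accuracy


def test_checkpoint_roundtrip_preserves_network_and_config(tmp_path):
    from toromorph import masker as msk

    rng = np.random.default_rng(30)
    x = rng.standard_normal((3, 1, 50, 50)).astype(nn.DTYPE)
    for cfg in (det.DetectorConfig(epochs=7, seed=4), msk.MaskerConfig(epochs=3)):
        net = det.build_network(cfg, rng)
        ref = net.forward(x)
        path = tmp_path / f"{type(cfg).__name__}.npz"
        det.save_checkpoint(net, cfg, path)
        net2, cfg2 = det.load_checkpoint(path)
        np.testing.assert_array_equal(net2.forward(x), ref)
        assert cfg2 == cfg


class TestOutputMap:
    def test_map_shape_follows_window_arithmetic(self, random_detector_net):
        img = tm.SceneImage(np.zeros((160, 140)), pixel_size=10.0)
        omap = det.compute_output_map(random_detector_net, img)
        # half size 80x70 -> (80-49) x (70-49)
        assert omap.values.shape == (31, 21)
        assert omap.values.min() >= 1.0 and omap.values.max() <= 2.0

    def test_map_equals_naive_window_loop(self, random_detector_net):
        """The raster scan is bit-identical to cutting each window out of the
        standardized half-size image and classifying it alone."""
        rng = np.random.default_rng(8)
        img = tm.SceneImage(rng.normal(100, 5, (150, 160)), pixel_size=10.0)
        omap = det.compute_output_map(random_detector_net, img)
        half = det.reduce_half(det.standardize_frame(img.pixels))
        for i in (0, 10, 25):
            for j in (0, 13, 30):
                window = half[i:i + 50, j:j + 50][None, None].astype(nn.DTYPE)
                p = random_detector_net.predict_proba(window)[0, 1]
                assert omap.values[i, j] == np.float32(1.0) + np.float32(p)

    def test_image_smaller_than_window_rejected(self, random_detector_net):
        img = tm.SceneImage(np.zeros((70, 70)), pixel_size=10.0)  # half: 35 < 50
        with pytest.raises(ValueError, match="smaller than"):
            det.compute_output_map(random_detector_net, img)

    def test_trained_map_peaks_at_particle_centres(
        self, trained_detector, fresh_scene
    ):
        net, _ = trained_detector
        img, gt = fresh_scene
        omap = det.compute_output_map(net, img)
        for p in gt.particles[:5]:
            # map index of the window centred on the particle
            i, j = p.cy // 2 - 25, p.cx // 2 - 25
            if 0 <= i < omap.values.shape[0] and 0 <= j < omap.values.shape[1]:
                assert omap.values[i, j] > 1.5  # classified as particle


class TestDetection:
    def test_uniform_map_yields_no_detections(self):
        omap = det.OutputMap(values=np.ones((60, 60)))
        img = tm.SceneImage(np.zeros((220, 220)), pixel_size=10.0)
        centers, crops = det.detect_particles(omap, img)
        assert len(centers) == 0 and crops == []

    def test_single_blob_detected_at_its_peak(self):
        values = np.ones((80, 80))
        yy, xx = np.mgrid[:80, :80]
        values += np.exp(-((yy - 40) ** 2 + (xx - 30) ** 2) / 40.0)
        omap = det.OutputMap(values=values)
        img = tm.SceneImage(np.zeros((260, 260)), pixel_size=10.0)
        centers, crops = det.detect_particles(omap, img)
        assert len(centers) == 1
        assert tuple(centers[0]) == (2 * (40 + 25), 2 * (30 + 25))
        assert crops[0].shape == (100, 100)

    def test_perfect_recall_on_separated_scene(self, trained_detector):
        """All particles found, none invented, centres within 5 px, on a
        scene with at least two diameters between particle centres."""
        net, _ = trained_detector
        img, gt = tm.generate_scene(
            tm.SceneSpec(seed=555, n_particles=10,
                         min_center_distance_nm=2 * 590.0)
        )
        omap = det.compute_output_map(net, img)
        centers, _ = det.detect_particles(omap, img)
        assert len(centers) == len(gt)
        d = np.linalg.norm(
            centers[:, None, :] - gt.centers()[None, :, :], axis=2
        )
        assert (np.sort(d.min(axis=1)) <= 5.0).all()
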