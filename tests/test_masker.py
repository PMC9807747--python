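"""Masking: training-set construction, per-pixel prediction, accuracy."""

import numpy as np
import pytest

import toromorph as tm
from toromorph import masker as msk
from toromorph import nn


@pytest.fixture(scope="module")
def small_sources(default_scenes):
    return tm.extract_mask_training_pairs(default_scenes, n_sources=4, seed=17)


class TestTrainingSetConstruction:
    def test_sample_count_is_sources_times_per_image(self, small_sources):
        ctx, masks = small_sources
        cfg = msk.MaskerConfig(per_image_samples=100)
        samples = msk.build_mask_training_set(ctx, masks, cfg)
        assert len(samples) == 4 * 100

    def test_labels_match_direct_mask_lookup(self, small_sources):
        """Ground-truth re-lookup oracle: every sample's label equals the
        mask value at its recorded cut centre."""
        ctx, masks = small_sources
        cfg = msk.MaskerConfig(per_image_samples=80, seed=2)
        samples = msk.build_mask_training_set(ctx, masks, cfg)
        for k in range(len(samples)):
            si = samples.source_index[k]
            cy, cx = samples.center[k]
            expect = 2 if masks[si][cy, cx] else 1
            assert samples.labels[k] == expect

    def test_zero_shift_single_rotation_centres_exactly(self, small_sources):
        ctx, masks = small_sources
        cfg = msk.MaskerConfig(per_image_samples=1, shift_range=0)
        samples = msk.build_mask_training_set(ctx, masks, cfg)
        # per_image_samples=1 still emits the 4 rotations of one centred cut
        assert len(samples) == 4 * 4
        assert (samples.center == 100).all()
        from toromorph.imaging import reduce_half, standardize_frame

        expect = reduce_half(standardize_frame(ctx[0])[50:150, 50:150])
        np.testing.assert_array_equal(samples.windows[0], expect.astype(np.float32))

    def test_label_conservation(self, small_sources):
        """Counts by label equal direct lookups over the recorded centres."""
        ctx, masks = small_sources
        cfg = msk.MaskerConfig(per_image_samples=60, seed=9)
        samples = msk.build_mask_training_set(ctx, masks, cfg)
        direct = sum(
            int(masks[samples.source_index[k]][tuple(samples.center[k])] > 0)
            for k in range(len(samples))
        )
        assert (samples.labels == 2).sum() == direct

    def test_shape_mismatch_rejected(self, small_sources):
        ctx, masks = small_sources
        with pytest.raises(ValueError, match="matching"):
            msk.build_mask_training_set(ctx, masks[:2])


class TestPredictMask:
    def test_equals_naive_per_pixel_loop(self, random_masker_net):
        """Raster mask prediction is bit-identical to classifying, for each
        half-resolution pixel, the reduced 100x100 window centred there."""
        rng = np.random.default_rng(3)
        context = rng.normal(100, 5, (200, 200))
        pm = msk.predict_mask(random_masker_net, context, full_res=False)
        from toromorph.imaging import reduce_half, standardize_frame

        frame = standardize_frame(context)
        half = reduce_half(frame)
        for hy in (25, 40, 74):
            for hx in (25, 58, 74):
                window = half[hy - 25: hy + 25, hx - 25: hx + 25]
                p = random_masker_net.predict_proba(
                    window[None, None].astype(nn.DTYPE)
                )[0, 1]
                fy, fx = 2 * hy - 50, 2 * hx - 50
                assert pm.mask[fy, fx] == int(p >= 0.5)

    def test_full_res_equals_naive_full_res_loop(self, random_masker_net):
        rng = np.random.default_rng(4)
        context = rng.normal(100, 5, (200, 200))
        pm = msk.predict_mask(random_masker_net, context, full_res=True)
        from toromorph.imaging import reduce_half, standardize_frame

        frame = standardize_frame(context)
        for y in (50, 77, 149):
            for x in (50, 100, 149):
                window = reduce_half(frame[y - 50: y + 50, x - 50: x + 50])
                p = random_masker_net.predict_proba(
                    window[None, None].astype(nn.DTYPE)
                )[0, 1]
                assert pm.mask[y - 50, x - 50] == int(p >= 0.5)

    def test_background_crop_gives_empty_mask(self, trained_masker):
        net, _ = trained_masker
        rng = np.random.default_rng(5)
        spec = tm.SceneSpec(seed=31, n_particles=0)
        img, _ = tm.generate_scene(spec)
        context = img.pixels[300:500, 300:500]
        pm = msk.predict_mask(net, context)
        assert pm.mask.sum() <= 25      # at most sporadic isolated pixels

    def test_wrong_size_rejected(self, random_masker_net):
        with pytest.raises(ValueError, match="context"):
            msk.predict_mask(random_masker_net, np.zeros((120, 130)))

    def test_trained_mask_overlaps_truth(self, trained_masker, fresh_scene):
        """IoU against ground truth on unseen particles."""
        net, _ = trained_masker
        img, gt = fresh_scene
        full = gt.full_mask(img.pixels.shape)
        ious = []
        for p in gt.particles[:8]:
            context = img.pixels[p.cy - 100: p.cy + 100, p.cx - 100: p.cx + 100]
            pm = msk.predict_mask(net, context, full_res=True)
            truth = full[p.cy - 50: p.cy + 50, p.cx - 50: p.cx + 50]
            inter = (pm.mask & truth).sum()
            union = (pm.mask | truth).sum()
            ious.append(inter / union)
        assert min(ious) >= 0.8


class TestThresholdCalibration:
    def test_mask_is_thresholded_probability_map(self, random_masker_net):
        rng = np.random.default_rng(8)
        context = rng.normal(100, 5, (200, 200))
        probs = msk.predict_mask_proba(random_masker_net, context)
        for t in (0.3, 0.5, 0.7):
            pm = msk.predict_mask(random_masker_net, context, threshold=t)
            np.testing.assert_array_equal(pm.mask, (probs >= t).astype(np.uint8))

    def test_calibration_matches_predicted_to_true_area(self, random_masker_net):
        """The chosen threshold makes total predicted area closest to the
        total mask area over the training contexts."""
        rng = np.random.default_rng(9)
        contexts = rng.normal(100, 5, (3, 200, 200))
        masks = np.zeros((3, 200, 200), dtype=np.uint8)
        masks[:, 80:120, 80:120] = 1
        t = msk.calibrate_mask_threshold(
            random_masker_net, contexts, masks, full_res=False
        )
        true_area = 3 * 40 * 40
        err_t = abs(
            sum(
                (msk.predict_mask_proba(random_masker_net, c) >= t).sum()
                for c in contexts
            )
            - true_area
        )
        for other in (0.25, 0.5, 0.75):
            err_o = abs(
                sum(
                    (msk.predict_mask_proba(random_masker_net, c) >= other).sum()
                    for c in contexts
                )
                - true_area
            )
            assert err_t <= err_o


class TestAccuracyEvaluation:
    def test_perfect_oracle_scores_one(self, small_sources):
        ctx, masks = small_sources
        cfg = msk.MaskerConfig(per_image_samples=40, seed=3)
        samples = msk.build_mask_training_set(ctx, masks, cfg)

        class Oracle:
            def predict_proba(self, x, batch=512):
                # answer the stored label by construction
                out = np.zeros((len(x), 2))
                out[np.arange(len(x)), want] = 1.0
                return out

        want = (samples.labels == 2).astype(int)
        assert msk.evaluate_mask_accuracy(Oracle(), samples) == 1.0

    def test_value_is_recount_of_matches(self, random_masker_net, small_sources):
        ctx, masks = small_sources
        cfg = msk.MaskerConfig(per_image_samples=30, seed=4)
        samples = msk.build_mask_training_set(ctx, masks, cfg)
        acc = msk.evaluate_mask_accuracy(random_masker_net, samples)
        pred = random_masker_net.predict_proba(
            samples.windows[:, None].astype(nn.DTYPE)
        ).argmax(axis=1)
        manual = sum(
            int(pred[k] == (samples.labels[k] == 2)) for k in range(len(samples))
        )
        assert acc == manual / len(samples)

    def test_random_net_near_chance_on_balanced_labels(self, random_masker_net):
        rng = np.random.default_rng(6)
        n = 400
        samples = msk.MaskSamples(
            windows=rng.normal(size=(n, 50, 50)).astype(np.float32),
            labels=np.array([1, 2] * (n // 2)),
            source_index=np.zeros(n, dtype=int),
            center=np.zeros((n, 2), dtype=int),
        )
        acc = msk.evaluate_mask_accuracy(random_masker_net, samples)
        # untrained network ignores the (noise) input-label pairing:
        # accuracy within binomial fluctuation of one half
        assert abs(acc - 0.5) < 5 * 0.5 / np.sqrt(n)

    def test_empty_heldout_rejected(self, random_masker_net):
        empty = msk.MaskSamples(
            windows=np.empty((0, 50, 50)), labels=np.empty(0, int),
            source_index=np.empty(0, int), center=np.empty((0, 2), int),
        )
        with pytest.raises(ValueError, match="empty"):
            msk.evaluate_mask_accuracy(random_masker_net, empty)


def test_single_class_training_warns_of_collapse():
    rng = np.random.default_rng(7)
    samples = msk.MaskSamples(
        windows=rng.normal(size=(64, 50, 50)).astype(np.float32),
        labels=np.full(64, 1),
        source_index=np.zeros(64, int),
        center=np.zeros((64, 2), int),
    )
    cfg = msk.MaskerConfig(epochs=5, holdout=16, seed=0, lr_decay_epochs=())
    net, hist = msk.train_masker(samples, cfg)
    assert any("collapse" in w for w in hist.warnings)
    assert hist.accuracy[-1] == 1.0     # constant prediction is always right
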