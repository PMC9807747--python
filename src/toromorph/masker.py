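"""Centre-pixel classification masking of particle crops.

Instead of an encoder-decoder segmenter, each pixel of a particle crop is
classified by asking a small CNN whether the 100x100 window centred on that
pixel (reduced to 50x50) has a particle at its centre.  Training samples are
cut from 200x200 hand-masked (here: ground-truth-masked) particle images
with random +/-25 px shifts and 90-degree rotations; the label is the mask
value at the centre of the cut region (2 = particle, 1 = background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .detector import build_network
from .imaging import reduce_half, standardize_frame


@dataclass
class MaskerConfig:
    """Architecture and training schedule of the masking network.

    Four conv layers (35@11x11, 21@7x7, 16@3x3, 32@3x3) with BN and ReLU.
    With valid convolutions these filter sizes admit only two 2x2 poolings
    on a 50x50 input (50->40->20->14->7->5->3), so pooling follows the
    first two conv layers; the head is the same 128-64-2 stack as the
    detector.
    """

    input_size: int = 50
    conv_filters: tuple[int, ...] = (35, 21, 16, 32)
    conv_sizes: tuple[int, ...] = (11, 7, 3, 3)
    pool_after: tuple[int, ...] = (0, 1)
    fc_sizes: tuple[int, ...] = (128, 64)
    shift_range: int = 25
    per_image_samples: int = 1000
    epochs: int = 1000
    holdout: int = 2000
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 128
    lr_decay_epochs: tuple[int, ...] = (8,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_range >= 50:
            raise ValueError("shift_range must stay below the crop half-width")
        if self.per_image_samples < 1:
            raise ValueError("per_image_samples must be at least 1")


@dataclass
class ParticleMask:
    """Binary mask of one particle crop, same frame as its source crop."""

    mask: np.ndarray            # (H, W) uint8 in {0, 1}
    crop_id: int | str = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.mask = m.astype(np.uint8)


@dataclass
class MaskSamples:
    """Labelled 50x50 windows with their provenance for re-lookup checks."""

    windows: np.ndarray         # (N, 50, 50) float
    labels: np.ndarray          # (N,) int, 2/1
    source_index: np.ndarray    # (N,) which context image
    center: np.ndarray          # (N, 2) full-res centre of the cut region

    def __len__(self) -> int:
        return len(self.windows)


def build_mask_training_set(
    crops: np.ndarray,
    masks: np.ndarray,
    cfg: MaskerConfig | None = None,
    crop: int = 100,
) -> MaskSamples:
    """Build centre-labelled window samples from masked context images.

    From each 200x200 source, ``per_image_samples`` windows are generated:
    random shifts of up to ``shift_range`` px from the context centre,
    100x100 cut, reduced to 50x50, then each cut replicated at the four
    90-degree in-plane rotations (shifts x 4 rotations = per_image_samples).
    Every sample's label is the source mask value at the recorded centre of
    its cut region; rotation about the window centre leaves it unchanged.
    """
    cfg = cfg or MaskerConfig()
    crops = np.asarray(crops, dtype=np.float64)
    masks = np.asarray(masks)
    if crops.shape != masks.shape or crops.ndim != 3:
        raise ValueError(
            f"crops {crops.shape} and masks {masks.shape} must be matching "
            "(N, H, W) stacks"
        )
    n_src, ch, cw = crops.shape
    half = crop // 2
    n_rot = 4
    n_shifts = int(np.ceil(cfg.per_image_samples / n_rot))
    total = n_src * n_shifts * n_rot

    rng = np.random.default_rng(cfg.seed)
    windows = np.empty((total, crop // 2, crop // 2), dtype=np.float32)
    labels = np.empty(total, dtype=np.int64)
    source_index = np.empty(total, dtype=np.int64)
    centers = np.empty((total, 2), dtype=np.int64)

    k = 0
    for si in range(n_src):
        frame = standardize_frame(crops[si])
        mask = masks[si]
        cy0, cx0 = ch // 2, cw // 2
        for _ in range(n_shifts):
            dy = int(rng.integers(-cfg.shift_range, cfg.shift_range + 1))
            dx = int(rng.integers(-cfg.shift_range, cfg.shift_range + 1))
            cy, cx = cy0 + dy, cx0 + dx
            cut = frame[cy - half: cy + half, cx - half: cx + half]
            reduced = reduce_half(cut)
            label = 2 if mask[cy, cx] else 1
            for r in range(n_rot):
                windows[k] = np.rot90(reduced, k=r)
                labels[k] = label
                source_index[k] = si
                centers[k] = (cy, cx)
                k += 1
    return MaskSamples(
        windows=windows, labels=labels, source_index=source_index, center=centers
    )


def train_masker(
    samples: MaskSamples,
    cfg: MaskerConfig | None = None,
    verbose: bool = False,
) -> tuple[nn.Network, nn.TrainingHistory]:
    """Train the masking network; deterministic for a fixed ``cfg.seed``.

    A single-class sample set still trains (the network collapses to the
    one label) but a class-collapse warning is attached to the history.
    """
    cfg = cfg or MaskerConfig()
    x = samples.windows[:, None, :, :].astype(nn.DTYPE)
    y = (samples.labels == 2).astype(np.int64)

    rng = np.random.default_rng(cfg.seed)
    net = build_network(cfg, rng)
    n_hold = min(cfg.holdout, max(len(x) - 2, 0))
    perm = rng.permutation(len(x))
    hold, train = perm[:n_hold], perm[n_hold:]
    hist = nn.fit(
        net, x[train], y[train],
        epochs=cfg.epochs, rng=rng,
        x_val=x[hold] if n_hold else None,
        y_val=y[hold] if n_hold else None,
        lr=cfg.lr, momentum=cfg.momentum, batch_size=cfg.batch_size,
        lr_decay_epochs=cfg.lr_decay_epochs,
        verbose=verbose,
    )
    if len(np.unique(y)) < 2:
        hist.warnings.append("class collapse: training labels contain one class")
    return net, hist


def predict_mask_proba(
    network: nn.Network,
    crop: np.ndarray,
    full_res: bool = False,
    window: int = 50,
) -> np.ndarray:
    """Particle-probability map for the central 100x100 region of a context.

    For every pixel of the central region, the 100x100 window centred there
    is (implicitly) cut, reduced to 50x50 and classified.  By default
    classification runs on the half-resolution pixel grid and the result is
    upsampled 2x with nearest neighbour (matching the 50 %-reduction
    training geometry at a quarter of the cost); ``full_res=True``
    classifies every full-resolution pixel.

    A bare 100x100 crop is accepted and reflect-padded to 200x200, with the
    caveat that the padding invents context beyond the crop border.
    """
    crop = np.asarray(crop, dtype=np.float64)
    context = 4 * window
    if crop.shape == (context // 2, context // 2):
        pad = context // 4
        crop = np.pad(crop, pad, mode="reflect")
    if crop.shape != (context, context):
        raise ValueError(
            f"expected a {context}x{context} context crop (or "
            f"{context // 2}x{context // 2} centre crop), got {crop.shape}"
        )
    frame = standardize_frame(crop)
    out_size = context // 2                 # central 100x100 full-res region
    offset = context // 4                   # its top-left corner = 50

    if not full_res:
        half_img = reduce_half(frame)       # 100x100
        probs = nn.sliding_response(network, half_img, window=window)
        # window top-left t classifies half-res pixel t + window/2
        core = probs[: out_size // 2, : out_size // 2]
        out = np.repeat(np.repeat(core, 2, axis=0), 2, axis=1)
    else:
        out = np.zeros((out_size, out_size), dtype=np.float32)
        for ay in (0, 1):
            for ax in (0, 1):
                phase = reduce_half(frame[ay:, ax:])
                probs = nn.sliding_response(network, phase, window=window)
                # phase window top-left t covers full-res rows
                # [ay + 2t, ay + 2t + 100); its centre is ay + 2t + 50.
                ys = np.arange(probs.shape[0]) * 2 + ay + offset
                xs = np.arange(probs.shape[1]) * 2 + ax + offset
                keep_y = (ys >= offset) & (ys < offset + out_size)
                keep_x = (xs >= offset) & (xs < offset + out_size)
                out[np.ix_(ys[keep_y] - offset, xs[keep_x] - offset)] = (
                    probs[np.ix_(keep_y, keep_x)]
                )
    return out


def predict_mask(
    network: nn.Network,
    crop: np.ndarray,
    full_res: bool = False,
    crop_id: int | str = 0,
    window: int = 50,
    threshold: float = 0.5,
) -> ParticleMask:
    """Binary mask of the central 100x100 region of a particle context crop.

    Thresholds :func:`predict_mask_proba` at ``threshold`` (class boundary
    0.5 by default; see :func:`calibrate_mask_threshold` for choosing it on
    training data).
    """
    probs = predict_mask_proba(network, crop, full_res=full_res, window=window)
    return ParticleMask(mask=(probs >= threshold).astype(np.uint8), crop_id=crop_id)


def calibrate_mask_threshold(
    network: nn.Network,
    contexts: np.ndarray,
    masks: np.ndarray,
    full_res: bool = True,
    grid: np.ndarray | None = None,
) -> float:
    """Pick the probability threshold whose predicted area matches the masks.

    The 0.5 class boundary can sit a fraction of a pixel inside or outside
    the true silhouette edge depending on the training draw, which biases
    axis measurements by a few nm per run.  Since the training masks are
    available (they are the supervision), the threshold is chosen so the
    total predicted area over the training contexts equals the total true
    area — a calibration that uses no evaluation data.
    """
    if grid is None:
        grid = np.linspace(0.1, 0.9, 33)
    true_area = sum(m[50:150, 50:150].sum() for m in masks)
    probs = [
        predict_mask_proba(network, c, full_res=full_res) for c in contexts
    ]
    best_t, best_err = 0.5, np.inf
    for t in grid:
        pred_area = sum((p >= t).sum() for p in probs)
        err = abs(float(pred_area) - float(true_area))
        if err < best_err:
            best_t, best_err = float(t), err
    return best_t


def evaluate_mask_accuracy(network: nn.Network, samples: MaskSamples) -> float:
    """Fraction of held-out samples whose predicted centre label is correct."""
    if len(samples) == 0:
        raise ValueError("held-out sample set is empty")
    x = samples.windows[:, None, :, :].astype(nn.DTYPE)
    pred = network.predict_proba(x).argmax(axis=1)
    return float((pred == (samples.labels == 2)).mean())
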