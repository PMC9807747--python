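"""Sliding-window CNN particle detection.

A four-conv-layer classifier is trained on 100x100 particle/background crops
(reduced to 50x50), then slid at stride 1 across the half-size micrograph to
produce an output map whose value is 2 at particle centres and 1 elsewhere.
The map is Gaussian-smoothed and thresholded; each surviving connected
region yields one detection at its response maximum.

Intensity normalisation is applied once per source frame (the whole scene is
standardised to zero mean, unit variance before windows are cut), so every
window of a frame sees the same affine transform.  This is what lets the
raster scan share convolution work between overlapping windows while staying
exactly equal to classifying each window independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .imaging import SceneImage, reduce_half, standardize_frame
from .synthdata import LabeledCrops


@dataclass
class DetectorConfig:
    """Architecture and training schedule of the detection network.

    Four convolutional layers (21@7x7, 16@5x5, 16@3x3, 32@3x3), each
    followed by batch normalisation and ReLU, with 2x2 max pooling after the
    first three; the head is a three-layer fully-connected stack 128-64-2
    ending in softmax.  Training runs shuffled mini-batch SGD with momentum.
    """

    input_size: int = 50
    conv_filters: tuple[int, ...] = (21, 16, 16, 32)
    conv_sizes: tuple[int, ...] = (7, 5, 3, 3)
    pool_after: tuple[int, ...] = (0, 1, 2)     # pooling after these conv layers
    fc_sizes: tuple[int, ...] = (128, 64)
    epochs: int = 580
    rotation_step: float = 10.0
    holdout: int = 1000
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 128
    lr_decay_epochs: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 2 != 0:
            raise ValueError("input_size must be even (half of the 100 px crop)")
        if self.rotation_step > 0 and 360.0 % self.rotation_step != 0:
            raise ValueError("rotation_step must divide 360")


@dataclass
class OutputMap:
    """Classifier response over a stride-``stride`` raster scan.

    ``values[i, j]`` is 1 + P(particle) for the window whose top-left corner
    sits at half-size coordinates ``(stride*i, stride*j)``; the window centre
    is ``origin_offset`` pixels further.  Full-resolution centre of entry
    (i, j): ``scale * (stride * i + origin_offset)``.
    """

    values: np.ndarray
    origin_offset: int = 25
    scale: int = 2
    stride: int = 1


def build_network(cfg: DetectorConfig, rng: np.random.Generator) -> nn.Network:
    layers: list[nn.Layer] = []
    in_ch = 1
    size = cfg.input_size
    for i, (f, k) in enumerate(zip(cfg.conv_filters, cfg.conv_sizes)):
        layers.append(nn.Conv2d(in_ch, f, k, rng, first=(i == 0)))
        layers.append(nn.BatchNorm(f))
        layers.append(nn.ReLU())
        size = size - k + 1
        if i in cfg.pool_after:
            layers.append(nn.MaxPool2())
            size //= 2
        in_ch = f
    layers.append(nn.Flatten())
    n_feat = in_ch * size * size
    for fc in cfg.fc_sizes:
        layers.append(nn.Dense(n_feat, fc, rng))
        layers.append(nn.ReLU())
        n_feat = fc
    layers.append(nn.Dense(n_feat, 2, rng))
    return nn.Network(layers)


def save_checkpoint(network: nn.Network, cfg, path) -> None:
    """Serialise a trained network and its config to one ``.npz`` file."""
    import dataclasses
    import json

    meta = {"config_class": type(cfg).__name__,
            "config": dataclasses.asdict(cfg)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **network.state_arrays())


def load_checkpoint(path) -> tuple[nn.Network, object]:
    """Rebuild the network (and config) stored by :func:`save_checkpoint`."""
    import json

    from . import masker as _masker

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cls = {"DetectorConfig": DetectorConfig,
               "MaskerConfig": _masker.MaskerConfig}[meta["config_class"]]
        raw = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["config"].items()
        }
        cfg = cls(**raw)
        net = build_network(cfg, np.random.default_rng(0))
        net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return net, cfg


def augment_rotations(crops: LabeledCrops, step: float = 10.0) -> LabeledCrops:
    """Expand a crop set by in-plane rotations in ``step``-degree increments.

    Rotations are about the crop centre with bilinear interpolation and
    reflective fill; multiples of 90 degrees reduce to exact lattice
    rotations.  Output count = input count * (360 / step); labels and class
    balance are preserved.
    """
    if step <= 0 or 360.0 % step != 0:
        raise ValueError(f"rotation step {step} does not divide 360")
    n_rot = int(round(360.0 / step))
    imgs = crops.images
    out = np.empty((len(imgs) * n_rot,) + imgs.shape[1:], dtype=imgs.dtype)
    labels = np.repeat(crops.labels, n_rot)
    for i, img in enumerate(imgs):
        for r in range(n_rot):
            angle = r * step
            if angle % 90 == 0:
                rot = np.rot90(img, k=int(angle // 90))
            else:
                rot = ndimage.rotate(
                    img, angle, reshape=False, order=1, mode="reflect"
                )
            out[i * n_rot + r] = rot
    return LabeledCrops(images=out, labels=labels)


def _prepare_inputs(crops: LabeledCrops, input_size: int) -> np.ndarray:
    """Reduce 100x100 crops to 50x50 network inputs (N, 1, 50, 50)."""
    reduced = np.stack([reduce_half(c) for c in crops.images])
    if reduced.shape[1:] != (input_size, input_size):
        raise ValueError(
            f"crops reduce to {reduced.shape[1:]}, expected "
            f"({input_size}, {input_size}); supply {2 * input_size}x"
            f"{2 * input_size} crops"
        )
    return reduced[:, None, :, :].astype(nn.DTYPE)


def train_detector(
    trainset: LabeledCrops,
    cfg: DetectorConfig | None = None,
    verbose: bool = False,
) -> tuple[nn.Network, nn.TrainingHistory]:
    """Train the detection network; deterministic for a fixed ``cfg.seed``.

    The labelled crops (classes 2 = particle, 1 = background) are reduced to
    the network input size; ``cfg.holdout`` randomly chosen samples are
    reserved for the per-epoch accuracy curve and never trained on.
    """
    cfg = cfg or DetectorConfig()
    labels = np.asarray(trainset.labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes (labels 1 and 2)")
    x = _prepare_inputs(trainset, cfg.input_size)
    y = (labels == 2).astype(np.int64)

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
    return net, hist


def compute_output_map(
    network: nn.Network,
    img: SceneImage,
    stride: int = 1,
    window: int = 50,
) -> OutputMap:
    """Raster-scan the half-size micrograph and map the classifier response.

    The frame is standardised, reduced to half size, and every ``window``-
    sized cutout (stride-1 by default) is classified; the response
    1 + P(particle), in [1, 2], is written at the window position.  Border
    positions where the window does not fit are simply absent from the map.
    """
    pixels = standardize_frame(img.pixels)
    half = reduce_half(pixels)
    if half.shape[0] < window or half.shape[1] < window:
        raise ValueError(
            f"half-size image {half.shape} smaller than the {window}px window"
        )
    probs = nn.sliding_response(network, half, window=window)
    if stride > 1:
        probs = probs[::stride, ::stride]
    return OutputMap(values=1.0 + probs, origin_offset=window // 2, stride=stride)


def detect_particles(
    output_map: OutputMap,
    img: SceneImage,
    smooth_kernel: int = 25,
    smooth_sigma: float = 7.0,
    threshold_frac: float = 0.8,
    crop: int = 100,
    absolute_threshold: float | None = None,
    min_peak_value: float = 1.2,
    peak_relative: bool = True,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Locate particle centres on a smoothed, thresholded output map.

    The map is smoothed with a 25x25 / 7-sigma Gaussian and the 80 % rule
    (``threshold_frac``) is applied *per response peak* (default): every
    local maximum whose absolute response reaches ``min_peak_value`` defines
    a region at 80 % of its own peak height, and the region's
    response-weighted centroid becomes one detection.  Smoothing spreads a
    particle's response in proportion to its size, so referencing the
    threshold to the scene-wide maximum instead (``peak_relative=False``,
    min-max normalisation) couples the cutoff to the largest particle
    present and systematically drops small ones; the per-peak reading keeps
    detection size-unbiased.  ``absolute_threshold`` switches to a plain
    fixed cutoff on the [1, 2] response scale.

    Centres are mapped back to full-resolution coordinates and
    ``crop``-sized cutouts of the input image are extracted around each
    (centres too close to the border yield no cutout and are dropped).
    An all-background map yields an empty result, not an error: the
    ``min_peak_value`` floor keeps background fluctuation below detection.

    Returns ``(centers, crops)`` with ``centers`` an (n, 2) array of
    (row, col) full-resolution coordinates.  An all-background map yields an
    empty result, not an error.
    """
    values = np.asarray(output_map.values, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("output map contains non-finite values")
    radius = max(smooth_kernel // 2, 1)
    smoothed = ndimage.gaussian_filter(
        values, sigma=smooth_sigma, radius=radius, mode="reflect"
    )
    eight = np.ones((3, 3), dtype=int)

    def centroid(mask: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
        # response-weighted centroid of the region: unlike the raw argmax it
        # is not biased toward the first element of a near-flat plateau
        ys, xs = np.nonzero(mask)
        w = weights[ys, xs] + 1e-12
        return float((ys * w).sum() / w.sum()), float((xs * w).sum() / w.sum())

    region_centroids: list[tuple[float, float]] = []
    if absolute_threshold is not None:
        above = smoothed >= absolute_threshold
        labels, n_regions = ndimage.label(above, structure=eight)
        for region in range(1, n_regions + 1):
            mask = labels == region
            if smoothed[mask].max() < min_peak_value:
                continue
            region_centroids.append(centroid(mask, smoothed - absolute_threshold))
    elif not peak_relative:
        lo, hi = smoothed.min(), smoothed.max()
        if hi <= lo:
            return np.empty((0, 2), dtype=np.int64), []
        norm = (smoothed - lo) / (hi - lo)
        above = norm >= threshold_frac
        labels, n_regions = ndimage.label(above, structure=eight)
        for region in range(1, n_regions + 1):
            mask = labels == region
            if smoothed[mask].max() < min_peak_value:
                continue
            region_centroids.append(centroid(mask, norm - threshold_frac))
    else:
        lo = smoothed.min()
        local_max = (
            smoothed == ndimage.maximum_filter(smoothed, size=13, mode="reflect")
        ) & (smoothed >= min_peak_value)
        peaks = np.argwhere(local_max)
        order = np.argsort(smoothed[local_max])[::-1]
        claimed = np.zeros_like(smoothed, dtype=bool)
        for py_, px_ in peaks[order]:
            if claimed[py_, px_]:
                continue            # shoulder or plateau twin of a taller peak
            level = lo + threshold_frac * (smoothed[py_, px_] - lo)
            labels, _ = ndimage.label(smoothed >= level, structure=eight)
            mask = labels == labels[py_, px_]
            claimed |= mask
            region_centroids.append(centroid(mask, smoothed - level))

    centers = []
    for py, px in region_centroids:
        # map position -> half-size window centre -> full resolution
        cy = output_map.scale * (output_map.stride * py + output_map.origin_offset)
        cx = output_map.scale * (output_map.stride * px + output_map.origin_offset)
        centers.append((int(round(cy)), int(round(cx))))
    centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)

    half_crop = crop // 2
    h, w = img.pixels.shape
    kept, crops_out = [], []
    for cy, cx in centers:
        if half_crop <= cy <= h - half_crop and half_crop <= cx <= w - half_crop:
            kept.append((cy, cx))
            crops_out.append(
                img.pixels[cy - half_crop: cy + half_crop,
                           cx - half_crop: cx + half_crop].copy()
            )
    return np.asarray(kept, dtype=np.int64).reshape(-1, 2), crops_out
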