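"""Micrograph I/O and dielectric-contrast preprocessing.

Scanning-electron-assisted dielectric micrographs carry low-frequency
background variation (illumination, specimen-holder gradients) on top of the
particle signal.  The standard cleanup is a mild sharpening Gaussian followed
by subtraction of a very broad Gaussian estimate of the background, leaving a
high-pass image in which low-dielectric particles remain dark.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from scipy import ndimage


@dataclass
class SceneImage:
    """A single-channel micrograph with physical pixel calibration.

    Attributes
    ----------
    pixels : (H, W) float ndarray
        Intensity in arbitrary detector units.
    pixel_size : float
        Physical sampling pitch in nm per pixel.
    provenance : str
        Free-text tag: ``raw``, ``preprocessed`` or ``synthetic``.
    """

    pixels: np.ndarray
    pixel_size: float
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"SceneImage requires a single-channel 2-D raster, got shape "
                f"{self.pixels.shape}"
            )
        h, w = self.pixels.shape
        if h < 50 or w < 50:
            raise ValueError(f"image too small: {h}x{w}, need at least 50x50")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite intensities")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PreprocessConfig:
    """Parameters of the sharpen + broad-background-subtraction filter.

    ``gf_kernel``/``gf_sigma`` define the small sharpening Gaussian
    (11 px, 1.2 sigma); ``bg_kernel``/``bg_sigma`` the broad background
    estimator (400 px, 200 sigma).  Kernels are centred taps; an even count
    is widened by one so the filter has a centre pixel.
    """

    gf_kernel: int = 11
    gf_sigma: float = 1.2
    bg_kernel: int = 400
    bg_sigma: float = 200.0
    invert: bool = False

    def __post_init__(self) -> None:
        if self.gf_sigma <= 0 or self.bg_sigma <= 0:
            raise ValueError("Gaussian sigmas must be positive")
        if self.gf_kernel < 1 or self.bg_kernel < 1:
            raise ValueError("kernel sizes must be at least 1 pixel")


def load_image(path: str | Path, pixel_size: float) -> SceneImage:
    """Read a grayscale TIFF/PNG raster as a :class:`SceneImage`.

    Raises
    ------
    OSError
        If the file is missing or unreadable.
    ValueError
        If the raster is not single-channel.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-channel raster, got shape {arr.shape}; "
            "convert multi-channel images to grayscale first"
        )
    return SceneImage(arr.astype(np.float64), pixel_size=pixel_size)


def save_image(img: SceneImage, path: str | Path) -> None:
    """Write a scene as 32-bit float TIFF (pixel size in metadata) or PNG."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(
            path,
            img.pixels.astype(np.float32),
            metadata={"pixel_size_nm": img.pixel_size, "provenance": img.provenance},
        )
    else:
        lo, hi = img.pixels.min(), img.pixels.max()
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        iio.imwrite(path, ((img.pixels - lo) * scale).astype(np.uint8))


def reduce_half(pixels: np.ndarray) -> np.ndarray:
    """Reduce an image to half size by 2x2 block averaging (odd edges cropped)."""
    h, w = pixels.shape
    h2, w2 = h // 2, w // 2
    return pixels[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def standardize_frame(pixels: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalisation of a whole frame.

    Applied once per source frame so that every window cut from the frame
    sees the same affine intensity transform.
    """
    mu = pixels.mean()
    sd = pixels.std()
    return (pixels - mu) / (sd if sd > 0 else 1.0)


def _gaussian(img: np.ndarray, sigma: float, kernel: int) -> np.ndarray:
    # radius so the tap count matches the requested kernel (odd-adjusted)
    radius = max(kernel // 2, 1)
    return ndimage.gaussian_filter(img, sigma=sigma, radius=radius, mode="reflect")


def preprocess(img: SceneImage, cfg: PreprocessConfig | None = None) -> SceneImage:
    """Sharpen and flatten a micrograph.

    The image is smoothed with the small Gaussian, then a broad Gaussian of
    the smoothed image is subtracted as the background estimate::

        out = GF_small(img) - GF_broad(GF_small(img))

    Dark (low-dielectric) particles stay dark (negative) under this sign
    convention; ``cfg.invert`` flips the sign for the opposite reading.
    Both filters use reflective edge handling, so images smaller than the
    broad kernel are still valid input.
    """
    cfg = cfg or PreprocessConfig()
    smoothed = _gaussian(img.pixels, cfg.gf_sigma, cfg.gf_kernel)
    background = _gaussian(smoothed, cfg.bg_sigma, cfg.bg_kernel)
    out = smoothed - background
    if cfg.invert:
        out = -out
    return replace(img, pixels=out, provenance="preprocessed")
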