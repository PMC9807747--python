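"""Hyperspectral Raman analysis: band images, pixel selection, averaging.

The melanin verification procedure: form band images at the two melanin
signatures (1372 and 1584 1/cm), add them, keep pixels whose added
intensity reaches the threshold (default 10), and average the spectra of
the kept pixels so the carbon peaks stand clear of single-pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema


@dataclass
class RamanCube:
    """(y, x, wavenumber) intensity stack on a strictly ascending grid."""

    intensities: np.ndarray
    wavenumbers: np.ndarray
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("cube must be (y, x, wavenumber)")
        if self.intensities.shape[2] != len(self.wavenumbers):
            raise ValueError("spectral axis length mismatch")
        if not (np.diff(self.wavenumbers) > 0).all():
            raise ValueError("wavenumber grid must be strictly ascending")
        if self.intensities.shape[0] < 1 or self.intensities.shape[1] < 1:
            raise ValueError("spatial dimensions must be at least 1")


@dataclass
class Spectrum:
    """One spectrum on the grid of its source cube."""

    intensities: np.ndarray
    wavenumbers: np.ndarray
    provenance: str = "single pixel"
    n_averaged: int = 1


def band_image(
    cube: RamanCube, center: float, halfwidth: float = 10.0
) -> np.ndarray:
    """Mean intensity within ``center +/- halfwidth`` 1/cm at each pixel."""
    wn = cube.wavenumbers
    if center < wn[0] or center > wn[-1]:
        raise ValueError(
            f"band {center} 1/cm outside the grid [{wn[0]}, {wn[-1]}]"
        )
    sel = np.abs(wn - center) <= halfwidth
    return cube.intensities[:, :, sel].mean(axis=2)


def extract_high_signal_pixels(
    cube: RamanCube,
    bands: tuple[float, ...] = (1372.0, 1584.0),
    band_halfwidth: float = 10.0,
    threshold: float = 10.0,
) -> np.ndarray:
    """Pixels whose added band image reaches the intensity threshold.

    The band images (window means) are summed over ``bands``; returns an
    (n, 2) array of (row, col) coordinates with added intensity >=
    ``threshold``.  Monotone in the threshold: raising it never adds pixels.
    """
    added = np.zeros(cube.intensities.shape[:2])
    for b in bands:
        added += band_image(cube, b, band_halfwidth)
    ys, xs = np.nonzero(added >= threshold)
    return np.stack([ys, xs], axis=1)


def average_spectra(cube: RamanCube, pixels: np.ndarray) -> Spectrum:
    """Channel-wise mean spectrum over a pixel set (order-independent)."""
    pixels = np.asarray(pixels).reshape(-1, 2)
    if len(pixels) == 0:
        raise ValueError("cannot average an empty pixel set")
    spec = cube.intensities[pixels[:, 0], pixels[:, 1], :].mean(axis=0)
    n = len(pixels)
    return Spectrum(
        intensities=spec,
        wavenumbers=cube.wavenumbers,
        provenance=f"average of {n}",
        n_averaged=n,
    )


def find_peaks(
    spec: Spectrum,
    window: tuple[float, float],
    k: int = 2,
    smooth_channels: int = 5,
) -> tuple[np.ndarray, bool]:
    """The ``k`` largest local maxima of a spectrum within a window.

    A short moving average (default 5 channels) suppresses single-channel
    noise spikes without moving grid-aligned peaks.  Returns
    ``(positions_in_1/cm, complete)`` where ``complete`` is False if fewer
    than ``k`` local maxima exist.
    """
    wn = spec.wavenumbers
    lo, hi = window
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(f"window {window} outside the grid")
    kernel = np.ones(smooth_channels) / smooth_channels
    smooth = np.convolve(spec.intensities, kernel, mode="same")
    sel = (wn >= lo) & (wn <= hi)
    sub = smooth[sel]
    sub_wn = wn[sel]
    (idx,) = argrelextrema(sub, np.greater)
    if len(idx) == 0:
        return np.empty(0), k == 0
    order = np.argsort(sub[idx])[::-1]
    top = idx[order[:k]]
    positions = np.sort(sub_wn[top])
    return positions, len(top) >= k
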