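"""Seeded synthetic scenes, training sets and Raman cubes with ground truth.

No micrographs are distributed with this package, so all quantitative tests
run on synthetic scenes that emulate the transmission-style dielectric
contrast of the real data: dark (low-dielectric) melanosome-like particles —
toroids and ellipsoids rendered from 3-D models — on a brighter, mildly
noisy cytoplasmic background with smooth nuisance blobs.  Every particle
carries full ground truth (centre, silhouette axes, tilt, binary mask), and
all randomness flows from one integer seed through one named Generator.

Two particle renderers are used:

* ellipsoids are drawn with the closed-form chord length through a triaxial
  ellipsoid viewed along one short axis, so the silhouette is *exactly* the
  drawn major x minor ellipse (random in-plane orientation);
* toroids are voxelised and ray-projected at a drawn tilt; their silhouette
  axes are recorded from the rendered mask (there is no simple closed form
  for a tilted torus outline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import SceneImage, standardize_frame
from .model3d import ToroidParams, build_toroid, project_at_angle


class PlacementError(RuntimeError):
    """Raised when the requested particles cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"placed only {achieved} of {requested} particles without overlap"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Axis distributions are (mean, sd) in nm of the particle silhouette major
    and minor axes; the defaults centre the major axis on the 590 nm mean
    particle diameter.  ``shape_mix`` is the toroid fraction; ``background``
    is (mean level, Gaussian noise sd, nuisance blob count, blob sigma px);
    ``contrast`` is the peak darkness of a particle below background.
    """

    width: int = 900
    height: int = 900
    pixel_size: float = 10.0                    # nm / px
    n_particles: int = 20
    shape_mix: float = 0.5                      # fraction toroid vs ellipsoid
    major_axis: tuple[float, float] = (590.0, 23.0)   # (mean, sd) nm
    minor_axis: tuple[float, float] = (280.0, 25.0)   # (mean, sd) nm
    tilt_range: tuple[float, float] = (0.0, 45.0)     # toroid tilt, degrees
    background: tuple[float, float, int, float] = (100.0, 2.0, 6, 40.0)
    contrast: float = 30.0
    contrast_gamma: float = 0.5                 # darkness ~ (thickness)^gamma
    margin: int = 105                           # keep centres this far from edges
    min_center_distance_nm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be non-negative")
        if self.major_axis[1] < 0 or self.minor_axis[1] < 0:
            raise ValueError("axis sd must be non-negative")
        if not 0.0 <= self.shape_mix <= 1.0:
            raise ValueError("shape_mix must be a fraction in [0, 1]")


@dataclass
class ParticleTruth:
    """Ground truth for one rendered particle."""

    id: int
    cy: int                     # centre row, full-resolution px
    cx: int                     # centre col, full-resolution px
    major_nm: float             # silhouette major axis
    minor_nm: float             # silhouette minor axis
    tilt_deg: float
    shape: str                  # "toroid" | "ellipsoid"
    bbox: tuple[int, int]       # (y0, x0) of the local mask in the scene
    mask: np.ndarray            # local binary mask raster


@dataclass
class GroundTruth:
    """Per-scene collection of particle records with disjoint masks."""

    particles: list[ParticleTruth] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.particles)

    def centers(self) -> np.ndarray:
        return np.array([(p.cy, p.cx) for p in self.particles]).reshape(-1, 2)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=np.uint8)
        for p in self.particles:
            y0, x0 = p.bbox
            h, w = p.mask.shape
            out[y0:y0 + h, x0:x0 + w] |= p.mask.astype(np.uint8)
        return out

    def to_records(self) -> list[dict]:
        return [
            dict(id=p.id, cx=p.cx, cy=p.cy, major_nm=p.major_nm,
                 minor_nm=p.minor_nm, tilt_deg=p.tilt_deg, shape=p.shape)
            for p in self.particles
        ]


@dataclass
class LabeledCrops:
    """A stack of fixed-size crops with interface labels 2/1 (particle/bg)."""

    images: np.ndarray          # (N, H, W) float
    labels: np.ndarray          # (N,) int, 2 = particle, 1 = background

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# particle rendering

def _ellipsoid_template(
    major_nm: float, minor_nm: float, phi_deg: float, pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Path length (nm) and mask of a face-on triaxial ellipsoid.

    Semi-axes (major/2, minor/2) in plane, minor/2 along the ray; silhouette
    is exactly the drawn ellipse, rotated in-plane by ``phi_deg``.
    """
    a, b = major_nm / 2.0, minor_nm / 2.0
    half_px = int(np.ceil(a / pixel_size)) + 2
    n = 2 * half_px + 1
    c = (np.arange(n) - half_px) * pixel_size
    yy, xx = np.meshgrid(c, c, indexing="ij")
    phi = np.deg2rad(phi_deg)
    xr = xx * np.cos(phi) + yy * np.sin(phi)
    yr = -xx * np.sin(phi) + yy * np.cos(phi)
    q = 1.0 - (xr / a) ** 2 - (yr / b) ** 2
    path = 2.0 * b * np.sqrt(np.clip(q, 0.0, None))
    return path, q > 0.0


def _toroid_template(
    outer_nm: float, tilt_deg: float, phi_deg: float, pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Path length (nm) and mask of a proportionally scaled, tilted toroid."""
    s = outer_nm / 590.0
    params = ToroidParams(
        outer_diameter=590.0 * s,
        hole_diameter=330.0 * s,
        thickness=170.0 * s,
        grid=int(np.ceil(590.0 * s / 4.0)) + 7,
        voxel_size=4.0,
    )
    proj = project_at_angle(build_toroid(params), tilt_deg, pixel_size)
    path = proj.pixels
    if phi_deg % 360.0 != 0.0:
        path = ndimage.rotate(path, phi_deg, reshape=False, order=1, mode="constant")
        path = np.clip(path, 0.0, None)
    mask = path > 0.5 * params.voxel_size
    return path, mask


def _nuisance_field(
    shape: tuple[int, int], count: int, sigma: float, amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth, low-amplitude blobs mimicking cytoplasmic texture."""
    field_img = np.zeros(shape)
    h, w = shape
    for _ in range(count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        amp = rng.uniform(-amplitude, amplitude)
        sz = sigma * rng.uniform(0.6, 1.6)
        y = np.arange(h)[:, None] - cy
        x = np.arange(w)[None, :] - cx
        field_img += amp * np.exp(-(y ** 2 + x ** 2) / (2 * sz ** 2))
    return field_img


def generate_scene(spec: SceneSpec) -> tuple[SceneImage, GroundTruth]:
    """Render one seeded scene and its ground truth.

    The scene is background texture + noise + nuisance blobs, minus the sum
    of particle projections (particles are darker than background, deepest
    where the projected material is thickest).  Particles are placed with
    non-overlapping bounding boxes by bounded rejection sampling; failure to
    place the requested count raises :class:`PlacementError`.  Identical
    spec (including seed) gives a bit-identical scene.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    bg_mean, noise_sd, n_blobs, blob_sigma = spec.background

    scene = np.full((h, w), bg_mean, dtype=np.float64)
    scene += _nuisance_field((h, w), n_blobs, blob_sigma, 0.15 * spec.contrast, rng)
    scene += rng.normal(0.0, noise_sd, size=(h, w))

    truth = GroundTruth()
    placed_boxes: list[tuple[int, int, int, int]] = []
    attempts = 0
    max_attempts = 60 * max(spec.n_particles, 1)
    pid = 0
    while pid < spec.n_particles and attempts < max_attempts:
        attempts += 1
        is_toroid = rng.random() < spec.shape_mix
        major = float(rng.normal(*spec.major_axis))
        minor = float(rng.normal(*spec.minor_axis))
        if minor > major:
            major, minor = minor, major
        major = max(major, 8 * spec.pixel_size)
        minor = max(minor, 6 * spec.pixel_size)
        phi = float(rng.uniform(0.0, 180.0))
        tilt = float(rng.uniform(*spec.tilt_range))

        # template footprint is known analytically, so placement can be
        # decided before paying the rendering cost
        if is_toroid:
            n_vox = int(np.ceil(major / 4.0)) + 7
            side = int(np.ceil(n_vox * 4.0 / spec.pixel_size))
            side += 1 - side % 2
        else:
            side = 2 * (int(np.ceil(major / 2.0 / spec.pixel_size)) + 2) + 1
        th = tw = side
        cy = int(rng.integers(spec.margin, h - spec.margin))
        cx = int(rng.integers(spec.margin, w - spec.margin))
        y0, x0 = cy - th // 2, cx - tw // 2
        if y0 < 0 or x0 < 0 or y0 + th > h or x0 + tw > w:
            continue
        box = (y0 - 5, x0 - 5, y0 + th + 5, x0 + tw + 5)
        if any(
            not (box[2] <= b[0] or b[2] <= box[0] or box[3] <= b[1] or b[3] <= box[1])
            for b in placed_boxes
        ):
            continue
        if spec.min_center_distance_nm is not None and len(truth.particles) > 0:
            d_px = spec.min_center_distance_nm / spec.pixel_size
            existing = truth.centers()
            if (((existing[:, 0] - cy) ** 2 + (existing[:, 1] - cx) ** 2).min()
                    < d_px ** 2):
                continue
        placed_boxes.append(box)

        if is_toroid:
            path, mask = _toroid_template(major, tilt, phi, spec.pixel_size)
        else:
            path, mask = _ellipsoid_template(major, minor, phi, spec.pixel_size)
        assert path.shape == (th, tw)

        # dielectric contrast saturates with material thickness, giving the
        # sharp particle rims seen in the observed images; gamma < 1 models
        # that saturation (1 would be a linear mass-thickness render)
        depth = (path / path.max()) ** spec.contrast_gamma
        scene[y0:y0 + th, x0:x0 + tw] -= spec.contrast * depth

        if is_toroid:
            maj_nm, min_nm = _mask_axes(mask, spec.pixel_size)
        else:
            maj_nm, min_nm = major, minor
        truth.particles.append(
            ParticleTruth(
                id=pid, cy=cy, cx=cx, major_nm=maj_nm, minor_nm=min_nm,
                tilt_deg=tilt if is_toroid else 0.0,
                shape="toroid" if is_toroid else "ellipsoid",
                bbox=(y0, x0), mask=mask.astype(np.uint8),
            )
        )
        pid += 1

    if pid < spec.n_particles:
        raise PlacementError(spec.n_particles, pid)
    img = SceneImage(scene, pixel_size=spec.pixel_size, provenance="synthetic")
    return img, truth


def _mask_axes(mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Second-moment equivalent-ellipse axes of a (hole-filled) mask, in nm."""
    from skimage import measure

    filled = ndimage.binary_fill_holes(mask)
    props = measure.regionprops(filled.astype(np.uint8))[0]
    return (
        props.axis_major_length * pixel_size,
        props.axis_minor_length * pixel_size,
    )


# ---------------------------------------------------------------------------
# detection training crops

def generate_detection_training_set(
    scenes: list[tuple[SceneImage, GroundTruth]],
    n_pos: int,
    n_neg: int,
    crop: int = 100,
    seed: int = 0,
) -> LabeledCrops:
    """Cut positive (particle-centred) and negative (background) crops.

    Each scene is standardised frame-wide before cutting, matching the
    normalisation applied when the detector later scans a whole frame.
    Positive crops are centred on ground-truth particle centres; negative
    crop centres lie at least ``crop/2`` from every particle centre.
    Labels follow the 2 (particle) / 1 (background) interface convention.
    """
    rng = np.random.default_rng(seed)
    half = crop // 2
    frames = [standardize_frame(img.pixels) for img, _ in scenes]

    pos_pool = [
        (si, p) for si, (_, gt) in enumerate(scenes) for p in gt.particles
        if half <= p.cy <= scenes[si][0].height - half
        and half <= p.cx <= scenes[si][0].width - half
    ]
    if n_pos > 0 and not pos_pool:
        raise ValueError("no particles available for positive crops")

    images = np.empty((n_pos + n_neg, crop, crop), dtype=np.float64)
    labels = np.empty(n_pos + n_neg, dtype=np.int64)
    for k in range(n_pos):
        si, p = pos_pool[int(rng.integers(len(pos_pool)))]
        images[k] = frames[si][p.cy - half: p.cy + half, p.cx - half: p.cx + half]
        labels[k] = 2

    min_d2 = float(half) ** 2
    for k in range(n_neg):
        placed = False
        for _ in range(2000):
            si = int(rng.integers(len(scenes)))
            h, w = frames[si].shape
            cy = int(rng.integers(half, h - half + 1))
            cx = int(rng.integers(half, w - half + 1))
            centers = scenes[si][1].centers()
            if len(centers) == 0 or (
                ((centers[:, 0] - cy) ** 2 + (centers[:, 1] - cx) ** 2).min() >= min_d2
            ):
                images[n_pos + k] = frames[si][cy - half: cy + half, cx - half: cx + half]
                labels[n_pos + k] = 1
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not sample background crop {k + 1}/{n_neg}: "
                "insufficient particle-free area"
            )
    return LabeledCrops(images=images, labels=labels)


def extract_mask_training_pairs(
    scenes: list[tuple[SceneImage, GroundTruth]],
    n_sources: int,
    context: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Particle-centred context crops with their ground-truth masks.

    Synthetic stand-in for the hand-masked particle images used to train
    the masking network: returns ``(contexts, masks)`` of shape
    ``(n_sources, context, context)``; masks are binary.  Contexts are cut
    raw (unnormalised) — the masker standardises per context.
    """
    rng = np.random.default_rng(seed)
    half = context // 2
    pool = []
    for si, (img, gt) in enumerate(scenes):
        full = gt.full_mask(img.pixels.shape)
        for p in gt.particles:
            if (half <= p.cy <= img.height - half
                    and half <= p.cx <= img.width - half):
                pool.append((si, p, full))
    if not pool:
        raise ValueError("no particle has enough margin for a context crop")
    contexts = np.empty((n_sources, context, context), dtype=np.float64)
    masks = np.empty((n_sources, context, context), dtype=np.uint8)
    for k in range(n_sources):
        si, p, full = pool[int(rng.integers(len(pool)))]
        img = scenes[si][0]
        sl = np.s_[p.cy - half: p.cy + half, p.cx - half: p.cx + half]
        contexts[k] = img.pixels[sl]
        masks[k] = full[sl]
    return contexts, masks


# ---------------------------------------------------------------------------
# Raman cubes

def generate_raman_cube(
    width: int = 120,
    height: int = 120,
    wavenumbers: np.ndarray | None = None,
    melanin_mask: np.ndarray | None = None,
    lipid_mask: np.ndarray | None = None,
    melanin_amplitude: float = 15.0,
    lipid_amplitude: float = 12.0,
    baseline: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Simulate a hyperspectral Raman scan with melanin and lipid bands.

    Melanin-mask pixels carry Gaussian peaks at 1372 and 1584 1/cm (the
    melanin signature), lipid-mask pixels a CH-stretch peak at 2909 1/cm;
    every pixel has a flat baseline plus seeded Gaussian noise.  Peak
    amplitudes are calibrated so the added 1372+1584 band image of melanin
    pixels sits well above the intensity-10 extraction threshold while the
    background stays far below it.
    """
    from .raman import RamanCube

    if wavenumbers is None:
        wavenumbers = np.arange(1200.0, 3101.0, 1.0)
    wavenumbers = np.asarray(wavenumbers, dtype=np.float64)
    if wavenumbers[0] > 1200.0 or wavenumbers[-1] < 3100.0:
        raise ValueError("wavenumber grid must cover at least 1200-3100 1/cm")
    if melanin_mask is None:
        melanin_mask = np.zeros((height, width), dtype=bool)
    melanin_mask = np.asarray(melanin_mask, dtype=bool)
    if melanin_mask.shape != (height, width):
        raise ValueError(
            f"melanin mask shape {melanin_mask.shape} does not match "
            f"({height}, {width})"
        )
    if lipid_mask is not None:
        lipid_mask = np.asarray(lipid_mask, dtype=bool)
        if lipid_mask.shape != (height, width):
            raise ValueError("lipid mask shape mismatch")

    rng = np.random.default_rng(seed)

    def peak(center: float, sigma: float) -> np.ndarray:
        return np.exp(-0.5 * ((wavenumbers - center) / sigma) ** 2)

    melanin_spec = melanin_amplitude * (peak(1372.0, 8.0) + peak(1584.0, 8.0))
    lipid_spec = lipid_amplitude * peak(2909.0, 10.0)

    cube = np.full((height, width, len(wavenumbers)), baseline, dtype=np.float64)
    cube += rng.normal(0.0, noise_sd, size=cube.shape)
    cube[melanin_mask] += melanin_spec
    if lipid_mask is not None:
        cube[lipid_mask] += lipid_spec
    return RamanCube(intensities=cube, wavenumbers=wavenumbers, pixel_size_um=0.2)
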