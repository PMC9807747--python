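"""Parametric 3-D particle models and transmission-style projections.

Melanosomes of the melanoma line appear as toroids (doughnuts) and those of
normal melanocytes as prolate ellipsoids.  Both are modelled as binary voxel
occupancy grids; a projection image at an arbitrary tilt is the path length
of occupied material along the viewing axis, computed by casting rays through
the rotated model (rotating ray directions rather than resampling voxels
avoids a second interpolation).

Geometry of the toroid: the three printed sizes (outer diameter 590 nm,
central hole 330 nm, thickness 170 nm) are inconsistent with a circular tube
cross-section (radial width 130 nm != axial 170 nm), so the tube is an
ellipse: centreline radius R = (outer + hole)/4, radial semi-axis
a = (outer - hole)/4, axial semi-axis b = thickness/2.  With the defaults
R = 230, a = 65, b = 85 nm, which reproduces all three printed extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import SceneImage


@dataclass
class ToroidParams:
    outer_diameter: float = 590.0   # nm
    hole_diameter: float = 330.0    # nm
    thickness: float = 170.0        # nm
    grid: int = 181                 # voxels per side
    voxel_size: float = 4.0         # nm

    def __post_init__(self) -> None:
        if not self.hole_diameter < self.outer_diameter:
            raise ValueError("hole_diameter must be smaller than outer_diameter")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.grid * self.voxel_size < self.outer_diameter:
            raise ValueError("grid does not enclose the toroid")

    @property
    def centerline_radius(self) -> float:
        return (self.outer_diameter + self.hole_diameter) / 4.0

    @property
    def tube_radial_semiaxis(self) -> float:
        return (self.outer_diameter - self.hole_diameter) / 4.0

    @property
    def tube_axial_semiaxis(self) -> float:
        return self.thickness / 2.0


@dataclass
class EllipsoidParams:
    long_axis: float = 710.0        # nm
    short_axis: float = 280.0       # nm
    grid: int = 100                 # voxels per side
    voxel_size: float = 8.0         # nm

    def __post_init__(self) -> None:
        if not self.short_axis > 0:
            raise ValueError("short_axis must be positive")
        if self.short_axis > self.long_axis:
            raise ValueError("short_axis must not exceed long_axis")
        if self.grid * self.voxel_size < self.long_axis:
            raise ValueError("grid does not enclose the ellipsoid")


@dataclass
class VoxelModel:
    """Binary occupancy grid of one particle (1 = material)."""

    occupancy: np.ndarray           # (n, n, n) uint8, axes (z, y, x)
    voxel_size: float               # nm
    params: object = None

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy must be binary")
        if occ.sum() == 0:
            raise ValueError("model has no occupied voxels")
        self.occupancy = occ.astype(np.uint8)


def _centered_coords(grid: int, voxel_size: float) -> np.ndarray:
    """Physical coordinate (nm) of each voxel centre along one axis."""
    return (np.arange(grid) - (grid - 1) / 2.0) * voxel_size


def build_toroid(p: ToroidParams | None = None) -> VoxelModel:
    """Voxelise an elliptical-tube torus, symmetry axis along z.

    A voxel is occupied iff its centre satisfies
    ``((sqrt(x^2+y^2) - R)/a)^2 + (z/b)^2 <= 1``.
    """
    p = p or ToroidParams()
    c = _centered_coords(p.grid, p.voxel_size)
    z, y, x = np.meshgrid(c, c, c, indexing="ij")
    r = np.hypot(x, y)
    R = p.centerline_radius
    a = p.tube_radial_semiaxis
    b = p.tube_axial_semiaxis
    occ = ((r - R) / a) ** 2 + (z / b) ** 2 <= 1.0
    return VoxelModel(occ, p.voxel_size, p)


def build_ellipsoid(p: EllipsoidParams | None = None) -> VoxelModel:
    """Voxelise a prolate spheroid, long axis along x."""
    p = p or EllipsoidParams()
    c = _centered_coords(p.grid, p.voxel_size)
    z, y, x = np.meshgrid(c, c, c, indexing="ij")
    ca = p.long_axis / 2.0
    cb = p.short_axis / 2.0
    occ = (x / ca) ** 2 + (y / cb) ** 2 + (z / cb) ** 2 <= 1.0
    return VoxelModel(occ, p.voxel_size, p)


def project_at_angle(
    m: VoxelModel,
    tilt: float,
    pixel_size: float,
    n_samples_per_voxel: int = 2,
) -> SceneImage:
    """Parallel projection of the model tilted about the in-plane x-axis.

    Rays run along the viewing (z) axis of the output frame; the model is
    rotated by ``tilt`` degrees about x, so 0 deg views the toroid face-on
    (annulus) and 90 deg edge-on.  Each output pixel holds the path length
    (nm) of occupied material along its ray, estimated by nearest-voxel
    sampling at ``voxel_size / n_samples_per_voxel`` steps.

    At 0 and 90 degrees with ``pixel_size == voxel_size`` the sampling grid
    coincides with the voxel lattice and the projection is exact.
    """
    if not np.isfinite(tilt):
        raise ValueError("tilt must be finite")
    if not 0.0 <= tilt <= 180.0:
        raise ValueError("tilt must lie in [0, 180] degrees")

    grid = m.occupancy.shape[0]
    extent = grid * m.voxel_size            # physical cube edge, nm
    half = extent / 2.0

    n_px = int(np.ceil(extent / pixel_size))
    if n_px % 2 == 0:
        n_px += 1                           # odd => a pixel centred at the origin
    u = (np.arange(n_px) - (n_px - 1) / 2.0) * pixel_size   # in-plane x (nm)
    v = u.copy()                                            # in-plane y (nm)

    step = m.voxel_size / n_samples_per_voxel
    # depth samples must span the rotated cube; the diagonal is sufficient
    depth_half = half * np.sqrt(3.0)
    n_w = int(np.ceil(2 * depth_half / step)) + 1
    w = (np.arange(n_w) - (n_w - 1) / 2.0) * step           # along the ray (nm)

    theta = np.deg2rad(tilt)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    occ = m.occupancy
    # world (model-frame) coordinates of sample points: rotate view frame by
    # -tilt about x.  view (u, v, w) -> model (x, y, z):
    #   x = u,  y = v*cos - w*sin,  z = v*sin + w*cos
    counts = np.zeros((n_px, n_px), dtype=np.int64)
    vv = v[:, None]
    to_index = lambda q: np.round(q / m.voxel_size + (grid - 1) / 2.0).astype(np.int64)
    xi = to_index(u)[None, :]               # (1, n_px), constant in depth
    for wk in w:                            # loop over depth keeps memory flat
        y_m = vv * cos_t - wk * sin_t
        z_m = vv * sin_t + wk * cos_t
        yi = to_index(y_m)                  # (n_px, 1)
        zi = to_index(z_m)
        inside = (yi >= 0) & (yi < grid) & (zi >= 0) & (zi < grid)
        row_ok = inside[:, 0]
        if not row_ok.any():
            continue
        yi_c = np.clip(yi[row_ok, 0], 0, grid - 1)
        zi_c = np.clip(zi[row_ok, 0], 0, grid - 1)
        xi_ok = (xi[0] >= 0) & (xi[0] < grid)
        xs = np.clip(xi[0], 0, grid - 1)
        counts[row_ok] += occ[zi_c[:, None], yi_c[:, None], xs[None, :]] * xi_ok[None, :]
    path = counts.astype(np.float64) * step
    return SceneImage(path, pixel_size=pixel_size, provenance="synthetic")
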