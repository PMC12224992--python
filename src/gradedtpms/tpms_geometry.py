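"""Graded Schwarz-Diamond TPMS geometry via coordinate transformation.

A TPMS is defined implicitly: for the Schwarz Diamond (SWD) family used
here the surface is the zero level set of

    F(x, y, z) = cos x · cos y · cos z − sin x · sin y · sin z

with arguments in radians and period 2π along each axis. Grading is done
not by warping the implicit function but by transforming its argument: the
argument vector x⃗ at a physical location X⃗ (mm) is the cumulative line
integral

    x_i(X⃗) = 2π ∫₀^{X_i} dX'_i / cs(X⃗)        (per axis i, other
                                                 coordinates held fixed)

so a locally larger unit cell size ``cs`` stretches the lattice locally
while the integral keeps the surface phase continuous — the unit-cell
morphology is preserved and only its scale changes, smoothly. The scaling
is applied equally along all three axes, which retains triple periodicity.

The material region is the sub-level set ``SD = F(x⃗) − c ≤ 0`` of the
signed-distance-like field, where ``c`` shifts the membrane surface (wall
thickness fine tuning). Voxelization thresholds SD at 0 and can stream in
Z-chunks so printer-scale volumes never have to be held in memory at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .field_model import CellSizeField
from .grids import RegularGrid


def swd_implicit(x, y, z):
    """Schwarz-Diamond implicit function, 2π-periodic in each argument."""
    return np.cos(x) * np.cos(y) * np.cos(z) - np.sin(x) * np.sin(y) * np.sin(z)


@dataclass
class ArgumentField:
    """Transformed TPMS argument x⃗ (radians) on a node grid.

    Each component is monotonically non-decreasing along its own axis and
    zero on the origin face of the integration.
    """

    grid: RegularGrid
    x: np.ndarray  # shape (*grid.shape, 3)

    def __post_init__(self) -> None:
        if self.x.shape != (*self.grid.shape, 3):
            raise ValueError(f"argument array shape {self.x.shape} != {(*self.grid.shape, 3)}")


@dataclass
class SignedDistanceField:
    """Scalar SD per voxel; material where SD ≤ 0."""

    grid: RegularGrid
    sd: np.ndarray
    offset_c: float = 0.0

    def __post_init__(self) -> None:
        if self.sd.shape != self.grid.shape:
            raise ValueError(f"sd shape {self.sd.shape} != grid shape {self.grid.shape}")


@dataclass
class VoxelStructure:
    """Boolean occupancy per voxel (True = material)."""

    grid: RegularGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if self.occupancy.shape != self.grid.shape:
            raise ValueError("occupancy shape mismatch")
        if self.occupancy.dtype != bool:
            self.occupancy = self.occupancy.astype(bool)


def transform_coordinates(cs_field: CellSizeField) -> ArgumentField:
    """Cumulative-integral coordinate transformation (argument field).

    Integrates 2π/cs along each axis from the minimum corner of the field's
    grid by the trapezoidal rule (exact for constant cs, where the map is
    the linear x_i = 2π X_i / cs). Because cs varies in all three
    coordinates, x₁ at a point depends on (X₂, X₃) through cs along the
    integration line — this is the mechanism that shifts the TPMS phase
    smoothly between regions of different scale.
    """
    cs = cs_field.cs
    if np.any(cs <= 0):
        raise ValueError("cell sizes must be strictly positive")
    grid = cs_field.grid
    inv = 1.0 / cs
    x = np.empty((*grid.shape, 3))
    for i in range(3):
        coord = grid.axis(i)
        if grid.shape[i] == 1:
            x[..., i] = 0.0
        else:
            x[..., i] = 2.0 * np.pi * cumulative_trapezoid(
                inv, coord, axis=i, initial=0.0
            )
    return ArgumentField(grid, x)


def _argument_interpolators(arg: ArgumentField):
    axes = arg.grid.axes()
    return [
        RegularGridInterpolator(axes, arg.x[..., i], bounds_error=False, fill_value=None)
        for i in range(3)
    ]


def signed_distance(
    arg: ArgumentField,
    offset_c: float = 0.0,
    voxel_grid: RegularGrid | None = None,
    implicit_fn=swd_implicit,
) -> SignedDistanceField:
    """SD = F(x⃗) − c per voxel.

    With ``voxel_grid`` given, the argument field (typically computed on a
    coarser node lattice) is tri-linearly interpolated to the voxel
    centers; otherwise SD is evaluated on the argument grid itself.
    ``implicit_fn`` defaults to the Schwarz Diamond but accepts any
    2π-periodic implicit TPMS function of (x, y, z).
    """
    if voxel_grid is None:
        xs = [arg.x[..., i] for i in range(3)]
        grid = arg.grid
        sd = implicit_fn(*xs) - offset_c
        return SignedDistanceField(grid, sd, offset_c)
    interp = _argument_interpolators(arg)
    pts = voxel_grid.points()
    xs = [f(pts).reshape(voxel_grid.shape) for f in interp]
    sd = implicit_fn(*xs) - offset_c
    return SignedDistanceField(voxel_grid, sd, offset_c)


def voxelize(sd: SignedDistanceField) -> VoxelStructure:
    """Threshold the SD field: material where SD ≤ 0."""
    return VoxelStructure(sd.grid, sd.sd <= 0.0)


def voxelize_chunked(
    arg: ArgumentField,
    voxel_grid: RegularGrid,
    offset_c: float = 0.0,
    chunk_slices: int = 16,
    implicit_fn=swd_implicit,
) -> Iterator[tuple[slice, np.ndarray]]:
    """Stream occupancy in Z-slabs without holding the full SD volume.

    Yields ``(z_slice, occupancy_slab)`` pairs; concatenating the slabs
    reproduces the monolithic :func:`voxelize` result exactly.
    """
    interp = _argument_interpolators(arg)
    ax, ay, az = voxel_grid.axes()
    nx, ny, nz = voxel_grid.shape
    for z0 in range(0, nz, chunk_slices):
        z1 = min(z0 + chunk_slices, nz)
        X, Y, Z = np.meshgrid(ax, ay, az[z0:z1], indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        shape = (nx, ny, z1 - z0)
        xs = [f(pts).reshape(shape) for f in interp]
        occ = (implicit_fn(*xs) - offset_c) <= 0.0
        yield slice(z0, z1), occ


def surface_area(sd: SignedDistanceField, *, cs_hint: float | None = None) -> float:
    """Area of the SD = 0 isosurface (marching cubes), in grid units².

    Returns 0 with a warning if the field does not cross zero. If
    ``cs_hint`` (the smallest unit cell size, in grid units) is given, warn
    when a unit cell spans fewer than 8 voxels along any axis.
    """
    if cs_hint is not None and cs_hint / max(sd.grid.spacing) < 8:
        warnings.warn(
            "fewer than 8 voxels per unit cell; surface area may be inaccurate",
            stacklevel=2,
        )
    lo, hi = sd.sd.min(), sd.sd.max()
    if lo > 0 or hi < 0:
        warnings.warn("signed-distance field has no zero crossing; area = 0", stacklevel=2)
        return 0.0
    verts, faces, _, _ = measure.marching_cubes(sd.sd, level=0.0, spacing=sd.grid.spacing)
    return float(measure.mesh_surface_area(verts, faces))


def surface_mesh(sd: SignedDistanceField) -> tuple[np.ndarray, np.ndarray]:
    """Marching-cubes triangulation (vertices in physical units, faces)."""
    verts, faces, _, _ = measure.marching_cubes(sd.sd, level=0.0, spacing=sd.grid.spacing)
    verts = verts + np.asarray(sd.grid.origin)
    if sd.grid.centered:
        verts = verts + 0.5 * np.asarray(sd.grid.spacing)
    return verts, faces


def porosity(vox: VoxelStructure, window: int = 1) -> tuple[np.ndarray, float]:
    """Windowed fluid fraction ε = 1 − mean(occupancy) and its global mean.

    ``window`` is the block edge in voxels; trailing partial blocks are
    averaged over the voxels available.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    occ = vox.occupancy.astype(float)
    if window == 1:
        eps = 1.0 - occ
    else:
        eps = 1.0 - measure.block_reduce(occ, (window, window, window), np.mean)
    return eps, float(1.0 - occ.mean())
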