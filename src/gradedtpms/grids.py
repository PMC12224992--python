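"""Regular structured grids shared by all field types.

Two sampling conventions coexist in the package and are made explicit per
grid instance:

* node grids (``centered=False``): samples at ``origin + i * spacing``,
  used for cell-size and argument fields that must include the domain
  corners;
* voxel grids (``centered=True``): samples at ``origin + (i + 1/2) * spacing``
  with half-open extents, used for signed-distance / occupancy volumes and
  for flow-solver cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RegularGrid:
    """A regular 3D sample grid.

    Parameters
    ----------
    shape : tuple of int
        Number of samples along (X, Y, Z).
    spacing : tuple of float
        Sample spacing along each axis (mm or m depending on context;
        callers keep track of units).
    origin : tuple of float
        Coordinate of the grid's minimum corner.
    centered : bool
        Whether samples sit at cell centers (voxel convention) or at nodes.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    centered: bool = False

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(not (s > 0) for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def axis(self, i: int) -> np.ndarray:
        """Sample coordinates along axis ``i``."""
        off = 0.5 if self.centered else 0.0
        return self.origin[i] + (np.arange(self.shape[i]) + off) * self.spacing[i]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.axis(0), self.axis(1), self.axis(2)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*self.axes(), indexing="ij")

    def points(self) -> np.ndarray:
        """All sample coordinates as an (N, 3) array in C order."""
        X, Y, Z = self.meshgrid()
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    @property
    def n_samples(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent covered (node grids: span of nodes; voxel grids:
        full half-open box)."""
        if self.centered:
            return tuple(n * s for n, s in zip(self.shape, self.spacing))
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))


def grid_from_box(
    box: tuple[float, float, float],
    spacing: float | tuple[float, float, float],
    *,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    centered: bool = False,
) -> RegularGrid:
    """Build a grid covering ``box`` (extents from ``origin``).

    Node grids include both faces of the box along each axis, using
    ``floor(extent/spacing) + 1`` nodes (the actual spacing is adjusted so the
    end node lands on the box face exactly);
    voxel grids tile the box with ``floor(extent/spacing)`` cells.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    shape = []
    true_spacing = []
    for ext, h in zip(box, spacing):
        if ext == 0:  # degenerate (2D) axis: a single sample
            shape.append(1)
            true_spacing.append(h)
            continue
        if h > ext:
            raise ValueError(f"spacing {h} exceeds domain extent {ext}")
        n = int(np.floor(ext / h + 1e-9))
        if centered:
            shape.append(max(n, 1))
            true_spacing.append(ext / max(n, 1))
        else:
            shape.append(n + 1)
            true_spacing.append(ext / n)
    return RegularGrid(tuple(shape), tuple(true_spacing), origin, centered=centered)
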