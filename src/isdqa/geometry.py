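"""Isodose surface extraction and geometric descriptors.

An isodose surface ``is_x`` is the closed surface of points receiving the
same percent dose ``x``.  It is extracted from the percent grid with
sub-voxel marching-cubes isosurfacing (vertices interpolated along voxel
edges), because the millimetre-scale tolerances of the method demand
sub-voxel geometry; a voxel-shell extraction (boundary voxels of the
``>= level`` region) is kept as an option for sensitivity studies.

The surface shape is parametrized by the Euclidean distances of its points
from the plan isocenter, ``d_x(n) = ||p_x(n) - iso||``.  The module also
computes isodose volumes (voxel counting of the ``>= level`` region),
equivalent-sphere radii ``(3V / 4 pi)**(1/3)``, and the radius-difference
curve over 1 % isodose increments used as the plan's local dose-gradient
measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .dose_io import PercentDoseGrid

__all__ = [
    "IsodoseSurface",
    "DistanceSample",
    "RadiusCurve",
    "MissingIsodoseError",
    "extract_isodose_surface",
    "distances_from_point",
    "enclosed_volume",
    "equivalent_radius",
    "build_radius_curve",
]

#: surfaces with fewer points are rejected: histograms and medians are
#: meaningless below this size
MIN_SURFACE_POINTS = 4


class MissingIsodoseError(ValueError):
    """The requested isodose does not exist (or degenerates) in the grid."""

    def __init__(self, level: float, reason: str = "not present in grid"):
        self.level = level
        super().__init__(f"isodose {level}%: {reason}")


@dataclass
class IsodoseSurface:
    """Point set of one isodose surface, positions in patient mm."""

    level: float
    points: np.ndarray  # (n, 3)
    source: str = "reference"

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class DistanceSample:
    """Euclidean distances of one surface's points from a fixed point."""

    level: float
    distances: np.ndarray  # (n,)
    parametrization_point: np.ndarray  # (3,)

    @property
    def n(self) -> int:
        return int(self.distances.size)

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


@dataclass
class RadiusCurve:
    """Equivalent-sphere radii of the 1-100 % isodose volumes.

    ``radius_diffs[i]`` is the radius gap between level ``levels[i]`` and the
    next higher level (forward difference; the last entry repeats the final
    backward difference).  Radii are made non-increasing by isotonic
    clipping before differencing, so the gaps are non-negative even in the
    presence of voxelisation noise.
    """

    levels: np.ndarray  # (100,) percent
    volumes: np.ndarray  # mm^3
    radii: np.ndarray  # mm, non-increasing
    radius_diffs: np.ndarray  # mm, >= 0

    def radius_at(self, level: float) -> float:
        """Piecewise-linear interpolation of the radius-vs-level curve."""
        return float(np.interp(level, self.levels, self.radii))


def extract_isodose_surface(
    grid: PercentDoseGrid,
    level: float,
    source: str = "reference",
    method: str = "marching_cubes",
) -> IsodoseSurface:
    """Extract the point set of the ``level``-% isodose surface.

    ``marching_cubes`` (default) yields sub-voxel vertices interpolated
    along voxel edges; ``voxel_shell`` yields the centres of boundary voxels
    of the ``>= level`` region.
    """
    if not 0 < level:
        raise ValueError(f"isodose level must be positive, got {level}")
    vmax = grid.max_percent
    if level >= vmax:
        raise MissingIsodoseError(level, f"at or above grid maximum ({vmax:.4g}%)")
    if level <= grid.values.min():
        raise MissingIsodoseError(level, "at or below grid minimum (open surface)")
    if method == "marching_cubes":
        try:
            verts, _, _, _ = measure.marching_cubes(
                grid.values, level=level, spacing=tuple(grid.spacing)
            )
        except (ValueError, RuntimeError) as exc:
            raise MissingIsodoseError(level, str(exc)) from exc
        points = verts + grid.origin
    elif method == "voxel_shell":
        from scipy import ndimage

        mask = grid.values >= level
        shell = mask & ~ndimage.binary_erosion(mask)
        idx = np.argwhere(shell)
        points = idx * grid.spacing + grid.origin
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    if points.shape[0] < MIN_SURFACE_POINTS:
        raise MissingIsodoseError(
            level, f"degenerate surface ({points.shape[0]} points)"
        )
    return IsodoseSurface(level=level, points=points, source=source)


def distances_from_point(surface: IsodoseSurface, point) -> DistanceSample:
    """Distances of every surface point from ``point``, order-preserving."""
    point = np.asarray(point, dtype=float).reshape(3)
    if surface.n_points == 0:
        raise ValueError("cannot compute distances of an empty surface")
    d = np.linalg.norm(surface.points - point, axis=1)
    return DistanceSample(
        level=surface.level, distances=d, parametrization_point=point
    )


def enclosed_volume(grid: PercentDoseGrid, level: float) -> float:
    """Volume (mm^3) of the region with dose >= ``level``, by voxel counting."""
    if not 0 < level:
        raise ValueError(f"isodose level must be positive, got {level}")
    return float(np.count_nonzero(grid.values >= level)) * grid.voxel_volume


def equivalent_radius(volume: float) -> float:
    """Radius (mm) of the sphere with the given volume (mm^3)."""
    if volume < 0:
        raise ValueError(f"volume must be non-negative, got {volume}")
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def build_radius_curve(grid: PercentDoseGrid) -> RadiusCurve:
    """Volumes, equivalent radii and successive radius gaps for levels 1-100 %.

    Expects a grid normalised so the maximum is 100 % (a warning is issued
    otherwise and levels above the maximum get zero volume).
    """
    if not np.isclose(grid.max_percent, 100.0, atol=0.5):
        warnings.warn(
            f"grid maximum is {grid.max_percent:.2f}%, not 100%; the radius "
            "curve assumes per-grid maximum normalisation",
            stacklevel=2,
        )
    levels = np.arange(1, 101, dtype=float)
    flat = np.sort(grid.values, axis=None)
    counts = flat.size - np.searchsorted(flat, levels, side="left")
    volumes = counts * grid.voxel_volume
    radii = (3.0 * volumes / (4.0 * np.pi)) ** (1.0 / 3.0)
    # isotonic clipping: enforce the physically required monotone decrease
    radii = np.minimum.accumulate(radii)
    diffs = np.empty_like(radii)
    diffs[:-1] = radii[:-1] - radii[1:]
    diffs[-1] = diffs[-2]
    return RadiusCurve(levels=levels, volumes=volumes, radii=radii, radius_diffs=diffs)
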