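"""Plan-specific tolerance bands derived from the MLC +/-1 mm QA criterion.

The acceptance band is built from the reference distribution alone:

1. The radius-difference curve (equivalent-sphere radius gap per 1 % isodose
   increment) measures the local dose gradient.  The level whose gap is
   closest to the midrange ``(max + min) / 2`` of the curve is the reference
   isodose ``ISO_mr`` (ties break toward the higher level).
2. On the interpolated radius-vs-level curve ``r(x)``, the isodoses located
   +/- 1 mm (the MLC QA spatial tolerance) from ``ISO_mr`` define a fixed
   dose interval: ``ISO_up`` toward higher levels (always closer to the
   isocenter) and ``ISO_low`` toward lower ones.
3. That dose interval is applied universally: for every evaluated level
   ``x`` the reference histogram at ``x`` is compared with the reference
   histograms at ``x + delta_up`` and ``x - delta_low``, yielding per-level
   Bray-Curtis acceptance limits ``BC_ISOup`` and ``BC_ISOlow``.  Because
   the same dose interval maps to different distances in steep and shallow
   gradient regions, the resulting spatial criterion is non-uniform.

Fractional limit levels are rounded to the nearest whole-percent isodose
(the method operates on 1 % increments throughout).  Levels whose limit
surfaces are missing or degenerate are dropped from the chart with a
warning, never given a fabricated limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dose_io import PercentDoseGrid
from .geometry import (
    MissingIsodoseError,
    RadiusCurve,
    build_radius_curve,
    distances_from_point,
    extract_isodose_surface,
)
from .histograms import bray_curtis, pair_histograms

__all__ = [
    "ToleranceBand",
    "ToleranceError",
    "select_iso_mr",
    "derive_dose_interval",
    "build_tolerance_band",
]

DEFAULT_SPATIAL_TOL_MM = 1.0  # MLC positional QA tolerance
DEFAULT_LEVELS = tuple(range(10, 101, 5))


class ToleranceError(ValueError):
    """Raised when no meaningful tolerance band can be derived."""


@dataclass
class ToleranceBand:
    """Per-isodose Bray-Curtis acceptance limits of one reference plan."""

    iso_mr: int
    delta_up: float  # percentage points toward higher isodoses
    delta_low: float  # percentage points toward lower isodoses
    limits: dict[int, tuple[float, float]]  # level -> (BC_ISOlow, BC_ISOup)
    dropped_levels: list[int] = field(default_factory=list)
    spatial_tol_mm: float = DEFAULT_SPATIAL_TOL_MM

    def __post_init__(self) -> None:
        if self.delta_up <= 0 or self.delta_low <= 0:
            raise ToleranceError(
                f"degenerate tolerance interval (delta_up={self.delta_up}, "
                f"delta_low={self.delta_low}); spatial tolerance too small "
                "for this gradient"
            )
        for level, (bc_low, bc_up) in self.limits.items():
            if bc_low <= 0 or bc_up <= 0:
                raise ToleranceError(
                    f"non-positive acceptance limit at isodose {level}%"
                )


def select_iso_mr(
    curve: RadiusCurve, level_range: tuple[int, int] | None = None
) -> int:
    """Reference isodose: level whose radius gap is closest to the midrange.

    ``level_range`` restricts the search (inclusive bounds), supporting a
    per-target choice on multi-prescription plans whose gradient curve has
    several local maxima.  Ties break toward the higher level.
    """
    levels = curve.levels
    diffs = curve.radius_diffs
    mask = np.isfinite(diffs)
    if level_range is not None:
        lo, hi = level_range
        mask &= (levels >= lo) & (levels <= hi)
    if mask.sum() < 2:
        raise ToleranceError("radius curve has fewer than 2 usable levels")
    d = diffs[mask]
    lv = levels[mask]
    dmax, dmin = d.max(), d.min()
    if dmax - dmin <= 1e-12:
        raise ToleranceError("flat radius-difference curve: no gradient structure")
    midrange = (dmax + dmin) / 2.0
    err = np.abs(d - midrange)
    best = err.min()
    # ties (within floating tolerance) resolve toward the higher level
    candidates = lv[err <= best + 1e-12]
    return int(candidates.max())


def derive_dose_interval(
    curve: RadiusCurve,
    iso_mr: int,
    spatial_tol: float = DEFAULT_SPATIAL_TOL_MM,
) -> tuple[float, float]:
    """Map the +/- ``spatial_tol`` mm criterion at ISO_mr to dose offsets.

    Returns ``(delta_low, delta_up)`` in percentage points, from linear
    interpolation of the radius-vs-level curve: ``ISO_up`` is the level
    whose equivalent radius is ``spatial_tol`` smaller than ISO_mr's,
    ``ISO_low`` the level whose radius is ``spatial_tol`` larger.  Results
    are clamped at the curve ends with a warning; a clamp that collapses an
    offset to zero is an error naming the direction.
    """
    if spatial_tol < 0:
        raise ToleranceError("spatial tolerance must be non-negative")
    levels = curve.levels
    radii = curve.radii  # non-increasing
    r_mr = float(np.interp(iso_mr, levels, radii))
    # invert the non-increasing r(x) with np.interp (needs ascending x)
    r_rev, lv_rev = radii[::-1], levels[::-1]

    def level_at_radius(r_target: float, direction: str) -> float:
        if r_target < radii[-1]:
            warnings.warn(
                f"radius target {r_target:.2f} mm below curve minimum; "
                f"ISO_{direction} clamped to level {levels[-1]:.0f}"
            )
            return float(levels[-1])
        if r_target > radii[0]:
            warnings.warn(
                f"radius target {r_target:.2f} mm above curve maximum; "
                f"ISO_{direction} clamped to level {levels[0]:.0f}"
            )
            return float(levels[0])
        return float(np.interp(r_target, r_rev, lv_rev))

    iso_up = level_at_radius(r_mr - spatial_tol, "up")
    iso_low = level_at_radius(r_mr + spatial_tol, "low")
    delta_up = iso_up - iso_mr
    delta_low = iso_mr - iso_low
    if spatial_tol > 0:
        if delta_up <= 0:
            raise ToleranceError(
                f"radius range too small to move {spatial_tol} mm toward the "
                "isocenter (upper direction)"
            )
        if delta_low <= 0:
            raise ToleranceError(
                f"radius range too small to move {spatial_tol} mm away from "
                "the isocenter (lower direction)"
            )
    return float(delta_low), float(delta_up)


def _round_level(x: float) -> int:
    """Half-up rounding to the nearest whole-percent isodose."""
    return int(np.floor(x + 0.5))


def build_tolerance_band(
    ref_grid: PercentDoseGrid,
    levels=DEFAULT_LEVELS,
    spatial_tol: float = DEFAULT_SPATIAL_TOL_MM,
    iso_mr_override: int | None = None,
    normalize: bool = True,
    extraction_method: str = "marching_cubes",
    curve: RadiusCurve | None = None,
    distance_cache: dict | None = None,
) -> ToleranceBand:
    """Derive the full per-isodose acceptance band of a reference plan.

    Only the reference distribution enters this computation.  ``curve`` and
    ``distance_cache`` allow the caller to reuse the radius curve and
    per-level distance samples across the band and the subsequent
    comparison (keyed by whole-percent level).
    """
    if curve is None:
        curve = build_radius_curve(ref_grid)
    iso_mr = (
        int(iso_mr_override) if iso_mr_override is not None else select_iso_mr(curve)
    )
    delta_low, delta_up = derive_dose_interval(curve, iso_mr, spatial_tol)
    cache = distance_cache if distance_cache is not None else {}

    def ref_distances(level: int):
        if level not in cache:
            surface = extract_isodose_surface(
                ref_grid, level, source="reference", method=extraction_method
            )
            cache[level] = distances_from_point(surface, ref_grid.isocenter)
        return cache[level]

    limits: dict[int, tuple[float, float]] = {}
    dropped: list[int] = []
    for level in levels:
        level = int(level)
        up_level = _round_level(level + delta_up)
        low_level = _round_level(level - delta_low)
        if up_level == level or low_level == level or low_level < 1:
            dropped.append(level)
            warnings.warn(
                f"isodose {level}%: tolerance interval rounds to the level "
                "itself; level dropped from the chart"
            )
            continue
        try:
            d_ref = ref_distances(level)
            d_up = ref_distances(up_level)
            d_low = ref_distances(low_level)
        except MissingIsodoseError as exc:
            dropped.append(level)
            warnings.warn(
                f"isodose {level}%: tolerance limit unavailable ({exc}); "
                "level dropped from the chart"
            )
            continue
        bc_up = bray_curtis(pair_histograms(d_ref, d_up), normalize=normalize)
        bc_low = bray_curtis(pair_histograms(d_ref, d_low), normalize=normalize)
        if bc_up <= 0 or bc_low <= 0:
            dropped.append(level)
            warnings.warn(
                f"isodose {level}%: zero acceptance limit (identical limit "
                "histograms); level dropped from the chart"
            )
            continue
        limits[level] = (bc_low, bc_up)
    if not limits:
        raise ToleranceError("no evaluated level admits a tolerance limit")
    return ToleranceBand(
        iso_mr=iso_mr,
        delta_up=delta_up,
        delta_low=delta_low,
        limits=limits,
        dropped_levels=dropped,
        spatial_tol_mm=spatial_tol,
    )
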