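"""Pre-flight check for rotations the isocentric parametrization cannot see.

Distances from the isocenter are invariant under any rotation of the dose
distribution about that point (or an axis through it): a rotated evaluated
distribution produces isocentric shape histograms identical to the
reference ones, so the ISD chart alone would miss the error.  Histograms
built from off-axis points break that invariance.

The check samples four isodoses (50, 75, 80 and 90 %) and, for each,
compares reference and evaluated histograms parametrized from the isocenter
and from three randomly drawn non-coplanar probe points.  When the
Bray-Curtis result is the same for all four points per sampled isodose, the
evaluated distribution is not rotated about the isocenter; a rotation is
suspected at a level where the isocentric value sits at the discretisation
floor while some probe point disagrees with it by a clear factor
(translations and genuine shape errors move all four values together, so
they are not flagged here - they are ISD territory).  Probe points are drawn uniformly inside the bounding box of the
reference 50 % isodose, non-coplanarity is enforced through a minimum
tetrahedron volume with the isocenter, and the draw is seeded for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_io import PercentDoseGrid
from .geometry import (
    MissingIsodoseError,
    distances_from_point,
    extract_isodose_surface,
)
from .histograms import bray_curtis, pair_histograms

__all__ = ["RotationCheckResult", "run_rotation_check", "ROTATION_CHECK_LEVELS"]

ROTATION_CHECK_LEVELS = (50, 75, 80, 90)
#: BC below this is "identical up to discretisation".  Binning a surface
#: extracted from a voxel grid carries a quadrature floor of roughly
#: bins x (vertex position error) / (histogram range) ~ 1-2 % at 1 mm
#: voxels, so genuinely invariant histograms still differ by that much,
#: while real rotations move probe-point values well above 4-5 %.
DEFAULT_EPS = 0.03
#: a rotation is the one error that leaves the isocentric value at the
#: floor while the probes disagree with it by a clear factor; translations
#: and shape errors move all four parametrization points together
DEFAULT_PROBE_RATIO = 2.0
#: minimum tetrahedron volume (mm^3) of isocenter + probes
MIN_TETRA_VOLUME = 1.0
_MAX_DRAWS = 100


@dataclass
class RotationCheckResult:
    levels_checked: tuple
    probe_points: np.ndarray  # (4, 3): isocenter then three probes (mm)
    bc_matrix: np.ndarray  # (n_levels, 4), NaN where a level was unusable
    rotation_suspected: bool
    seed: int
    eps: float = DEFAULT_EPS
    probe_ratio: float = DEFAULT_PROBE_RATIO

    @property
    def per_level_suspected(self) -> np.ndarray:
        """Rotation signature per level: iso at the floor, probes far above.

        The four Bray-Curtis values must agree for an unrotated plan; a
        level is suspicious when the isocentric value is floor-small
        (< eps) while the best probe disagrees with it by more than
        ``probe_ratio`` and exceeds eps itself.
        """
        iso_bc = self.bc_matrix[:, 0]
        probe_max = np.max(
            np.nan_to_num(self.bc_matrix[:, 1:], nan=-np.inf), axis=1
        )
        usable = ~np.isnan(iso_bc)
        iso = np.nan_to_num(iso_bc, nan=np.inf)
        return usable & (iso < self.eps) & (
            probe_max > np.maximum(self.eps, self.probe_ratio * iso)
        )


def _draw_probe_points(
    rng: np.random.Generator, iso: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    for _ in range(_MAX_DRAWS):
        probes = rng.uniform(lo, hi, size=(3, 3))
        volume = abs(np.linalg.det(probes - iso)) / 6.0
        if volume > MIN_TETRA_VOLUME:
            return probes
    raise ValueError(
        "could not draw non-coplanar probe points (degenerate 50% isodose "
        "bounding box?)"
    )


def run_rotation_check(
    ref: PercentDoseGrid,
    evaluated: PercentDoseGrid,
    seed: int = 0,
    levels=ROTATION_CHECK_LEVELS,
    eps: float = DEFAULT_EPS,
    probe_ratio: float = DEFAULT_PROBE_RATIO,
    extraction_method: str = "marching_cubes",
) -> RotationCheckResult:
    """Probe four isodoses for a rotation about the isocenter.

    Deterministic for a fixed seed.  Levels missing in either grid are
    recorded as NaN rows and excluded from the verdict.
    """
    rng = np.random.default_rng(seed)
    iso = np.asarray(ref.isocenter, dtype=float)
    mask = ref.values >= 50.0
    if not mask.any():
        raise MissingIsodoseError(50.0, "no 50% region for probe sampling")
    idx = np.argwhere(mask)
    lo = idx.min(axis=0) * ref.spacing + ref.origin
    hi = idx.max(axis=0) * ref.spacing + ref.origin
    probes = _draw_probe_points(rng, iso, lo, hi)
    points = np.vstack([iso[None, :], probes])

    bc_matrix = np.full((len(levels), 4), np.nan)
    for i, level in enumerate(levels):
        try:
            ref_surface = extract_isodose_surface(
                ref, level, source="reference", method=extraction_method
            )
            eval_surface = extract_isodose_surface(
                evaluated, level, source="evaluated", method=extraction_method
            )
        except MissingIsodoseError:
            continue
        for j, point in enumerate(points):
            pair = pair_histograms(
                distances_from_point(ref_surface, point),
                distances_from_point(eval_surface, point),
            )
            bc_matrix[i, j] = bray_curtis(pair, normalize=True)

    result = RotationCheckResult(
        levels_checked=tuple(levels),
        probe_points=points,
        bc_matrix=bc_matrix,
        rotation_suspected=False,
        seed=seed,
        eps=eps,
        probe_ratio=probe_ratio,
    )
    result.rotation_suspected = bool(result.per_level_suspected.any())
    return result
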