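"""The ISD comparison engine.

For each evaluated isodose level ``x`` the reference and evaluated surfaces
are parametrized into shape histograms on shared bin edges and compared with
Bray-Curtis dissimilarity ``BC_x``.  The signed, normalised Isodose Surface
Difference is::

    ISD% = +100 * BC_x / BC_ISOup   if median_eval >= median_ref  (hotter)
           -100 * BC_x / BC_ISOlow  otherwise                     (cooler)

where the medians are of the raw isocentric distances (an evaluated surface
whose median distance exceeds the reference's lies farther from the
isocenter, i.e. the evaluated plan is hotter there) and the per-level limits
come from the reference-only tolerance band.  ISD = 0 % means identical
binned shapes; |ISD| = 100 % means the deviation reaches its acceptance
limit, so the rendered chart can draw straight tolerance lines at +/-100 %
for every level even though the raw limits are level-dependent and
asymmetric.

The curve splits into two clinical regions at ISO_mr: levels strictly above
it conform to the target ("PTV"), the rest dominate organ-at-risk dose
("NormalTissue").  The summary statistic is the mean absolute ISD over the
levels with valid limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dose_io import PercentDoseGrid
from .geometry import (
    MissingIsodoseError,
    distances_from_point,
    extract_isodose_surface,
)
from .histograms import bray_curtis, pair_histograms
from .tolerance import (
    DEFAULT_LEVELS,
    DEFAULT_SPATIAL_TOL_MM,
    ToleranceBand,
    build_tolerance_band,
)

__all__ = ["ISDConfig", "ISDEntry", "ISDCurve", "compute_isd_entry",
           "classify_region", "compare_distributions"]


@dataclass
class ISDConfig:
    """Tunable parameters of an ISD comparison."""

    levels: tuple = DEFAULT_LEVELS
    spatial_tol_mm: float = DEFAULT_SPATIAL_TOL_MM
    normalize_histograms: bool = True
    iso_mr_override: int | None = None
    #: implement the alternative reading of the normalisation (hot deviations
    #: divided by BC_ISOlow instead of BC_ISOup) for sensitivity analysis
    swap_limit_pairing: bool = False
    extraction_method: str = "marching_cubes"  # or "voxel_shell"
    run_rotation_check: bool = True
    rotation_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ISDEntry:
    """One evaluated isodose level of the ISD chart."""

    level: int
    bc: float
    median_ref: float
    median_eval: float
    sign: int  # +1 hotter, -1 cooler
    isd_percent: float
    limit_used: str  # "BC_ISOup" or "BC_ISOlow"
    bc_limit_low: float
    bc_limit_up: float
    region: str  # "PTV" or "NormalTissue"

    @property
    def within_tolerance(self) -> bool:
        return abs(self.isd_percent) <= 100.0


@dataclass
class ISDCurve:
    """The full ISD chart for one reference/evaluated comparison."""

    entries: list[ISDEntry]
    band: ToleranceBand
    rotation: object | None = None  # RotationCheckResult when requested
    skipped_levels: list[int] = field(default_factory=list)

    @property
    def iso_mr(self) -> int:
        return self.band.iso_mr

    @property
    def mean_abs_isd(self) -> float:
        """Mean |ISD%| over the levels with valid limits."""
        return float(np.mean([abs(e.isd_percent) for e in self.entries]))

    @property
    def all_within_tolerance(self) -> bool:
        return all(e.within_tolerance for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        """One row per evaluated level, ready for delimited-text export."""
        rows = [
            {
                "level": e.level,
                "bc": e.bc,
                "bc_limit_low": e.bc_limit_low,
                "bc_limit_up": e.bc_limit_up,
                "median_ref_mm": e.median_ref,
                "median_eval_mm": e.median_eval,
                "sign": e.sign,
                "isd_percent": e.isd_percent,
                "limit_used": e.limit_used,
                "region": e.region,
                "within_tolerance": e.within_tolerance,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows).sort_values("level").reset_index(drop=True)


def compute_isd_entry(
    bc: float,
    limits: tuple[float, float],
    median_eval: float,
    median_ref: float,
    level: int = 0,
    iso_mr: int = 0,
    swap_limit_pairing: bool = False,
) -> ISDEntry:
    """Signed normalised ISD at one level.

    ``limits`` is the ``(BC_ISOlow, BC_ISOup)`` pair of the tolerance band.
    A median tie takes the positive (hotter) branch.
    """
    bc_low, bc_up = limits
    if bc_low <= 0 or bc_up <= 0:
        raise ValueError(f"missing or degenerate tolerance limit at level {level}")
    hotter = median_eval >= median_ref
    if hotter:
        limit = bc_low if swap_limit_pairing else bc_up
        limit_name = "BC_ISOlow" if swap_limit_pairing else "BC_ISOup"
        isd = 100.0 * bc / limit
        sign = +1
    else:
        limit = bc_up if swap_limit_pairing else bc_low
        limit_name = "BC_ISOup" if swap_limit_pairing else "BC_ISOlow"
        isd = -100.0 * bc / limit
        sign = -1
    return ISDEntry(
        level=int(level),
        bc=float(bc),
        median_ref=float(median_ref),
        median_eval=float(median_eval),
        sign=sign,
        isd_percent=float(isd),
        limit_used=limit_name,
        bc_limit_low=float(bc_low),
        bc_limit_up=float(bc_up),
        region=classify_region(level, iso_mr),
    )


def classify_region(level: float, iso_mr: float) -> str:
    """Levels strictly above ISO_mr are "PTV", the rest "NormalTissue"."""
    return "PTV" if level > iso_mr else "NormalTissue"


def compare_distributions(
    ref: PercentDoseGrid,
    evaluated: PercentDoseGrid,
    config: ISDConfig | None = None,
) -> ISDCurve:
    """Run the full ISD pipeline on two percent dose grids.

    Both grids must carry registered isocenters (the only spatial
    registration the method needs).  Stages: tolerance band from the
    reference alone; per level, surface extraction in both grids, shared-edge
    histogram pairing, Bray-Curtis value, raw-distance medians, signed
    normalised ISD; optionally the rotation pre-flight check.
    """
    config = config or ISDConfig()
    if not np.allclose(ref.isocenter, evaluated.isocenter, atol=1e-6):
        warnings.warn(
            "reference and evaluated isocenters differ; the comparison "
            "assumes they designate the same physical point"
        )
    ref_cache: dict = {}
    band = build_tolerance_band(
        ref,
        levels=config.levels,
        spatial_tol=config.spatial_tol_mm,
        iso_mr_override=config.iso_mr_override,
        normalize=config.normalize_histograms,
        extraction_method=config.extraction_method,
        distance_cache=ref_cache,
    )
    entries: list[ISDEntry] = []
    skipped = list(band.dropped_levels)
    for level, limits in sorted(band.limits.items()):
        try:
            eval_surface = extract_isodose_surface(
                evaluated, level, source="evaluated",
                method=config.extraction_method,
            )
        except MissingIsodoseError as exc:
            skipped.append(level)
            warnings.warn(f"evaluated distribution: {exc}; level skipped")
            continue
        d_ref = ref_cache[level]
        d_eval = distances_from_point(eval_surface, evaluated.isocenter)
        pair = pair_histograms(d_ref, d_eval)
        bc = bray_curtis(pair, normalize=config.normalize_histograms)
        entries.append(
            compute_isd_entry(
                bc,
                limits,
                median_eval=d_eval.median,
                median_ref=d_ref.median,
                level=level,
                iso_mr=band.iso_mr,
                swap_limit_pairing=config.swap_limit_pairing,
            )
        )
    if len(entries) < 2:
        raise ValueError(
            f"fewer than 2 usable isodose levels ({len(entries)}); "
            "cannot assemble an ISD curve"
        )
    rotation = None
    if config.run_rotation_check:
        from .rotation import run_rotation_check

        try:
            rotation = run_rotation_check(
                ref, evaluated, seed=config.rotation_seed,
                extraction_method=config.extraction_method,
            )
        except MissingIsodoseError as exc:
            warnings.warn(f"rotation pre-flight check skipped: {exc}")
    return ISDCurve(entries=entries, band=band, rotation=rotation,
                    skipped_levels=sorted(skipped))
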