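"""Synthetic verification plans with analytically known isodose geometry.

These stand in for phantom verification plans: radially structured dose
fields sampled on a regular grid (default 1x1x1 mm), with a closed-form
relation between isodose level and isodose radius, so every geometric stage
of the pipeline can be checked against an exact oracle.  The module also
implements the error-induction protocol used throughout: rigid shifts of the
dose field in 1 mm steps along the longitudinal / lateral / vertical axes or
composite directions, with the isocenter left untouched (the error is in the
delivered dose, not in the registration).

Shapes
------
``sphere``
    Isotropic falloff around the isocenter; the level-``x`` isodose is a
    sphere of radius ``r(x)`` known in closed form.
``ellipsoid``
    Anisotropic falloff with semi-axes ``(a, b, c)``; isodoses are scaled
    copies of the unit ellipsoid, optionally rotated about the isocenter by
    a fixed angle (the rotation is applied analytically while sampling, so a
    rotated plan carries no resampling error).
``two_lobe``
    Pointwise maximum of two displaced spherical falloffs - a dual-target
    analogue producing a radius-difference curve with two local maxima.

Falloff profiles (``rho`` = normalised radius)
----------------------------------------------
linear      ``D = d_max * max(0, 1 - rho)``
quadratic   ``D = d_max * max(0, 1 - rho**2)``
sigmoid     ``D = d_max * s(rho) / s(0)`` with ``s(rho) = 1 / (1 + exp((rho - 1) * R0 / w))``
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dose_io import DoseGrid

__all__ = [
    "SyntheticPlanSpec",
    "ShiftSpec",
    "SHIFT_AXES",
    "make_plan",
    "apply_shift",
    "analytic_isodose_radius",
]

#: axis-name convention for rigid shifts: lateral = x, vertical = y,
#: longitudinal = z (patient coordinate axes of the internal (x, y, z) order)
SHIFT_AXES = {"lateral": 0, "vertical": 1, "longitudinal": 2}


@dataclass
class SyntheticPlanSpec:
    """Parameters of a synthetic plan; a fixed spec yields a fixed grid.

    ``radius_mm`` is the falloff scale R0: for the linear profile the dose
    reaches zero at ``rho = 1`` i.e. at distance R0 (sphere) or on the
    ellipsoid with semi-axes ``semi_axes_mm``.  ``sigmoid_width_mm`` is the
    sigmoid transition width w (the 50 %-of-centre level sits at ``rho = 1``).
    """

    shape: str = "sphere"  # sphere | ellipsoid | two_lobe
    falloff: str = "linear"  # linear | quadratic | sigmoid
    d_max: float = 2.0  # Gy
    radius_mm: float = 50.0
    semi_axes_mm: tuple[float, float, float] = (50.0, 35.0, 25.0)
    sigmoid_width_mm: float = 5.0
    lobe_offset_mm: float = 25.0  # two_lobe: centres at +/- offset along x
    lobe_radius_ratio: float = 0.7  # two_lobe: second lobe R0 ratio
    grid_shape: tuple[int, int, int] = (101, 101, 101)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0  # rotation of the shape about the isocenter
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sigma: float = 0.0  # additive Gaussian noise, fraction of d_max
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "two_lobe"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.falloff not in ("linear", "quadratic", "sigmoid"):
            raise ValueError(f"unknown falloff {self.falloff!r}")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        half_extent = min(
            (n - 1) / 2 * s for n, s in zip(self.grid_shape, self.spacing_mm)
        )
        scale = (
            self.radius_mm if self.shape != "ellipsoid" else max(self.semi_axes_mm)
        )
        if self.falloff != "sigmoid" and scale > 2.0 * half_extent:
            raise ValueError(
                f"falloff scale {scale} mm incompatible with grid half-extent "
                f"{half_extent} mm"
            )

    def to_json_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticPlanSpec":
        d = dict(d)
        for key in (
            "semi_axes_mm",
            "grid_shape",
            "spacing_mm",
            "isocenter_mm",
            "rotation_axis",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    ux, uy, uz = axis / norm
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    k = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer([ux, uy, uz], [ux, uy, uz])


def _profile(spec: SyntheticPlanSpec, rho: np.ndarray) -> np.ndarray:
    """Dose as a fraction of d_max at normalised radius rho."""
    if spec.falloff == "linear":
        return np.clip(1.0 - rho, 0.0, None)
    if spec.falloff == "quadratic":
        return np.clip(1.0 - rho**2, 0.0, None)
    # sigmoid, renormalised so the profile is exactly 1 at rho = 0
    k = spec.radius_mm / spec.sigmoid_width_mm
    s0 = 1.0 / (1.0 + np.exp(-k))
    return 1.0 / (1.0 + np.exp((rho - 1.0) * k)) / s0


def _normalized_radius(spec: SyntheticPlanSpec, offsets: np.ndarray) -> np.ndarray:
    """rho field for points at ``offsets`` (mm) from the isocenter."""
    if spec.shape == "ellipsoid":
        scaled = offsets / np.asarray(spec.semi_axes_mm)
        return np.sqrt((scaled**2).sum(axis=-1))
    return np.linalg.norm(offsets, axis=-1) / spec.radius_mm


def make_plan(spec: SyntheticPlanSpec) -> DoseGrid:
    """Sample the analytic dose field of ``spec`` at voxel centres."""
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    iso = np.asarray(spec.isocenter_mm, dtype=float)
    # grid centred on the isocenter
    origin = iso - (np.asarray(shape) - 1) / 2 * spacing
    axes = [origin[i] + np.arange(shape[i]) * spacing[i] - iso[i] for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    offsets = np.stack([gx, gy, gz], axis=-1)
    if spec.rotation_deg != 0.0:
        # rotating the shape by R about the isocenter == sampling at R^T x;
        # applied analytically, so a rotated plan carries no resampling error
        rot = _rotation_matrix(spec.rotation_axis, spec.rotation_deg)
        offsets = offsets @ rot
    if spec.shape == "two_lobe":
        centre = np.array([spec.lobe_offset_mm, 0.0, 0.0])
        spec_a = spec
        rho_a = _normalized_radius_sphere(offsets - centre, spec_a.radius_mm)
        rho_b = _normalized_radius_sphere(
            offsets + centre, spec_a.radius_mm * spec.lobe_radius_ratio
        )
        frac = np.maximum(_profile(spec, rho_a), _profile(spec, rho_b))
    else:
        rho = _normalized_radius(spec, offsets)
        frac = _profile(spec, rho)
    values = spec.d_max * frac
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(
            0.0, spec.noise_sigma * spec.d_max, size=values.shape
        )
        values = np.clip(values, 0.0, None)
    return DoseGrid(values=values, spacing=spacing, origin=origin, isocenter=iso)


def _normalized_radius_sphere(offsets: np.ndarray, r0: float) -> np.ndarray:
    return np.linalg.norm(offsets, axis=-1) / r0


@dataclass
class ShiftSpec:
    """A rigid positional error applied to the delivered dose field."""

    vector_mm: tuple[float, float, float]
    axis: str = field(default="composite")

    def __post_init__(self) -> None:
        self.vector_mm = tuple(float(v) for v in np.asarray(self.vector_mm).reshape(3))

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector_mm))

    @classmethod
    def along(cls, axis: str, magnitude_mm: float) -> "ShiftSpec":
        """Single-direction shift along ``lateral``/``vertical``/``longitudinal``."""
        if axis not in SHIFT_AXES:
            raise ValueError(f"axis must be one of {sorted(SHIFT_AXES)}")
        vec = [0.0, 0.0, 0.0]
        vec[SHIFT_AXES[axis]] = float(magnitude_mm)
        return cls(vector_mm=tuple(vec), axis=axis)


def apply_shift(grid: DoseGrid, shift: ShiftSpec, order: int = 3) -> DoseGrid:
    """Rigidly translate the dose field, keeping the isocenter metadata fixed.

    The field is resampled onto the original grid with spline interpolation
    (tricubic by default) and clipped at zero; this mimics a setup/delivery
    error recalculated against a fixed verification geometry.
    """
    extent = min(
        (n - 1) * s for n, s in zip(grid.values.shape, grid.spacing)
    )
    if shift.magnitude >= extent / 4:
        raise ValueError(
            f"shift of {shift.magnitude:.1f} mm exceeds a quarter of the grid "
            f"extent ({extent:.0f} mm)"
        )
    shift_voxels = np.asarray(shift.vector_mm) / grid.spacing
    # field translated by +t: new(x) = old(x - t)
    values = ndimage.shift(
        grid.values, shift_voxels, order=order, mode="constant", cval=0.0
    )
    values = np.clip(values, 0.0, None)
    return DoseGrid(
        values=values,
        spacing=grid.spacing,
        origin=grid.origin,
        isocenter=grid.isocenter,
    )


def analytic_isodose_radius(spec: SyntheticPlanSpec, level: float) -> float:
    """Closed-form radius (mm) of the ``level``-% isodose of ``spec``.

    For spheres this is the geometric radius; for ellipsoids the
    equivalent-sphere radius ``rho(level) * (a b c)**(1/3)`` of the scaled
    isodose ellipsoid.  Levels are percent of the field maximum.
    """
    if spec.shape == "two_lobe":
        raise ValueError("two_lobe plans have no closed-form isodose radius")
    if not 0 < level <= 100:
        raise ValueError(f"level must be in (0, 100], got {level}")
    f = level / 100.0
    if spec.falloff == "linear":
        rho = 1.0 - f
    elif spec.falloff == "quadratic":
        rho = float(np.sqrt(1.0 - f))
    else:  # sigmoid: invert f = s(rho)/s(0)
        k = spec.radius_mm / spec.sigmoid_width_mm
        s0 = 1.0 / (1.0 + np.exp(-k))
        inner = 1.0 / (f * s0) - 1.0
        if inner <= 0:
            return 0.0
        rho = 1.0 + np.log(inner) / k
        rho = max(rho, 0.0)
    if spec.shape == "ellipsoid":
        a, b, c = spec.semi_axes_mm
        return float(rho * (a * b * c) ** (1.0 / 3.0))
    return float(rho * spec.radius_mm)
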