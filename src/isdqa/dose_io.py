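"""Reading, writing and normalising 3D dose grids.

Two on-disk representations are supported:

* DICOM RTDOSE (the format treatment planning systems export), read with
  :mod:`pydicom`.  Dose is reconstructed as ``stored_value * DoseGridScaling``
  and the spatial metadata (``ImagePositionPatient``, ``PixelSpacing``,
  ``GridFrameOffsetVector``) is resolved into metric patient coordinates.
* A plain array container (NumPy ``.npz`` archive holding the dose array and
  a JSON metadata sidecar), used for synthetic plans and round-trip tests.

Internally everything is a :class:`DoseGrid`: a float array indexed ``(x, y,
z)`` with per-axis voxel spacing, the position of the first voxel centre
(``origin``) and the plan isocenter, all in millimetres, dose in Gy.
Percent-of-maximum grids (:class:`PercentDoseGrid`) are derived from a
``DoseGrid`` via :func:`to_percent`; isodose levels are always expressed in
percent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DoseGrid",
    "PercentDoseGrid",
    "DoseIOError",
    "load_dose_grid",
    "save_dose_grid",
    "to_percent",
]

#: maximum allowed deviation (mm) between successive slice gaps in an RTDOSE
SLICE_SPACING_TOL = 1e-3


class DoseIOError(ValueError):
    """Raised for unreadable files or missing/inconsistent spatial metadata."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise DoseIOError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass
class DoseGrid:
    """A 3D absorbed-dose field with spatial metadata.

    Attributes
    ----------
    values : ndarray
        Dose in Gy, axis order ``(x, y, z)``, all values >= 0.
    spacing : ndarray
        Per-axis voxel size in mm, strictly positive.
    origin : ndarray
        Patient coordinates (mm) of the centre of voxel ``[0, 0, 0]``.
    isocenter : ndarray
        Parametrization point of the plan in patient coordinates (mm).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    isocenter: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DoseIOError(f"dose array must be 3D, got {self.values.ndim}D")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise DoseIOError("dose values must be finite and non-negative")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise DoseIOError("voxel spacing must be strictly positive")
        self.origin = _as_vec3(self.origin, "origin")
        self.isocenter = _as_vec3(self.isocenter, "isocenter")
        lo, hi = self.bounds
        if np.any(self.isocenter < lo) or np.any(self.isocenter > hi):
            warnings.warn(
                "isocenter lies outside the dose grid bounding box; distance "
                "histograms remain defined but may be poorly centred",
                stacklevel=2,
            )

    @property
    def d_max(self) -> float:
        """Maximum dose in the grid (Gy)."""
        return float(self.values.max())

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corner of the voxel-centre bounding box (mm)."""
        upper = self.origin + (np.array(self.values.shape) - 1) * self.spacing
        return self.origin.copy(), upper

    def voxel_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinate vectors (mm)."""
        return tuple(
            self.origin[i] + np.arange(self.values.shape[i]) * self.spacing[i]
            for i in range(3)
        )


@dataclass
class PercentDoseGrid:
    """A dose grid expressed in percent of a normalisation dose.

    Under the default per-grid-maximum normalisation the values span
    ``[0, 100]`` with at least one voxel at exactly 100.  Under an explicit
    normalisation dose the values may exceed 100 (isodose levels above 100
    are then simply extractable).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    isocenter: np.ndarray
    normalization_dose: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DoseIOError("percent dose array must be 3D")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise DoseIOError("percent dose values must be finite, non-negative")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise DoseIOError("voxel spacing must be strictly positive")
        self.origin = _as_vec3(self.origin, "origin")
        self.isocenter = _as_vec3(self.isocenter, "isocenter")

    @property
    def max_percent(self) -> float:
        return float(self.values.max())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel (mm^3)."""
        return float(np.prod(self.spacing))

    def voxel_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + np.arange(self.values.shape[i]) * self.spacing[i]
            for i in range(3)
        )


# ---------------------------------------------------------------------------
# plain array container
# ---------------------------------------------------------------------------

def save_dose_grid(grid: DoseGrid, path) -> Path:
    """Write a :class:`DoseGrid` to the plain array container (``.npz``).

    The archive holds the raw float64 dose array plus a JSON sidecar with
    spacing, origin, isocenter and units; the round trip is bit-exact.
    """
    path = Path(path)
    meta = {
        "format": "isdqa-dose-container",
        "version": 1,
        "units": "Gy",
        "axis_order": "xyz",
        "spacing_mm": list(map(float, grid.spacing)),
        "origin_mm": list(map(float, grid.origin)),
        "isocenter_mm": list(map(float, grid.isocenter)),
    }
    np.savez(path, values=grid.values, meta_json=np.bytes_(json.dumps(meta)))
    # np.savez appends .npz if missing
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _load_container(path: Path, isocenter_override) -> DoseGrid:
    try:
        with np.load(path, allow_pickle=False) as archive:
            values = archive["values"]
            meta = json.loads(bytes(archive["meta_json"]).decode("utf-8"))
    except Exception as exc:  # noqa: BLE001 - normalise into DoseIOError
        raise DoseIOError(f"unreadable dose container {path}: {exc}") from exc
    try:
        spacing = meta["spacing_mm"]
        origin = meta["origin_mm"]
    except KeyError as exc:
        raise DoseIOError(f"dose container {path} lacks spatial metadata") from exc
    iso = isocenter_override if isocenter_override is not None else meta.get(
        "isocenter_mm"
    )
    if iso is None:
        raise DoseIOError(
            "isocenter absent from container metadata and no override given"
        )
    return DoseGrid(values=values, spacing=spacing, origin=origin, isocenter=iso)


# ---------------------------------------------------------------------------
# DICOM RTDOSE
# ---------------------------------------------------------------------------

def _load_rtdose(path: Path, isocenter_override) -> DoseGrid:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # noqa: BLE001
        raise DoseIOError(f"unreadable DICOM file {path}: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTDOSE" and getattr(
        ds, "Modality", None
    ) != "DOSE":
        warnings.warn(f"{path}: Modality is not RTDOSE; reading anyway")
    for tag in ("ImagePositionPatient", "PixelSpacing", "GridFrameOffsetVector"):
        if getattr(ds, tag, None) is None:
            raise DoseIOError(f"{path}: missing spatial metadata {tag}")
    orientation = np.asarray(
        getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float
    )
    if not np.allclose(orientation, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise DoseIOError(
            "only axis-aligned (identity orientation) RTDOSE grids are supported"
        )
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if offsets.size < 2:
        raise DoseIOError("RTDOSE must contain at least two frames")
    gaps = np.diff(offsets)
    if np.ptp(gaps) > SLICE_SPACING_TOL or gaps[0] <= 0:
        raise DoseIOError(
            f"non-uniform or non-positive slice spacing (ptp={np.ptp(gaps):.2g} mm)"
        )
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    frames = ds.pixel_array.astype(float) * scaling  # (frame=z, row=y, col=x)
    values = np.transpose(frames, (2, 1, 0))  # -> (x, y, z)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    spacing = (col_spacing, row_spacing, float(gaps[0]))
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    if isocenter_override is None:
        raise DoseIOError(
            "RTDOSE objects carry no isocenter; pass isocenter_override "
            "(e.g. the plan isocenter from the RTPLAN)"
        )
    return DoseGrid(
        values=values, spacing=spacing, origin=origin, isocenter=isocenter_override
    )


def load_dose_grid(path, isocenter_override=None) -> DoseGrid:
    """Load a dose grid from DICOM RTDOSE or the plain array container.

    Parameters
    ----------
    path : path-like
        ``.npz`` containers are detected by suffix; anything else is
        attempted as DICOM.
    isocenter_override : 3-vector (mm), optional
        Overrides (container) or supplies (DICOM) the isocenter.
    """
    path = Path(path)
    if not path.exists():
        raise DoseIOError(f"no such file: {path}")
    if path.suffix == ".npz":
        return _load_container(path, isocenter_override)
    return _load_rtdose(path, isocenter_override)


# ---------------------------------------------------------------------------
# percent normalisation
# ---------------------------------------------------------------------------

def to_percent(
    grid: DoseGrid,
    normalization: str = "global_max",
    dose: float | None = None,
) -> PercentDoseGrid:
    """Express a dose grid in percent of a normalisation dose.

    ``global_max`` (default) normalises each distribution to its own maximum,
    so isodose levels run from 0 to 100 within every grid independently.
    ``explicit_dose`` normalises to a caller-supplied dose in Gy (e.g. the
    prescription dose); values may then exceed 100.
    """
    if normalization == "global_max":
        norm = grid.d_max
    elif normalization == "explicit_dose":
        if dose is None:
            raise DoseIOError("explicit_dose normalisation requires dose=")
        norm = float(dose)
    else:
        raise DoseIOError(f"unknown normalization {normalization!r}")
    if norm <= 0:
        raise DoseIOError(f"normalisation dose must be positive, got {norm}")
    return PercentDoseGrid(
        values=grid.values * (100.0 / norm),
        spacing=grid.spacing,
        origin=grid.origin,
        isocenter=grid.isocenter,
        normalization_dose=norm,
    )
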