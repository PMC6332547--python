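"""Dose grids, structure masks and normal-lung definitions.

A treatment plan is represented by a regular 3D dose grid (Gy) plus boolean
structure masks congruent with it (bilateral lungs, GTV, CTV, PTV, PGTV).
The three normal-lung volumes compared throughout the package are built here:

* ``TOTAL_LUNG``        -- both lungs as contoured;
* ``LUNG_MINUS_PGTV``   -- lungs minus the intrapulmonary part of the PGTV;
* ``LUNG_MINUS_PTV``    -- lungs minus the intrapulmonary part of the PTV.

"Intrapulmonary part" means the subtraction is the plain set difference
``lungs AND NOT target``: target voxels outside the lungs never remove lung
volume (the overlap rule).  Voxel membership is by voxel center; volumes are
voxel count times voxel volume, with no partial-volume weighting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "DoseGrid",
    "StructureMask",
    "LungDefinition",
    "expand_margin",
    "normal_lung_mask",
    "save_structures",
    "load_structures",
]


@dataclass(frozen=True)
class DoseGrid:
    """Regular 3D scalar field of absorbed dose.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Dose per voxel in Gy; finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths in mm per axis, strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"dose grid must be 3D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose values must be finite")
        if np.any(values < 0):
            raise ValueError("dose values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class StructureMask:
    """Named boolean voxel mask congruent with a :class:`DoseGrid`."""

    name: str
    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={voxels.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0

    def is_empty(self) -> bool:
        return not self.voxels.any()


class LungDefinition(str, Enum):
    """The three normal-lung volume conventions being compared."""

    TOTAL_LUNG = "total"
    LUNG_MINUS_PGTV = "lungpgtv"
    LUNG_MINUS_PTV = "lungptv"


def expand_margin(mask: StructureMask, margin_mm: float, name: str | None = None) -> StructureMask:
    """Uniform (isotropic in physical space) margin expansion of a mask.

    Returns the Euclidean dilation: every voxel whose center lies within
    ``margin_mm`` of the center of any voxel of the input is set.  Anisotropic
    voxel spacing is handled by computing distances in mm.  The result is
    always a superset of the input and is clipped at the grid boundary.

    Parameters
    ----------
    mask : StructureMask
    margin_mm : float
        Physical margin, >= 0.  A zero margin returns an identical mask.
    name : str, optional
        Name for the result; default ``"{mask.name}+{margin_mm:g}mm"``.
    """
    margin_mm = float(margin_mm)
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    if name is None:
        name = f"{mask.name}+{margin_mm:g}mm"
    if mask.is_empty():
        warnings.warn(f"expand_margin: mask {mask.name!r} is empty; returned unchanged")
        return StructureMask(name, mask.voxels.copy(), mask.spacing)
    if margin_mm == 0:
        return StructureMask(name, mask.voxels.copy(), mask.spacing)

    # Exact Euclidean distance from every background voxel center to the mask,
    # in physical units; threshold with a relative epsilon so voxels exactly at
    # the margin radius are included (<= comparison).
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
    out = dist <= margin_mm * (1.0 + 1e-12) + 1e-9

    border = np.zeros_like(out)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    if (out & border).any():
        logger.warning(
            "expand_margin: dilation of %r by %g mm reaches the grid boundary; clipped",
            mask.name, margin_mm,
        )
    return StructureMask(name, out, mask.spacing)


def normal_lung_mask(
    lungs: StructureMask,
    mode: LungDefinition,
    target: StructureMask | None = None,
) -> StructureMask:
    """Build one of the three normal-lung volumes.

    ``TOTAL_LUNG`` returns the lungs unchanged (no target is accepted).  The
    other modes subtract only the intrapulmonary part of the given target:
    ``result = lungs AND NOT target``, hence
    ``volume(result) = volume(lungs) - volume(lungs ∩ target)``.
    """
    mode = LungDefinition(mode)
    if mode is LungDefinition.TOTAL_LUNG:
        if target is not None:
            raise ValueError("TOTAL_LUNG takes no target structure")
        return StructureMask(mode.value, lungs.voxels.copy(), lungs.spacing)
    if target is None:
        raise ValueError(f"mode {mode.name} requires a target structure")
    if target.voxels.shape != lungs.voxels.shape:
        raise ValueError(
            f"grid mismatch: lungs {lungs.voxels.shape} vs target {target.voxels.shape}"
        )
    if target.spacing != lungs.spacing:
        raise ValueError(
            f"grid mismatch: lungs spacing {lungs.spacing} vs target {target.spacing}"
        )
    return StructureMask(mode.value, lungs.voxels & ~target.voxels, lungs.spacing)


# -- flat-binary serialization (DICOM-RT deliberately unsupported) -----------

def save_structures(path: str | Path, dose: DoseGrid, masks: dict[str, StructureMask]) -> None:
    """Write a dose grid and its masks as flat binary arrays + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dose.values.astype("<f8").tofile(path / "dose.bin")
    for mask_name, mask in masks.items():
        if mask.voxels.shape != dose.shape:
            raise ValueError(f"mask {mask_name!r} shape mismatch with dose grid")
        mask.voxels.astype("u1").tofile(path / f"{mask_name}.bin")
    meta = {
        "shape": list(dose.shape),
        "spacing_mm": list(dose.spacing),
        "dose_dtype": "<f8",
        "mask_dtype": "u1",
        "structures": sorted(masks),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_structures(path: str | Path) -> tuple[DoseGrid, dict[str, StructureMask]]:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    shape = tuple(meta["shape"])
    spacing = tuple(meta["spacing_mm"])
    values = np.fromfile(path / "dose.bin", dtype=meta["dose_dtype"]).reshape(shape)
    dose = DoseGrid(values, spacing)
    masks = {
        name: StructureMask(
            name,
            np.fromfile(path / f"{name}.bin", dtype=meta["mask_dtype"]).reshape(shape).astype(bool),
            spacing,
        )
        for name in meta["structures"]
    }
    return dose, masks
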