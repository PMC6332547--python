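"""Cumulative dose-volume histograms and the V5 / V20 / MLD endpoints.

The three dosimetric endpoints are computed directly from the voxel set, not
from the binned histogram, so there is no discretization error; the DVH object
is a reporting artifact.  V_x uses the inclusive convention: the percent of
structure volume receiving a dose >= x Gy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DoseGrid, LungDefinition, StructureMask

__all__ = ["DVH", "DoseMetrics", "compute_dvh", "vx", "mld", "compute_metrics"]

DEFAULT_BIN_WIDTH_GY = 0.1


@dataclass(frozen=True)
class DVH:
    """Cumulative DVH: percent of structure volume receiving >= each dose.

    ``bin_edges`` are ascending doses in Gy starting at 0 with constant width;
    ``cum_volume_pct`` is non-increasing, starts at 100 and lies in [0, 100].
    """

    bin_edges: np.ndarray
    cum_volume_pct: np.ndarray
    structure_volume_cm3: float

    def value_at(self, dose_gy: float) -> float:
        """Cumulative volume percent at the bin edge nearest below ``dose_gy``."""
        idx = int(np.searchsorted(self.bin_edges, dose_gy, side="right")) - 1
        idx = max(idx, 0)
        return float(self.cum_volume_pct[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.bin_edges, "volume_pct": self.cum_volume_pct})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DoseMetrics:
    """V5 (%), V20 (%) and mean dose (Gy) for one normal-lung definition."""

    v5: float
    v20: float
    mld: float
    definition: LungDefinition

    def __post_init__(self):
        if not 0.0 <= self.v20 <= self.v5 <= 100.0:
            raise ValueError(f"need 0 <= V20 <= V5 <= 100, got V5={self.v5}, V20={self.v20}")
        if self.mld < 0:
            raise ValueError(f"MLD must be >= 0, got {self.mld}")


def _mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if mask.voxels.shape != dose.shape:
        raise ValueError(f"grid mismatch: dose {dose.shape} vs mask {mask.voxels.shape}")
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty; dose statistics are undefined")
    return dose.values[mask.voxels]


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH_GY) -> DVH:
    """Cumulative DVH by voxel counting on a uniform dose grid of edges.

    Edges run from 0 to just past the maximum dose inside the mask in steps of
    ``bin_width``; the value at each edge is the percent of mask voxels with
    dose >= that edge.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    doses = np.sort(_mask_doses(dose, mask))
    n = doses.size
    n_edges = int(np.ceil(doses[-1] / bin_width)) + 2  # cover max dose, end at 0%
    edges = np.arange(n_edges) * bin_width
    # voxels with dose >= edge == n - (number strictly below edge)
    cum = 100.0 * (n - np.searchsorted(doses, edges, side="left")) / n
    return DVH(edges, cum, mask.volume_cm3)


def vx(dose: DoseGrid, mask: StructureMask, threshold_gy: float) -> float:
    """Percent of structure volume receiving >= ``threshold_gy`` (inclusive)."""
    doses = _mask_doses(dose, mask)
    return float(100.0 * np.count_nonzero(doses >= threshold_gy) / doses.size)


def mld(dose: DoseGrid, mask: StructureMask) -> float:
    """Mean dose over the mask voxels, in Gy."""
    return float(np.mean(_mask_doses(dose, mask)))


def compute_metrics(dose: DoseGrid, mask: StructureMask, definition: LungDefinition) -> DoseMetrics:
    """V5, V20 and MLD of one normal-lung mask in one call."""
    doses = _mask_doses(dose, mask)
    return DoseMetrics(
        v5=float(100.0 * np.count_nonzero(doses >= 5.0) / doses.size),
        v20=float(100.0 * np.count_nonzero(doses >= 20.0) / doses.size),
        mld=float(doses.mean()),
        definition=LungDefinition(definition),
    )
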