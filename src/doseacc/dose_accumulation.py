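"""Dose warping, summation and DVH machinery.

Weekly dose grids are pulled back onto the planning anatomy through the
per-week displacement fields (trilinear interpolation, zero-dose fill) and
summed voxelwise into the cumulated dose.  Dose-volume histograms are
cumulative curves of the structure volume fraction receiving at least each
dose level, on fixed-width bins (0.1 Gy by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_image import Volume, VectorField, warp_volume

__all__ = [
    "DoseGrid",
    "DvhCurve",
    "warp_dose",
    "accumulate",
    "compute_dvh",
    "mean_dose",
    "dvh_difference",
]


@dataclass
class DoseGrid(Volume):
    """A dose volume (Gy, values >= 0) with a provenance tag."""

    provenance: str = "week"

    def __post_init__(self):
        self.unit = "Gy"
        super().__post_init__()
        if np.any(self.voxels < 0):
            raise ValueError("dose values must be nonnegative")

    @classmethod
    def from_volume(cls, vol: Volume, provenance: str = "week") -> "DoseGrid":
        return cls(vol.voxels, vol.spacing, vol.origin, "Gy", provenance)


def warp_dose(weekly: DoseGrid, fld: VectorField) -> DoseGrid:
    """Pull a weekly dose onto the planning grid; zero dose outside."""
    return DoseGrid.from_volume(warp_volume(weekly, fld, fill=0.0), weekly.provenance)


def accumulate(doses: list, weights=None) -> DoseGrid:
    """Voxelwise (optionally weighted) sum of dose grids on a common geometry."""
    if not doses:
        raise ValueError("accumulate needs at least one dose grid")
    ref = doses[0]
    for d in doses[1:]:
        if not ref.same_geometry(d):
            raise ValueError("all dose grids must share the planning geometry")
    if weights is None:
        weights = np.ones(len(doses))
    total = sum(w * d.voxels for w, d in zip(weights, doses))
    return DoseGrid(total, ref.spacing, ref.origin, "Gy", "cumulated")


def _mask_values(dose: Volume, mask) -> np.ndarray:
    m = mask.voxels if isinstance(mask, Volume) else np.asarray(mask)
    m = m > 0.5
    if m.shape != dose.shape:
        raise ValueError("mask and dose must share geometry")
    if not m.any():
        raise ValueError("mask is empty")
    return dose.voxels[m]


@dataclass
class DvhCurve:
    """Cumulative dose-volume curve: % of volume receiving >= each dose."""

    edges: np.ndarray       # dose thresholds, Gy
    volume_pct: np.ndarray  # same length, starts at 100, ends at 0

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.volume_pct = np.asarray(self.volume_pct, dtype=np.float64)
        if self.edges.shape != self.volume_pct.shape:
            raise ValueError("edges and volume_pct must align")
        if np.any(np.diff(self.volume_pct) > 1e-9):
            raise ValueError("DVH must be monotone non-increasing")

    def scaled(self, factor: float) -> "DvhCurve":
        """The same curve with all doses multiplied by ``factor``."""
        return DvhCurve(self.edges * factor, self.volume_pct.copy())

    def at(self, doses: np.ndarray) -> np.ndarray:
        """Evaluate the curve at arbitrary doses.

        Between tabulated edges the next edge's value is used (the volume
        fraction receiving at least a dose can only drop between edges),
        so a uniform-dose step is honoured exactly.
        """
        doses = np.asarray(doses, dtype=np.float64)
        idx = np.searchsorted(self.edges, doses, side="left")
        out = np.where(
            idx >= len(self.edges), 0.0, self.volume_pct[np.clip(idx, 0, len(self.edges) - 1)]
        )
        return np.where(doses <= self.edges[0], 100.0, out)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.edges, "volume_pct": self.volume_pct})


def compute_dvh(dose: Volume, mask, bin_width_gy: float = 0.1) -> DvhCurve:
    """Cumulative DVH of ``dose`` restricted to ``mask``."""
    vals = _mask_values(dose, mask)
    top = float(vals.max())
    nbins = int(np.ceil(top / bin_width_gy)) + 2
    edges = np.arange(nbins) * bin_width_gy
    pct = np.array([100.0 * np.mean(vals >= e) for e in edges])
    pct[0] = 100.0
    return DvhCurve(edges, pct)


def mean_dose(dose: Volume, mask) -> float:
    """Arithmetic mean dose over the mask voxels, in Gy."""
    return float(np.mean(_mask_values(dose, mask)))


def dvh_difference(
    weekly: DvhCurve,
    plan: DvhCurve,
    scale_to_total: float = 1.0,
    bin_width_gy: float = 0.1,
) -> pd.DataFrame:
    """Weekly-minus-planning DVH difference on a shared dose axis.

    The weekly curve (typically per-fraction dose) is first rescaled to the
    total-course dose scale via ``scale_to_total`` (e.g. 35 fractions);
    both curves are then evaluated on shared ``bin_width_gy`` bins and
    subtracted, giving a volume-% difference per dose bin.
    """
    wk = weekly.scaled(scale_to_total)
    top = max(wk.edges[-1], plan.edges[-1])
    edges = np.arange(int(np.ceil(top / bin_width_gy)) + 1) * bin_width_gy
    diff = wk.at(edges) - plan.at(edges)
    return pd.DataFrame({"dose_gy": edges, "volume_pct_diff": diff})
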