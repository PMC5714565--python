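"""Differential and cumulative dose-volume histograms for masked structures."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, MaskError
from .grids import ImageGrid, StructureMask

__all__ = ["DoseQuantity", "DVHCurve", "compute_dvh", "dvh_statistics"]

DEFAULT_BIN_WIDTH_GY = 0.5


class DoseQuantity(str, enum.Enum):
    PHYSICAL = "PHYSICAL"
    BED = "BED"
    EQ2 = "EQ2"


@dataclass
class DVHCurve:
    """Differential DVH on uniform bins, with absolute volumes per bin.

    ``bin_edges`` has length ``n+1``; ``diff_volume_cm3`` (length ``n``)
    holds the structure volume whose dose falls in each half-open bin
    ``[lo, hi)`` (top bin closed).  Voxel-wise summary statistics computed at
    construction are carried along, since binning loses a little precision.
    """

    bin_edges: np.ndarray
    diff_volume_cm3: np.ndarray
    structure: str
    dose_quantity: DoseQuantity = DoseQuantity.PHYSICAL
    mean_gy: float | None = None
    sd_gy: float | None = None
    min_gy: float | None = None
    max_gy: float | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.diff_volume_cm3 = np.asarray(self.diff_volume_cm3, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.diff_volume_cm3) + 1:
            raise ValueError("bin_edges must have one more entry than diff_volume_cm3")
        if np.any(self.diff_volume_cm3 < 0):
            raise ValueError("bin volumes must be >= 0")
        self.dose_quantity = DoseQuantity(self.dose_quantity)

    @property
    def total_volume_cm3(self) -> float:
        return float(self.diff_volume_cm3.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative DVH: volume receiving at least each bin-edge dose.

        Returns (edges, volumes); volumes start at the total structure
        volume and end at 0.
        """
        suffix = np.concatenate([np.cumsum(self.diff_volume_cm3[::-1])[::-1], [0.0]])
        return self.bin_edges, suffix

    def volume_at_least(self, dose_gy: float) -> float:
        """Interpolated absolute volume (cm³) receiving >= ``dose_gy``."""
        edges, cum = self.cumulative()
        return float(np.interp(dose_gy, edges, cum))

    def to_frame(self) -> pd.DataFrame:
        _, cum = self.cumulative()
        return pd.DataFrame({
            "bin_lo_gy": self.bin_edges[:-1],
            "bin_hi_gy": self.bin_edges[1:],
            "diff_cm3": self.diff_volume_cm3,
            "cum_cm3": cum[:-1],
        })

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# structure: {self.structure}\n")
            fh.write(f"# dose_quantity: {self.dose_quantity.value}\n")
            self.to_frame().to_csv(fh, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DVHCurve":
        path = Path(path)
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                body_start = i + 1
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        edges = np.concatenate([df["bin_lo_gy"].to_numpy(), [df["bin_hi_gy"].iloc[-1]]])
        return cls(edges, df["diff_cm3"].to_numpy(),
                   structure=meta.get("structure", path.stem),
                   dose_quantity=meta.get("dose_quantity", "PHYSICAL"))


def compute_dvh(dose: ImageGrid, mask: StructureMask,
                bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> DVHCurve:
    """Histogram the voxel doses inside a structure.

    Each voxel contributes its full volume to the bin containing its dose
    (all-in/all-out masks, no fractional occupancy).  Bins are uniform,
    half-open ``[lo, hi)`` with the top bin closed, starting at 0 Gy.
    Voxel-wise mean/SD/min/max are attached to the curve; the SD is the
    volume-weighted population SD.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    mask.require_nonempty()
    if not mask.grid.same_geometry(dose):
        raise GeometryError(
            f"mask '{mask.name}' geometry does not match the dose grid")

    doses = dose.values[mask.indices]
    vox_vol = dose.voxel_volume_cm3
    n_bins = max(1, int(np.ceil((doses.max() + 1e-12) / bin_width_gy)))
    edges = bin_width_gy * np.arange(n_bins + 1)
    counts, _ = np.histogram(doses, bins=edges)  # top edge closed
    return DVHCurve(
        edges, counts * vox_vol, structure=mask.name,
        dose_quantity=DoseQuantity.PHYSICAL,
        mean_gy=float(doses.mean()),
        sd_gy=float(doses.std()),
        min_gy=float(doses.min()),
        max_gy=float(doses.max()),
    )


def dvh_statistics(curve: DVHCurve,
                   vx_thresholds_gy: tuple[float, ...] = ()) -> dict:
    """Summary statistics computed from bin centres weighted by bin volume.

    Returns mean, volume-weighted population SD, Dmin/Dmax of occupied bins,
    total volume, and ``V{x}Gy`` absolute and percent volumes for each
    requested threshold (inclusive).
    """
    v = curve.diff_volume_cm3
    total = v.sum()
    if total <= 0:
        raise MaskError("DVH has zero total volume")
    centers = curve.bin_centers
    mean = float(np.sum(centers * v) / total)
    sd = float(np.sqrt(np.sum(v * (centers - mean) ** 2) / total))
    occupied = np.nonzero(v)[0]
    stats = {
        "structure": curve.structure,
        "dose_quantity": curve.dose_quantity.value,
        "volume_cm3": float(total),
        "mean_gy": mean,
        "sd_gy": sd,
        "dmin_gy": float(curve.bin_edges[occupied[0]]),
        "dmax_gy": float(curve.bin_edges[occupied[-1] + 1]),
    }
    for x in vx_thresholds_gy:
        # inclusive threshold: a bin counts fully if it lies at/above x or
        # its interval contains x
        inside = (curve.bin_edges[:-1] <= x) & (x <= curve.bin_edges[1:])
        vol = float(v[(curve.bin_edges[:-1] >= x) | inside].sum())
        stats[f"V{x:g}Gy_cm3"] = vol
        stats[f"V{x:g}Gy_pct"] = 100.0 * vol / total
    return stats
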