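"""PET scanner activity calibration from a sphere phantom.

A PET scanner imaging ⁹⁰Y sees only the tiny internal pair-production
branch, so the usual vendor activity calibration does not apply.  The
scanner is instead characterized by a single scalar sensitivity
(observed counts per second per MBq of ⁹⁰Y in the field of view), measured
with a phantom of hot spheres in a cold background.  Small spheres read low
because of resolution (partial-volume) losses, so per-insert values are
reported alongside the pooled estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MaskError, QuantityError
from .grids import ImageGrid, Quantity, StructureMask

__all__ = [
    "DEFAULT_SENSITIVITY_CPS_PER_MBQ",
    "PhantomSpec",
    "InsertSummary",
    "CalibrationResult",
    "fit_sensitivity",
    "counts_to_activity",
]

#: default scanner sensitivity (cps/MBq) shipped with the package config
DEFAULT_SENSITIVITY_CPS_PER_MBQ = 0.32


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and fill of a sphere calibration phantom.

    Defaults describe a rectangular phantom with four hot spheres
    (0.22–65.45 cm³) at 2.996 MBq/ml in an 8.26 L cold background.
    """

    insert_volumes_cm3: tuple[float, ...] = (0.22, 2.0, 16.0, 65.45)
    insert_concentration_mbq_ml: float = 2.996
    background_volume_l: float = 8.26
    background_concentration_mbq_ml: float = 0.0

    def __post_init__(self):
        if any(v <= 0 for v in self.insert_volumes_cm3):
            raise ValueError("insert volumes must be positive")
        if self.insert_concentration_mbq_ml < 0 or self.background_concentration_mbq_ml < 0:
            raise ValueError("concentrations must be >= 0")
        if self.background_volume_l <= 0:
            raise ValueError("background volume must be positive")


@dataclass(frozen=True)
class InsertSummary:
    name: str
    volume_cm3: float
    mean_count_rate_cps: float          # per voxel
    observed_cps_per_mbq: float         # per-insert sensitivity estimate
    true_concentration_mbq_ml: float


@dataclass
class CalibrationResult:
    """Scanner sensitivity estimate with per-insert diagnostics.

    ``sensitivity`` is the volume-weighted mean over the included inserts.
    Because the pooling rule for a sphere set is a modelling choice, the
    unweighted mean and the largest-insert (plateau) value are reported too.
    """

    sensitivity_cps_per_mbq: float
    sensitivity_unweighted: float
    sensitivity_largest_insert: float
    insert_summaries: list[InsertSummary] = field(default_factory=list)
    fit_residuals: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.sensitivity_cps_per_mbq <= 0:
            raise ValueError("sensitivity must be positive")

    def to_dict(self) -> dict:
        return {
            "sensitivity_cps_per_mbq": self.sensitivity_cps_per_mbq,
            "sensitivity_unweighted": self.sensitivity_unweighted,
            "sensitivity_largest_insert": self.sensitivity_largest_insert,
            "fit_residuals": list(self.fit_residuals),
            "inserts": [vars(s) for s in self.insert_summaries],
        }


def fit_sensitivity(count_image: ImageGrid,
                    insert_masks: list[StructureMask],
                    spec: PhantomSpec,
                    min_volume_cm3: float = 0.0) -> CalibrationResult:
    """Estimate scanner sensitivity (cps/MBq) from a phantom acquisition.

    For each insert the mean per-voxel count rate is divided by the true
    per-voxel activity (true concentration × voxel volume, in MBq), giving a
    per-insert cps/MBq.  The pooled sensitivity is the volume-weighted mean
    over inserts with volume >= ``min_volume_cm3`` (default: all), so the
    partial-volume roll-off of small spheres remains visible per insert.

    Parameters
    ----------
    count_image
        Grid with quantity COUNT_RATE (cps per voxel).
    insert_masks
        True geometric insert masks, one per entry in ``spec``.
    spec
        Phantom description; insert order must match ``insert_masks``.
    """
    if count_image.quantity is not Quantity.COUNT_RATE:
        raise QuantityError("fit_sensitivity requires a COUNT_RATE image")
    if spec.insert_concentration_mbq_ml <= 0:
        raise ValueError("true insert concentration must be > 0")
    if len(insert_masks) != len(spec.insert_volumes_cm3):
        raise ValueError("number of masks must match number of phantom inserts")

    vox_ml = count_image.voxel_volume_cm3
    true_per_voxel_mbq = spec.insert_concentration_mbq_ml * vox_ml

    summaries: list[InsertSummary] = []
    for mask, vol in zip(insert_masks, spec.insert_volumes_cm3):
        mask.require_nonempty()
        if not mask.grid.same_geometry(count_image):
            raise MaskError(f"mask '{mask.name}' is not co-registered to the count image")
        mean_cps = float(count_image.values[mask.indices].mean())
        summaries.append(InsertSummary(
            name=mask.name,
            volume_cm3=float(vol),
            mean_count_rate_cps=mean_cps,
            observed_cps_per_mbq=mean_cps / true_per_voxel_mbq,
            true_concentration_mbq_ml=spec.insert_concentration_mbq_ml,
        ))

    included = [s for s in summaries if s.volume_cm3 >= min_volume_cm3]
    if not included:
        raise ValueError("volume threshold excludes every insert")
    vols = np.array([s.volume_cm3 for s in included])
    obs = np.array([s.observed_cps_per_mbq for s in included])
    weighted = float(np.sum(vols * obs) / vols.sum())
    unweighted = float(obs.mean())
    largest = float(obs[np.argmax(vols)])
    residuals = [float(o / weighted - 1.0) for o in obs]
    return CalibrationResult(weighted, unweighted, largest, summaries, residuals)


def counts_to_activity(count_image: ImageGrid,
                       sensitivity_cps_per_mbq: float) -> ImageGrid:
    """Convert a PET count-rate image (cps/voxel) to activity concentration.

    Per voxel::

        conc [Bq/ml] = cps / (sensitivity [cps/MBq] × 1e-6 [MBq/Bq] × voxel ml)

    The operation is linear; the reference time is propagated unchanged.
    """
    if count_image.quantity is not Quantity.COUNT_RATE:
        raise QuantityError(
            f"counts_to_activity requires COUNT_RATE input, got {count_image.quantity}")
    if sensitivity_cps_per_mbq <= 0:
        raise ValueError("sensitivity must be > 0")
    vox_ml = count_image.voxel_volume_cm3
    conc = count_image.values / (sensitivity_cps_per_mbq * 1e-6 * vox_ml)
    return count_image.with_values(conc, Quantity.ACTIVITY_CONC)
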