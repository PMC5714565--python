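"""Classical two-compartment partition-model dosimetry.

Before voxel-level PET dosimetry, the absorbed dose from ⁹⁰Y microspheres
was estimated by partitioning the administered activity between tumour and
normal liver according to an uptake ratio r measured on pretreatment
planar scintigraphy:

    Dt = 49.8 · (A/M) · r / (1 + (Mt/M)(r − 1))      [Gy]
    Dl = 49.8 · (A/M) · 1 / (1 + (Mt/M)(r − 1))      [Gy]

with A the administered activity (GBq), M the total liver mass (kg), Mt the
tumour mass (kg).  The 49.8 Gy·kg/GBq constant is the conventional
whole-organ dose per unit activity for ⁹⁰Y and is used as printed in the
standard formula rather than recomputed from nuclear data.  The model
assumes uniform uptake within each compartment, so mass-weighted energy
closes exactly: Mt·Dt + (M−Mt)·Dl = 49.8·A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .dvh import DVHCurve

__all__ = ["GY_KG_PER_GBQ", "PartitionInputs", "PartitionDoses",
           "partition_doses", "compare_with_voxel_dose"]

GY_KG_PER_GBQ = 49.8


@dataclass(frozen=True)
class PartitionInputs:
    """Inputs to the partition model.

    ``lung_shunt_fraction`` optionally removes the hepatopulmonary shunt
    from the activity before dosing (off by default; shunt estimation itself
    is out of scope — only the scalar is consumed).
    """

    administered_activity_gbq: float
    liver_mass_kg: float                # tumour + normal liver
    tumor_mass_kg: float
    uptake_ratio: float                 # tumour/liver activity concentration ratio
    lung_shunt_fraction: float = 0.0

    def __post_init__(self):
        if self.administered_activity_gbq <= 0:
            raise ValueError("administered activity must be > 0")
        if not 0 < self.tumor_mass_kg < self.liver_mass_kg:
            raise ValueError("tumour mass must satisfy 0 < Mt < M")
        if self.uptake_ratio <= 0:
            raise ValueError("uptake ratio must be > 0")
        if not 0 <= self.lung_shunt_fraction < 1:
            raise ValueError("lung shunt fraction must be in [0, 1)")

    @property
    def effective_activity_gbq(self) -> float:
        return self.administered_activity_gbq * (1.0 - self.lung_shunt_fraction)


class PartitionDoses(NamedTuple):
    tumor_gy: float
    normal_liver_gy: float


def partition_doses(inp: PartitionInputs) -> PartitionDoses:
    """Tumour and normal-liver absorbed dose from the partition model.

    Satisfies Dt/Dl = r and the energy closure
    Mt·Dt + (M−Mt)·Dl = 49.8·A_effective to floating-point precision.
    """
    a = inp.effective_activity_gbq
    m, mt, r = inp.liver_mass_kg, inp.tumor_mass_kg, inp.uptake_ratio
    common = GY_KG_PER_GBQ * a / m / (1.0 + (mt / m) * (r - 1.0))
    return PartitionDoses(tumor_gy=common * r, normal_liver_gy=common)


def compare_with_voxel_dose(inp: PartitionInputs,
                            gtv_dvh: DVHCurve,
                            liver_dvh: DVHCurve) -> dict:
    """Percent difference of partition-model doses vs voxel-dosimetry means.

    Positive values mean the partition model overestimates relative to the
    image-based mean dose of the same compartment.
    """
    doses = partition_doses(inp)

    def _mean(curve: DVHCurve) -> float:
        if curve.mean_gy is not None:
            return curve.mean_gy
        return float((curve.bin_centers * curve.diff_volume_cm3).sum()
                     / curve.total_volume_cm3)

    rows = {}
    for label, part_gy, curve in (("target", doses.tumor_gy, gtv_dvh),
                                  ("normal_liver", doses.normal_liver_gy, liver_dvh)):
        pet_gy = _mean(curve)
        rows[label] = {
            "partition_gy": part_gy,
            "voxel_mean_gy": pet_gy,
            "difference_pct": 100.0 * (part_gy - pet_gy) / pet_gy,
        }
    return rows
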