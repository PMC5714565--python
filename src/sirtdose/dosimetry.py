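"""Convolution dosimetry and time-integration of the decaying dose rate.

The instantaneous dose-rate field is the 3D discrete convolution of the
per-voxel activity (Bq) with the voxel S-value kernel (Gy per Bq·s).
Microspheres are a permanent implant with no biological clearance, so the
dose rate decays mono-exponentially with the physical decay constant and the
total dose is the analytic integral to infinity, R₀/λ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from . import calibration as _calibration
from .errors import GeometryError, QuantityError, TimeError
from .grids import GridGeometry, ImageGrid, Quantity, resample_to_grid, write_rtdose
from .kernel import VoxelKernel, resample_kernel

__all__ = [
    "Y90_HALF_LIFE_DAYS",
    "Y90_LAMBDA_PER_DAY",
    "DecayModel",
    "dose_rate_map",
    "integrate_to_total_dose",
    "total_absorbed_energy_j",
    "run_dose_pipeline",
]

log = logging.getLogger(__name__)

Y90_HALF_LIFE_DAYS = 2.67
#: ln 2 / 2.67 d, rounded as conventionally quoted
Y90_LAMBDA_PER_DAY = 0.2596

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class DecayModel:
    """Mono-exponential physical decay of a permanent implant.

    ``lambda_per_day`` and ``half_life_days`` must agree (λ = ln2/T½ within
    0.1%); there is no biological clearance term.
    """

    lambda_per_day: float = Y90_LAMBDA_PER_DAY
    half_life_days: float = Y90_HALF_LIFE_DAYS

    def __post_init__(self):
        if self.lambda_per_day <= 0 or self.half_life_days <= 0:
            raise ValueError("decay parameters must be positive")
        implied = math.log(2.0) / self.half_life_days
        if abs(implied - self.lambda_per_day) > 1e-3 * self.lambda_per_day:
            raise ValueError(
                f"lambda {self.lambda_per_day}/d inconsistent with half-life "
                f"{self.half_life_days} d (ln2/T½ = {implied:.5f}/d)")

    @classmethod
    def from_half_life(cls, half_life_days: float) -> "DecayModel":
        return cls(math.log(2.0) / half_life_days, half_life_days)

    @property
    def lambda_per_second(self) -> float:
        return self.lambda_per_day / _SECONDS_PER_DAY

    @property
    def lambda_per_hour(self) -> float:
        return self.lambda_per_day / 24.0


def dose_rate_map(activity: ImageGrid, kernel: VoxelKernel) -> ImageGrid:
    """Instantaneous dose-rate field (Gy/s) from an activity map (Bq/ml).

    Per-voxel activity (Bq) is the concentration times the voxel volume in
    ml; the output is its 3D discrete convolution with the S values,
    zero-padded at the boundary (activity outside the field of view is
    zero).  The kernel pitch must match the grid spacing within 0.1% on each
    axis — resample the kernel first otherwise.
    """
    if activity.quantity is not Quantity.ACTIVITY_CONC:
        raise QuantityError(
            f"dose_rate_map requires ACTIVITY_CONC input, got {activity.quantity}")
    if np.any(activity.values < 0):
        raise ValueError("activity map contains negative values")
    for a in range(3):
        if abs(kernel.pitch[a] - activity.spacing[a]) > 1e-3 * activity.spacing[a]:
            raise GeometryError(
                f"kernel pitch {kernel.pitch} does not match grid spacing "
                f"{activity.spacing} within 0.1%; resample the kernel first")

    per_voxel_bq = activity.values * activity.voxel_volume_cm3
    rate = signal.fftconvolve(per_voxel_bq, kernel.svalues, mode="same")
    # FFT round-off can leave tiny negatives in cold regions
    np.clip(rate, 0.0, None, out=rate)
    return activity.with_values(rate, Quantity.DOSE_RATE)


def integrate_to_total_dose(dose_rate: ImageGrid, decay: DecayModel,
                            t_admin_h: float = 0.0,
                            decay_correct: bool = True) -> ImageGrid:
    """Total physical dose (Gy) from the dose rate at imaging time.

    The implant decays as R(t) = R₀ e^(−λ(t−t_admin)); integrating to
    infinity gives D = R₀/λ.  With ``decay_correct`` (default) the imaged
    rate is first corrected back to administration,
    R₀ = R(t_ref)·e^(+λ(t_ref−t_admin)), so D is the full delivered dose;
    switched off, D = R(t_ref)/λ is the dose delivered from imaging time
    onward.
    """
    if dose_rate.quantity is not Quantity.DOSE_RATE:
        raise QuantityError(
            f"integrate_to_total_dose requires DOSE_RATE input, got {dose_rate.quantity}")
    t_ref = dose_rate.reference_time_h
    if t_ref is None:
        t_ref = t_admin_h
    if t_ref < t_admin_h:
        raise TimeError(f"reference time {t_ref} h precedes administration {t_admin_h} h")

    factor = 1.0
    if decay_correct:
        factor = math.exp(decay.lambda_per_hour * (t_ref - t_admin_h))
    dose = dose_rate.values * factor / decay.lambda_per_second
    out = dose_rate.with_values(dose, Quantity.DOSE)
    out.reference_time_h = t_admin_h if decay_correct else t_ref
    return out


def total_absorbed_energy_j(dose: ImageGrid, density_g_cm3: float = 1.0) -> float:
    """Σ dose × voxel mass over the grid, in joules."""
    mass_kg = dose.voxel_volume_cm3 * density_g_cm3 / 1000.0
    return float(dose.values.sum() * mass_kg)


def run_dose_pipeline(pet: ImageGrid,
                      sensitivity_cps_per_mbq: float,
                      kernel: VoxelKernel,
                      decay: DecayModel = DecayModel(),
                      t_admin_h: float = 0.0,
                      target_geometry: GridGeometry | None = None,
                      rtdose_path: str | Path | None = None,
                      decay_correct: bool = True) -> ImageGrid:
    """Chain the full PET-to-dose pipeline and optionally export RT Dose.

    Stages: counts → activity concentration (scanner sensitivity), kernel
    resampling to the PET pitch, convolution to a dose-rate map, linear
    resampling onto the target (CT) geometry if given, integration of the
    decaying dose rate to total dose, and DICOM RT Dose export.  Per-stage
    totals are logged.
    """
    activity = _calibration.counts_to_activity(pet, sensitivity_cps_per_mbq)
    total_mbq = activity.values.sum() * activity.voxel_volume_cm3 * 1e-6
    log.info("total imaged activity: %.3f MBq at t=%s h", total_mbq,
             activity.reference_time_h)

    k = resample_kernel(kernel, activity.spacing)
    log.info("kernel resampled to pitch %s mm; truncation %.2f%%",
             k.pitch, 100 * k.truncation_fraction())

    rate = dose_rate_map(activity, k)
    if target_geometry is not None:
        rate = resample_to_grid(rate, target_geometry, mode="linear")

    dose = integrate_to_total_dose(rate, decay, t_admin_h, decay_correct)
    log.info("total absorbed energy: %.4e J; max dose %.2f Gy",
             total_absorbed_energy_j(dose), dose.values.max())

    if rtdose_path is not None:
        write_rtdose(dose, rtdose_path)
    return dose
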