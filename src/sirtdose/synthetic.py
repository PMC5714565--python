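"""Synthetic phantoms and virtual patients with known ground truth.

Every pipeline stage is testable without external data: this module
rasterizes the sphere calibration phantom (hot spheres in a cold
background) and a virtual radioembolization patient (ellipsoidal liver
containing hot spherical tumours, optionally with cold sub-spheres that
emulate geographic misses).  The forward model — activity → counts via the
scanner sensitivity, activity → dose via the same kernel machinery the
pipeline uses — is exact, so reconstruction errors are attributable to the
stage under test, not to the fixture.

What these fixtures do *not* emulate: PET reconstruction physics (sinogram
noise structure, scatter, randoms), respiratory motion, and microsphere
clustering.  Resolution loss is approximated by an isotropic Gaussian PSF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import PhantomSpec
from .dosimetry import DecayModel, dose_rate_map, integrate_to_total_dose
from .errors import GeometryError
from .grids import GridGeometry, ImageGrid, Quantity, StructureMask
from .kernel import VoxelKernel, generate_test_kernel, resample_kernel

__all__ = [
    "VirtualPatient",
    "activity_to_counts",
    "make_calibration_phantom",
    "make_virtual_patient",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _sphere_mask(geom: GridGeometry, center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    axes = [geom.axis_coords(a) - center_mm[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return xx ** 2 + yy ** 2 + zz ** 2 <= radius_mm ** 2


def _sphere_radius_mm(volume_cm3: float) -> float:
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def activity_to_counts(activity: ImageGrid, sensitivity_cps_per_mbq: float) -> ImageGrid:
    """Forward model: activity concentration (Bq/ml) → PET count rate (cps).

    Exact inverse of the calibration conversion:
    cps = conc × voxel ml × 1e-6 × sensitivity.
    """
    mbq_per_voxel = activity.values * activity.voxel_volume_cm3 * 1e-6
    return activity.with_values(mbq_per_voxel * sensitivity_cps_per_mbq,
                                Quantity.COUNT_RATE)


def make_calibration_phantom(spec: PhantomSpec = PhantomSpec(),
                             spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
                             sensitivity_cps_per_mbq: float = 0.32,
                             noise: str = "none",
                             blur_fwhm_mm: float = 0.0,
                             acquisition_time_s: float = 1800.0,
                             seed: int | None = None,
                             ) -> tuple[ImageGrid, list[StructureMask]]:
    """Rasterize a sphere phantom and simulate its PET count-rate image.

    The phantom box is sized to hold the background volume plus the inserts;
    spheres are laid out along the box diagonal mid-plane with guaranteed
    separation.  The count image is ``sensitivity × activity per voxel``,
    optionally blurred with a Gaussian PSF surrogate and degraded with
    Poisson counting noise over ``acquisition_time_s``.

    Returns the count-rate grid and the true geometric insert masks (the
    reproducible ground truth; no threshold contouring).

    Raises
    ------
    GeometryError
        If the requested inserts cannot be placed without overlap.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    total_cm3 = spec.background_volume_l * 1000.0 + sum(spec.insert_volumes_cm3)
    side_mm = (total_cm3 * 1000.0) ** (1.0 / 3.0)
    shape = tuple(int(np.ceil(side_mm / s)) for s in spacing_mm)
    geom = GridGeometry(shape, spacing_mm)

    radii = [_sphere_radius_mm(v) for v in spec.insert_volumes_cm3]
    margin = 1.5 * max(spacing_mm)
    needed = sum(2 * r + margin for r in radii) + margin
    span = geom.extent()[0][1] - geom.extent()[0][0]
    if needed > span:
        raise GeometryError(
            f"inserts need {needed:.0f} mm along x but the phantom box spans "
            f"{span:.0f} mm; inserts would overlap")

    yc = 0.5 * (geom.extent()[1][0] + geom.extent()[1][1])
    zc = 0.5 * (geom.extent()[2][0] + geom.extent()[2][1])
    conc = np.full(shape, spec.background_concentration_mbq_ml)
    masks: list[StructureMask] = []
    x = geom.extent()[0][0] + margin
    for idx, (r, vol) in enumerate(zip(radii, spec.insert_volumes_cm3)):
        center = np.array([x + r, yc, zc])
        inside = _sphere_mask(geom, center, r)
        conc[inside] = spec.insert_concentration_mbq_ml
        mask_grid = ImageGrid(inside.astype(float), spacing_mm, quantity=Quantity.MASK)
        masks.append(StructureMask(f"insert_{idx:02d}_{vol:g}cm3", mask_grid))
        x += 2 * r + margin

    cps = conc * geom.voxel_volume_cm3 * sensitivity_cps_per_mbq
    if blur_fwhm_mm > 0:
        sigma = [blur_fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing_mm]
        cps = ndimage.gaussian_filter(cps, sigma)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(cps * acquisition_time_s)
        cps = counts / acquisition_time_s
    count_image = ImageGrid(cps, spacing_mm, quantity=Quantity.COUNT_RATE)
    return count_image, masks


@dataclass
class VirtualPatient:
    """Ground-truth bundle for a simulated radioembolization patient."""

    activity_truth: ImageGrid            # Bq/ml at t_image
    dose_truth: ImageGrid                # Gy, forward-computed with the same kernel
    masks: list[StructureMask]           # "liver", "GTV_00", ... (GTVs include cold spots)
    admin_activity_gbq: float
    t_admin_h: float
    t_image_h: float
    kernel: VoxelKernel
    decay: DecayModel
    seed: int | None = None

    @property
    def liver_mask(self) -> StructureMask:
        return next(m for m in self.masks if m.name == "liver")

    @property
    def gtv_masks(self) -> list[StructureMask]:
        return [m for m in self.masks if m.name.startswith("GTV")]


def make_virtual_patient(n_tumors: int = 1,
                         tumor_volumes_cm3: tuple[float, ...] = (100.0,),
                         liver_volume_cm3: float = 1500.0,
                         tumor_to_liver_ratio: float = 4.0,
                         admin_activity_gbq: float = 1.2,
                         kernel: VoxelKernel | None = None,
                         seed: int | None = 0,
                         shape: tuple[int, int, int] = (128, 128, 128),
                         spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
                         t_image_h: float = 5.0,
                         cold_volumes_cm3: tuple[float, ...] = (),
                         extrahepatic_fraction: float = 0.0,
                         decay: DecayModel = DecayModel(),
                         ) -> VirtualPatient:
    """Build a virtual SIRT patient with exact activity bookkeeping.

    An ellipsoidal liver of the requested volume holds spherical tumours;
    activity at imaging time is ``admin × e^(−λ·t_image) × (1 −
    extrahepatic_fraction)``, distributed so the tumour:normal-liver
    concentration ratio equals ``tumor_to_liver_ratio``.  Optional cold
    sub-spheres inside the first tumours receive zero activity while
    remaining part of the GTV — the geographic-miss configuration that
    drives the Poisson TCP to zero.  ``dose_truth`` is forward-computed from
    the activity with the (synthetic, unless supplied) voxel S-value kernel
    and decay-corrected to administration.  All randomness is seeded.
    """
    if len(tumor_volumes_cm3) != n_tumors:
        raise ValueError("tumor_volumes_cm3 must have n_tumors entries")
    if not 0 <= extrahepatic_fraction < 1:
        raise ValueError("extrahepatic_fraction must be in [0, 1)")
    if sum(tumor_volumes_cm3) >= liver_volume_cm3:
        raise GeometryError("tumours do not fit inside the liver volume")

    rng = np.random.default_rng(seed)
    geom = GridGeometry(shape, spacing_mm)
    center = np.array([0.5 * (lo + hi) for lo, hi in geom.extent()])

    # ellipsoidal liver, semi-axes a : 0.8a : 0.65a
    a = (3.0 * liver_volume_cm3 * 1000.0 / (4.0 * np.pi * 0.8 * 0.65)) ** (1 / 3)
    semi = np.array([a, 0.8 * a, 0.65 * a])
    for ax in range(3):
        lo, hi = geom.extent()[ax]
        if center[ax] - semi[ax] < lo or center[ax] + semi[ax] > hi:
            raise GeometryError("liver ellipsoid does not fit in the grid")
    axes = [geom.axis_coords(ax) - center[ax] for ax in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    liver = (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0

    masks = [StructureMask("liver", ImageGrid(liver.astype(float), spacing_mm,
                                              quantity=Quantity.MASK))]
    tumor_union = np.zeros(shape, dtype=bool)
    tumor_masks_np: list[np.ndarray] = []
    for i, vol in enumerate(tumor_volumes_cm3):
        r = _sphere_radius_mm(vol)
        placed = False
        for _ in range(200):
            u = rng.uniform(-0.6, 0.6, size=3)
            c = center + u * semi
            if np.sum(((c - center) / np.maximum(semi - r, 1e-6)) ** 2) > 1.0:
                continue
            sph = _sphere_mask(geom, c, r)
            if not np.any(sph & tumor_union):
                placed = True
                break
        if not placed:
            raise GeometryError(f"could not place tumour {i} without overlap")
        tumor_union |= sph
        tumor_masks_np.append(sph)
        masks.append(StructureMask(f"GTV_{i:02d}", ImageGrid(sph.astype(float),
                                                             spacing_mm,
                                                             quantity=Quantity.MASK)))

    cold = np.zeros(shape, dtype=bool)
    for i, vol in enumerate(cold_volumes_cm3):
        host = tumor_masks_np[i % len(tumor_masks_np)]
        r = _sphere_radius_mm(vol)
        host_idx = np.argwhere(host)
        c_idx = host_idx[len(host_idx) // 2]
        c_mm = np.array([geom.axis_coords(ax)[c_idx[ax]] for ax in range(3)])
        cold |= _sphere_mask(geom, c_mm, r) & host

    vox_ml = geom.voxel_volume_cm3
    hot_tumor = tumor_union & ~cold
    normal = liver & ~tumor_union
    v_hot = hot_tumor.sum() * vox_ml
    v_norm = normal.sum() * vox_ml

    lam = decay.lambda_per_day
    total_bq = (admin_activity_gbq * 1e9 * np.exp(-lam * t_image_h / 24.0)
                * (1.0 - extrahepatic_fraction))
    r = tumor_to_liver_ratio
    c_norm = total_bq / (v_norm + r * v_hot)       # Bq/ml in normal liver
    conc = np.zeros(shape)
    conc[normal] = c_norm
    conc[hot_tumor] = r * c_norm
    activity = ImageGrid(conc, spacing_mm, quantity=Quantity.ACTIVITY_CONC,
                         reference_time_h=t_image_h)

    if kernel is None:
        kernel = generate_test_kernel(pitch=spacing_mm, extent=6)
    k = resample_kernel(kernel, spacing_mm)
    rate = dose_rate_map(activity, k)
    dose = integrate_to_total_dose(rate, decay, t_admin_h=0.0, decay_correct=True)

    return VirtualPatient(activity, dose, masks, admin_activity_gbq,
                          t_admin_h=0.0, t_image_h=t_image_h, kernel=k,
                          decay=decay, seed=seed)
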