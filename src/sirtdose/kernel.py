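"""Voxel S-value kernels: loading, validation, synthesis and resampling.

A voxel S value is the absorbed dose (Gy) to a target voxel per unit
cumulated activity (Bq·s) in a source voxel, tabulated for a nuclide in a
homogeneous unit-density medium.  Kernels are stored centre-aligned with odd
dimensions on every axis, so offset (0,0,0) is the self-dose voxel and
convolution alignment is unambiguous.

The package does not bundle any published Monte Carlo S-value table; those
are inputs the user supplies as TSV.  For self-contained tests,
:func:`generate_test_kernel` synthesizes a physically plausible kernel from
an isotropic exponential point-dose profile — it is labelled synthetic and
is not a Monte Carlo transport result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError, KernelError

__all__ = [
    "Y90_MEAN_ENERGY_MEV",
    "MEV_TO_J",
    "VoxelKernel",
    "load_kernel",
    "save_kernel",
    "generate_test_kernel",
    "resample_kernel",
]

#: mean emitted energy per ⁹⁰Y decay (beta spectrum mean), MeV
Y90_MEAN_ENERGY_MEV = 0.9337
MEV_TO_J = 1.602e-13

#: apparent attenuation of the synthetic ⁹⁰Y-like point profile (mm⁻¹);
#: gives a mean deposition range of ~3.3 mm, comparable to the ⁹⁰Y beta mean
#: path in soft tissue.
DEFAULT_ATTENUATION_PER_MM = 0.3


@dataclass
class VoxelKernel:
    """3D table of voxel S values at a stated pitch.

    Attributes
    ----------
    svalues
        Odd-shaped 3D array; value at offset ``(i, j, k)`` (indices relative
        to the array centre) is Gy per Bq·s.
    pitch
        Voxel pitch (dx, dy, dz) in mm.
    nuclide
        Label, e.g. "Y-90".
    medium_density
        g/cm³ of the homogeneous medium (1.0 for water/soft tissue).
    mean_energy_mev
        Mean emitted energy per decay, used for the energy-closure check.
    synthetic
        True for kernels produced by :func:`generate_test_kernel`.
    """

    svalues: np.ndarray
    pitch: tuple[float, float, float]
    nuclide: str = "Y-90"
    medium_density: float = 1.0
    mean_energy_mev: float = Y90_MEAN_ENERGY_MEV
    synthetic: bool = False

    def __post_init__(self):
        self.svalues = np.asarray(self.svalues, dtype=np.float64)
        self.pitch = tuple(float(p) for p in self.pitch)
        if self.svalues.ndim != 3:
            raise KernelError("kernel must be 3D")
        if any(n % 2 == 0 for n in self.svalues.shape):
            raise KernelError(f"kernel dimensions must be odd, got {self.svalues.shape}")
        if any(p <= 0 for p in self.pitch):
            raise KernelError(f"pitch must be positive, got {self.pitch}")

    @property
    def center(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.svalues.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.pitch
        return dx * dy * dz / 1000.0

    @property
    def voxel_mass_kg(self) -> float:
        return self.voxel_volume_cm3 * self.medium_density / 1000.0

    @property
    def energy_per_decay_j(self) -> float:
        return self.mean_energy_mev * MEV_TO_J

    def s(self, i: int, j: int, k: int) -> float:
        """S value at integer offset (i, j, k) from the source voxel."""
        c = self.center
        return float(self.svalues[c[0] + i, c[1] + j, c[2] + k])

    def total_energy_per_decay(self) -> float:
        """Σ S × voxel mass over the table: energy (J) captured per decay."""
        return float(self.svalues.sum() * self.voxel_mass_kg)

    def truncation_fraction(self) -> float:
        """Fraction of the emitted energy lost to the table's finite extent."""
        return 1.0 - self.total_energy_per_decay() / self.energy_per_decay_j

    def validate(self, truncation_tol: float = 0.05, sym_rtol: float = 1e-9) -> None:
        """Check kernel invariants, raising :class:`KernelError` on failure.

        Invariants: non-negative values; the centre is the array maximum;
        reflection symmetry on each axis; and energy closure — Σ S·mass must
        equal the mean emitted energy per decay within ``truncation_tol``
        (the table's finite extent always loses some energy).
        """
        s = self.svalues
        if np.any(s < 0):
            raise KernelError("kernel contains negative S values")
        if s[self.center] < s.max():
            raise KernelError("central S value is not the kernel maximum")
        for axis in range(3):
            if not np.allclose(s, np.flip(s, axis=axis), rtol=sym_rtol, atol=0):
                raise KernelError(f"kernel not reflection-symmetric on axis {axis}")
        trunc = self.truncation_fraction()
        if not -truncation_tol <= trunc <= truncation_tol:
            raise KernelError(
                f"kernel energy check failed: Σ S·mass = "
                f"{self.total_energy_per_decay():.4e} J vs expected "
                f"{self.energy_per_decay_j:.4e} J (truncation {trunc:+.2%}, "
                f"tolerance ±{truncation_tol:.0%})")


def _symmetrize(s: np.ndarray, warn_rtol: float = 0.01) -> np.ndarray:
    """Average mirror pairs on each axis; warn above 1% asymmetry."""
    out = s
    for axis in range(3):
        flipped = np.flip(out, axis=axis)
        denom = np.maximum(np.abs(out), np.abs(flipped))
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(denom > 0, np.abs(out - flipped) / denom, 0.0)
        if rel.max() > warn_rtol:
            warnings.warn(f"kernel table asymmetric on axis {axis} "
                          f"(max {rel.max():.1%}); symmetrizing by averaging")
        out = 0.5 * (out + flipped)
    return out


# ---------------------------------------------------------------------------
# TSV format
# ---------------------------------------------------------------------------

def save_kernel(k: VoxelKernel, path: str | Path) -> Path:
    """Write a kernel as the package's TSV table format.

    Header lines (``# key: value``) give nuclide, pitch and density; rows are
    ``i j k S`` with S in Gy per Bq·s and (i,j,k) offsets from the centre.
    """
    path = Path(path)
    c = k.center
    with open(path, "w") as fh:
        fh.write(f"# nuclide: {k.nuclide}\n")
        fh.write(f"# pitch_mm: {k.pitch[0]:.6g} {k.pitch[1]:.6g} {k.pitch[2]:.6g}\n")
        fh.write(f"# medium_density_g_cm3: {k.medium_density:.6g}\n")
        fh.write(f"# mean_energy_mev: {k.mean_energy_mev:.6g}\n")
        if k.synthetic:
            fh.write("# synthetic: true\n")
        fh.write("# columns: i j k S_Gy_per_Bq_s\n")
        for idx in np.ndindex(k.svalues.shape):
            val = k.svalues[idx]
            if val > 0 or idx == c:
                i, j, kk = (idx[a] - c[a] for a in range(3))
                fh.write(f"{i} {j} {kk} {val:.10e}\n")
    return path


def load_kernel(path: str | Path) -> VoxelKernel:
    """Load a voxel S-value kernel from a sparse (i, j, k, S) TSV table.

    Octant-only tables (all offsets >= 0) are expanded by reflection
    symmetry; missing far offsets are filled with zero; the table must
    include the (0,0,0) self-dose entry.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}: malformed kernel row {line!r}")
            i, j, k = (int(p) for p in parts[:3])
            s = float(parts[3])
            if s < 0:
                raise KernelError(f"{path}: negative S value at offset ({i},{j},{k})")
            rows.append((i, j, k, s))
    if not rows:
        raise FormatError(f"{path}: empty kernel table")
    if not any((i, j, k) == (0, 0, 0) for i, j, k, _ in rows):
        raise FormatError(f"{path}: kernel table missing the (0,0,0) self-dose entry")

    pitch = tuple(float(p) for p in meta.get("pitch_mm", "6 6 6").split())
    if len(pitch) != 3:
        raise FormatError(f"{path}: pitch_mm header must have three components")

    octant_only = all(i >= 0 and j >= 0 and k >= 0 for i, j, k, _ in rows)
    half = [max(abs(r[a]) for r in rows) for a in range(3)]
    shape = tuple(2 * h + 1 for h in half)
    s = np.zeros(shape)
    c = tuple(half)
    for i, j, k, v in rows:
        s[c[0] + i, c[1] + j, c[2] + k] = v
    if octant_only:
        for i, j, k, v in rows:
            for si in ((1,) if i == 0 else (1, -1)):
                for sj in ((1,) if j == 0 else (1, -1)):
                    for sk in ((1,) if k == 0 else (1, -1)):
                        s[c[0] + si * i, c[1] + sj * j, c[2] + sk * k] = v
    else:
        s = _symmetrize(s)

    return VoxelKernel(
        s, pitch,
        nuclide=meta.get("nuclide", "Y-90"),
        medium_density=float(meta.get("medium_density_g_cm3", 1.0)),
        mean_energy_mev=float(meta.get("mean_energy_mev", Y90_MEAN_ENERGY_MEV)),
        synthetic=meta.get("synthetic", "").lower() == "true",
    )


# ---------------------------------------------------------------------------
# Synthetic test kernel
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic spiral), shape (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def generate_test_kernel(pitch: tuple[float, float, float] = (6.0, 6.0, 6.0),
                         mean_energy_mev: float = Y90_MEAN_ENERGY_MEV,
                         attenuation_per_mm: float = DEFAULT_ATTENUATION_PER_MM,
                         extent: int = 3,
                         medium_density: float = 1.0,
                         n_radial: int = 192,
                         n_dirs: int = 1024) -> VoxelKernel:
    """Synthesize an analytic voxel S-value kernel for tests.

    The point-dose model deposits each decay's energy isotropically at a
    radial distance drawn from an exponential density
    ``μ e^(−μr)`` (μ = ``attenuation_per_mm``).  The voxel-pair S value is
    the double integral of that profile over the source and target voxel
    volumes, evaluated deterministically: the source-average reduces to a
    separable triangular overlap weight, integrated in spherical coordinates
    over ``n_radial`` radii × ``n_dirs`` directions (no singularity, since
    the r² of the volume element cancels the 1/r² of the profile).

    The result is rescaled so that Σ S·mass equals the emitted energy per
    decay *exactly* at the generated extent, and is flagged ``synthetic``.

    Parameters
    ----------
    extent
        Half-width in voxels per axis; the kernel is (2·extent+1)³.
        A warning is issued if the extent captures < 99% of the profile's
        energy before rescaling.
    """
    if mean_energy_mev <= 0 or attenuation_per_mm <= 0:
        raise ValueError("nuclide constants must be positive")
    if extent < 1:
        raise ValueError("extent must be >= 1")
    pitch = tuple(float(p) for p in pitch)
    mu = float(attenuation_per_mm)

    contained = 1.0 - np.exp(-mu * (extent * min(pitch)))
    if contained < 0.99:
        warnings.warn(f"kernel extent {extent} captures only {contained:.1%} "
                      "of the point-profile energy before rescaling")

    dirs = _fibonacci_sphere(n_dirs)            # (n_dirs, 3)
    half_diag = float(np.linalg.norm(pitch))
    shape = (2 * extent + 1,) * 3
    frac = np.zeros(shape)
    c = extent

    # one octant by symmetry, mirrored below
    for oi in range(extent + 1):
        for oj in range(extent + 1):
            for ok in range(extent + 1):
                off_mm = np.array([oi * pitch[0], oj * pitch[1], ok * pitch[2]])
                d = float(np.linalg.norm(off_mm))
                r_lo = max(0.0, d - half_diag)
                r_hi = d + half_diag
                r = np.linspace(r_lo, r_hi, n_radial)
                pts = r[:, None, None] * dirs[None, :, :]       # (nr, nd, 3)
                t = (pts - off_mm) / np.asarray(pitch)
                w = np.prod(np.clip(1.0 - np.abs(t), 0.0, None), axis=2)
                W = w.mean(axis=1)                              # angular mean
                integrand = mu * np.exp(-mu * r) * W
                frac[c + oi, c + oj, c + ok] = np.trapezoid(integrand, r)

    # mirror the computed octant onto the full grid
    for axis in range(3):
        idx_lo = [slice(None)] * 3
        idx_hi = [slice(None)] * 3
        idx_lo[axis] = slice(0, c)
        idx_hi[axis] = slice(None, c, -1)
        frac[tuple(idx_lo)] = frac[tuple(idx_hi)]

    energy_j = mean_energy_mev * MEV_TO_J
    voxel_mass_kg = pitch[0] * pitch[1] * pitch[2] / 1000.0 * medium_density / 1000.0
    s = energy_j * frac / voxel_mass_kg
    s *= energy_j / (s.sum() * voxel_mass_kg)   # exact energy closure at this extent
    return VoxelKernel(s, pitch, nuclide="synthetic-Y90-like",
                       medium_density=medium_density,
                       mean_energy_mev=mean_energy_mev, synthetic=True)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_kernel(k: VoxelKernel,
                    target_pitch: tuple[float, float, float]) -> VoxelKernel:
    """Resample a kernel to a new voxel pitch, conserving deposited energy.

    The S values are converted to a dose-deposition density (S per target
    voxel volume), interpolated with a tricubic spline at the new offset
    positions, clipped to be non-negative, and renormalized so Σ S·mass is
    preserved exactly.  The output extent covers the same physical radius as
    the input and keeps odd dimensions.
    """
    target_pitch = tuple(float(p) for p in target_pitch)
    if any(p <= 0 for p in target_pitch):
        raise KernelError(f"target pitch must be positive, got {target_pitch}")
    phys_radius = [k.pitch[a] * (k.svalues.shape[a] // 2) for a in range(3)]
    if any(target_pitch[a] > 2 * phys_radius[a] + k.pitch[a] for a in range(3)):
        raise GeometryError("target pitch exceeds the kernel's physical extent")

    if np.allclose(target_pitch, k.pitch, rtol=1e-12):
        return VoxelKernel(k.svalues.copy(), k.pitch, k.nuclide, k.medium_density,
                           k.mean_energy_mev, k.synthetic)

    src_vol = k.pitch[0] * k.pitch[1] * k.pitch[2]
    density = k.svalues / src_vol            # density per mm³ of target voxel

    half = [int(np.ceil(phys_radius[a] / target_pitch[a])) for a in range(3)]
    c_src = k.center
    axes = [(np.arange(-half[a], half[a] + 1) * target_pitch[a]) / k.pitch[a] + c_src[a]
            for a in range(3)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))
    new_density = ndimage.map_coordinates(density, coords, order=3,
                                          mode="constant", cval=0.0)
    tgt_vol = target_pitch[0] * target_pitch[1] * target_pitch[2]
    s_new = np.clip(new_density, 0.0, None) * tgt_vol
    s_new = _symmetrize(s_new, warn_rtol=np.inf)  # remove interpolation noise

    # renormalize: conserve Σ S·mass (mass ∝ voxel volume)
    energy_src = k.svalues.sum() * src_vol
    energy_new = s_new.sum() * tgt_vol
    if energy_new <= 0:
        raise KernelError("resampled kernel lost all energy")
    s_new *= energy_src / energy_new
    return VoxelKernel(s_new, target_pitch, k.nuclide, k.medium_density,
                       k.mean_energy_mev, k.synthetic)
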