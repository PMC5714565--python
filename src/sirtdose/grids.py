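"""3D image grids and the imaging formats the dosimetry pipeline touches.

The in-memory data model is deliberately minimal: a scalar field on a
regular axis-aligned grid, with voxel spacing and origin in millimetres and
a declared physical quantity.  Voxel index ``(i, j, k)`` maps to physical
position ``origin + index * spacing``; the array axis order is fixed as
(x, y, z) regardless of on-disk layout, so convolution kernels never need
axis flips.

Readers/writers cover NIfTI (nibabel), NRRD (SimpleITK), DICOM image
series and DICOM RT Dose (pydicom).  RT Structure Set contour parsing and
image registration are out of scope; masks arrive as co-registered binary
volumes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError, MaskError, QuantityError

__all__ = [
    "Quantity",
    "GridGeometry",
    "ImageGrid",
    "StructureMask",
    "read_image",
    "write_nifti",
    "write_rtdose",
    "resample_to_grid",
]


class Quantity(str, enum.Enum):
    """Physical quantity carried by an :class:`ImageGrid`."""

    COUNT_RATE = "COUNT_RATE"        # counts per second per voxel (cps)
    ACTIVITY_CONC = "ACTIVITY_CONC"  # Bq/ml
    DOSE_RATE = "DOSE_RATE"          # Gy/s
    DOSE = "DOSE"                    # Gy
    MASK = "MASK"                    # dimensionless {0, 1}


#: quantities that interpolate as point-sampled (intensive) fields
_INTENSIVE = {Quantity.ACTIVITY_CONC, Quantity.DOSE_RATE, Quantity.DOSE,
              Quantity.COUNT_RATE}


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a regular grid (mm, axis order x,y,z)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise GeometryError(f"grid shape must be 3D with dims >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis (mm)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self) -> list[tuple[float, float]]:
        """Physical [min, max] of voxel-centre coordinates per axis (mm)."""
        return [(self.origin[a], self.origin[a] + self.spacing[a] * (self.shape[a] - 1))
                for a in range(3)]


@dataclass
class ImageGrid:
    """A 3D scalar field with spacing/origin in mm and a declared quantity.

    Parameters
    ----------
    values
        3D float array, axis order (x, y, z).
    spacing
        Voxel pitch ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        Physical position of voxel (0,0,0) in mm.
    quantity
        One of :class:`Quantity`.
    reference_time_h
        Acquisition time as hours after radionuclide administration, or
        ``None`` when time is irrelevant (masks, kernels).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quantity: Quantity = Quantity.COUNT_RATE
    reference_time_h: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        self.quantity = Quantity(self.quantity)
        if self.quantity is Quantity.MASK:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValueError("MASK grids may contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Voxel volume in cm³ (= ml), the product of the spacings / 1000."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.shape, self.spacing, self.origin)

    def same_geometry(self, other: "ImageGrid | GridGeometry", rtol: float = 1e-6) -> bool:
        g = other.geometry if isinstance(other, ImageGrid) else other
        return (self.shape == tuple(g.shape)
                and np.allclose(self.spacing, g.spacing, rtol=rtol)
                and np.allclose(self.origin, g.origin, rtol=rtol, atol=1e-6))

    def with_values(self, values: np.ndarray, quantity: Quantity | None = None) -> "ImageGrid":
        """Copy of this grid with new values (and optionally quantity)."""
        return ImageGrid(values, self.spacing, self.origin,
                         quantity or self.quantity, self.reference_time_h)


@dataclass
class StructureMask:
    """Named binary mask co-registered to the grid it annotates."""

    name: str
    grid: ImageGrid

    def __post_init__(self):
        if self.grid.quantity is not Quantity.MASK:
            raise QuantityError(f"mask '{self.name}' grid must carry quantity MASK")

    @property
    def indices(self) -> np.ndarray:
        return self.grid.values > 0.5

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.grid.values))

    @property
    def volume_cm3(self) -> float:
        """Structure volume: number of 1-voxels times the voxel volume."""
        return self.voxel_count * self.grid.voxel_volume_cm3

    def require_nonempty(self) -> None:
        if self.voxel_count == 0:
            raise MaskError(f"mask '{self.name}' is empty")


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_descrip(grid: ImageGrid) -> bytes:
    tref = "" if grid.reference_time_h is None else f";tref_h={grid.reference_time_h:.6g}"
    return f"qty={grid.quantity.value}{tref}".encode()[:79]


def _parse_descrip(raw: bytes) -> tuple[Quantity | None, float | None]:
    qty, tref = None, None
    raw = raw.split(b"\x00", 1)[0]
    try:
        for part in raw.decode(errors="ignore").split(";"):
            if part.startswith("qty="):
                qty = Quantity(part[4:])
            elif part.startswith("tref_h="):
                tref = float(part[7:])
    except (ValueError, KeyError):
        pass
    return qty, tref


def write_nifti(grid: ImageGrid, path: str | Path) -> Path:
    """Write an :class:`ImageGrid` as NIfTI-1, embedding quantity metadata.

    The affine is diagonal with the grid spacing and origin; the quantity and
    reference time are stored in the header ``descrip`` field so that a
    round-trip through :func:`read_image` restores them.
    """
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.values, affine)
    img.header["descrip"] = _nifti_descrip(grid)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path, quantity: Quantity | None) -> ImageGrid:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj, dtype=np.float64)
    if values.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI volume, got ndim={values.ndim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    qty, tref = _parse_descrip(bytes(img.header["descrip"].tobytes()))
    if quantity is not None:
        qty = quantity
    elif qty is None:
        warnings.warn(f"{path}: no quantity metadata; assuming COUNT_RATE")
        qty = Quantity.COUNT_RATE
    return ImageGrid(values, zooms, origin, qty, tref)


# ---------------------------------------------------------------------------
# NRRD (via SimpleITK)
# ---------------------------------------------------------------------------

def _read_nrrd(path: Path, quantity: Quantity | None) -> ImageGrid:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise FormatError(f"{path}: unreadable NRRD ({exc})") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NRRD volume")
    values = np.transpose(arr, (2, 1, 0)).astype(np.float64)
    if quantity is None:
        warnings.warn(f"{path}: NRRD carries no quantity metadata; assuming COUNT_RATE")
        quantity = Quantity.COUNT_RATE
    return ImageGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()), quantity)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_DICOM_UNIT_MAP = {
    "BQML": Quantity.ACTIVITY_CONC,
    "CPS": Quantity.COUNT_RATE,
    "CNTS": Quantity.COUNT_RATE,
    "GY": Quantity.DOSE,
}


def _read_dicom_series(path: Path, quantity: Quantity | None) -> ImageGrid:
    """Read a single-frame DICOM image series from a directory.

    Slices are sorted along the slice normal; RescaleSlope/Intercept are
    applied.  Mixed orientations or non-uniform slice spacing raise
    :class:`GeometryError`.
    """
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"{path}: no readable DICOM image slices found")

    orientations = {tuple(round(float(v), 6) for v in getattr(s, "ImageOrientationPatient",
                                                              [1, 0, 0, 0, 1, 0]))
                    for s in slices}
    if len(orientations) > 1:
        raise GeometryError(f"{path}: mixed slice orientations in series")

    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(slices) > 1:
        dzs = np.diff(zs)
        dz = float(np.mean(dzs))
        if dz <= 0 or np.any(np.abs(dzs - dz) > 1e-3 * abs(dz) + 1e-6):
            raise GeometryError(f"{path}: inconsistent slice spacing {dzs}")
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    planes = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(s.pixel_array.astype(np.float64) * slope + intercept)
    stack = np.stack(planes, axis=0)          # (z, rows=y, cols=x)
    values = np.transpose(stack, (2, 1, 0))   # -> (x, y, z)

    first = slices[0]
    py, px = (float(v) for v in first.PixelSpacing)  # row spacing, col spacing
    origin = tuple(float(v) for v in first.ImagePositionPatient)

    if quantity is None:
        units = str(getattr(first, "Units", "")).upper()
        quantity = _DICOM_UNIT_MAP.get(units)
        if quantity is None:
            warnings.warn(f"{path}: DICOM Units '{units or '?'}' unrecognized; "
                          "assuming COUNT_RATE")
            quantity = Quantity.COUNT_RATE
    return ImageGrid(values, (px, py, dz), origin, quantity)


def _read_rtdose(path: Path) -> ImageGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols)
    if arr.ndim == 2:
        arr = arr[None]
    values = np.transpose(arr, (2, 1, 0))
    py, px = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        dz = float(np.mean(np.diff(offsets)))
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0))
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return ImageGrid(values, (px, py, dz), origin, Quantity.DOSE)


#: organizational UID root used for generated DICOM objects
_UID_PREFIX = "1.2.826.0.1.3680043.10.1543."


def write_rtdose(dose: ImageGrid, path: str | Path,
                 frame_of_reference: str | None = None,
                 bits: int = 16) -> Path:
    """Write a dose grid as a DICOM RT Dose object.

    ``DoseGridScaling`` is chosen so the maximum voxel maps to the full
    integer range (16-bit by default, 32-bit optional), guaranteeing that the
    stored maximum uses at least 90% of the range and that reading the file
    back reproduces every voxel within one scaling quantum.

    Parameters
    ----------
    dose
        Grid with quantity DOSE; values must be finite and >= 0.
    frame_of_reference
        FrameOfReferenceUID to stamp, generated when omitted.
    bits
        16 or 32.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if dose.quantity is not Quantity.DOSE:
        raise QuantityError(f"write_rtdose requires quantity DOSE, got {dose.quantity}")
    if np.any(dose.values < 0):
        raise ValueError("dose values must be >= 0 for RT Dose export")
    if bits not in (16, 32):
        raise ValueError("bits must be 16 or 32")

    path = Path(path)
    vmax = float(dose.values.max())
    int_max = 2 ** bits - 1
    scaling = vmax / int_max if vmax > 0 else 1.0
    stored = np.round(dose.values / scaling).astype(np.uint16 if bits == 16 else np.uint32)
    stored_disk = np.transpose(stored, (2, 1, 0))  # (frames, rows, cols)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid(prefix=_UID_PREFIX)
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid(prefix=_UID_PREFIX)
    ds.StudyInstanceUID = generate_uid(prefix=_UID_PREFIX)
    ds.FrameOfReferenceUID = frame_of_reference or generate_uid(prefix=_UID_PREFIX)
    ds.PatientName = ""
    ds.PatientID = ""
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = list(dose.origin)
    ds.PixelSpacing = [dose.spacing[1], dose.spacing[0]]  # row (y), col (x)
    ds.SliceThickness = dose.spacing[2]
    nz = dose.shape[2]
    ds.NumberOfFrames = nz
    ds.GridFrameOffsetVector = [i * dose.spacing[2] for i in range(nz)]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.Rows = dose.shape[1]
    ds.Columns = dose.shape[0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = bits
    ds.BitsStored = bits
    ds.HighBit = bits - 1
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = np.ascontiguousarray(stored_disk).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# Dispatch reader
# ---------------------------------------------------------------------------

def read_image(path: str | Path, fmt: str | None = None,
               quantity: Quantity | None = None) -> ImageGrid:
    """Read a 3D image from NIfTI, NRRD, a DICOM series directory, or a
    DICOM RT Dose file.

    Parameters
    ----------
    path
        File (NIfTI/NRRD/single DICOM) or directory (DICOM series).
    fmt
        Optional hint: "nifti", "nrrd", "dicom", "rtdose". Inferred from the
        path when omitted.
    quantity
        Override the quantity recorded in (or absent from) the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt is None:
        name = path.name.lower()
        if path.is_dir():
            fmt = "dicom"
        elif name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith(".nrrd"):
            fmt = "nrrd"
        elif name.endswith(".dcm"):
            fmt = "dicom-file"
        else:
            raise FormatError(f"cannot infer format of {path}")

    if fmt == "nifti":
        return _read_nifti(path, quantity)
    if fmt == "nrrd":
        return _read_nrrd(path, quantity)
    if fmt == "dicom":
        return _read_dicom_series(path, quantity)
    if fmt in ("rtdose", "dicom-file"):
        import pydicom

        ds = pydicom.dcmread(str(path), stop_before_pixels=True)
        if getattr(ds, "Modality", "") == "RTDOSE":
            return _read_rtdose(path)
        raise FormatError(f"{path}: single DICOM files are supported for RT Dose only")
    raise FormatError(f"unknown format hint '{fmt}'")


def read_mask(path: str | Path, name: str | None = None) -> StructureMask:
    """Read a binary NIfTI volume as a named structure mask."""
    path = Path(path)
    grid = read_image(path, quantity=Quantity.MASK)
    grid.values = (grid.values > 0.5).astype(np.float64)
    return StructureMask(name or path.name.split(".")[0], grid)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_coords_in_source(src: ImageGrid, target: GridGeometry) -> np.ndarray:
    """Source index coordinates of every target voxel centre, shape (3, ...)."""
    axes = [(target.origin[a] + target.spacing[a] * np.arange(target.shape[a])
             - src.origin[a]) / src.spacing[a] for a in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def _overlap_matrix(n_src: int, d_src: float, o_src: float,
                    n_tgt: int, d_tgt: float, o_tgt: float) -> np.ndarray:
    """1D interval-overlap lengths between source and target voxels (mm)."""
    src_lo = o_src + (np.arange(n_src) - 0.5) * d_src
    src_hi = src_lo + d_src
    tgt_lo = o_tgt + (np.arange(n_tgt) - 0.5) * d_tgt
    tgt_hi = tgt_lo + d_tgt
    lo = np.maximum(tgt_lo[:, None], src_lo[None, :])
    hi = np.minimum(tgt_hi[:, None], src_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def resample_to_grid(src: ImageGrid, target: "GridGeometry | ImageGrid",
                     mode: str = "linear") -> ImageGrid:
    """Resample a grid onto a target geometry.

    Modes
    -----
    ``linear``
        Trilinear interpolation of the (intensive) field at target voxel
        centres; the natural choice for Bq/ml, Gy/s, Gy.
    ``nearest``
        Nearest-neighbour sampling; mandatory for MASK grids so output stays
        binary.
    ``volume_preserving``
        Exact axis-separable box-overlap averaging: each target voxel takes
        the overlap-volume-weighted mean of the source voxels it covers, so
        the integral (value × voxel volume) over the common extent is
        conserved.

    Voxels outside the source extent are filled with 0 (air / absent tissue
    contributes nothing).
    """
    tgt = target.geometry if isinstance(target, ImageGrid) else target
    if src.quantity is Quantity.MASK and mode != "nearest":
        raise QuantityError("MASK grids must be resampled with mode='nearest'")
    if mode not in ("linear", "nearest", "volume_preserving"):
        raise ValueError(f"unknown resampling mode '{mode}'")

    # reject zero overlap of physical extents
    for a in range(3):
        s_lo, s_hi = src.geometry.extent()[a]
        t_lo, t_hi = tgt.extent()[a]
        if t_lo - 0.5 * tgt.spacing[a] > s_hi + 0.5 * src.spacing[a] or \
           t_hi + 0.5 * tgt.spacing[a] < s_lo - 0.5 * src.spacing[a]:
            raise GeometryError("source and target geometries do not overlap")

    if src.same_geometry(tgt):
        out = src.values.copy()
    elif mode == "volume_preserving":
        mats = [_overlap_matrix(src.shape[a], src.spacing[a], src.origin[a],
                                tgt.shape[a], tgt.spacing[a], tgt.origin[a])
                for a in range(3)]
        acc = np.einsum("ai,ijk->ajk", mats[0], src.values)
        acc = np.einsum("bj,ajk->abk", mats[1], acc)
        acc = np.einsum("ck,abk->abc", mats[2], acc)
        out = acc / (tgt.spacing[0] * tgt.spacing[1] * tgt.spacing[2])
    else:
        order = 1 if mode == "linear" else 0
        coords = _target_coords_in_source(src, tgt)
        out = ndimage.map_coordinates(src.values, coords, order=order,
                                      mode="constant", cval=0.0)
    return ImageGrid(out, tgt.spacing, tgt.origin, src.quantity, src.reference_time_h)
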