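"""Reading, writing and validating CT volumes and coronary territory masks.

Geometric conventions used by every downstream feature:

* arrays are indexed ``(slice, row, col)`` = ``(i, j, k)``;
* slice index 0 is the superior-most ("top") slice after normalization;
* voxel ``(i, j, k)`` sits at the local mm position ``(k*dx, j*dy, i*dz)``;
  all distances are computed in mm, never in voxel units, because calcium
  scans are strongly anisotropic (typically 0.5 x 0.5 mm in-plane with
  2.5 mm slices).

NIfTI and NRRD files are handled through SimpleITK; DICOM series through
pydicom (slices sorted by their patient z position, so a shuffled directory
listing yields the same volume).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

#: Territory label codes shared across the package.
TERRITORY_CODES = {0: "BG", 1: "LM", 2: "LAD", 3: "LCX", 4: "RCA"}
TERRITORY_NAMES = ("LM", "LAD", "LCX", "RCA")


class FormatError(ValueError):
    """File cannot be parsed in the requested format."""


class GeometryError(ValueError):
    """Required geometric metadata is missing or inconsistent."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D HU volume with geometry.

    Attributes
    ----------
    data : ndarray, shape (n_slices, n_rows, n_cols)
        HU values; slice 0 is the superior-most slice.
    spacing : (dx, dy, dz) in mm
        In-plane column/row spacing and slice spacing.
    origin : (x0, y0, z0) in mm
        Physical position of voxel (0, 0, 0); informational only, local
        coordinates are used for all distance features.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise GeometryError(f"volume must be 3D with >= 1 slice, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise FormatError("volume contains non-finite HU values")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "data", arr.astype(np.float64, copy=False))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def voxel_position_mm(self, i, j, k) -> np.ndarray:
        """Local mm position (x, y, z) of voxel centre (i, j, k)."""
        dx, dy, dz = self.spacing
        return np.array([np.asarray(k) * dx, np.asarray(j) * dy, np.asarray(i) * dz], dtype=float).T


@dataclass(frozen=True)
class TerritoryMask:
    """Integer label volume assigning voxels to coronary territories.

    ``spacing`` is optional (None skips the spacing check in
    :func:`validate_pair`); masks read from files carry the file's spacing.
    """

    labels: np.ndarray
    code_map: dict = field(default_factory=lambda: dict(TERRITORY_CODES))
    spacing: tuple | None = None

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise FormatError("mask voxels are not integer-valued")
            lab = lab.astype(np.int32)
        codes = set(np.unique(lab).tolist())
        unknown = sorted(codes - set(self.code_map))
        if unknown:
            raise FormatError(f"mask contains unknown label codes {unknown}; known codes: {sorted(self.code_map)}")
        object.__setattr__(self, "labels", lab.astype(np.int32, copy=False))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def validate_pair(vol: CTVolume, mask: TerritoryMask) -> tuple[CTVolume, TerritoryMask]:
    """Check that a volume and mask share shape (and spacing, when the mask
    carries one); returns the pair unchanged."""
    if vol.shape != mask.shape:
        raise GeometryError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    if mask.spacing is not None and any(
            abs(a - b) > 1e-6 for a, b in zip(mask.spacing, vol.spacing)):
        raise GeometryError(
            f"volume spacing {vol.spacing} != mask spacing {tuple(mask.spacing)}")
    return vol, mask


# ---------------------------------------------------------------------------
# SimpleITK-backed readers/writers (NIfTI, NRRD)
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    """Convert a SimpleITK image to (array, spacing, origin), superior-first.

    SimpleITK arrays are indexed (z, y, x) with the physical z direction given
    by the last column of the direction matrix (LPS: +z is superior). If the
    slice index runs inferior->superior we flip so index 0 is superior.
    """
    arr = sitk.GetArrayFromImage(img).astype(np.float64)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D image, got {arr.ndim}D")
    sx, sy, sz = img.GetSpacing()
    direction = np.array(img.GetDirection()).reshape(3, 3)
    origin = np.array(img.GetOrigin(), dtype=float)
    d_zz = direction[2, 2]
    if d_zz > 0:
        # slice index increases toward superior -> reverse so slice 0 is top
        arr = arr[::-1].copy()
        origin = origin + direction @ np.array([0.0, 0.0, sz * (arr.shape[0] - 1)])
    return arr, (float(sx), float(sy), float(sz)), tuple(float(v) for v in origin)


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(s) for s in origin))
    # increasing slice index moves inferior: slice 0 stays the top slice
    img.SetDirection((1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, -1.0))
    return img


def _read_sitk_file(path: str) -> sitk.Image:
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps all I/O failures in RuntimeError
        raise FormatError(f"cannot read image {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(dirpath: str) -> tuple[np.ndarray, tuple, tuple]:
    files = sorted(
        os.path.join(dirpath, f) for f in os.listdir(dirpath) if not f.startswith(".")
    )
    if not files:
        raise FormatError(f"no files in DICOM directory {dirpath!r}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise FormatError(f"cannot parse DICOM file {f!r}: {exc}") from exc
        slices.append(ds)
    for ds in slices:
        if not hasattr(ds, "PixelSpacing"):
            raise GeometryError("DICOM slice missing PixelSpacing")
        if not hasattr(ds, "ImagePositionPatient"):
            raise GeometryError("DICOM slice missing ImagePositionPatient")
    # LPS: +z is superior, so superior-first means descending z position
    slices.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
        dz_steps = np.abs(np.diff(zs))
        if dz_steps.max() - dz_steps.min() > 1e-3:
            raise GeometryError("non-uniform DICOM slice spacing")
        dz = float(dz_steps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 0) or 0)
        if dz <= 0:
            raise GeometryError("DICOM series missing slice spacing (SliceThickness)")
    arrays = []
    for ds in slices:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(a * slope + intercept)
    data = np.stack(arrays, axis=0)
    ipp = slices[0].ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return data, (col_sp, row_sp, dz), origin


def write_dicom_series(vol: CTVolume, dirpath: str) -> list[str]:
    """Write a CTVolume as one DICOM file per slice (int16 HU, slope 1)."""
    os.makedirs(dirpath, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=["calciomics-series"])
    study_uid = generate_uid(entropy_srcs=["calciomics-study"])
    dx, dy, dz = vol.spacing
    x0, y0, z0 = vol.origin
    paths = []
    for i in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"calciomics-{i}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.PixelSpacing = [f"{dy:.6f}", f"{dx:.6f}"]
        ds.SliceThickness = f"{dz:.6f}"
        # superior-first: physical z decreases with slice index
        ds.ImagePositionPatient = [f"{x0:.6f}", f"{y0:.6f}", f"{z0 - i * dz:.6f}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        sl = np.round(vol.data[i]).astype(np.int16)
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = sl.tobytes()
        path = os.path.join(dirpath, f"slice_{i:04d}.dcm")
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    p = str(path)
    if os.path.isdir(p):
        return "dicom_series"
    if p.endswith((".nii", ".nii.gz")):
        return "nifti"
    if p.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise FormatError(f"cannot infer format of {p!r}; pass format= explicitly")


def read_volume(path: str, format: str | None = None) -> CTVolume:
    """Read a CT volume from NIfTI, NRRD or a DICOM series directory.

    Slices are reordered so index 0 is the superior-most slice; spacing is
    taken from file metadata (missing spacing raises :class:`GeometryError`).
    """
    fmt = format or _infer_format(path)
    if fmt == "dicom_series":
        data, spacing, origin = _read_dicom_series(path)
    elif fmt in ("nifti", "nrrd"):
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path!r}")
        data, spacing, origin = _from_sitk(_read_sitk_file(path))
    else:
        raise FormatError(f"unknown volume format {fmt!r}")
    return CTVolume(data=data, spacing=spacing, origin=origin)


def write_volume(vol: CTVolume, path: str) -> str:
    """Write a CTVolume to NIfTI or NRRD (by extension)."""
    sitk.WriteImage(_to_sitk(vol.data, vol.spacing, vol.origin), str(path))
    return str(path)


def read_mask(path: str, format: str | None = None, code_map: dict | None = None) -> TerritoryMask:
    """Read a territory label mask; unknown label codes are rejected.

    A JSON sidecar ``<path>.codes.json`` mapping code -> territory name
    overrides the default code map.
    """
    fmt = format or _infer_format(path)
    if fmt == "dicom_series":
        data, spacing, _ = _read_dicom_series(path)
    else:
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path!r}")
        data, spacing, _ = _from_sitk(_read_sitk_file(path))
    if code_map is None:
        sidecar = str(path) + ".codes.json"
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                code_map = {int(k): v for k, v in json.load(fh).items()}
        else:
            code_map = dict(TERRITORY_CODES)
    return TerritoryMask(labels=data, code_map=code_map, spacing=spacing)


def write_mask(mask: TerritoryMask, path: str, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> str:
    sitk.WriteImage(_to_sitk(mask.labels.astype(np.int16), spacing, origin), str(path))
    return str(path)


def crop(vol: CTVolume, n_slices: int) -> CTVolume:
    """First ``n_slices`` slices of a volume (test/debug helper)."""
    return replace(vol, data=vol.data[:n_slices])
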