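"""CT volume input/output.

Reads CT volumes from a DICOM series directory or a NIfTI file into the
canonical in-memory representation (:class:`CTVolume`), and writes the
final overview images as 8-bit RGB PNG.

Every loader reorients the data into one fixed anatomical convention so
the projection stage can define anterior-posterior and lateral views
unambiguously:

* axis 0 (x): subject-left -> subject-right
* axis 1 (y): anterior -> posterior
* axis 2 (z): inferior -> superior

HU values are kept as signed floating point without clamping; radiopaque
implants routinely exceed the 12-bit storage range and the red rule needs
values above 2800 HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from nibabel import orientations as nio
from PIL import Image
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CTVolume",
    "CompositeImage",
    "FormatError",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "write_dicom_series",
    "write_png",
]

# Canonical orientation codes relative to a voxel->RAS affine:
# R = toward subject right (+x), P = toward posterior (-y), S = superior (+z).
_CANONICAL_AXCODES = ("R", "P", "S")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class CTVolume:
    """A CT volume in Hounsfield units on the canonical axes.

    Attributes
    ----------
    voxels
        3D float array of HU values, indexed ``[x, y, z]`` with x running
        subject-left to subject-right, y anterior to posterior and z
        inferior to superior.
    spacing
        Voxel size ``(sx, sy, sz)`` in mm.
    origin
        RAS position (mm) of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {vox.ndim}D")
        if any(n < 2 for n in vox.shape):
            raise ValueError(
                f"every dimension must be >= 2, got shape {vox.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.isfinite(vox).all():
            raise ValueError("volume contains non-finite HU values")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class CompositeImage:
    """Final 8-bit RGB overview image.

    Every pixel is either gray (r == g == b), pure red (255, 0, 0) or pure
    blue (0, 0, 255).
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    view: str = "anterior_posterior"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (rows, cols, 3) pixels, got {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        r, g, b = px[..., 0], px[..., 1], px[..., 2]
        gray = (r == g) & (g == b)
        red = (r == 255) & (g == 0) & (b == 0)
        blue = (r == 0) & (g == 0) & (b == 255)
        if not (gray | red | blue).all():
            raise ValueError("pixels must be gray, pure red or pure blue")
        object.__setattr__(self, "pixels", px)


# ---------------------------------------------------------------------------
# orientation handling

def _canonicalize(
    data: np.ndarray, affine: np.ndarray
) -> tuple[np.ndarray, tuple[float, ...], tuple[float, ...]]:
    """Reorient ``data`` (with voxel->RAS ``affine``) onto the canonical axes."""
    ornt = nio.io_orientation(affine)
    target = nio.axcodes2ornt(_CANONICAL_AXCODES)
    xform = nio.ornt_transform(ornt, target)
    out = np.ascontiguousarray(nio.apply_orientation(data, xform))
    new_affine = affine @ nio.inv_ornt_aff(xform, data.shape)
    spacing = tuple(float(np.linalg.norm(new_affine[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in new_affine[:3, 3])
    return out, spacing, origin


def _canonical_affine(spacing, origin) -> np.ndarray:
    """Voxel->RAS affine of a canonical volume (y axis runs anterior->posterior)."""
    sx, sy, sz = spacing
    aff = np.diag([sx, -sy, sz, 1.0])
    aff[:3, 3] = origin
    return aff


# ---------------------------------------------------------------------------
# readers

def read_nifti(file_path: str | Path) -> CTVolume:
    """Read a NIfTI volume (``.nii`` / ``.nii.gz``) as a canonical CTVolume.

    The affine's axis permutation/flips are applied so the returned axes
    follow the canonical left->right / anterior->posterior /
    inferior->superior convention.
    """
    file_path = Path(file_path)
    if not file_path.exists():
        raise FileNotFoundError(f"no such file: {file_path}")
    img = nib.load(file_path)
    if len(img.shape) != 3:
        raise FormatError(
            f"expected a 3D volume, got {len(img.shape)}D data in {file_path}"
        )
    data = img.get_fdata(dtype=np.float64)
    vox, spacing, origin = _canonicalize(data, img.affine)
    return CTVolume(vox, spacing, origin)


def read_dicom_series(directory_path: str | Path) -> CTVolume:
    """Read a single-frame CT DICOM series directory as a canonical CTVolume.

    Slices are ordered by their spatial position along the slice normal
    (not by file name) and stored values are converted to HU via the
    modality rescale, ``HU = raw * RescaleSlope + RescaleIntercept``.
    """
    directory_path = Path(directory_path)
    if not directory_path.is_dir():
        raise FileNotFoundError(f"no such directory: {directory_path}")
    files = sorted(p for p in directory_path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except pydicom.errors.InvalidDicomError:
            continue
    if len(datasets) < 2:
        raise FormatError(
            f"{directory_path}: need >= 2 DICOM slices, found {len(datasets)}"
        )

    first = datasets[0]
    rows, cols = int(first.Rows), int(first.Columns)
    iop = np.asarray([float(v) for v in first.ImageOrientationPatient])
    col_dir, row_dir = iop[:3], iop[3:]
    normal = np.cross(col_dir, row_dir)

    for ds in datasets:
        if int(ds.Rows) != rows or int(ds.Columns) != cols:
            raise FormatError(
                "inconsistent in-plane dimensions across slices: "
                f"{(rows, cols)} vs {(int(ds.Rows), int(ds.Columns))}"
            )
        for tag in ("RescaleSlope", "RescaleIntercept"):
            if getattr(ds, tag, None) is None:
                raise FormatError(f"missing required DICOM tag {tag}")

    datasets.sort(
        key=lambda ds: float(
            np.dot(normal, [float(v) for v in ds.ImagePositionPatient])
        )
    )

    ps_row, ps_col = (float(v) for v in first.PixelSpacing)
    ipp0 = np.asarray([float(v) for v in datasets[0].ImagePositionPatient])
    ipp1 = np.asarray([float(v) for v in datasets[1].ImagePositionPatient])
    slice_vec = ipp1 - ipp0
    if np.linalg.norm(slice_vec) == 0:
        raise FormatError("duplicate slice positions in series")

    # volume indexed (col, row, slice); HU via modality rescale
    slices = []
    for ds in datasets:
        raw = ds.pixel_array.astype(np.float64)
        hu = raw * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(hu.T)  # (col, row)
    vol = np.stack(slices, axis=2)

    # voxel->LPS affine, then LPS->RAS (negate x and y)
    aff_lps = np.eye(4)
    aff_lps[:3, 0] = col_dir * ps_col
    aff_lps[:3, 1] = row_dir * ps_row
    aff_lps[:3, 2] = slice_vec
    aff_lps[:3, 3] = ipp0
    aff_ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ aff_lps

    vox, spacing, origin = _canonicalize(vol, aff_ras)
    return CTVolume(vox, spacing, origin)


# ---------------------------------------------------------------------------
# writers

def write_nifti(volume: CTVolume, file_path: str | Path) -> None:
    """Write a canonical CTVolume to NIfTI."""
    aff = _canonical_affine(volume.spacing, volume.origin)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), aff)
    nib.save(img, str(file_path))


def write_dicom_series(volume: CTVolume, directory_path: str | Path) -> None:
    """Write a canonical CTVolume as a minimal single-frame CT DICOM series.

    Uses the standard axial orientation (columns toward subject left, rows
    toward posterior) with RescaleSlope 1 / RescaleIntercept -1024; HU are
    rounded to the nearest integer for storage.
    """
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    sx, sy, sz = volume.spacing
    ox, oy, oz = volume.origin
    nx, ny, nz = volume.shape
    intercept = -1024.0
    raw = np.rint(volume.voxels - intercept)
    if raw.min() < 0 or raw.max() > 65535:
        raise ValueError("HU range not storable as 16-bit with intercept -1024")
    raw = raw.astype(np.uint16)

    series_uid, study_uid, frame_uid = generate_uid(), generate_uid(), generate_uid()
    for k in range(nz):
        # pixel (row r, col c) = voxel (nx-1-c, r, k); columns run toward
        # subject left as in a standard axial acquisition
        arr = raw[::-1, :, k].T.copy()  # (rows=ny, cols=nx)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{sy:g}", f"{sx:g}"]  # row spacing, col spacing
        ds.SliceThickness = f"{sz:g}"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        # LPS position of pixel (0, 0) = voxel (nx-1, 0, k)
        ds.ImagePositionPatient = [
            f"{-(ox + (nx - 1) * sx):g}",
            f"{-oy:g}",
            f"{oz + k * sz:g}",
        ]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = f"{intercept:g}"
        ds.PixelData = arr.tobytes()
        ds.save_as(directory_path / f"slice_{k:04d}.dcm", enforce_file_format=True)


def write_png(image: CompositeImage, file_path: str | Path) -> None:
    """Write a CompositeImage as an 8-bit RGB PNG (lossless round trip)."""
    Image.fromarray(image.pixels, mode="RGB").save(str(file_path), format="PNG")
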