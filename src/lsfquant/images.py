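"""Spatially-aware image containers and readers/writers.

Volumes (CT, reconstructed SPECT) are read from NIfTI files or DICOM series
directories into :class:`ImageVolume`; anterior/posterior planar scintigrams
into :class:`PlanarImage`.  All geometry is expressed in DICOM LPS
millimetres; NIfTI RAS affines are converted on read and restored on write.

No registration happens anywhere in the package: SPECT and CT are assumed
hardware-fused on the same gantry, so a frame-of-reference mismatch between
the two series is a hard error rather than something to fix.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .exceptions import FormatError, FrameOfReferenceError, GeometryError
from .geometry import AffineGeometry

__all__ = [
    "Modality",
    "View",
    "ImageVolume",
    "PlanarImage",
    "read_volume",
    "write_volume",
    "read_planar",
    "read_planar_pair",
    "write_planar",
]

log = logging.getLogger("lsfquant")

# LPS <-> RAS: negate the L/R and A/P axes.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


class Modality(str, enum.Enum):
    CT = "CT"
    SPECT_AC = "SPECT_AC"  # attenuation-corrected reconstruction
    SPECT_NC = "SPECT_NC"  # reconstruction without attenuation correction


class View(str, enum.Enum):
    ANTERIOR = "ANTERIOR"
    POSTERIOR = "POSTERIOR"


@dataclass
class ImageVolume:
    """A 3D voxel array (counts for SPECT, HU for CT) with full geometry."""

    voxels: np.ndarray
    geometry: AffineGeometry
    modality: Modality
    frame_of_reference: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(f"volume must be 3D, got ndim={self.voxels.ndim}")
        if self.voxels.shape != self.geometry.shape:
            raise GeometryError(
                f"voxel shape {self.voxels.shape} != grid shape {self.geometry.shape}"
            )
        self.modality = Modality(self.modality)
        if self.modality in (Modality.SPECT_AC, Modality.SPECT_NC) and np.any(
            self.voxels < 0
        ):
            raise FormatError("SPECT volumes must have non-negative counts")

    @property
    def spacing(self) -> np.ndarray:
        return self.geometry.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.geometry.origin

    @property
    def orientation(self) -> np.ndarray:
        return self.geometry.orientation

    @property
    def total(self) -> float:
        return float(self.voxels.sum())

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)


@dataclass
class PlanarImage:
    """A 2D planar scintigram.

    Axis convention: ``pixels[i, j]`` with i along patient left (for the
    ANTERIOR view; mirrored for POSTERIOR, as recorded by the camera) and j
    along patient superior.  The posterior member of a pair is stored as
    acquired (mirrored); it is un-mirrored exactly once, downstream, when
    counts are extracted.
    """

    pixels: np.ndarray
    pixel_spacing: float
    view: View

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(f"planar image must be 2D, got ndim={self.pixels.ndim}")
        if self.pixel_spacing <= 0:
            raise FormatError("pixel spacing must be positive")
        if np.any(self.pixels < 0):
            raise FormatError("planar counts must be non-negative")
        self.view = View(self.view)

    @property
    def total(self) -> float:
        return float(self.pixels.sum())


# --------------------------------------------------------------------------- #
# NIfTI volume I/O
# --------------------------------------------------------------------------- #
def _lps_geometry_from_nifti(img) -> AffineGeometry:
    affine = _RAS2LPS @ np.asarray(img.affine, dtype=float)
    return AffineGeometry(affine, img.shape[:3])


def _read_nifti_volume(path, modality, frame_of_reference) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim > 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI volume, got shape {data.shape}")
    geom = _lps_geometry_from_nifti(img)
    return ImageVolume(data, geom, modality, frame_of_reference or "")


def write_volume(volume: ImageVolume, path) -> Path:
    """Write a volume as NIfTI (.nii / .nii.gz), converting LPS back to RAS."""
    affine_ras = _RAS2LPS @ volume.geometry.matrix
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), affine_ras)
    nib.save(img, str(path))
    return Path(path)


# --------------------------------------------------------------------------- #
# DICOM series
# --------------------------------------------------------------------------- #
_MODALITY_FROM_DICOM = {"CT": Modality.CT, "NM": Modality.SPECT_AC, "PT": Modality.SPECT_AC}


def _read_dicom_series(path, modality, frame_of_reference) -> ImageVolume:
    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"{path}: no DICOM image slices found")

    fors = {str(getattr(ds, "FrameOfReferenceUID", "")) for ds in slices}
    if len(fors) > 1:
        raise FrameOfReferenceError(
            "mixed frames of reference in series: " + " vs ".join(sorted(fors))
        )
    for_uid = fors.pop()

    iops = {tuple(np.round(np.asarray(ds.ImageOrientationPatient, float), 6)) for ds in slices}
    if len(iops) > 1:
        raise FormatError(f"{path}: slices do not share an orientation")
    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]  # along increasing column / row index
    normal = np.cross(row_dir, col_dir)

    # Sort slices along the geometric normal and check gap uniformity.
    pos = np.array([np.asarray(ds.ImagePositionPatient, float) for ds in slices])
    proj = pos @ normal
    order = np.argsort(proj)
    slices = [slices[i] for i in order]
    proj = proj[order]
    if len(slices) > 1:
        gaps = np.diff(proj)
        med = float(np.median(gaps))
        if med <= 0 or np.any(np.abs(gaps - med) > 0.01 * abs(med)):
            raise FormatError(
                f"{path}: non-uniform slice spacing (gaps {np.round(gaps, 4).tolist()})"
            )
        slice_spacing = med
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    ps = np.asarray(slices[0].PixelSpacing, dtype=float)  # (row, col) mm
    spacing = np.array([ps[1], ps[0], slice_spacing])

    def _pixels(ds):
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        inter = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        return arr * slope + inter

    # voxels[i, j, k] with i = column index (row_dir), j = row index (col_dir)
    vol = np.stack([_pixels(ds).T for ds in slices], axis=-1)
    orientation = np.column_stack([row_dir, col_dir, normal])
    origin = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    geom = AffineGeometry.from_components(spacing, origin, orientation, vol.shape)

    if modality is None:
        tag = str(getattr(slices[0], "Modality", "CT"))
        modality = _MODALITY_FROM_DICOM.get(tag, Modality.CT)
    if modality == Modality.CT:
        vol = vol  # HU may be negative
    else:
        vol = np.clip(vol, 0, None)
    return ImageVolume(vol, geom, modality, frame_of_reference or for_uid)


def read_volume(path, format=None, modality=None, frame_of_reference=None) -> ImageVolume:
    """Read a volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : str or Path
        ``.nii``/``.nii.gz`` file, or a directory of DICOM slices.
    format : {"NIFTI", "DICOM_SERIES", None}
        Autodetected from the path when ``None``.
    modality : Modality or str, optional
        Override the modality label (required for NIfTI SPECT volumes, which
        carry no modality metadata; defaults to CT for NIfTI).
    frame_of_reference : str, optional
        Override/assign the frame-of-reference identifier.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if format is None:
        format = "DICOM_SERIES" if p.is_dir() else "NIFTI"
    if modality is not None:
        modality = Modality(modality)
    if format == "NIFTI":
        return _read_nifti_volume(p, modality or Modality.CT, frame_of_reference)
    if format == "DICOM_SERIES":
        return _read_dicom_series(p, modality, frame_of_reference)
    raise FormatError(f"unknown volume format {format!r}")


# --------------------------------------------------------------------------- #
# Planar images
# --------------------------------------------------------------------------- #
def _read_planar_any(path, view) -> PlanarImage:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.suffix.lower() in (".nii", ".gz"):
        img = nib.load(str(p))
        data = np.squeeze(np.asanyarray(img.dataobj, dtype=float))
        if data.ndim != 2:
            raise FormatError(f"{p}: expected a 2D planar image, got shape {data.shape}")
        spacing = float(img.header.get_zooms()[0])
        return PlanarImage(data, spacing, view)
    ds = pydicom.dcmread(str(p))
    arr = np.squeeze(ds.pixel_array.astype(float))
    if arr.ndim != 2:
        raise FormatError(f"{p}: expected a single-frame planar image")
    ps = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", [1.0, 1.0])
    return PlanarImage(arr.T, float(ps[0]), view)


def read_planar(path, view) -> PlanarImage:
    """Read one planar scintigram (NIfTI 2D or single-frame DICOM)."""
    return _read_planar_any(path, View(view))


def read_planar_pair(path_ant, path_post) -> tuple[PlanarImage, PlanarImage]:
    """Read an anterior/posterior planar pair.

    The posterior image is returned exactly as stored (camera orientation,
    i.e. left-right mirrored); it is mirrored once, downstream, when organ
    counts are extracted.
    """
    ant = _read_planar_any(path_ant, View.ANTERIOR)
    post = _read_planar_any(path_post, View.POSTERIOR)
    if ant.pixels.shape != post.pixels.shape:
        raise FormatError(
            f"planar pair shape mismatch: {ant.pixels.shape} vs {post.pixels.shape}"
        )
    if not np.isclose(ant.pixel_spacing, post.pixel_spacing, rtol=1e-6):
        raise FormatError("planar pair pixel spacing mismatch")
    return ant, post


def write_planar(image: PlanarImage, path) -> Path:
    """Write a planar image as 2D NIfTI."""
    affine = np.diag([image.pixel_spacing, image.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(image.pixels.astype(np.float64), affine)
    nib.save(img, str(path))
    return Path(path)
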