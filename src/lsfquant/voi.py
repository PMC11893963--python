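"""Transfer CT-grid organ masks onto the SPECT grid and build augmented VOIs.

Respiratory motion smears SPECT counts outside the CT-derived organ
boundaries, so the transferred masks are dilated ("pixel augmentation") by a
metric ball specified in millimetres — anisotropic SPECT grids therefore
behave isotropically — with optional extra dilation along the cranio-caudal
(patient S-I) axis where breathing displacement is largest.

Contested voxels are resolved with lung priority: the augmented liver VOI is
adjusted to avoid overlap with the lung VOIs, so the liver never steals
counts from the lungs.  Precedence, highest first:

    original lung > original liver > augmented lung > augmented liver

Original voxels are never removed by augmentation.  When both augmented
lungs claim a voxel it goes to the nearer lung (Euclidean mm distance to the
original mask); exact ties go to the right lung.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import GeometryError, MaskError
from .geometry import AffineGeometry
from .images import ImageVolume, _RAS2LPS
from .segmentation import MaskLabel, MaskSource, OrganMask

__all__ = [
    "AugmentationParams",
    "CropCorrection",
    "VOISet",
    "resample_mask",
    "augment_vois",
    "correct_cropped_lung",
    "mask_volume",
    "export_label_volume",
]

log = logging.getLogger("lsfquant")


@dataclass(frozen=True)
class AugmentationParams:
    """Margin sizes for VOI augmentation, in millimetres.

    ``extra_cranio_caudal_mm`` is added to the dilation radius along the
    patient S-I axis only (ellipsoidal structuring element), for both organs.

    Defaults: equal 5 mm in-plane margins for liver and lungs (about one
    SPECT voxel) plus 5 mm extra cranio-caudally, covering the ±7.5 mm
    displacement of typical 15 mm peak-to-peak breathing motion.  Unequal
    liver/lung margins would bias the count *ratio* the LSF is built from,
    so the two organs get the same radius by default.
    """

    liver_radius_mm: float = 5.0
    lung_radius_mm: float = 5.0
    extra_cranio_caudal_mm: float = 5.0

    def __post_init__(self):
        if min(self.liver_radius_mm, self.lung_radius_mm, self.extra_cranio_caudal_mm) < 0:
            raise MaskError("augmentation radii must be >= 0")

    def as_dict(self) -> dict:
        return {
            "liver_radius_mm": self.liver_radius_mm,
            "lung_radius_mm": self.lung_radius_mm,
            "extra_cranio_caudal_mm": self.extra_cranio_caudal_mm,
        }


@dataclass(frozen=True)
class CropCorrection:
    """Count imputation for a lung apex cut off by the SPECT field of view.

    Counts are imputed, not mask voxels, so reported organ volumes stay
    honest about what was actually imaged.
    """

    reference_lung_volume_cm3: float
    imaged_lung_volume_cm3: float
    estimated_missing_fraction: float
    added_counts: float
    apex_window_mm: float = 20.0

    def __post_init__(self):
        if not (0.0 <= self.estimated_missing_fraction < 1.0):
            raise MaskError("missing fraction must be in [0, 1)")
        if self.added_counts < 0:
            raise MaskError("imputed counts must be >= 0")

    def as_dict(self) -> dict:
        return {
            "reference_lung_volume_cm3": self.reference_lung_volume_cm3,
            "imaged_lung_volume_cm3": self.imaged_lung_volume_cm3,
            "estimated_missing_fraction": self.estimated_missing_fraction,
            "added_counts": self.added_counts,
            "apex_window_mm": self.apex_window_mm,
        }


@dataclass
class VOISet:
    """Finalized liver + left/right lung VOIs on the SPECT grid.

    ``provenance`` marks, per organ, which true voxels were added by
    augmentation (original voxels are False).
    """

    liver: OrganMask
    lung_left: OrganMask
    lung_right: OrganMask
    augmentation: AugmentationParams
    provenance: dict = field(default_factory=dict)
    crop_correction: CropCorrection | None = None

    def __post_init__(self):
        geom = self.liver.geometry
        for m in (self.lung_left, self.lung_right):
            if not m.geometry.approx_equal(geom):
                raise MaskError("VOISet masks must share one grid")
        if (self.liver.mask & (self.lung_left.mask | self.lung_right.mask)).any():
            raise MaskError("finalized liver VOI overlaps a lung VOI")

    @property
    def geometry(self) -> AffineGeometry:
        return self.liver.geometry

    @property
    def lung_mask(self) -> np.ndarray:
        return self.lung_left.mask | self.lung_right.mask

    def masks(self) -> dict:
        return {
            MaskLabel.LIVER: self.liver,
            MaskLabel.LUNG_LEFT: self.lung_left,
            MaskLabel.LUNG_RIGHT: self.lung_right,
        }

    def volumes_cm3(self) -> dict:
        return {label.value: m.volume_cm3 for label, m in self.masks().items()}


# --------------------------------------------------------------------------- #
def mask_volume(mask: OrganMask) -> float:
    """Mask volume in cm^3 (true-voxel count x voxel volume)."""
    return mask.volume_cm3


# --------------------------------------------------------------------------- #
def resample_mask(mask: OrganMask, target: AffineGeometry) -> OrganMask:
    """Nearest-neighbour resample of a binary mask onto ``target``.

    Each target voxel centre is mapped through the target affine to patient
    mm and back through the inverse source affine; the voxel is true iff the
    continuous source index rounds to a true in-bounds source voxel.
    """
    src = mask.geometry
    # composite: target index -> source continuous index
    comp = np.linalg.inv(src.matrix) @ target.matrix
    idx = np.indices(target.shape, dtype=float).reshape(3, -1).T
    src_idx = idx @ comp[:3, :3].T + comp[:3, 3]
    nearest = np.rint(src_idx).astype(np.int64)
    inside = np.all((nearest >= 0) & (nearest < np.array(src.shape)), axis=1)
    out = np.zeros(int(np.prod(target.shape)), dtype=bool)
    ii = nearest[inside]
    out[inside] = mask.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    out = out.reshape(target.shape)
    if mask.mask.any() and not out.any():
        log.warning(
            "%s: mask is empty after resampling (entirely outside target extent)",
            mask.label.value,
        )
    return OrganMask(mask.label, out, target, mask.source, allow_empty=True)


# --------------------------------------------------------------------------- #
def _ball_structure(spacing, radius_mm: float, extra_cc_mm: float, cc_axis: int):
    """Boolean ellipsoid structuring element: index offsets d with
    sum_i (d_i * spacing_i / semi_i)^2 <= 1, semi = radius (+ extra on the
    cranio-caudal index axis)."""
    semi = np.full(3, float(radius_mm))
    semi[cc_axis] += float(extra_cc_mm)
    if np.all(semi == 0):
        return None  # identity
    half = np.floor(semi / np.asarray(spacing, float)).astype(int)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) for h in half], indexing="ij"
    )
    q = np.zeros(grids[0].shape, dtype=float)
    for g, s, a in zip(grids, spacing, semi):
        if a > 0:
            q += (g * s / a) ** 2
        else:
            q += np.where(g == 0, 0.0, np.inf)
    return q <= 1.0 + 1e-12


def _dilate(mask: np.ndarray, structure) -> np.ndarray:
    if structure is None or not mask.any():
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=structure)


def augment_vois(
    liver: OrganMask,
    lung_left: OrganMask,
    lung_right: OrganMask,
    params: AugmentationParams = AugmentationParams(),
) -> VOISet:
    """Dilate the transferred organ masks and resolve overlaps, lungs first.

    Inputs must share the SPECT grid and be pairwise disjoint; overlap on
    input indicates an upstream bug and is a hard error.
    """
    geom = liver.geometry
    for m in (lung_left, lung_right):
        if not m.geometry.approx_equal(geom):
            raise MaskError("augment_vois: masks are not on one grid")
    if (
        (liver.mask & lung_left.mask).any()
        or (liver.mask & lung_right.mask).any()
        or (lung_left.mask & lung_right.mask).any()
    ):
        raise MaskError("augment_vois: input masks overlap (upstream bug)")

    spacing = geom.spacing
    cc_axis, _ = geom.patient_axis(2)
    s_lung = _ball_structure(spacing, params.lung_radius_mm, params.extra_cranio_caudal_mm, cc_axis)
    s_liver = _ball_structure(spacing, params.liver_radius_mm, params.extra_cranio_caudal_mm, cc_axis)

    d_ll = _dilate(lung_left.mask, s_lung)
    d_lr = _dilate(lung_right.mask, s_lung)
    d_liver = _dilate(liver.mask, s_liver)

    orig_lung = lung_left.mask | lung_right.mask
    orig_any = orig_lung | liver.mask

    # tier 3: augmented-lung voxels not already claimed by an original mask
    aug_lung = (d_ll | d_lr) & ~orig_any
    both = aug_lung & d_ll & d_lr
    final_ll = lung_left.mask | (aug_lung & d_ll & ~both)
    final_lr = lung_right.mask | (aug_lung & d_lr & ~both)
    if both.any():
        # nearer original lung wins; exact tie -> right lung
        dist_l = ndimage.distance_transform_edt(~lung_left.mask, sampling=spacing)
        dist_r = ndimage.distance_transform_edt(~lung_right.mask, sampling=spacing)
        to_left = both & (dist_l + 1e-9 < dist_r)
        final_ll |= to_left
        final_lr |= both & ~to_left

    # tier 4: augmented liver gets whatever is left
    final_liver = liver.mask | (d_liver & ~orig_any & ~final_ll & ~final_lr)

    prov = {
        MaskLabel.LIVER: final_liver & ~liver.mask,
        MaskLabel.LUNG_LEFT: final_ll & ~lung_left.mask,
        MaskLabel.LUNG_RIGHT: final_lr & ~lung_right.mask,
    }
    mk = lambda src, m: src.with_mask(m, source=MaskSource.AUGMENTED)
    return VOISet(
        liver=mk(liver, final_liver),
        lung_left=mk(lung_left, final_ll),
        lung_right=mk(lung_right, final_lr),
        augmentation=params,
        provenance=prov,
    )


# --------------------------------------------------------------------------- #
def correct_cropped_lung(
    voiset: VOISet,
    spect: ImageVolume,
    reference_lung_volume_cm3: float,
    apex_window_mm: float = 20.0,
    discrepancy_warn_fraction: float = 0.25,
) -> VOISet:
    """Impute counts for a lung apex cropped by the SPECT field of view.

    Cropping is detected when the lung mask touches the superior face of the
    SPECT volume.  The missing volume (reference minus imaged) is filled at
    the mean count concentration of the most-superior ``apex_window_mm`` of
    imaged lung.  Masks are left unchanged; only a :class:`CropCorrection`
    carrying ``added_counts`` is attached.

    The imaged volume and the apex concentration are measured on the
    *original* (pre-augmentation) lung voxels — the augmentation shell is a
    count-capture margin, not anatomy, and would bias both.
    """
    added_ll = voiset.provenance.get(MaskLabel.LUNG_LEFT)
    added_lr = voiset.provenance.get(MaskLabel.LUNG_RIGHT)
    lung = voiset.lung_mask
    if added_ll is not None:
        lung = lung & ~added_ll & ~added_lr
    imaged_cm3 = lung.sum() * voiset.geometry.voxel_volume_mm3 / 1000.0
    if reference_lung_volume_cm3 < imaged_cm3 * (1 - 1e-9):
        raise MaskError(
            f"reference lung volume {reference_lung_volume_cm3:.1f} cm^3 is smaller "
            f"than the imaged volume {imaged_cm3:.1f} cm^3"
        )
    geom = voiset.geometry
    if not spect.geometry.approx_equal(geom):
        raise GeometryError("SPECT volume and VOISet are not on one grid")

    axis, sign = geom.patient_axis(2)
    face = -1 if sign > 0 else 0
    face_slice = [slice(None)] * 3
    face_slice[axis] = face
    touches = bool(lung[tuple(face_slice)].any())

    if not touches:
        if reference_lung_volume_cm3 > imaged_cm3 * (1 + discrepancy_warn_fraction):
            log.warning(
                "reference lung volume %.0f cm^3 exceeds imaged %.0f cm^3 by >%.0f%% "
                "but the lung does not touch the superior image face; no crop "
                "correction applied",
                reference_lung_volume_cm3, imaged_cm3, 100 * discrepancy_warn_fraction,
            )
        return voiset

    missing_cm3 = max(reference_lung_volume_cm3 - imaged_cm3, 0.0)
    if missing_cm3 == 0.0:
        corr = CropCorrection(reference_lung_volume_cm3, imaged_cm3, 0.0, 0.0, apex_window_mm)
        return replace(voiset, crop_correction=corr)

    # patient-z of every lung voxel; apex window = top `apex_window_mm`
    idx = np.argwhere(lung)
    z = geom.index_to_mm(idx)[:, 2]
    zmax = z.max()
    in_window = z >= zmax - apex_window_mm
    sel = idx[in_window]
    counts = spect.voxels[sel[:, 0], sel[:, 1], sel[:, 2]].sum()
    window_cm3 = len(sel) * geom.voxel_volume_mm3 / 1000.0
    conc = counts / window_cm3 if window_cm3 > 0 else 0.0
    added = conc * missing_cm3
    corr = CropCorrection(
        reference_lung_volume_cm3,
        imaged_cm3,
        missing_cm3 / reference_lung_volume_cm3,
        float(added),
        apex_window_mm,
    )
    log.warning(
        "lung touches the superior image face: imputing %.0f counts for %.0f cm^3 "
        "of missing lung (%.1f%% of reference)",
        added, missing_cm3, 100 * corr.estimated_missing_fraction,
    )
    return replace(voiset, crop_correction=corr)


# --------------------------------------------------------------------------- #
_LABEL_VALUES = {MaskLabel.LIVER: 1, MaskLabel.LUNG_LEFT: 2, MaskLabel.LUNG_RIGHT: 3}


def export_label_volume(voiset: VOISet, path) -> None:
    """Write the VOISet as a NIfTI label volume (0 bg, 1 liver, 2 left lung,
    3 right lung) on the SPECT grid."""
    labels = np.zeros(voiset.geometry.shape, dtype=np.int16)
    for label, m in voiset.masks().items():
        labels[m.mask] = _LABEL_VALUES[label]
    affine_ras = _RAS2LPS @ voiset.geometry.matrix
    nib.save(nib.Nifti1Image(labels, affine_ras), str(path))
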