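"""Liver and lung masks on the CT grid.

Three providers, in decreasing order of clinical fidelity:

* :func:`load_masks` — user-supplied mask files (e.g. exported from an ML
  segmenter) on the CT grid;
* :func:`run_external_segmenter` — out-of-process adapter around an external
  ML segmentation command (TotalSegmentator-style); never required by tests;
* :func:`threshold_segment_ct` — Hounsfield-window segmentation, adequate for
  phantoms and synthetic studies where organ densities are controlled.
"""

from __future__ import annotations

import enum
import logging
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import ExternalToolError, MaskError, SegmentationError
from .geometry import AffineGeometry
from .images import ImageVolume, Modality, _lps_geometry_from_nifti

__all__ = [
    "MaskLabel",
    "MaskSource",
    "OrganMask",
    "load_masks",
    "threshold_segment_ct",
    "run_external_segmenter",
]

log = logging.getLogger("lsfquant")


class MaskLabel(str, enum.Enum):
    LIVER = "LIVER"
    LUNG_LEFT = "LUNG_LEFT"
    LUNG_RIGHT = "LUNG_RIGHT"


class MaskSource(str, enum.Enum):
    FILE = "FILE"
    THRESHOLD = "THRESHOLD"
    EXTERNAL_ML = "EXTERNAL_ML"
    AUGMENTED = "AUGMENTED"


@dataclass
class OrganMask:
    """A binary organ mask on a stated grid."""

    label: MaskLabel
    mask: np.ndarray
    geometry: AffineGeometry
    source: MaskSource
    allow_empty: bool = False

    def __post_init__(self):
        self.label = MaskLabel(self.label)
        self.source = MaskSource(self.source)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise MaskError(
                f"{self.label.value}: mask shape {self.mask.shape} != grid "
                f"shape {self.geometry.shape}"
            )
        if not self.allow_empty and not self.mask.any():
            raise MaskError(f"{self.label.value}: mask is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        """True-voxel count x voxel volume, in cm^3."""
        return self.voxel_count * self.geometry.voxel_volume_mm3 / 1000.0

    def with_mask(self, mask, source=None) -> "OrganMask":
        return replace(
            self, mask=mask, source=self.source if source is None else source,
            allow_empty=True,
        )


# --------------------------------------------------------------------------- #
def load_masks(paths: dict, ct: ImageVolume) -> list[OrganMask]:
    """Load per-organ mask files (NIfTI) onto the CT grid.

    Values are binarised at 0.5, so probabilistic maps are accepted.  Each
    file's grid must match the CT grid within 1e-3 mm.
    """
    masks = []
    for label, path in paths.items():
        label = MaskLabel(label)
        img = nib.load(str(path))
        geom = _lps_geometry_from_nifti(img)
        if not geom.approx_equal(ct.geometry, tol_mm=1e-3):
            raise MaskError(
                f"{label.value} mask grid does not match the CT grid:\n"
                f"  mask: {geom.describe()}\n  ct:   {ct.geometry.describe()}"
            )
        data = np.squeeze(np.asanyarray(img.dataobj, dtype=float))
        masks.append(OrganMask(label, data > 0.5, ct.geometry, MaskSource.FILE))
    return masks


# --------------------------------------------------------------------------- #
def threshold_segment_ct(
    ct: ImageVolume,
    lung_hu_window: tuple = (-950.0, -300.0),
    liver_hu_window: tuple = (-50.0, 200.0),
    min_lung_cm3: float = 50.0,
) -> list[OrganMask]:
    """Hounsfield-window segmentation of liver and both lungs.

    Lungs: voxels inside ``lung_hu_window``, connected-component filtered to
    the two largest components (each at least ``min_lung_cm3``), split into
    left/right by the component centroid on the patient L-R axis.  Liver:
    largest component inside ``liver_hu_window``.  Holes are filled per organ.
    """
    if ct.modality != Modality.CT:
        raise SegmentationError("threshold segmentation requires a CT volume")
    vox_cm3 = ct.geometry.voxel_volume_mm3 / 1000.0

    lung_bin = (ct.voxels >= lung_hu_window[0]) & (ct.voxels <= lung_hu_window[1])
    labels, n = ndimage.label(lung_bin)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    else:
        sizes = np.array([])
    big = [(int(sz), i + 1) for i, sz in enumerate(sizes) if sz * vox_cm3 >= min_lung_cm3]
    if len(big) < 2:
        raise SegmentationError(
            f"found {len(big)} lung component(s) >= {min_lung_cm3} cm^3 in window "
            f"{lung_hu_window}; supply mask files instead"
        )
    big.sort(reverse=True)
    comp_a, comp_b = big[0], big[1]

    def _centroid_lr(comp_id):
        idx = np.array(ndimage.center_of_mass(lung_bin, labels, comp_id))
        return ct.geometry.index_to_mm(idx)[0]  # LPS x: +x is patient LEFT

    xa, xb = _centroid_lr(comp_a[1]), _centroid_lr(comp_b[1])
    if np.isclose(xa, xb):
        # tie on the L-R axis: the larger component is the RIGHT lung
        right_id, left_id = comp_a[1], comp_b[1]
    elif xa > xb:
        left_id, right_id = comp_a[1], comp_b[1]
    else:
        left_id, right_id = comp_b[1], comp_a[1]

    lung_left = ndimage.binary_fill_holes(labels == left_id)
    lung_right = ndimage.binary_fill_holes(labels == right_id)

    liver_bin = (ct.voxels >= liver_hu_window[0]) & (ct.voxels <= liver_hu_window[1])
    liver_lab, nl = ndimage.label(liver_bin)
    if nl == 0:
        raise SegmentationError(
            f"no voxels in the liver window {liver_hu_window}; supply mask files"
        )
    liver_sizes = ndimage.sum_labels(
        np.ones_like(liver_lab), liver_lab, index=np.arange(1, nl + 1)
    )
    liver = ndimage.binary_fill_holes(liver_lab == (int(np.argmax(liver_sizes)) + 1))
    liver &= ~(lung_left | lung_right)  # hole-filling must not swallow lung

    geom = ct.geometry
    return [
        OrganMask(MaskLabel.LIVER, liver, geom, MaskSource.THRESHOLD),
        OrganMask(MaskLabel.LUNG_LEFT, lung_left, geom, MaskSource.THRESHOLD),
        OrganMask(MaskLabel.LUNG_RIGHT, lung_right, geom, MaskSource.THRESHOLD),
    ]


# --------------------------------------------------------------------------- #
_DEFAULT_OUTPUT_NAMES = {
    MaskLabel.LIVER: "liver.nii.gz",
    MaskLabel.LUNG_LEFT: "lung_left.nii.gz",
    MaskLabel.LUNG_RIGHT: "lung_right.nii.gz",
}


def run_external_segmenter(
    ct_path,
    command_template: str,
    outdir=None,
    output_names: dict | None = None,
    timeout: float | None = None,
) -> dict:
    """Invoke an external ML segmenter out-of-process and collect its masks.

    ``command_template`` is a shell command with ``{input}`` and ``{outdir}``
    placeholders, e.g. ``"TotalSegmentator -i {input} -o {outdir} --fast"``.
    ``output_names`` maps each :class:`MaskLabel` to the file name the tool
    writes (label naming is configuration, not an assumption).  Returns a
    label -> path map suitable for :func:`load_masks`.
    """
    outdir = Path(outdir) if outdir else Path(tempfile.mkdtemp(prefix="lsfquant_seg_"))
    outdir.mkdir(parents=True, exist_ok=True)
    names = dict(_DEFAULT_OUTPUT_NAMES)
    if output_names:
        names.update({MaskLabel(k): v for k, v in output_names.items()})

    cmd = command_template.format(input=str(ct_path), outdir=str(outdir))
    proc = subprocess.run(
        cmd, shell=True, capture_output=True, text=True, timeout=timeout
    )
    plog = (proc.stdout or "") + (proc.stderr or "")
    if proc.returncode != 0:
        raise ExternalToolError(
            f"external segmenter exited with code {proc.returncode}: {cmd}", log=plog
        )
    result, missing = {}, []
    for label, name in names.items():
        path = outdir / name
        if path.exists():
            result[label] = path
        else:
            missing.append(f"{label.value} ({name})")
    if missing:
        raise ExternalToolError(
            "external segmenter did not produce: " + ", ".join(missing), log=plog
        )
    return result
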