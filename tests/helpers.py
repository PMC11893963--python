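"""Shared test utilities: a minimal DICOM CT series writer and brute-force
oracles for resampling and VOI augmentation (deliberately independent of the
library's fast paths)."""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from lsfquant.geometry import AffineGeometry
from lsfquant.segmentation import MaskLabel


# --------------------------------------------------------------------------- #
# DICOM writing
# --------------------------------------------------------------------------- #
def write_ct_series(
    dirpath,
    volume: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    frame_uid=None,
    superior_first=False,
    frame_uid_per_slice=None,
    gap_jitter_mm=None,
):
    """Write ``volume[i, j, k]`` as an axial CT series (identity orientation).

    ``superior_first`` writes the slice files in reversed z order (the reader
    must sort geometrically).  ``frame_uid_per_slice`` / ``gap_jitter_mm``
    inject the error conditions the reader must reject.
    """
    dirpath.mkdir(parents=True, exist_ok=True)
    frame_uid = frame_uid or generate_uid()
    series_uid, study_uid = generate_uid(), generate_uid()
    nk = volume.shape[2]
    order = range(nk - 1, -1, -1) if superior_first else range(nk)
    vol_u16 = np.clip(np.rint(volume), 0, 65535).astype(np.uint16)

    for file_index, k in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = (
            frame_uid_per_slice[k] if frame_uid_per_slice else frame_uid
        )
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z = origin[2] + k * spacing[2]
        if gap_jitter_mm and k in gap_jitter_mm:
            z += gap_jitter_mm[k]
        ds.ImagePositionPatient = [origin[0], origin[1], z]
        ds.PixelSpacing = [spacing[1], spacing[0]]  # [row, col] mm
        ds.SliceThickness = spacing[2]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[0]
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = vol_u16[:, :, k].T.tobytes()  # rows = j, cols = i
        ds.save_as(dirpath / f"slice{file_index:03d}.dcm", enforce_file_format=True)
    return frame_uid


# --------------------------------------------------------------------------- #
# Brute-force oracles
# --------------------------------------------------------------------------- #
def resample_oracle(mask: np.ndarray, src: AffineGeometry, tgt: AffineGeometry):
    """Per-voxel-centre loop: map each target index to mm, back to a
    continuous source index, round, look up."""
    out = np.zeros(tgt.shape, dtype=bool)
    for idx in np.ndindex(tgt.shape):
        mm = tgt.index_to_mm(np.array(idx, dtype=float))
        si = src.mm_to_index(mm)
        n = np.rint(si).astype(int)
        if np.all(n >= 0) and np.all(n < np.array(src.shape)):
            out[idx] = mask[tuple(n)]
    return out


def _offsets(spacing, radius, cc_extra, cc_axis=2):
    semi = np.array([float(radius)] * 3)
    semi[cc_axis] += cc_extra
    if np.all(semi == 0):
        return [(0, 0, 0)]
    half = np.floor(semi / np.asarray(spacing, float)).astype(int)
    offs = []
    for dx in range(-half[0], half[0] + 1):
        for dy in range(-half[1], half[1] + 1):
            for dz in range(-half[2], half[2] + 1):
                q = 0.0
                for d, s, a in zip((dx, dy, dz), spacing, semi):
                    if a > 0:
                        q += (d * s / a) ** 2
                    elif d != 0:
                        q = np.inf
                if q <= 1.0 + 1e-12:
                    offs.append((dx, dy, dz))
    return offs


def _shift(mask, off):
    out = np.zeros_like(mask)
    src, dst = [], []
    for d, n in zip(off, mask.shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    if all(s.stop > s.start if s.stop is not None else True for s in src):
        out[tuple(dst)] = mask[tuple(src)]
    return out


def dilate_oracle(mask, spacing, radius, cc_extra, cc_axis=2):
    out = np.zeros_like(mask)
    for off in _offsets(spacing, radius, cc_extra, cc_axis):
        out |= _shift(mask, off)
    return out


def _min_dist_mm(points_mm, target_mm):
    if len(points_mm) == 0:
        return np.inf
    return float(np.sqrt(((points_mm - target_mm) ** 2).sum(axis=1)).min())


def augment_oracle(liver, lung_left, lung_right, spacing, params, cc_axis=2):
    """Brute-force precedence evaluation over every voxel.

    Tiers: original lung > original liver > augmented lung (nearer original
    lung wins; tie -> right) > augmented liver.  Returns final boolean masks
    keyed by :class:`MaskLabel`.
    """
    d_ll = dilate_oracle(lung_left, spacing, params.lung_radius_mm,
                         params.extra_cranio_caudal_mm, cc_axis)
    d_lr = dilate_oracle(lung_right, spacing, params.lung_radius_mm,
                         params.extra_cranio_caudal_mm, cc_axis)
    d_liver = dilate_oracle(liver, spacing, params.liver_radius_mm,
                            params.extra_cranio_caudal_mm, cc_axis)
    sp = np.asarray(spacing, float)
    pts_l = np.argwhere(lung_left) * sp
    pts_r = np.argwhere(lung_right) * sp

    out = {
        MaskLabel.LIVER: np.zeros_like(liver),
        MaskLabel.LUNG_LEFT: np.zeros_like(liver),
        MaskLabel.LUNG_RIGHT: np.zeros_like(liver),
    }
    for idx in np.ndindex(liver.shape):
        if lung_left[idx]:
            out[MaskLabel.LUNG_LEFT][idx] = True
        elif lung_right[idx]:
            out[MaskLabel.LUNG_RIGHT][idx] = True
        elif liver[idx]:
            out[MaskLabel.LIVER][idx] = True
        elif d_ll[idx] or d_lr[idx]:
            if d_ll[idx] and d_lr[idx]:
                mm = np.array(idx) * sp
                if _min_dist_mm(pts_l, mm) + 1e-9 < _min_dist_mm(pts_r, mm):
                    out[MaskLabel.LUNG_LEFT][idx] = True
                else:
                    out[MaskLabel.LUNG_RIGHT][idx] = True
            elif d_ll[idx]:
                out[MaskLabel.LUNG_LEFT][idx] = True
            else:
                out[MaskLabel.LUNG_RIGHT][idx] = True
        elif d_liver[idx]:
            out[MaskLabel.LIVER][idx] = True
    return out
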