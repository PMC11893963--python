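"""End-to-end convenience pipeline: CT masks -> SPECT VOIs -> LSF.

Thin orchestration over the module surface, shared by the CLI, the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

from .images import ImageVolume
from .quantify import CountSummary, LSFResult, lsf_3d, organ_counts
from .segmentation import MaskLabel, OrganMask
from .voi import AugmentationParams, VOISet, augment_vois, correct_cropped_lung, resample_mask

__all__ = ["SpectPipelineOutput", "spect_lsf_pipeline"]


@dataclass
class SpectPipelineOutput:
    voiset: VOISet
    counts: CountSummary
    result: LSFResult
    pre_augmentation_volumes_cm3: dict


def spect_lsf_pipeline(
    spect: ImageVolume,
    masks,
    params: AugmentationParams = AugmentationParams(),
    reference_lung_volume_cm3: float | None = None,
) -> SpectPipelineOutput:
    """Resample CT-grid organ masks to the SPECT grid, augment, count, LSF.

    ``masks`` is an iterable of liver / left-lung / right-lung
    :class:`OrganMask` (any grid sharing the SPECT frame of reference).
    When ``reference_lung_volume_cm3`` is given, a cropped lung apex is
    detected and its counts imputed.
    """
    by_label: dict[MaskLabel, OrganMask] = {m.label: m for m in masks}
    missing = {MaskLabel.LIVER, MaskLabel.LUNG_LEFT, MaskLabel.LUNG_RIGHT} - set(by_label)
    if missing:
        raise ValueError(f"missing masks: {sorted(m.value for m in missing)}")

    resampled = {
        label: resample_mask(m, spect.geometry) for label, m in by_label.items()
    }
    pre_volumes = {label.value: m.volume_cm3 for label, m in resampled.items()}
    voiset = augment_vois(
        resampled[MaskLabel.LIVER],
        resampled[MaskLabel.LUNG_LEFT],
        resampled[MaskLabel.LUNG_RIGHT],
        params,
    )
    if reference_lung_volume_cm3 is not None:
        voiset = correct_cropped_lung(voiset, spect, reference_lung_volume_cm3)
    counts = organ_counts(spect, voiset)
    result = lsf_3d(
        counts,
        parameters={
            "augmentation": params.as_dict(),
            "crop_correction": voiset.crop_correction.as_dict()
            if voiset.crop_correction
            else None,
        },
    )
    return SpectPipelineOutput(voiset, counts, result, pre_volumes)
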