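"""Mask resampling, VOI augmentation with lung-priority overlap resolution,
crop correction, and mask volumes — each checked against brute-force oracles."""

import numpy as np
import pytest

from lsfquant import (
    AugmentationParams,
    ImageVolume,
    MaskError,
    MaskLabel,
    MaskSource,
    Modality,
    NoiseModel,
    OrganMask,
    PhantomSpec,
    augment_vois,
    build_phantom,
    correct_cropped_lung,
    mask_volume,
    resample_mask,
    spect_lsf_pipeline,
)
from lsfquant.geometry import AffineGeometry

from helpers import augment_oracle, resample_oracle

RNG = np.random.default_rng(20240915)


def _mask(label, arr, geom, allow_empty=False):
    return OrganMask(label, arr, geom, MaskSource.FILE, allow_empty=allow_empty)


def _geom(spacing, origin, shape):
    return AffineGeometry.from_components(spacing, origin, None, shape)


# --------------------------------------------------------------------------- #
# resample_mask
# --------------------------------------------------------------------------- #
def test_identity_resample_is_bit_identical():
    geom = _geom((2, 2, 2), (0, 0, 0), (10, 10, 10))
    arr = RNG.random((10, 10, 10)) > 0.6
    m = _mask(MaskLabel.LIVER, arr, geom)
    out = resample_mask(m, geom)
    assert np.array_equal(out.mask, arr)


def test_cube_volume_preserved_within_voxel_shell():
    """A 20 mm cube on a 1 mm grid resampled to 4.8 mm keeps its 8 cm^3
    volume within one target-voxel surface shell."""
    src = _geom((1, 1, 1), (0, 0, 0), (40, 40, 40))
    arr = np.zeros((40, 40, 40), dtype=bool)
    arr[10:30, 10:30, 10:30] = True  # 20 mm cube, 8 cm^3
    m = _mask(MaskLabel.LIVER, arr, src)
    tgt = _geom((4.8, 4.8, 4.8), (0.4, 0.4, 0.4), (9, 9, 9))
    out = resample_mask(m, tgt)
    # oracle equality
    assert np.array_equal(out.mask, resample_oracle(arr, src, tgt))
    # one-voxel-shell volume bound: cube face area 6*(20 mm)^2 x 4.8 mm
    shell_cm3 = 6 * 20 * 20 * 4.8 / 1000.0
    assert abs(mask_volume(out) - 8.0) <= shell_cm3


def test_mask_outside_target_extent_is_empty_with_warning(caplog):
    src = _geom((1, 1, 1), (0, 0, 0), (5, 5, 5))
    m = _mask(MaskLabel.LUNG_LEFT, np.ones((5, 5, 5), bool), src)
    tgt = _geom((1, 1, 1), (1000, 1000, 1000), (5, 5, 5))
    with caplog.at_level("WARNING", logger="lsfquant"):
        out = resample_mask(m, tgt)
    assert not out.mask.any()
    assert "empty after resampling" in caplog.text


@pytest.mark.parametrize("trial", range(8))
def test_resample_equals_voxel_centre_loop_oracle(trial):
    """Nearest-neighbour fast path is set-identical to a per-voxel-centre
    loop on random source/target geometries (grid ratios up to ~5)."""
    rng = np.random.default_rng(100 + trial)
    src_sp = rng.uniform(0.8, 4.0, 3)
    tgt_sp = rng.uniform(0.8, 5.0, 3)
    src = _geom(src_sp, rng.uniform(-5, 5, 3), (12, 11, 13))
    tgt = _geom(tgt_sp, rng.uniform(-5, 5, 3), (9, 10, 8))
    arr = rng.random((12, 11, 13)) > 0.5
    m = _mask(MaskLabel.LIVER, arr, src, allow_empty=True)
    fast = resample_mask(m, tgt).mask
    assert np.array_equal(fast, resample_oracle(arr, src, tgt))


# --------------------------------------------------------------------------- #
# augment_vois
# --------------------------------------------------------------------------- #
def _three_masks(geom, liver, ll, lr):
    return (
        _mask(MaskLabel.LIVER, liver, geom, allow_empty=True),
        _mask(MaskLabel.LUNG_LEFT, ll, geom, allow_empty=True),
        _mask(MaskLabel.LUNG_RIGHT, lr, geom, allow_empty=True),
    )


def test_zero_radii_is_identity():
    geom = _geom((2, 2, 2), (0, 0, 0), (12, 12, 12))
    liver = np.zeros((12, 12, 12), bool)
    ll = np.zeros_like(liver)
    lr = np.zeros_like(liver)
    liver[2:5, 2:5, 2:5] = True
    ll[8:10, 8:10, 8:10] = True
    lr[8:10, 2:4, 2:4] = True
    vs = augment_vois(*_three_masks(geom, liver, ll, lr), AugmentationParams(0, 0, 0))
    assert np.array_equal(vs.liver.mask, liver)
    assert np.array_equal(vs.lung_left.mask, ll)
    assert np.array_equal(vs.lung_right.mask, lr)
    assert not any(p.any() for p in vs.provenance.values())


def test_single_voxel_dilates_to_metric_cross():
    """One liver voxel on a 2 mm grid with a 2 mm radius becomes the 7-voxel
    6-connected cross (offsets with Euclidean mm norm <= 2)."""
    geom = _geom((2, 2, 2), (0, 0, 0), (7, 7, 7))
    liver = np.zeros((7, 7, 7), bool)
    liver[3, 3, 3] = True
    ll = np.zeros_like(liver)
    lr = np.zeros_like(liver)
    ll[0, 0, 0] = lr[6, 6, 6] = True  # far away
    vs = augment_vois(
        *_three_masks(geom, liver, ll, lr), AugmentationParams(2.0, 0.0, 0.0)
    )
    expected = np.zeros_like(liver)
    for off in [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
        expected[3 + off[0], 3 + off[1], 3 + off[2]] = True
    assert np.array_equal(vs.liver.mask & ~ll & ~lr, expected)


def test_contested_gap_voxels_go_to_lung():
    """Liver and lung cubes one voxel apart, both radii one voxel: every
    contested gap voxel is assigned to the lung (oracle comparison)."""
    geom = _geom((2, 2, 2), (0, 0, 0), (14, 6, 14))
    liver = np.zeros((14, 6, 14), bool)
    lr = np.zeros_like(liver)
    ll = np.zeros_like(liver)
    liver[4:9, 1:5, 2:6] = True
    lr[4:9, 1:5, 7:11] = True  # gap of one voxel at k == 6
    ll[12:14, 1:5, 7:11] = True
    params = AugmentationParams(2.0, 2.0, 0.0)
    vs = augment_vois(*_three_masks(geom, liver, ll, lr), params)
    oracle = augment_oracle(liver, ll, lr, (2, 2, 2), params)
    for label, m in vs.masks().items():
        assert np.array_equal(m.mask, oracle[label]), label
    # the gap layer adjacent to both organs belongs to the lung
    gap = np.zeros_like(liver)
    gap[4:9, 1:5, 6] = True
    assert (vs.lung_right.mask & gap).sum() == gap.sum()


def test_augment_rejects_overlapping_inputs():
    geom = _geom((2, 2, 2), (0, 0, 0), (6, 6, 6))
    a = np.zeros((6, 6, 6), bool)
    a[2:4, 2:4, 2:4] = True
    with pytest.raises(MaskError, match="overlap"):
        augment_vois(*_three_masks(geom, a, a, np.zeros_like(a)))


def test_dilation_extensive_and_monotone():
    geom = _geom((3, 3, 3), (0, 0, 0), (16, 16, 16))
    rng = np.random.default_rng(7)
    liver = np.zeros((16, 16, 16), bool)
    liver[3:7, 3:7, 3:7] = True
    ll = np.zeros_like(liver)
    ll[10:13, 10:13, 10:13] = True
    lr = np.zeros_like(liver)
    lr[10:13, 3:6, 3:6] = True
    masks = _three_masks(geom, liver, ll, lr)
    prev_sizes = None
    for r in (0.0, 3.0, 6.0, 9.0):
        vs = augment_vois(*masks, AugmentationParams(r, r, 0.0))
        # extensive: originals always kept
        assert (vs.liver.mask & liver).sum() == liver.sum()
        assert (vs.lung_left.mask & ll).sum() == ll.sum()
        assert (vs.lung_right.mask & lr).sum() == lr.sum()
        sizes = [vs.liver.voxel_count, vs.lung_left.voxel_count, vs.lung_right.voxel_count]
        if prev_sizes is not None:
            assert all(s >= p for s, p in zip(sizes, prev_sizes))
        prev_sizes = sizes


@pytest.mark.parametrize("case", range(100))
def test_augmentation_fuzz_against_bruteforce_oracle(case):
    """Randomized adjacent masks and radii: finalized VOIs equal the
    brute-force precedence oracle; liver and lungs stay disjoint; no
    original lung voxel is ever lost."""
    rng = np.random.default_rng(5000 + case)
    shape = tuple(rng.integers(8, 13, 3))
    spacing = rng.choice([1.0, 2.0, 3.0], 3)
    geom = _geom(spacing, (0, 0, 0), shape)

    def blob():
        m = np.zeros(shape, bool)
        lo = [rng.integers(0, s - 3) for s in shape]
        hi = [l + rng.integers(1, 4) for l in lo]
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return m

    liver, ll, lr = blob(), blob(), blob()
    ll &= ~liver
    lr &= ~(liver | ll)
    params = AugmentationParams(
        float(rng.choice([0, 2, 4, 6])),
        float(rng.choice([0, 2, 4, 6])),
        float(rng.choice([0, 2, 4])),
    )
    vs = augment_vois(*_three_masks(geom, liver, ll, lr), params)
    oracle = augment_oracle(liver, ll, lr, spacing, params)
    for label, m in vs.masks().items():
        assert np.array_equal(m.mask, oracle[label]), (label, params)
    assert not (vs.liver.mask & (vs.lung_left.mask | vs.lung_right.mask)).any()
    assert ((vs.lung_left.mask | vs.lung_right.mask) & (ll | lr)).sum() == (ll | lr).sum()


# --------------------------------------------------------------------------- #
# mask_volume
# --------------------------------------------------------------------------- #
def test_mask_volume_simple_and_empty():
    geom = _geom((1, 1, 1), (0, 0, 0), (10, 10, 10))
    arr = np.zeros((10, 10, 10), bool)
    arr.flat[:1000] = True
    assert mask_volume(_mask(MaskLabel.LIVER, arr, geom)) == pytest.approx(1.0)
    empty = _mask(MaskLabel.LIVER, np.zeros_like(arr), geom, allow_empty=True)
    assert mask_volume(empty) == 0.0


def test_mask_volume_matches_closed_form_ellipsoid():
    """Rasterized (60, 50, 40) mm semi-axis ellipsoid volume is within 1% of
    (4/3) pi abc."""
    geom = _geom((1, 1, 1), (-65, -55, -45), (130, 110, 90))
    idx = np.indices(geom.shape, dtype=float).reshape(3, -1).T
    mm = geom.index_to_mm(idx)
    rel = mm / np.array([60.0, 50.0, 40.0])
    arr = ((rel**2).sum(axis=1) <= 1).reshape(geom.shape)
    vol = mask_volume(_mask(MaskLabel.LIVER, arr, geom))
    analytic = 4 / 3 * np.pi * 60 * 50 * 40 / 1000.0
    assert vol == pytest.approx(analytic, rel=0.01)


# --------------------------------------------------------------------------- #
# correct_cropped_lung
# --------------------------------------------------------------------------- #
def _simple_voiset_and_spect(lung_top_touches=True):
    shape = (10, 10, 12)
    geom = _geom((4, 4, 4), (0, 0, 0), shape)
    liver = np.zeros(shape, bool)
    liver[2:8, 2:8, 0:3] = True
    ll = np.zeros(shape, bool)
    lr = np.zeros(shape, bool)
    top = shape[2] if lung_top_touches else shape[2] - 2
    ll[6:9, 2:8, 5:top] = True
    lr[1:4, 2:8, 5:top] = True
    vs = augment_vois(*_three_masks(geom, liver, ll, lr), AugmentationParams(0, 0, 0))
    spect = ImageVolume(np.full(shape, 2.0), geom, Modality.SPECT_AC)
    return vs, spect


def test_no_crop_when_lung_clear_of_superior_face(caplog):
    vs, spect = _simple_voiset_and_spect(lung_top_touches=False)
    imaged = vs.lung_left.volume_cm3 + vs.lung_right.volume_cm3
    with caplog.at_level("WARNING", logger="lsfquant"):
        out = correct_cropped_lung(vs, spect, reference_lung_volume_cm3=imaged * 1.5)
    assert out.crop_correction is None
    assert "no crop correction" in caplog.text


def test_zero_missing_volume_imputes_zero_counts():
    vs, spect = _simple_voiset_and_spect(lung_top_touches=True)
    imaged = vs.lung_left.volume_cm3 + vs.lung_right.volume_cm3
    out = correct_cropped_lung(vs, spect, reference_lung_volume_cm3=imaged)
    assert out.crop_correction is not None
    assert out.crop_correction.added_counts == 0.0
    assert out.crop_correction.estimated_missing_fraction == 0.0


def test_crop_correction_recovers_cropped_phantom_counts():
    """Cropping ~10% of a uniform-concentration lung and supplying the true
    reference volume restores total lung counts within 2% of the uncropped
    study."""
    base = dict(
        seed=11, noise=NoiseModel.NONE, psf_fwhm_mm=0.0,
        target_total_counts=None, counts_per_mbq=5000.0,
    )
    full = build_phantom(PhantomSpec(**base))
    ref = (
        full.truth_mask(MaskLabel.LUNG_LEFT).volume_cm3
        + full.truth_mask(MaskLabel.LUNG_RIGHT).volume_cm3
    )
    uncropped = spect_lsf_pipeline(
        full.spect, full.truth_masks, AugmentationParams(0, 0, 0)
    )
    # FOV cut: 40 mm superior margin + 45 mm into the lung apex
    cropped_study = build_phantom(PhantomSpec(**base, spect_superior_crop_mm=85.0))
    out = spect_lsf_pipeline(
        cropped_study.spect,
        cropped_study.truth_masks,
        AugmentationParams(0, 0, 0),
        reference_lung_volume_cm3=ref,
    )
    corr = out.voiset.crop_correction
    assert corr is not None
    assert 0.05 < corr.estimated_missing_fraction < 0.2
    assert out.counts.total_lung == pytest.approx(uncropped.counts.total_lung, rel=0.02)


def test_reference_smaller_than_imaged_rejected():
    vs, spect = _simple_voiset_and_spect()
    with pytest.raises(MaskError, match="smaller"):
        correct_cropped_lung(vs, spect, reference_lung_volume_cm3=1.0)
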