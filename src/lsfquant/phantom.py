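"""Digital liver/lung phantom and acquisition simulator.

In-silico stand-in for a fillable anthropomorphic liver/lung phantom scanned
on a SPECT/CT system: three ellipsoidal compartments (liver, left lung,
right lung) with configurable Tc-99m activity concentrations, material
densities and attenuation, system blur, cranio-caudal respiratory motion and
Poisson counting noise.  It emits

* a CT volume (HU from the material map, with seeded speckle in bead-filled
  lungs),
* ground-truth organ masks on both the CT and the emulated SPECT grid,
* an emulated attenuation-corrected SPECT reconstruction (activity map ->
  motion blur -> Gaussian PSF -> count scaling -> optional Poisson draw),
* attenuated anterior/posterior planar projections (Beer-Lambert line
  integrals; the posterior view is recorded mirrored, as a camera would),
* assayed ground-truth activities and the resulting true LSF.

The simulator emulates the *reconstructed* AC SPECT directly rather than
projecting and running an OSEM engine: the LSF is a count ratio and is
robust to reconstruction corrections, so the quantification layer can be
exercised without a tomographic reconstruction code.

Four acquisition scenarios mirror the physical phantom experiments:
A (patient configuration, bead-filled lungs), B (liver and lungs separated
by an extra 10 cm), C (water-filled lungs), D (separated + water-filled).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import PhantomError, UndefinedLSFError
from .geometry import AffineGeometry
from .images import ImageVolume, Modality, PlanarImage, View
from .quantify import GroundTruthActivities, lsf_ground_truth
from .segmentation import MaskLabel, MaskSource, OrganMask

__all__ = [
    "Material",
    "LungFill",
    "NoiseModel",
    "Compartment",
    "PhantomSpec",
    "PhantomStudy",
    "build_phantom",
    "simulate_spect",
    "simulate_planar",
]

log = logging.getLogger("lsfquant")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class Material(str, enum.Enum):
    WATER = "WATER"
    BEAD_LUNG = "BEAD_LUNG"  # water + styrofoam beads, lung-like density
    AIR = "AIR"


#: Hounsfield units per material (bead lungs get seeded speckle on top).
DEFAULT_HU = {Material.WATER: 0.0, Material.BEAD_LUNG: -700.0, Material.AIR: -1000.0}

#: Linear attenuation coefficients at 140 keV, cm^-1.
DEFAULT_MU_CM = {Material.WATER: 0.154, Material.BEAD_LUNG: 0.05, Material.AIR: 0.0}


class LungFill(str, enum.Enum):
    WATER = "WATER"
    BEADS = "BEADS"


class NoiseModel(str, enum.Enum):
    NONE = "NONE"
    POISSON = "POISSON"


@dataclass(frozen=True)
class Compartment:
    """One ellipsoidal fillable compartment in patient LPS mm."""

    label: MaskLabel
    center_mm: tuple
    semi_axes_mm: tuple
    material: Material
    concentration_mbq_per_ml: float

    def __post_init__(self):
        if self.concentration_mbq_per_ml < 0:
            raise PhantomError("activity concentration must be >= 0")
        if min(self.semi_axes_mm) <= 0:
            raise PhantomError("ellipsoid semi-axes must be positive")

    @property
    def analytic_volume_cm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def indicator(self, geometry: AffineGeometry) -> np.ndarray:
        """Rasterize by voxel centre: inside iff the ellipsoid inequality
        holds at the centre."""
        idx = np.indices(geometry.shape, dtype=float).reshape(3, -1).T
        mm = geometry.index_to_mm(idx)
        rel = (mm - np.asarray(self.center_mm)) / np.asarray(self.semi_axes_mm)
        inside = (rel**2).sum(axis=1) <= 1.0
        return inside.reshape(geometry.shape)


def _default_compartments() -> dict:
    """Compartments sized to the physical phantom: liver 1785 cm^3, left
    lung 883 cm^3, right lung 1308 cm^3 (lungs 2191 cm^3 total), in patient
    configuration (lungs directly superior to the liver).  Default
    concentrations give a true LSF of ~13.5%."""
    return {
        MaskLabel.LIVER: Compartment(
            MaskLabel.LIVER, (0.0, 0.0, 0.0), (95.0, 75.0, 60.0),
            Material.WATER, 0.10,
        ),
        MaskLabel.LUNG_LEFT: Compartment(
            MaskLabel.LUNG_LEFT, (62.0, 0.0, 140.0), (50.0, 55.0, 76.7),
            Material.BEAD_LUNG, 0.0127,
        ),
        MaskLabel.LUNG_RIGHT: Compartment(
            MaskLabel.LUNG_RIGHT, (-62.0, 0.0, 150.0), (60.0, 60.0, 86.7),
            Material.BEAD_LUNG, 0.0127,
        ),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom + acquisition."""

    compartments: dict = field(default_factory=_default_compartments)
    liver_lung_gap_mm: float = 0.0  # extra cranio-caudal separation (B/D: 100)
    lung_fill: LungFill = LungFill.BEADS
    bead_hu_mean: float = -700.0
    bead_hu_sd: float = 50.0
    attenuation_cm: dict = field(default_factory=lambda: dict(DEFAULT_MU_CM))
    ct_spacing_mm: tuple = (2.4, 2.4, 2.4)
    spect_spacing_mm: tuple = (4.8, 4.8, 4.8)
    margin_mm: tuple = (30.0, 30.0, 40.0)
    psf_fwhm_mm: float = 12.0
    motion_amplitude_mm: float = 0.0  # peak-to-peak cranio-caudal
    motion_phases: int = 21
    noise: NoiseModel = NoiseModel.POISSON
    seed: int = 0
    target_total_counts: float | None = 2.0e6
    counts_per_mbq: float | None = None  # overrides target_total_counts
    planar_target_counts: float | None = 1.0e6  # per view
    spect_superior_crop_mm: float = 0.0  # emulated FOV cut at the lung apex
    frame_of_reference = "phantom"

    # ------------------------------------------------------------------ #
    @classmethod
    def scenario(cls, name: str, **overrides) -> "PhantomSpec":
        """Scenario presets A-D (separation and lung fill)."""
        name = name.upper()
        if name not in "ABCD" or len(name) != 1:
            raise PhantomError(f"unknown scenario {name!r}; expected A, B, C or D")
        kw = {}
        if name in ("B", "D"):
            kw["liver_lung_gap_mm"] = 100.0
        if name in ("C", "D"):
            kw["lung_fill"] = LungFill.WATER
        kw.update(overrides)
        return cls(**kw)

    # ------------------------------------------------------------------ #
    def effective_compartments(self) -> dict:
        """Apply the liver-lung gap and the lung-fill material."""
        out = {}
        for label, c in self.compartments.items():
            if label in (MaskLabel.LUNG_LEFT, MaskLabel.LUNG_RIGHT):
                cx, cy, cz = c.center_mm
                mat = (
                    Material.WATER
                    if self.lung_fill == LungFill.WATER
                    else Material.BEAD_LUNG
                )
                c = replace(
                    c,
                    center_mm=(cx, cy, cz + self.liver_lung_gap_mm),
                    material=mat,
                )
            out[label] = c
        return out

    def _grid(self, spacing, superior_crop_mm=0.0) -> AffineGeometry:
        comps = self.effective_compartments().values()
        lo = np.min(
            [np.asarray(c.center_mm) - np.asarray(c.semi_axes_mm) for c in comps],
            axis=0,
        ) - np.asarray(self.margin_mm)
        hi = np.max(
            [np.asarray(c.center_mm) + np.asarray(c.semi_axes_mm) for c in comps],
            axis=0,
        ) + np.asarray(self.margin_mm)
        hi = hi.copy()
        hi[2] -= superior_crop_mm
        spacing = np.asarray(spacing, dtype=float)
        shape = np.ceil((hi - lo) / spacing).astype(int)
        if np.any(shape < 2):
            raise PhantomError("superior crop removes the whole phantom")
        origin = lo + spacing / 2.0
        return AffineGeometry.from_components(spacing, origin, None, tuple(shape))

    def ct_geometry(self) -> AffineGeometry:
        return self._grid(self.ct_spacing_mm)

    def spect_geometry(self) -> AffineGeometry:
        return self._grid(self.spect_spacing_mm, self.spect_superior_crop_mm)

    def as_dict(self) -> dict:
        return {
            "compartments": {
                label.value: {
                    "center_mm": list(c.center_mm),
                    "semi_axes_mm": list(c.semi_axes_mm),
                    "material": c.material.value,
                    "concentration_mbq_per_ml": c.concentration_mbq_per_ml,
                }
                for label, c in self.compartments.items()
            },
            "liver_lung_gap_mm": self.liver_lung_gap_mm,
            "lung_fill": self.lung_fill.value,
            "attenuation_cm": {m.value: v for m, v in self.attenuation_cm.items()},
            "ct_spacing_mm": list(self.ct_spacing_mm),
            "spect_spacing_mm": list(self.spect_spacing_mm),
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "motion_amplitude_mm": self.motion_amplitude_mm,
            "motion_phases": self.motion_phases,
            "noise": self.noise.value,
            "seed": self.seed,
            "target_total_counts": self.target_total_counts,
            "counts_per_mbq": self.counts_per_mbq,
            "planar_target_counts": self.planar_target_counts,
            "spect_superior_crop_mm": self.spect_superior_crop_mm,
        }


@dataclass
class PhantomStudy:
    """All outputs of one simulated phantom acquisition."""

    spec: PhantomSpec
    ct: ImageVolume
    truth_masks: list  # OrganMask on the CT grid
    spect_truth_masks: list  # OrganMask on the (uncropped) SPECT grid
    activity_map: ImageVolume  # MBq per voxel on the uncropped SPECT grid
    mu_map: np.ndarray  # mm^-1, on the uncropped SPECT grid
    truth: GroundTruthActivities
    true_lsf_percent: float
    spect: ImageVolume | None = None
    planar_ant: PlanarImage | None = None
    planar_post: PlanarImage | None = None
    planar_rois: dict | None = None  # 2D bool arrays, anterior frame

    def truth_mask(self, label: MaskLabel, grid: str = "ct") -> OrganMask:
        masks = self.truth_masks if grid == "ct" else self.spect_truth_masks
        for m in masks:
            if m.label == label:
                return m
        raise KeyError(label)


# --------------------------------------------------------------------------- #
def _rng_streams(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    keys = ("ct_speckle", "spect_noise", "planar_noise")
    return {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}


def build_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Rasterize the phantom, record the ground truth, then simulate the AC
    SPECT and the planar pair."""
    comps = spec.effective_compartments()

    ct_geom = spec.ct_geometry()
    spect_geom_full = spec._grid(spec.spect_spacing_mm)  # truth grid, uncropped

    ct_masks = {label: c.indicator(ct_geom) for label, c in comps.items()}
    sp_masks = {label: c.indicator(spect_geom_full) for label, c in comps.items()}

    labels = list(comps)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if (ct_masks[a] & ct_masks[b]).any() or (sp_masks[a] & sp_masks[b]).any():
                raise PhantomError(f"compartments overlap: {a.value} and {b.value}")

    rngs = _rng_streams(spec.seed)

    # --- CT: HU from materials, speckle in bead lungs ---------------------- #
    hu = np.full(ct_geom.shape, DEFAULT_HU[Material.AIR], dtype=float)
    for label, c in comps.items():
        m = ct_masks[label]
        if c.material == Material.BEAD_LUNG:
            hu[m] = spec.bead_hu_mean + spec.bead_hu_sd * rngs["ct_speckle"].standard_normal(
                int(m.sum())
            )
        else:
            hu[m] = DEFAULT_HU[c.material]
    ct = ImageVolume(hu, ct_geom, Modality.CT, spec.frame_of_reference)

    # --- activity / attenuation maps on the SPECT grid --------------------- #
    vox_ml = spect_geom_full.voxel_volume_mm3 / 1000.0
    activity = np.zeros(spect_geom_full.shape, dtype=float)
    # background is air (mu configurable, e.g. for uniform-medium tests)
    mu = np.full(
        spect_geom_full.shape, spec.attenuation_cm[Material.AIR] / 10.0, dtype=float
    )
    for label, c in comps.items():
        m = sp_masks[label]
        activity[m] += c.concentration_mbq_per_ml * vox_ml
        mu[m] = spec.attenuation_cm[c.material] / 10.0
    activity_map = ImageVolume(
        activity, spect_geom_full, Modality.SPECT_AC, spec.frame_of_reference
    )

    # --- ground truth ------------------------------------------------------ #
    # assayed activity = concentration x rasterized compartment volume, i.e.
    # exactly what was put into each compartment of this digital phantom
    act = {
        label: comps[label].concentration_mbq_per_ml * sp_masks[label].sum() * vox_ml
        for label in comps
    }
    truth = GroundTruthActivities(
        right_lung_mbq=act[MaskLabel.LUNG_RIGHT],
        left_lung_mbq=act[MaskLabel.LUNG_LEFT],
        liver_mbq=act[MaskLabel.LIVER],
    )
    if sum(act.values()) <= 0:
        raise UndefinedLSFError("phantom has zero activity everywhere")
    true_lsf = lsf_ground_truth(truth).lsf_percent

    mk = lambda label, mask, geom: OrganMask(
        label, mask, geom, MaskSource.THRESHOLD, allow_empty=True
    )
    study = PhantomStudy(
        spec=spec,
        ct=ct,
        truth_masks=[mk(label, ct_masks[label], ct_geom) for label in comps],
        spect_truth_masks=[mk(label, sp_masks[label], spect_geom_full) for label in comps],
        activity_map=activity_map,
        mu_map=mu,
        truth=truth,
        true_lsf_percent=true_lsf,
    )

    study.spect = simulate_spect(study, spec, rng=rngs["spect_noise"])
    study.planar_ant, study.planar_post = simulate_planar(
        study, spec, rng=rngs["planar_noise"]
    )
    study.planar_rois = planar_truth_rois(study)
    return study


# --------------------------------------------------------------------------- #
def _motion_kernel(amplitude_mm: float, spacing_mm: float, n_phases: int):
    """Integer-voxel dwell kernel for sinusoidal cranio-caudal motion.

    ``n_phases`` displacements are sampled uniformly in time over one
    breathing cycle (arcsine dwell marginal); each fractional-voxel shift is
    split between its two neighbouring integer offsets with linear weights,
    which conserves both total counts and the count centroid.
    """
    if amplitude_mm <= 0:
        return None
    phases = (np.arange(n_phases) + 0.5) / n_phases
    disp_vox = (amplitude_mm / 2.0) * np.sin(2.0 * np.pi * phases) / spacing_mm
    m = int(np.ceil(np.abs(disp_vox).max())) + 1
    kernel = np.zeros(2 * m + 1)
    for d in disp_vox:
        lo = int(np.floor(d))
        w = d - lo
        kernel[lo + m] += (1.0 - w) / n_phases
        kernel[lo + m + 1] += w / n_phases
    return kernel


def _apply_motion(vol: np.ndarray, geometry: AffineGeometry, spec: PhantomSpec):
    axis, _ = geometry.patient_axis(2)
    kernel = _motion_kernel(
        spec.motion_amplitude_mm, float(geometry.spacing[axis]), spec.motion_phases
    )
    if kernel is None:
        return vol
    return ndimage.convolve1d(vol, kernel, axis=axis, mode="constant", cval=0.0)


def _apply_psf(vol: np.ndarray, spacing, fwhm_mm: float):
    if fwhm_mm <= 0:
        return vol
    sigma = fwhm_mm * _FWHM_TO_SIGMA / np.asarray(spacing, dtype=float)
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="constant", cval=0.0)


def simulate_spect(
    study: PhantomStudy, spec: PhantomSpec | None = None, rng=None
) -> ImageVolume:
    """Emulate a reconstructed AC SPECT volume from the activity map.

    Pipeline: respiratory dwell blur along the patient S-I axis -> isotropic
    Gaussian PSF -> global count scaling (to ``target_total_counts``, or by
    ``counts_per_mbq``) -> optional seeded Poisson draw -> superior FOV crop.
    Blurring conserves total counts to <0.1% (margin-edge loss excepted).
    """
    spec = spec or study.spec
    if rng is None:
        rng = _rng_streams(spec.seed)["spect_noise"]
    geom = study.activity_map.geometry
    img = study.activity_map.voxels.astype(float)

    img = _apply_motion(img, geom, spec)
    img = _apply_psf(img, geom.spacing, spec.psf_fwhm_mm)

    if spec.counts_per_mbq is not None:
        img = img * spec.counts_per_mbq
    elif spec.target_total_counts is not None:
        tot = img.sum()
        if tot > 0:
            img = img * (spec.target_total_counts / tot)

    if spec.noise == NoiseModel.POISSON:
        img = rng.poisson(img).astype(float)

    if spec.spect_superior_crop_mm > 0:
        crop_geom = spec.spect_geometry()
        axis, sign = geom.patient_axis(2)
        n = crop_geom.shape[axis]
        sl = [slice(None)] * 3
        sl[axis] = slice(0, n) if sign > 0 else slice(geom.shape[axis] - n, None)
        img = img[tuple(sl)]
        geom = crop_geom
    return ImageVolume(img, geom, Modality.SPECT_AC, spec.frame_of_reference)


# --------------------------------------------------------------------------- #
def _transmission(mu: np.ndarray, dy_mm: float, axis: int, toward_start: bool):
    """Beer-Lambert transmission from each voxel to the volume face along
    ``axis``; the voxel's own thickness counts half, so the anterior and
    posterior path lengths sum exactly to the full column."""
    tau = np.cumsum(mu, axis=axis) * dy_mm
    self_half = 0.5 * mu * dy_mm
    if toward_start:
        path = tau - 2.0 * self_half + self_half  # mu up to (excl.) voxel + half self
    else:
        total = np.take(tau, [-1], axis=axis)
        path = total - tau + self_half
    return np.exp(-path)


def simulate_planar(
    study: PhantomStudy, spec: PhantomSpec | None = None, rng=None
) -> tuple[PlanarImage, PlanarImage]:
    """Attenuated anterior/posterior planar projections of the activity map.

    Each voxel contributes activity x exp(-integral of mu) along the ray to
    the anterior (-y) or posterior (+y) exit face, accumulated into the
    detector pixel; an in-plane Gaussian PSF and optional Poisson noise
    follow.  The posterior image is returned in camera orientation
    (left-right mirrored), as a real acquisition stores it.
    """
    spec = spec or study.spec
    if rng is None:
        rng = _rng_streams(spec.seed)["planar_noise"]
    geom = study.activity_map.geometry
    act = _apply_motion(study.activity_map.voxels.astype(float), geom, spec)
    mu = study.mu_map

    y_axis, y_sign = geom.patient_axis(1)  # patient +y = posterior
    x_axis, _ = geom.patient_axis(0)
    z_axis, _ = geom.patient_axis(2)
    dy = float(geom.spacing[y_axis])
    px, pz = float(geom.spacing[x_axis]), float(geom.spacing[z_axis])
    if not np.isclose(px, pz):
        raise PhantomError("planar simulation needs equal x/z spacing")

    # anterior camera sits at the -y face: start of the axis if +y points
    # into the array, else the end
    ant_toward_start = y_sign > 0
    t_ant = _transmission(mu, dy, y_axis, toward_start=ant_toward_start)
    t_post = _transmission(mu, dy, y_axis, toward_start=not ant_toward_start)

    ant = np.sum(act * t_ant, axis=y_axis)
    post = np.sum(act * t_post, axis=y_axis)
    # collapse to (x, z) pixel axes
    if x_axis > z_axis:
        ant, post = ant.T, post.T

    sigma = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / px
    if spec.psf_fwhm_mm > 0:
        ant = ndimage.gaussian_filter(ant, sigma, mode="constant", cval=0.0)
        post = ndimage.gaussian_filter(post, sigma, mode="constant", cval=0.0)

    if spec.planar_target_counts is not None:
        for name, arr in (("ant", ant), ("post", post)):
            tot = arr.sum()
            if tot > 0:
                arr *= spec.planar_target_counts / tot

    if spec.noise == NoiseModel.POISSON:
        ant = rng.poisson(ant).astype(float)
        post = rng.poisson(post).astype(float)

    post_camera = np.flip(post, axis=0)  # camera behind the patient mirrors L-R
    return (
        PlanarImage(ant, px, View.ANTERIOR),
        PlanarImage(post_camera, px, View.POSTERIOR),
    )


def planar_truth_rois(study: PhantomStudy) -> dict:
    """2D organ ROIs (anterior frame) by projecting the SPECT-grid truth
    masks along the patient A-P axis."""
    geom = study.activity_map.geometry
    y_axis, _ = geom.patient_axis(1)
    x_axis, _ = geom.patient_axis(0)
    z_axis, _ = geom.patient_axis(2)
    rois = {}
    for m in study.spect_truth_masks:
        proj = m.mask.any(axis=y_axis)
        if x_axis > z_axis:
            proj = proj.T
        rois[m.label.value.lower()] = proj
    return rois
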