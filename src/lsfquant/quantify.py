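"""Count extraction and every lung-shunt-fraction formula.

Three LSF estimators share the same ratio form, lung / (lung + liver) x 100:

* 3D SPECT  — voxel count totals under the finalized VOIs (plus any counts
  imputed for a cropped lung apex);
* 2D planar — geometric mean sqrt(anterior x posterior) of the per-view organ
  count totals, the standard clinical depth-compensation;
* ground truth — net assayed activities (assay minus residual), decay
  corrected to a common reference time with the Tc-99m half-life.

Cohort comparison statistics (planar vs SPECT percentage difference and
quartile spread) live here too.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ActivityError, GeometryError, UndefinedLSFError
from .images import ImageVolume, Modality, PlanarImage, View
from .segmentation import MaskLabel
from .voi import VOISet

__all__ = [
    "TC99M_HALF_LIFE_H",
    "LSFMethod",
    "CountSummary",
    "PlanarCountSummary",
    "GroundTruthActivities",
    "LSFResult",
    "QuartileSummary",
    "organ_counts",
    "lsf_3d",
    "planar_organ_counts",
    "lsf_planar",
    "lsf_ground_truth",
    "percentage_difference",
    "quartile_summary",
    "accuracy_vs_truth",
    "load_cohort_csv",
    "cohort_comparison",
]

log = logging.getLogger("lsfquant")

#: Physical half-life of Tc-99m in hours.
TC99M_HALF_LIFE_H = 6.0067


class LSFMethod(str, enum.Enum):
    SPECT_3D = "SPECT_3D"
    PLANAR_2D = "PLANAR_2D"
    GROUND_TRUTH = "GROUND_TRUTH"


# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class CountSummary:
    """Organ count totals from a reconstructed SPECT volume."""

    liver: float
    lung_left: float
    lung_right: float
    crop_added: float = 0.0

    def __post_init__(self):
        for name in ("liver", "lung_left", "lung_right", "crop_added"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} counts must be >= 0")

    @property
    def total_lung(self) -> float:
        return self.lung_left + self.lung_right + self.crop_added

    @property
    def total_liver(self) -> float:
        return self.liver

    def as_dict(self) -> dict:
        return {
            "liver": self.liver,
            "lung_left": self.lung_left,
            "lung_right": self.lung_right,
            "crop_added": self.crop_added,
            "total_lung": self.total_lung,
        }


@dataclass(frozen=True)
class PlanarCountSummary:
    """Per-view organ totals and their geometric means."""

    lung_ant: float
    lung_post: float
    liver_ant: float
    liver_post: float

    @property
    def geomean_lung(self) -> float:
        return math.sqrt(self.lung_ant * self.lung_post)

    @property
    def geomean_liver(self) -> float:
        return math.sqrt(self.liver_ant * self.liver_post)

    def as_dict(self) -> dict:
        return {
            "lung_ant": self.lung_ant,
            "lung_post": self.lung_post,
            "liver_ant": self.liver_ant,
            "liver_post": self.liver_post,
            "geomean_lung": self.geomean_lung,
            "geomean_liver": self.geomean_liver,
        }


@dataclass(frozen=True)
class GroundTruthActivities:
    """Assayed compartment activities and residuals, in MBq.

    ``assay_time_h`` / ``residual_assay_time_h`` / ``reference_time_h`` are
    clock times in hours on any common scale; every activity is decay
    corrected to the reference time before the LSF formula is applied.
    """

    right_lung_mbq: float
    left_lung_mbq: float
    liver_mbq: float
    right_lung_residual_mbq: float = 0.0
    left_lung_residual_mbq: float = 0.0
    liver_residual_mbq: float = 0.0
    assay_time_h: float = 0.0
    residual_assay_time_h: float | None = None
    reference_time_h: float = 0.0

    def __post_init__(self):
        vals = [
            self.right_lung_mbq, self.left_lung_mbq, self.liver_mbq,
            self.right_lung_residual_mbq, self.left_lung_residual_mbq,
            self.liver_residual_mbq,
        ]
        if any(v < 0 for v in vals):
            raise ActivityError("activities and residuals must be >= 0")

    def as_dict(self) -> dict:
        return {
            "right_lung_mbq": self.right_lung_mbq,
            "left_lung_mbq": self.left_lung_mbq,
            "liver_mbq": self.liver_mbq,
            "right_lung_residual_mbq": self.right_lung_residual_mbq,
            "left_lung_residual_mbq": self.left_lung_residual_mbq,
            "liver_residual_mbq": self.liver_residual_mbq,
            "assay_time_h": self.assay_time_h,
            "residual_assay_time_h": self.residual_assay_time_h,
            "reference_time_h": self.reference_time_h,
        }


@dataclass(frozen=True)
class LSFResult:
    """An LSF estimate with its method tag and everything that produced it."""

    lsf_percent: float
    method: LSFMethod
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.lsf_percent <= 100.0):
            raise ValueError(f"LSF must be in [0, 100] %, got {self.lsf_percent}")


@dataclass(frozen=True)
class QuartileSummary:
    n: int
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def as_dict(self) -> dict:
        return {"n": self.n, "q1": self.q1, "q3": self.q3, "iqr": self.iqr}


# --------------------------------------------------------------------------- #
def organ_counts(spect: ImageVolume, voiset: VOISet) -> CountSummary:
    """Sum SPECT voxel values under each finalized VOI.

    Counts imputed by a crop correction are folded into the lung total.
    """
    if spect.modality not in (Modality.SPECT_AC, Modality.SPECT_NC):
        raise ValueError("organ_counts expects a SPECT volume")
    if not spect.geometry.approx_equal(voiset.geometry):
        raise GeometryError(
            "SPECT grid does not match the VOISet grid:\n"
            f"  spect: {spect.geometry.describe()}\n"
            f"  vois:  {voiset.geometry.describe()}"
        )
    sums = {
        label: float(spect.voxels[m.mask].sum()) for label, m in voiset.masks().items()
    }
    crop = voiset.crop_correction.added_counts if voiset.crop_correction else 0.0
    return CountSummary(
        liver=sums[MaskLabel.LIVER],
        lung_left=sums[MaskLabel.LUNG_LEFT],
        lung_right=sums[MaskLabel.LUNG_RIGHT],
        crop_added=crop,
    )


def _ratio_percent(lung: float, liver: float) -> float:
    denom = lung + liver
    if denom <= 0:
        raise UndefinedLSFError("LSF undefined: lung and liver totals are both zero")
    return lung / denom * 100.0


def lsf_3d(counts: CountSummary, parameters: dict | None = None) -> LSFResult:
    """LSF% = Total Lung Count / (Total Lung Count + Total Liver Count) x 100."""
    lsf = _ratio_percent(counts.total_lung, counts.total_liver)
    details = {"counts": counts.as_dict()}
    if parameters:
        details["parameters"] = dict(parameters)
    return LSFResult(lsf, LSFMethod.SPECT_3D, details)


# --------------------------------------------------------------------------- #
def planar_organ_counts(
    ant: PlanarImage, post: PlanarImage, rois: dict
) -> PlanarCountSummary:
    """Extract per-view organ totals from an anterior/posterior pair.

    The posterior image is mirrored left-right exactly once here, so the 2D
    organ ROIs (defined in the anterior frame) apply to both views.  ``rois``
    maps ROI names to 2D boolean arrays; any key containing ``"lung"``
    (case-insensitive) contributes to the lung total, any containing
    ``"liver"`` to the liver total.
    """
    if ant.view != View.ANTERIOR or post.view != View.POSTERIOR:
        raise ValueError("planar_organ_counts expects (anterior, posterior)")
    if ant.pixels.shape != post.pixels.shape:
        raise ValueError("anterior/posterior shape mismatch")
    post_px = np.flip(post.pixels, axis=0)  # undo the camera's L-R mirror

    lung_a = lung_p = liver_a = liver_p = 0.0
    seen = False
    for name, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != ant.pixels.shape:
            raise ValueError(
                f"ROI {name!r} shape {roi.shape} != planar shape {ant.pixels.shape}"
            )
        a, p = float(ant.pixels[roi].sum()), float(post_px[roi].sum())
        key = str(name).lower()
        if "lung" in key:
            lung_a += a
            lung_p += p
            seen = True
        elif "liver" in key:
            liver_a += a
            liver_p += p
            seen = True
    if not seen:
        raise ValueError("rois must contain at least one lung or liver ROI")
    for organ, tot in (("lung", lung_p), ("liver", liver_p)):
        if tot == 0:
            log.warning("posterior %s total is zero; its geometric mean is zero", organ)
    return PlanarCountSummary(lung_a, lung_p, liver_a, liver_p)


def lsf_planar(counts: PlanarCountSummary, parameters: dict | None = None) -> LSFResult:
    """LSF% = Geomean Lung / (Geomean Lung + Geomean Liver) x 100."""
    lsf = _ratio_percent(counts.geomean_lung, counts.geomean_liver)
    details = {"counts": counts.as_dict()}
    if parameters:
        details["parameters"] = dict(parameters)
    return LSFResult(lsf, LSFMethod.PLANAR_2D, details)


# --------------------------------------------------------------------------- #
def decay_correct(activity_mbq: float, from_time_h: float, to_time_h: float) -> float:
    """Decay-correct a Tc-99m activity from one clock time to another."""
    return activity_mbq * 2.0 ** (-(to_time_h - from_time_h) / TC99M_HALF_LIFE_H)


def lsf_ground_truth(a: GroundTruthActivities) -> LSFResult:
    """Phantom ground truth from net assayed activities.

    LSF% = ((RLA - rlr) + (LLA - llr))
         / ((RLA - rlr) + (LLA - llr) + (LA - lr)) x 100
    with every activity decay corrected to the reference time first.
    """
    t_res = (
        a.assay_time_h if a.residual_assay_time_h is None else a.residual_assay_time_h
    )
    rla = decay_correct(a.right_lung_mbq, a.assay_time_h, a.reference_time_h)
    lla = decay_correct(a.left_lung_mbq, a.assay_time_h, a.reference_time_h)
    la = decay_correct(a.liver_mbq, a.assay_time_h, a.reference_time_h)
    rlr = decay_correct(a.right_lung_residual_mbq, t_res, a.reference_time_h)
    llr = decay_correct(a.left_lung_residual_mbq, t_res, a.reference_time_h)
    lr = decay_correct(a.liver_residual_mbq, t_res, a.reference_time_h)
    nets = {"right lung": rla - rlr, "left lung": lla - llr, "liver": la - lr}
    bad = [k for k, v in nets.items() if v < 0]
    if bad:
        raise ActivityError(
            "negative net activity after decay correction for: " + ", ".join(bad)
        )
    lung = nets["right lung"] + nets["left lung"]
    lsf = _ratio_percent(lung, nets["liver"])
    return LSFResult(
        lsf,
        LSFMethod.GROUND_TRUTH,
        {"activities": a.as_dict(), "net_mbq": nets, "half_life_h": TC99M_HALF_LIFE_H},
    )


# --------------------------------------------------------------------------- #
def percentage_difference(planar_lsf_percent: float, spect_lsf_percent: float) -> float:
    """PD = (PL - TF) / TF x 100 — planar relative to the SPECT value."""
    if spect_lsf_percent <= 0:
        raise UndefinedLSFError("percentage difference undefined for SPECT LSF <= 0")
    return (planar_lsf_percent - spect_lsf_percent) / spect_lsf_percent * 100.0


def accuracy_vs_truth(measured: LSFResult, truth: LSFResult) -> float:
    """Signed relative error (%) of a measured LSF against the ground truth."""
    if truth.lsf_percent <= 0:
        raise UndefinedLSFError("accuracy undefined for zero ground-truth LSF")
    return (measured.lsf_percent - truth.lsf_percent) / truth.lsf_percent * 100.0


def quartile_summary(values) -> QuartileSummary:
    """Quartiles at ranks (n+1)/4 and 3(n+1)/4 of the sorted values.

    Fractional ranks interpolate linearly between adjacent order statistics;
    ranks are clipped to [1, n].  (This is the classic (n+1)-based quartile
    definition, numpy's ``method="weibull"``.)
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("quartile_summary requires at least one value")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="weibull")
    return QuartileSummary(n=int(arr.size), q1=float(q1), q3=float(q3))


# --------------------------------------------------------------------------- #
def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table with columns case_id, planar_lsf_percent,
    spect_lsf_percent."""
    df = pd.read_csv(path)
    required = {"case_id", "planar_lsf_percent", "spect_lsf_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def cohort_comparison(df: pd.DataFrame) -> dict:
    """Planar-vs-SPECT cohort statistics.

    Returns per-case percentage differences plus both readings of the
    "average difference": the mean of per-case PDs and the PD of the cohort
    means (these differ in general), and quartile summaries of both LSF
    columns.
    """
    pl = df["planar_lsf_percent"].to_numpy(float)
    tf = df["spect_lsf_percent"].to_numpy(float)
    ok = tf > 0
    if not ok.all():
        log.warning("%d case(s) with SPECT LSF <= 0 excluded from PD", (~ok).sum())
    pd_cases = (pl[ok] - tf[ok]) / tf[ok] * 100.0
    out = {
        "n": int(len(df)),
        "mean_planar_lsf_percent": float(pl.mean()),
        "mean_spect_lsf_percent": float(tf.mean()),
        "per_case_pd_percent": pd_cases.tolist(),
        "mean_of_per_case_pd_percent": float(pd_cases.mean()) if pd_cases.size else None,
        "pd_of_means_percent": percentage_difference(float(pl.mean()), float(tf.mean()))
        if tf.mean() > 0
        else None,
        "planar_quartiles": quartile_summary(pl).as_dict(),
        "spect_quartiles": quartile_summary(tf).as_dict(),
    }
    return out
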