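"""Structured LSF reports.

Every analysis run ends in an :class:`LSFReport` that records the inputs,
the organ volumes before and after augmentation, the raw counts, every
augmentation or crop parameter actually applied, and the resulting LSF —
enough to recompute the LSF from the report alone.  Reports render as
schema-stable JSON (lossless round trip) or as a short human-readable text
summary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from . import __version__
from .exceptions import ReportError
from .quantify import (
    CountSummary,
    LSFMethod,
    LSFResult,
    PlanarCountSummary,
    lsf_3d,
    lsf_planar,
)
from .voi import VOISet

__all__ = ["LSFReport", "build_report", "render_report", "report_from_json"]

_SCHEMA = "lsfquant-report/1"


@dataclass
class LSFReport:
    metadata: dict
    results: list  # of LSFResult
    counts: dict | None = None  # CountSummary or PlanarCountSummary as dict
    volumes_cm3: dict = field(default_factory=dict)  # before/after augmentation
    augmentation: dict | None = None
    crop_correction: dict | None = None
    config: dict = field(default_factory=dict)
    software_version: str = __version__
    schema: str = _SCHEMA

    def as_dict(self) -> dict:
        return {
            "schema": self.schema,
            "software_version": self.software_version,
            "metadata": self.metadata,
            "results": [
                {
                    "method": r.method.value,
                    "lsf_percent": r.lsf_percent,
                    "lsf_percent_2dp": round(r.lsf_percent, 2),
                    "details": r.details,
                }
                for r in self.results
            ],
            "counts": self.counts,
            "volumes_cm3": self.volumes_cm3,
            "augmentation": self.augmentation,
            "crop_correction": self.crop_correction,
            "config": self.config,
        }


def _check_self_consistent(report: LSFReport) -> None:
    """The recorded LSF must be reproducible from the recorded counts."""
    for r in report.results:
        c = r.details.get("counts")
        if not c:
            continue
        if r.method == LSFMethod.SPECT_3D:
            recomputed = lsf_3d(
                CountSummary(
                    liver=c["liver"],
                    lung_left=c["lung_left"],
                    lung_right=c["lung_right"],
                    crop_added=c.get("crop_added", 0.0),
                )
            ).lsf_percent
        elif r.method == LSFMethod.PLANAR_2D:
            recomputed = lsf_planar(
                PlanarCountSummary(
                    c["lung_ant"], c["lung_post"], c["liver_ant"], c["liver_post"]
                )
            ).lsf_percent
        else:
            continue
        if not math.isclose(recomputed, r.lsf_percent, rel_tol=1e-9):
            raise ReportError(
                f"report is inconsistent: recorded {r.method.value} LSF "
                f"{r.lsf_percent} vs {recomputed} recomputed from its counts"
            )


def build_report(
    metadata: dict,
    results,
    voiset: VOISet | None = None,
    counts=None,
    pre_augmentation_volumes_cm3: dict | None = None,
    config: dict | None = None,
) -> LSFReport:
    """Assemble a fully-populated report from a completed pipeline run.

    ``metadata`` must identify the study (a ``study`` key at minimum).  Any
    pixel augmentation or crop correction in ``voiset`` is recorded.
    """
    if not isinstance(metadata, dict) or "study" not in metadata:
        raise ReportError("report metadata must contain a 'study' field")
    results = list(results)
    if not results:
        raise ReportError("report requires at least one LSF result")

    volumes = {}
    augmentation = crop = None
    if voiset is not None:
        volumes["after_augmentation"] = voiset.volumes_cm3()
        augmentation = voiset.augmentation.as_dict()
        if voiset.crop_correction is not None:
            crop = voiset.crop_correction.as_dict()
    if pre_augmentation_volumes_cm3:
        volumes["before_augmentation"] = dict(pre_augmentation_volumes_cm3)

    report = LSFReport(
        metadata=dict(metadata),
        results=results,
        counts=counts.as_dict() if counts is not None else None,
        volumes_cm3=volumes,
        augmentation=augmentation,
        crop_correction=crop,
        config=dict(config or {}),
    )
    _check_self_consistent(report)
    return report


def render_report(report: LSFReport, format: str = "JSON") -> str:
    """Render as schema-stable JSON (sorted keys) or a human text summary."""
    fmt = str(format).upper()
    if fmt == "JSON":
        return json.dumps(report.as_dict(), indent=2, sort_keys=True)
    if fmt == "TEXT":
        lines = [
            "Lung Shunt Fraction report",
            f"  software: lsfquant {report.software_version}",
            f"  study:    {report.metadata.get('study')}",
        ]
        for r in report.results:
            lines.append(f"  LSF ({r.method.value}): {r.lsf_percent:.2f} %")
        for stage, vols in report.volumes_cm3.items():
            pretty = ", ".join(f"{k}={v:.1f}" for k, v in vols.items())
            lines.append(f"  volumes {stage} (cm^3): {pretty}")
        if report.augmentation:
            a = report.augmentation
            lines.append(
                "  augmentation: liver %.1f mm, lung %.1f mm, +%.1f mm cranio-caudal"
                % (a["liver_radius_mm"], a["lung_radius_mm"], a["extra_cranio_caudal_mm"])
            )
        if report.crop_correction:
            c = report.crop_correction
            lines.append(
                "  crop correction: %.0f counts imputed for %.1f%% missing lung"
                % (c["added_counts"], 100 * c["estimated_missing_fraction"])
            )
        return "\n".join(lines) + "\n"
    raise ReportError(f"unknown report format {format!r}; use JSON or TEXT")


def report_from_json(text: str) -> LSFReport:
    """Parse a JSON report back into an :class:`LSFReport` (lossless)."""
    d = json.loads(text)
    if d.get("schema") != _SCHEMA:
        raise ReportError(f"unknown report schema {d.get('schema')!r}")
    results = [
        LSFResult(r["lsf_percent"], LSFMethod(r["method"]), r.get("details", {}))
        for r in d["results"]
    ]
    return LSFReport(
        metadata=d["metadata"],
        results=results,
        counts=d.get("counts"),
        volumes_cm3=d.get("volumes_cm3", {}),
        augmentation=d.get("augmentation"),
        crop_correction=d.get("crop_correction"),
        config=d.get("config", {}),
        software_version=d.get("software_version", __version__),
    )
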