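"""Cohort aggregation and technique-vs-technique comparison reports.

Per-patient plan metrics are collected into :class:`PlanRecord` objects;
:func:`compare_techniques` reduces a paired cohort (every patient planned
with both techniques) to per-metric cohort means and sample standard
deviations and the percent change of each metric between technique cohort
means, with the reference technique (single-arc by convention) as the
base.  Percent change is the ratio of cohort means, not the mean of
per-patient ratios; both interpretations are offered but ratio-of-means is
the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .dose_metrics import (
    DEFAULT_CRITERIA,
    CriterionResult,
    MetricSpec,
    compute_metric,
    evaluate_criteria,
)
from .dvh_core import CumulativeDVH, as_cumulative, as_differential
from .radiobiology import (
    DEFAULT_LKB_PARAMS,
    DEFAULT_TCP_PARAMS,
    LKBParameters,
    TCPParameters,
    lkb_ntcp,
    tcp_from_dvh,
)

__all__ = [
    "PlanRecord",
    "MetricSummary",
    "CohortReport",
    "STANDARD_METRICS",
    "build_plan_records",
    "percent_change",
    "cohort_summary",
    "compare_techniques",
    "render_report",
]

#: Metric set reported per structure in the standard plan-evaluation sheet.
STANDARD_METRICS: dict[str, tuple[str, ...]] = {
    "PTV": ("D99%", "mean", "max"),
    "CTV": ("D99%", "mean", "max"),
    "Rectum": ("D30%", "D50%", "V17Gy", "V35Gy", "mean", "max"),
    "Bladder": ("D30%", "D50%", "V17Gy", "V35Gy", "mean", "max"),
    "LeftFemoralHead": ("D5%", "mean", "max"),
    "RightFemoralHead": ("D5%", "mean", "max"),
}
_FALLBACK_METRICS = ("mean", "max")

#: Reference technique: percent changes are expressed relative to this.
DEFAULT_REFERENCE = "single-arc"


@dataclass
class PlanRecord:
    """Metrics of one plan (one patient, one technique).

    ``metrics`` maps structure name -> metric label -> value; labels must
    be unique per structure (dict keys enforce this).
    """

    patient_id: str
    technique: str
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    monitor_units: float | None = None
    tcp: float | None = None
    ntcp: float | None = None
    criteria: list[CriterionResult] = field(default_factory=list)


@dataclass(frozen=True)
class MetricSummary:
    """Cohort mean/SD per technique and the percent change between them."""

    structure: str
    label: str
    reference_mean: float
    reference_sd: float | None
    other_mean: float
    other_sd: float | None
    percent_change: float | None


@dataclass
class CohortReport:
    reference_technique: str
    other_technique: str
    n_patients: int
    metrics: list[MetricSummary]
    mu_change_percent: float | None = None
    tcp_change_percent: float | None = None
    ntcp_change_percent: float | None = None

    def to_dict(self) -> dict:
        return {
            "reference_technique": self.reference_technique,
            "other_technique": self.other_technique,
            "n_patients": self.n_patients,
            "mu_change_percent": self.mu_change_percent,
            "tcp_change_percent": self.tcp_change_percent,
            "ntcp_change_percent": self.ntcp_change_percent,
            "metrics": [
                {
                    "structure": m.structure,
                    "label": m.label,
                    "reference_mean": m.reference_mean,
                    "reference_sd": m.reference_sd,
                    "other_mean": m.other_mean,
                    "other_sd": m.other_sd,
                    "percent_change": m.percent_change,
                }
                for m in self.metrics
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortReport":
        return cls(
            reference_technique=d["reference_technique"],
            other_technique=d["other_technique"],
            n_patients=d["n_patients"],
            mu_change_percent=d.get("mu_change_percent"),
            tcp_change_percent=d.get("tcp_change_percent"),
            ntcp_change_percent=d.get("ntcp_change_percent"),
            metrics=[MetricSummary(**m) for m in d["metrics"]],
        )


def build_plan_records(
    plans: dict[str, dict[str, dict[str, CumulativeDVH]]],
    monitor_units: dict[str, dict[str, float]] | None = None,
    *,
    tcp_params: TCPParameters = DEFAULT_TCP_PARAMS,
    lkb_params: LKBParameters = DEFAULT_LKB_PARAMS,
    tcp_structure: str = "PTV",
    ntcp_structure: str = "Rectum",
    criteria=DEFAULT_CRITERIA,
) -> list[PlanRecord]:
    """Reduce a patient -> technique -> structure DVH map to plan records.

    Computes the standard metric sheet per structure, evaluates the plan
    criteria (only those whose structures exist in the plan), and — when
    the named structures are present — the target TCP and the
    organ-at-risk NTCP from the converted differential DVHs.
    """
    records = []
    for pid, by_tech in plans.items():
        for technique, by_struct in by_tech.items():
            cumulative = {name: as_cumulative(dvh)
                          for name, dvh in by_struct.items()}
            metrics: dict[str, dict[str, float]] = {}
            for name, dvh in cumulative.items():
                labels = STANDARD_METRICS.get(name, _FALLBACK_METRICS)
                metrics[name] = {
                    lab: compute_metric(dvh, MetricSpec.from_label(lab))
                    for lab in labels
                }
            rec = PlanRecord(
                patient_id=pid,
                technique=technique,
                metrics=metrics,
                monitor_units=(monitor_units or {}).get(pid, {}).get(technique),
            )
            if tcp_structure in by_struct:
                rec.tcp = tcp_from_dvh(
                    as_differential(by_struct[tcp_structure]), tcp_params
                )
            if ntcp_structure in by_struct:
                rec.ntcp, _ = lkb_ntcp(
                    as_differential(by_struct[ntcp_structure]), lkb_params
                )
            applicable = [c for c in criteria if c.structure in by_struct]
            rec.criteria = evaluate_criteria(cumulative, applicable)
            records.append(rec)
    return records


def percent_change(reference: float, other: float) -> float:
    """100 * (other - reference) / reference; negative = lower than
    the reference."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return 100.0 * (other - reference) / reference


def _mean_sd(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def cohort_summary(
    records: Iterable[PlanRecord], structure: str, label: str
) -> dict[str, tuple[float, float | None]]:
    """Per-technique (mean, sample SD) of one metric across patients.

    Raises if any record of a technique lacks the metric, naming the
    patients concerned.
    """
    by_tech: dict[str, list[float]] = {}
    missing: list[str] = []
    for rec in records:
        value = rec.metrics.get(structure, {}).get(label)
        if value is None:
            missing.append(f"{rec.patient_id}/{rec.technique}")
            continue
        by_tech.setdefault(rec.technique, []).append(value)
    if missing:
        raise KeyError(
            f"metric {structure}:{label} missing for plans: {', '.join(missing)}"
        )
    if not by_tech:
        raise ValueError("no records supplied")
    return {tech: _mean_sd(vals) for tech, vals in by_tech.items()}


def _paired_techniques(records: list[PlanRecord], reference: str) -> tuple[str, str]:
    techniques = sorted({r.technique for r in records})
    if len(techniques) != 2:
        raise ValueError(f"expected exactly 2 techniques, found {techniques}")
    if reference not in techniques:
        raise ValueError(
            f"reference technique '{reference}' not in cohort {techniques}"
        )
    other = next(t for t in techniques if t != reference)
    by_patient: dict[str, set[str]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, set()).add(r.technique)
    unpaired = sorted(p for p, ts in by_patient.items() if len(ts) != 2)
    if unpaired:
        raise ValueError(f"patients missing one technique: {', '.join(unpaired)}")
    return reference, other


def _scalar_change(
    records: list[PlanRecord], attr: str, reference: str, other: str
) -> float | None:
    ref_vals = [getattr(r, attr) for r in records if r.technique == reference]
    oth_vals = [getattr(r, attr) for r in records if r.technique == other]
    if any(v is None for v in ref_vals + oth_vals) or not ref_vals:
        return None
    ref_mean = float(np.mean(ref_vals))
    if ref_mean == 0:
        return None
    return percent_change(ref_mean, float(np.mean(oth_vals)))


def compare_techniques(
    records: list[PlanRecord],
    reference_technique: str = DEFAULT_REFERENCE,
    metric_order: list[str] | None = None,
) -> CohortReport:
    """Full paired-cohort comparison.

    Per-metric cohort means/SDs and percent change of the second technique
    relative to the reference; MU, TCP and NTCP changes when those fields
    are present on every record.
    """
    if not records:
        raise ValueError("no records supplied")
    reference, other = _paired_techniques(records, reference_technique)

    pairs = sorted(
        {
            (structure, label)
            for r in records
            for structure, labels in r.metrics.items()
            for label in labels
        }
    )
    if metric_order:
        rank = {lab: i for i, lab in enumerate(metric_order)}
        pairs.sort(key=lambda p: (p[0], rank.get(p[1], len(rank)), p[1]))

    summaries = []
    for structure, label in pairs:
        stats = cohort_summary(records, structure, label)
        ref_mean, ref_sd = stats[reference]
        oth_mean, oth_sd = stats[other]
        change = percent_change(ref_mean, oth_mean) if ref_mean != 0 else None
        summaries.append(
            MetricSummary(structure, label, ref_mean, ref_sd, oth_mean, oth_sd, change)
        )

    n_patients = len({r.patient_id for r in records})
    return CohortReport(
        reference_technique=reference,
        other_technique=other,
        n_patients=n_patients,
        metrics=summaries,
        mu_change_percent=_scalar_change(records, "monitor_units", reference, other),
        tcp_change_percent=_scalar_change(records, "tcp", reference, other),
        ntcp_change_percent=_scalar_change(records, "ntcp", reference, other),
    )


def _fmt(x: float | None, nd: int = 1) -> str:
    return "-" if x is None else f"{x:.{nd}f}"


def render_report(report: CohortReport, format: str = "text") -> str:
    """Serialize a cohort report as text, CSV or JSON (deterministic
    ordering; 1-decimal display for doses/percents)."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    header = [
        "structure", "metric",
        f"{report.reference_technique}_mean", f"{report.reference_technique}_sd",
        f"{report.other_technique}_mean", f"{report.other_technique}_sd",
        "percent_change",
    ]
    rows = [
        [
            m.structure, m.label,
            _fmt(m.reference_mean), _fmt(m.reference_sd),
            _fmt(m.other_mean), _fmt(m.other_sd),
            _fmt(m.percent_change),
        ]
        for m in report.metrics
    ]
    if format == "csv":
        lines = [",".join(header)] + [",".join(r) for r in rows]
        for name, value in (
            ("monitor_units", report.mu_change_percent),
            ("tcp", report.tcp_change_percent),
            ("ntcp", report.ntcp_change_percent),
        ):
            if value is not None:
                lines.append(f"_summary,{name},,,,,{_fmt(value)}")
        return "\n".join(lines) + "\n"
    if format == "text":
        widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
                  for i, h in enumerate(header)]
        def fmt_row(r):
            return "  ".join(s.ljust(w) for s, w in zip(r, widths)).rstrip()
        lines = [
            f"Cohort comparison: {report.other_technique} vs "
            f"{report.reference_technique} (n={report.n_patients})",
            fmt_row(header),
            fmt_row(["-" * w for w in widths]),
        ]
        lines += [fmt_row(r) for r in rows]
        if report.mu_change_percent is not None:
            lines.append(f"Monitor units change: {_fmt(report.mu_change_percent)}%")
        if report.tcp_change_percent is not None:
            lines.append(f"TCP change: {_fmt(report.tcp_change_percent, 2)}%")
        if report.ntcp_change_percent is not None:
            lines.append(f"NTCP change: {_fmt(report.ntcp_change_percent, 1)}%")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format '{format}'")
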