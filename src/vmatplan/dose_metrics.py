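"""Dose-volume metrics (Dx%, VxGy, mean, max) and criteria evaluation.

All metrics are read off the cumulative DVH with linear interpolation in
(dose, volume) — no smoothing — so every value is reproducible by hand from
the curve samples.

Conventions
-----------
Dx% is the minimum dose received by the hottest x% of the structure volume:
the dose at which the interpolated cumulative curve crosses down through
x/100.  Where the curve is flat at exactly x/100 the upper end of the flat
run is returned (the hottest x% all receive at least that dose).  VxGy is
the percent volume receiving at least x Gy.  The maximum dose is
DVH-derived (the dose where the curve reaches the epsilon volume), not a
3D point dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .dvh_core import (
    CumulativeDVH,
    DifferentialDVH,
    cumulative_to_differential,
)

__all__ = [
    "MetricSpec",
    "CriterionSpec",
    "CriterionResult",
    "dose_at_volume",
    "volume_at_dose",
    "mean_dose",
    "max_dose",
    "compute_metric",
    "evaluate_criteria",
    "load_criteria",
    "DEFAULT_CRITERIA",
]


@dataclass(frozen=True)
class MetricSpec:
    """One DVH metric: D_at_volume (Dx%), V_at_dose (VxGy), mean or max."""

    kind: str  # D_at_volume | V_at_dose | mean | max
    parameter: float = 0.0  # percent volume for Dx%, dose Gy for VxGy
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("D_at_volume", "V_at_dose", "mean", "max"):
            raise ValueError(f"unknown metric kind '{self.kind}'")
        if self.kind == "D_at_volume" and not (0 < self.parameter <= 100):
            raise ValueError(f"Dx% requires x in (0, 100], got {self.parameter}")
        if self.kind == "V_at_dose" and self.parameter < 0:
            raise ValueError(f"VxGy requires x >= 0, got {self.parameter}")
        if not self.label:
            object.__setattr__(self, "label", _default_label(self))

    @classmethod
    def from_label(cls, label: str) -> "MetricSpec":
        """Parse labels like ``D99%``, ``V17Gy``, ``mean``, ``max``."""
        s = label.strip()
        low = s.lower()
        if low in ("mean", "mean_dose"):
            return cls("mean", label=s)
        if low in ("max", "max_dose", "maximum"):
            return cls("max", label=s)
        if low.startswith("d") and low.endswith("%"):
            return cls("D_at_volume", float(s[1:-1]), label=s)
        if low.startswith("v") and low.endswith("gy"):
            return cls("V_at_dose", float(s[1:-2]), label=s)
        raise ValueError(f"unrecognized metric label '{label}'")


def _default_label(m: MetricSpec) -> str:
    if m.kind == "D_at_volume":
        return f"D{m.parameter:g}%"
    if m.kind == "V_at_dose":
        return f"V{m.parameter:g}Gy"
    return m.kind


@dataclass(frozen=True)
class CriterionSpec:
    """A pass/fail plan criterion: metric on a structure vs a threshold."""

    structure: str
    metric: MetricSpec
    comparator: str  # "<=" or ">="
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in ("<=", ">="):
            raise ValueError(f"comparator must be <= or >=, got '{self.comparator}'")
        if not np.isfinite(self.threshold):
            raise ValueError("criterion threshold must be finite")


@dataclass(frozen=True)
class CriterionResult:
    structure: str
    label: str
    measured: float
    comparator: str
    threshold: float
    passed: bool


#: Prostate VMAT plan evaluation criteria (doses in Gy).
DEFAULT_CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec("PTV", MetricSpec.from_label("D99%"), ">=", 74.1),
    CriterionSpec("Rectum", MetricSpec.from_label("D30%"), "<=", 70.0),
    CriterionSpec("Rectum", MetricSpec.from_label("D50%"), "<=", 53.0),
    CriterionSpec("Bladder", MetricSpec.from_label("D30%"), "<=", 70.0),
    CriterionSpec("Bladder", MetricSpec.from_label("D50%"), "<=", 53.0),
    CriterionSpec("LeftFemoralHead", MetricSpec.from_label("D5%"), "<=", 53.0),
    CriterionSpec("RightFemoralHead", MetricSpec.from_label("D5%"), "<=", 53.0),
)


def _downcrossing(doses: np.ndarray, vols: np.ndarray, level: float) -> float:
    """Dose where the piecewise-linear curve (doses, vols) crosses down
    through ``level``; flat runs at exactly ``level`` resolve to their
    upper end.  Returns the last dose if the curve never drops below."""
    below = vols < level
    if not below.any():
        return float(doses[-1])
    j = int(np.argmax(below))
    if j == 0:
        return float(doses[0])
    d0, d1 = doses[j - 1], doses[j]
    v0, v1 = vols[j - 1], vols[j]
    if v0 <= level:  # flat at (or noise-equal to) the level: take upper end
        return float(d0)
    return float(d0 + (v0 - level) / (v0 - v1) * (d1 - d0))


def dose_at_volume(c: CumulativeDVH, x: float) -> float:
    """Dx%: minimum dose (Gy) received by the hottest x% of the volume."""
    if not (0 < x <= 100):
        raise ValueError(f"volume percentage must be in (0, 100], got {x}")
    return _downcrossing(c.dose_edges, c.volume_at_or_above, x / 100.0)


def volume_at_dose(c: CumulativeDVH, d: float) -> float:
    """VxGy: percent volume receiving at least ``d`` Gy."""
    if d < 0:
        raise ValueError(f"dose must be >= 0 Gy, got {d}")
    v = np.interp(d, c.dose_edges, c.volume_at_or_above, right=0.0)
    return float(100.0 * v)


def mean_dose(dvh: CumulativeDVH | DifferentialDVH) -> float:
    """Volume-weighted mean dose (Gy), via the differential form."""
    if isinstance(dvh, CumulativeDVH):
        dvh = cumulative_to_differential(dvh)
    return dvh.mean_dose()


def max_dose(c: CumulativeDVH, epsilon_volume: float = 0.0) -> float:
    """DVH-resolution maximum dose: where V(D) falls to ``epsilon_volume``.

    With epsilon_volume > 0 this is a near-maximum dose (the dose to the
    hottest ``epsilon_volume`` fraction).
    """
    if not (0 <= epsilon_volume < 1):
        raise ValueError(f"epsilon_volume must be in [0, 1), got {epsilon_volume}")
    vols = c.volume_at_or_above
    reached = vols <= epsilon_volume
    if not reached.any():
        return float(c.dose_edges[-1])
    j = int(np.argmax(reached))
    if j == 0:
        return float(c.dose_edges[0])
    d0, d1 = c.dose_edges[j - 1], c.dose_edges[j]
    v0, v1 = vols[j - 1], vols[j]
    if v0 == v1:
        return float(d1)
    return float(d0 + (v0 - epsilon_volume) / (v0 - v1) * (d1 - d0))


def compute_metric(c: CumulativeDVH, metric: MetricSpec) -> float:
    if metric.kind == "D_at_volume":
        return dose_at_volume(c, metric.parameter)
    if metric.kind == "V_at_dose":
        return volume_at_dose(c, metric.parameter)
    if metric.kind == "mean":
        return mean_dose(c)
    return max_dose(c)


def evaluate_criteria(
    dvhs: CumulativeDVH | dict[str, CumulativeDVH],
    criteria: Iterable[CriterionSpec],
) -> list[CriterionResult]:
    """Evaluate criteria against one DVH or a {structure: DVH} map.

    Every criterion is reported; a criterion naming a structure missing
    from the map raises rather than being silently skipped.
    """
    results = []
    for crit in criteria:
        if isinstance(dvhs, CumulativeDVH):
            dvh = dvhs
        else:
            if crit.structure not in dvhs:
                raise KeyError(
                    f"criterion '{crit.metric.label}' names structure "
                    f"'{crit.structure}' which is not in the plan"
                )
            dvh = dvhs[crit.structure]
        measured = compute_metric(dvh, crit.metric)
        passed = (
            measured <= crit.threshold
            if crit.comparator == "<="
            else measured >= crit.threshold
        )
        results.append(
            CriterionResult(
                crit.structure, crit.metric.label, measured,
                crit.comparator, crit.threshold, passed,
            )
        )
    return results


def load_criteria(path) -> list[CriterionSpec]:
    """Read a criteria sheet: a JSON/YAML list of
    ``{structure, metric, comparator, threshold}`` entries."""
    from pathlib import Path

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        entries = yaml.safe_load(text)
    else:
        import json

        entries = json.loads(text)
    return [
        CriterionSpec(
            structure=e["structure"],
            metric=MetricSpec.from_label(e["metric"]),
            comparator=e["comparator"],
            threshold=float(e["threshold"]),
        )
        for e in entries
    ]
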