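"""Dose-volume histogram containers, validation, conversion and CSV I/O.

A cumulative DVH gives, for each dose threshold D, the fraction of a
structure's volume receiving at least D; the differential form gives the
fraction of volume per dose bin.  Radiobiological models consume the
differential form, plan-evaluation metrics the cumulative one, so lossless
conversion between the two is the backbone of the package.

Volumes are stored internally as relative fractions of the structure volume;
absolute cm3 appear only at the I/O boundary, converted through the
structure's total volume.  Doses are Gy everywhere (cGy converted at parse
time).

File dialect
------------
One structure per CSV file.  ``#``-prefixed ``key=value`` header lines carry
the metadata (``structure``, ``patient_id``, ``technique``,
``total_volume_cm3``, ``dose_unit`` Gy|cGy, ``volume_type``
cumulative|differential, ``volume_unit`` percent|cm3|fraction), followed by
two comma-separated columns ``dose,volume``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DVHValidationError",
    "StructureInfo",
    "CumulativeDVH",
    "DifferentialDVH",
    "read_dvh",
    "write_dvh",
    "read_manifest",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "as_cumulative",
    "as_differential",
    "resample",
]

#: Default dose grid resolution (Gy) for generated / resampled DVHs,
#: matching typical treatment-planning-system export resolution.
DEFAULT_BIN_WIDTH = 0.1

#: Relative tolerance below which monotonicity violations in a cumulative
#: DVH are treated as float-rounding noise and clamped; larger ones raise.
MONOTONE_NOISE_TOL = 1e-6


class DVHValidationError(ValueError):
    """Raised when a DVH violates its structural invariants."""


@dataclass(frozen=True)
class StructureInfo:
    """Identity and absolute volume of one contoured structure."""

    name: str
    total_volume: float  # cm3
    patient_id: str = ""
    technique: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise DVHValidationError("structure name must be non-empty")
        if not (self.total_volume > 0):
            raise DVHValidationError(
                f"total_volume must be > 0 cm3, got {self.total_volume}"
            )


def _validate_doses(doses: np.ndarray, *, require_zero_start: bool) -> None:
    if doses.ndim != 1 or doses.size < 1:
        raise DVHValidationError("dose axis must be a non-empty 1-D array")
    if not np.all(np.isfinite(doses)):
        raise DVHValidationError("dose axis contains non-finite values")
    if np.any(doses < 0):
        row = int(np.argmax(doses < 0))
        raise DVHValidationError(f"negative dose at row {row}: {doses[row]}")
    diffs = np.diff(doses)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise DVHValidationError(
            f"dose column not strictly increasing at row {row}: {doses[row]}"
        )
    if require_zero_start and doses[0] != 0.0:
        raise DVHValidationError(
            f"cumulative DVH must start at dose 0, got {doses[0]}"
        )


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: fraction of volume receiving at least each dose.

    ``dose_edges`` are bin lower edges in Gy, strictly increasing and
    starting at 0; ``volume_at_or_above`` holds the matching relative
    volume fractions, non-increasing from 1.0.
    """

    structure: StructureInfo
    dose_edges: np.ndarray
    volume_at_or_above: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        vols = np.asarray(self.volume_at_or_above, dtype=float)
        _validate_doses(edges, require_zero_start=True)
        if vols.shape != edges.shape:
            raise DVHValidationError("dose and volume columns differ in length")
        if not np.all(np.isfinite(vols)):
            raise DVHValidationError("volume column contains non-finite values")
        if np.any(vols < -MONOTONE_NOISE_TOL) or np.any(vols > 1 + MONOTONE_NOISE_TOL):
            row = int(np.argmax((vols < -MONOTONE_NOISE_TOL) | (vols > 1 + MONOTONE_NOISE_TOL)))
            raise DVHValidationError(
                f"volume fraction outside [0, 1] at row {row}: {vols[row]}"
            )
        if abs(vols[0] - 1.0) > MONOTONE_NOISE_TOL:
            raise DVHValidationError(
                f"cumulative DVH must start at volume fraction 1.0, got {vols[0]}"
            )
        rises = np.diff(vols)
        if np.any(rises > MONOTONE_NOISE_TOL):
            row = int(np.argmax(rises > MONOTONE_NOISE_TOL)) + 1
            raise DVHValidationError(
                f"cumulative volume increases with dose at row {row}: "
                f"{vols[row - 1]} -> {vols[row]}"
            )
        # clamp float-rounding noise into a clean monotone [0, 1] curve
        vols = np.clip(vols, 0.0, 1.0)
        vols[0] = 1.0
        vols = np.minimum.accumulate(vols)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume_at_or_above", vols)

    @property
    def max_edge(self) -> float:
        return float(self.dose_edges[-1])

    def volume_cm3(self) -> np.ndarray:
        """Absolute volume (cm3) at or above each dose edge."""
        return self.volume_at_or_above * self.structure.total_volume


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: fractional volume per dose bin.

    ``bin_centers`` are Gy, strictly increasing; ``fractional_volumes``
    are non-negative and sum to 1.
    """

    structure: StructureInfo
    bin_centers: np.ndarray
    fractional_volumes: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        vols = np.asarray(self.fractional_volumes, dtype=float)
        _validate_doses(centers, require_zero_start=False)
        if vols.shape != centers.shape:
            raise DVHValidationError("dose and volume columns differ in length")
        if not np.all(np.isfinite(vols)):
            raise DVHValidationError("volume column contains non-finite values")
        if np.any(vols < -1e-12):
            row = int(np.argmax(vols < -1e-12))
            raise DVHValidationError(
                f"negative fractional volume at row {row}: {vols[row]}"
            )
        vols = np.clip(vols, 0.0, None)
        total = float(vols.sum())
        if abs(total - 1.0) > 1e-9:
            raise DVHValidationError(
                f"fractional volumes must sum to 1 (got {total!r})"
            )
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "fractional_volumes", vols)

    def mean_dose(self) -> float:
        return float(self.fractional_volumes @ self.bin_centers)


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------

def cumulative_to_differential(c: CumulativeDVH) -> DifferentialDVH:
    """Difference a cumulative DVH into fractional volumes per bin.

    Bin i spans [edge_i, edge_{i+1}); its fractional volume is
    V(edge_i) - V(edge_{i+1}) and its center the edge midpoint.  Any
    residual volume still present at the last edge is absorbed into the
    final bin so the fractions always sum to 1.
    """
    edges = c.dose_edges
    vols = c.volume_at_or_above
    if edges.size < 2:
        raise DVHValidationError(
            "cumulative DVH needs at least 2 samples to difference"
        )
    vi = vols[:-1] - vols[1:]
    vi[-1] += vols[-1]  # residual volume at/above the last edge
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DifferentialDVH(c.structure, centers, vi)


def differential_to_cumulative(d: DifferentialDVH) -> CumulativeDVH:
    """Accumulate a differential DVH back to cumulative form.

    Edges are induced midway between adjacent bin centers (with the end
    edges mirrored about the outer centers and the lowest edge clipped to
    0); V at each edge is the total fraction in bins at or above it.  On
    uniform grids this inverts :func:`cumulative_to_differential` exactly.
    """
    centers = d.bin_centers
    vi = d.fractional_volumes
    if centers.size == 1:
        # mirror the lone center about 0: edges [0, 2c] (a step function)
        c0 = centers[0] if centers[0] > 0 else DEFAULT_BIN_WIDTH / 2
        inner = np.array([0.0, 2.0 * c0])
    else:
        mids = 0.5 * (centers[:-1] + centers[1:])
        first = 2 * centers[0] - mids[0]
        last = 2 * centers[-1] - mids[-1]
        inner = np.concatenate([[first], mids, [last]])
    inner[0] = max(inner[0], 0.0)
    if inner[0] > 0:
        edges = np.concatenate([[0.0], inner])
    else:
        edges = inner
    # V(edge) = sum of fractions in bins whose center is >= edge
    vols = np.array([vi[centers >= e].sum() for e in edges])
    return CumulativeDVH(d.structure, edges, vols)


def as_differential(dvh: CumulativeDVH | DifferentialDVH) -> DifferentialDVH:
    """Coerce either DVH form to differential."""
    if isinstance(dvh, DifferentialDVH):
        return dvh
    return cumulative_to_differential(dvh)


def as_cumulative(dvh: CumulativeDVH | DifferentialDVH) -> CumulativeDVH:
    """Coerce either DVH form to cumulative."""
    if isinstance(dvh, CumulativeDVH):
        return dvh
    return differential_to_cumulative(dvh)


def resample(c: CumulativeDVH, bin_width: float = DEFAULT_BIN_WIDTH) -> CumulativeDVH:
    """Linearly interpolate a cumulative DVH onto a uniform dose grid.

    The grid runs from 0 to the smallest multiple of ``bin_width`` at or
    above the last edge.  Linear interpolation of a monotone curve is
    monotone, and resampling an already-uniform DVH at its own width is the
    identity.
    """
    if not (bin_width > 0):
        raise DVHValidationError(f"bin_width must be > 0, got {bin_width}")
    n = int(np.ceil(round(c.max_edge / bin_width, 9)))
    grid = np.arange(n + 1) * bin_width
    vols = np.interp(grid, c.dose_edges, c.volume_at_or_above)
    return CumulativeDVH(c.structure, grid, vols)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = (
    "structure",
    "patient_id",
    "technique",
    "total_volume_cm3",
    "dose_unit",
    "volume_type",
    "volume_unit",
)


def _parse_header(lines: list[str], path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    for key in ("structure", "total_volume_cm3", "volume_type"):
        if key not in meta:
            raise DVHValidationError(f"{path}: missing header key '{key}'")
    if meta["volume_type"] not in ("cumulative", "differential"):
        raise DVHValidationError(
            f"{path}: volume_type must be cumulative|differential, "
            f"got '{meta['volume_type']}'"
        )
    if meta.get("dose_unit", "Gy") not in ("Gy", "cGy"):
        raise DVHValidationError(
            f"{path}: dose_unit must be Gy|cGy, got '{meta.get('dose_unit')}'"
        )
    if meta.get("volume_unit", "fraction") not in ("percent", "cm3", "fraction"):
        raise DVHValidationError(
            f"{path}: volume_unit must be percent|cm3|fraction, "
            f"got '{meta.get('volume_unit')}'"
        )
    return meta


def read_dvh(path: str | Path) -> CumulativeDVH | DifferentialDVH:
    """Read one DVH CSV file, validating and normalizing on the way in.

    Doses in cGy are converted to Gy; volumes in percent or cm3 are
    normalized to fractions of the header's total volume.  Returns the DVH
    type declared by the ``volume_type`` header.
    """
    path = Path(path)
    text = path.read_text()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_header(header_lines, str(path))

    total_volume = float(meta["total_volume_cm3"])
    info = StructureInfo(
        name=meta["structure"],
        total_volume=total_volume,
        patient_id=meta.get("patient_id", ""),
        technique=meta.get("technique", ""),
    )
    data = np.genfromtxt(io.StringIO(text), delimiter=",", comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] != 2 or np.any(~np.isfinite(data)):
        raise DVHValidationError(f"{path}: expected two numeric columns dose,volume")
    doses = data[:, 0].astype(float)
    vols = data[:, 1].astype(float)
    if meta.get("dose_unit", "Gy") == "cGy":
        doses = doses / 100.0
    unit = meta.get("volume_unit", "fraction")
    if unit == "percent":
        vols = vols / 100.0
    elif unit == "cm3":
        vols = vols / total_volume
    try:
        if meta["volume_type"] == "cumulative":
            return CumulativeDVH(info, doses, vols)
        return DifferentialDVH(info, doses, vols)
    except DVHValidationError as exc:
        raise DVHValidationError(f"{path}: {exc}") from exc


def write_dvh(
    dvh: CumulativeDVH | DifferentialDVH,
    path: str | Path,
    *,
    volume_unit: str = "fraction",
) -> Path:
    """Write a DVH to the CSV dialect; re-reading reproduces it to < 1e-9."""
    if volume_unit not in ("percent", "cm3", "fraction"):
        raise DVHValidationError(f"unsupported volume_unit '{volume_unit}'")
    path = Path(path)
    info = dvh.structure
    if isinstance(dvh, CumulativeDVH):
        vtype, doses, vols = "cumulative", dvh.dose_edges, dvh.volume_at_or_above
    else:
        vtype, doses, vols = "differential", dvh.bin_centers, dvh.fractional_volumes
    if volume_unit == "percent":
        out_vols = vols * 100.0
    elif volume_unit == "cm3":
        out_vols = vols * info.total_volume
    else:
        out_vols = vols
    lines = [
        f"# structure={info.name}",
        f"# patient_id={info.patient_id}",
        f"# technique={info.technique}",
        f"# total_volume_cm3={info.total_volume:.10g}",
        "# dose_unit=Gy",
        f"# volume_type={vtype}",
        f"# volume_unit={volume_unit}",
        "# columns=dose,volume",
    ]
    lines += [f"{d:.12g},{v:.12g}" for d, v in zip(doses, out_vols)]
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(
    path: str | Path,
) -> tuple[
    dict[str, dict[str, dict[str, CumulativeDVH | DifferentialDVH]]],
    dict[str, dict[str, float]],
]:
    """Load a plan manifest and every DVH file it references.

    The manifest is JSON with ``plans`` mapping patient_id -> technique ->
    structure name -> DVH file path (relative paths resolved against the
    manifest's directory) and an optional ``monitor_units`` map of
    patient_id -> technique -> MU.  Returns ``(plans, monitor_units)``
    with the DVHs already read and validated; a missing file raises an
    error naming the patient and structure.
    """
    path = Path(path)
    import json

    manifest = json.loads(path.read_text())
    base = path.parent
    plans: dict[str, dict[str, dict[str, CumulativeDVH | DifferentialDVH]]] = {}
    for pid, by_tech in manifest.get("plans", {}).items():
        plans[pid] = {}
        for technique, by_struct in by_tech.items():
            plans[pid][technique] = {}
            for name, rel in by_struct.items():
                fp = base / rel
                if not fp.exists():
                    raise DVHValidationError(
                        f"manifest references missing DVH file for patient "
                        f"{pid}, structure {name}: {fp}"
                    )
                plans[pid][technique][name] = read_dvh(fp)
    mus = {
        pid: {tech: float(v) for tech, v in by_tech.items()}
        for pid, by_tech in manifest.get("monitor_units", {}).items()
    }
    return plans, mus
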