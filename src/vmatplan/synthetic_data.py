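"""Seeded synthetic prostate-VMAT cohorts for end-to-end testing.

The emulated study design is five patients, each planned twice
(single-arc and double-arc) at a 78 Gy prescription; per-structure DVHs
drive all downstream metrics and models.  This module fabricates such
cohorts with the statistical structure the analysis assumes, so the whole
pipeline is exercisable without patient data.

Curve families
--------------
Target (PTV): a probit-shaped falloff ``V(D) = Phi((D_c - D)/sigma)``,
truncated and renormalized to reach 0 at the maximum dose and 1 at zero
dose.  ``(D_c, sigma)`` are solved so the realized D99% and maximum dose
hit the sampled targets exactly (before dose-grid discretization).

Organ at risk: ``V(D) = f * S(D) + (1 - f) * T(D)`` where ``f`` is the
fraction of the organ overlapping the high-dose (target) region, ``S`` a
probit component centered near the prescription dose, and ``T`` a
Weibull-survival low-dose tail ``exp(-(D/tau)^k)`` truncated at the
maximum dose.  The two tail parameters are solved numerically from two
volume targets (V17Gy and V35Gy), or from D5% with a fixed shape for
lateral structures (femoral heads); one exponential time constant alone
cannot realize both published VxGy levels, hence the second parameter.

Paired-cohort structure
-----------------------
The emulated study is paired: every patient is planned with both
techniques, and the published per-metric SDs are between-patient spreads.
Anatomy (structure volumes, overlap fractions) is therefore drawn once
per patient and shared between that patient's two plans, and each metric
draw decomposes into a patient-level random effect (shared by the two
techniques) plus a smaller technique-specific residual, with correlation
``paired_correlation`` (default 0.8: plan metrics of the same patient
track each other because the same anatomy drives both optimizations).
All randomness flows from one top-level seed through per-patient
substreams, so cohorts are reproducible patient by patient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .dvh_core import CumulativeDVH, StructureInfo, write_dvh
from .radiobiology import normal_cdf

__all__ = [
    "InfeasibleModelError",
    "StructureModel",
    "CohortConfig",
    "GeneratedCohort",
    "probit_falloff",
    "weibull_tail",
    "target_dvh_from_params",
    "oar_dvh_from_params",
    "lateral_dvh_from_params",
    "generate_target_dvh",
    "generate_oar_dvh",
    "generate_cohort",
    "reference_cohort_config",
]

PRESCRIPTION_DOSE = 78.0  # Gy, 39 x 2 Gy


class InfeasibleModelError(ValueError):
    """Raised when sampled/requested DVH targets cannot be realized."""


# ---------------------------------------------------------------------------
# curve primitives
# ---------------------------------------------------------------------------

def probit_falloff(dose, center: float, sigma: float, d_max: float):
    """Truncated, renormalized probit falloff: 1 at dose 0, 0 at d_max.

    ``sigma -> 0`` degenerates to a unit step at ``center``.
    """
    dose = np.asarray(dose, dtype=float)
    if sigma <= 0:
        return np.where(dose < min(center, d_max), 1.0, 0.0)
    lo = normal_cdf((center - d_max) / sigma)
    hi = normal_cdf(center / sigma)
    v = (normal_cdf((center - dose) / sigma) - lo) / (hi - lo)
    return np.clip(np.where(dose >= d_max, 0.0, v), 0.0, 1.0)


def weibull_tail(dose, tau: float, k: float, d_cut: float):
    """Truncated Weibull survival: exp(-(D/tau)^k), renormalized to reach
    0 at ``d_cut`` and 1 at dose 0."""
    dose = np.asarray(dose, dtype=float)
    e_cut = math.exp(-((d_cut / tau) ** k))
    v = (np.exp(-((np.clip(dose, 0, None) / tau) ** k)) - e_cut) / (1.0 - e_cut)
    return np.clip(np.where(dose >= d_cut, 0.0, v), 0.0, 1.0)


def _dose_grid(d_max: float, bin_width: float) -> np.ndarray:
    n = int(math.ceil(round(d_max / bin_width, 9)))
    return np.arange(n + 1) * bin_width


# ---------------------------------------------------------------------------
# curve calibration
# ---------------------------------------------------------------------------

def _solve_target_shape(d99: float, d_max: float) -> tuple[float, float]:
    """Solve (center, sigma) of the truncated probit so V(d99) = 0.99."""
    if not (0 < d99 < d_max):
        raise InfeasibleModelError(
            f"target needs 0 < D99% < max dose, got D99%={d99}, max={d_max}"
        )
    center = 0.5 * (d99 + d_max)

    def gap(sigma: float) -> float:
        return float(probit_falloff(d99, center, sigma, d_max)) - 0.99

    # sigma -> 0: step beyond d99 -> V=1 (gap>0); huge sigma: near-linear
    # falloff -> V(d99) well below 0.99 (gap<0)
    return center, brentq(gap, 1e-6, 1e3, xtol=1e-12)


# clinical cumulative DVH tails are moderately convex; Weibull shapes
# outside this band are degenerate (near-flat or cliff) curves
_TAIL_SHAPE_RANGE = (0.3, 5.0)
_TAIL_TAU_RANGE = (0.5, 5000.0)


def _solve_tail_tau(d: float, t: float, k: float, d_cut: float) -> float:
    """tau such that the truncated Weibull passes through (d, t) for a
    fixed shape k; T(d) is strictly increasing in tau."""
    lo, hi = _TAIL_TAU_RANGE
    f = lambda tau: float(weibull_tail(d, tau, k, d_cut)) - t
    if f(hi) < 0:
        raise InfeasibleModelError(
            f"tail value T({d})={t:.4f} unreachable below cutoff {d_cut:.1f}"
        )
    if f(lo) > 0:
        raise InfeasibleModelError(f"tail value T({d})={t:.4f} too small")
    return brentq(f, lo, hi, xtol=1e-12)


def _solve_tail_shape(
    t_pairs: list[tuple[float, float]], d_cut: float
) -> tuple[float, float]:
    """Solve (tau, k) of the truncated Weibull through two (dose, value)
    points: the inner solve pins tau on the lower point for a trial shape,
    the outer solve adjusts the shape until the upper point matches too."""
    (d_lo, t_lo), (d_hi, t_hi) = t_pairs
    if not (0 < t_hi < t_lo < 1):
        raise InfeasibleModelError(
            f"tail targets must satisfy 0 < T({d_hi})={t_hi:.4f} < "
            f"T({d_lo})={t_lo:.4f} < 1"
        )

    def gap(k: float) -> float:
        tau = _solve_tail_tau(d_lo, t_lo, k, d_cut)
        return float(weibull_tail(d_hi, tau, k, d_cut)) - t_hi

    # the lower anchor point may be unreachable for very flat shapes
    # (truncation caps the curve); bracket from the smallest feasible k
    k_lo, k_hi = _TAIL_SHAPE_RANGE
    g_lo = None
    for k_try in np.linspace(k_lo, k_hi, 25):
        try:
            g_lo, k_lo = gap(float(k_try)), float(k_try)
            break
        except InfeasibleModelError:
            continue
    if g_lo is None:
        raise InfeasibleModelError(
            f"tail targets {t_pairs} unreachable below cutoff {d_cut:.1f}"
        )
    g_hi = gap(k_hi)
    if g_lo * g_hi > 0:
        raise InfeasibleModelError(
            f"tail targets {t_pairs} need a shape outside "
            f"[{k_lo:.2f}, {k_hi}] (degenerate curve)"
        )
    k = brentq(gap, k_lo, k_hi, xtol=1e-12)
    tau = _solve_tail_tau(d_lo, t_lo, k, d_cut)
    return tau, k


def _solve_lateral_tau(d_at_5pct: float, k: float, d_max: float) -> float:
    """Solve tau so the truncated Weibull has V(d_at_5pct) = 0.05."""
    if not (0 < d_at_5pct < d_max):
        raise InfeasibleModelError(
            f"need 0 < D5% < max dose, got D5%={d_at_5pct}, max={d_max}"
        )
    limit = 1.0 - (d_at_5pct / d_max) ** k  # tau -> inf limit of V(d5)
    if limit <= 0.05:
        raise InfeasibleModelError(
            f"D5%={d_at_5pct} too close to max dose {d_max} for tail shape k={k}"
        )

    def gap(tau: float) -> float:
        return float(weibull_tail(d_at_5pct, tau, k, d_max)) - 0.05

    return brentq(gap, 1e-2, 1e4, xtol=1e-12)


# ---------------------------------------------------------------------------
# DVH construction from explicit parameters
# ---------------------------------------------------------------------------

def target_dvh_from_params(
    info: StructureInfo,
    d99: float,
    max_dose: float,
    bin_width: float = 0.1,
) -> CumulativeDVH:
    """Target DVH realizing the given D99% and maximum dose exactly
    (up to dose-grid interpolation)."""
    center, sigma = _solve_target_shape(d99, max_dose)
    grid = _dose_grid(max_dose, bin_width)
    vols = probit_falloff(grid, center, sigma, max_dose)
    vols[0] = 1.0
    return CumulativeDVH(info, grid, vols)


def oar_dvh_from_params(
    info: StructureInfo,
    v17: float,
    v35: float,
    max_dose: float,
    overlap_fraction: float,
    overlap_dose: float,
    overlap_sigma: float = 1.2,
    bin_width: float = 0.1,
) -> CumulativeDVH:
    """Overlap-organ DVH (rectum/bladder style) realizing V17Gy and V35Gy.

    ``v17``/``v35`` are fractions in (0, 1).  The overlap component puts
    ``overlap_fraction`` of the organ at near-prescription doses centered
    on ``overlap_dose``; the tail parameters are solved so the composite
    curve hits both VxGy targets exactly.
    """
    f = overlap_fraction
    if not (0 <= f < 1):
        raise InfeasibleModelError(f"overlap fraction must be in [0, 1), got {f}")

    def overlap(dose):
        return probit_falloff(dose, overlap_dose, overlap_sigma, max_dose)

    t_pairs = []
    for d_ref, v_ref in ((17.0, v17), (35.0, v35)):
        t = (v_ref - f * float(overlap(d_ref))) / (1.0 - f)
        if not (0 < t < 1):
            raise InfeasibleModelError(
                f"V{d_ref:g}Gy={100 * v_ref:.1f}% unreachable with overlap "
                f"fraction {f:.3f}"
            )
        t_pairs.append((d_ref, t))
    tau, k = _solve_tail_shape(t_pairs, max_dose)

    grid = _dose_grid(max_dose, bin_width)
    vols = f * overlap(grid) + (1 - f) * weibull_tail(grid, tau, k, max_dose)
    vols[0] = 1.0
    return CumulativeDVH(info, grid, np.minimum.accumulate(vols))


def lateral_dvh_from_params(
    info: StructureInfo,
    d5: float,
    max_dose: float,
    tail_shape: float = 2.5,
    bin_width: float = 0.1,
) -> CumulativeDVH:
    """Lateral-organ DVH (femoral-head style): pure low-dose tail, no
    high-dose overlap, realizing the given D5%."""
    tau = _solve_lateral_tau(d5, tail_shape, max_dose)
    grid = _dose_grid(max_dose, bin_width)
    vols = weibull_tail(grid, tau, tail_shape, max_dose)
    vols[0] = 1.0
    return CumulativeDVH(info, grid, vols)


# ---------------------------------------------------------------------------
# cohort models
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Generation model of one structure across both techniques.

    ``targets`` maps technique -> metric label -> (mean, SD) of the value
    the generated DVH should realize; labels by role:

    - target: ``D99%``, ``max`` (Gy)
    - overlap_oar: ``V17Gy``, ``V35Gy`` (%), ``max``, ``overlap_dose`` (Gy)
    - lateral_oar: ``D5%``, ``max`` (Gy)

    ``volume_range`` (cm3) and ``overlap_fraction`` are patient anatomy,
    drawn once per patient and shared by both techniques.
    """

    name: str
    role: str  # target | overlap_oar | lateral_oar
    volume_range: tuple[float, float]
    targets: dict[str, dict[str, tuple[float, float]]]
    overlap_fraction: tuple[float, float] | None = None  # (mean, SD)
    overlap_sigma: float = 1.2
    tail_shape: float = 2.5

    def __post_init__(self) -> None:
        if self.role not in ("target", "overlap_oar", "lateral_oar"):
            raise ValueError(f"unknown structure role '{self.role}'")
        if self.role == "overlap_oar" and self.overlap_fraction is None:
            raise ValueError("overlap_oar requires an overlap_fraction model")
        for tech, metric_map in self.targets.items():
            for label, (_, sd) in metric_map.items():
                if sd < 0:
                    raise ValueError(f"{self.name}/{tech}/{label}: SD must be >= 0")


@dataclass
class CohortConfig:
    """Study-design knobs of one synthetic paired cohort."""

    structures: list[StructureModel]
    n_patients: int = 5
    seed: int = 1234
    techniques: tuple[str, str] = ("single-arc", "double-arc")
    prescription_dose: float = PRESCRIPTION_DOSE
    bin_width: float = 0.1
    monitor_units: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: within-patient correlation of a metric between the two techniques
    paired_correlation: float = 0.8

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class GeneratedCohort:
    """In-memory result of :func:`generate_cohort`."""

    config: CohortConfig
    plans: dict[str, dict[str, dict[str, CumulativeDVH]]]  # pid -> tech -> structure
    monitor_units: dict[str, dict[str, float]]  # pid -> tech -> MU
    manifest_path: Path | None = None


_MAX_REDRAWS = 200


#: draws are truncated at this many SDs from the configured mean
_DRAW_CLIP_SD = 2.5


def _draw(
    rng: np.random.Generator,
    mean_sd: tuple[float, float],
    patient_z: float | None = None,
    rho: float = 0.0,
) -> float:
    """One metric draw; with a patient-level effect ``patient_z`` the value
    is mean + sd * (rho * z_patient + sqrt(1 - rho^2) * z_technique),
    truncated to +-2.5 SD about the mean."""
    mean, sd = mean_sd
    if sd <= 0:
        return float(mean)
    eps = float(rng.standard_normal())
    if patient_z is None or rho <= 0:
        z = eps
    else:
        z = rho * patient_z + math.sqrt(1.0 - rho * rho) * eps
    return mean + sd * float(np.clip(z, -_DRAW_CLIP_SD, _DRAW_CLIP_SD))


def _sample_anatomy(model: StructureModel, rng: np.random.Generator) -> dict:
    """Patient-level state shared by both plans: volume, overlap fraction,
    and one standard-normal "dose burden" effect driving every metric of
    the structure (a patient whose organ sits close to the target runs hot
    in all of its dose metrics at once)."""
    lo, hi = model.volume_range
    anatomy = {"volume": float(rng.uniform(lo, hi))}
    if model.overlap_fraction is not None:
        f_mean, f_sd = model.overlap_fraction
        anatomy["overlap_fraction"] = float(
            np.clip(rng.normal(f_mean, f_sd), 0.005, 0.6)
        )
    anatomy["z"] = float(rng.standard_normal())
    return anatomy


def _structure_dvh(
    model: StructureModel,
    technique: str,
    rng: np.random.Generator,
    anatomy: dict,
    info: StructureInfo,
    bin_width: float,
    rho: float = 0.0,
) -> CumulativeDVH:
    """Sample this technique's metric targets and realize the DVH,
    redrawing the technique residuals (bounded) when a draw is
    geometrically infeasible."""
    spec = model.targets[technique]
    z = anatomy.get("z")

    def draw(label: str) -> float:
        return _draw(rng, spec[label], z, rho)

    last_err: InfeasibleModelError | None = None
    for _ in range(_MAX_REDRAWS):
        try:
            if model.role == "target":
                return target_dvh_from_params(
                    info, draw("D99%"), draw("max"), bin_width
                )
            if model.role == "overlap_oar":
                v17 = draw("V17Gy") / 100.0
                v35 = draw("V35Gy") / 100.0
                dmax = draw("max")
                d_ov = draw("overlap_dose")
                if not (0 < v35 < v17 < 1) or not (d_ov < dmax):
                    raise InfeasibleModelError("incoherent OAR draw")
                return oar_dvh_from_params(
                    info, v17, v35, dmax,
                    anatomy["overlap_fraction"], d_ov,
                    model.overlap_sigma, bin_width,
                )
            return lateral_dvh_from_params(
                info, draw("D5%"), draw("max"), model.tail_shape, bin_width
            )
        except InfeasibleModelError as err:
            last_err = err
    raise InfeasibleModelError(
        f"{model.name}/{technique}: no feasible draw in {_MAX_REDRAWS} tries "
        f"(last: {last_err})"
    )


def generate_target_dvh(
    model: StructureModel,
    rng: np.random.Generator,
    technique: str = "single-arc",
    patient_id: str = "",
    bin_width: float = 0.1,
) -> CumulativeDVH:
    """Sample and realize one target-structure DVH."""
    if model.role != "target":
        raise ValueError(f"structure '{model.name}' has role '{model.role}'")
    anatomy = _sample_anatomy(model, rng)
    info = StructureInfo(model.name, anatomy["volume"], patient_id, technique)
    return _structure_dvh(model, technique, rng, anatomy, info, bin_width)


def generate_oar_dvh(
    model: StructureModel,
    rng: np.random.Generator,
    technique: str = "single-arc",
    patient_id: str = "",
    bin_width: float = 0.1,
) -> CumulativeDVH:
    """Sample and realize one organ-at-risk DVH (overlap or lateral)."""
    if model.role not in ("overlap_oar", "lateral_oar"):
        raise ValueError(f"structure '{model.name}' has role '{model.role}'")
    anatomy = _sample_anatomy(model, rng)
    info = StructureInfo(model.name, anatomy["volume"], patient_id, technique)
    return _structure_dvh(model, technique, rng, anatomy, info, bin_width)


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> GeneratedCohort:
    """Generate the full paired cohort; optionally write DVH CSV files and
    a plan manifest under ``out_dir``.

    Each patient gets an independent substream derived from the top-level
    seed, so cohorts are reproducible patient by patient and byte-identical
    across runs with the same seed.
    """
    plans: dict[str, dict[str, dict[str, CumulativeDVH]]] = {}
    mus: dict[str, dict[str, float]] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng([config.seed, i])
        anatomy = {m.name: _sample_anatomy(m, rng) for m in config.structures}
        plans[pid] = {}
        mus[pid] = {}
        for technique in config.techniques:
            plans[pid][technique] = {}
            for model in config.structures:
                info = StructureInfo(
                    model.name, anatomy[model.name]["volume"], pid, technique
                )
                plans[pid][technique][model.name] = _structure_dvh(
                    model, technique, rng, anatomy[model.name], info,
                    config.bin_width, config.paired_correlation,
                )
            if technique in config.monitor_units:
                mus[pid][technique] = round(_draw(rng, config.monitor_units[technique]))

    cohort = GeneratedCohort(config=config, plans=plans, monitor_units=mus)
    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest: dict = {
            "seed": config.seed,
            "prescription_dose_gy": config.prescription_dose,
            "plans": {},
            "monitor_units": mus,
        }
        for pid, by_tech in plans.items():
            manifest["plans"][pid] = {}
            for technique, by_struct in by_tech.items():
                manifest["plans"][pid][technique] = {}
                for name, dvh in by_struct.items():
                    rel = Path(pid) / technique / f"{name}.csv"
                    write_dvh(dvh, out_dir / rel)
                    manifest["plans"][pid][technique][name] = str(rel)
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        cohort.manifest_path = manifest_path
    return cohort


# ---------------------------------------------------------------------------
# cohort configuration mirroring the published study summaries
# ---------------------------------------------------------------------------

def reference_cohort_config(n_patients: int = 5, seed: int = 1234) -> CohortConfig:
    """Default cohort: five paired prostate VMAT plans at 78 Gy.

    Metric targets encode the published cohort means and SDs per technique
    (PTV D99% 72.5+-0.8 vs 74.6+-0.4 Gy, rectal V17Gy 61.1 vs 47.7% etc.);
    structure-volume ranges span the published per-patient volumes.  The
    overlap component of the double-arc plans is centered slightly higher
    (78.3 vs 77.3 Gy), reflecting the reported higher dose in the
    PTV-rectum overlap that drives its higher rectal NTCP.
    """
    s = "single-arc"
    d = "double-arc"
    structures = [
        StructureModel(
            name="PTV", role="target", volume_range=(107.0, 196.1),
            targets={
                s: {"D99%": (72.5, 0.8), "max": (82.7, 0.8)},
                d: {"D99%": (74.6, 0.4), "max": (82.8, 0.7)},
            },
        ),
        StructureModel(
            name="Rectum", role="overlap_oar", volume_range=(42.3, 110.1),
            overlap_fraction=(0.10, 0.02),
            targets={
                s: {"V17Gy": (61.1, 8.5), "V35Gy": (29.6, 5.9),
                    "max": (80.1, 0.8), "overlap_dose": (77.3, 0.4)},
                d: {"V17Gy": (47.7, 9.0), "V35Gy": (25.1, 4.9),
                    "max": (80.1, 0.8), "overlap_dose": (78.3, 0.4)},
            },
        ),
        StructureModel(
            name="Bladder", role="overlap_oar", volume_range=(182.5, 552.6),
            overlap_fraction=(0.06, 0.015),
            targets={
                s: {"V17Gy": (40.7, 9.8), "V35Gy": (25.1, 5.3),
                    "max": (80.7, 1.4), "overlap_dose": (77.3, 0.4)},
                d: {"V17Gy": (35.4, 7.8), "V35Gy": (20.8, 4.9),
                    "max": (80.7, 1.1), "overlap_dose": (78.3, 0.4)},
            },
        ),
        StructureModel(
            name="LeftFemoralHead", role="lateral_oar",
            volume_range=(146.6, 201.4),
            targets={
                s: {"D5%": (31.0, 6.6), "max": (40.4, 5.7)},
                d: {"D5%": (41.6, 2.1), "max": (49.4, 2.4)},
            },
        ),
        StructureModel(
            name="RightFemoralHead", role="lateral_oar",
            volume_range=(153.4, 246.0),
            targets={
                s: {"D5%": (28.4, 4.9), "max": (38.9, 3.8)},
                d: {"D5%": (39.4, 3.9), "max": (47.1, 5.8)},
            },
        ),
    ]
    return CohortConfig(
        structures=structures,
        n_patients=n_patients,
        seed=seed,
        monitor_units={s: (536.0, 47.0), d: (640.2, 61.0)},
    )
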