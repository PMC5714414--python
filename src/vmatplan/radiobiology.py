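"""Tumor control and normal-tissue complication probability models.

TCP: a logistic dose-response ``TCP(D) = e^(p+qD) / (1 + e^(p+qD))``
parameterized by the dose giving 50% control (D50) and the normalized
slope at that point (gamma50); applied per differential-DVH bin as an
independent "tumorlet" and combined by the volume-weighted product
``TCP = prod_i TCP(D_i)^{v_i}``.

NTCP: the Lyman probit model with Kutcher-Burman DVH reduction.  A
heterogeneous DVH is reduced to an effective fraction of the organ
``v_eff = sum_i v_i (D_i / D_ref)^(1/n)`` uniformly irradiated at the
reference (maximum) dose; the tolerance dose scales with partial volume as
``TD50(v) = TD50(1) * v^(-n)`` and ``NTCP = Phi((D_ref - TD50(v)) /
(m TD50(v)))``.

Doses are total-course physical doses; no fractionation (LQ/EQD2)
correction is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erfc, expit

from .dvh_core import DifferentialDVH

__all__ = [
    "TCPParameters",
    "LKBParameters",
    "LKBIntermediate",
    "tcp_params_from_d50_gamma50",
    "tcp_uniform",
    "tcp_from_dvh",
    "kb_effective_volume",
    "lkb_ntcp",
    "lyman_ntcp_uniform",
    "normal_cdf",
    "DEFAULT_TCP_PARAMS",
    "DEFAULT_LKB_PARAMS",
    "load_model_parameters",
]

#: |t| beyond which the probit saturates to 0/1 at double precision.
_PROBIT_SATURATION = 8.0


@dataclass(frozen=True)
class TCPParameters:
    """Logistic TCP parameters.

    D50 is the dose (Gy) giving 50% control and gamma50 the normalized
    dose-response slope there; the logistic coefficients follow as
    ``q = 4 gamma50 / D50`` (Gy^-1) and ``p = -4 gamma50``, which makes
    TCP(D50) = 0.5 and D50 * TCP'(D50) = gamma50 exact.
    """

    D50: float
    gamma50: float

    def __post_init__(self) -> None:
        if not (self.D50 > 0 and self.gamma50 > 0):
            raise ValueError("D50 and gamma50 must both be > 0")

    @property
    def q(self) -> float:
        return 4.0 * self.gamma50 / self.D50

    @property
    def p(self) -> float:
        return -4.0 * self.gamma50


@dataclass(frozen=True)
class LKBParameters:
    """Lyman model parameters: whole-volume TD50(1) in Gy, probit slope m,
    volume exponent n."""

    TD50_1: float
    m: float
    n: float

    def __post_init__(self) -> None:
        if not (self.TD50_1 > 0 and self.m > 0 and self.n > 0):
            raise ValueError("TD50_1, m and n must all be > 0")


@dataclass(frozen=True)
class LKBIntermediate:
    """Audit trail of one NTCP evaluation: the effective uniformly
    irradiated fraction, the reference dose it is referred to, the
    partial-volume tolerance dose, and the probit argument."""

    veff: float
    D_ref: float
    TD50_v: float
    t: float


#: Default prostate TCP parameters; clinical dose-response summaries for
#: prostate put D50 near 67.5 Gy with gamma50 around 2.  Overridable via
#: the model-parameter file.
DEFAULT_TCP_PARAMS = TCPParameters(D50=67.5, gamma50=2.0)

#: Rectal Lyman parameter set (late rectal toxicity tolerance).
DEFAULT_LKB_PARAMS = LKBParameters(TD50_1=80.0, m=0.15, n=0.12)


def tcp_params_from_d50_gamma50(D50: float, gamma50: float) -> TCPParameters:
    """Build logistic TCP coefficients from (D50, gamma50)."""
    return TCPParameters(D50=D50, gamma50=gamma50)


def tcp_uniform(D, params: TCPParameters = DEFAULT_TCP_PARAMS):
    """Logistic TCP for a uniform dose D (Gy); overflow-safe."""
    D = np.asarray(D, dtype=float)
    out = expit(params.p + params.q * D)
    return float(out) if out.ndim == 0 else out


def _log_tcp(D: np.ndarray, params: TCPParameters) -> np.ndarray:
    # log of the logistic, stable for large negative arguments
    z = params.p + params.q * np.asarray(D, dtype=float)
    return -np.logaddexp(0.0, -z)


def tcp_from_dvh(
    d: DifferentialDVH, params: TCPParameters = DEFAULT_TCP_PARAMS
) -> float:
    """Whole-volume TCP as the tumorlet product prod TCP(D_i)^{v_i}.

    Accumulated in the log domain; bins with zero fractional volume do not
    contribute (0 * log 0 treated as 0).
    """
    vi = d.fractional_volumes
    mask = vi > 0
    log_terms = _log_tcp(d.bin_centers[mask], params)
    if np.any(np.isneginf(log_terms)):
        return 0.0
    return float(math.exp(float(vi[mask] @ log_terms)))


def kb_effective_volume(
    d: DifferentialDVH, n: float, D_ref: float | None = None
) -> tuple[float, float]:
    """Kutcher-Burman effective volume of a heterogeneous DVH.

    Returns ``(veff, D_ref)`` with ``veff = sum_i v_i (D_i / D_ref)^(1/n)``;
    D_ref defaults to the maximum dose with nonzero volume.  Zero-dose bins
    contribute nothing.  Scaling all doses by a constant leaves veff
    unchanged.
    """
    if not (n > 0):
        raise ValueError(f"volume exponent n must be > 0, got {n}")
    vi = d.fractional_volumes
    Di = d.bin_centers
    hot = (vi > 0) & (Di > 0)
    if not hot.any():
        raise ValueError("DVH has no irradiated volume (all doses zero)")
    if D_ref is None:
        D_ref = float(Di[hot].max())
    if not (D_ref > 0):
        raise ValueError(f"reference dose must be > 0 Gy, got {D_ref}")
    veff = float(vi[hot] @ np.power(Di[hot] / D_ref, 1.0 / n))
    return veff, D_ref


def normal_cdf(t):
    """Standard normal CDF Phi(t) via the complementary error function."""
    t = np.asarray(t, dtype=float)
    out = 0.5 * erfc(-t / math.sqrt(2.0))
    return float(out) if out.ndim == 0 else out


def lkb_ntcp(
    d: DifferentialDVH,
    params: LKBParameters = DEFAULT_LKB_PARAMS,
    D_ref: float | None = None,
) -> tuple[float, LKBIntermediate]:
    """Lyman-Kutcher-Burman NTCP of a differential DVH.

    Reduces the DVH to (veff, D_ref), evaluates the partial-volume
    tolerance dose TD50(veff) = TD50(1) veff^(-n) and the probit argument
    t = (D_ref - TD50(veff)) / (m TD50(veff)), and returns
    (Phi(t), intermediates).  A DVH with no irradiated volume yields
    NTCP = 0 with veff flagged as 0.
    """
    vi = d.fractional_volumes
    if not ((vi > 0) & (d.bin_centers > 0)).any():
        return 0.0, LKBIntermediate(veff=0.0, D_ref=0.0, TD50_v=math.inf, t=-math.inf)
    veff, D_ref = kb_effective_volume(d, params.n, D_ref)
    td50_v = params.TD50_1 * veff ** (-params.n)
    t = (D_ref - td50_v) / (params.m * td50_v)
    return float(normal_cdf(t)), LKBIntermediate(veff, D_ref, td50_v, t)


def lyman_ntcp_uniform(
    D: float, v: float, params: LKBParameters = DEFAULT_LKB_PARAMS
) -> float:
    """Closed-form Lyman NTCP for a uniform dose D to a partial volume v.

    Direct evaluation of Phi((D - TD50(v)) / (m TD50(v))) with
    TD50(v) = TD50(1) v^(-n); the KB-reduced path must agree with this on
    uniform partial-volume DVHs.
    """
    if not (0 < v <= 1):
        raise ValueError(f"partial volume must be in (0, 1], got {v}")
    if D <= 0:
        return 0.0
    td50_v = params.TD50_1 * v ** (-params.n)
    t = (D - td50_v) / (params.m * td50_v)
    return float(normal_cdf(t))


def load_model_parameters(path: str | Path) -> tuple[TCPParameters, LKBParameters]:
    """Read a JSON/YAML model-parameter file.

    Layout: ``{"tcp": {"D50": ..., "gamma50": ...},
    "ntcp": {"TD50_1": ..., "m": ..., "n": ...}}``; missing sections fall
    back to the package defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    tcp_cfg = cfg.get("tcp", {})
    ntcp_cfg = cfg.get("ntcp", {})
    tcp = TCPParameters(
        D50=float(tcp_cfg.get("D50", DEFAULT_TCP_PARAMS.D50)),
        gamma50=float(tcp_cfg.get("gamma50", DEFAULT_TCP_PARAMS.gamma50)),
    )
    lkb = LKBParameters(
        TD50_1=float(ntcp_cfg.get("TD50_1", DEFAULT_LKB_PARAMS.TD50_1)),
        m=float(ntcp_cfg.get("m", DEFAULT_LKB_PARAMS.m)),
        n=float(ntcp_cfg.get("n", DEFAULT_LKB_PARAMS.n)),
    )
    return tcp, lkb
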