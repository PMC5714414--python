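"""Unit, oracle and property tests for the TCP and LKB NTCP models."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from vmatplan import (
    DifferentialDVH,
    LKBParameters,
    StructureInfo,
    TCPParameters,
    kb_effective_volume,
    lkb_ntcp,
    load_model_parameters,
    lyman_ntcp_uniform,
    normal_cdf,
    tcp_from_dvh,
    tcp_params_from_d50_gamma50,
    tcp_uniform,
)
from vmatplan.radiobiology import DEFAULT_LKB_PARAMS

RECTAL = LKBParameters(TD50_1=80.0, m=0.15, n=0.12)
PROSTATE = TCPParameters(D50=67.5, gamma50=2.0)


def _phi_quadrature(t: float) -> float:
    """Independent probit oracle: adaptive quadrature of the Gaussian
    density from -infinity to t."""
    val, _ = quad(lambda x: math.exp(-x * x / 2.0) / math.sqrt(2 * math.pi),
                  -np.inf, t, limit=200)
    return val


class TestTCPParameters:
    def test_coefficient_algebra(self):
        params = tcp_params_from_d50_gamma50(67.5, 2.0)
        assert params.q == pytest.approx(8.0 / 67.5, rel=1e-12)
        assert params.p == pytest.approx(-8.0)
        # p + q * D50 = 0 pins the 50% point
        assert params.p + params.q * params.D50 == pytest.approx(0.0, abs=1e-12)

    def test_half_control_at_d50(self):
        for d50, g in [(60.0, 1.0), (67.5, 2.0), (80.0, 3.5)]:
            assert tcp_uniform(d50, TCPParameters(d50, g)) == pytest.approx(0.5)

    def test_normalized_slope_by_finite_differences(self):
        for d50, g in [(67.5, 2.0), (55.0, 1.3)]:
            params = TCPParameters(d50, g)
            h = 1e-4
            slope = (tcp_uniform(d50 + h, params) - tcp_uniform(d50 - h, params)) / (2 * h)
            assert d50 * slope == pytest.approx(g, abs=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            TCPParameters(-1.0, 2.0)
        with pytest.raises(ValueError):
            TCPParameters(67.5, 0.0)


class TestTCPUniform:
    def test_prescription_dose_value(self):
        # logit = -8 + (8/67.5)*78 = 1.24444...; 1/(1 + e^-logit)
        assert tcp_uniform(78.0, PROSTATE) == pytest.approx(0.7763366865676725,
                                                            abs=1e-12)

    def test_bounded_and_overflow_safe(self):
        assert 0.0 < tcp_uniform(0.0, PROSTATE) < 0.5
        extreme = TCPParameters(D50=67.5, gamma50=200.0)
        assert tcp_uniform(0.0, extreme) >= 0.0
        assert tcp_uniform(1000.0, extreme) <= 1.0
        assert np.isfinite(tcp_uniform(0.0, extreme))


class TestTCPFromDVH:
    def test_uniform_dvh_matches_uniform_formula(self, uniform_dvh_factory):
        d = uniform_dvh_factory(78.0)
        assert tcp_from_dvh(d, PROSTATE) == pytest.approx(
            tcp_uniform(78.0, PROSTATE), abs=1e-12)

    def test_equal_halves_at_same_dose(self, info):
        d = DifferentialDVH(info, [69.999999, 70.000001], [0.5, 0.5])
        assert tcp_from_dvh(d, PROSTATE) == pytest.approx(
            tcp_uniform(70.0, PROSTATE), abs=1e-6)

    def test_two_bin_product_oracle(self, info):
        d = DifferentialDVH(info, [70.0, 80.0], [0.5, 0.5])
        expected = math.sqrt(tcp_uniform(70.0, PROSTATE)
                             * tcp_uniform(80.0, PROSTATE))
        assert tcp_from_dvh(d, PROSTATE) == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_bin_refinement_invariance(self, seed):
        """Splitting any bin into sub-bins at the same dose leaves the
        tumorlet product unchanged (exponent additivity)."""
        rng = np.random.default_rng(seed)
        info = StructureInfo("CTV", 40.0)
        doses = np.sort(rng.uniform(40, 85, 4))
        doses += np.arange(4) * 1e-6  # enforce strictly increasing
        vols = rng.dirichlet(np.ones(4))
        coarse = DifferentialDVH(info, doses, vols)
        # split each bin into two half-volume bins at (almost) the same dose
        fine_doses = np.sort(np.concatenate([doses - 5e-10, doses + 5e-10]))
        fine_vols = np.repeat(vols / 2.0, 2)
        fine = DifferentialDVH(info, fine_doses, fine_vols)
        assert tcp_from_dvh(fine, PROSTATE) == pytest.approx(
            tcp_from_dvh(coarse, PROSTATE), abs=1e-7)

    def test_monotone_under_dose_escalation(self, info):
        d1 = DifferentialDVH(info, [60.0, 75.0], [0.4, 0.6])
        d2 = DifferentialDVH(info, [66.0, 82.5], [0.4, 0.6])
        assert tcp_from_dvh(d2, PROSTATE) > tcp_from_dvh(d1, PROSTATE)


class TestEffectiveVolume:
    def test_uniform_dvh_gives_unity(self, uniform_dvh_factory):
        veff, d_ref = kb_effective_volume(uniform_dvh_factory(64.0), n=0.12)
        assert veff == pytest.approx(1.0, abs=1e-12)
        assert d_ref == 64.0

    def test_two_bin_oracle(self, info):
        # 0.5 + 0.5 * (35/70)^(1/0.12) = 0.5 + 0.5 * 0.5^8.3333
        d = DifferentialDVH(info, [35.0, 70.0], [0.5, 0.5])
        veff, d_ref = kb_effective_volume(d, n=0.12)
        assert d_ref == 70.0
        assert veff == pytest.approx(0.5 + 0.5 * 0.5 ** (1 / 0.12), rel=1e-9)
        assert veff == pytest.approx(0.50155, abs=5e-6)

    def test_dose_scaling_invariance(self, info):
        d1 = DifferentialDVH(info, [30.0, 60.0, 75.0], [0.3, 0.3, 0.4])
        d2 = DifferentialDVH(info, [33.0, 66.0, 82.5], [0.3, 0.3, 0.4])
        v1, _ = kb_effective_volume(d1, n=0.12)
        v2, _ = kb_effective_volume(d2, n=0.12)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_zero_dose_bins_ignored(self, partial_dvh_factory):
        veff, d_ref = kb_effective_volume(partial_dvh_factory(70.0, 0.5), n=0.12)
        assert veff == pytest.approx(0.5)
        assert d_ref == 70.0

    def test_requires_irradiated_volume(self, info):
        d = DifferentialDVH(info, [0.0], [1.0])
        with pytest.raises(ValueError):
            kb_effective_volume(d, n=0.12)


class TestLKBNTCP:
    def test_whole_organ_tolerance_fixed_point(self, uniform_dvh_factory):
        ntcp, inter = lkb_ntcp(uniform_dvh_factory(80.0), RECTAL)
        assert inter.t == pytest.approx(0.0, abs=1e-12)
        assert ntcp == pytest.approx(0.5, abs=1e-12)

    def test_half_organ_oracle(self, partial_dvh_factory):
        # TD50(0.5) = 80 * 0.5^-0.12 = 86.94 Gy; t = (70-TD50)/(0.15 TD50)
        ntcp, inter = lkb_ntcp(partial_dvh_factory(70.0, 0.5), RECTAL)
        td50_half = 80.0 * 0.5 ** -0.12
        assert inter.TD50_v == pytest.approx(td50_half, rel=1e-12)
        assert td50_half == pytest.approx(86.94, abs=5e-3)
        t_expected = (70.0 - td50_half) / (0.15 * td50_half)
        assert inter.t == pytest.approx(t_expected, rel=1e-12)
        assert t_expected == pytest.approx(-1.299, abs=1e-3)
        assert ntcp == pytest.approx(_phi_quadrature(t_expected), abs=1e-9)
        assert ntcp == pytest.approx(0.097, abs=1e-3)

    def test_dose_escalation_strictly_increases_ntcp(self, info):
        d1 = DifferentialDVH(info, [40.0, 75.0], [0.7, 0.3])
        d2 = DifferentialDVH(info, [44.0, 82.5], [0.7, 0.3])
        n1, _ = lkb_ntcp(d1, RECTAL)
        n2, _ = lkb_ntcp(d2, RECTAL)
        assert n2 > n1

    def test_volume_effect(self, partial_dvh_factory):
        """Below TD50(1), irradiating less of the organ lowers NTCP."""
        ntcps = [lkb_ntcp(partial_dvh_factory(70.0, v), RECTAL)[0]
                 for v in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert np.all(np.diff(ntcps) > 0)

    def test_zero_dose_dvh_flagged(self, info):
        ntcp, inter = lkb_ntcp(DifferentialDVH(info, [0.0], [1.0]), RECTAL)
        assert ntcp == 0.0
        assert inter.veff == 0.0

    @pytest.mark.parametrize("dose, volume", [
        (60.0, 0.25), (70.0, 0.5), (75.0, 0.33), (80.0, 1.0), (90.0, 0.8),
    ])
    def test_kb_reduction_matches_closed_form_lyman(
            self, partial_dvh_factory, uniform_dvh_factory, dose, volume):
        dvh = (uniform_dvh_factory(dose) if volume == 1.0
               else partial_dvh_factory(dose, volume))
        via_reduction, _ = lkb_ntcp(dvh, RECTAL)
        closed_form = lyman_ntcp_uniform(dose, volume, RECTAL)
        assert via_reduction == pytest.approx(closed_form, abs=1e-12)

    @given(
        doses=st.lists(st.floats(5.0, 90.0), min_size=1, max_size=6,
                       unique=True),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_probabilities_always_in_unit_interval(self, doses, seed):
        rng = np.random.default_rng(seed)
        info = StructureInfo("Rectum", 60.0)
        vols = rng.dirichlet(np.ones(len(doses)))
        d = DifferentialDVH(info, np.sort(doses), vols)
        ntcp, _ = lkb_ntcp(d, RECTAL)
        tcp = tcp_from_dvh(d, PROSTATE)
        assert 0.0 <= ntcp <= 1.0
        assert 0.0 <= tcp <= 1.0


class TestNormalCdf:
    def test_symmetry_fixed_points(self):
        assert normal_cdf(0.0) == pytest.approx(0.5, abs=1e-15)
        assert normal_cdf(1.96) == pytest.approx(0.9750021048517795, abs=1e-12)

    @given(t=st.floats(-8, 8))
    @settings(max_examples=60, deadline=None)
    def test_reflection_identity(self, t):
        assert normal_cdf(t) + normal_cdf(-t) == pytest.approx(1.0, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        for t in np.linspace(-6, 6, 13):
            assert normal_cdf(t) == pytest.approx(_phi_quadrature(t), abs=1e-10)

    def test_saturation(self):
        assert normal_cdf(-40.0) == 0.0
        assert normal_cdf(40.0) == 1.0


class TestParameterFiles:
    def test_json_round_trip(self, tmp_path):
        p = tmp_path / "params.json"
        p.write_text(json.dumps({
            "tcp": {"D50": 66.0, "gamma50": 1.8},
            "ntcp": {"TD50_1": 76.9, "m": 0.13, "n": 0.09},
        }))
        tcp, lkb = load_model_parameters(p)
        assert (tcp.D50, tcp.gamma50) == (66.0, 1.8)
        assert (lkb.TD50_1, lkb.m, lkb.n) == (76.9, 0.13, 0.09)

    def test_yaml_with_defaults(self, tmp_path):
        p = tmp_path / "params.yaml"
        p.write_text("tcp:\n  D50: 70.0\n")
        tcp, lkb = load_model_parameters(p)
        assert tcp.D50 == 70.0
        assert lkb == DEFAULT_LKB_PARAMS
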