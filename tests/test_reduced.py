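"""Reduced-order transfer model: scalings, bounds, regression, regimes."""

import math

import numpy as np
import pytest

from fetocap import (
    LEVEQUE_PREFACTOR,
    CapillarySummary,
    TransportParameters,
    annular_diffusion_bound,
    classify_regime,
    equilibrated_transfer,
    equivalent_radius,
    leveque_transfer,
    poiseuille_resistance,
    predict_transfer,
    regression_flow,
    sensitivity_factor,
    villous_corrected_transfer,
)
from fetocap.fixtures import reference_capillaries
from fetocap.reduced import read_summaries, write_summaries


def _round_2sf(x: float) -> float:
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + 1)


def test_leveque_prefactor_value():
    assert LEVEQUE_PREFACTOR == pytest.approx(
        (12 * math.pi**2) ** (1 / 3) / math.gamma(4 / 3), rel=1e-14
    )
    assert round(LEVEQUE_PREFACTOR, 1) == 5.5


class TestPoiseuille:
    def test_reference_magnitude(self):
        r = poiseuille_resistance(1e-3, 164.0, 6.09)
        assert r == pytest.approx(3.03e-4, rel=0.01)

    def test_scalings(self):
        base = poiseuille_resistance(1e-3, 100.0, 3.0)
        assert poiseuille_resistance(1e-3, 200.0, 3.0) == pytest.approx(2 * base)
        assert poiseuille_resistance(1e-3, 100.0, 6.0) == pytest.approx(base / 16)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_resistance(1e-3, 100.0, 0.0)


class TestEquivalentRadius:
    def test_cylinder_round_trip(self):
        for r, L in [(1.0, 10.0), (4.7, 185.0), (0.3, 2.0)]:
            assert equivalent_radius(math.pi * r**2 * L, L) == pytest.approx(r, rel=1e-12)

    def test_unit_case(self):
        assert equivalent_radius(math.pi * 5.0, 5.0) == pytest.approx(1.0)

    def test_reference_capillary(self):
        # villous volume 6.88e4 um^3 at 18.5% capillary fraction, L = 185 um
        assert equivalent_radius(0.185 * 6.88e4, 185.0) == pytest.approx(4.68, abs=0.01)


class TestTransferFormulas:
    def test_leveque_zero_dp(self, params):
        assert leveque_transfer(params, 100.0, 1e-4, 0.0) == 0.0

    def test_leveque_cube_root_scaling(self, params):
        n1 = leveque_transfer(params, 100.0, 1e-4, 1.0)
        assert leveque_transfer(params, 100.0, 1e-4, 8.0) == pytest.approx(2 * n1, rel=1e-12)

    def test_equilibrated_reference_value(self, params):
        # c_mat*B*dP/R with dP = 0.5 Pa, R = 4.0e-4 Pa s/um^3 -> 3.95e-7 ug/s
        n = equilibrated_transfer(params, 4.0e-4, 0.5)
        assert n == pytest.approx(141 * 2.24e-18 * 1250 * 1e6, rel=1e-12)
        assert n == pytest.approx(3.95e-7, rel=0.01)

    def test_equilibrated_linearity(self, params):
        n1 = equilibrated_transfer(params, 4e-4, 1.0)
        assert equilibrated_transfer(params, 4e-4, 2.0) == pytest.approx(2 * n1)

    def test_annular_bound_diverges_when_capillary_touches_surface(self, params):
        with pytest.raises(ValueError, match="touches the villous surface"):
            annular_diffusion_bound(params, 100.0, 4.7, 0.0)


class TestRegression:
    def test_zero_dp(self, params):
        n, k1, k2 = regression_flow(params, 100.0, 1e-4, 0.0)
        assert n == 0.0 and k1 > 0 and k2 > 0

    def test_low_dp_asymptote_is_equilibrated(self, params):
        _, k1, k2 = regression_flow(params, 100.0, 1e-4, 1.0)
        dp = (1e-6 * k2 / k1) ** 1.5  # K1*dP^{2/3} = 1e-6 K2
        n, _, _ = regression_flow(params, 100.0, 1e-4, dp)
        assert n == pytest.approx(equilibrated_transfer(params, 1e-4, dp), rel=1e-5)

    def test_high_dp_asymptote_is_leveque(self, params):
        _, k1, k2 = regression_flow(params, 100.0, 1e-4, 1.0)
        crossover = (k2 / k1) ** 1.5
        n, _, _ = regression_flow(params, 100.0, 1e-4, 1e6 * crossover)
        assert n == pytest.approx(
            leveque_transfer(params, 100.0, 1e-4, 1e6 * crossover), rel=1e-3
        )

    def test_crossover_point_identity(self, params):
        _, k1, k2 = regression_flow(params, 100.0, 1e-4, 1.0)
        dp = (k2 / k1) ** 1.5
        n, _, _ = regression_flow(params, 100.0, 1e-4, dp)
        assert n == pytest.approx(k2 * dp ** (1 / 3) / 2.0, rel=1e-12)

    def test_monotone_and_concave_in_dp(self, params):
        dps = np.logspace(-3, 3, 40)
        ns = np.array([regression_flow(params, 100.0, 1e-4, d)[0] for d in dps])
        assert np.all(np.diff(ns) > 0)
        # concavity: chord below curve on a linear grid
        lin = np.linspace(0.1, 100.0, 30)
        nl = np.array([regression_flow(params, 100.0, 1e-4, d)[0] for d in lin])
        mid = np.array(
            [regression_flow(params, 100.0, 1e-4, 0.5 * (a + b))[0] for a, b in zip(lin[:-1], lin[1:])]
        )
        assert np.all(mid >= 0.5 * (nl[:-1] + nl[1:]) - 1e-18)


class TestVillousCorrection:
    def test_symmetric_case(self):
        n, frac = villous_corrected_transfer(2.0, 2.0)
        assert n == pytest.approx(1.0) and frac == pytest.approx(0.5)

    def test_saturates_at_n_max(self):
        n, _ = villous_corrected_transfer(1e9 * 3.0, 3.0)
        assert n == pytest.approx(3.0, rel=1e-8)

    def test_reduces_to_n_flow_for_large_n_max(self):
        n, frac = villous_corrected_transfer(2.5, 1e12)
        assert n == pytest.approx(2.5, rel=1e-10) and frac == pytest.approx(1.0)

    def test_bounded_above_by_both_arguments(self, rng):
        for _ in range(100):
            nf, nm = rng.uniform(1e-9, 10.0, size=2)
            n, _ = villous_corrected_transfer(nf, nm)
            assert n < nf and n < nm


class TestRegimeClassification:
    def test_equilibrated_at_small_peclet(self, params):
        ratio = 147.0 * 4.7 / (51 + 4.7) ** 2
        u0 = 0.01 * ratio * params.D / (params.B * 4.7)  # Pe = 0.01*ratio
        regime = classify_regime(params, u0, 4.7, 51.0, 147.0, 1e-9, 1e-6)
        assert regime == "flow_limited_equilibrated"

    def test_diffusion_limited_when_flow_overwhelms_bound(self, params):
        regime = classify_regime(params, 1e4, 4.7, 51.0, 147.0, 100e-6, 1e-6)
        assert regime == "diffusion_limited"

    def test_boundary_peclet_is_crossover(self, params):
        ratio = 147.0 * 4.7 / (51 + 4.7) ** 2
        u0 = ratio * params.D / (params.B * 4.7)  # Pe exactly at the ratio
        regime = classify_regime(params, u0, 4.7, 51.0, 147.0, 1e-9, 1e-6)
        assert regime == "crossover"

    def test_threshold_below_one_rejected(self, params):
        with pytest.raises(ValueError):
            classify_regime(params, 1.0, 4.7, 51.0, 147.0, 1e-9, 1e-6, threshold=0.5)


class TestSensitivity:
    @pytest.mark.parametrize(
        "mode,regime,expected",
        [
            ("uniform", "low_Pe", 1.1**3),
            ("uniform", "high_Pe", 1.1 ** (5 / 3)),
            ("radius_only", "low_Pe", 1.1**4),
            ("radius_only", "high_Pe", 1.1 ** (4 / 3)),
        ],
    )
    def test_exponents(self, mode, regime, expected):
        assert sensitivity_factor(1.1, mode, regime) == pytest.approx(expected, rel=1e-12)

    def test_identity_at_unity(self):
        for mode in ("uniform", "radius_only"):
            for regime in ("low_Pe", "high_Pe"):
                assert sensitivity_factor(1.0, mode, regime) == 1.0

    def test_uniform_factors_match_transfer_formula_ratios(self, params):
        # the k^3 / k^{5/3} exponents follow from R ~ L/R0^4 in the
        # equilibrated and boundary-layer formulas respectively
        k, L, R0, dp = 1.37, 120.0, 4.0, 2.0
        r_before = poiseuille_resistance(params.mu, L, R0)
        r_after = poiseuille_resistance(params.mu, k * L, k * R0)
        ratio_eq = equilibrated_transfer(params, r_after, dp) / equilibrated_transfer(
            params, r_before, dp
        )
        assert ratio_eq == pytest.approx(sensitivity_factor(k, "uniform", "low_Pe"), rel=1e-12)
        ratio_lev = leveque_transfer(params, k * L, r_after, dp) / leveque_transfer(
            params, L, r_before, dp
        )
        assert ratio_lev == pytest.approx(sensitivity_factor(k, "uniform", "high_Pe"), rel=1e-12)


class TestReferenceTable:
    def test_length_squared_over_resistance_row(self):
        # internal consistency of the packaged table: L^2/R to 2 s.f.
        expected = {"image1": 5.9e7, "image2": 6.7e7, "image3": 2.8e7}
        for s in reference_capillaries():
            assert s.L**2 / s.R_resistance == pytest.approx(expected[s.label], rel=0.015)

    def test_annular_bound_reproduces_tabulated_predictions(self, params):
        # tabulated predictions are printed to 2 significant figures
        expected = {"image1": 1.8e-6, "image2": 3.3e-6, "image3": 1.2e-6}
        for s in reference_capillaries():
            n = annular_diffusion_bound(params, s.A, s.radius, s.d)
            assert _round_2sf(n) == pytest.approx(expected[s.label], rel=1e-9)

    def test_csv_round_trip_lossless(self, tmp_path):
        rows = reference_capillaries()
        path = tmp_path / "summaries.csv"
        write_summaries(rows, path)
        back = read_summaries(path)
        assert len(back) == len(rows)
        for a, b in zip(rows, back):
            assert a.label == b.label
            for f in ("L", "L_path", "V_cap", "d", "A", "R_resistance", "N_max_numeric"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)


class TestPredictPipeline:
    def test_prediction_invariants_across_pressure_ladder(self, params):
        s = reference_capillaries()[1]
        prev = 0.0
        for dp in (0.5, 1.0, 2.0, 5.0, 10.0, 20.0):
            pred = predict_transfer(s, params, dp)
            assert pred.N_corrected > prev
            assert pred.N_corrected <= pred.N_max
            assert pred.N_corrected <= pred.N_flow_regression
            assert 0.0 < pred.N_ratio <= 1.0
            prev = pred.N_corrected

    def test_numeric_bound_preferred_over_closed_form(self, params):
        s = reference_capillaries()[0]
        with_numeric = predict_transfer(s, params, 1.0)
        without = predict_transfer(s, params, 1.0, use_numeric_nmax=False)
        assert with_numeric.N_max == pytest.approx(s.N_max_numeric)
        assert without.N_max == pytest.approx(
            annular_diffusion_bound(params, s.A, s.radius, s.d)
        )

    def test_radius_precedence_documented(self):
        s = CapillarySummary(L=100.0, d=10.0, A=1000.0, V_cap=math.pi * 4.0 * 100.0, R0=3.0)
        assert s.radius == 3.0  # explicit R0 wins over V/(pi L)
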