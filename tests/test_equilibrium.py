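"""Pairwise equilibrium, occupancy product and titration curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import prozone as pz
from conftest import bisect_pairwise

GOLDEN = (3 - math.sqrt(5)) / 2  # root of SX^2 - 3 SX + 1 on [0, 1]

amounts = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)
pos_amounts = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False)


class TestPairwiseEquilibrium:
    @pytest.mark.parametrize("s, x, kd, expected", [
        (2, 5, 0, 2.0),           # tight binding: min of totals
        (5, 2, 0, 2.0),
        (0, 7, 1, 0.0),           # no scaffold
        (3, 0, 0.5, 0.0),         # no ligand
        (1, 1, 1, GOLDEN),        # closed-form quadratic root
    ])
    def test_examples(self, s, x, kd, expected):
        assert pz.solve_pairwise_equilibrium(s, x, kd) == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("s, x, kd", [
        (1, 1, 1), (2, 10, 0.01), (5, 2, 3.7), (100, 0.3, 0.5), (7, 7, 1e-6),
    ])
    def test_against_bisection_oracle(self, s, x, kd):
        assert pz.solve_pairwise_equilibrium(s, x, kd) == pytest.approx(
            bisect_pairwise(s, x, kd), rel=1e-9)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, -1, 1), (1, 1, -1),
                                     (float("nan"), 1, 1), (1, float("inf"), 1)])
    def test_domain_errors(self, bad):
        with pytest.raises(pz.DomainError):
            pz.solve_pairwise_equilibrium(*bad)

    @settings(derandomize=True, max_examples=200)
    @given(amounts, amounts, amounts)
    def test_mass_balance_residual(self, s, x, kd):
        sx = pz.solve_pairwise_equilibrium(s, x, kd)
        assert 0.0 <= sx <= min(s, x) + 1e-12
        residual = (s - sx) * (x - sx) - kd * sx
        assert abs(residual) <= 1e-9 * max(1.0, s * x)

    @settings(derandomize=True, max_examples=100)
    @given(pos_amounts, pos_amounts, pos_amounts,
           st.floats(min_value=1.0, max_value=10.0))
    def test_monotonicity(self, s, x, kd, factor):
        base = pz.solve_pairwise_equilibrium(s, x, kd)
        assert pz.solve_pairwise_equilibrium(s * factor, x, kd) >= base - 1e-12
        assert pz.solve_pairwise_equilibrium(s, x * factor, kd) >= base - 1e-12
        assert pz.solve_pairwise_equilibrium(s, x, kd * factor) <= base + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(pos_amounts, pos_amounts)
    def test_weak_binding_limit(self, s, x):
        kd = 1e6 * (s + x)
        assert pz.solve_pairwise_equilibrium(s, x, kd) == pytest.approx(
            s * x / kd, rel=0.01)

    def test_continuity_near_tight_binding(self):
        # stable form must not lose digits when kd << totals
        exact = pz.solve_pairwise_equilibrium(2.0, 5.0, 0.0)
        near = pz.solve_pairwise_equilibrium(2.0, 5.0, 1e-12)
        assert near == pytest.approx(exact, rel=1e-10)
        assert near < exact


class TestOccupancyProbability:
    @pytest.mark.parametrize("s, x, kd, expected", [
        (2, 5, 0, 1.0),   # excess ligand, tight binding
        (5, 2, 0, 0.4),   # 2 of 5 scaffolds carry the scarce ligand
        (1, 1, 1, GOLDEN),
    ])
    def test_examples(self, s, x, kd, expected):
        assert pz.occupancy_probability(s, x, kd) == pytest.approx(
            expected, rel=1e-12)

    def test_undefined_at_zero_scaffold(self):
        with pytest.raises(pz.DomainError):
            pz.occupancy_probability(0.0, 1.0, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(pos_amounts, amounts, amounts)
    def test_in_unit_interval(self, s, x, kd):
        assert 0.0 <= pz.occupancy_probability(s, x, kd) <= 1.0


def _scenario(s_total, totals, kds):
    if np.isscalar(kds):
        kds = [kds] * len(totals)
    return pz.ScaffoldScenario(
        s_total=s_total,
        ligands=tuple(pz.LigandSpec(f"L{i}", t, k)
                      for i, (t, k) in enumerate(zip(totals, kds))),
    )


class TestFullComplexLevel:
    def test_discrete_worked_case(self):
        # 5 scaffolds, tight binding, (2, 5, 10): both possible fulls form
        res = pz.full_complex_level(_scenario(5, (2, 5, 10), 0))
        assert res.full_complex == pytest.approx(2.0)
        assert res.p_bound == pytest.approx((0.4, 1.0, 1.0))

    def test_exact_coverage(self):
        assert pz.full_complex_level(
            _scenario(2, (2, 2, 2), 0)).full_complex == pytest.approx(2.0)

    def test_product_of_quadratic_roots(self):
        sc = _scenario(2, (2, 10, 20), 0.01)
        expected = 2.0 * math.prod(
            bisect_pairwise(2.0, x, 0.01) / 2.0 for x in (2, 10, 20))
        res = pz.full_complex_level(sc)
        assert res.full_complex == pytest.approx(expected, rel=1e-9)
        # the value the model reports for this canonical mid-panel case
        assert res.full_complex == pytest.approx(1.860, abs=5e-4)

    def test_zero_scaffold_returns_zeros(self):
        res = pz.full_complex_level(_scenario(0, (2, 5), 1))
        assert res.full_complex == 0.0
        assert res.bound == (0.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(pos_amounts, st.lists(pos_amounts, min_size=1, max_size=4),
           st.floats(min_value=0, max_value=100))
    def test_conservation_bound(self, s, totals, kd):
        res = pz.full_complex_level(_scenario(s, totals, kd))
        assert res.full_complex <= min(totals) * (1 + 1e-12)
        assert res.full_complex <= min(res.bound) * (1 + 1e-12)
        for b, t in zip(res.bound, totals):
            assert 0.0 <= b <= min(s, t) * (1 + 1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(pos_amounts, st.lists(pos_amounts, min_size=2, max_size=4))
    def test_tight_binding_closed_form(self, s, totals):
        res = pz.full_complex_level(_scenario(s, totals, 0))
        assert res.full_complex == pytest.approx(
            pz.tight_binding_full_complex(s, totals), rel=1e-12)

    def test_tight_binding_pieces(self):
        # sorted totals x1 <= x2 <= x3: S on the rising flank, the plateau,
        # the first decline (x1 x2 / S) and the far flank (x1 x2 x3 / S^2)
        x1, x2, x3 = 2.0, 5.0, 10.0
        assert pz.tight_binding_full_complex(1.0, (x1, x2, x3)) == 1.0
        assert pz.tight_binding_full_complex(3.0, (x1, x2, x3)) == x1
        assert pz.tight_binding_full_complex(8.0, (x1, x2, x3)) == x1 * x2 / 8.0
        assert pz.tight_binding_full_complex(40.0, (x1, x2, x3)) == \
            x1 * x2 * x3 / 40.0 ** 2


class TestTitrationCurve:
    def test_sharp_optimum_for_equal_ligands(self):
        curve = pz.titration_curve(_scenario(1, (2, 2, 2), 0), 0.1, 100, 201)
        values = curve.full_complex
        i = int(np.argmax(values))
        nearest = int(np.argmin(np.abs(np.log(np.array(curve.s_grid) / 2.0))))
        assert i == nearest
        assert values[i] == pytest.approx(2.0, rel=0.04)  # grid resolution
        # a grid containing S_T = 2 exactly attains the peak value exactly
        exact = pz.titration_curve(_scenario(1, (2, 2, 2), 0), 1.0, 4.0, 4,
                                   spacing="linear")
        assert max(exact.full_complex) == 2.0
        assert exact.s_grid[int(np.argmax(exact.full_complex))] == 2.0

    def test_plateau_framed_by_two_scarcest(self):
        curve = pz.titration_curve(_scenario(1, (2, 10, 20), 0), 0.1, 100, 301)
        grid = np.array(curve.s_grid)
        values = curve.full_complex
        inside = (grid >= 2.0) & (grid <= 10.0)
        assert np.all(values[inside] == pytest.approx(2.0, rel=1e-12))
        assert values[grid < 1.0].max() < 1.0 + 1e-12
        assert values[grid > 20.0].max() < 1.0 + 1e-12

    def test_two_point_grid_matches_direct_calls(self, scenario_2_10_20):
        curve = pz.titration_curve(scenario_2_10_20, 5.0, 10.0, 2)
        assert curve.s_grid == (5.0, 10.0)
        for s, res in zip(curve.s_grid, curve.results):
            direct = pz.full_complex_level(scenario_2_10_20.with_s_total(s))
            assert res.full_complex == direct.full_complex
            assert res.p_bound == direct.p_bound

    def test_endpoints_exact_log_spacing(self, scenario_2_10_20):
        curve = pz.titration_curve(scenario_2_10_20, 0.037, 123.4, 50)
        assert curve.s_grid[0] == 0.037 and curve.s_grid[-1] == 123.4

    @pytest.mark.parametrize("kwargs", [
        dict(s_min=0.0, s_max=1.0), dict(s_min=2.0, s_max=1.0),
        dict(s_min=1.0, s_max=2.0, n_points=1),
        dict(s_min=1.0, s_max=2.0, spacing="cubic"),
    ])
    def test_invalid_grid(self, scenario_2_10_20, kwargs):
        with pytest.raises(pz.DomainError):
            pz.titration_curve(scenario_2_10_20, **kwargs)

    def test_default_grid_spans_both_flanks(self, scenario_2_10_20):
        curve = pz.titration_curve(scenario_2_10_20)
        assert len(curve.s_grid) == 200
        assert curve.s_grid[0] == pytest.approx(0.01 * 20)
        assert curve.s_grid[-1] == pytest.approx(100 * 20)


class TestSerialization:
    def test_curve_csv_header_and_precision(self, scenario_2_10_20):
        curve = pz.titration_curve(scenario_2_10_20, 1.0, 10.0, 5)
        text = pz.curve_to_csv(curve)
        lines = text.strip().split("\n")
        assert lines[0] == "s_total,p_bound_Raf,p_bound_MEK,p_bound_ERK,full_complex"
        cells = lines[1].split(",")
        # 12 significant digits round-trip through the text form
        assert float(cells[-1]) == pytest.approx(
            curve.results[0].full_complex, rel=1e-11)

    def test_scenario_json_roundtrip_byte_identical(self, scenario_2_10_20):
        text = scenario_2_10_20.to_json()
        again = pz.ScaffoldScenario.from_json(text)
        assert again == scenario_2_10_20
        assert again.to_json() == text

    def test_missing_ligands_field_named_in_error(self):
        with pytest.raises(pz.ValidationError, match="ligands"):
            pz.ScaffoldScenario.from_json('{"s_total": 1.0}')

    def test_duplicate_names_rejected(self):
        with pytest.raises(pz.ValidationError):
            pz.ScaffoldScenario(1.0, (pz.LigandSpec("A", 1, 0),
                                      pz.LigandSpec("A", 2, 0)))
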