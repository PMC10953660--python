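"""Boundary shapes, crossing probabilities, solved constants and inflations."""

import numpy as np
import pytest

import gseqdesign as g
from gseqdesign.exceptions import InvalidSpecError
from conftest import mc_sequential_reject

T5 = np.arange(1, 6) / 5


class TestBoundaryValues:
    def test_pocock_is_flat(self):
        eff, fut = g.boundary_values("pocock", 2.413, 5)
        assert np.allclose(eff, 2.413)
        assert fut.size == 0

    def test_obf_sqrt_scaling(self):
        eff, _ = g.boundary_values("obf", 2.040, 5)
        assert eff[0] == pytest.approx(2.040 * np.sqrt(5), abs=1e-9)
        assert eff[-1] == pytest.approx(2.040)

    def test_wang_tsiatis_power_family(self):
        eff, _ = g.boundary_values("wt", 2.136, 5, delta_shape=0.25)
        expected = [3.194, 2.686, 2.427, 2.259, 2.136]
        assert np.allclose(eff, expected, atol=2e-3)

    def test_inner_wedge_futility_series(self):
        # constants fitted to the published five-look example
        eff, fut = g.boundary_values(
            "iw", 2.0725, 5, delta_shape=0.25, constant_futility=1.4772
        )
        assert np.allclose(fut, [0.0, 0.388, 1.072, 1.613, 2.073], atol=2e-3)
        assert fut[0] == 0.0  # truncated at zero
        assert fut[-1] == pytest.approx(eff[-1], abs=1e-9)  # wedge closes

    def test_method_aliases(self):
        assert g.Method.parse("obf") is g.Method.OBRIEN_FLEMING
        assert g.Method.parse("iw") is g.Method.INNER_WEDGE
        with pytest.raises(InvalidSpecError):
            g.Method.parse("nope")


class TestCrossingProbabilities:
    def test_single_look_is_fixed_test(self):
        res = g.crossing_probabilities([1.959964], None, [1.0], drift=0.0)
        assert res.total_reject == pytest.approx(0.05, abs=1e-6)

    def test_unreachable_boundary(self):
        res = g.crossing_probabilities([10.0, 10.0], None, [0.5, 1.0], drift=0.0)
        assert res.total_reject < 1e-6

    def test_flat_pocock_bounds_hold_size(self):
        res = g.crossing_probabilities([2.4132] * 5, None, T5, drift=0.0)
        assert res.total_reject == pytest.approx(0.05, abs=2e-4)

    def test_probability_bookkeeping(self, iw_plan5):
        res = g.crossing_probabilities(
            iw_plan5.efficacy_bounds, iw_plan5.futility_bounds, T5, drift=1.5
        )
        total = res.total_reject + res.total_accept_early
        # the wedge closes at the final look: every path is decided
        assert total == pytest.approx(1.0, abs=1e-5)
        assert res.expected_info_fraction < 1.0

    def test_bad_info_fractions_rejected(self):
        with pytest.raises(InvalidSpecError):
            g.crossing_probabilities([2.0, 2.0], None, [0.8, 0.5], 0.0)
        with pytest.raises(InvalidSpecError):
            g.crossing_probabilities([2.0, 2.0], None, [0.5, 0.9], 0.0)


class TestSolveConstant:
    @pytest.mark.parametrize(
        "method, delta, expected",
        [
            ("pocock", None, 2.413),
            ("obf", None, 2.040),
            ("wt", 0.25, 2.136),
        ],
    )
    def test_five_look_constants(self, method, delta, expected):
        c = g.solve_constant(method, 5, 0.05, delta_shape=delta)
        assert c == pytest.approx(expected, abs=2e-3)

    def test_single_look_reduces_to_fixed_quantile(self):
        for method in ("pocock", "obf", "wt"):
            c = g.solve_constant(method, 1, 0.05, delta_shape=0.25)
            assert c == pytest.approx(1.959964, abs=1e-6)

    def test_pocock_constant_increases_with_looks(self):
        cs = [g.solve_constant("pocock", r, 0.05) for r in (1, 2, 3, 5, 8)]
        assert cs == sorted(cs)
        assert cs[-1] > cs[0]

    def test_wt_shape_limits_match_pocock_and_obf(self):
        assert g.solve_constant("wt", 5, 0.05, 0.5) == pytest.approx(
            g.solve_constant("pocock", 5, 0.05), abs=1e-3
        )
        assert g.solve_constant("wt", 5, 0.05, 0.0) == pytest.approx(
            g.solve_constant("obf", 5, 0.05), abs=1e-3
        )

    def test_inner_wedge_not_accepted(self):
        with pytest.raises(InvalidSpecError):
            g.solve_constant("iw", 5, 0.05, 0.25)


class TestInnerWedge:
    def test_five_look_example(self, iw_plan5):
        assert iw_plan5.constant_efficacy == pytest.approx(2.073, abs=2e-3)
        assert iw_plan5.inflation == pytest.approx(1.199, abs=2e-3)
        # first efficacy bound 3.10 (3 s.f.), second futility bound 0.388
        assert iw_plan5.efficacy_bounds[0] == pytest.approx(3.10, abs=5e-3)
        assert iw_plan5.futility_bounds[1] == pytest.approx(0.388, abs=2e-3)

    def test_single_look_degenerates_to_fixed_design(self):
        cw1, cw2, infl = g.solve_inner_wedge(1, 0.05, 0.1, 0.25)
        assert cw1 == pytest.approx(1.959964, abs=1e-6)
        assert cw2 == pytest.approx(1.281552, abs=1e-6)
        assert infl == 1.0

    def test_size_and_power_calibration(self, iw_plan5):
        t = iw_plan5.info_fractions
        size = g.crossing_probabilities(
            iw_plan5.efficacy_bounds, iw_plan5.futility_bounds, t, 0.0
        ).total_reject
        drift = iw_plan5.constant_efficacy + iw_plan5.constant_futility
        power = g.crossing_probabilities(
            iw_plan5.efficacy_bounds, iw_plan5.futility_bounds, t, drift
        ).total_reject
        assert size == pytest.approx(0.05, abs=2e-4)
        assert power == pytest.approx(0.90, abs=2e-4)


class TestInflation:
    @pytest.mark.parametrize(
        "method, delta, expected",
        [
            ("pocock", None, 1.207),
            ("obf", None, 1.026),
            ("wt", 0.25, 1.066),
        ],
    )
    def test_five_look_inflations(self, method, delta, expected):
        rho = g.inflation_factor(method, 5, 0.05, 0.1, delta_shape=delta)
        assert rho == pytest.approx(expected, abs=2e-3)

    def test_single_look_identity(self):
        assert g.inflation_factor("pocock", 1, 0.05, 0.1) == 1.0

    def test_ordering_at_example_settings(self):
        obf = g.inflation_factor("obf", 5, 0.05, 0.1)
        wt = g.inflation_factor("wt", 5, 0.05, 0.1, 0.25)
        poc = g.inflation_factor("pocock", 5, 0.05, 0.1)
        assert obf < wt < poc

    def test_power_calibration(self, pocock_plan5):
        """At the design drift scaled by the solved inflation, power = 1-beta."""
        drift = (g.normal_quantile(0.975) + g.normal_quantile(0.9)) * np.sqrt(
            pocock_plan5.inflation
        )
        res = g.crossing_probabilities(
            pocock_plan5.efficacy_bounds, None, T5, drift
        )
        assert res.total_reject == pytest.approx(0.90, abs=2e-4)


class TestAdjustSampleSize:
    @pytest.mark.parametrize(
        "inflation, expected",
        [(1.207, 318), (1.026, 270), (1.066, 281), (1.199, 316), (1.0, 263)],
    )
    def test_rounded_base_convention(self, inflation, expected):
        assert g.adjust_sample_size(263, inflation) == expected

    def test_accepts_fixed_design(self, fixed_example):
        assert g.adjust_sample_size(fixed_example, 1.207) == 318

    def test_rejects_deflation(self, fixed_example):
        with pytest.raises(InvalidSpecError):
            g.adjust_sample_size(fixed_example, 0.9)


def test_recursion_matches_monte_carlo_with_futility():
    """Cross-check the integration engine against simulated paths.

    A three-look inner wedge exercises both boundary types; 2e5 simulated
    correlated sequential normals must agree with the recursion within
    three Monte Carlo standard errors at the null and at the design drift.
    """
    cw1, cw2, _ = g.solve_inner_wedge(3, 0.05, 0.1, 0.25)
    eff, fut = g.boundary_values("iw", cw1, 3, 0.25, constant_futility=cw2)
    t = np.arange(1, 4) / 3
    for drift in (0.0, cw1 + cw2):
        exact = g.crossing_probabilities(eff, fut, t, drift).total_reject
        rate, se = mc_sequential_reject(eff, fut, t, drift, 200_000, seed=7)
        assert abs(rate - exact) <= 3 * se


def test_plan_json_round_trip(tmp_path, iw_plan5):
    path = tmp_path / "plan.json"
    iw_plan5.to_json(path)
    back = g.SequentialPlan.from_json(path)
    assert back.method is g.Method.INNER_WEDGE
    assert back.n_adjusted_per_group == iw_plan5.n_adjusted_per_group
    assert np.allclose(back.efficacy_bounds, iw_plan5.efficacy_bounds)
    assert np.allclose(back.futility_bounds, iw_plan5.futility_bounds)
    assert back.inflation == pytest.approx(iw_plan5.inflation, rel=1e-12)
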