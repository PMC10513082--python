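"""Decision outputs: NMB identities, ICER verdicts, PSA/CEAC, tornado, scenarios."""

import math

import numpy as np
import pandas as pd
import pytest

from glp1ce.cea import (
    ModelBundle,
    PSAResult,
    complication_breakdown,
    compute_ceac,
    default_bundle,
    icer,
    inmb_paired,
    nmb,
    one_way_sa,
    run_base_case,
    run_psa,
    scenario_horizons,
)


@pytest.fixture(scope="module")
def bundle():
    return default_bundle(cohort_n=200, seed=17)


@pytest.fixture(scope="module")
def base_results(bundle):
    return run_base_case(bundle)


class TestNMB:
    def test_published_magnitude_arithmetic(self):
        # printed means of the cheapest/most-effective arm reproduce its NMB
        assert nmb(42092.0, 12.65, 12728.0) == pytest.approx(118917.2, abs=0.01)

    def test_degenerate_cases(self):
        assert nmb(0.0, 0.0, 12728.0) == 0.0
        assert nmb(500.0, 1.0, 0.0) == -500.0

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(0.0, 0.0, -1.0)


class TestINMB:
    def test_arm_vs_itself_is_degenerate_zero(self, base_results, bundle):
        r = base_results["exenatide"]
        out = inmb_paired(r, r, bundle.wtp)
        assert out == {"inmb": 0.0, "lo": 0.0, "hi": 0.0}

    def test_antisymmetry_under_common_random_numbers(self, base_results, bundle):
        a, b = base_results["loxenatide"], base_results["exenatide"]
        ab = inmb_paired(a, b, bundle.wtp)["inmb"]
        ba = inmb_paired(b, a, bundle.wtp)["inmb"]
        assert ab == pytest.approx(-ba, abs=1e-9)

    def test_constructed_shift_recovered(self, base_results, bundle):
        import copy

        ref = base_results["exenatide"]
        shifted = copy.deepcopy(ref)
        shifted.cost = shifted.cost - 500.0  # 500 USD cheaper for everyone
        out = inmb_paired(shifted, ref, bundle.wtp)
        assert out["inmb"] == pytest.approx(500.0, abs=1e-9)

    def test_costlier_equal_qaly_arm_is_negative(self, base_results, bundle):
        import copy

        ref = base_results["exenatide"]
        worse = copy.deepcopy(ref)
        worse.cost = worse.cost + 100.0
        assert inmb_paired(worse, ref, bundle.wtp)["inmb"] < 0

    def test_mismatched_cohorts_rejected(self, base_results, bundle):
        import copy

        ref = base_results["exenatide"]
        short = copy.deepcopy(ref)
        short.cost = short.cost[:-1]
        short.qaly = short.qaly[:-1]
        with pytest.raises(ValueError):
            inmb_paired(short, ref, bundle.wtp)


class TestICER:
    def test_dominant_and_dominated_verdicts(self):
        assert icer({"cost_mean": 90.0, "qaly_mean": 1.1},
                    {"cost_mean": 100.0, "qaly_mean": 1.0})["verdict"] == "dominant"
        assert icer({"cost_mean": 110.0, "qaly_mean": 0.9},
                    {"cost_mean": 100.0, "qaly_mean": 1.0})["verdict"] == "dominated"

    def test_ratio_arithmetic(self):
        out = icer({"cost_mean": 1100.0, "qaly_mean": 1.1},
                   {"cost_mean": 100.0, "qaly_mean": 1.0})
        assert out["icer"] == pytest.approx(10_000.0)

    def test_near_zero_qaly_difference_flagged_unstable(self):
        out = icer({"cost_mean": 200.0, "qaly_mean": 1.0},
                   {"cost_mean": 100.0, "qaly_mean": 1.0})
        assert out["verdict"] == "unstable"
        assert math.isnan(out["icer"])


class TestBreakdown:
    def test_sum_column_equals_row_total(self, base_results):
        for res in base_results.values():
            table = complication_breakdown(res)
            cats = list(res.categories)
            assert np.allclose(
                table["Sum"], table[cats].sum(axis=1), atol=1e-9
            )

    def test_twelve_categories_present(self, base_results):
        table = complication_breakdown(base_results["dulaglutide"])
        assert len([c for c in table.columns if c not in ("arm", "Sum")]) == 12

    def test_zero_event_world_all_zero_row(self, pset, zero_cost_draw, zero_event_model):
        from glp1ce.microsim import run_arm
        from glp1ce.riskengine import PatientState
        from conftest import clean_profile

        res = run_arm([PatientState()] * 3, clean_profile(), zero_event_model,
                      zero_cost_draw, seed=0, horizon=5)
        table = complication_breakdown(res)
        assert float(table.loc["cost", "Sum"]) == 0.0
        assert float(table.loc["disutility", "Sum"]) == 0.0


class TestPSA:
    def test_single_iteration_with_fixed_parameters_equals_base_case(self, pset):
        bundle = default_bundle(cohort_n=50, seed=23, effect_sd=None)
        # degenerate PSA: replace every spec by its point value
        from glp1ce.params import Parameter, ParameterSet, fit_distribution

        fixed = ParameterSet(discount_rate=pset.discount_rate, wtp=pset.wtp)
        for p in bundle.pset:
            fixed.add(Parameter(p.name, p.value, p.units,
                                fit_distribution("fixed", p.value, p.value, p.value),
                                p.group))
        bundle_fixed = ModelBundle(
            pset=fixed, risk_model=bundle.risk_model, profiles=bundle.profiles,
            cohort=bundle.cohort, sim_seed=bundle.sim_seed, horizon=bundle.horizon,
        )
        psa = run_psa(bundle_fixed, iterations=1, seed=3)
        base = run_base_case(bundle_fixed)
        for j, arm in enumerate(psa.arms):
            assert psa.cost[0, j] == pytest.approx(base[arm].cost.mean(), rel=1e-12)
            assert psa.qaly[0, j] == pytest.approx(base[arm].qaly.mean(), rel=1e-12)

    def test_fixed_seed_reproduces_psa(self):
        bundle = default_bundle(cohort_n=40, seed=29)
        p1 = run_psa(bundle, iterations=3, seed=5)
        p2 = run_psa(bundle, iterations=3, seed=5)
        assert np.array_equal(p1.cost, p2.cost)
        assert np.array_equal(p1.qaly, p2.qaly)

    def test_effect_uncertainty_changes_iterations(self):
        bundle = default_bundle(cohort_n=40, seed=29)
        psa = run_psa(bundle, iterations=4, seed=5)
        assert np.std(psa.cost[:, 0]) > 0


class TestCEAC:
    def test_probabilities_sum_to_one_everywhere(self):
        rng = np.random.default_rng(0)
        psa = PSAResult(arms=("a", "b", "c"),
                        cost=rng.uniform(1000, 2000, (50, 3)),
                        qaly=rng.uniform(1, 2, (50, 3)),
                        draw_index=np.arange(50), seed=0)
        curve = compute_ceac(psa, [0, 5000, 12728, 40000])
        sums = curve.groupby("wtp").probability.sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_strictly_dominant_arm_has_probability_one(self):
        cost = np.tile([100.0, 200.0], (20, 1))
        qaly = np.tile([2.0, 1.0], (20, 1))
        psa = PSAResult(arms=("good", "bad"), cost=cost, qaly=qaly,
                        draw_index=np.arange(20), seed=0)
        curve = compute_ceac(psa, [0, 10_000])
        good = curve[curve.arm == "good"].probability
        assert np.all(good == 1.0)

    def test_identical_arms_split_evenly(self):
        cost = np.tile([100.0, 100.0, 100.0, 100.0], (10, 1))
        qaly = np.tile([1.0, 1.0, 1.0, 1.0], (10, 1))
        psa = PSAResult(arms=tuple("abcd"), cost=cost, qaly=qaly,
                        draw_index=np.arange(10), seed=0)
        curve = compute_ceac(psa, [12728.0])
        assert np.allclose(curve.probability, 0.25, atol=1e-12)

    def test_noisy_symmetric_arms_win_about_equally(self):
        rng = np.random.default_rng(7)
        k, iters = 3, 600
        cost = 1000.0 + rng.normal(0, 50, (iters, k))
        qaly = 1.0 + rng.normal(0, 0.05, (iters, k))
        psa = PSAResult(arms=tuple("xyz"), cost=cost, qaly=qaly,
                        draw_index=np.arange(iters), seed=0)
        curve = compute_ceac(psa, [12728.0])
        # binomial 3-sigma band around 1/3
        se = math.sqrt((1 / k) * (1 - 1 / k) / iters)
        assert np.all(np.abs(curve.probability - 1 / k) < 3.5 * se)

    def test_constructed_crossing_at_designed_wtp(self):
        # NMB(A) = w*0.1 - 1000, NMB(B) = w*0.2 - 2000 cross at w* = 10000
        cost = np.tile([1000.0, 2000.0], (5, 1))
        qaly = np.tile([0.1, 0.2], (5, 1))
        psa = PSAResult(arms=("A", "B"), cost=cost, qaly=qaly,
                        draw_index=np.arange(5), seed=0)
        grid = np.arange(8000, 12001, 400)
        curve = compute_ceac(psa, grid)
        a = curve[curve.arm == "A"].set_index("wtp").probability
        assert a[9600.0] == 1.0 and a[10400.0] == 0.0
        assert a[10000.0] == pytest.approx(0.5)  # exact tie, split evenly

    def test_empty_grid_rejected(self):
        psa = PSAResult(arms=("a",), cost=np.ones((2, 1)), qaly=np.ones((2, 1)),
                        draw_index=np.arange(2), seed=0)
        with pytest.raises(ValueError):
            compute_ceac(psa, [])


class TestOneWaySA:
    def test_unread_parameter_has_zero_range(self, bundle):
        entries = one_way_sa(bundle, ["Baseline_HDL"], "loxenatide")
        assert len(entries) == 1
        assert entries[0].range == pytest.approx(0.0, abs=1e-9)

    def test_comparator_price_monotonically_raises_inmb(self, bundle):
        # raising the reference arm's pack price makes the other arm look better
        entries = one_way_sa(bundle, ["Cost_exenatide_600ug"], "loxenatide")
        e = entries[0]
        assert e.inmb_high > e.inmb_low

    def test_discount_parameter_evaluated_at_stated_bounds(self, bundle):
        spec = bundle.pset["Discount"].spec
        assert (spec.low, spec.high) == (0.0, 0.08)
        entries = one_way_sa(bundle, ["Discount"], "loxenatide")
        assert entries[0].range > 0.0

    def test_entries_sorted_by_range(self, bundle):
        entries = one_way_sa(
            bundle,
            ["Cost_loxenatide_100ug", "Baseline_HDL", "Disu_T2DM_without_complications"],
            "loxenatide", top=None,
        )
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)

    def test_unknown_parameter_skipped_with_warning(self, bundle):
        with pytest.warns(UserWarning, match="unknown"):
            entries = one_way_sa(bundle, ["no_such_param"], "loxenatide")
        assert entries == []


class TestScenarios:
    def test_table_shape_and_monotonicity(self):
        bundle = default_bundle(cohort_n=80, seed=37)
        table = scenario_horizons(bundle, (10, 20, 30, 40))
        assert len(table) == 4 * len(bundle.profiles)
        for arm, grp in table.groupby("arm"):
            grp = grp.sort_values("horizon")
            assert grp.cost.is_monotonic_increasing
            assert grp.qaly.is_monotonic_increasing

    def test_horizon_beyond_lifetime_equals_base_case(self):
        bundle = default_bundle(cohort_n=30, seed=41)
        base = run_base_case(bundle)
        table = scenario_horizons(bundle, (120,))
        for arm, res in base.items():
            row = table[table.arm == arm].iloc[0]
            assert row.cost == pytest.approx(res.cost.mean(), rel=1e-12)
            assert row.qaly == pytest.approx(res.qaly.mean(), rel=1e-12)

    def test_invalid_horizon_rejected(self, bundle):
        with pytest.raises(ValueError):
            scenario_horizons(bundle, (0,))
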