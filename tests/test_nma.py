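"""Network meta-analysis: structure, sampler correctness, diagnostics."""

import math

import numpy as np
import pytest

from glp1ce.nma import (
    build_network,
    design_by_treatment,
    fit_nma,
    gelman_rubin,
    i_squared,
    node_split,
    relative_effects,
)
from glp1ce.synthetic import (
    DEFAULT_TRUE_EFFECTS,
    SyntheticNMAConfig,
    default_nma_config,
    gen_nma_dataset,
)


def two_treatment_dataset(truth=-0.10, n_studies=12, n=400, sd=0.08, seed=3,
                          het=0.0):
    cfg = SyntheticNMAConfig(
        treatments=("A", "B"),
        true_effects={"A": {"y": 0.0}, "B": {"y": truth}},
        heterogeneity_sd={"y": het},
        studies=[(("A", "B"), n, sd)] * n_studies,
        seed=seed,
    )
    return gen_nma_dataset(cfg)


def triangle_dataset(seed=11, shift_ab=0.0, n=300, per_design=3):
    truths = {"A": {"y": 0.0}, "B": {"y": -0.05}, "C": {"y": -0.08}}
    cfg = SyntheticNMAConfig(
        treatments=("A", "B", "C"),
        true_effects=truths,
        heterogeneity_sd={"y": 0.005},
        studies=[(("A", "B"), n, 0.08)] * per_design
        + [(("B", "C"), n, 0.08)] * per_design
        + [(("A", "C"), n, 0.08)] * per_design,
        seed=seed,
    )
    ds = gen_nma_dataset(cfg)
    if shift_ab:
        mask = (ds.arms.design == "A/B") & (ds.arms.treatment == "B")
        ds.arms.loc[mask, "mean_change_rate"] += shift_ab
    return ds


@pytest.fixture(scope="module")
def six_treatment_fit():
    ds = gen_nma_dataset(default_nma_config(seed=5))
    res = fit_nma(ds, "hba1c", reference="placebo", chains=4, kept=4000,
                  burnin=2000, seed=7)
    return ds, res


class TestBuildNetwork:
    def test_chain_network_edges(self):
        cfg = SyntheticNMAConfig(
            treatments=("A", "B", "C"),
            true_effects={t: {"y": 0.0} for t in "ABC"},
            heterogeneity_sd={"y": 0.0},
            studies=[(("A", "B"), 10, 0.1), (("B", "C"), 10, 0.1)],
        )
        net = build_network(gen_nma_dataset(cfg), "y")
        assert net["connected"]
        assert net["edges"] == {("A", "B"): 1, ("B", "C"): 1}

    def test_packaged_roster_is_a_connected_seven_node_network(self):
        net = build_network(gen_nma_dataset(default_nma_config(seed=0)), "hba1c")
        assert len(net["nodes"]) == 7
        assert net["connected"]
        assert net["n_studies"] == 9
        # placebo-lixisenatide has two trials in the roster
        assert net["edges"][("lixisenatide", "placebo")] == 2


class TestGelmanRubin:
    def test_constant_chains_convention(self):
        assert gelman_rubin(np.ones((4, 100))) == 1.0

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(0, 1, size=(4, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_disjoint_means_flagged(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(0, 1, size=(4, 500)) + np.arange(4)[:, None] * 10
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestFitNMA:
    def test_two_arm_matches_inverse_variance_oracle(self):
        ds = two_treatment_dataset()
        diffs, weights = [], []
        for _, g in ds.endpoint("y").groupby("study"):
            g = g.set_index("treatment")
            d = g.loc["B", "mean_change_rate"] - g.loc["A", "mean_change_rate"]
            v = (g.loc["B", "sd"] ** 2 / g.loc["B", "n"]
                 + g.loc["A", "sd"] ** 2 / g.loc["A", "n"])
            diffs.append(d)
            weights.append(1.0 / v)
        fe = np.average(diffs, weights=weights)
        fe_se = math.sqrt(1.0 / np.sum(weights))
        res = fit_nma(ds, "y", reference="A", chains=3, kept=2500, burnin=1200, seed=9)
        post = res.contrast_draws("A", "B")
        assert abs(post.mean() - fe) < 3 * fe_se
        assert res.converged

    def test_recovers_known_truths_within_three_posterior_sd(self, six_treatment_fit):
        _, res = six_treatment_fit
        base = DEFAULT_TRUE_EFFECTS["placebo"]["hba1c"]
        for t in res.treatments:
            if t == "placebo":
                continue
            truth = DEFAULT_TRUE_EFFECTS[t]["hba1c"] - base
            x = res.contrast_draws("placebo", t)
            assert abs(x.mean() - truth) < 3 * x.std(ddof=1), t

    def test_identical_arms_centre_at_zero(self):
        cfg = SyntheticNMAConfig(
            treatments=("A", "B"),
            true_effects={"A": {"y": -0.05}, "B": {"y": -0.05}},
            heterogeneity_sd={"y": 0.0},
            studies=[(("A", "B"), 500, 0.05)] * 10,
            seed=21,
        )
        ds = gen_nma_dataset(cfg)
        res = fit_nma(ds, "y", reference="A", chains=2, kept=1500, burnin=800, seed=3)
        x = res.contrast_draws("A", "B")
        assert abs(x.mean()) < 3 * x.std(ddof=1)

    def test_seed_fixes_posterior_summaries(self):
        ds = two_treatment_dataset(n_studies=4)
        r1 = fit_nma(ds, "y", chains=2, kept=500, burnin=300, seed=5)
        r2 = fit_nma(ds, "y", chains=2, kept=500, burnin=300, seed=5)
        assert np.array_equal(r1.d_draws, r2.d_draws)
        assert np.array_equal(r1.tau_draws, r2.tau_draws)

    def test_disconnected_or_bad_dispersion_rejected(self):
        ds = two_treatment_dataset(n_studies=3)
        ds.arms.loc[0, "sd"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_nma(ds, "y", chains=2, kept=200, burnin=100, seed=1)


class TestConsistencyAlgebra:
    def test_contrast_matrix_is_skew_and_transitive(self, six_treatment_fit):
        _, res = six_treatment_fit
        t = res.treatments
        for a, b in [(t[0], t[1]), (t[2], t[4])]:
            ab = res.contrast_draws(a, b).mean()
            ba = res.contrast_draws(b, a).mean()
            assert ab == pytest.approx(-ba, abs=1e-12)
        # transitivity of posterior means of basic-parameter combinations
        ac = res.contrast_draws(t[0], t[2]).mean()
        ab = res.contrast_draws(t[0], t[1]).mean()
        bc = res.contrast_draws(t[1], t[2]).mean()
        assert ac == pytest.approx(ab + bc, abs=1e-12)

    def test_rereferencing_leaves_pairwise_contrasts_unchanged(self, six_treatment_fit):
        _, res = six_treatment_fit
        tab_a = relative_effects(res, reference="placebo")
        tab_b = relative_effects(res, reference="semaglutide")
        row = lambda tab, a, b: tab[(tab.reference == a) & (tab.treatment == b)]["mean"].iloc[0]
        assert row(tab_a, "exenatide", "loxenatide") == row(tab_b, "exenatide", "loxenatide")

    def test_self_contrast_is_zero(self, six_treatment_fit):
        _, res = six_treatment_fit
        assert np.all(res.contrast_draws("exenatide", "exenatide") == 0.0)

    def test_unknown_reference_rejected(self, six_treatment_fit):
        _, res = six_treatment_fit
        with pytest.raises(ValueError, match="unknown reference"):
            relative_effects(res, reference="benaglutide")


class TestNodeSplit:
    def test_consistent_triangle_no_inconsistency(self):
        out = node_split(triangle_dataset(seed=11), "y", ("A", "B"),
                         chains=2, kept=2000, burnin=1000, seed=13)
        assert abs(out["difference"]) < 3 * out["difference_sd"]
        assert out["p_value"] > 0.05

    def test_injected_inconsistency_detected(self):
        ds = triangle_dataset(seed=12, shift_ab=-0.06, per_design=4)
        out = node_split(ds, "y", ("A", "B"), chains=2, kept=2000,
                         burnin=1000, seed=14)
        assert out["p_value"] < 0.05
        assert out["direct"] < out["indirect"]

    def test_star_network_not_splittable(self):
        cfg = SyntheticNMAConfig(
            treatments=("A", "B", "C"),
            true_effects={t: {"y": 0.0} for t in "ABC"},
            heterogeneity_sd={"y": 0.0},
            studies=[(("A", "B"), 50, 0.1), (("A", "C"), 50, 0.1)],
            seed=1,
        )
        ds = gen_nma_dataset(cfg)
        with pytest.raises(ValueError, match="indirect"):
            node_split(ds, "y", ("A", "B"), chains=2, kept=200, burnin=100, seed=1)
        with pytest.raises(ValueError, match="direct"):
            node_split(ds, "y", ("B", "C"), chains=2, kept=200, burnin=100, seed=1)


class TestDesignByTreatment:
    def test_i_squared_boundary_identities(self):
        assert i_squared(4.0, 4) == 0.0
        assert i_squared(8.0, 4) == 50.0
        assert i_squared(1.0, 4) == 0.0  # floored at zero

    def test_consistent_network_p_values_spread_under_null(self):
        truths = {"A": {"y": 0.0}, "B": {"y": -0.05}, "C": {"y": -0.08}}
        ps = []
        for rep in range(40):
            cfg = SyntheticNMAConfig(
                treatments=("A", "B", "C"),
                true_effects=truths,
                heterogeneity_sd={"y": 0.0},
                studies=[(("A", "B"), 300, 0.08), (("B", "C"), 300, 0.08),
                         (("A", "C"), 300, 0.08)] * 2,
                seed=100 + rep,
            )
            ds = gen_nma_dataset(cfg)
            rep_out = design_by_treatment(ds, "y")
            assert rep_out.estimable
            ps.append(rep_out.p_value)
        ps = np.asarray(ps)
        # p-values should spread over (0,1) rather than cluster: crude
        # Kolmogorov-Smirnov distance from uniform
        from scipy import stats

        d, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_inconsistency_inflates_q(self):
        ds = triangle_dataset(seed=55, shift_ab=-0.08, per_design=4)
        out = design_by_treatment(ds, "y")
        assert out.p_value < 0.05
        assert out.i2 > 50.0

    def test_single_design_not_estimable(self):
        ds = two_treatment_dataset(n_studies=5)
        out = design_by_treatment(ds, "y")
        assert not out.estimable
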