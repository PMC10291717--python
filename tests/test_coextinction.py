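"""Stochastic coextinction cascades: oracle agreement and closed forms."""

import numpy as np
import pytest

from conftest import make_table
from _oracles import exact_mean_extinction_pct
from multimut.coextinction import (
    DependencyStructure,
    bootstrap_size_control,
    build_dependencies,
    robustness_experiment,
    sequential_removal,
    simulate_cascade,
    single_removal_experiment,
    species_role_map,
)
from multimut.network import DISPERSAL, POLLINATION, assemble_multilayer
from multimut.roles import CONNECTOR, PERIPHERAL


def deps_from(partners, R, groups=None):
    return DependencyStructure(
        partners=partners,
        R=R,
        groups=groups or {sp: "plant" for sp in partners},
    )


def chain_deps(r_a=0.5, r_b=0.8, r_c=0.9):
    """A - B - C chain with asymmetric dependence of B."""
    return deps_from(
        {"A": {"B": 1.0}, "B": {"A": 0.3, "C": 0.7}, "C": {"B": 1.0}},
        {"A": r_a, "B": r_b, "C": r_c},
    )


def star_deps(r_hub=0.5, r_leaf=0.9):
    partners = {"H": {"L1": 1 / 3, "L2": 1 / 3, "L3": 1 / 3}}
    for leaf in ("L1", "L2", "L3"):
        partners[leaf] = {"H": 1.0}
    R = {"H": r_hub, "L1": r_leaf, "L2": r_leaf, "L3": r_leaf}
    return deps_from(partners, R)


def five_species_deps():
    partners = {
        "P1": {"a1": 0.5, "a2": 0.5},
        "P2": {"a2": 0.3, "a3": 0.7},
        "a1": {"P1": 1.0},
        "a2": {"P1": 0.4, "P2": 0.6},
        "a3": {"P2": 1.0},
    }
    R = {"P1": 0.7, "P2": 0.6, "a1": 0.9, "a2": 0.5, "a3": 0.8}
    return deps_from(partners, R)


TOYS = {
    "chain": (chain_deps(), "B"),
    "star": (star_deps(), "H"),
    "five": (five_species_deps(), "P1"),
    "pair": (deps_from({"X": {"Y": 1.0}, "Y": {"X": 1.0}}, {"X": 1.0, "Y": 1.0}), "X"),
}


class TestBuildDependencies:
    def test_single_partner_dependence_is_one(self, toy_network):
        deps = build_dependencies(toy_network, 0.5)
        assert deps.partners["pol2"] == {"pA": 1.0}

    def test_plant_normalization_spans_both_layers(self):
        pol = make_table(
            "s", POLLINATION, [("pA", "a1", 2), ("pA", "a2", 2), ("pB", "a3", 96)]
        )
        disp = make_table("s", DISPERSAL, [("pA", "d1", 6), ("pC", "d1", 94)])
        deps = build_dependencies(assemble_multilayer(pol, disp), 0.5)
        assert deps.partners["pA"] == pytest.approx({"a1": 0.2, "a2": 0.2, "d1": 0.6})

    def test_all_rows_sum_to_one(self, preset_networks):
        deps = build_dependencies(preset_networks["intact"], 0.5)
        for sp, row in deps.partners.items():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12), sp

    def test_per_layer_normalization_splits_plant_budget(self):
        pol = make_table("s", POLLINATION, [("pA", "a1", 1), ("pA", "a2", 3)])
        disp = make_table("s", DISPERSAL, [("pA", "d1", 2)])
        deps = build_dependencies(
            assemble_multilayer(pol, disp), 0.5, plant_normalization="per-layer"
        )
        assert deps.partners["pA"] == pytest.approx({"a1": 0.125, "a2": 0.375, "d1": 0.5})

    def test_r_outside_unit_interval_rejected(self, toy_network):
        with pytest.raises(ValueError, match="R must lie"):
            build_dependencies(toy_network, 1.5)


class TestSimulateCascade:
    def test_no_propagation_when_r_zero(self):
        deps = deps_from(
            {"A": {"B": 1.0}, "B": {"A": 1.0}}, {"A": 0.0, "B": 0.0}
        )
        result = simulate_cascade(deps, "A", np.random.default_rng(0))
        assert result.extinct == {"A"}
        assert result.E == pytest.approx(100.0 / 2)

    def test_obligate_pair_always_collapses(self):
        deps, primary = TOYS["pair"]
        result = simulate_cascade(deps, primary, np.random.default_rng(1))
        assert result.extinct == {"X", "Y"}
        assert result.E == 100.0

    def test_unknown_species_rejected(self):
        deps, _ = TOYS["chain"]
        with pytest.raises(KeyError):
            simulate_cascade(deps, "nope", np.random.default_rng(0))

    @pytest.mark.parametrize("toy", sorted(TOYS))
    def test_monte_carlo_matches_exact_enumeration(self, toy):
        """MC mean E agrees with the Bernoulli outcome tree within 3 SE."""
        deps, primary = TOYS[toy]
        exact = exact_mean_extinction_pct(deps.partners, deps.R, primary)
        rng = np.random.default_rng(2024)
        n = 20_000
        sample = np.fromiter(
            (simulate_cascade(deps, primary, rng).E for _ in range(n)), dtype=float, count=n
        )
        se = sample.std(ddof=1) / np.sqrt(n)
        if se == 0:
            assert sample.mean() == pytest.approx(exact)
        else:
            assert abs(sample.mean() - exact) < 3 * se

    def test_mean_E_nondecreasing_in_R(self):
        """Raising one species' intrinsic dependence never lowers expected E."""
        lo = chain_deps(r_b=0.3)
        hi = chain_deps(r_b=0.9)
        e_lo = exact_mean_extinction_pct(lo.partners, lo.R, "A")
        e_hi = exact_mean_extinction_pct(hi.partners, hi.R, "A")
        assert e_hi >= e_lo
        # and the simulator tracks the same ordering
        n = 20_000
        rng = np.random.default_rng(5)
        m_lo = np.mean([simulate_cascade(lo, "A", rng).E for _ in range(n)])
        rng = np.random.default_rng(5)
        m_hi = np.mean([simulate_cascade(hi, "A", rng).E for _ in range(n)])
        assert m_hi >= m_lo - 0.5


class TestSingleRemoval:
    def test_r_zero_gives_exact_floor(self):
        deps, _ = TOYS["five"]
        deps = deps_from(deps.partners, {sp: 0.0 for sp in deps.partners})
        table = single_removal_experiment(deps, reps=10, seed=0)
        assert (table["mean_E"] == 100.0 / 5).all()
        assert (table["sd_E"] == 0.0).all()

    def test_deterministic_pair_has_zero_variance(self):
        deps, _ = TOYS["pair"]
        table = single_removal_experiment(deps, reps=50, seed=0)
        assert (table["mean_E"] == 100.0).all()
        assert (table["sd_E"] == 0.0).all()

    def test_hub_removal_propagates_more_than_leaf(self):
        deps = star_deps(r_hub=0.9, r_leaf=0.9)
        table = single_removal_experiment(deps, reps=400, seed=1).set_index("species")
        assert table.loc["H", "mean_E"] > table.loc["L1", "mean_E"]

    def test_reproducible_given_seed(self):
        deps, _ = TOYS["five"]
        t1 = single_removal_experiment(deps, reps=30, seed=9)
        t2 = single_removal_experiment(deps, reps=30, seed=9)
        assert t1.equals(t2)


class TestSequentialRemoval:
    def test_r_zero_curve_is_straight_line(self):
        deps, _ = TOYS["five"]
        deps = deps_from(deps.partners, {sp: 0.0 for sp in deps.partners})
        curve = sequential_removal(deps, "random", seed=0)
        assert curve.auc == 0.5
        np.testing.assert_allclose(curve.y, 1 - curve.x)

    def test_single_species_network(self):
        deps = deps_from({"A": {}}, {"A": 0.0})
        # a species with no partners: row is empty, removal empties the net
        curve = sequential_removal(deps, "random", seed=0)
        assert curve.x.tolist() == [0.0, 1.0]
        assert curve.y.tolist() == [1.0, 0.0]
        assert curve.auc == 0.5

    def test_curve_endpoints_and_monotonicity(self):
        deps, _ = TOYS["five"]
        roles = {sp: PERIPHERAL for sp in deps.partners}
        roles["P1"] = CONNECTOR
        for scenario in ("most-to-least", "least-to-most", "random"):
            curve = sequential_removal(deps, scenario, roles, seed=3)
            assert (curve.x[0], curve.y[0]) == (0.0, 1.0)
            assert (curve.x[-1], curve.y[-1]) == (1.0, 0.0)
            assert (np.diff(curve.x) > 0).all()
            assert (np.diff(curve.y) <= 0).all()
            assert 0.0 <= curve.auc <= 0.5

    def test_obligate_star_less_robust_than_no_propagation(self):
        deps = star_deps(r_hub=1.0, r_leaf=1.0)
        roles = {"H": CONNECTOR, "L1": PERIPHERAL, "L2": PERIPHERAL, "L3": PERIPHERAL}
        aucs = robustness_experiment(deps, "most-to-least", roles, n_runs=50, seed=0)
        assert aucs["auc"].mean() < 0.5

    def test_unknown_scenario_rejected(self):
        deps, _ = TOYS["pair"]
        with pytest.raises(ValueError, match="unknown scenario"):
            sequential_removal(deps, "alphabetical")


class TestRobustnessExperiment:
    def test_r_zero_degenerate_distribution(self):
        deps, _ = TOYS["five"]
        deps = deps_from(deps.partners, {sp: 0.0 for sp in deps.partners})
        aucs = robustness_experiment(deps, "random", n_runs=25, seed=0)
        assert (aucs["auc"] == 0.5).all()

    def test_bit_reproducible_given_seed(self):
        deps, _ = TOYS["five"]
        a = robustness_experiment(deps, "random", n_runs=40, seed=7)
        b = robustness_experiment(deps, "random", n_runs=40, seed=7)
        assert a.equals(b)

    def test_stronger_dependence_reduces_mean_auc(self):
        deps, _ = TOYS["five"]
        weak = deps_from(deps.partners, {sp: 0.1 for sp in deps.partners})
        strong = deps_from(deps.partners, {sp: 0.9 for sp in deps.partners})
        n = 1000
        a_weak = robustness_experiment(weak, "random", n_runs=n, seed=0)["auc"]
        a_strong = robustness_experiment(strong, "random", n_runs=n, seed=0)["auc"]
        se = np.sqrt(a_weak.var(ddof=1) / n + a_strong.var(ddof=1) / n)
        assert a_strong.mean() <= a_weak.mean() + 2 * se


class TestSpeciesRoleMap:
    def test_plant_takes_most_connected_of_its_two_roles(self):
        import pandas as pd

        df = pd.DataFrame(
            [("p1", POLLINATION, CONNECTOR), ("p1", DISPERSAL, PERIPHERAL)],
            columns=["species", "layer", "role"],
        )
        assert species_role_map(df) == {"p1": CONNECTOR}


class TestBootstrapSizeControl:
    def test_full_size_with_r_zero_is_degenerate(self, preset_pair):
        pol, disp = preset_pair["invaded"]
        net = assemble_multilayer(pol, disp)
        targets = {
            "plant": len(net.plants),
            "pollinator": len(net.pollinators),
            "disperser": len(net.dispersers),
        }
        out = bootstrap_size_control(
            pol, disp, targets, reps=3, R_config=0.0, single_reps=2, auc_runs=2, seed=0
        )
        assert (out["n_species"] == net.n_species).all()
        assert (out["mean_E"] == 100.0 / net.n_species).all()
        np.testing.assert_allclose(out["mean_auc_random"], 0.5)

    def test_downsampling_to_invaded_counts(self, preset_pair):
        pol, disp = preset_pair["intact"]
        targets = {"plant": 24, "pollinator": 67, "disperser": 4}
        out = bootstrap_size_control(
            pol, disp, targets, reps=4, R_config=0.5, single_reps=3, auc_runs=3, seed=1
        )
        assert len(out) == 4
        assert (out["n_species"] <= 24 + 67 + 4).all()
        assert out["mean_E"].between(0, 100).all()

    def test_excess_target_rejected(self, preset_pair):
        pol, disp = preset_pair["invaded"]
        with pytest.raises(ValueError, match="exceeds available"):
            bootstrap_size_control(pol, disp, {"disperser": 99}, reps=1)
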