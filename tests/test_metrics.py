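"""Density, module detection (with reachability oracle), hubs, comparisons."""

import itertools

import numpy as np
import pytest

from conftest import make_network
from mlcnet.correlation import SpearmanCorrelation
from mlcnet.metrics import (compare_networks, density, hub_ranking,
                            metrics_report, modules)
from mlcnet.network import build_network
from mlcnet.simulate import (CohortSpec, PlantedBlock, default_study_spec,
                             generate_cohort)
from mlcnet.cohort import VariableMeta


def union_find_components(nodes, edges):
    """Independent union-find oracle for connected components."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


class TestDensity:
    def test_complete_graph(self):
        net = make_network([(a, b) for a, b in
                            itertools.combinations("ABCDE", 2)])
        assert density(net) == 1.0

    def test_edgeless(self):
        net = make_network([], nodes=list("ABCDE"))
        assert density(net) == 0.0

    def test_path_counts_all_pairs(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "D")])
        assert density(net) == 0.5  # 3 / 6

    def test_isolated_nodes_enter_denominator(self):
        net = make_network([("A", "B")], nodes=list("ABCD"))
        assert density(net) == pytest.approx(1 / 6)

    def test_too_few_nodes_errors(self):
        with pytest.raises(ValueError):
            density(make_network([], nodes=["A"]))


class TestModules:
    def test_two_triangles(self):
        net = make_network(
            [("A", "B"), ("B", "C"), ("A", "C"),
             ("X", "Y"), ("Y", "Z"), ("X", "Z")]
        )
        mods = modules(net)
        assert mods.sizes() == (3, 3)

    def test_naming_majority_and_mixed(self):
        levels = {"A": "bone_marrow", "B": "bone_marrow", "C": "bone_marrow",
                  "D": "clinical", "E": "blood"}
        net = make_network([("A", "B"), ("B", "C"), ("D", "E")],
                           levels=levels)
        mods = modules(net)
        assert mods.names == ("bone_marrow", "mixed")

    def test_edgeless_network_has_no_modules(self):
        assert len(modules(make_network([], nodes=list("AB")))) == 0

    def test_ordering_is_deterministic(self):
        net = make_network([("A", "B"), ("C", "D"), ("E", "F"), ("F", "G")])
        mods = modules(net)
        assert mods.sizes() == (3, 2, 2)

    def test_default_cohort_modules_match_union_find_oracle(self, default_cohort):
        cohort, _ = default_cohort
        corr = SpearmanCorrelation().fit(cohort)
        net = build_network(corr, cohort.levels, 0.01)
        expected = union_find_components(net.graph.nodes,
                                         list(net.graph.edges))
        assert set(modules(net).modules) == expected

    def test_random_small_graphs_match_reachability_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            k = rng.integers(2, 9)
            nodes = [f"N{i}" for i in range(k)]
            pairs = list(itertools.combinations(nodes, 2))
            chosen = [p for p in pairs if rng.random() < 0.3]
            net = make_network(chosen, nodes=nodes)
            assert set(modules(net).modules) == union_find_components(
                nodes, chosen
            )


class TestHubs:
    def test_star_center_first(self):
        net = make_network([("HUB", x) for x in "ABCDE"])
        ranking = hub_ranking(net, 1)
        assert ranking == [("HUB", 5)]

    def test_edgeless_alphabetical(self):
        net = make_network([], nodes=["c", "a", "b", "d"])
        assert hub_ranking(net, 3) == [("a", 0), ("b", 0), ("c", 0)]

    def test_k_validation(self):
        with pytest.raises(ValueError):
            hub_ranking(make_network([("A", "B")]), 0)

    def test_planted_hub_recovered(self):
        """Blocks all containing Eos make it the top-degree node."""
        names = ["Eos"] + [f"V{i}" for i in range(9)]
        variables = [VariableMeta(n, "blood", "continuous") for n in names]
        blocks = (
            PlantedBlock(["Eos", "V0", "V1", "V2"], 0.45, ("g",)),
            PlantedBlock(["Eos", "V3", "V4", "V5"], 0.45, ("g",)),
            PlantedBlock(["Eos", "V6", "V7"], 0.45, ("g",)),
        )
        wins = 0
        reps = 100
        for r in range(reps):
            spec = CohortSpec(group_sizes=(("g", 60),), variables=variables,
                              blocks=blocks, missing_rate=0.0, seed=2000 + r)
            cohort, _ = generate_cohort(spec)
            net = build_network(SpearmanCorrelation().fit(cohort),
                                cohort.levels, 0.01)
            wins += hub_ranking(net, 1)[0][0] == "Eos"
        assert wins / reps >= 0.9


class TestCompare:
    def test_identity(self):
        net = make_network([("A", "B"), ("B", "C")], nodes=list("ABCDE"))
        c = compare_networks(net, net, k=3)
        assert c.density_diff == 0
        assert c.edge_jaccard == 1.0
        assert c.hub_overlap == 3
        assert c.shared_variables == 5

    def test_extremes(self):
        full = make_network([(a, b) for a, b in
                             itertools.combinations("ABCDE", 2)])
        empty = make_network([], nodes=list("ABCDE"))
        c = compare_networks(full, empty)
        assert c.density_diff == 1.0
        assert c.edge_jaccard == 0.0

    def test_no_shared_variables_errors(self):
        with pytest.raises(ValueError, match="share"):
            compare_networks(make_network([("A", "B")]),
                             make_network([("X", "Y")]))

    def test_jaccard_restricted_to_shared_subgraph(self):
        a = make_network([("A", "B"), ("A", "Q")], nodes=["A", "B", "Q"])
        b = make_network([("A", "B"), ("R", "A")], nodes=["A", "B", "R"])
        c = compare_networks(a, b)
        assert c.edge_jaccard == 1.0  # only (A,B) lies in the shared subgraph
        assert c.shared_variables == 2

    def test_copd_network_denser_than_never_smokers(self):
        """Planted group asymmetry shows up as a positive density gap."""
        wins = 0
        reps = 100
        for r in range(reps):
            cohort, _ = generate_cohort(default_study_spec(3000 + r))
            nets = {}
            for g in ("copd", "never_smoker"):
                sub = cohort.select_subjects((cohort.groups == g).to_numpy())
                corr = SpearmanCorrelation().fit(sub)
                nets[g] = build_network(corr, sub.levels, 0.01)
            c = compare_networks(nets["copd"], nets["never_smoker"])
            wins += c.density_diff > 0
        assert wins / reps >= 0.9


def test_metrics_report_shape(default_cohort):
    cohort, _ = default_cohort
    net = build_network(SpearmanCorrelation().fit(cohort), cohort.levels, 0.01)
    rep = metrics_report(net)
    assert rep["n_nodes"] == 47
    assert rep["n_modules"] == len(modules(net))
    assert 0 <= rep["density"] <= 1
    assert rep["largest_module_size"] >= 2
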