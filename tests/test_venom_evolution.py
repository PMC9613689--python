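"""Orthogroup comparison, Wagner parsimony dating and origin classification."""

import itertools

import numpy as np
import pytest

from parawasp.simulate import SCENARIOS, gen_gene_trees, gen_presence_absence
from parawasp.simulate.genetrees import EXPECTED_MODEL
from parawasp.trees import (
    DEFAULT_ANASTATUS,
    DEFAULT_CHALCIDOIDEA,
    find_node,
    load_tree,
    node_ages,
    node_name,
)
from parawasp.venom_evolution import (
    OrthoGroup,
    classify_venom_origin,
    compare_venom_ogs,
    filter_ogs,
    infer_duplication_nodes,
    wagner_age,
)


class TestCompareVenomOgs:
    def make_og(self, og_id, a_total, a_venom, b_total, b_venom):
        members, venom = [], set()
        for i in range(a_total):
            g = f"{og_id}_A{i}"
            members.append(("A", g))
            if i < a_venom:
                venom.add(g)
        for i in range(b_total):
            g = f"{og_id}_B{i}"
            members.append(("B", g))
            if i < b_venom:
                venom.add(g)
        return OrthoGroup(og_id, members, venom)

    def test_hand_partitioned_toy_set(self):
        ogs = [
            self.make_og("og1", 2, 2, 2, 2),  # strictly conserved
            self.make_og("og2", 3, 2, 3, 1),  # shared, unequal copy number
            self.make_og("og3", 1, 1, 1, 0),  # A-specific venom
            self.make_og("og4", 1, 0, 2, 2),  # B-specific venom
            self.make_og("og5", 2, 0, 2, 0),  # no venom at all
        ]
        res = compare_venom_ogs(ogs, "A", "B")
        assert res["shared"] == ["og1", "og2"]
        assert res["strictly_conserved"] == ["og1"]
        assert res["a_specific"] == ["og3"]
        assert res["b_specific"] == ["og4"]

    def test_partition_is_disjoint_and_exhaustive(self):
        ogs = [
            self.make_og(f"og{i}", 1 + i % 3, i % 3, 1 + (i + 1) % 3, (i + 1) % 3)
            for i in range(12)
        ]
        res = compare_venom_ogs(ogs, "A", "B")
        venom_ogs = {og.og_id for og in ogs if og.venom}
        parts = [set(res["shared"]), set(res["a_specific"]), set(res["b_specific"])]
        assert set.union(*parts) == venom_ogs
        assert sum(len(p) for p in parts) == len(venom_ogs)
        assert set(res["strictly_conserved"]) <= set(res["shared"])


class TestFilterOgs:
    ANA = frozenset({"Anastatus_japonicus", "Anastatus_fulloi"})

    def og(self, og_id, species_counts):
        members = [
            (sp, f"{og_id}_{sp}_{i}")
            for sp, n in species_counts.items()
            for i in range(n)
        ]
        return OrthoGroup(og_id, members)

    def test_anastatus_specific_dropped(self):
        og = self.og("x", {"Anastatus_japonicus": 3, "Anastatus_fulloi": 3})
        assert filter_ogs([og], self.ANA) == []

    def test_small_og_dropped(self):
        og = self.og("x", {"Anastatus_japonicus": 1, "Nasonia_vitripennis": 1,
                           "Apis_mellifera": 1, "Pteromalus_puparum": 1})
        assert filter_ogs([og], self.ANA) == []

    def test_qualifying_og_retained(self):
        og = self.og("x", {"Anastatus_japonicus": 2, "Anastatus_fulloi": 1,
                           "Nasonia_vitripennis": 2, "Apis_mellifera": 1})
        assert [o.og_id for o in filter_ogs([og], self.ANA)] == ["x"]


def random_ultrametric_newick(rng, n_leaves):
    """Random ultrametric tree built by successive pairwise joins."""
    nodes = [(f"L{i}", 0.0) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        h = max(h_i, h_j) + rng.uniform(0.5, 2.0)
        nwk = f"({nwk_i}:{h - h_i:.6f},{nwk_j}:{h - h_j:.6f})"
        nodes.append((nwk, h))
    return nodes[0][0] + ";"


def enumerate_wagner(tree, presence):
    """Exhaustive minimum-change enumeration: returns (min cost, best age,
    nodes that are the oldest-present node in some optimal labeling of that
    age)."""
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    ages = node_ages(tree)
    leaf_state = {
        n: int(presence.get(n.taxon.label, 0)) for n in nodes if n.is_leaf()
    }
    best_cost, best_age, best_nodes = None, None, set()
    for bits in itertools.product((0, 1), repeat=len(internal)):
        state = dict(leaf_state)
        state.update(zip(internal, bits))
        cost = sum(
            abs(state[n] - state[n.parent_node])
            for n in nodes
            if n.parent_node is not None
        )
        present = [n for n in nodes if state[n] == 1]
        if not present:
            continue
        age = max(ages[n] for n in present)
        oldest = {n for n in present if ages[n] == age}
        if best_cost is None or cost < best_cost:
            best_cost, best_age, best_nodes = cost, age, set(oldest)
        elif cost == best_cost:
            if age > best_age:
                best_age, best_nodes = age, set(oldest)
            elif age == best_age:
                best_nodes |= oldest
    return best_cost, best_age, best_nodes


class TestWagnerAge:
    def test_single_species_presence_dates_to_that_tip(self, species_tree):
        node = wagner_age({"Anastatus_japonicus": 1}, species_tree)
        assert node_name(node) == "Anastatus_japonicus"

    def test_shared_anastatus_presence_dates_to_their_ancestor(self, species_tree):
        node = wagner_age(
            {"Anastatus_japonicus": 1, "Anastatus_fulloi": 1}, species_tree
        )
        assert node_name(node) == "Anastatus_ANC"

    def test_ubiquitous_presence_dates_to_root(self, species_tree):
        presence = {t.label: 1 for t in species_tree.taxon_namespace}
        assert wagner_age(presence, species_tree) is species_tree.seed_node

    def test_all_absent_raises(self, species_tree):
        with pytest.raises(ValueError):
            wagner_age({}, species_tree)

    def test_matches_exhaustive_enumeration_on_random_trees(self, rng):
        """200 random presence vectors over random <= 10-leaf trees."""
        ages_checked = 0
        for _ in range(200):
            n_leaves = int(rng.integers(3, 11))
            tree = load_tree(random_ultrametric_newick(rng, n_leaves))
            presence = {
                f"L{i}": int(rng.random() < 0.5) for i in range(n_leaves)
            }
            if not any(presence.values()):
                presence[f"L{int(rng.integers(n_leaves))}"] = 1
            node = wagner_age(presence, tree)
            _, best_age, best_nodes = enumerate_wagner(tree, presence)
            ages = node_ages(tree)
            assert ages[node] == pytest.approx(best_age)
            assert node in best_nodes
            ages_checked += 1
        assert ages_checked == 200

    def test_noiseless_planted_gain_recovered_everywhere(self, species_tree):
        matrix, truth = gen_presence_absence(
            species_tree, "EPA", loss_prob=0.0, n_ogs=30, seed=4
        )
        for _, row in matrix.iterrows():
            node = wagner_age(row.to_dict(), species_tree)
            assert node_name(node) == "EPA"

    def test_planted_gain_recovered_despite_losses(self, species_tree):
        # EPA's immediate descendants are two cherries, so single losses tie
        # and the gain-early preference keeps the true node; only multi-tip
        # losses (rare at p = 0.1) can pull the date tipward
        matrix, _ = gen_presence_absence(
            species_tree, "EPA", loss_prob=0.1, n_ogs=200, seed=8
        )
        hits = sum(
            node_name(wagner_age(row.to_dict(), species_tree)) == "EPA"
            for _, row in matrix.iterrows()
        )
        assert hits >= 180  # >= 90% recovery

    def test_empty_matrix(self, species_tree):
        matrix, _ = gen_presence_absence(species_tree, "CA", 0.1, 0, seed=1)
        assert matrix.empty


def lca_reconciliation_events(gene_tree, species_map, species_tree):
    """Brute-force LCA reconciliation oracle for duplication calls."""
    sp_leaves = {
        node_name(leaf): leaf for leaf in species_tree.leaf_node_iter()
    }
    sp_ancestors = {}
    for name, leaf in sp_leaves.items():
        chain = []
        n = leaf
        while n is not None:
            chain.append(n)
            n = n.parent_node
        sp_ancestors[name] = chain

    def lca(species_set):
        chains = [sp_ancestors[sp] for sp in species_set]
        common = set(chains[0]).intersection(*map(set, chains[1:]))
        return next(n for n in chains[0] if n in common)

    mapping, events = {}, {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            mapping[node] = sp_leaves[species_map[node.taxon.label]]
        else:
            species = {
                species_map[l.taxon.label] for l in node.leaf_iter()
            }
            mapping[node] = lca(species)
            events[node] = (
                "duplication"
                if any(mapping[node] is mapping[c] for c in node.child_nodes())
                else "speciation"
            )
    return events


class TestDuplicationInference:
    def test_same_species_cherry_is_duplication(self):
        tree = load_tree("(('A|1':1,'A|2':1):1,'B|1':2);")
        species_map = {"A|1": "A", "A|2": "A", "B|1": "B"}
        events = infer_duplication_nodes(tree, species_map)
        internal = {
            node_name(n) or i: e for i, (n, e) in enumerate(events.items())
        }
        assert "duplication" in internal.values()
        assert list(events.values()).count("duplication") == 1

    def test_disjoint_clades_are_speciation(self):
        tree = load_tree("(('A|1':1,'B|1':1):1,('C|1':1,'D|1':1):1);")
        species_map = {l: l.split("|")[0] for l in ["A|1", "B|1", "C|1", "D|1"]}
        events = infer_duplication_nodes(tree, species_map)
        assert set(events.values()) == {"speciation"}

    def test_agrees_with_lca_reconciliation_on_consistent_trees(self, species_tree):
        for scenario in SCENARIOS:
            trees, _ = gen_gene_trees(scenario, n_trees=5, seed=17)
            for rec in trees:
                events = infer_duplication_nodes(rec["tree"], rec["species_map"])
                oracle = lca_reconciliation_events(
                    rec["tree"], rec["species_map"], species_tree
                )
                assert events == oracle


class TestOriginClassifier:
    @pytest.mark.parametrize("scenario", SCENARIOS)
    def test_full_accuracy_on_noiseless_scenarios(self, scenario):
        trees, truth = gen_gene_trees(scenario, n_trees=50, seed=29)
        expected = truth["expected_model"]
        for rec in trees:
            calls = classify_venom_origin(
                rec["tree"],
                rec["species_map"],
                rec["venom_leaves"],
                DEFAULT_CHALCIDOIDEA,
                DEFAULT_ANASTATUS,
            )
            assert set(calls) == rec["venom_leaves"]
            assert all(model == expected for model in calls.values())

    def test_unknown_scenario_raises(self):
        with pytest.raises(ValueError):
            gen_gene_trees("hgt", n_trees=1, seed=0)

    def test_missing_venom_leaf_raises(self):
        trees, _ = gen_gene_trees("single_copy", n_trees=1, seed=0)
        rec = trees[0]
        with pytest.raises(ValueError):
            classify_venom_origin(
                rec["tree"],
                rec["species_map"],
                {"NotALeaf|g1"},
                DEFAULT_CHALCIDOIDEA,
                DEFAULT_ANASTATUS,
            )
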