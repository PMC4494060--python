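"""Generalized-parsimony reconstruction against exhaustive enumeration."""

import numpy as np
import pandas as pd
import pytest

from oracles import exhaustive_sankoff_cost, random_rooted_binary_tree

from archflux.core_io import OrthologMatrix
from archflux.geneflux import (
    CostScheme,
    EventReconstruction,
    clade_unique_families,
    cost_matrix,
    flux_summary,
    node_id_map,
    sankoff_reconstruct,
    transition_cost,
)
from archflux.synthetic import simulate_gene_content_evolution
from conftest import make_tree


class TestTransitionCost:
    def test_identity_is_free(self):
        assert transition_cost(1, 1) == 0.0
        assert transition_cost(4, 4) == 0.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [(0, 1, 10.0), (1, 0, 5.0), (1, 2, 1.0), (2, 4, 0.4),
         (0, 3, 11.2), (0, 2, 11.0), (3, 0, 5.0), (1, 3, 1.2),
         (3, 2, 0.2), (3, 1, 0.4)],
    )
    def test_event_cost_scheme(self, a, b, expected):
        assert transition_cost(a, b) == pytest.approx(expected)

    def test_no_cheaper_multi_edge_decomposition_of_gain(self):
        # c(0,b) must equal the cheapest chain of single transitions
        costs = CostScheme()
        K = costs.max_copies
        C = cost_matrix(costs)
        # Floyd-Warshall shortest paths over repeated edges
        D = C.copy()
        for k in range(K + 1):
            D = np.minimum(D, D[:, [k]] + D[[k], :])
        assert np.allclose(D, C)

    def test_states_beyond_cap_rejected(self):
        with pytest.raises(ValueError, match="states"):
            transition_cost(0, 9)

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            CostScheme(gain=-1)


class TestSankoffExamples:
    def test_family_in_every_leaf_costs_nothing(self, quartet_tree):
        m = OrthologMatrix(pd.DataFrame(
            {t: [1] for t in "ABCD"}, index=["f"]))
        rec = sankoff_reconstruct(m, quartet_tree)
        assert rec.total_cost == 0.0
        assert (rec.states.loc["f"] == 1).all()
        assert rec.events.empty

    def test_half_present_family_is_one_cherry_stem_loss_by_default(
        self, quartet_tree
    ):
        # free root: present ancestrally, lost once on the (C,D) stem
        m = OrthologMatrix(pd.DataFrame(
            {"A": [1], "B": [1], "C": [0], "D": [0]}, index=["f"]))
        rec = sankoff_reconstruct(m, quartet_tree)
        assert rec.total_cost == 5.0
        assert int(rec.totals["losses"].sum()) == 1

    def test_single_gain_on_cherry_stem_under_root_charge(self, quartet_tree):
        m = OrthologMatrix(pd.DataFrame(
            {"A": [1], "B": [1], "C": [0], "D": [0]}, index=["f"]))
        rec = sankoff_reconstruct(m, quartet_tree, charge_root=True)
        assert rec.total_cost == 10.0
        gains = rec.events[rec.events["type"] == "gain"]
        assert len(gains) == 1
        # the gain sits on the stem of the (A,B) cherry, root stays absent
        assert rec.states.loc["f", rec.root_id] == 0
        assert rec.states.loc["f", "A"] == 1

    def test_root_presence_plus_single_loss_under_root_charge(
        self, quartet_tree
    ):
        m = OrthologMatrix(pd.DataFrame(
            {"A": [1], "B": [1], "C": [1], "D": [0]}, index=["f"]))
        rec = sankoff_reconstruct(m, quartet_tree, charge_root=True)
        assert rec.total_cost == 15.0  # root acquisition 10 + one loss 5
        assert rec.states.loc["f", rec.root_id] == 1
        assert int(rec.totals["losses"].sum()) == 1

    def test_matrix_taxon_missing_from_tree_rejected(self, quartet_tree):
        m = OrthologMatrix(pd.DataFrame({"A": [1], "Z": [1]}, index=["f"]))
        with pytest.raises(ValueError, match="absent from tree"):
            sankoff_reconstruct(m, quartet_tree)

    def test_unrooted_tree_rejected(self):
        tree = make_tree("(A:1,B:1,C:1);")
        m = OrthologMatrix(pd.DataFrame({"A": [1], "B": [1], "C": [1]},
                                        index=["f"]))
        with pytest.raises(ValueError, match="unrooted"):
            sankoff_reconstruct(m, tree)

    def test_presence_absence_mode_ignores_duplications(self, quartet_tree):
        m = OrthologMatrix(pd.DataFrame(
            {"A": [5], "B": [1], "C": [1], "D": [1]}, index=["f"]))
        rec = sankoff_reconstruct(m, quartet_tree, presence_absence=True)
        assert rec.mode == "presence_absence"
        assert rec.total_cost == 0.0  # everywhere-present once collapsed
        assert rec.states.loc["f"].max() == 1


class TestSankoffProperties:
    @pytest.mark.parametrize("charge_root", [True, False])
    def test_total_cost_matches_exhaustive_enumeration(self, charge_root):
        rng = np.random.default_rng(42)
        costs = CostScheme(max_copies=3)
        for trial in range(200):
            n_leaves = int(rng.integers(3, 6))
            labels = [f"T{i}" for i in range(n_leaves)]
            tree = random_rooted_binary_tree(labels, rng)
            states = {l: int(rng.integers(0, 4)) for l in labels}
            if all(v == 0 for v in states.values()):
                states[labels[0]] = 1
            m = OrthologMatrix(pd.DataFrame(
                {l: [states[l]] for l in labels}, index=["f"]))
            rec = sankoff_reconstruct(m, tree, costs,
                                      charge_root=charge_root)
            expected = exhaustive_sankoff_cost(tree, states, costs, 3,
                                               charge_root)
            assert rec.total_cost == pytest.approx(expected), (
                f"trial {trial}: {states}"
            )

    def test_reported_events_sum_to_total_cost(self):
        rng = np.random.default_rng(7)
        costs = CostScheme()
        labels = [f"T{i}" for i in range(6)]
        tree = random_rooted_binary_tree(labels, rng)
        counts = pd.DataFrame(
            rng.integers(0, 4, size=(30, 6)), columns=labels,
            index=[f"f{i:02d}" for i in range(30)],
        )
        counts = counts[counts.sum(axis=1) > 0]
        m = OrthologMatrix(counts)
        rec = sankoff_reconstruct(m, tree, costs)
        ids = node_id_map(tree)
        for fam in rec.states.index:
            total = 0.0
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    total += transition_cost(
                        int(rec.states.loc[fam, ids[node]]),
                        int(rec.states.loc[fam, ids[child]]), costs,
                    )
            assert total == pytest.approx(rec.per_family_cost[fam])

    def test_raising_gain_cost_never_reduces_losses(self):
        rng = np.random.default_rng(13)
        labels = [f"T{i}" for i in range(5)]
        for trial in range(20):
            tree = random_rooted_binary_tree(labels, rng)
            counts = pd.DataFrame(
                rng.integers(0, 3, size=(20, 5)), columns=labels,
                index=[f"f{i:02d}" for i in range(20)],
            )
            counts = counts[counts.sum(axis=1) > 0]
            m = OrthologMatrix(counts)
            low = sankoff_reconstruct(m, tree, CostScheme(gain=6))
            high = sankoff_reconstruct(m, tree, CostScheme(gain=20))
            assert (high.totals["losses"].sum()
                    >= low.totals["losses"].sum())

    def test_family_in_all_leaves_present_at_root(self):
        rng = np.random.default_rng(5)
        labels = [f"T{i}" for i in range(6)]
        tree = random_rooted_binary_tree(labels, rng)
        m = OrthologMatrix(pd.DataFrame({l: [1, 2] for l in labels},
                                        index=["f1", "f2"]))
        for charge in (True, False):
            rec = sankoff_reconstruct(m, tree, charge_root=charge)
            assert (rec.states[rec.root_id] >= 1).all()

    def test_focal_loss_branch_recovered_from_simulation(self):
        tree = make_tree(
            "(((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3):0.2,"
            "(E:0.4,F:0.4):0.3):0.0;"
        )
        matrix, truth = simulate_gene_content_evolution(
            tree, root_families=300, gain_rate=0.05, loss_rate=0.5,
            dup_rate=0.05, seed=17, focal_branch="N1", loss_multiplier=10.0,
        )
        rec = sankoff_reconstruct(matrix, tree)
        inferred = rec.totals.loc[
            rec.totals.index != rec.root_id, "losses"
        ]
        assert inferred.idxmax() == "N1"


class TestFluxSummary:
    def make_recon(self, totals: pd.DataFrame) -> EventReconstruction:
        return EventReconstruction(
            tree=None, states=pd.DataFrame(), events=pd.DataFrame(),
            totals=totals, total_cost=0.0, per_family_cost=pd.Series(dtype=float),
        )

    def test_zero_events_fold_undefined(self):
        totals = pd.DataFrame(
            {"gains": [0, 0], "losses": [0, 0], "expansions": [0, 0],
             "contractions": [0, 0], "families_at_child": [5, 5],
             "branch_length": [0.1, 0.2], "is_internal": [True, True]},
            index=pd.Index(["N1", "N2"], name="branch"),
        )
        with pytest.warns(UserWarning, match="undefined"):
            s = flux_summary(self.make_recon(totals), focal_branch="N1")
        # zero losses everywhere: rates are 0, fold 0/0 is undefined
        assert (s.per_branch["losses"] == 0).all()

    def test_forced_fold_arithmetic(self):
        totals = pd.DataFrame(
            {"gains": [0, 0, 0], "losses": [10, 5, 5],
             "expansions": [0] * 3, "contractions": [0] * 3,
             "families_at_child": [50, 50, 50],
             "branch_length": [0.1, 0.5, 0.5],
             "is_internal": [True, True, True]},
            index=pd.Index(["focal", "N1", "N2"], name="branch"),
        )
        s = flux_summary(self.make_recon(totals), focal_branch="focal")
        assert s.per_branch.loc["focal", "loss_rate"] == pytest.approx(100.0)
        assert s.fold_vs_background == (pytest.approx(10.0), pytest.approx(10.0))

    def test_missing_lengths_drop_rates_with_warning(self):
        totals = pd.DataFrame(
            {"gains": [1, 2], "losses": [3, 4], "expansions": [0, 0],
             "contractions": [0, 0], "families_at_child": [5, 5],
             "branch_length": [np.nan, 0.5], "is_internal": [True, True]},
            index=pd.Index(["N1", "N2"], name="branch"),
        )
        with pytest.warns(UserWarning, match="loss_rate"):
            s = flux_summary(self.make_recon(totals))
        assert np.isnan(s.per_branch.loc["N1", "loss_rate"])
        assert s.per_branch.loc["N2", "loss_rate"] == pytest.approx(8.0)


class TestCladeUnique:
    def test_strict_and_relaxed_modes(self):
        m = OrthologMatrix(pd.DataFrame(
            {"A": [1, 1, 1], "B": [1, 0, 0], "C": [0, 0, 1], "D": [0, 0, 0]},
            index=["all_in", "partial", "leaky"],
        ))
        clade = {"A", "B"}
        assert clade_unique_families(m, clade, "strict") == ["all_in"]
        assert clade_unique_families(m, clade, "relaxed") == ["all_in", "partial"]

    def test_empty_clade_rejected(self, simple_matrix):
        with pytest.raises(ValueError, match="empty"):
            clade_unique_families(simple_matrix, set())
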