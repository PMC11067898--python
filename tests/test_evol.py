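import itertools

import numpy as np
import pytest

import nichekit.evol as evol
from nichekit import build_bin_table, graft_taxon, read_newick, \
    reconstruct_bins, summarize_evolution
from nichekit.evol import ABSENT, PRESENT, UNCERTAIN


# ---------------------------------------------------------------------------
# bin tables


class TestBuildBinTable:
    def test_full_range_taxon_all_present(self):
        occ = {"a": np.linspace(0, 10, 200)}
        m = {"a": np.array([0.0, 10.0])}
        t = build_bin_table(occ, m, n_bins=5, trim=0.0)
        assert np.all(t.row("a") == PRESENT)

    def test_inaccessible_upper_half_uncertain(self):
        occ = {"a": np.linspace(0, 4, 50), "b": np.linspace(0, 10, 50)}
        m = {"a": np.array([0.0, 5.0]), "b": np.array([0.0, 10.0])}
        t = build_bin_table(occ, m, n_bins=10, trim=0.0)
        # bins wholly above a's accessible ceiling of 5 are uncertain
        assert np.all(t.row("a")[5:] == UNCERTAIN)
        assert np.all(t.row("a")[:5] != UNCERTAIN)

    def test_toy_interval_intersection(self):
        # occupied quantile interval [2.1, 4.9] on bins of width 1 over
        # [0, 10]; M covers [0, 6]
        occ = {"a": np.linspace(2.1, 4.9, 41), "b": np.linspace(0, 10, 40)}
        m = {"a": np.array([0.0, 6.0]), "b": np.array([0.0, 10.0])}
        t = build_bin_table(occ, m, n_bins=10, trim=0.0)
        row = t.row("a")
        assert np.all(row[2:5] == PRESENT)          # bins [2,3),[3,4),[4,5)
        assert np.all(row[:2] == ABSENT)
        assert row[5] == ABSENT
        assert np.all(row[6:] == UNCERTAIN)

    def test_present_run_contiguous_after_smoothing(self):
        # bimodal occurrences: interior gap bins are recoded present
        occ = {"a": np.r_[np.linspace(0, 2, 50), np.linspace(8, 10, 50)]}
        m = {"a": np.array([0.0, 10.0])}
        t = build_bin_table(occ, m, n_bins=10, trim=0.0)
        pres = np.flatnonzero(t.row("a") == PRESENT)
        assert np.array_equal(pres, np.arange(pres[0], pres[-1] + 1))

    def test_every_taxon_has_a_present_bin(self):
        rng = np.random.default_rng(0)
        occ = {f"t{i}": rng.normal(i, 0.5, 30) for i in range(4)}
        m = {f"t{i}": np.array([-3.0, 6.0]) for i in range(4)}
        t = build_bin_table(occ, m, n_bins=20)
        assert np.all((t.states == PRESENT).sum(axis=1) >= 1)

    def test_empty_occurrences_error(self):
        with pytest.raises(ValueError, match="no occurrence"):
            build_bin_table({"a": np.array([])}, {"a": np.array([0.0, 1.0])})


# ---------------------------------------------------------------------------
# grafting


class TestGraftTaxon:
    def test_midpoint_split_arithmetic(self):
        t = read_newick(data="((A:2.0,B:1.0):1.0,C:2.0);")
        t2 = graft_taxon(t, "N", "A")
        leaf_n = next(l for l in t2.leaf_node_iter()
                      if l.taxon.label == "N")
        leaf_a = next(l for l in t2.leaf_node_iter()
                      if l.taxon.label == "A")
        assert leaf_n.edge.length == pytest.approx(1.0)
        assert leaf_a.edge.length == pytest.approx(1.0)
        assert leaf_n.parent_node is leaf_a.parent_node
        assert leaf_n.parent_node.edge.length == pytest.approx(1.0)

    def test_other_path_lengths_unchanged(self):
        t = read_newick(data="((A:2.0,B:1.0):1.0,(C:0.5,D:0.5):2.5);")
        before = t.phylogenetic_distance_matrix()
        t2 = graft_taxon(t, "N", "C")
        after = t2.phylogenetic_distance_matrix()
        tips = ["A", "B", "C", "D"]
        for a, b in itertools.combinations(tips, 2):
            d1 = before.distance(t.taxon_namespace.get_taxon(a),
                                 t.taxon_namespace.get_taxon(b))
            d2 = after.distance(t2.taxon_namespace.get_taxon(a),
                                t2.taxon_namespace.get_taxon(b))
            assert d1 == pytest.approx(d2, abs=1e-12)
        assert len(t2.leaf_nodes()) == len(t.leaf_nodes()) + 1
        # input tree untouched
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == tips

    def test_errors(self):
        t = read_newick(data="((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError):
            graft_taxon(t, "N", "Z")
        with pytest.raises(ValueError):
            graft_taxon(t, "B", "A")


# ---------------------------------------------------------------------------
# parsimony reconstruction


from oracles import parsimony_oracle


def make_table(taxa, states_by_bin):
    states = np.array(states_by_bin).T  # bins x taxa -> taxa x bins
    edges = np.linspace(0, 1, states.shape[1] + 1)
    return evol.NicheBinTable("v", edges, taxa, states)


class TestReconstructBins:
    def test_constant_character_no_changes(self):
        t = read_newick(data="((A:1,B:1):1,(C:1,D:1):1);")
        table = make_table(["A", "B", "C", "D"], [[1, 1, 1, 1]])
        anc = reconstruct_bins(table, t)
        assert anc.changes_per_bin[0] == 0
        assert np.all(anc.node_states == PRESENT)

    def test_single_absent_tip_is_terminal_loss(self):
        t = read_newick(data="(((A:1,B:1):1,(C:1,D:1):1):1,E:3);")
        table = make_table(list("ABCDE"), [[0, 1, 1, 1, 1]])
        anc = reconstruct_bins(table, t)
        assert anc.changes_per_bin[0] == 1
        assert anc.states_of("node0")[0] == PRESENT  # root present
        assert anc.branch_changes["A"] == (0, 1)

    def test_balanced_split_root_ambiguous(self):
        t = read_newick(data="((A:1,B:1):1,(C:1,D:1):1);")
        table = make_table(list("ABCD"), [[1, 1, 0, 0]])
        anc = reconstruct_bins(table, t)
        assert anc.changes_per_bin[0] == 1
        assert anc.states_of("node0")[0] == UNCERTAIN  # ambiguous root

    def test_uncertain_tips_are_missing_data(self):
        t = read_newick(data="((A:1,B:1):1,(C:1,D:1):1);")
        table = make_table(list("ABCD"), [[1, -1, -1, 1]])
        anc = reconstruct_bins(table, t)
        assert anc.changes_per_bin[0] == 0
        # tip rows keep their input coding
        assert anc.states_of("B")[0] == UNCERTAIN

    def test_all_uncertain_bin_skipped(self):
        t = read_newick(data="((A:1,B:1):1,C:1);")
        table = make_table(list("ABC"), [[-1, -1, -1], [1, 1, 0]])
        anc = reconstruct_bins(table, t)
        assert anc.skipped_bins == [0]

    @pytest.mark.parametrize("newick", [
        "((A:1,B:1):1,C:1);",
        "((A:1,B:1):1,(C:1,D:1):1);",
        "(((A:1,B:1):1,C:2):1,(D:1,E:1):2);",
        "((A:1,B:1,C:1):1,(D:1,E:1):1,F:2);",  # polytomies
    ])
    def test_change_counts_match_enumeration_oracle(self, newick):
        tree = read_newick(data=newick)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rng = np.random.default_rng(hash(newick) % 2**31)
        bins = []
        for _ in range(25):
            states = rng.choice([PRESENT, ABSENT, UNCERTAIN], size=len(taxa),
                                p=[0.4, 0.4, 0.2])
            if np.all(states == UNCERTAIN):
                states[0] = PRESENT
            bins.append(states)
        table = make_table(taxa, bins)
        anc = reconstruct_bins(table, tree)
        for b in range(len(bins)):
            tip_states = dict(zip(taxa, bins[b]))
            assert anc.changes_per_bin[b] == parsimony_oracle(tree, tip_states)

    def test_invariant_to_tip_order(self):
        t1 = read_newick(data="((A:1,B:1):1,C:1);")
        t2 = read_newick(data="(C:1,(B:1,A:1):1);")
        tab1 = make_table(list("ABC"), [[1, 0, 0], [1, 1, 0]])
        tab2 = make_table(list("CBA"), [[0, 0, 1], [0, 1, 1]])
        a1 = reconstruct_bins(tab1, t1)
        a2 = reconstruct_bins(tab2, t2)
        assert np.array_equal(a1.changes_per_bin, a2.changes_per_bin)
        for tip in "ABC":
            assert np.array_equal(a1.states_of(tip), a2.states_of(tip))

    def test_taxa_mismatch_errors(self):
        t = read_newick(data="((A:1,B:1):1,C:1);")
        table = make_table(["A", "B"], [[1, 1]])
        with pytest.raises(ValueError, match="match"):
            reconstruct_bins(table, t)


class TestSummarizeEvolution:
    def test_constant_characters_all_zero(self):
        t = read_newick(data="((A:1,B:1):1,C:1);")
        table = make_table(list("ABC"), [[1, 1, 1], [0, 0, 0]])
        rep = summarize_evolution(reconstruct_bins(table, t))
        assert all(c.gained == 0 and c.lost == 0 for c in rep)

    def test_descendants_splitting_ancestor_range_contract(self):
        # partitioning pattern: a broad outgroup, two descendants each
        # occupying half the ancestral bins -> both terminal branches
        # contraction-dominated
        t = read_newick(data="((A:1,B:1):1,OUT:2);")
        bins = []
        for b in range(10):
            a_state = PRESENT if b < 5 else ABSENT
            b_state = PRESENT if b >= 5 else ABSENT
            bins.append([a_state, b_state, PRESENT])
        table = make_table(["A", "B", "OUT"], bins)
        rep = {c.child_id: c for c in
               summarize_evolution(reconstruct_bins(table, t))}
        assert rep["A"].contraction_dominated
        assert rep["B"].contraction_dominated
        assert not rep["OUT"].contraction_dominated

    def test_changes_equal_hamming_distance_of_resolved_states(self):
        t = read_newick(data="((A:1,B:1):1,C:1);")
        rng = np.random.default_rng(1)
        bins = [rng.choice([0, 1], size=3) for _ in range(30)]
        table = make_table(list("ABC"), bins)
        anc = reconstruct_bins(table, t)
        ids = anc.node_ids
        states = {nid: anc.node_states[i] for i, nid in enumerate(ids)}
        tipA = states["A"]
        root_children = anc.tree.seed_node.child_nodes()
        inner = next(n for n in root_children if not n.is_leaf())
        inner_id = ids[list(anc.tree.preorder_node_iter()).index(inner)]
        inner_states = states[inner_id]
        resolved = (inner_states != UNCERTAIN) & (tipA != UNCERTAIN)
        hamming = int((inner_states[resolved] != tipA[resolved]).sum())
        rep = {c.child_id: c for c in summarize_evolution(anc)}
        assert rep["A"].gained + rep["A"].lost == hamming
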