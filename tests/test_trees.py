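"""Tree engine: ML distances (closed form + grid oracle), NJ (additive
recovery + independent skbio cross-check), bootstrap, rooting, ladderize,
import/export."""

import random

import dendropy
import numpy as np
import pytest


from metalphylo.trees import (AnnotatedTree, UndefinedDistanceError,
                              bipartition_support, bootstrap_support,
                              build_nj, distance_matrix, import_tree,
                              ladderize, ml_pairwise_distance, nj_tree,
                              rf_distance, root_with_outgroup,
                              serialize_tree)


def random_additive_tree(n_leaves, seed):
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        rng=random.Random(seed))
    for e in t.preorder_edge_iter():
        if e.length is None or e.length <= 0:
            e.length = 0.05 + random.Random(seed).random() * 0.2
    pdm = t.phylogenetic_distance_matrix()
    labels = [tx.label for tx in t.taxon_namespace]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.distance(t.taxon_namespace[i],
                                       t.taxon_namespace[j])
    return t, D, labels


class TestMlDistance:
    def test_identical_sequences_distance_zero(self, poisson):
        assert ml_pairwise_distance("ACDEFG", "ACDEFG", poisson) == 0.0

    def test_equal_rates_closed_form(self, poisson):
        """Under the 20-state equal-rates model the ML distance equals
        -(19/20) ln(1 - (20/19) p) for mismatch fraction p."""
        rng = np.random.default_rng(1)
        for p_target in (0.05, 0.2, 0.5):
            a = rng.integers(0, 20, 3000)
            b = a.copy()
            swap = rng.random(3000) < p_target
            b[swap] = (b[swap] + rng.integers(1, 20, swap.sum())) % 20
            p = float((a != b).mean())
            expected = -(19 / 20) * np.log(1 - (20 / 19) * p)
            got = ml_pairwise_distance(a, b, poisson)
            assert got == pytest.approx(expected, abs=1e-6)

    def test_optimum_matches_grid_search(self, lg):
        """The bounded optimiser lands within one step of a brute-force
        grid over t."""
        from metalphylo.trees import _loglik_from_counts, _pair_counts
        rng = np.random.default_rng(2)
        grid = np.arange(0.001, 2.0, 0.001)
        for _ in range(5):
            a = rng.integers(0, 20, 400)
            b = a.copy()
            swap = rng.random(400) < 0.25
            b[swap] = rng.integers(0, 20, swap.sum())
            counts = _pair_counts(a, b)
            lls = [_loglik_from_counts(counts, lg, t) for t in grid]
            t_grid = grid[int(np.argmax(lls))]
            t_opt = ml_pairwise_distance(a, b, lg)
            assert abs(t_opt - t_grid) <= 0.001 + 1e-9

    def test_no_shared_columns_raises(self, poisson):
        with pytest.raises(UndefinedDistanceError):
            ml_pairwise_distance("AC--", "--DE", poisson)

    def test_saturated_pair_capped_with_warning(self, poisson):
        a = np.arange(20).repeat(5)
        b = (a + 7) % 20           # every site mismatched
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.warns(UserWarning, match="saturated"):
                d = ml_pairwise_distance(a, b, poisson)
        assert d == 10.0

    def test_gap_columns_excluded_pairwise(self, poisson):
        d_full = ml_pairwise_distance("AAAAC", "AAAAA", poisson)
        d_gap = ml_pairwise_distance("AAAAC--", "AAAAA-C", poisson)
        assert d_gap == pytest.approx(d_full, abs=1e-9)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5 -> va=1, vb=2, vc=3
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        at = build_nj(D, labels=["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in at.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_matrix_exact_recovery(self):
        """NJ is consistent: additive matrices give back the generating
        topology (RF = 0) with near-exact branch lengths."""
        for seed in range(20):
            n = 6 + seed % 7
            true, D, labels = random_additive_tree(n, seed)
            at = build_nj(D, labels=labels)
            assert rf_distance(at, AnnotatedTree(true)) == 0

    def test_agrees_with_skbio_on_additive_input(self):
        """Independent cross-check: scikit-bio's NJ yields the same
        topology on additive input."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        _, D, labels = random_additive_tree(8, 99)
        ours = build_nj(D, labels=labels)
        theirs = skbio_nj(DistanceMatrix(D, ids=labels))
        t2 = import_tree(str(theirs).strip())
        assert rf_distance(ours, t2) == 0

    def test_tie_break_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        a = serialize_tree(build_nj(D, labels=list("dcba")))
        b = serialize_tree(build_nj(D, labels=list("dcba")))
        assert a == b

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            build_nj(np.array([[0, 1], [1, 0]]), labels=["a", "b"])
        bad = np.array([[0, 1, 2], [1, 0, np.nan], [2, np.nan, 0]])
        with pytest.raises(ValueError):
            build_nj(bad, labels=list("abc"))
        asym = np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]], float)
        with pytest.raises(ValueError):
            build_nj(asym, labels=list("abc"))

    def test_negative_branch_lengths_clamped(self):
        D = np.array([[0.0, 0.1, 0.4, 0.4],
                      [0.1, 0.0, 0.4, 0.4],
                      [0.4, 0.4, 0.0, 0.01],
                      [0.4, 0.4, 0.01, 0.0]])
        at = build_nj(D, labels=list("abcd"))
        for e in at.tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0


class TestDistanceMatrixPolicies:
    def test_impute_fills_disjoint_fragments(self, poisson):
        rows = [("full1", "AAAAACCCCC"), ("full2", "AAAAACCCCG"),
                ("fragN", "AAAAA-----"), ("fragC", "-----CCCCC")]
        with pytest.raises(UndefinedDistanceError):
            distance_matrix(rows, poisson)
        D, ids = distance_matrix(rows, poisson, on_undefined="impute")
        i, j = ids.index("fragN"), ids.index("fragC")
        assert np.isfinite(D[i, j])
        # imputed through a full-length row: d <= d(fragN,full)+d(full,fragC)
        k = ids.index("full1")
        assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


@pytest.fixture(scope="module")
def perfect_alignment():
    blocks = {"A": "AAAAACCCCC", "B": "AAAAACCCCG",
              "C": "CCCCCAAAAA", "D": "CCCCCAAAAG",
              "E": "GGGGGAAAAA"}
    return [(k, v * 30) for k, v in blocks.items()]


class TestBootstrap:

    def test_perfect_signal_full_support(self, perfect_alignment, poisson):
        at = bootstrap_support(perfect_alignment, poisson,
                               n_replicates=20, seed=3)
        sups = [nd.support for nd in
                at.tree.preorder_internal_node_iter() if nd.parent_node]
        assert sups and all(s == 100.0 for s in sups)
        assert at.support_kind == "bootstrap"

    def test_zero_replicates_flagged(self, perfect_alignment, poisson):
        at = bootstrap_support(perfect_alignment, poisson,
                               n_replicates=0, seed=3)
        sups = [nd.support for nd in
                at.tree.preorder_internal_node_iter() if nd.parent_node]
        assert all(s is None for s in sups)

    def test_seed_reproducible(self, perfect_alignment, poisson):
        a = bootstrap_support(perfect_alignment, poisson, 10, seed=7)
        b = bootstrap_support(perfect_alignment, poisson, 10, seed=7)
        assert serialize_tree(a) == serialize_tree(b)

    def test_supports_within_range(self, poisson, rng):
        from metalphylo.models import AMINO_ACIDS
        rows = [(f"t{i}", "".join(rng.choice(list(AMINO_ACIDS), size=60)))
                for i in range(5)]
        at = bootstrap_support(rows, poisson, 10, seed=1)
        for nd in at.tree.preorder_internal_node_iter():
            if nd.parent_node and nd.support is not None:
                assert 0.0 <= nd.support <= 100.0


class TestRooting:
    def test_single_taxon_outgroup(self):
        at = import_tree("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_with_outgroup(at, {"A"})
        assert rooted.rooted
        kids = rooted.tree.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"A"} in sides
        assert {"B", "C", "D"} in sides

    def test_clade_outgroup_both_sides_monophyletic(self):
        at = import_tree("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_with_outgroup(at, {"C", "D"})
        sides = [{lf.taxon.label for lf in k.leaf_iter()}
                 for k in rooted.tree.seed_node.child_nodes()]
        assert {"C", "D"} in sides and {"A", "B"} in sides

    def test_rooting_preserves_bipartitions(self):
        at = import_tree("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        before = rf_distance(at, root_with_outgroup(at, {"E"}))
        assert before == 0

    def test_non_monophyletic_outgroup_warns(self):
        at = import_tree("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.warns(UserWarning, match="not monophyletic"):
            rooted = root_with_outgroup(at, {"A", "B"})
        assert rooted.rooted

    def test_outgroup_covering_all_taxa_rejected(self):
        at = import_tree("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            root_with_outgroup(at, {"A", "B", "C"})

    def test_missing_outgroup_taxon_rejected(self):
        at = import_tree("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="absent"):
            root_with_outgroup(at, {"Z"})

    def test_synthetic_truth_ingroup_recovered(self, small_family, lg):
        """Rooting on the true outgroup subfamily separates exactly the
        generative ingroup."""
        _, records, truth = small_family
        at = nj_tree([(r.id, str(r.seq)) for r in records], lg)
        ib4 = set(truth.records[truth.records.subfamily == "IB-4"]
                  .sequence_id)
        rooted = root_with_outgroup(at, ib4)
        sides = [{lf.taxon.label for lf in k.leaf_iter()}
                 for k in rooted.tree.seed_node.child_nodes()]
        assert ib4 in sides


class TestLadderize:
    def test_idempotent(self):
        at = import_tree("((A:1,(B:1,C:1):1):1,(D:1,E:1):1);")
        once = serialize_tree(ladderize(at))
        twice = serialize_tree(ladderize(ladderize(at)))
        assert once == twice

    def test_topology_unchanged(self):
        at = import_tree("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        assert rf_distance(at, ladderize(at)) == 0

    def test_fixed_point_on_random_trees(self):
        for seed in range(10):
            t, _, _ = random_additive_tree(10, seed + 100)
            at = AnnotatedTree(t)
            once = serialize_tree(ladderize(at))
            assert serialize_tree(ladderize(ladderize(at))) == once


class TestImportExport:
    def test_pp_support_detected(self):
        at = import_tree("(A:1,(B:1,(C:1,D:1)0.82:1):1);")
        assert at.support_kind == "pp"
        sups = [nd.support for nd in
                at.tree.preorder_internal_node_iter()
                if nd.support is not None]
        assert 0.82 in sups

    def test_bootstrap_support_detected(self):
        at = import_tree("(A:1,(B:1,(C:1,D:1)97:1):1);")
        assert at.support_kind == "bootstrap"

    def test_roundtrip_preserves_bipartitions_and_lengths(self, tmp_path):
        src = "((A:0.5,B:0.25)0.9:0.1,(C:1,D:2)0.8:0.3,E:1);"
        at = import_tree(src)
        path = tmp_path / "t.nwk"
        serialize_tree(at, path)
        back = import_tree(str(path))
        assert rf_distance(at, back) == 0
        a_len = sorted(e.length for e in at.tree.preorder_edge_iter()
                       if e.length is not None)
        b_len = sorted(e.length for e in back.tree.preorder_edge_iter()
                       if e.length is not None)
        np.testing.assert_allclose(a_len, b_len, atol=1e-9)

    def test_nexus_translate_table_resolved(self, tmp_path):
        nexus = (
            "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=3;\n"
            "TAXLABELS Homo_sapiens Mus_musculus Danio_rerio;\nEND;\n"
            "BEGIN TREES;\nTRANSLATE\n1 Homo_sapiens,\n2 Mus_musculus,\n"
            "3 Danio_rerio;\nTREE t1 = ((1:1,2:1):1,3:2);\nEND;\n")
        p = tmp_path / "t.nex"
        p.write_text(nexus)
        at = import_tree(str(p), schema="nexus")
        assert set(at.leaf_labels()) == {"Homo sapiens", "Mus musculus",
                                         "Danio rerio"}

    def test_malformed_tree_raises_parse_error(self):
        with pytest.raises(ValueError, match="could not parse"):
            import_tree("((A:1,B:1;")


def test_bipartition_support_lookup(poisson):
    blocks = {"A": "AAAAACCCCC", "B": "AAAAACCCCG",
              "C": "CCCCCAAAAA", "D": "CCCCCAAAAG"}
    aln = [(k, v * 30) for k, v in blocks.items()]
    at = bootstrap_support(aln, poisson, 10, seed=2)
    assert bipartition_support(at, {"A", "B"}) == 100.0
    assert bipartition_support(at, {"A", "C"}) is None


def test_signal_concatenation_does_not_reduce_true_support(poisson):
    blocks = {"A": "AAAAACCCCC", "B": "AAAAACCCCG",
              "C": "CCCCCAAAAA", "D": "CCCCCAAAAG", "E": "GGGGGTTTTT"}
    weak = [(k, v * 3) for k, v in blocks.items()]
    strong = [(k, v * 6) for k, v in blocks.items()]
    s_weak = bipartition_support(
        bootstrap_support(weak, poisson, 20, seed=5), {"A", "B"})
    s_strong = bipartition_support(
        bootstrap_support(strong, poisson, 20, seed=5), {"A", "B"})
    assert s_strong is not None and s_weak is not None
    assert s_strong >= s_weak
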