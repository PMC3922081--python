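"""Specificity transfer, taxonomy, motif calls, collapsing, subgroups."""

import pandas as pd
import pytest

from metalphylo.annotate import (MotifCall, PanelRecord, ReferencePanel,
                                 TaxonomyTable, annotate_tree,
                                 assign_subgroups, best_hit_label,
                                 call_tm6_motif, classify_motif,
                                 collapse_clades, sw_bits)
from metalphylo.masking import MaskedAlignment
from metalphylo.simulate import mock_taxonomy, simulate_background
from metalphylo.trees import import_tree


@pytest.fixture(scope="module")
def panel():
    return ReferencePanel([
        PanelRecord("CopA_ref", "MKVCPCLLAVGHTTWQRNDEFYIKSMPLVAWDER",
                    "Me+", "IB-1"),
        PanelRecord("HMA4_ref", "MKVSPCLLAVGHSSWQRNDAAYIKSMPLVAWGGH",
                    "Me2+", "IB-2"),
    ])


class TestBestHitLabel:
    def test_identical_query_gets_self_labels(self, panel):
        spec, cls, bits = best_hit_label(
            "MKVCPCLLAVGHTTWQRNDEFYIKSMPLVAWDER", panel, min_score=20)
        assert (spec, cls) == ("Me+", "IB-1")
        assert bits > 20

    def test_two_substitutions_still_hit_nearest(self, panel):
        query = "MKVCPCLLAVGHTTWQRNDEFYIKSMPAVG"  # CopA_ref with 2 subs
        # independent oracle: direct local-alignment bit scores per record
        scores = {r.seq_id: sw_bits(query, r.sequence)[0] for r in panel}
        assert scores["CopA_ref"] > scores["HMA4_ref"]
        spec, cls, _ = best_hit_label(query, panel, min_score=20)
        assert (spec, cls) == ("Me+", "IB-1")

    def test_decoy_below_min_score_unassigned(self, panel):
        decoy = str(simulate_background(1, (30, 2), seed=77)[0].seq)
        spec, cls, bits = best_hit_label(decoy, panel, min_score=50)
        assert (spec, cls) == ("unassigned", "unassigned")
        assert bits < 50

    def test_tie_breaks_lexicographically(self):
        dup = ReferencePanel([
            PanelRecord("b_ref", "MKVCPCLLAVGH", "Me2+", "IB-2"),
            PanelRecord("a_ref", "MKVCPCLLAVGH", "Me+", "IB-1"),
        ])
        spec, cls, _ = best_hit_label("MKVCPCLLAVGH", dup, min_score=5)
        assert (spec, cls) == ("Me+", "IB-1")

    def test_panel_labels_required(self):
        with pytest.raises(ValueError):
            ReferencePanel([PanelRecord("x", "ACDE", "", "IB-1")])
        with pytest.raises(ValueError):
            ReferencePanel([PanelRecord("x", "ACDE", "Me+", "IB-1"),
                            PanelRecord("x", "ACDE", "Me+", "IB-1")])


def test_panel_fasta_roundtrip(tmp_path, panel):
    path = tmp_path / "panel.fasta"
    panel.write_fasta(path)
    back = ReferencePanel.from_fasta(path)
    assert [(r.seq_id, r.specificity, r.class_label) for r in back] == \
           [(r.seq_id, r.specificity, r.class_label) for r in panel]


class TestTaxonomy:
    def test_tsv_roundtrip_and_lineage(self, tmp_path):
        df = mock_taxonomy(["spA", "spB"])
        path = tmp_path / "tax.tsv"
        df.to_csv(path, sep="\t", index=False)
        tax = TaxonomyTable.from_tsv(path)
        lin = [tax.name_of(t) for t in tax.lineage(tax.id_of("spA"))]
        assert lin[0] == "root" and lin[-1] == "spA"
        assert "phylum" in tax.ranks()

    def test_ncbi_dump_format(self, tmp_path):
        nodes = ("1\t|\t1\t|\tno rank\t|\n"
                 "2\t|\t1\t|\tsuperkingdom\t|\n"
                 "9606\t|\t2\t|\tspecies\t|\n")
        names = ("1\t|\troot\t|\t\t|\tscientific name\t|\n"
                 "2\t|\tBacteria\t|\t\t|\tscientific name\t|\n"
                 "2\t|\teubacteria\t|\t\t|\tsynonym\t|\n"
                 "9606\t|\tHomo sapiens\t|\t\t|\tscientific name\t|\n")
        (tmp_path / "nodes.dmp").write_text(nodes)
        (tmp_path / "names.dmp").write_text(names)
        tax = TaxonomyTable.from_ncbi_dump(tmp_path / "nodes.dmp",
                                           tmp_path / "names.dmp")
        assert tax.name_of(9606) == "Homo sapiens"
        assert tax.ancestor_at_rank(9606, "superkingdom") == 2

    def test_multiple_roots_rejected(self):
        df = pd.DataFrame([
            dict(tax_id=1, parent_id=1, rank="root", name="r1"),
            dict(tax_id=2, parent_id=2, rank="root", name="r2"),
        ])
        with pytest.raises(ValueError, match="root"):
            TaxonomyTable(df)

    def test_lca(self):
        tax = TaxonomyTable(mock_taxonomy(["spA", "spB", "spC"], n_phyla=1))
        ids = [tax.id_of(s) for s in ("spA", "spB")]
        assert tax.name_of(tax.lca(ids)) == "Phylum1"


class TestMotifCalls:
    @pytest.fixture()
    def aln(self):
        #                      123456789
        return MaskedAlignment(
            ["ref", "spc", "apc", "cph", "gapd"],
            ["MKCPCWQRS", "MKSPCWQRS", "MKAPCWQRS", "MKCPHWQRS",
             "MK-P-WQRS"])

    def test_reference_anchored_trigram_reading(self, aln):
        calls = call_tm6_motif(aln, ("ref", [3, 4, 5]))
        assert calls["ref"].trigram == "CPC"
        assert calls["spc"].trigram == "SPC"
        assert calls["apc"].trigram == "APC"
        assert calls["cph"].trigram == "CPH"
        assert calls["gapd"].trigram == "unresolved"

    def test_motif_classes(self, aln):
        calls = call_tm6_motif(aln, ("ref", [3, 4, 5]))
        assert calls["ref"].motif_class == "CPx"
        assert calls["cph"].motif_class == "CPx"
        assert calls["spc"].motif_class == "SPC"
        assert calls["apc"].motif_class == "APC"
        assert calls["gapd"].motif_class == "other"
        assert classify_motif("GGG") == "other"

    def test_gapped_reference_columns_map_through(self):
        aln = MaskedAlignment(["ref", "x"], ["MK--CPCW", "MKAACPCW"])
        calls = call_tm6_motif(aln, ("ref", [3, 4, 5]))
        assert calls["ref"].columns == (5, 6, 7)
        assert calls["x"].trigram == "CPC"

    def test_reference_gapped_at_alignment_columns_rejected(self):
        aln = MaskedAlignment(["ref", "x"], ["MK-PCW", "MKAPCW"])
        with pytest.raises(ValueError, match="gapped"):
            call_tm6_motif(aln, ("ref", [3, 4, 5]), coords="alignment")

    def test_synthetic_truth_recovered_exactly(self, small_family):
        """With invariant motif columns, motif calls match the generative
        labels for every sequence."""
        cfg, records, truth = small_family
        aln = MaskedAlignment.from_records(records)
        ref = truth.records.sequence_id.iloc[0]
        start = int(truth.records.motif_start.iloc[0])
        calls = call_tm6_motif(aln, (ref, [start, start + 1, start + 2]))
        for _, row in truth.records.iterrows():
            assert calls[row.sequence_id].trigram == row.motif


class TestAnnotateAndCollapse:
    @pytest.fixture()
    def world(self):
        tax = TaxonomyTable(mock_taxonomy(["sp1", "sp2", "sp3", "sp4"],
                                          n_phyla=1))
        at = import_tree("((sp1_a:1,sp2_a:1):1,(sp3_a:1,sp4_a:1):1);")
        at.tree.is_rooted = True
        leaf_tax = {f"sp{i}_a": tax.id_of(f"sp{i}") for i in range(1, 5)}
        return tax, at, leaf_tax

    def test_lca_annotation_on_internal_nodes(self, world):
        tax, at, leaf_tax = world
        annotate_tree(at, tax, leaf_tax)
        names = [nd.taxon_name for nd in
                 at.tree.preorder_internal_node_iter()]
        assert "Phylum1" in names  # all species share the phylum

    def test_unmapped_leaf_warned_not_dropped(self, world):
        tax, at, leaf_tax = world
        leaf_tax = dict(leaf_tax)
        del leaf_tax["sp4_a"]
        with pytest.warns(UserWarning, match="sp4_a"):
            annotate_tree(at, tax, leaf_tax)
        assert len(at.leaf_labels()) == 4

    def test_collapse_uniform_genus_clade(self):
        tax = TaxonomyTable(mock_taxonomy(["sp1", "sp2"], n_phyla=1))
        at = import_tree("((sp1_a:1,sp1_b:1):1,(sp2_a:1,sp2_b:2):1);")
        at.tree.is_rooted = True
        leaf_tax = {"sp1_a": tax.id_of("sp1"), "sp1_b": tax.id_of("sp1"),
                    "sp2_a": tax.id_of("sp2"), "sp2_b": tax.id_of("sp2")}
        out = collapse_clades(at, tax, leaf_tax, "genus")
        labels = out.leaf_labels()
        assert sorted(labels) == ["Genus_sp1", "Genus_sp2"]
        counts = {lf.taxon.label: lf.n_collapsed
                  for lf in out.tree.leaf_node_iter()}
        assert counts == {"Genus_sp1": 2, "Genus_sp2": 2}
        # branch length carries the clade's maximum depth
        depths = {lf.taxon.label: lf.edge.length
                  for lf in out.tree.leaf_node_iter()}
        assert depths["Genus_sp2"] == pytest.approx(3.0)  # 1 (stem) + 2

    def test_paraphyletic_taxon_collapses_to_two_nodes(self):
        tax = TaxonomyTable(mock_taxonomy(["sp1", "sp2"], n_phyla=1))
        at = import_tree(
            "((sp1_a:1,sp1_b:1):1,((sp2_a:1,sp2_b:1):1,(sp1_c:1,sp1_d:1):1):1);")
        at.tree.is_rooted = True
        leaf_tax = {l: tax.id_of(l.split("_")[0])
                    for l in at.leaf_labels()}
        out = collapse_clades(at, tax, leaf_tax, "genus")
        names = out.leaf_labels()
        assert names.count("Genus_sp1") == 2
        assert names.count("Genus_sp2") == 1

    def test_collapse_at_absent_rank_rejected(self, world):
        tax, at, leaf_tax = world
        with pytest.raises(ValueError, match="rank"):
            collapse_clades(at, tax, leaf_tax, "tribe")

    def test_collapse_below_annotations_unchanged(self, world):
        tax, at, leaf_tax = world
        out = collapse_clades(at, tax, leaf_tax, "species")
        # every species occurs once, so single-leaf "clades" collapse to
        # themselves: leaf count is preserved
        assert len(out.leaf_labels()) == 4


class TestAssignSubgroups:
    def test_disjoint_anchor_clades(self):
        at = import_tree(
            "(((hma2:1,hma3:1):1,hma4:1):1,(hma1:1,(x1:1,x2:1):1):1);")
        at.tree.is_rooted = True
        res = assign_subgroups(at, {"IB-2": ["hma2", "hma3", "hma4"],
                                    "IB-4": ["hma1"]})
        assert res.assignments["hma2"] == "IB-2"
        assert res.assignments["hma1"] == "IB-4"
        # co-clade leaves of the single-anchor subgroup get its label
        assert res.assignments["x1"] == "IB-4"
        assert res.monophyletic == {"IB-2": True, "IB-4": True}

    def test_nested_clades_resolve_to_smallest(self):
        at = import_tree("(((a1:1,b1:1):1,a2:1):1,(c1:1,c2:1):1);")
        at.tree.is_rooted = True
        res = assign_subgroups(at, {"big": ["a1", "a2", "c1"],
                                    "small": ["b1"]})
        assert res.assignments["b1"] == "small"
        assert res.assignments["a2"] == "big"
        assert res.assignments["c2"] == "big"

    def test_anchors_always_assigned_home(self):
        at = import_tree("((a1:1,(b1:1,b2:1):1):1,(a2:1,a3:1):1);")
        at.tree.is_rooted = True
        res = assign_subgroups(at, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert res.assignments["a1"] == "A"
        assert res.monophyletic["A"] is False  # clade spans B's anchors

    def test_identical_anchor_clades_rejected(self):
        at = import_tree("((a1:1,b1:1):1,(c1:1,c2:1):1);")
        at.tree.is_rooted = True
        with pytest.raises(ValueError, match="indistinguishable"):
            assign_subgroups(at, {"X": ["a1", "c1"], "Y": ["b1", "c2"]})

    def test_overlapping_anchor_sets_rejected(self):
        at = import_tree("((a1:1,b1:1):1,c1:1);")
        with pytest.raises(ValueError, match="disjoint"):
            assign_subgroups(at, {"X": ["a1"], "Y": ["a1"]})

    def test_partition_is_disjoint_and_total(self):
        at = import_tree(
            "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(c1:1,c2:1):1);")
        at.tree.is_rooted = True
        res = assign_subgroups(at, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert set(res.assignments) == set(at.leaf_labels())
        frame = res.to_frame()
        assert len(frame) == len(at.leaf_labels())

    def test_synthetic_truth_full_recovery_at_low_divergence(
            self, small_family, lg):
        from metalphylo.trees import nj_tree, root_with_outgroup
        _, records, truth = small_family
        at = nj_tree([(r.id, str(r.seq)) for r in records], lg)
        true_sub = dict(zip(truth.records.sequence_id,
                            truth.records.subfamily))
        ib4_all = {s for s, g in true_sub.items() if g == "IB-4"}
        ib4 = sorted(ib4_all)[:2]
        ib2 = sorted(s for s, g in true_sub.items() if g == "IB-2")[:2]
        rooted = root_with_outgroup(at, ib4_all)
        res = assign_subgroups(rooted, {"IB-2": ib2, "IB-4": ib4})
        correct = sum(res.assignments[l] == true_sub[l]
                      for l in true_sub)
        assert correct == len(true_sub)
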