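"""Tree and sequence annotation: specificity transfer, taxonomy, motifs,
clade collapsing and subgroup assignment.

Substrate-specificity labels are transferred from a curated reference panel
by best local-alignment hit (exact Smith-Waterman, BLOSUM62, affine gaps
11/1 — the panel is small, so no heuristic search is needed).  The
metal-binding TM6 motif (CPx / SPC / APC trigram) is read at the homologous
alignment columns of a stated anchor protein rather than predicted from
membrane topology.  Subgroups (IB-1, chloroplast IB-1, IB-2, IB-4) are
assigned from a rooted tree as the smallest clades spanning each subgroup's
anchor proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIFICITY_LABELS = {"Me+", "Me2+", "Ca", "Na/K", "H", "Mg", "K-Kdp",
                      "flippase"}

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class PanelRecord:
    seq_id: str
    sequence: str
    specificity: str
    class_label: str
    organism: str = ""


@dataclass
class ReferencePanel:
    """Labeled reference proteins anchoring specificity transfer."""

    records: list[PanelRecord]

    def __post_init__(self):
        ids = [r.seq_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("panel sequence ids must be unique")
        for r in self.records:
            if not r.specificity or not r.class_label:
                raise ValueError(
                    f"panel record {r.seq_id!r} lacks a specificity or "
                    f"class label")

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @classmethod
    def from_fasta(cls, path) -> "ReferencePanel":
        """Read a panel FASTA with ``label=... class=...`` descriptions."""
        from Bio import SeqIO
        records = []
        for rec in SeqIO.parse(path, "fasta"):
            fields = dict(kv.split("=", 1) for kv in rec.description.split()
                          if "=" in kv)
            records.append(PanelRecord(rec.id, str(rec.seq),
                                       fields.get("label", ""),
                                       fields.get("class", ""),
                                       fields.get("organism", "")))
        return cls(records)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.seq_id} label={r.specificity} "
                         f"class={r.class_label}\n{r.sequence}\n")


_ALIGNER = None


def _local_aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align
        a = Align.PairwiseAligner()
        a.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        a.mode = "local"
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def sw_bits(query: str, subject: str) -> tuple[float, int]:
    """Smith-Waterman bit score and aligned query span length.

    Raw score S converts to bits with the Karlin-Altschul formula
    ``(lambda * S - ln K) / ln 2`` using the published gapped BLOSUM62
    (11/1) parameters.
    """
    aligner = _local_aligner()
    q = "".join(c for c in query.upper() if c.isalpha())
    s = "".join(c for c in subject.upper() if c.isalpha())
    alns = aligner.align(q, s)
    score = alns.score
    try:
        best = alns[0]
        qspan = int(best.aligned[0][-1][1] - best.aligned[0][0][0])
    except (IndexError, ValueError):
        qspan = 0
    bits = (_KA_LAMBDA * score - np.log(_KA_K)) / np.log(2.0)
    return float(bits), qspan


def best_hit_label(query, panel: ReferencePanel, min_score: float = 50.0):
    """Transfer the labels of the best-scoring panel record.

    Ties break by longer aligned span, then lexicographically smaller id.
    Returns ``(specificity, class_label, bits)``; below ``min_score`` the
    labels are ``("unassigned", "unassigned", bits)``.
    """
    if len(panel) == 0:
        raise ValueError("reference panel is empty")
    qseq = str(query.seq) if hasattr(query, "seq") else str(query)
    best = None
    for rec in panel:
        bits, span = sw_bits(qseq, rec.sequence)
        key = (-bits, -span, rec.seq_id)
        if best is None or key < best[0]:
            best = (key, rec, bits)
    _, rec, bits = best
    if bits < min_score:
        return "unassigned", "unassigned", bits
    return rec.specificity, rec.class_label, bits


@dataclass
class TaxonomyTable:
    """NCBI-like taxonomy: (tax_id, parent_id, rank, name) rows."""

    nodes: pd.DataFrame

    def __post_init__(self):
        df = self.nodes
        required = {"tax_id", "parent_id", "rank", "name"}
        if not required <= set(df.columns):
            raise ValueError(f"taxonomy table needs columns {sorted(required)}")
        self._parent = dict(zip(df.tax_id, df.parent_id))
        self._rank = dict(zip(df.tax_id, df["rank"]))
        self._name = dict(zip(df.tax_id, df["name"]))
        self._by_name = dict(zip(df["name"], df.tax_id))
        roots = [t for t, p in self._parent.items() if p == t or p == 0]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, "
                             f"found {len(roots)}")
        self.root = roots[0]
        for t in self._parent:
            if self.root not in self.lineage(t):
                raise ValueError(f"tax id {t} does not resolve to the root")

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t",
                         names=["tax_id", "parent_id", "rank", "name"],
                         header=None, comment="#")
        if str(df.iloc[0, 0]).strip() == "tax_id":  # header present
            df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df)

    @classmethod
    def from_ncbi_dump(cls, nodes_path, names_path) -> "TaxonomyTable":
        """Read NCBI-style nodes.dmp / names.dmp (scientific names)."""
        nodes = pd.read_csv(nodes_path, sep="|", header=None,
                            usecols=[0, 1, 2],
                            names=["tax_id", "parent_id", "rank"])
        for c in nodes.columns:
            if nodes[c].dtype == object:
                nodes[c] = nodes[c].str.strip()
        names = pd.read_csv(names_path, sep="|", header=None,
                            usecols=[0, 1, 3],
                            names=["tax_id", "name", "name_class"])
        for c in ("name", "name_class"):
            names[c] = names[c].str.strip()
        names = names[names.name_class == "scientific name"]
        df = nodes.merge(names[["tax_id", "name"]], on="tax_id")
        return cls(df)

    def lineage(self, tax_id) -> list:
        """Path root -> tax_id (inclusive)."""
        path = [tax_id]
        seen = {tax_id}
        while True:
            p = self._parent.get(path[-1])
            if p is None:
                raise KeyError(f"unknown tax id {path[-1]}")
            if p == path[-1] or p == 0:
                break
            if p in seen:
                raise ValueError(f"taxonomy cycle at tax id {p}")
            path.append(p)
            seen.add(p)
        return path[::-1]

    def name_of(self, tax_id) -> str:
        return self._name[tax_id]

    def rank_of(self, tax_id) -> str:
        return self._rank[tax_id]

    def id_of(self, name):
        return self._by_name[name]

    def ranks(self) -> set:
        return set(self._rank.values())

    def ancestor_at_rank(self, tax_id, rank):
        """Tax id of the ancestor at the given rank, or None."""
        for t in self.lineage(tax_id):
            if self._rank[t] == rank:
                return t
        return None

    def lca(self, tax_ids) -> int:
        """Lowest common ancestor of a set of tax ids."""
        paths = [self.lineage(t) for t in tax_ids]
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca


MOTIF_CLASSES = {"SPC": "SPC", "APC": "APC"}


def classify_motif(trigram: str) -> str:
    if trigram == "unresolved":
        return "other"
    if trigram.startswith("CP"):
        return "CPx"
    return MOTIF_CLASSES.get(trigram, "other")


@dataclass
class MotifCall:
    leaf_id: str
    trigram: str                  # 3 residues or "unresolved"
    columns: tuple[int, int, int] | None  # 1-based alignment columns
    motif_class: str = ""

    def __post_init__(self):
        if self.trigram != "unresolved" and len(self.trigram) != 3:
            raise ValueError("motif trigram must have 3 residues")
        if not self.motif_class:
            self.motif_class = classify_motif(self.trigram)


def call_tm6_motif(masked_alignment, reference_anchor,
                   coords: str = "ungapped") -> dict[str, MotifCall]:
    """Read the TM6 metal-binding trigram at reference-anchored columns.

    ``reference_anchor`` is ``(reference_leaf_id, motif_positions)`` with
    positions 1-based; with ``coords="ungapped"`` they refer to residues of
    the reference sequence and are mapped through its gap pattern, with
    ``coords="alignment"`` they are alignment columns directly.  Rows with
    a gap at any motif column are called "unresolved".
    """
    ref_id, positions = reference_anchor
    positions = list(positions)
    if len(positions) == 2:  # (start, implicit trigram)
        positions = [positions[0], positions[0] + 1, positions[0] + 2]
    ref_row = masked_alignment.row(ref_id)
    if coords == "ungapped":
        cols = []
        count = 0
        want = set(positions)
        for j, c in enumerate(ref_row):
            if c not in "-.":
                count += 1
                if count in want:
                    cols.append(j + 1)
        if len(cols) != len(positions):
            raise ValueError("motif positions exceed reference length")
    else:
        cols = positions
    for col in cols:
        if ref_row[col - 1] in "-.":
            raise ValueError(
                f"reference {ref_id!r} is gapped at motif column {col}")
    calls = {}
    for leaf_id, row in zip(masked_alignment.ids, masked_alignment.rows):
        chars = [row[c - 1] for c in cols]
        if any(c in "-." for c in chars):
            calls[leaf_id] = MotifCall(leaf_id, "unresolved", tuple(cols))
        else:
            calls[leaf_id] = MotifCall(leaf_id, "".join(chars).upper(),
                                       tuple(cols))
    return calls


def annotate_tree(atree, taxonomy: TaxonomyTable, leaf_tax_map: dict,
                  labels: dict | None = None,
                  motifs: dict | None = None):
    """Attach taxonomy / specificity / motif metadata to a tree (in place).

    Leaves carry their full lineage; each internal node is annotated with
    the name and rank of the lowest taxon shared by all its descendant
    leaves.  Unmapped leaves get taxon "unknown" with a warning, never a
    silent drop.
    """
    labels = labels or {}
    motifs = motifs or {}
    tree = atree.tree
    for leaf in tree.leaf_node_iter():
        lid = leaf.taxon.label
        tax = leaf_tax_map.get(lid)
        if tax is None:
            warnings.warn(f"leaf {lid!r} has no taxonomy mapping")
            leaf.tax_id = None
            leaf.lineage_names = ["unknown"]
        else:
            leaf.tax_id = tax
            leaf.lineage_names = [taxonomy.name_of(t)
                                  for t in taxonomy.lineage(tax)]
        lab = labels.get(lid)
        if lab is not None:
            leaf.specificity = lab[0] if isinstance(lab, tuple) else lab
            leaf.class_label = lab[1] if isinstance(lab, tuple) else None
        call = motifs.get(lid)
        if call is not None:
            leaf.motif = call.trigram
            leaf.motif_class = call.motif_class
    for nd in tree.postorder_internal_node_iter():
        tax_ids = [lf.tax_id for lf in nd.leaf_iter()]
        if any(t is None for t in tax_ids):
            nd.taxon_name = "unknown"
            nd.taxon_rank = None
            continue
        lca = taxonomy.lca(set(tax_ids))
        nd.taxon_name = taxonomy.name_of(lca)
        nd.taxon_rank = taxonomy.rank_of(lca)
    return atree


def collapse_clades(atree, taxonomy: TaxonomyTable, leaf_tax_map: dict,
                    rank: str):
    """Collapse maximal monophyletic same-taxon clades at a rank.

    Each collapsed clade becomes a pendant node named for the taxon,
    carrying the leaf count (``node.n_collapsed``) and the clade's maximum
    leaf depth as branch length.  Taxa that are not monophyletic yield one
    collapsed node per clade.  Leaves without an ancestor at the rank stay
    uncollapsed.
    """
    if rank not in taxonomy.ranks():
        raise ValueError(f"rank {rank!r} absent from taxonomy")
    out = atree.clone()
    tree = out.tree

    def rank_taxon(leaf):
        tax = leaf_tax_map.get(leaf.taxon.label)
        if tax is None:
            return None
        return taxonomy.ancestor_at_rank(tax, rank)

    # postorder: find maximal uniform clades
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd._rank_taxon = rank_taxon(nd)
            nd._uniform = nd._rank_taxon is not None
        else:
            kids = nd.child_nodes()
            taxa = {k._rank_taxon for k in kids}
            nd._uniform = (all(k._uniform for k in kids)
                           and len(taxa) == 1 and None not in taxa)
            nd._rank_taxon = taxa.pop() if len(taxa) == 1 else None

    def max_depth(node):
        if node.is_leaf():
            return 0.0
        return max((c.edge.length or 0.0) + max_depth(c)
                   for c in node.child_nodes())

    import dendropy
    for nd in list(tree.preorder_node_iter()):
        if nd.is_leaf() or not nd._uniform or nd.parent_node is None:
            continue
        if nd.parent_node._uniform:
            continue                     # not maximal
        leaves = list(nd.leaf_iter())
        name = taxonomy.name_of(nd._rank_taxon)
        depth = max_depth(nd)
        parent = nd.parent_node
        edge_len = nd.edge.length or 0.0
        parent.remove_child(nd)
        tip = dendropy.Node()
        tip.taxon = dendropy.Taxon(label=name)
        tip.edge.length = edge_len + depth
        tip.n_collapsed = len(leaves)
        tip.collapsed = True
        parent.add_child(tip)
    tree.update_taxon_namespace()
    for nd in tree.preorder_node_iter():
        for attr in ("_uniform", "_rank_taxon"):
            if hasattr(nd, attr):
                delattr(nd, attr)
    return out


@dataclass
class SubgroupAssignment:
    """Leaf -> subgroup partition anchored on reference proteins."""

    assignments: dict[str, str]            # leaf id -> subgroup | unassigned
    anchors: dict[str, set]                # subgroup -> anchor leaf ids
    clades: dict[str, set] = field(default_factory=dict)
    monophyletic: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()),
            columns=["leaf_id", "subgroup"])


def assign_subgroups(atree, anchors: dict[str, list]) -> SubgroupAssignment:
    """Assign every leaf to an anchor-defined subgroup clade.

    Each subgroup's clade starts as the smallest clade of the rooted tree
    containing all of that subgroup's anchor leaves, then grows to the
    largest enclosing clade that still excludes every other subgroup's
    anchors (so a single-anchor subgroup claims its whole surrounding
    clade).  Nested clades resolve to the smallest, anchors always stay
    with their own subgroup, and leaves outside every anchor clade are
    "unassigned".  A subgroup is reported monophyletic when its smallest
    anchor-spanning clade contains no other subgroup's anchors.
    """
    tree = atree.tree
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    anchor_sets = {sg: set(ids) for sg, ids in anchors.items()}
    all_anchors = [a for s in anchor_sets.values() for a in s]
    if len(all_anchors) != len(set(all_anchors)):
        raise ValueError("subgroup anchor sets must be disjoint")
    missing = set(all_anchors) - set(leaf_by_label)
    if missing:
        raise ValueError(f"anchor leaves absent from tree: {sorted(missing)}")

    clades = {}
    for sg, ids in anchor_sets.items():
        taxa = [leaf_by_label[i].taxon for i in ids]
        mrca = tree.mrca(taxa=taxa)
        others = {a for o, s in anchor_sets.items() if o != sg for a in s}
        spanning = {lf.taxon.label for lf in mrca.leaf_iter()}
        if not (spanning & others):
            # grow while no foreign anchor enters the clade
            node = mrca
            while node.parent_node is not None:
                parent_leaves = {lf.taxon.label
                                 for lf in node.parent_node.leaf_iter()}
                if parent_leaves & others:
                    break
                node = node.parent_node
                spanning = parent_leaves
        clades[sg] = spanning
    seen = {}
    for sg, cl in clades.items():
        key = frozenset(cl)
        if key in seen:
            raise ValueError(
                f"subgroups {seen[key]!r} and {sg!r} resolve to the same "
                f"clade; indistinguishable anchors")
        seen[key] = sg

    order = sorted(clades, key=lambda sg: (len(clades[sg]), sg))
    assignments = {}
    for lf in leaf_by_label:
        assignments[lf] = "unassigned"
        for sg in order:                   # smallest clade wins
            if lf in clades[sg]:
                assignments[lf] = sg
                break
    for sg, ids in anchor_sets.items():
        for a in ids:
            assignments[a] = sg            # anchors stay home
    monophyletic = {}
    for sg in clades:
        others = {a for o, s in anchor_sets.items() if o != sg for a in s}
        monophyletic[sg] = not (clades[sg] & others)
    return SubgroupAssignment(assignments, anchor_sets, clades,
                              monophyletic)
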