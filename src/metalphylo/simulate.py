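"""Synthetic gene families with known truth.

Generates protein superfamilies on a species tree: subfamilies descend from a
duplicated ancestral gene (each with its own clade-specific transmembrane
motif, e.g. CPC vs SPC vs APC), gene copies are born and lost by a
continuous-time birth--death walk down the species tree, and sequences evolve
site-wise under an empirical amino-acid model with discrete-gamma rates.
Decoy (background) proteins and fragmentary, error-prone EST reads complete
the picture, so that every downstream stage of the pipeline can be verified
against generative truth without any external download.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (SubstitutionModel, aa_to_codes, codes_to_aa,
                     get_model)

# fixed offsets deriving stage-local RNG streams from the one global seed
_SEED_OFFSET_FAMILY = 11
_SEED_OFFSET_BACKGROUND = 211
_SEED_OFFSET_EST = 311
_SEED_OFFSET_CODON = 411


@dataclass
class SimConfig:
    """Configuration of one synthetic superfamily.

    Parameters
    ----------
    species_tree
        Newick string (or ``dendropy.Tree``) with branch lengths in expected
        substitutions per site; leaf labels are species ids.
    duplication_rate, loss_rate
        Birth--death event rates per gene lineage per unit branch length.
    root_sequence_length
        Length of the ancestral protein, in residues (no indels are
        simulated, so all family members share this length).
    motif_spec
        Mapping subfamily label -> invariant 3-residue motif written at the
        anchor column (e.g. ``{"IB-1": "CPC", "IB-4": "SPC"}``); one
        subfamily root gene is created per entry.
    motif_anchor
        1-based column of the first motif residue.
    substitution_model_id
        ``"LG"`` or ``"Poisson"``.
    gamma_shape
        Discrete-gamma (+G4) shape for across-site rate variation.
    subfamily_stem_length
        Branch length separating each subfamily root from the superfamily
        ancestor (the ancient-duplication stems) when no explicit
        ``subfamily_tree`` is given.
    subfamily_tree
        Optional Newick over the subfamily labels describing the ancient
        duplication history (e.g. separating the monovalent- from the
        divalent-metal pump ancestor before the within-class
        duplications); defaults to a star with ``subfamily_stem_length``
        stems.
    forced_root_duplication
        Subfamily labels that start with two gene copies at the species-tree
        root (a nested ancient duplication, like the paired chloroplast
        copper pumps of green plants).
    """

    species_tree: str | dendropy.Tree
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    root_sequence_length: int = 300
    motif_spec: dict[str, str] = field(default_factory=lambda: {"IB-1": "CPC"})
    motif_anchor: int = 150
    substitution_model_id: str = "LG"
    gamma_shape: float | None = 1.0
    subfamily_stem_length: float = 0.4
    subfamily_tree: str | None = None
    forced_root_duplication: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("duplication and loss rates must be >= 0")
        if not 1 <= self.motif_anchor <= self.root_sequence_length - 2:
            raise ValueError(
                "motif anchor must lie within [1, root_sequence_length - 2]"
            )
        labels = list(self.motif_spec)
        if len(labels) != len(set(labels)):
            raise ValueError("subfamily labels must be distinct")
        for label, motif in self.motif_spec.items():
            if len(motif) != 3:
                raise ValueError(f"motif for {label!r} must have 3 residues")

    def tree(self) -> dendropy.Tree:
        if isinstance(self.species_tree, dendropy.Tree):
            return self.species_tree
        return dendropy.Tree.get(data=self.species_tree, schema="newick")

    def model(self) -> SubstitutionModel:
        return get_model(self.substitution_model_id, self.gamma_shape)


@dataclass
class FamilyTruth:
    """Generative ground truth for one simulated family."""

    gene_tree: dendropy.Tree | None
    records: pd.DataFrame  # sequence_id, species_id, subfamily, motif, motif_start
    empty: bool = False

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def motif_of(self, sequence_id: str) -> str:
        row = self.records.loc[self.records.sequence_id == sequence_id]
        return row.motif.iloc[0]


class _GeneLineage:
    __slots__ = ("codes", "copy_id")

    def __init__(self, codes, copy_id):
        self.codes = codes
        self.copy_id = copy_id


def _evolve(codes: np.ndarray, t: float, model: SubstitutionModel,
            categories: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence for time t, sites pre-assigned to categories."""
    if t <= 0:
        return codes.copy()
    out = codes.copy()
    P = model.transition_matrices(t)
    for c in range(P.shape[0]):
        sites = np.nonzero(categories == c)[0]
        if sites.size == 0:
            continue
        probs = P[c][codes[sites]]
        u = rng.random(sites.size)
        out[sites] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.minimum(out, 19)


def simulate_family(config: SimConfig):
    """Simulate one superfamily; returns ``(records, truth)``.

    Duplication/loss events are Poisson along each species-tree branch per
    surviving gene lineage.  The true gene tree joins the per-subfamily gene
    trees through stem branches at a superfamily root.  If every lineage is
    lost the result is an explicit empty family (``truth.empty``), not an
    exception.
    """
    rng = np.random.default_rng(config.seed + _SEED_OFFSET_FAMILY)
    model = config.model()
    L = config.root_sequence_length
    categories = rng.integers(0, len(model.rates), size=L)
    root_codes = rng.choice(20, size=L, p=model.frequencies)
    species_tree = config.tree()

    truth_rows = []
    fasta_records = []
    subfamily_subtrees: dict[str, dendropy.Node] = {}
    anchor0 = config.motif_anchor - 1

    # ancient-duplication history over subfamilies: evolve the superfamily
    # root sequence down the guide tree to obtain each subfamily's root
    if config.subfamily_tree is not None:
        guide = dendropy.Tree.get(data=config.subfamily_tree,
                                  schema="newick")
        guide_labels = {lf.taxon.label for lf in guide.leaf_node_iter()}
        if guide_labels != set(config.motif_spec):
            raise ValueError("subfamily_tree leaves must match motif_spec "
                             "labels")
    else:
        star = ",".join(f"{lab}:{config.subfamily_stem_length:g}"
                        for lab in config.motif_spec)
        guide = dendropy.Tree.get(data=f"({star});", schema="newick")
    sub_roots: dict[str, tuple[np.ndarray, float]] = {}

    def walk_guide(node, codes):
        for child in node.child_nodes():
            blen = child.edge.length or 0.0
            child_codes = _evolve(codes, blen, model, categories, rng)
            if child.is_leaf():
                sub_roots[child.taxon.label] = (child_codes, blen)
            else:
                walk_guide(child, child_codes)

    walk_guide(guide.seed_node, root_codes)

    for label, motif in config.motif_spec.items():
        sub_root_codes, stem_len = sub_roots[label]
        n_start = 2 if label in config.forced_root_duplication else 1
        counter = [0]

        def new_node(edge_length=0.0, event=None):
            nd = dendropy.Node()
            nd.edge.length = edge_length
            if event:
                nd.annotations.add_new("event", event)
            return nd

        sub_root = new_node(stem_len,
                            "duplication" if n_start == 2 else None)
        # state walked down the species tree: list of (lineage, gene-tree node)
        start = []
        for _ in range(n_start):
            counter[0] += 1
            gn = new_node(0.0)
            sub_root.add_child(gn)
            start.append((_GeneLineage(sub_root_codes, counter[0]), gn))
        if n_start == 1:
            # avoid a superfluous unifurcation under the subfamily root
            sub_root.clear_child_nodes()
            start = [(start[0][0], sub_root)]

        def walk_branch(lineage, gnode, blen):
            """Evolve one gene lineage along a species branch; may branch/die.

            Returns list of (lineage, gene node) surviving at the bottom.
            """
            total = config.duplication_rate + config.loss_rate
            survivors = [(lineage, gnode, 0.0)]  # (lin, node, time consumed)
            out = []
            while survivors:
                lin, nd, used = survivors.pop()
                left = blen - used
                if total > 0:
                    wait = rng.exponential(1.0 / total)
                else:
                    wait = np.inf
                if wait >= left:
                    codes = _evolve(lin.codes, left, model, categories, rng)
                    nd.edge.length = (nd.edge.length or 0.0) + left
                    out.append((_GeneLineage(codes, lin.copy_id), nd))
                    continue
                codes = _evolve(lin.codes, wait, model, categories, rng)
                nd.edge.length = (nd.edge.length or 0.0) + wait
                if rng.random() < config.duplication_rate / total:
                    # the current node becomes the duplication node
                    nd.annotations.add_new("event", "duplication")
                    for _ in range(2):
                        counter[0] += 1
                        child = new_node(0.0)
                        nd.add_child(child)
                        survivors.append(
                            (_GeneLineage(codes, counter[0]), child,
                             used + wait))
                else:
                    nd.annotations.add_new("event", "loss")
                    # lineage dies; node pruned later
            return out

        def descend(state, snode):
            """Recurse over the species tree; state = surviving lineages."""
            results = []
            if snode.is_leaf():
                return [(lin, gn, snode.taxon.label) for lin, gn in state]
            for child in snode.child_nodes():
                blen = child.edge.length or 0.0
                child_state = []
                for lin, gn in state:
                    # each lineage continues independently into the child;
                    # speciation copies the lineage into each child
                    counter[0] += 1
                    branch_node = new_node(0.0)
                    gn.add_child(branch_node)
                    child_state.extend(
                        walk_branch(_GeneLineage(lin.codes, counter[0]),
                                    branch_node, blen))
                results.extend(descend(child_state, child))
            return results

        leaves = descend(start, species_tree.seed_node)

        motif_codes = aa_to_codes(motif)
        copy_counts: dict[str, int] = {}
        for lin, gnode, species in leaves:
            codes = lin.codes.copy()
            codes[anchor0:anchor0 + 3] = motif_codes
            copy_counts[species] = copy_counts.get(species, 0) + 1
            seq_id = f"{species}|{label}|g{copy_counts[species]}"
            gnode.taxon = dendropy.Taxon(label=seq_id)
            fasta_records.append(
                SeqRecord(Seq(codes_to_aa(codes)), id=seq_id,
                          description=f"subfamily={label} species={species}"))
            truth_rows.append(dict(sequence_id=seq_id, species_id=species,
                                   subfamily=label, motif=motif,
                                   motif_start=config.motif_anchor))
        subfamily_subtrees[label] = sub_root

    columns = ["sequence_id", "species_id", "subfamily", "motif",
               "motif_start"]
    records_df = pd.DataFrame(truth_rows, columns=columns)
    if records_df.empty:
        return [], FamilyTruth(None, records_df, empty=True)

    # mirror the guide tree's internal structure; subfamily subtrees hang
    # at its leaf positions, internal guide nodes are ancient duplications
    def assemble(gnode):
        if gnode.is_leaf():
            return subfamily_subtrees[gnode.taxon.label]
        nd = dendropy.Node()
        nd.edge.length = gnode.edge.length
        nd.annotations.add_new("event", "duplication")
        for child in gnode.child_nodes():
            nd.add_child(assemble(child))
        return nd

    root = assemble(guide.seed_node)
    ns = dendropy.TaxonNamespace()
    gene_tree = dendropy.Tree(seed_node=root, taxon_namespace=ns)
    _prune_dead(gene_tree)
    gene_tree.update_taxon_namespace()
    return fasta_records, FamilyTruth(gene_tree, records_df)


def _prune_dead(tree: dendropy.Tree) -> None:
    """Remove lost lineages and suppress the resulting unifurcations."""
    changed = True
    while changed:
        changed = False
        for nd in tree.seed_node.postorder_iter():
            if nd is tree.seed_node:
                continue
            if nd.is_leaf() and nd.taxon is None:
                nd.parent_node.remove_child(nd)
                changed = True
    tree.suppress_unifurcations()


def simulate_background(n: int, length_distribution=(350.0, 80.0),
                        residue_frequencies=None, seed: int = 0):
    """Draw ``n`` i.i.d. decoy proteins (non-family background).

    Lengths are normal (clipped at 10); residues i.i.d. from
    ``residue_frequencies`` (default: LG stationary frequencies).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if residue_frequencies is None:
        residue_frequencies = get_model("LG").frequencies
    freqs = np.asarray(residue_frequencies, float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("residue frequencies must sum to 1 within 1e-9")
    rng = np.random.default_rng(seed + _SEED_OFFSET_BACKGROUND)
    mean, sd = length_distribution
    records = []
    for i in range(n):
        length = max(10, int(round(rng.normal(mean, sd))))
        codes = rng.choice(20, size=length, p=freqs)
        records.append(SeqRecord(Seq(codes_to_aa(codes)), id=f"decoy{i:05d}",
                                 description="background"))
    return records


_CODONS_BY_AA: dict[str, list[str]] = {}


def _codon_table():
    if not _CODONS_BY_AA:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS_BY_AA.setdefault(aa, []).append(codon)
        for aa in _CODONS_BY_AA:
            _CODONS_BY_AA[aa].sort()
    return _CODONS_BY_AA


def back_translate(protein: str, seed: int = 0) -> str:
    """Back-translate with uniform synonymous codon choice (no codon bias)."""
    rng = np.random.default_rng(seed + _SEED_OFFSET_CODON)
    table = _codon_table()
    codons = []
    for aa in protein:
        choices = table.get(aa)
        if choices is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons)


def fragment_to_ests(gene_cds, mean_fragments_per_gene: float = 3.0,
                     fragment_length_distribution=(300.0, 60.0),
                     error_rate: float = 0.01, seed: int = 0):
    """Shred CDSs into sense-strand EST fragments with point errors.

    Returns ``(fragments, truth)`` where truth maps each fragment to its
    source gene, reading frame (+1/+2/+3 relative to the CDS) and 1-based
    coordinates.  Fragments longer than their source are truncated and
    flagged.
    """
    rng = np.random.default_rng(seed + _SEED_OFFSET_EST)
    mean_len, sd_len = fragment_length_distribution
    nts = "ACGT"
    fragments, rows = [], []
    k = 0
    for rec in gene_cds:
        cds = str(rec.seq).upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length of {rec.id!r} is not a multiple of 3")
        n_frag = rng.poisson(mean_fragments_per_gene)
        for _ in range(n_frag):
            length = max(30, int(round(rng.normal(mean_len, sd_len))))
            truncated = False
            if length >= len(cds):
                length, truncated = len(cds), length > len(cds)
                start = 0
            else:
                start = int(rng.integers(0, len(cds) - length + 1))
            frag = list(cds[start:start + length])
            n_err = 0
            if error_rate > 0:
                hit = np.nonzero(rng.random(length) < error_rate)[0]
                for pos in hit:
                    alts = [c for c in nts if c != frag[pos]]
                    frag[pos] = alts[rng.integers(3)]
                    n_err += 1
            frag_id = f"est{k:05d}"
            k += 1
            fragments.append(SeqRecord(Seq("".join(frag)), id=frag_id,
                                       description=f"source={rec.id}"))
            rows.append(dict(fragment_id=frag_id, source_gene=rec.id,
                             frame=(3 - start % 3) % 3 + 1, start=start + 1,
                             end=start + length, n_errors=n_err,
                             truncated=truncated))
    truth = pd.DataFrame(rows, columns=["fragment_id", "source_gene", "frame",
                                        "start", "end", "n_errors",
                                        "truncated"])
    return fragments, truth


def balanced_species_tree(n_species: int = 8, depth: float = 0.3,
                          prefix: str = "sp") -> str:
    """A balanced ultrametric species tree in Newick, labels sp1..spN."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    labels = [f"{prefix}{i + 1}" for i in range(n_species)]

    def build(lo, hi, d):
        if hi - lo == 1:
            return f"{labels[lo]}:{d:g}"
        mid = (lo + hi + 1) // 2
        half = d / 2
        return f"({build(lo, mid, half)},{build(mid, hi, half)}):{half:g}"

    mid = (n_species + 1) // 2
    half = depth / 2
    return f"({build(0, mid, half)},{build(mid, n_species, half)});"


def mock_taxonomy(species: list[str], n_phyla: int = 2) -> pd.DataFrame:
    """A small NCBI-like taxonomy: root / domain / phylum / genus / species.

    Species are dealt round-robin into ``n_phyla`` phyla split between a mock
    prokaryote and a mock eukaryote domain; each species gets its own genus.
    """
    rows = [dict(tax_id=1, parent_id=1, rank="root", name="root")]
    doms = ["Prokaryota", "Eukaryota"]
    for d, name in enumerate(doms):
        rows.append(dict(tax_id=2 + d, parent_id=1, rank="domain", name=name))
    for p in range(n_phyla):
        rows.append(dict(tax_id=10 + p, parent_id=2 + (p % 2),
                         rank="phylum", name=f"Phylum{p + 1}"))
    for i, sp in enumerate(species):
        phylum = 10 + (i % n_phyla)
        rows.append(dict(tax_id=100 + i, parent_id=phylum, rank="genus",
                         name=f"Genus_{sp}"))
        rows.append(dict(tax_id=1000 + i, parent_id=100 + i, rank="species",
                         name=sp))
    return pd.DataFrame(rows)


def write_fasta(records, path) -> None:
    from Bio import SeqIO
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def records_to_fasta_str(records) -> str:
    from Bio import SeqIO
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
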