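"""Pipeline recipes tying the stages together, with full provenance.

Two end-to-end recipes mirror the two halves of a superfamily study:

* the *prokaryote* recipe — profile search over whole proteomes, empirical
  E-value threshold detection, masking, a distance tree, architecture
  assignment and a per-genome census;
* the *metal-subtree* recipe — a single metal-pump superfamily with four
  subgroups, optional EST fragment integration, bootstrap support for the
  monovalent/divalent split, subgroup assignment, motif calls and TM-region
  logos.

Without input files both recipes run on synthetic data whose generative
truth is returned alongside the results, so recovery can be measured.  All
stages communicate through documented file formats when an output directory
is given, and every written file embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import est as est_mod
from . import masking as msk
from . import profile_hmm as ph
from . import simulate as sim
from . import trees as trm
from .census import (census as census_table, cooccurrence, extract_region,
                     logo as logo_matrix, taxonomic_breakdown)
from .models import get_model

METAL_MOTIFS = {"IB-1": "CPC", "IB-1-chloroplast": "CPC",
                "IB-2": "CPC", "IB-4": "SPC"}
METAL_SUBFAMILY_TREE = ("((IB-1:0.25,IB-1-chloroplast:0.25):0.2,"
                        "(IB-2:0.25,IB-4:0.25):0.2);")
ME_PLUS = ("IB-1", "IB-1-chloroplast")
ME_2PLUS = ("IB-2", "IB-4")

ARCHITECTURES = {"AI": "CPC", "AII": "DKT", "AIII": "GES"}
PROK_SUBFAMILY_TREE = "((AI:0.25,AII:0.25):0.15,AIII:0.4);"


@dataclass
class PipelineConfig:
    """Declarative parameters of one pipeline run (1:1 with YAML keys).

    The synthetic-generator defaults define the study conditions every
    stage is verified under; see the methods note for the rationale behind
    each value.
    """

    seed: int = 0
    # synthetic world
    n_species: int = 6
    species_depth: float = 0.3
    duplication_rate: float = 0.1
    loss_rate: float = 0.05
    root_sequence_length: int = 300
    motif_anchor: int = 150
    gamma_shape: float = 1.0
    model: str = "LG"
    decoys_per_genome: int = 12
    background_length: tuple = (300.0, 50.0)
    # homolog search
    calibration_decoys: int = 500
    occupancy_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    min_gap_orders: float = 3.0
    # masking / trees
    mask_preset: str = "medium"
    bootstrap_replicates: int = 100
    anchors_per_subgroup: int = 2
    # EST stage (metal recipe)
    est: bool = False
    est_mean_fragments: float = 2.0
    est_fragment_length: tuple = (300.0, 60.0)
    est_error_rate: float = 0.01
    est_min_match_states: int = 50
    est_min_bits: float = 15.0
    est_decoy_genes: int = 3
    # optional real inputs (override synthetic generation when given)
    proteome_files: dict | None = None
    seed_alignment_file: str | None = None
    taxonomy_file: str | None = None
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for name in ("proteome_files", "seed_alignment_file",
                     "taxonomy_file"):
            val = getattr(cfg, name)
            paths = (val.values() if isinstance(val, dict)
                     else [val] if val else [])
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        return cfg

    def to_yaml(self, path=None) -> str:
        txt = yaml.safe_dump(asdict(self), sort_keys=True)
        if path:
            Path(path).write_text(txt)
        return txt

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RecipeResult:
    config: PipelineConfig
    truth: sim.FamilyTruth | None
    taxonomy: ann.TaxonomyTable | None
    tree: trm.AnnotatedTree | None
    assignment: ann.SubgroupAssignment | None
    census_matrix: pd.DataFrame | None
    metrics: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)


def _provenance(config: PipelineConfig, recipe: str) -> str:
    return (f"# metalphylo {recipe} seed={config.seed} "
            f"config={config.config_hash}\n")


def _write_table(df: pd.DataFrame, path: Path, config, recipe,
                 index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config, recipe))
        df.to_csv(fh, sep="\t", index=index)


def _species_world(config: PipelineConfig):
    species = [f"sp{i + 1}" for i in range(config.n_species)]
    tree = sim.balanced_species_tree(config.n_species, config.species_depth)
    if config.taxonomy_file:
        taxonomy = ann.TaxonomyTable.from_tsv(config.taxonomy_file)
    else:
        taxonomy = ann.TaxonomyTable(sim.mock_taxonomy(species))
    tax_map = {sp: taxonomy.id_of(sp) for sp in species}
    return species, tree, taxonomy, tax_map


def _pick_anchors(truth: sim.FamilyTruth, present: set, per_subgroup: int):
    anchors = {}
    for sg, grp in truth.records.groupby("subfamily"):
        ids = sorted(set(grp.sequence_id) & present)
        if not ids:
            raise StageError("anchors", f"no anchor available for {sg!r}")
        anchors[sg] = ids[:per_subgroup]
    return anchors


def _log_stage(log, stage, t0, **info):
    log.append(dict(stage=stage, seconds=round(time.time() - t0, 3), **info))


def run_prokaryote_recipe(config: PipelineConfig) -> RecipeResult:
    """Search -> threshold -> mask -> tree -> architectures -> census."""
    log: list[dict] = []
    t0 = time.time()
    if config.proteome_files is not None and not config.proteome_files:
        raise StageError("input", "no input proteomes given")
    species, sp_tree, taxonomy, tax_map = _species_world(config)
    model = get_model(config.model, config.gamma_shape)

    # synthetic superfamily: one subfamily per architecture
    simcfg = sim.SimConfig(
        species_tree=sp_tree, duplication_rate=config.duplication_rate,
        loss_rate=config.loss_rate,
        root_sequence_length=config.root_sequence_length,
        motif_spec=dict(ARCHITECTURES), motif_anchor=config.motif_anchor,
        substitution_model_id=config.model, gamma_shape=config.gamma_shape,
        subfamily_tree=PROK_SUBFAMILY_TREE, seed=config.seed)
    family, truth = sim.simulate_family(simcfg)
    if truth.empty:
        raise StageError("simulate", "all gene lineages were lost")
    _log_stage(log, "simulate", t0, n_family=len(family))

    # proteomes = family members + per-genome decoys
    t0 = time.time()
    decoys = sim.simulate_background(
        config.decoys_per_genome * len(species),
        tuple(config.background_length), seed=config.seed + 1)
    proteomes = {sp: [] for sp in species}
    for rec in family:
        proteomes[rec.id.split("|")[0]].append(rec)
    for i, rec in enumerate(decoys):
        sp = species[i % len(species)]
        rec.id = f"{sp}|{rec.id}"
        proteomes[sp].append(rec)
    db_size = sum(len(v) for v in proteomes.values())

    # seed alignment: the family members of every other genome (a curated
    # subset standing in for the reference alignment of the search stage)
    if config.seed_alignment_file:
        seed_aln = msk.MaskedAlignment.read(config.seed_alignment_file)
    else:
        seed_ids = {r.id for r in family
                    if int(r.id.split("|")[0][2:]) % 2 == 1}
        seed_aln = msk.MaskedAlignment.from_records(
            [r for r in family if r.id in seed_ids])
    profile = ph.build_profile(seed_aln, config.occupancy_threshold,
                               config.pseudocount_weight, name="prokaryote")
    cal_decoys = sim.simulate_background(
        config.calibration_decoys, tuple(config.background_length),
        seed=config.seed + 2)
    ph.calibrate_evalues(profile, cal_decoys, database_size=db_size,
                         min_decoys=min(500, config.calibration_decoys))
    _log_stage(log, "profile", t0, match_states=profile.match_state_count)

    t0 = time.time()
    hits_all = ph.screen_proteomes(profile, proteomes,
                                   evalue_cutoff=float("inf"))
    brk = ph.detect_threshold_break(hits_all, config.min_gap_orders)
    if brk is None:
        raise StageError("threshold", "no E-value breakdown found")
    threshold, gap = brk
    hits = hits_all[hits_all.evalue <= threshold].reset_index(drop=True)
    _log_stage(log, "screen", t0, n_hits=len(hits),
               threshold=float(threshold))

    # mask: family sequences are indel-free, so insertion filtering is a
    # no-op and block selection trims poorly conserved stretches
    t0 = time.time()
    seq_of = {rec.id: str(rec.seq) for sp in proteomes
              for rec in proteomes[sp]}
    aln = msk.MaskedAlignment(list(hits.seq_id),
                              [seq_of[i] for i in hits.seq_id])
    aln = msk.drop_insertion_columns(aln)
    aln = msk.select_blocks(aln, config.mask_preset)
    aln = msk.drop_partial_sequences(aln)
    _log_stage(log, "mask", t0, kept_columns=len(aln.kept_columns))

    t0 = time.time()
    tree = trm.nj_tree(aln, model)
    anchors = _pick_anchors(truth, set(aln.ids), config.anchors_per_subgroup)
    # root between AIII and the (AI, AII) pair, the deepest split of the
    # architecture history; using AI+AII anchors keeps AIII intact
    rooted = trm.root_with_outgroup(
        tree, set(anchors["AI"]) | set(anchors["AII"]))
    rooted = trm.ladderize(rooted)
    assignment = ann.assign_subgroups(rooted, anchors)
    leaf_tax = {lid: tax_map[lid.split("|")[0]] for lid in aln.ids}
    ann.annotate_tree(rooted, taxonomy, leaf_tax)
    _log_stage(log, "tree", t0, n_leaves=len(aln.ids))

    t0 = time.time()
    assigned = {l: s for l, s in assignment.assignments.items()}
    genome_map = {l: l.split("|")[0] for l in assigned}
    matrix = census_table(assigned, genome_map,
                        categories=list(ARCHITECTURES), genomes=species)
    venn = cooccurrence(matrix, list(ARCHITECTURES))
    breakdown = taxonomic_breakdown(matrix, taxonomy, tax_map, "phylum")
    _log_stage(log, "census", t0)

    # recovery metrics against generative truth
    true_sub = dict(zip(truth.records.sequence_id, truth.records.subfamily))
    family_ids = set(true_sub)
    hit_ids = set(hits.seq_id)
    monophyly = {}
    for arch in ARCHITECTURES:
        leaves = {l for l in aln.ids if true_sub.get(l) == arch}
        monophyly[arch] = (trm.bipartition_support(rooted, leaves)
                           is not None or _is_clade(rooted, leaves))
    correct = sum(assigned.get(l) == true_sub.get(l) for l in aln.ids)
    metrics = dict(
        threshold=float(threshold), gap_orders=float(gap),
        n_hits=len(hits),
        family_recall=len(hit_ids & family_ids) / len(family_ids),
        decoy_hits=len(hit_ids - family_ids),
        architecture_monophyly=monophyly,
        assignment_accuracy=correct / len(aln.ids),
        match_states=profile.match_state_count,
        seed_alignment_length=seed_aln.width,
    )

    result = RecipeResult(config, truth, taxonomy, rooted, assignment,
                          matrix, metrics,
                          dict(profile=profile, hits=hits, masked=aln,
                               venn=venn, breakdown=breakdown, log=log))
    if config.outdir:
        _write_prok_outputs(result)
    return result


def _is_clade(atree: trm.AnnotatedTree, leaves: set) -> bool:
    if not leaves:
        return False
    tree = atree.tree
    taxa = [lf.taxon for lf in tree.leaf_node_iter()
            if lf.taxon.label in leaves]
    if len(taxa) == 1:
        return True
    mrca = tree.mrca(taxa=taxa)
    return {lf.taxon.label for lf in mrca.leaf_iter()} == leaves


def _write_prok_outputs(result: RecipeResult) -> None:
    cfg = result.config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    recipe = "prokaryote"
    ph.write_profile(result.artifacts["profile"], out / "profile.txt")
    _write_table(result.artifacts["hits"], out / "hits.tsv", cfg, recipe)
    _write_table(result.artifacts["masked"].mask_table(), out / "mask.tsv",
                 cfg, recipe)
    result.artifacts["masked"].write(out / "alignment.masked.fasta",
                                     kept_only=True)
    with open(out / "tree.nwk", "w") as fh:
        fh.write(_provenance(cfg, recipe))
        fh.write(result.tree.as_newick())
    _write_table(result.census_matrix, out / "census.tsv", cfg, recipe,
                 index=True)
    _write_table(pd.DataFrame(sorted(result.artifacts["venn"].items()),
                              columns=["region", "n_genomes"]),
                 out / "venn.tsv", cfg, recipe)
    _write_table(result.artifacts["breakdown"], out / "breakdown.tsv",
                 cfg, recipe)
    _write_table(result.assignment.to_frame(), out / "subgroups.tsv",
                 cfg, recipe)
    truth_df = result.truth.records if result.truth else pd.DataFrame()
    _write_table(truth_df, out / "truth.tsv", cfg, recipe)
    (out / "run_log.json").write_text(
        json.dumps(dict(seed=cfg.seed, config=cfg.config_hash,
                        recipe=recipe, metrics=_jsonable(result.metrics),
                        stages=result.artifacts["log"]), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_metal_subtree_recipe(config: PipelineConfig) -> RecipeResult:
    """Metal superfamily: (EST ->) mask -> tree+bootstrap -> root ->
    subgroups -> motifs -> collapse -> census -> logos."""
    log: list[dict] = []
    t0 = time.time()
    species, sp_tree, taxonomy, tax_map = _species_world(config)
    model = get_model(config.model, config.gamma_shape)
    simcfg = sim.SimConfig(
        species_tree=sp_tree, duplication_rate=config.duplication_rate,
        loss_rate=config.loss_rate,
        root_sequence_length=config.root_sequence_length,
        motif_spec=dict(METAL_MOTIFS), motif_anchor=config.motif_anchor,
        substitution_model_id=config.model, gamma_shape=config.gamma_shape,
        subfamily_tree=METAL_SUBFAMILY_TREE,
        forced_root_duplication=("IB-1-chloroplast",), seed=config.seed)
    family, truth = sim.simulate_family(simcfg)
    if truth.empty:
        raise StageError("simulate", "all gene lineages were lost")
    family_aln = msk.MaskedAlignment.from_records(family)
    anchors = _pick_anchors(truth, set(family_aln.ids),
                            config.anchors_per_subgroup)
    missing = [a for sg in anchors.values() for a in sg
               if a not in set(family_aln.ids)]
    if missing:
        raise StageError("anchors", f"anchor ids missing from hits: "
                                    f"{missing}")
    _log_stage(log, "simulate", t0, n_family=len(family))

    # EST stage: shred family CDSs plus decoy CDSs, recruit against the
    # family profile, merge per organism, control orthology, insert
    est_report = None
    contig_truth = {}
    aug_aln = None
    if config.est:
        t0 = time.time()
        profile = ph.build_profile(family_aln, config.occupancy_threshold,
                                   config.pseudocount_weight, name="metal")
        cal = sim.simulate_background(
            config.calibration_decoys, tuple(config.background_length),
            seed=config.seed + 2)
        ph.calibrate_evalues(profile, cal,
                             min_decoys=min(500, config.calibration_decoys))
        gene_of = dict(zip(truth.records.sequence_id,
                           truth.records.subfamily))
        cds = [type(family[0])(
                   seq=type(family[0].seq)(
                       sim.back_translate(str(r.seq),
                                          seed=config.seed + 3 + i)),
                   id=r.id, description="")
               for i, r in enumerate(family)]
        frags, frag_truth = sim.fragment_to_ests(
            cds, config.est_mean_fragments,
            tuple(config.est_fragment_length), config.est_error_rate,
            seed=config.seed + 4)
        decoy_prot = sim.simulate_background(
            config.est_decoy_genes, (config.root_sequence_length, 1.0),
            seed=config.seed + 5)
        decoy_cds = [type(family[0])(
                         seq=type(family[0].seq)(
                             sim.back_translate(str(r.seq),
                                                seed=config.seed + 6 + i)),
                         id=f"decoy|{r.id}", description="")
                     for i, r in enumerate(decoy_prot)]
        dfrags, dtruth = sim.fragment_to_ests(
            decoy_cds, config.est_mean_fragments,
            tuple(config.est_fragment_length), config.est_error_rate,
            seed=config.seed + 7)
        dtruth = dtruth.assign(
            fragment_id=["d" + f for f in dtruth.fragment_id])
        for f in dfrags:
            f.id = "d" + f.id
        source_of = dict(zip(frag_truth.fragment_id,
                             frag_truth.source_gene))
        source_of.update(zip(dtruth.fragment_id, dtruth.source_gene))

        placed = []
        for frag in list(frags) + list(dfrags):
            org = source_of[frag.id].split("|")[0]
            placed.append(est_mod.recruit_fragment(
                profile, frag, config.est_min_bits,
                config.est_min_match_states, organism_id=org))
        by_org: dict[str, list] = {}
        for p in placed:
            if p.recruited:
                by_org.setdefault(p.organism_id, []).append(p)
        contigs = []
        for org in sorted(by_org):
            contigs.extend(est_mod.merge_gene_fragments(by_org[org]))

        panels = {sg: [r for r in family
                       if gene_of[r.id] == sg][:3]
                  for sg in METAL_MOTIFS}
        aug_aln = family_aln
        inserted = []
        for contig in contigs:
            members = contig.fragment_id.split("+")
            sources = {source_of[m] for m in members}
            subfams = {gene_of.get(s) for s in sources}
            best_sg = max(panels, key=lambda sg: max(
                ann.sw_bits(contig.peptide.replace("-", ""),
                            str(r.seq))[0] for r in panels[sg]))
            others = [r for sg in panels if sg != best_sg
                      for r in panels[sg]]
            verdict = est_mod.orthology_filter(contig, panels[best_sg],
                                               others)
            if verdict == "ortholog":
                aug_aln = est_mod.insert_into_alignment(aug_aln, contig,
                                                        profile)
                inserted.append(contig)
                contig_truth[contig.fragment_id] = (
                    subfams.pop() if len(subfams) == 1 else "mixed")
        est_report = est_mod.fragment_report(placed)
        _log_stage(log, "est", t0, n_fragments=len(placed),
                   n_contigs=len(contigs), n_inserted=len(inserted))

    # masking cascade; the loose preset tolerates fragment gap columns
    t0 = time.time()
    masked = msk.drop_insertion_columns(family_aln)
    masked = msk.select_blocks(masked, config.mask_preset)
    masked = msk.drop_partial_sequences(masked)
    aug_masked = None
    if aug_aln is not None:
        aug_masked = msk.drop_insertion_columns(aug_aln)
        aug_masked = msk.select_blocks(aug_masked, "loose")
    _log_stage(log, "mask", t0, kept_columns=len(masked.kept_columns))

    t0 = time.time()
    btree = trm.bootstrap_support(masked, model,
                                  config.bootstrap_replicates,
                                  seed=config.seed + 8)
    # root on the deepest split (monovalent vs divalent pumps); anchors of
    # the two divalent subgroups span exactly the Me2+ side
    rooted = trm.root_with_outgroup(
        btree, set(anchors["IB-2"]) | set(anchors["IB-4"]))
    rooted = trm.ladderize(rooted)
    assignment = ann.assign_subgroups(rooted, anchors)
    _log_stage(log, "tree", t0, n_leaves=len(masked.ids))

    aug_assignment = None
    aug_tree = None
    if aug_masked is not None:
        t0 = time.time()
        aug_tree = trm.nj_tree(aug_masked, model, on_undefined="impute",
                               min_shared_columns=30)
        aug_rooted = trm.root_with_outgroup(
            aug_tree, set(anchors["IB-2"]) | set(anchors["IB-4"]))
        aug_assignment = ann.assign_subgroups(aug_rooted, anchors)
        aug_tree = aug_rooted
        _log_stage(log, "est-tree", t0, n_leaves=len(aug_masked.ids))

    # motif calls anchored on the first monovalent-pump reference
    t0 = time.time()
    ref_id = anchors["IB-1"][0]
    motif_start = int(truth.records.set_index("sequence_id")
                      .loc[ref_id, "motif_start"])
    calls = ann.call_tm6_motif(family_aln,
                               (ref_id, [motif_start, motif_start + 1,
                                         motif_start + 2]))
    leaf_tax = {lid: tax_map[lid.split("|")[0]] for lid in masked.ids}
    labels = {lid: ("Me+" if assignment.assignments[lid] in ME_PLUS
                    else "Me2+", assignment.assignments[lid])
              for lid in masked.ids
              if assignment.assignments[lid] != "unassigned"}
    ann.annotate_tree(rooted, taxonomy, leaf_tax, labels, calls)
    collapsed = ann.collapse_clades(rooted, taxonomy, leaf_tax, "genus")
    _log_stage(log, "annotate", t0)

    # census + TM6 logos (region around the motif, reference numbering)
    t0 = time.time()
    assigned = dict(assignment.assignments)
    genome_map = {l: l.split("|")[0] for l in assigned}
    matrix = census_table(assigned, genome_map,
                        categories=list(METAL_MOTIFS), genomes=species)
    venn = cooccurrence(matrix, ["IB-2", "IB-4"])
    breakdown = taxonomic_breakdown(matrix, taxonomy, tax_map,
                                        "phylum")
    lo = max(1, motif_start - 5)
    hi = min(config.root_sequence_length, motif_start + 7)
    region = extract_region(family_aln, ref_id, (lo, hi))
    logos = {}
    for sg in METAL_MOTIFS:
        ids = [l for l, s in assigned.items() if s == sg]
        if not ids:
            continue
        sub = msk.MaskedAlignment(
            ids, [region.rows[region.ids.index(i)] for i in ids])
        sub.column_labels = region.column_labels
        logos[sg] = logo_matrix(sub)
    _log_stage(log, "census", t0)

    # recovery metrics
    true_sub = dict(zip(truth.records.sequence_id, truth.records.subfamily))
    correct = sum(assigned[l] == true_sub[l] for l in masked.ids)
    me_leaves = {l for l in masked.ids if true_sub[l] in ME_PLUS}
    me_support = trm.bipartition_support(rooted, me_leaves)
    motif_ok = sum(calls[l].trigram == truth.motif_of(l)
                   for l in family_aln.ids)
    metrics = dict(
        n_family=len(family),
        assignment_accuracy=correct / len(masked.ids),
        me_split_bootstrap=me_support,
        motif_call_accuracy=motif_ok / len(family_aln.ids),
        subgroup_monophyly=assignment.monophyletic,
        bootstrap_dropped=btree.n_bootstrap_dropped,
    )
    if aug_assignment is not None:
        n_contig = len(contig_truth)
        placed_ok = sum(
            aug_assignment.assignments.get(cid) == sub
            for cid, sub in contig_truth.items() if sub != "mixed")
        n_scored = sum(1 for s in contig_truth.values() if s != "mixed")
        metrics.update(
            n_contigs_inserted=n_contig,
            contig_placement_accuracy=(placed_ok / n_scored
                                       if n_scored else None),
            decoy_contigs_inserted=sum(
                1 for cid in contig_truth if cid.startswith("dest")),
        )

    result = RecipeResult(config, truth, taxonomy, rooted, assignment,
                          matrix, metrics,
                          dict(masked=masked, venn=venn,
                               breakdown=breakdown, logos=logos,
                               motif_calls=calls, collapsed=collapsed,
                               est_report=est_report,
                               aug_tree=aug_tree,
                               aug_masked=aug_masked,
                               aug_assignment=aug_assignment,
                               contig_truth=contig_truth, log=log))
    if config.outdir:
        _write_metal_outputs(result)
    return result


def _write_metal_outputs(result: RecipeResult) -> None:
    cfg = result.config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    recipe = "metal-subtree"
    with open(out / "tree.nwk", "w") as fh:
        fh.write(_provenance(cfg, recipe))
        fh.write(result.tree.as_newick())
    with open(out / "tree.collapsed.nwk", "w") as fh:
        fh.write(_provenance(cfg, recipe))
        fh.write(result.artifacts["collapsed"].as_newick())
    _write_table(result.assignment.to_frame(), out / "subgroups.tsv",
                 cfg, recipe)
    motif_df = pd.DataFrame(
        [dict(leaf_id=c.leaf_id, trigram=c.trigram,
              motif_class=c.motif_class)
         for c in result.artifacts["motif_calls"].values()])
    _write_table(motif_df, out / "motifs.tsv", cfg, recipe)
    _write_table(result.census_matrix, out / "census.tsv", cfg, recipe,
                 index=True)
    _write_table(pd.DataFrame(sorted(result.artifacts["venn"].items()),
                              columns=["region", "n_genomes"]),
                 out / "venn.tsv", cfg, recipe)
    _write_table(result.artifacts["breakdown"], out / "breakdown.tsv",
                 cfg, recipe)
    for sg, lg in result.artifacts["logos"].items():
        _write_table(lg, out / f"logo.{sg}.tsv", cfg, recipe, index=True)
    if result.artifacts["est_report"] is not None:
        _write_table(result.artifacts["est_report"], out / "est_report.tsv",
                     cfg, recipe)
    truth_df = result.truth.records if result.truth else pd.DataFrame()
    _write_table(truth_df, out / "truth.tsv", cfg, recipe)
    (out / "run_log.json").write_text(
        json.dumps(dict(seed=cfg.seed, config=cfg.config_hash,
                        recipe=recipe, metrics=_jsonable(result.metrics),
                        stages=result.artifacts["log"]), indent=2))
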