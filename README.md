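# metalphylo

Phylogenomic classification of protein superfamilies, built around the
workflow used to resolve **metal P-type ATPases** — the membrane pumps
that export Cu⁺/Ag⁺ (monovalent, Me⁺) and Zn²⁺/Cd²⁺/Pb²⁺ (divalent,
Me²⁺) cations — into subgroups of distinct evolutionary origin
(IB-1, chloroplast IB-1, IB-2, IB-4). It is written for molecular
evolutionists who need a reproducible, scriptable version of the
classic superfamily pipeline:

1. **Homolog retrieval** — a profile HMM built from a seed alignment
   (columns with ≥ 50% residue occupancy become match states), scored in
   unihit local mode; E-values from a maximum-likelihood Gumbel fit to
   decoy bit scores, `E(s) = n·P(S ≥ s)`; and an *empirical threshold
   detector* that finds the largest gap in sorted log₁₀ E-values — the
   "breakdown" separating a tight family from background ATP-binding
   proteins.
2. **Alignment masking** — the 50%-insertion-column rule, Gblocks-style
   conserved-block selection with loose/medium/strict presets, and
   removal of sequences > 50% missing.
3. **Tree inference** — maximum-likelihood pairwise distances under
   LG (+Γ₄) or the 20-state equal-rates model, neighbor joining with
   deterministic tie-breaking, 100-replicate nonparametric bootstrap,
   outgroup rooting and ladderization; external ML/Bayesian trees import
   from Newick/NEXUS with supports auto-tagged (posterior probability vs
   bootstrap).
4. **Annotation** — substrate-specificity transfer by best
   Smith–Waterman hit against a labeled reference panel, NCBI-style
   taxonomy annotation with clade collapsing, the TM6 metal-binding
   trigram (CPx vs SPC vs APC) read at reference-anchored alignment
   columns, and subgroup assignment from anchor-spanning clades.
5. **EST integration** — six-frame translation, recruitment of
   fragments against the calibrated family profile, column-space contig
   merging, an orthology score-margin filter, and insertion into the
   alignment without touching existing rows.
6. **Census** — per-genome presence/absence matrices, co-occurrence
   (Venn) regions, taxonomic breakdowns, and sequence-logo matrices for
   the transmembrane metal-binding regions.

A first-class **synthetic-data generator** simulates superfamilies on a
species tree (ancient duplications over a subfamily guide tree,
birth–death gene duplication/loss, site-wise LG+Γ₄ evolution, invariant
clade-specific motifs, error-prone EST fragments) so that every stage is
tested against generative truth — no downloads required. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Run the full metal-subfamily recipe on synthetic data (four subfamilies
with motifs CPC/CPC/CPC/SPC, a nested duplication in the chloroplast
Me⁺ subfamily, 100 bootstrap replicates):

```bash
metalphylo run --recipe metal-subtree --seed 11 --outdir out/
```

which prints the recovery metrics of the run:

```json
{
  "n_family": 30,
  "assignment_accuracy": 1.0,
  "me_split_bootstrap": 100.0,
  "motif_call_accuracy": 1.0,
  "subgroup_monophyly": {
    "IB-1": true,
    "IB-1-chloroplast": true,
    "IB-2": true,
    "IB-4": true
  },
  "bootstrap_dropped": 0
}
```

Reading this: the simulated family had 30 members; every leaf was
assigned to its true subgroup by the anchor-clade rule
(`assignment_accuracy` 1.0); the bipartition separating monovalent from
divalent pumps appeared in 100% of bootstrap replicates
(`me_split_bootstrap`); every TM6 motif call (CPC vs SPC) matched the
generative label; and all four subgroups were recovered as monophyletic
clades. `out/` contains the rooted annotated tree (`tree.nwk`), the
genus-collapsed tree, subgroup and motif tables, the per-genome census
with Venn and phylum breakdowns, per-subgroup TM6 logo matrices, and a
`run_log.json` with per-stage wall times — every file carries a
provenance header with the seed and config hash, and reruns are
byte-identical.

The same works in Python:

```python
from metalphylo import PipelineConfig, run_metal_subtree_recipe
result = run_metal_subtree_recipe(PipelineConfig(seed=11))
print(result.metrics["assignment_accuracy"])
result.assignment.to_frame()          # leaf -> subgroup table
result.artifacts["logos"]["IB-4"]     # TM6 logo matrix (frequencies)
```

Individual stages are plain functions (`build_profile`,
`detect_threshold_break`, `select_blocks`, `nj_tree`,
`assign_subgroups`, `recruit_fragment`, `census`, ...) and have matching
CLI subcommands (`metalphylo search|mask|tree|census ...`).

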