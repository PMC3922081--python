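# Methods

`metalphylo` implements a complete desk-scale pipeline for resolving a
protein superfamily — modelled on the metal-transporting P-type ATPases —
into subgroups of distinct evolutionary origin, together with a
synthetic-data generator that makes every stage verifiable against known
truth. This note documents the models, the numerical choices, and the
limits of what the synthetic tests demonstrate.

## Homolog retrieval: profile HMM and E-values

A profile HMM is estimated from a seed alignment. A column becomes a match
state when its residue occupancy is at least the `occupancy_threshold`
(default 0.5, exposed as a parameter): this is why a profile always has
fewer match states than a gappy seed alignment has columns. Match
emissions are residue counts smoothed with background-proportional
pseudocounts of total weight `pseudocount_weight` (default 1.0);
transition probabilities are counted from each row's implied
match/insert/delete path with one pseudo-observation per allowed
transition (Plan7 topology: no I–D or D–I transitions; inserts after a
deletion fold into D→M).

Scoring is unihit local, in the style of modern profile-search tools:

- N and C flank states emit from the background with a self-loop
  probability of `n/(n+2)` for a target of length `n`, so flank emissions
  cancel against the null and only transitions cost;
- entry into match state *k* has probability proportional to `L−k+1` and
  exit from match state *j* is `1/(L−j+1)`, which makes every
  (entry, exit) match interval equally likely a priori;
- a small B→D1 mass (one extra "entry cell", `1/(1+L(L+1)/2)`) keeps the
  all-delete path defined, so even an empty query has a finite score;
- the null model is an i.i.d. background sequence with a length-conditioned
  geometric transition (`n/(n+1)` self-loop).

Bit scores are log-odds against this null. Forward and Viterbi
dynamic programs are exact for this architecture: the test suite checks
them against brute-force enumeration of every state path on small
profiles to 1e-9 bits. Ambiguity codes (B, Z, J, X, U, O and `*` from
translated stops) score as background-weighted averages over their member
residues, so real proteomes never crash the scanner. Deliberately out of
scope: HMMER's MSV/bias composition filters, multihit mode, and DNA
profiles.

E-values come from a maximum-likelihood Gumbel fit
(`scipy.stats.gumbel_r`) to decoy Viterbi bit scores:
`E(s) = n_db · P(S ≥ s)`. Calibration requires at least 500 decoys and
fails loudly on degenerate score variance.

The operational "breakdown" threshold is the largest gap in consecutive
sorted log10 E-values of a screen; if it spans at least `min_gap_orders`
(default 3 decades) the threshold is the geometric midpoint of the
flanking E-values. Zero E-values are clamped to the smallest positive
float; gap ties resolve toward the smaller (more stringent) threshold.
This formalises the empirical practice of cutting a hit list at a visible
E-value discontinuity; no published algorithm exists for it, so the rule
and its default are this package's own.

## Alignment masking

Three filters, applied in order, each returning a `MaskedAlignment` with
per-column provenance in original coordinates (1-based):

1. **Insertion columns**: a column with residues in *less than* 50% of
   the sequences is discarded; exactly 50% is kept (the strict reading of
   "less than half", kept as a documented switch via
   `occupancy_threshold`). Idempotent.
2. **Block selection** (Gblocks-style): a column is *nonconserved* unless
   its most frequent residue occurs in more than `min_conserved_fraction`
   of the sequences (gaps never count toward the numerator; the per-preset
   gap rule can disqualify a column outright), and *highly conserved* at
   `min_flank_fraction`. Runs of more than `max_contiguous_nonconserved`
   nonconserved columns are removed, remaining regions are trimmed inward
   to highly-conserved flanks, and blocks shorter than `min_block_length`
   are dropped. The presets are:

   | preset | conserved | flank | max NC run | min block | gaps |
   |--------|-----------|-------|------------|-----------|------|
   | loose  | 0.5       | 0.5   | 10         | 5         | ≤ half |
   | medium | 0.5       | 0.85  | 8          | 10        | none |
   | strict | 0.5       | 0.90  | 4          | 15        | none |

   The qualitative names are not defined numerically anywhere
   authoritative; these values follow the reference program's documented
   parameter families and were chosen so the kept-column sets nest
   (strict ⊆ medium ⊆ loose), which the tests verify on random
   alignments.
3. **Partial sequences**: rows with *more than* `missing_threshold`
   (default 50%) missing characters relative to the most residue-rich row
   are removed (strict inequality: exactly 50% missing is kept).

A basic progressive aligner is included as a fallback only (guide tree
from 3-mer distances + NJ, midpoint-rooted; profile–profile global
alignment with BLOSUM62 and affine gaps 10/1, first gap residue costing
the full opening penalty). Production alignments are expected to come
from a dedicated aligner and be imported; the fallback exists so the
pipeline is self-contained and is validated against a full
dynamic-programming oracle on pairs.

## Tree inference

The in-house engine is maximum-likelihood pairwise distances + neighbor
joining. Full ML/Bayesian topology search is intentionally not
re-implemented; externally computed trees import from Newick/NEXUS with
supports auto-tagged (all values ≤ 1 → posterior probabilities, else
bootstrap percentages).

- **Distances**: likelihood of an aligned pair under a reversible
  amino-acid model (LG or the 20-state equal-rates "Poisson" model) with
  optional discrete-gamma heterogeneity (k = 4 equal-probability
  categories, category rates by the mean-of-quantile-interval rule),
  maximised over t ∈ (0, 10] by bounded scalar optimisation
  (`xatol` 1e-9). Gap columns are deleted pairwise. Identical sequences
  return exactly 0; pairs at the bound are capped at t_max = 10 with a
  warning. In the equal-rates limit the optimum matches the closed form
  −(19/20)·ln(1 − (20/19)p) to 1e-6, which the tests assert.
- **NJ**: canonical Saitou–Nei with Studier–Keppler updates, negative
  branch lengths clamped to 0, and Q-criterion ties broken toward the
  pair whose smallest member labels sort lexicographically lowest —
  full determinism at no cost. Exact recovery on additive matrices is the
  acceptance check; `skbio.tree.nj` is the independent cross-check.
- **Bootstrap**: columns resampled with replacement; replicate r draws
  its RNG from `seed + r`, so supports are reproducible and replicates
  independent. Support = percentage of kept replicates containing each
  internal bipartition of the point tree; replicates hitting an undefined
  distance are dropped and counted.
- **Fragment-bearing matrices**: when translated EST contigs are in the
  alignment, two short contigs may share few or no columns. Distances for
  pairs sharing fewer than `min_shared_columns` (the recipe uses 30) are
  treated as missing and completed by the shortest additive path through
  a third taxon, `min_k (d_ik + d_kj)` — sparse overlaps concentrated on
  conserved columns otherwise underestimate divergence and cluster
  unrelated fragments ("fragment attraction"). `ml_pairwise_distance`
  itself still raises on disjoint rows.
- **Rooting** places the root on the branch subtending the smallest clade
  containing all outgroup taxa, splitting its length evenly; a
  non-monophyletic outgroup falls back to the branch maximising
  outgroup/ingroup separation, with a warning. Ladderization sorts
  children by descendant count with lexicographic tie-breaks and is a
  fixed point.

## Annotation, motifs and subgroups

Substrate-specificity labels transfer from a small curated reference
panel by best local alignment — exact Smith–Waterman (BLOSUM62, gaps
11/1, via Biopython's `PairwiseAligner`), converted to bits with the
published gapped Karlin–Altschul parameters (λ = 0.267, K = 0.041). Ties
break by longer aligned span, then smaller id. Queries below `min_score`
(default 50 bits) stay "unassigned".

The TM6 metal-binding trigram (CPC/CPH/CPS → class CPx; SPC; APC) is read
at the three alignment columns homologous to a stated anchor protein's
motif (positions given in the anchor's own ungapped numbering), not
predicted from membrane topology — transmembrane prediction is out of
scope, and anchored columns are exact whenever the alignment is. Rows
gapped at any motif column are "unresolved".

Subgroup assignment is anchored on reference proteins: each subgroup's
clade starts as the smallest rooted clade spanning its anchors and grows
to the largest enclosing clade that excludes every other subgroup's
anchors. The growth step is what lets a single-anchor subgroup claim its
surrounding clade; without it the "clade" would be the anchor leaf
itself. Leaves inside nested clades go to the smallest; anchors always
stay with their own subgroup; a subgroup is monophyletic when its
*spanning* clade contains no foreign anchors. Clade collapsing replaces
every maximal same-taxon clade at the chosen rank by one pendant node
carrying the leaf count, with the clade's maximum leaf depth added to its
branch length; non-monophyletic taxa simply yield several collapsed nodes
with the same name.

## EST integration

Fragments are translated in all six frames; the best-scoring frame is
recruited against the calibrated family profile. Thresholds formalise
what is otherwise manual curation: `min_bits` 15 (decoy fragments score
near 0), `min_match_states` 50 ("too partial to place" — a judgment
call, roughly a sixth of the family core), and at most 2% stops/unknowns
inside the matched region. Contig assembly happens in alignment-column
space after recruitment (deterministic, no read-overlap heuristics):
fragments of one organism merge when their match-state intervals overlap
by ≥ 10 columns with ≤ 5% disagreement, consensus by recruitment score;
disagreeing overlaps stay separate as putative paralogs. Orthology is a
score-margin rule: "ortholog" iff the best local-alignment score against
the ortholog panel beats the paralog panel by ≥ 5 bits. Insertion writes
residues at the matched seed-alignment columns only; existing rows and
the column mask are untouched (checked bytewise in tests), and
insert-state residues are dropped with their count logged.

## Synthetic data: what it emulates and what it does not

The generator is the package's ground-truth instrument, not a demo. One
superfamily is simulated as: an ancestral protein (stationary draw from
the model), evolved down a *subfamily guide tree* whose internal nodes
are the ancient duplications (for the metal recipe:
`((IB-1, IB-1-chloroplast), (IB-2, IB-4))` with 0.25 stems and a 0.2
internal branch, so the monovalent/divalent split is a real bipartition
with its own branch); each subfamily root then descends the species tree
under a birth–death walk (duplication/loss events Poisson per unit branch
length per lineage), and sequences evolve site-wise under LG (+Γ4 via
matrix exponentials of the eigendecomposed generator). Clade-specific
motifs are enforced post hoc by overwriting the three anchor columns in
every member — the simplest way to make truth labels exact. EST reads
are back-translated CDSs (uniform synonymous codons) shredded into
sense-strand fragments with uniform offsets and i.i.d. point errors.

Default study conditions (the `PipelineConfig` defaults): 6 species on a
balanced tree of depth 0.3 substitutions/site, duplication rate 0.1 and
loss rate 0.05 per unit branch length, 300-residue core (about the size
of the unambiguously aligned region of a real P-type ATPase alignment),
motif anchor at position 150, gamma shape 1.0, 12 decoys per genome with
lengths ~N(300, 50), 500 calibration decoys, medium mask preset, 100
bootstrap pseudo-replicates, 2 EST fragments per gene of ~300 nt with 1%
error. These produce families of ~25–40 members whose subfamilies are
well separated (between-subfamily distance ≥ 0.9 vs within ≤ 0.6) —
deliberately a *favourable* regime: the tests demonstrate that the
machinery is correct, not that the method succeeds on arbitrarily hard
data.

Features of real data the generator does **not** emulate: indels inside
the family core (alignment columns are known by construction, so the
masking stages are exercised mainly by decoys and fragments), codon
usage bias, rate shifts across the tree, compositional heterogeneity,
contamination and horizontal transfer, and the scale of real proteome
screens (hundreds of genomes, thousands of hits). Passing tests
therefore certify the implementation and its internal consistency; they
do not certify recovery rates on deeply diverged real superfamilies.

## Pipeline recipes and provenance

`run_prokaryote_recipe` chains search → empirical threshold → mask → NJ
tree → architecture assignment → census/Venn/breakdown.
`run_metal_subtree_recipe` chains (optional EST integration) → mask →
bootstrap tree → outgroup rooting → subgroup assignment → motif calls →
genus-level collapse → census and TM6 logo matrices. Both root between
the two deepest groups (jointly using the anchors of the divalent
subgroups, or of AI+AII) — rooting on a *single* subgroup's anchor pair
would place the root inside that subgroup and break its monophyly. All
outputs are plain TSV/Newick/JSON with a one-line provenance header
(recipe, seed, config hash); reruns with the same config are
byte-identical below the header. Logo matrices track gap mass as its own
column so every row sums to 1 exactly; information-mode heights use
`R = log2(20) − H` with gaps excluded from the entropy and no
small-sample correction.

## Known limitations

- The NJ engine is a surrogate for full ML/Bayesian inference; on real
  data the intended workflow imports externally computed trees for the
  annotation stages.
- The Gumbel null is fitted to Viterbi scores of i.i.d. decoys;
  compositionally biased real sequences would need a bias correction the
  package does not implement.
- `align_progressive` is a fallback without iterative refinement; its
  alignments on diverged real sequences will be worse than a dedicated
  aligner's.
- The orthology margin rule is a deliberate formalisation of an
  unpublished manual procedure; the 5-bit default is a design choice, not
  an estimate.
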