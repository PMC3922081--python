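"""Multiple-alignment construction and masking.

Implements the alignment-filtering cascade applied before tree inference:
insertion columns (residues in fewer than half the sequences) are discarded,
the remaining positions are filtered by a Gblocks-style conserved-block
selection with named presets, and sequences that are mostly missing relative
to the longest one are removed.  A basic progressive aligner (k-mer guide
tree + profile-profile global alignment with affine gaps) is provided as a
fallback; externally computed alignments can be imported from FASTA or
Stockholm.

Every operation returns a :class:`MaskedAlignment` carrying full per-column
provenance, so the kept-column set used downstream is always auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

KEPT = "kept"
DROPPED_INSERTION = "dropped-insertion"
DROPPED_BLOCK = "dropped-block"

GAP_CHARS = "-."


@dataclass
class MaskedAlignment:
    """An alignment plus per-column keep/drop provenance.

    ``column_status`` always refers to the original column coordinates
    (1-based externally); masking operations refine the status of columns
    that are still kept, never resurrect dropped ones.
    """

    ids: list[str]
    rows: list[str]
    column_status: list[str] = None
    preset_name: str | None = None
    removed_rows: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows must have uniform length")
        if self.column_status is None:
            self.column_status = [KEPT] * self.width

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def kept_columns(self) -> list[int]:
        """1-based original indices of kept columns."""
        return [i + 1 for i, s in enumerate(self.column_status) if s == KEPT]

    @property
    def index_map(self) -> dict[int, int]:
        """1-based original column -> 1-based kept-column index."""
        return {orig: j + 1 for j, orig in enumerate(self.kept_columns)}

    def kept_rows(self) -> list[str]:
        """Row strings restricted to kept columns."""
        cols = [c - 1 for c in self.kept_columns]
        return ["".join(r[c] for c in cols) for r in self.rows]

    def kept_alignment(self) -> "MaskedAlignment":
        return MaskedAlignment(list(self.ids), self.kept_rows(),
                               preset_name=self.preset_name)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "MaskedAlignment":
        ids, rows = [], []
        for r in records:
            if hasattr(r, "seq"):
                ids.append(r.id)
                rows.append(str(r.seq).upper())
            else:
                ids.append(r[0])
                rows.append(r[1].upper())
        return cls(ids, rows)

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "MaskedAlignment":
        from Bio import SeqIO
        return cls.from_records(SeqIO.parse(path, fmt))

    def write(self, path, fmt: str = "fasta", kept_only: bool = False) -> None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        rows = self.kept_rows() if kept_only else self.rows
        recs = [SeqRecord(Seq(s), id=i, description="")
                for i, s in zip(self.ids, rows)]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, fmt)

    def mask_table(self):
        import pandas as pd
        return pd.DataFrame({"column": np.arange(1, self.width + 1),
                             "status": self.column_status})


@dataclass(frozen=True)
class BlockPreset:
    """Parameter family for Gblocks-style block selection.

    Fractions refer to the number of sequences: a column is *conserved*
    when its most frequent residue occurs in more than
    ``min_conserved_fraction`` of the sequences, and *highly conserved*
    (usable as a block flank) at ``min_flank_fraction``.
    """

    name: str
    min_conserved_fraction: float
    min_flank_fraction: float
    max_contiguous_nonconserved: int
    min_block_length: int
    allowed_gap_rule: str  # none | half | all

    def __post_init__(self):
        if not (0.5 <= self.min_conserved_fraction
                <= self.min_flank_fraction <= 1.0):
            raise ValueError(
                "need 0.5 <= min_conserved_fraction <= min_flank_fraction <= 1")
        if self.min_block_length < 2:
            raise ValueError("min_block_length must be >= 2")
        if self.allowed_gap_rule not in ("none", "half", "all"):
            raise ValueError("allowed_gap_rule must be none, half or all")


# presets follow the reference program's documented parameter families;
# "loose" relaxes flanks, stretch length, block length and gaps, "strict"
# tightens them, so kept sets nest: strict <= medium <= loose
PRESETS = {
    "loose": BlockPreset("loose", 0.5, 0.5, 10, 5, "half"),
    "medium": BlockPreset("medium", 0.5, 0.85, 8, 10, "none"),
    "strict": BlockPreset("strict", 0.5, 0.9, 4, 15, "none"),
}


def drop_insertion_columns(alignment: MaskedAlignment,
                           occupancy_threshold: float = 0.5
                           ) -> MaskedAlignment:
    """Discard columns whose residue occupancy is below the threshold.

    A column with residues in *less than* ``occupancy_threshold`` of the
    sequences is an insertion column; occupancy exactly at the threshold is
    kept.  Idempotent.
    """
    status = list(alignment.column_status)
    n = alignment.n_rows
    for j in range(alignment.width):
        if status[j] != KEPT:
            continue
        occ = sum(r[j] not in GAP_CHARS for r in alignment.rows) / n
        if occ < occupancy_threshold:
            status[j] = DROPPED_INSERTION
    return replace(alignment, ids=list(alignment.ids),
                   rows=list(alignment.rows), column_status=status)


def _column_class(column: list[str], n: int, preset: BlockPreset) -> int:
    """0 = nonconserved, 1 = conserved, 2 = highly conserved (flank)."""
    gaps = sum(c in GAP_CHARS for c in column)
    if preset.allowed_gap_rule == "none" and gaps > 0:
        return 0
    if preset.allowed_gap_rule == "half" and gaps > n / 2:
        return 0
    residues = [c for c in column if c not in GAP_CHARS]
    if not residues:
        return 0
    top = max(residues.count(a) for a in set(residues))
    # "more than the fraction": the Gblocks convention floor(f*n) + 1
    conserved_count = int(np.floor(preset.min_conserved_fraction * n)) + 1
    flank_count = max(conserved_count,
                      int(np.ceil(preset.min_flank_fraction * n)))
    if top >= flank_count:
        return 2
    if top >= conserved_count:
        return 1
    return 0


def select_blocks(alignment: MaskedAlignment,
                  preset: BlockPreset | str = "medium") -> MaskedAlignment:
    """Gblocks-style selection of reliably aligned blocks.

    Columns are classified as nonconserved / conserved / highly conserved
    by the identity fraction of their most common residue (gaps never count
    toward the numerator; the gap rule can disqualify a column outright).
    Runs of more than ``max_contiguous_nonconserved`` nonconserved columns
    are rejected, the remaining candidate regions are trimmed inward to
    highly-conserved flanks, and blocks shorter than ``min_block_length``
    are discarded.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    n = alignment.n_rows
    status = list(alignment.column_status)
    kept = [j for j, s in enumerate(status) if s == KEPT]
    if not kept:
        return replace(alignment, column_status=status,
                       preset_name=preset.name)
    classes = {}
    for j in kept:
        col = [r[j] for r in alignment.rows]
        classes[j] = _column_class(col, n, preset)

    keep_flags = {j: True for j in kept}
    # 1. reject long runs of nonconserved columns
    for is_nc, grp in itertools.groupby(kept, key=lambda j: classes[j] == 0):
        run = list(grp)
        if is_nc and len(run) > preset.max_contiguous_nonconserved:
            for j in run:
                keep_flags[j] = False
    # 2. trim candidate regions to highly-conserved flanks
    regions = [list(g) for ok, g in
               itertools.groupby(kept, key=lambda j: keep_flags[j]) if ok]
    blocks = []
    for region in regions:
        while region and classes[region[0]] != 2:
            keep_flags[region[0]] = False
            region.pop(0)
        while region and classes[region[-1]] != 2:
            keep_flags[region[-1]] = False
            region.pop()
        # 3. enforce minimum block length
        if len(region) < preset.min_block_length:
            for j in region:
                keep_flags[j] = False
        elif region:
            blocks.append(region)
    for j in kept:
        if not keep_flags[j]:
            status[j] = DROPPED_BLOCK
    return replace(alignment, ids=list(alignment.ids),
                   rows=list(alignment.rows), column_status=status,
                   preset_name=preset.name)


def drop_partial_sequences(alignment: MaskedAlignment,
                           missing_threshold: float = 0.5
                           ) -> MaskedAlignment:
    """Remove rows with more than ``missing_threshold`` missing characters
    relative to the longest (most residue-rich) sequence.

    The rule is strict: a row exactly at the threshold is kept.
    """
    counts = [sum(c not in GAP_CHARS for c in r) for r in alignment.rows]
    if not counts:
        return alignment
    longest = max(counts)
    cutoff = (1.0 - missing_threshold) * longest
    keep_ids, keep_rows, removed = [], [], list(alignment.removed_rows)
    for i, c in enumerate(counts):
        if c < cutoff:
            removed.append(alignment.ids[i])
        else:
            keep_ids.append(alignment.ids[i])
            keep_rows.append(alignment.rows[i])
    return MaskedAlignment(keep_ids, keep_rows,
                           column_status=list(alignment.column_status),
                           preset_name=alignment.preset_name,
                           removed_rows=removed)


# -- progressive alignment fallback ---------------------------------------

_BLOSUM = None


def _blosum62():
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices
        _BLOSUM = substitution_matrices.load("BLOSUM62")
    return _BLOSUM


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    sa = {a[i:i + k] for i in range(max(len(a) - k + 1, 1))}
    sb = {b[i:i + k] for i in range(max(len(b) - k + 1, 1))}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def _profile_matrix(rows: list[str]) -> np.ndarray:
    """(width, 21) residue+gap frequency profile in BLOSUM index space."""
    from .models import AMINO_ACIDS
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    width = len(rows[0])
    prof = np.zeros((width, 21))
    for r in rows:
        for j, c in enumerate(r):
            prof[j, idx.get(c, 20) if c not in GAP_CHARS else 20] += 1
    return prof / len(rows)


def _pp_score_matrix() -> np.ndarray:
    from .models import AMINO_ACIDS
    m = _blosum62()
    S = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            S[i, j] = m[a][b]
    return S


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    gap_open: float = 10.0, gap_extend: float = 1.0):
    """Global profile-profile alignment (Gotoh affine gaps).

    The first residue of a gap costs ``gap_open``, each further one
    ``gap_extend``.  Column score is the expected BLOSUM62 score between a
    residue drawn from each profile column (gap mass contributes zero).
    Returns (merged_rows_a, merged_rows_b, score).
    """
    S = _pp_score_matrix()
    pa = _profile_matrix(rows_a)[:, :20]
    pb = _profile_matrix(rows_b)[:, :20]
    na, nb = pa.shape[0], pb.shape[0]
    sub = pa @ S @ pb.T                      # (na, nb) expected column score
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)       # gap in b
    Y = np.full((na + 1, nb + 1), NEG)       # gap in a
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, nb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, na + 1):
        Mm1 = M[i - 1]
        Xm1 = X[i - 1]
        Ym1 = Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        si = sub[i - 1]
        for j in range(1, nb + 1):
            best = max(Mm1[j - 1], Xm1[j - 1], Ym1[j - 1])
            Mi[j] = best + si[j - 1]
            Xi[j] = max(Mm1[j] - gap_open, Xm1[j] - gap_extend)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend)
    # traceback (deterministic preference M > X > Y on ties)
    i, j = na, nb
    finals = [("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])]
    state = max(finals, key=lambda c: c[1])[0]
    score = max(v for _, v in finals)
    ops = []
    while i > 0 or j > 0:
        if i == 0:
            ops.append("Y")
            j -= 1
            continue
        if j == 0:
            ops.append("X")
            i -= 1
            continue
        if state == "M":
            prev = max([("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                        ("Y", Y[i - 1, j - 1])], key=lambda c: c[1])[0]
            ops.append("M")
            i -= 1
            j -= 1
            state = prev
        elif state == "X":
            prev = ("M" if M[i - 1, j] - gap_open
                    >= X[i - 1, j] - gap_extend else "X")
            ops.append("X")
            i -= 1
            state = prev
        else:
            prev = ("M" if M[i, j - 1] - gap_open
                    >= Y[i, j - 1] - gap_extend else "Y")
            ops.append("Y")
            j -= 1
            state = prev
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for r, row in zip(rows_a, out_a):
                row.append(r[ia])
            ia += 1
        else:
            for row in out_a:
                row.append("-")
        if op in ("M", "Y"):
            for r, row in zip(rows_b, out_b):
                row.append(r[ib])
            ib += 1
        else:
            for row in out_b:
                row.append("-")
    return (["".join(r) for r in out_a], ["".join(r) for r in out_b],
            float(score))


def align_progressive(sequences, gap_open: float = 10.0,
                      gap_extend: float = 1.0) -> MaskedAlignment:
    """Progressive multiple alignment (built-in fallback aligner).

    Guide tree: neighbor joining on k-mer distances, midpoint-rooted;
    profiles are then merged postorder with global affine-gap
    profile-profile alignment.  Deterministic for a given input order.
    """
    from .profile_hmm import _normalise_rows
    pairs = _normalise_rows(sequences)
    if len(pairs) < 2:
        raise ValueError("need at least 2 sequences to align")
    from .models import AMINO_ACIDS
    legal = set(AMINO_ACIDS) | set("BZJXUO*")
    for sid, seq in pairs:
        bad = set(seq.upper()) - legal
        if bad:
            raise ValueError(
                f"sequence {sid!r} contains illegal characters {sorted(bad)}")
    ids = [p[0] for p in pairs]
    seqs = [p[1].upper() for p in pairs]
    if len(pairs) == 2:
        a, b, _ = _align_profiles([seqs[0]], [seqs[1]], gap_open, gap_extend)
        return MaskedAlignment(ids, [a[0], b[0]])

    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(seqs[i], seqs[j])
    from .trees import build_nj
    guide = build_nj(D, labels=[str(i) for i in range(n)]).tree
    guide.reroot_at_midpoint(update_bipartitions=False)

    def merge(node):
        if node.is_leaf():
            i = int(node.taxon.label)
            return [ids[i]], [seqs[i]]
        children = [merge(c) for c in node.child_nodes()]
        cur_ids, cur_rows = children[0]
        for nxt_ids, nxt_rows in children[1:]:
            a, b, _ = _align_profiles(cur_rows, nxt_rows, gap_open,
                                      gap_extend)
            cur_ids = cur_ids + nxt_ids
            cur_rows = a + b
        return cur_ids, cur_rows

    out_ids, out_rows = merge(guide.seed_node)
    order = [out_ids.index(i) for i in ids]
    return MaskedAlignment(ids, [out_rows[k] for k in order])
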