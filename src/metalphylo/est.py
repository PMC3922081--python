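"""EST/CDS fragment integration into an existing family alignment.

Single-pass cDNA fragments are translated in all six frames, the best frame
is recruited against the family's calibrated profile HMM, fragments that hit
too few profile columns are rejected as too partial to place, fragments of
one gene from one organism are merged in alignment-column space, orthology
is controlled by comparing local-alignment scores against ortholog and
paralog reference panels, and accepted fragments are written into the
alignment at their matched match-state columns without touching any existing
row or column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masking import MaskedAlignment
from .profile_hmm import ProfileHMM, score_sequence

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class PlacedFragment:
    fragment_id: str
    organism_id: str
    frame: int
    peptide: str                  # one char per match state of the span
    qstart: int                   # 1-based match-state interval (closed)
    qend: int
    bits: float
    verdict: str | None = None    # ortholog | paralog | ambiguous
    n_matched: int = 0
    n_insert_dropped: int = 0
    rejected: str | None = None   # rejection reason, when not recruited
    match_columns: np.ndarray | None = None  # seed-alignment columns

    @property
    def recruited(self) -> bool:
        return self.rejected is None


def translate_six_frames(record) -> list[tuple[int, str]]:
    """Translate a nucleotide record in all six frames.

    Stops render as '*', ambiguous codons as 'X'.  Frame -k is frame +k of
    the reverse complement.
    """
    from Bio.Seq import Seq
    seq = Seq(str(record.seq) if hasattr(record, "seq") else str(record))
    out = []
    rc = seq.reverse_complement()
    for frame in FRAMES:
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        sub = s[off: off + 3 * ((len(s) - off) // 3)]
        out.append((frame, str(sub.translate())))
    return out


def recruit_fragment(profile: ProfileHMM, record, min_bits: float = 15.0,
                     min_match_states: int = 50,
                     max_bad_fraction: float = 0.02,
                     organism_id: str | None = None) -> PlacedFragment:
    """Score all six frames and keep the best placement, or reject.

    Rejection reasons: ``below-min-bits`` (no frame reaches ``min_bits``),
    ``too-partial`` (fewer than ``min_match_states`` profile columns
    matched), ``low-quality`` (too many stops/unknowns inside the matched
    region).
    """
    frag_id = record.id if hasattr(record, "id") else "fragment"
    if organism_id is None:
        organism_id = frag_id.split("|")[0]
    best = None
    for frame, pep in translate_six_frames(record):
        res = score_sequence(profile, pep, traceback=True, forward=False)
        if best is None or res.viterbi_bits > best[1].viterbi_bits:
            best = (frame, res)
    frame, res = best
    placed = PlacedFragment(
        fragment_id=frag_id, organism_id=organism_id, frame=frame,
        peptide=res.match_residues or "", qstart=res.qstart or 0,
        qend=res.qend or 0, bits=res.viterbi_bits,
        n_matched=res.n_matched, n_insert_dropped=res.n_insert_dropped)
    if profile.match_columns is not None and res.qstart:
        placed.match_columns = profile.match_columns[
            res.qstart - 1: res.qend]
    if res.viterbi_bits < min_bits:
        placed.rejected = "below-min-bits"
    elif res.n_matched < min_match_states:
        placed.rejected = "too-partial"
    else:
        bad = sum(c in "*X" for c in placed.peptide)
        if placed.peptide and bad / len(placed.peptide) > max_bad_fraction:
            placed.rejected = "low-quality"
    return placed


def merge_gene_fragments(fragments: list[PlacedFragment],
                         min_overlap_columns: int = 10,
                         max_overlap_mismatch: float = 0.05
                         ) -> list[PlacedFragment]:
    """Merge one organism's fragments that agree on their column overlap.

    Fragments whose match-state intervals overlap by at least
    ``min_overlap_columns`` with at most ``max_overlap_mismatch``
    disagreement are assumed to come from one gene and merged (consensus by
    recruitment score); disagreeing overlaps stay separate as putative
    paralogs.  Assembly happens in alignment-column space, after
    recruitment, so it is deterministic.
    """
    frags = [f for f in fragments if f.recruited]
    if len(frags) <= 1:
        return list(frags)
    orgs = {f.organism_id for f in frags}
    if len(orgs) > 1:
        raise ValueError(f"fragments from multiple organisms: {sorted(orgs)}")

    def columns(f):
        return {f.qstart + i: c for i, c in enumerate(f.peptide)
                if c != "-"}

    merged: list[dict] = []                # {'cols': {col: (res, bits)}, ...}
    for f in sorted(frags, key=lambda f: (-f.bits, f.fragment_id)):
        fcols = columns(f)
        target = None
        for grp in merged:
            shared = set(fcols) & set(grp["cols"])
            if len(shared) < min_overlap_columns:
                continue
            mism = sum(fcols[c] != grp["cols"][c][0] for c in shared)
            if mism / len(shared) <= max_overlap_mismatch:
                target = grp
                break
        if target is None:
            merged.append({"cols": {c: (r, f.bits) for c, r in fcols.items()},
                           "members": [f]})
        else:
            for c, r in fcols.items():
                if c not in target["cols"] or f.bits > target["cols"][c][1]:
                    target["cols"][c] = (r, f.bits)
            target["members"].append(f)

    out = []
    for grp in merged:
        cols = grp["cols"]
        members = grp["members"]
        lo, hi = min(cols), max(cols)
        pep = "".join(cols.get(c, ("-",))[0] for c in range(lo, hi + 1))
        rep = members[0]
        # the union interval no longer matches any member's column slice;
        # sub-slice a member's global mapping when available
        cols = None
        if rep.match_columns is not None:
            full = np.asarray(rep.match_columns)
            if full.size == rep.qend - rep.qstart + 1:
                # reconstruct the seed-column array for the union interval
                # from the contiguous match-state -> column offset
                offset = int(full[0]) - rep.qstart
                if np.array_equal(full,
                                  np.arange(rep.qstart, rep.qend + 1)
                                  + offset):
                    cols = np.arange(lo, hi + 1) + offset
        contig = PlacedFragment(
            fragment_id="+".join(sorted(m.fragment_id for m in members)),
            organism_id=rep.organism_id, frame=rep.frame, peptide=pep,
            qstart=lo, qend=hi, bits=max(m.bits for m in members),
            n_matched=sum(c != "-" for c in pep),
            match_columns=cols)
        out.append(contig)
    return sorted(out, key=lambda f: f.fragment_id)


def orthology_filter(fragment: PlacedFragment, ortholog_panel,
                     paralog_panel, margin: float = 5.0) -> str:
    """Ortholog/paralog verdict by panel score margin (bits).

    "ortholog" when the best local-alignment score against the ortholog
    panel beats the paralog panel by at least ``margin`` bits, "paralog"
    for the converse, "ambiguous" within the margin.
    """
    from .annotate import sw_bits
    if not ortholog_panel or not paralog_panel:
        raise ValueError("both panels must be non-empty")
    pep = fragment.peptide.replace("-", "")

    def best(panel):
        scores = []
        for rec in panel:
            seq = str(rec.seq) if hasattr(rec, "seq") else str(rec[1])
            scores.append(sw_bits(pep, seq)[0])
        return max(scores)

    so, sp = best(ortholog_panel), best(paralog_panel)
    if so - sp >= margin:
        verdict = "ortholog"
    elif sp - so >= margin:
        verdict = "paralog"
    else:
        verdict = "ambiguous"
    fragment.verdict = verdict
    return verdict


def insert_into_alignment(alignment: MaskedAlignment,
                          placed: PlacedFragment,
                          profile: ProfileHMM | None = None
                          ) -> MaskedAlignment:
    """Write an ortholog fragment into the alignment as a new gapped row.

    Fragment residues go to the seed-alignment columns of their matched
    match states; everything else is gap-filled.  Existing rows and the
    column mask are untouched (insert-state residues were already dropped
    at recruitment, with their count logged on the fragment).
    """
    if placed.verdict != "ortholog":
        raise ValueError(
            f"only ortholog fragments may be inserted "
            f"(verdict: {placed.verdict!r})")
    cols = placed.match_columns
    if cols is None:
        if profile is None:
            raise ValueError("fragment carries no match columns and no "
                             "profile was given")
        cols = profile.match_columns[placed.qstart - 1: placed.qend]
    row = ["-"] * alignment.width
    for col, res in zip(cols, placed.peptide):
        if res != "-":
            row[col - 1] = res
    return MaskedAlignment(
        list(alignment.ids) + [placed.fragment_id],
        list(alignment.rows) + ["".join(row)],
        column_status=list(alignment.column_status),
        preset_name=alignment.preset_name,
        removed_rows=list(alignment.removed_rows))


def fragment_report(fragments: list[PlacedFragment]):
    """Per-fragment TSV-ready report of the recruitment stage."""
    import pandas as pd
    rows = [dict(fragment_id=f.fragment_id, organism=f.organism_id,
                 frame=f.frame, qstart=f.qstart, qend=f.qend,
                 bits=round(f.bits, 2), n_matched=f.n_matched,
                 verdict=f.verdict or "",
                 action="recruited" if f.recruited else f.rejected)
            for f in fragments]
    return pd.DataFrame(rows)
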