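"""Gene-family census statistics and sequence-logo matrices.

Per-genome presence/absence counts of protein categories (architectures,
subgroups, or motif classes), genome co-occurrence (Venn) regions,
taxonomic breakdowns at a chosen rank, and residue-frequency logo matrices
for reference-numbered alignment regions (the transmembrane metal-binding
segments).  All outputs are plain tables; every partition is
integer-conserving by construction and checked in tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .models import AMINO_ACIDS
from .masking import MaskedAlignment, GAP_CHARS


def census(assignments, genome_map, categories=None,
           genomes=None) -> pd.DataFrame:
    """Counts of proteins per genome x category.

    ``assignments`` maps protein id -> category (dict or two-column
    DataFrame); ``genome_map`` maps protein id -> genome id.  Categories
    or genomes given explicitly appear in the output even when empty.
    Presence = count >= 1 (see :func:`presence`).
    """
    if isinstance(assignments, pd.DataFrame):
        pairs = list(zip(assignments.iloc[:, 0], assignments.iloc[:, 1]))
    else:
        pairs = list(assignments.items())
    unmapped = [p for p, _ in pairs if p not in genome_map]
    if unmapped:
        raise KeyError(f"proteins without a genome mapping: "
                       f"{sorted(unmapped)[:10]}")
    cats = sorted({c for _, c in pairs} | set(categories or []))
    gens = sorted({genome_map[p] for p, _ in pairs} | set(genomes or []))
    mat = pd.DataFrame(0, index=pd.Index(gens, name="genome"),
                       columns=pd.Index(cats, name="category"))
    for prot, cat in pairs:
        mat.loc[genome_map[prot], cat] += 1
    return mat


def presence(matrix: pd.DataFrame) -> pd.DataFrame:
    return (matrix >= 1).astype(int)


def cooccurrence(matrix: pd.DataFrame, categories) -> dict[str, int]:
    """Genome counts of every non-empty Venn region plus "none".

    For k categories (2 or 3) the regions are all subsets of present
    categories; counts always sum to the number of genomes.
    """
    categories = list(categories)
    if len(categories) not in (2, 3):
        raise ValueError("co-occurrence is defined for 2 or 3 categories")
    missing = [c for c in categories if c not in matrix.columns]
    if missing:
        raise ValueError(f"categories absent from matrix: {missing}")
    pres = presence(matrix[categories])
    out = {}
    for r in range(1, len(categories) + 1):
        for combo in combinations(categories, r):
            others = [c for c in categories if c not in combo]
            mask = pres[list(combo)].all(axis=1)
            if others:
                mask &= ~pres[others].any(axis=1)
            out["&".join(combo)] = int(mask.sum())
    out["none"] = int((~pres.any(axis=1)).sum())
    return out


def taxonomic_breakdown(matrix: pd.DataFrame, taxonomy, genome_tax_map,
                        rank: str) -> pd.DataFrame:
    """Per category: genomes and distinct taxa (at ``rank``) containing it.

    Returns a long table (category, taxon, n_genomes, fraction) plus
    per-category totals accessible via ``attrs["totals"]``.  Genomes whose
    lineage lacks the rank are pooled under "unranked" with a warning.
    """
    import warnings
    pres = presence(matrix)
    taxon_of = {}
    for g in matrix.index:
        tax = genome_tax_map.get(g)
        t = taxonomy.ancestor_at_rank(tax, rank) if tax is not None else None
        if t is None:
            warnings.warn(f"genome {g!r} has no taxon at rank {rank!r}")
            taxon_of[g] = "unranked"
        else:
            taxon_of[g] = taxonomy.name_of(t)
    rows = []
    totals = {}
    for cat in matrix.columns:
        present_genomes = pres.index[pres[cat] > 0]
        by_taxon = {}
        for g in present_genomes:
            by_taxon[taxon_of[g]] = by_taxon.get(taxon_of[g], 0) + 1
        n_total = len(present_genomes)
        totals[cat] = dict(n_genomes=n_total, n_taxa=len(by_taxon))
        for taxon, n in sorted(by_taxon.items()):
            rows.append(dict(category=cat, taxon=taxon, n_genomes=n,
                             fraction=n / n_total if n_total else 0.0))
    df = pd.DataFrame(rows, columns=["category", "taxon", "n_genomes",
                                     "fraction"])
    df.attrs["totals"] = totals
    return df


def extract_region(alignment: MaskedAlignment, reference_id: str,
                   reference_interval) -> MaskedAlignment:
    """Slice the alignment at a reference protein's ungapped interval.

    ``reference_interval`` is 1-based closed in ungapped reference
    coordinates; the returned sub-alignment carries the reference numbering
    of its columns in ``column_labels``.
    """
    lo, hi = reference_interval
    ref_row = alignment.row(reference_id)
    ungapped_len = sum(c not in GAP_CHARS for c in ref_row)
    if not (1 <= lo <= hi <= ungapped_len):
        raise ValueError(
            f"interval [{lo}, {hi}] outside reference length {ungapped_len}")
    cols = []
    count = 0
    for j, c in enumerate(ref_row):
        if c not in GAP_CHARS:
            count += 1
            if lo <= count <= hi:
                cols.append(j)
    sub_rows = ["".join(r[j] for j in cols) for r in alignment.rows]
    sub = MaskedAlignment(list(alignment.ids), sub_rows)
    sub.column_labels = list(range(lo, hi + 1))
    sub.reference_id = reference_id
    return sub


def split_by_taxon(sub_alignment: MaskedAlignment, taxonomy, row_tax_map,
                   in_group_taxon) -> tuple[MaskedAlignment, MaskedAlignment]:
    """Split rows into (in-group, outgroup) by taxonomy membership.

    A row is in-group when ``in_group_taxon`` (name or tax id) lies on its
    lineage.  The split is disjoint and exhaustive; unmapped rows raise.
    """
    if isinstance(in_group_taxon, str):
        in_group_taxon = taxonomy.id_of(in_group_taxon)
    in_ids, in_rows, out_ids, out_rows = [], [], [], []
    for rid, row in zip(sub_alignment.ids, sub_alignment.rows):
        tax = row_tax_map.get(rid)
        if tax is None:
            raise KeyError(f"row {rid!r} has no taxonomy mapping")
        if in_group_taxon in taxonomy.lineage(tax):
            in_ids.append(rid)
            in_rows.append(row)
        else:
            out_ids.append(rid)
            out_rows.append(row)
    labels = getattr(sub_alignment, "column_labels", None)
    parts = []
    for ids, rows in ((in_ids, in_rows), (out_ids, out_rows)):
        part = MaskedAlignment(ids, rows if rows else [])
        if labels is not None:
            part.column_labels = list(labels)
        parts.append(part)
    return parts[0], parts[1]


def logo(sub_alignment: MaskedAlignment, mode: str = "frequency"
         ) -> pd.DataFrame:
    """Residue-frequency (or information-scaled) logo matrix.

    Frequency mode: letter height = residue occurrence frequency in the
    column (gap mass tracked in its own column, so each row sums to 1).
    Information mode: height = frequency x R with R = log2(20) - H(column),
    the gap-excluded Shannon information (no small-sample correction).
    Rows are indexed by reference numbering when the sub-alignment carries
    ``column_labels``.
    """
    if mode not in ("frequency", "information"):
        raise ValueError("mode must be 'frequency' or 'information'")
    rows = sub_alignment.rows
    if not rows:
        raise ValueError("empty sub-alignment")
    n = len(rows)
    width = len(rows[0])
    labels = getattr(sub_alignment, "column_labels",
                     list(range(1, width + 1)))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    freq = np.zeros((width, 21))           # 20 residues + gap
    for r in rows:
        for j, c in enumerate(r):
            if c in GAP_CHARS:
                freq[j, 20] += 1
            else:
                k = aa_index.get(c.upper())
                if k is None:
                    freq[j, 20] += 1       # unknowns pooled with gap mass
                else:
                    freq[j, k] += 1
    freq /= n
    df = pd.DataFrame(freq, index=pd.Index(labels, name="position"),
                      columns=list(AMINO_ACIDS) + ["-"])
    df.attrs["n_sequences"] = n
    df.attrs["mode"] = mode
    if mode == "frequency":
        return df
    heights = df.copy()
    for j in range(width):
        res = freq[j, :20]
        tot = res.sum()
        if tot <= 0:
            heights.iloc[j, :20] = 0.0
            continue
        p = res / tot
        nz = p[p > 0]
        H = float(-(nz * np.log2(nz)).sum())
        R = np.log2(20.0) - H
        heights.iloc[j, :20] = res / tot * R
    heights["-"] = 0.0
    return heights


def consensus(logo_df: pd.DataFrame) -> str:
    """Most frequent residue per column (gap mass ignored)."""
    res = logo_df[list(AMINO_ACIDS)]
    return "".join(res.columns[np.argmax(res.to_numpy(), axis=1)])
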