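"""Profile hidden Markov models for superfamily homolog retrieval.

A profile is built from a seed alignment: columns whose residue occupancy
reaches a threshold (default 50%) become match states, the rest emit from the
background.  Scoring follows the classic Plan7 layout in unihit local mode:
background-emitting N/C flank states, uniform entry/exit over match-state
intervals, and a target-length-conditioned null model, so that reported bit
scores are log-odds against an i.i.d. background sequence.  E-values come
from a maximum-likelihood Gumbel fit to decoy bit scores.

The empirical "breakdown" heuristic (:func:`detect_threshold_break`) finds
the largest gap in sorted log10 E-values of a screen, the operational rule
for separating a tight homolog family from the next-best scoring background
families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gumbel_r

from .models import AMINO_ACIDS, lg_model

LOG0 = -np.inf

# ambiguity codes scored as background-weighted averages over their members
AMBIGUITY = {"B": "ND", "Z": "QE", "J": "IL", "X": AMINO_ACIDS,
             "U": "C", "O": "K", "*": AMINO_ACIDS}


class NoMatchStatesError(ValueError):
    """Raised when no alignment column satisfies the occupancy rule."""


class CalibrationError(RuntimeError):
    """Raised when decoy scores cannot support a Gumbel fit."""


@dataclass
class Calibration:
    mu: float
    lam: float
    n_decoys: int
    database_size: int


@dataclass
class ProfileHMM:
    """Profile HMM over the 20-letter amino-acid alphabet.

    ``match_emissions`` is (L, 20) in probability space; transition arrays
    are indexed by the source match state (``t_mm[k]`` leaves M_{k+1}).
    ``match_columns`` records the 1-based seed-alignment column of each
    match state for coordinate bookkeeping downstream.
    """

    match_emissions: np.ndarray
    background: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    insert_emissions: np.ndarray | None = None
    match_columns: np.ndarray | None = None
    name: str = "profile"
    calibration: Calibration | None = None

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, float)
        self.background = np.asarray(self.background, float)
        L = self.match_emissions.shape[0]
        if self.match_emissions.shape != (L, 20):
            raise ValueError("match emissions must be (L, 20)")
        if np.any(np.abs(self.match_emissions.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each match emission row must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.insert_emissions is None:
            self.insert_emissions = self.background.copy()
        if self.match_columns is None:
            self.match_columns = np.arange(1, L + 1)

    @property
    def match_state_count(self) -> int:
        return self.match_emissions.shape[0]

    # -- local-mode architecture ------------------------------------------
    # Entry into M_k carries probability proportional to (L - k + 1) and a
    # matching exit probability 1/(L - j + 1) leaves M_j, which together
    # make every (entry, exit) match-state interval equally likely a
    # priori.  A small B->D1 mass (one extra "entry cell") keeps the
    # all-delete path defined, so even an empty sequence has a score.
    def local_entry_exit(self):
        L = self.match_state_count
        p_bd = 1.0 / (1.0 + L * (L + 1) / 2.0)
        ks = np.arange(1, L + 1)
        entry = (1.0 - p_bd) * 2.0 * (L - ks + 1) / (L * (L + 1))
        exit_ = 1.0 / (L - ks + 1.0)
        return entry, exit_, p_bd

    def evalue(self, bits, database_size: int | None = None):
        """E-value of a bit score under the fitted Gumbel null."""
        if self.calibration is None:
            raise CalibrationError("profile is not calibrated")
        cal = self.calibration
        n = database_size if database_size is not None else cal.database_size
        z = -cal.lam * (np.asarray(bits, float) - cal.mu)
        return n * -np.expm1(-np.exp(z))


@dataclass
class ScoreResult:
    viterbi_bits: float
    forward_bits: float
    qstart: int | None = None   # first/last match state on the best path
    qend: int | None = None
    sstart: int | None = None   # 1-based positions on the target sequence
    send: int | None = None
    match_residues: str | None = None  # one char per match state in span
    n_matched: int = 0          # match states emitting a residue
    n_insert_dropped: int = 0


def _normalise_rows(rows):
    """Accept SeqRecords, (id, seq) pairs, or a MaskedAlignment."""
    out = []
    if hasattr(rows, "ids") and hasattr(rows, "rows"):
        return list(zip(rows.ids, rows.rows))
    for r in rows:
        if hasattr(r, "seq"):
            out.append((r.id, str(r.seq)))
        else:
            out.append((r[0], r[1]))
    return out


def build_profile(seed_alignment, occupancy_threshold: float = 0.5,
                  pseudocount_weight: float = 1.0,
                  background: np.ndarray | None = None,
                  name: str = "profile") -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns with residue occupancy >= ``occupancy_threshold`` become match
    states; emission probabilities are residue counts smoothed with
    ``pseudocount_weight`` total background-proportional pseudo-mass, and
    transition probabilities are counted from the implied state paths with
    one pseudo-observation per allowed transition.
    """
    rows = _normalise_rows(seed_alignment)
    if not rows:
        raise ValueError("seed alignment is empty")
    seqs = [s.upper() for _, s in rows]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("seed alignment rows must have uniform length")
    if background is None:
        background = lg_model().frequencies
    bg = np.asarray(background, float)

    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    mat = np.array([[aa_index.get(c, -1) for c in s] for s in seqs])
    is_res = np.array([[c not in "-." for c in s] for s in seqs])
    occupancy = is_res.mean(axis=0)
    match_cols = np.nonzero(occupancy >= occupancy_threshold)[0]
    L = match_cols.size
    if L == 0:
        raise NoMatchStatesError(
            f"no column reaches occupancy {occupancy_threshold}")

    emis = np.tile(bg * pseudocount_weight, (L, 1))
    for k, col in enumerate(match_cols):
        codes = mat[:, col]
        for c in codes[codes >= 0]:
            emis[k, c] += 1.0
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts from each row's implied M/I/D path through the core
    cnt = {t: np.ones(max(L - 1, 1)) for t in
           ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    col_kind = np.full(width, -1)            # match index or -1 (insert col)
    col_kind[match_cols] = np.arange(L)
    for r in range(len(seqs)):
        prev = None                          # ('M'|'D', k) at last match col
        n_ins = 0
        for col in range(width):
            k = col_kind[col]
            if k < 0:
                if is_res[r, col]:
                    n_ins += 1
                continue
            cur = "M" if is_res[r, col] else "D"
            if prev is not None and k > 0:
                pk = k - 1
                if n_ins > 0 and prev[0] == "M":
                    cnt["mi"][pk] += 1
                    cnt["ii"][pk] += max(0, n_ins - 1)
                    cnt["im"][pk] += 1 if cur == "M" else 0
                    # I->D folded into I->M (Plan7 has no I->D)
                else:
                    key = (prev[0] + cur).lower()
                    if key in cnt:
                        cnt[key][pk] += 1
            prev = (cur, k)
            n_ins = 0
    m_tot = cnt["mm"] + cnt["mi"] + cnt["md"]
    i_tot = cnt["im"] + cnt["ii"]
    d_tot = cnt["dm"] + cnt["dd"]
    return ProfileHMM(
        match_emissions=emis, background=bg,
        t_mm=cnt["mm"] / m_tot, t_mi=cnt["mi"] / m_tot,
        t_md=cnt["md"] / m_tot,
        t_im=cnt["im"] / i_tot, t_ii=cnt["ii"] / i_tot,
        t_dm=cnt["dm"] / d_tot, t_dd=cnt["dd"] / d_tot,
        match_columns=match_cols + 1, name=name)


def _emission_lodds(profile: ProfileHMM, seq: str) -> np.ndarray:
    """(n, L) emission log-odds for each residue against each match state."""
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    ratio = profile.match_emissions / profile.background[None, :]  # (L, 20)
    cols = []
    bg = profile.background
    for c in seq:
        i = aa_index.get(c)
        if i is not None:
            cols.append(np.log(ratio[:, i]))
        else:
            members = AMBIGUITY.get(c, AMINO_ACIDS)
            idx = [aa_index[m] for m in members]
            w = bg[idx] / bg[idx].sum()
            cols.append(np.log(ratio[:, idx] @ w))
    return np.array(cols)                    # (n, L)


def _log(x):
    with np.errstate(divide="ignore"):
        return np.log(x)


def score_sequence(profile: ProfileHMM, seq: str,
                   traceback: bool = False,
                   forward: bool = True) -> ScoreResult:
    """Viterbi and forward bit scores of ``seq`` against the profile.

    Scores are log-odds (bits) against the length-conditioned i.i.d.
    background null.  With ``traceback=True`` the best-path match-state
    span and per-match-state residues are recovered (needed for fragment
    recruitment and alignment insertion).
    """
    seq = str(seq).upper().replace("-", "").replace(".", "")
    n = len(seq)
    L = profile.match_state_count
    entry, exit_, p_bd = profile.local_entry_exit()

    p_lp = n / (n + 2.0)
    null_trans = n * np.log(n / (n + 1.0)) + np.log(1.0 / (n + 1.0)) if n else 0.0
    lg_lp = _log(p_lp)
    lg_stop = _log(1.0 - p_lp)

    lent = _log(entry)
    lex = _log(exit_)
    keep = _log(1.0 - exit_)                 # applied to core out-transitions
    keep[-1] = LOG0                          # M_L always exits
    lt_mm = keep[:-1] + _log(profile.t_mm[:L - 1] if L > 1 else [])
    lt_mi = keep[:-1] + _log(profile.t_mi[:L - 1] if L > 1 else [])
    lt_md = keep[:-1] + _log(profile.t_md[:L - 1] if L > 1 else [])
    lt_im = _log(profile.t_im[:L - 1] if L > 1 else [])
    lt_ii = _log(profile.t_ii[:L - 1] if L > 1 else [])
    lt_dm = _log(profile.t_dm[:L - 1] if L > 1 else [])
    lt_dd = _log(profile.t_dd[:L - 1] if L > 1 else [])

    lodds = _emission_lodds(profile, seq) if n else np.zeros((0, L))
    ins_ratio = profile.insert_emissions / profile.background
    ins_lo = (_emission_lodds(
        ProfileHMM(match_emissions=ins_ratio[None, :] * profile.background
                   / (ins_ratio[None, :] * profile.background).sum(),
                   background=profile.background), seq)[:, 0]
        + np.log((ins_ratio * profile.background).sum())
        if n and not np.allclose(ins_ratio, 1.0) else np.zeros(n))

    def times(count, lg):
        # count * lg with the convention 0 * -inf = 0
        count = np.asarray(count, float)
        out = np.zeros_like(count)
        nz = count != 0
        out[nz] = count[nz] * lg
        return out

    VB = lg_stop + times(np.arange(n + 1), lg_lp)  # in B after i residues

    C = np.concatenate([[0.0], np.cumsum(lt_dd)]) if L > 1 else np.zeros(1)

    def finish_deletes(cand, op):
        # cand[k] = score of entering D_{k+1} fresh; extend along the chain
        shifted = cand - C
        shifted[~np.isfinite(shifted)] = LOG0
        return op.accumulate(shifted) + C

    def run(op):
        VM = np.full((n + 1, L), LOG0)
        VI = np.full((n + 1, L), LOG0)
        VD = np.full((n + 1, L), LOG0)
        lg_pbd = np.log(p_bd)
        cand = np.full(L, LOG0)
        cand[0] = VB[0] + lg_pbd             # i = 0: only deletes reachable
        VD[0] = finish_deletes(cand, op)
        lt_mm_p = np.concatenate([[LOG0], lt_mm])
        lt_im_p = np.concatenate([[LOG0], lt_im])
        lt_dm_p = np.concatenate([[LOG0], lt_dm])
        for i in range(1, n + 1):
            prev_m = np.concatenate([[LOG0], VM[i - 1, :-1]])
            prev_i = np.concatenate([[LOG0], VI[i - 1, :-1]])
            prev_d = np.concatenate([[LOG0], VD[i - 1, :-1]])
            srcs = np.stack([
                np.full(L, VB[i - 1]) + lent,
                prev_m + lt_mm_p,
                prev_i + lt_im_p,
                prev_d + lt_dm_p,
            ])
            VM[i] = lodds[i - 1] + op.reduce(srcs, axis=0)
            if L > 1:
                vi = op(VM[i - 1, :-1] + lt_mi, VI[i - 1, :-1] + lt_ii)
                VI[i, :-1] = vi + ins_lo[i - 1]
            cand = np.full(L, LOG0)
            cand[0] = VB[i] + lg_pbd
            if L > 1:
                cand[1:] = VM[i, :-1] + lt_md
            VD[i] = finish_deletes(cand, op)
        VE = op.reduce(VM + lex[None, :], axis=1)
        VE = op(VE, VD[:, L - 1])            # D_L -> E
        totals = VE + times(n - np.arange(n + 1), lg_lp) + lg_stop
        best = op.reduce(totals)
        return best, (VM, VI, VD, totals)

    f_nats = run(np.logaddexp)[0] if forward else np.nan
    v_nats, mats = run(np.maximum)
    ln2 = np.log(2.0)
    result = ScoreResult(viterbi_bits=float((v_nats - null_trans) / ln2),
                         forward_bits=float((f_nats - null_trans) / ln2))
    if traceback and np.isfinite(v_nats):
        _traceback(profile, seq, lodds, mats, result,
                   (VB, lent, lex, lt_mm, lt_mi, lt_md, lt_im, lt_ii,
                    lt_dm, lt_dd, p_bd))
    return result


def _traceback(profile, seq, lodds, mats, result, params):
    """Recover the best local path by re-comparing stored DP cells."""
    VM, VI, VD, totals = mats
    (VB, lent, lex, lt_mm, lt_mi, lt_md, lt_im, lt_ii,
     lt_dm, lt_dd, p_bd) = params
    L = profile.match_state_count
    lg_pbd = np.log(p_bd)

    i = int(np.argmax(totals))
    m_end = VM[i] + lex
    if np.max(m_end) >= VD[i, L - 1]:
        state, k = "M", int(np.argmax(m_end))
    else:
        state, k = "D", L - 1
    span_chars: dict[int, str] = {}
    send = i
    sstart = None
    first_k = None
    last_k = None
    n_matched = 0
    n_ins = 0
    while True:
        if state == "M":
            span_chars[k] = seq[i - 1]
            n_matched += 1
            first_k = k
            if last_k is None:
                last_k = k
            sstart = i
            cands = [("B", VB[i - 1] + lent[k])]
            if k > 0:
                cands += [("M", VM[i - 1, k - 1] + lt_mm[k - 1]),
                          ("I", VI[i - 1, k - 1] + lt_im[k - 1]),
                          ("D", VD[i - 1, k - 1] + lt_dm[k - 1])]
            best = max(cands, key=lambda c: c[1])
            i -= 1
            if best[0] == "B":
                break
            state = best[0]
            if state != "I":
                k -= 1
            else:
                k -= 1  # I_k sits between M_k and M_{k+1}
        elif state == "I":
            n_ins += 1
            from_i = VI[i - 1, k] + lt_ii[k]
            from_m = VM[i - 1, k] + lt_mi[k]
            i -= 1
            state = "I" if from_i > from_m else "M"
        else:  # D
            span_chars[k] = "-"
            first_k = k
            if last_k is None:
                last_k = k
            if k == 0:
                break
            from_m = VM[i, k - 1] + lt_md[k - 1]
            from_d = VD[i, k - 1] + lt_dd[k - 1]
            entry = VB[i] + lg_pbd if k == 0 else LOG0
            if from_m >= from_d:
                state = "M"
            else:
                state = "D"
            k -= 1
    if first_k is not None:
        result.qstart = first_k + 1
        result.qend = last_k + 1
        result.sstart = sstart
        result.send = send
        result.match_residues = "".join(
            span_chars.get(j, "-") for j in range(first_k, last_k + 1))
        result.n_matched = n_matched
        result.n_insert_dropped = n_ins


def fit_gumbel(scores) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (mu, lambda) fit to a score sample."""
    scores = np.asarray(scores, float)
    if scores.size < 2 or np.std(scores) < 1e-9:
        raise CalibrationError("degenerate decoy score variance")
    mu, beta = gumbel_r.fit(scores)
    return float(mu), float(1.0 / beta)


def calibrate_evalues(profile: ProfileHMM, decoys,
                      database_size: int | None = None,
                      min_decoys: int = 500) -> ProfileHMM:
    """Fit the Gumbel null from decoy Viterbi bit scores (in place).

    ``decoys`` may be sequence records/strings or a precomputed score
    array.  E-values are then ``E(s) = n * P(S >= s)`` under the fit,
    with ``n`` the database size (default: the decoy count).
    """
    if isinstance(decoys, np.ndarray) and decoys.dtype.kind == "f":
        scores = decoys
    else:
        decoys = list(decoys)
        seqs = [str(d.seq) if hasattr(d, "seq") else str(d) for d in decoys]
        if len(seqs) < min_decoys:
            raise ValueError(f"need >= {min_decoys} decoys, got {len(seqs)}")
        scores = np.array([score_sequence(profile, s,
                                          forward=False).viterbi_bits
                           for s in seqs])
    mu, lam = fit_gumbel(scores)
    n = database_size if database_size is not None else scores.size
    profile.calibration = Calibration(mu=mu, lam=lam,
                                      n_decoys=int(scores.size),
                                      database_size=int(n))
    return profile


HIT_COLUMNS = ["seq_id", "proteome_id", "bits", "evalue", "qstart", "qend"]


def screen_proteomes(profile: ProfileHMM, proteomes,
                     evalue_cutoff: float = 10.0,
                     database_size: int | None = None) -> pd.DataFrame:
    """Score every sequence of every proteome; keep hits with E <= cutoff.

    ``proteomes`` maps proteome id -> FASTA path or list of records.
    Unreadable files are reported (``result.attrs["errors"]``) and skipped.
    Rows are sorted by ascending E-value.
    """
    if profile.calibration is None:
        raise CalibrationError("screening requires a calibrated profile")
    from Bio import SeqIO
    rows, errors = [], []
    for pid, source in proteomes.items():
        try:
            if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
                records = list(SeqIO.parse(source, "fasta"))
                if not records:
                    raise ValueError("no FASTA records")
            else:
                records = list(source)
        except Exception as exc:  # noqa: BLE001 - per-file error, continue
            errors.append(f"{pid} ({source}): {exc}")
            warnings.warn(f"skipping unreadable proteome {pid}: {exc}")
            continue
        for rec in records:
            res = score_sequence(profile, str(rec.seq), traceback=True,
                                 forward=False)
            ev = float(profile.evalue(res.viterbi_bits, database_size))
            if ev <= evalue_cutoff:
                rows.append((rec.id, pid, res.viterbi_bits, ev,
                             res.qstart, res.qend))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df = df.sort_values(["evalue", "seq_id"], kind="stable",
                        ignore_index=True)
    df.attrs["errors"] = errors
    return df


def detect_threshold_break(hits, min_gap_orders: float = 3.0):
    """Largest gap in sorted log10 E-values; the empirical family boundary.

    Returns ``(threshold, gap_in_orders)`` with the threshold at the
    geometric midpoint of the flanking E-values, or ``None`` when no gap
    reaches ``min_gap_orders``.  Zero E-values are clamped to the smallest
    positive float; gap-size ties resolve toward the smaller (more
    stringent) threshold.
    """
    if isinstance(hits, pd.DataFrame):
        evalues = hits["evalue"].to_numpy(float)
    else:
        evalues = np.asarray(hits, float)
    evalues = evalues[np.isfinite(evalues) & (evalues >= 0)]
    if evalues.size < 2:
        raise ValueError("need at least 2 hits with finite E-values")
    tiny = np.nextafter(0, 1)
    logs = np.sort(np.log10(np.clip(evalues, tiny, None)))
    gaps = np.diff(logs)
    if gaps.size == 0 or np.all(gaps <= 0):
        return None
    best = int(np.argmax(gaps))              # first max = smaller threshold
    if gaps[best] < min_gap_orders:
        return None
    threshold = 10.0 ** ((logs[best] + logs[best + 1]) / 2.0)
    return float(threshold), float(gaps[best])


# -- plain-text profile serialisation -------------------------------------

def write_profile(profile: ProfileHMM, path) -> None:
    """Versioned plain-text dump of all profile parameters."""
    with open(path, "w") as fh:
        fh.write("metalphylo-profile v1\n")
        fh.write(f"name\t{profile.name}\n")
        fh.write(f"L\t{profile.match_state_count}\n")
        fh.write("alphabet\t" + AMINO_ACIDS + "\n")
        fh.write("match_columns\t" +
                 ",".join(map(str, profile.match_columns)) + "\n")
        if profile.calibration:
            c = profile.calibration
            fh.write(f"calibration\t{c.mu:.17g}\t{c.lam:.17g}\t{c.n_decoys}"
                     f"\t{c.database_size}\n")
        fh.write("background\t" +
                 ",".join(f"{x:.17g}" for x in profile.background) + "\n")
        for label, arr in [("match_emissions", profile.match_emissions),
                           ("insert_emissions",
                            profile.insert_emissions[None, :])]:
            for row in np.atleast_2d(arr):
                fh.write(label + "\t" + ",".join(f"{x:.17g}" for x in row) + "\n")
        for label in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            fh.write(label + "\t" +
                     ",".join(f"{x:.17g}" for x in getattr(profile, label)) + "\n")


def read_profile(path) -> ProfileHMM:
    fields: dict[str, list] = {}
    meta = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "metalphylo-profile v1":
            raise ValueError(f"unrecognised profile format: {header!r}")
        for line in fh:
            key, *vals = line.rstrip("\n").split("\t")
            if key in ("name",):
                meta[key] = vals[0]
            elif key == "calibration":
                meta[key] = Calibration(float(vals[0]), float(vals[1]),
                                        int(vals[2]), int(vals[3]))
            elif key in ("L", "alphabet"):
                continue
            else:
                fields.setdefault(key, []).append(
                    np.array([float(x) for x in vals[0].split(",")]))
    return ProfileHMM(
        match_emissions=np.array(fields["match_emissions"]),
        background=fields["background"][0],
        t_mm=fields["t_mm"][0], t_mi=fields["t_mi"][0],
        t_md=fields["t_md"][0], t_im=fields["t_im"][0],
        t_ii=fields["t_ii"][0], t_dm=fields["t_dm"][0],
        t_dd=fields["t_dd"][0],
        insert_emissions=fields["insert_emissions"][0],
        match_columns=fields["match_columns"][0].astype(int),
        name=meta.get("name", "profile"),
        calibration=meta.get("calibration"))
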