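"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
profile scores are obtained by exhaustively enumerating every state path of
the documented local architecture, alignments by full Needleman-Wunsch
tables, distances by grid search.  They are only feasible at toy sizes.
"""

import math

import numpy as np

from metalphylo.models import AMINO_ACIDS

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def enumerate_profile_paths(profile, seq):
    """All-path (forward) and best-path (Viterbi) bit scores by enumeration.

    Builds the unihit local state machine (N/C background flanks, uniform
    entry/exit over match intervals, B->D1 all-delete entry) from the
    profile's probability parameters and recursively enumerates every path
    emitting ``seq``, summing/maximising path log-odds against the
    length-conditioned i.i.d. null.
    """
    seq = seq.upper()
    n = len(seq)
    L = profile.match_state_count
    entry, exit_, p_bd = profile.local_entry_exit()
    p_lp = n / (n + 2.0)
    bg = profile.background
    em = profile.match_emissions

    def em_lo(k, c):
        i = AA_INDEX[c]
        return math.log(em[k, i] / bg[i])

    paths = []  # log-odds of each complete path

    def core(k_next, pos, acc, in_state):
        """Explore from 'about to use match index k_next' (0-based)."""
        # in_state: ('M', k) just emitted by match k, ('D', k), ('I', k)
        kind, k = in_state
        if kind == "M":
            # option: exit
            end(pos, acc + math.log(exit_[k]))
            if k + 1 < L:
                stay = math.log(1.0 - exit_[k])
                # M -> M
                if pos < n:
                    core(None, pos + 1,
                         acc + stay + math.log(profile.t_mm[k])
                         + em_lo(k + 1, seq[pos]), ("M", k + 1))
                # M -> I_k
                if pos < n:
                    core(None, pos + 1,
                         acc + stay + math.log(profile.t_mi[k]), ("I", k))
                # M -> D
                core(None, pos,
                     acc + stay + math.log(profile.t_md[k]), ("D", k + 1))
        elif kind == "I":
            if pos < n:
                core(None, pos + 1, acc + math.log(profile.t_ii[k]),
                     ("I", k))
            if pos < n and k + 1 < L:
                core(None, pos + 1,
                     acc + math.log(profile.t_im[k])
                     + em_lo(k + 1, seq[pos]), ("M", k + 1))
        else:  # D
            if k == L - 1:
                end(pos, acc)            # D_L -> E with probability 1
                return
            core(None, pos, acc + math.log(profile.t_dd[k]), ("D", k + 1))
            if pos < n:
                core(None, pos + 1,
                     acc + math.log(profile.t_dm[k])
                     + em_lo(k + 1, seq[pos]), ("M", k + 1))

    def end(pos, acc):
        # E -> C flank emits the remaining n - pos residues
        rest = n - pos
        tail = rest * math.log(p_lp) if rest else 0.0
        paths.append(acc + tail + math.log(1.0 - p_lp))

    for lead in range(n + 1):
        head = lead * math.log(p_lp) if lead else 0.0
        head += math.log(1.0 - p_lp)
        # enter at any match state (emitting) ...
        for k in range(L):
            if lead < n:
                core(None, lead + 1,
                     head + math.log(entry[k]) + em_lo(k, seq[lead]),
                     ("M", k))
        # ... or down the all-delete chain
        core(None, lead, head + math.log(p_bd), ("D", 0))

    null = (n * math.log(n / (n + 1.0)) + math.log(1.0 / (n + 1.0))
            if n else 0.0)
    ln2 = math.log(2.0)
    forward = (np.logaddexp.reduce(np.array(paths)) - null) / ln2
    viterbi = (max(paths) - null) / ln2
    return float(viterbi), float(forward)


def random_profile(rng, L, with_columns=False):
    """A random valid ProfileHMM with L match states."""
    from metalphylo.profile_hmm import ProfileHMM

    def dirichlet(k, size):
        x = rng.gamma(1.0, size=(size, k))
        return x / x.sum(axis=1, keepdims=True)

    bg = dirichlet(20, 1)[0]
    em = dirichlet(20, L)
    m3 = dirichlet(3, max(L - 1, 1))
    i2 = dirichlet(2, max(L - 1, 1))
    d2 = dirichlet(2, max(L - 1, 1))
    return ProfileHMM(match_emissions=em, background=bg,
                      t_mm=m3[:, 0], t_mi=m3[:, 1], t_md=m3[:, 2],
                      t_im=i2[:, 0], t_ii=i2[:, 1],
                      t_dm=d2[:, 0], t_dd=d2[:, 1])


def grid_ml_distance(counts_fn, model, seq_a, seq_b, t_grid):
    """Grid-search ML distance oracle (see tree tests)."""
    from metalphylo.trees import pairwise_loglik
    best_t, best_ll = None, -np.inf
    for t in t_grid:
        ll = pairwise_loglik(seq_a, seq_b, model, t)
        if ll > best_ll:
            best_t, best_ll = t, ll
    return best_t


def nw_global_score(a, b, matrix, gap_open, gap_extend):
    """Affine-gap global alignment score (Gotoh), first gap residue costs
    ``gap_open``, later ones ``gap_extend``."""
    na, nb = len(a), len(b)
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in b (consumes a)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, nb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = matrix[a[i - 1]][b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[na, nb], X[na, nb], Y[na, nb])
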