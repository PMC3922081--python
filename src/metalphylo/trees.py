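"""Distance-based tree inference and tree handling.

The in-house engine computes maximum-likelihood pairwise distances under a
reversible amino-acid model (optionally +G4) and assembles topologies with
canonical neighbor joining; nonparametric bootstrap proportions are attached
by column resampling.  Externally computed trees (e.g. from full ML or
Bayesian searches) can be imported from Newick/NEXUS with their support
values auto-tagged as bootstrap percentages or posterior probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .models import SubstitutionModel, aa_to_codes

T_MAX_DEFAULT = 10.0


class UndefinedDistanceError(ValueError):
    """No shared non-gap column between two aligned sequences."""


@dataclass
class AnnotatedTree:
    """A dendropy tree plus support/metadata conventions.

    Internal-node supports live in ``node.support``; ``support_kind`` is
    ``"bootstrap"`` (percentages on [0, 100]) or ``"pp"`` (posterior
    probabilities on [0, 1]).
    """

    tree: dendropy.Tree
    support_kind: str | None = None
    n_bootstrap_dropped: int = 0

    @property
    def rooted(self) -> bool:
        return bool(self.tree.is_rooted)

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clone(self) -> "AnnotatedTree":
        t = self.tree.clone(depth=1)
        for src, dst in zip(self.tree.preorder_node_iter(),
                            t.preorder_node_iter()):
            if hasattr(src, "support"):
                dst.support = src.support
        return AnnotatedTree(t, self.support_kind, self.n_bootstrap_dropped)

    def bipartition_masks(self) -> set[int]:
        self.tree.encode_bipartitions()
        return {e.bipartition.split_bitmask
                for e in self.tree.preorder_edge_iter()
                if e.head_node.parent_node is not None}

    def as_newick(self) -> str:
        return serialize_tree(self)


def pairwise_loglik(codes_a: np.ndarray, codes_b: np.ndarray,
                    model: SubstitutionModel, t: float) -> float:
    """Independent-sites log-likelihood of an aligned pair at distance t."""
    counts = _pair_counts(codes_a, codes_b)
    return _loglik_from_counts(counts, model, t)


def _pair_counts(codes_a, codes_b) -> np.ndarray:
    mask = (codes_a >= 0) & (codes_b >= 0)
    if not mask.any():
        raise UndefinedDistanceError("no shared non-gap columns")
    counts = np.zeros((20, 20))
    np.add.at(counts, (codes_a[mask], codes_b[mask]), 1.0)
    return counts


def _loglik_from_counts(counts, model, t) -> float:
    M = model.frequencies[:, None] * model.mixture_transition(t)
    with np.errstate(divide="ignore"):
        logM = np.log(M)
    logM[counts == 0] = 0.0
    return float((counts * logM).sum())


def ml_pairwise_distance(seq_a, seq_b, model: SubstitutionModel,
                         t_max: float = T_MAX_DEFAULT) -> float:
    """ML distance between two aligned sequences (pairwise gap deletion).

    The likelihood is maximised over t >= 0 by bounded one-dimensional
    optimisation; identical sequences return exactly 0 and saturated pairs
    are capped at ``t_max`` with a warning.
    """
    a = seq_a if isinstance(seq_a, np.ndarray) else aa_to_codes(str(seq_a))
    b = seq_b if isinstance(seq_b, np.ndarray) else aa_to_codes(str(seq_b))
    if a.size != b.size:
        raise ValueError("sequences must be aligned (equal length)")
    counts = _pair_counts(a, b)
    if counts.sum() == np.trace(counts):
        return 0.0
    res = minimize_scalar(lambda t: -_loglik_from_counts(counts, model, t),
                          bounds=(1e-9, t_max), method="bounded",
                          options={"xatol": 1e-9})
    t_hat = float(res.x)
    if t_hat >= t_max - 1e-3:
        warnings.warn("pairwise distance saturated; capped at t_max")
        return t_max
    return t_hat


def distance_matrix(alignment, model: SubstitutionModel,
                    t_max: float = T_MAX_DEFAULT,
                    on_undefined: str = "raise",
                    min_shared_columns: int = 1):
    """All pairwise ML distances of an alignment.

    ``alignment`` is a MaskedAlignment (kept columns are used) or a list of
    (id, row) pairs.  Pairs sharing fewer than ``min_shared_columns``
    non-gap columns (possible when fragments are present) raise by
    default; ``on_undefined="impute"`` fills them by the shortest additive
    path through a third taxon (min_k d_ik + d_kj) — the standard remedy
    for the fragment-attraction artifact of sparse overlaps —
    ``on_undefined="tmax"`` caps them at ``t_max``.  Returns (D, labels).
    """
    ids, rows = _ids_rows(alignment)
    codes = [aa_to_codes(r) for r in rows]
    n = len(ids)
    D = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                shared = int(np.sum((codes[i] >= 0) & (codes[j] >= 0)))
                if shared < min_shared_columns:
                    raise UndefinedDistanceError(
                        f"only {shared} shared columns")
                d = ml_pairwise_distance(codes[i], codes[j], model, t_max)
            except UndefinedDistanceError:
                if on_undefined == "raise":
                    raise
                undefined.append((i, j))
                d = np.nan
            D[i, j] = D[j, i] = d
    if undefined:
        warnings.warn(f"{len(undefined)} pairs without shared columns; "
                      f"distances {'imputed' if on_undefined == 'impute' else 'capped'}")
        for i, j in undefined:
            if on_undefined == "impute":
                via = D[i, :] + D[j, :]
                via[i] = via[j] = np.nan
                d = np.nanmin(via) if np.any(np.isfinite(via)) else t_max
            else:
                d = t_max
            D[i, j] = D[j, i] = min(d, t_max)
    return D, ids


def _ids_rows(alignment):
    if hasattr(alignment, "kept_rows"):
        return list(alignment.ids), alignment.kept_rows()
    ids, rows = zip(*((r[0], r[1]) if not hasattr(r, "seq")
                      else (r.id, str(r.seq)) for r in alignment))
    return list(ids), list(rows)


def build_nj(distance_matrix, labels=None,
             taxon_namespace: dendropy.TaxonNamespace | None = None
             ) -> AnnotatedTree:
    """Canonical neighbor joining (Saitou & Nei / Studier & Keppler).

    Negative branch lengths are clamped to 0; ties in the Q criterion are
    broken deterministically toward the pair whose (lexicographically
    smallest) leaf labels sort lowest.
    """
    D = np.asarray(distance_matrix, float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.any(~np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(D, D.T) or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must be symmetric with zero "
                         "diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    ns = taxon_namespace or dendropy.TaxonNamespace()

    nodes = []
    reps = []                                # smallest leaf label per cluster
    for lab in labels:
        taxon = ns.get_taxon(lab) or ns.new_taxon(lab)
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
        reps.append(lab)
    active = list(range(n))
    D = D.copy()

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        vi = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        vj = D[i, j] - vi
        parent = dendropy.Node()
        nodes[i].edge.length = max(vi, 0.0)
        nodes[j].edge.length = max(vj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new cluster
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D[i, :] = new_row
        D[:, i] = new_row
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for idx, v in ((a, va), (b, vb), (c, vc)):
        nodes[idx].edge.length = max(v, 0.0)
        root.add_child(nodes[idx])
    tree = dendropy.Tree(seed_node=root, taxon_namespace=ns)
    tree.is_rooted = False
    return AnnotatedTree(tree)


def nj_tree(alignment, model: SubstitutionModel, taxon_namespace=None,
            on_undefined: str = "raise",
            min_shared_columns: int = 1) -> AnnotatedTree:
    """Distance matrix + NJ in one step."""
    D, ids = distance_matrix(alignment, model, on_undefined=on_undefined,
                             min_shared_columns=min_shared_columns)
    return build_nj(D, labels=ids, taxon_namespace=taxon_namespace)


def bootstrap_support(alignment, model: SubstitutionModel,
                      n_replicates: int = 100, seed: int = 0
                      ) -> AnnotatedTree:
    """Point NJ tree with nonparametric bootstrap proportions.

    Columns are resampled with replacement per replicate (replicate r uses
    seed ``seed + r``), a tree is built per replicate, and each internal
    edge of the point tree is annotated with the percentage of replicates
    containing its bipartition.  Replicates with an undefined pairwise
    distance are dropped and counted.
    """
    ids, rows = _ids_rows(alignment)
    if len(ids) < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    ns = dendropy.TaxonNamespace()
    point = nj_tree(list(zip(ids, rows)), model, taxon_namespace=ns)
    point.tree.encode_bipartitions()
    if n_replicates == 0:
        for nd in point.tree.preorder_internal_node_iter():
            nd.support = None
        return point

    width = len(rows[0])
    mats = [aa_to_codes(r) for r in rows]
    arr = np.array(mats)
    counts: dict[int, int] = {}
    n_used = 0
    n_dropped = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        cols = rng.integers(0, width, size=width)
        sub = arr[:, cols]
        try:
            n_tax = len(ids)
            D = np.zeros((n_tax, n_tax))
            for i in range(n_tax):
                for j in range(i + 1, n_tax):
                    D[i, j] = D[j, i] = ml_pairwise_distance(
                        sub[i], sub[j], model)
        except UndefinedDistanceError:
            n_dropped += 1
            continue
        rep_tree = build_nj(D, labels=ids, taxon_namespace=ns)
        n_used += 1
        for mask in rep_tree.bipartition_masks():
            counts[mask] = counts.get(mask, 0) + 1
    for edge in point.tree.preorder_edge_iter():
        nd = edge.head_node
        if nd.parent_node is None or nd.is_leaf():
            continue
        mask = edge.bipartition.split_bitmask
        nd.support = (100.0 * counts.get(mask, 0) / n_used
                      if n_used else None)
    return AnnotatedTree(point.tree, support_kind="bootstrap",
                         n_bootstrap_dropped=n_dropped)


def root_with_outgroup(atree: AnnotatedTree, outgroup_taxa) -> AnnotatedTree:
    """Root on the branch subtending the outgroup.

    If the outgroup is monophyletic in the unrooted tree the root goes on
    the branch separating it from the ingroup; otherwise the branch
    maximising outgroup/ingroup separation is used and a warning emitted.
    """
    out = atree.clone()
    tree = out.tree
    labels = set(tree.taxon_namespace.labels())
    og = {t if isinstance(t, str) else t.label for t in outgroup_taxa}
    if not og:
        raise ValueError("outgroup set is empty")
    missing = og - labels
    if missing:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(missing)}")
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if og >= present:
        raise ValueError("outgroup cannot contain every taxon")

    tree.encode_bipartitions()
    ns = tree.taxon_namespace
    og_mask = ns.taxa_bitmask(taxa=[ns.get_taxon(t) for t in og])
    all_mask = ns.taxa_bitmask(taxa=[ns.get_taxon(t) for t in present])
    n_og = len(og)
    n_in = len(present) - n_og
    best_edge, best_score, exact = None, -1.0, False
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        side = edge.bipartition.leafset_bitmask
        for mask in (side, side ^ all_mask):
            og_here = bin(mask & og_mask).count("1")
            in_here = bin(mask & all_mask & ~og_mask).count("1")
            score = og_here / n_og + (n_in - in_here) / n_in
            if mask & all_mask == og_mask:
                best_edge, exact = edge, True
                break
            if score > best_score:
                best_edge, best_score = edge, score
        if exact:
            break
    if not exact:
        warnings.warn("outgroup is not monophyletic; rooting on the branch "
                      "maximising outgroup/ingroup separation")
    length = best_edge.length or 0.0
    tree.reroot_at_edge(best_edge, length1=length / 2.0,
                        length2=length / 2.0, update_bipartitions=True)
    tree.is_rooted = True
    return AnnotatedTree(tree, out.support_kind, out.n_bootstrap_dropped)


def ladderize(atree: AnnotatedTree, direction: str = "ascending"
              ) -> AnnotatedTree:
    """Sort children by descendant-leaf count (ties: smallest leaf label).

    Idempotent; the bipartition set is unchanged.
    """
    out = atree.clone()
    sign = 1 if direction == "ascending" else -1

    def key(node):
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        return (sign * len(leaves), min(leaves))

    for nd in out.tree.postorder_internal_node_iter():
        nd.set_child_nodes(sorted(nd.child_nodes(), key=key))
    return out


def import_tree(source, schema: str = "newick") -> AnnotatedTree:
    """Read a Newick/NEXUS tree, auto-tagging internal-node supports.

    Internal node labels that parse as numbers become supports; if every
    support is <= 1 they are tagged posterior probabilities, otherwise
    bootstrap percentages.
    """
    kwargs = dict(schema=schema)
    if schema == "newick":
        kwargs["preserve_underscores"] = True
    try:
        if isinstance(source, str) and ("(" in source or ";" in source):
            tree = dendropy.Tree.get(data=source, **kwargs)
        else:
            tree = dendropy.Tree.get(path=source, **kwargs)
    except Exception as exc:
        raise ValueError(f"could not parse tree ({schema}): {exc}") from exc
    supports = []
    for nd in tree.preorder_internal_node_iter():
        val = None
        if nd.label is not None:
            try:
                val = float(nd.label)
            except ValueError:
                val = None
        nd.support = val
        if val is not None:
            supports.append(val)
    kind = None
    if supports:
        kind = "pp" if max(supports) <= 1.0 else "bootstrap"
    return AnnotatedTree(tree, support_kind=kind)


def serialize_tree(atree: AnnotatedTree, path=None, schema: str = "newick",
                   support_digits: int = 4) -> str | None:
    """Write supports back into internal labels and serialise."""
    out = atree.clone()
    for nd in out.tree.preorder_internal_node_iter():
        sup = getattr(nd, "support", None)
        if sup is not None:
            nd.label = f"{sup:.{support_digits}g}"
    txt = out.tree.as_string(schema=schema, suppress_rooting=False,
                             unquoted_underscores=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(txt)
        return None
    return txt


def bipartition_support(atree: AnnotatedTree, leaf_set) -> float | None:
    """Support of the edge splitting ``leaf_set`` from the rest, if present.

    Returns the support value of the internal edge whose bipartition
    matches the given leaf set (or its complement), or ``None`` when the
    tree does not contain that bipartition.
    """
    tree = atree.tree
    want = set(leaf_set)
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    comp = all_leaves - want
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        here = {lf.taxon.label for lf in nd.leaf_iter()}
        if here == want or here == comp:
            sup = getattr(nd, "support", None)
            if sup is not None:       # a rerooted twin edge may lack one
                return sup
    return None


def rf_distance(a: AnnotatedTree, b: AnnotatedTree) -> int:
    """Unrooted Robinson-Foulds distance between two trees' topologies."""
    ns = dendropy.TaxonNamespace()
    trees = []
    for at in (a, b):
        t = dendropy.Tree.get(data=at.tree.as_string(schema="newick"),
                              schema="newick", taxon_namespace=ns,
                              preserve_underscores=True)
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
        trees.append(t)
    from dendropy.calculate import treecompare
    return int(treecompare.symmetric_difference(*trees))
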