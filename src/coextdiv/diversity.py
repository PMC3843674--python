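"""Tree-based diversity metrics: FD, PD and quadratic-entropy originality.

Functional diversity (FD) and phylogenetic diversity (PD) are both
measured as the summed branch length needed to connect the surviving
species on a fixed tree — the functional dendrogram (built from LHS
trait distances by UPGMA) or the dated phylogeny.  The single
behavioural difference between them is the root: FD excludes the path
above the most recent common ancestor of the survivors, so FD of one
species is zero, whereas PD includes the root path, so PD of one
species is that species' root-to-leaf distance.

Species "originality" quantifies each species' relative contribution to
tree-based diversity: it is the weight vector on the simplex that
maximizes Rao's quadratic entropy for the tree's cophenetic distance
matrix.  Weights are nonnegative and sum to one.
"""
from __future__ import annotations

import numpy as np
import pandas as _pandas
import dendropy
from skbio import DistanceMatrix

from .errors import IncomputableDistanceError, InvalidArgumentError
from .io import TRAIT_COLUMNS
from .trees import TreeIndex

__all__ = [
    "trait_distance_matrix",
    "upgma",
    "fd",
    "pd",
    "originality",
    "total_originality",
]


def trait_distance_matrix(traits, standardize: bool = True,
                          log_transform=()) -> DistanceMatrix:
    """Pairwise Euclidean trait distances with pairwise-available handling
    of missing values.

    For each species pair the squared differences are summed over the
    traits non-missing in *both* species and the distance is rescaled by
    ``sqrt(n_traits / t_shared)`` so that species pairs with fewer shared
    traits are comparable to fully observed pairs.  ``log_transform``
    names traits to log10-transform first; with ``standardize`` each
    trait is z-scored across species (traits live on wildly different
    scales: mm^2/mg, m, mg).

    Raises
    ------
    IncomputableDistanceError
        If some species pair shares no non-missing trait.
    """
    traits = traits[list(TRAIT_COLUMNS)].astype(float).copy()
    for name in log_transform:
        if name not in traits.columns:
            raise InvalidArgumentError(f"unknown trait {name!r}")
        traits[name] = np.log10(traits[name])
    values = traits.to_numpy()
    present = ~np.isnan(values)
    if standardize:
        mean = np.nanmean(values, axis=0)
        std = np.nanstd(values, axis=0, ddof=1)
        std[~(std > 0)] = 1.0
        values = (values - mean) / std
    filled = np.where(present, values, 0.0)
    n_traits = values.shape[1]
    # shared[i, j] = number of traits present in both i and j
    shared = present.astype(float) @ present.T.astype(float)
    # squared differences restricted to shared traits; filled is zero where
    # absent so the cross term already only counts shared traits
    sq_shared = np.einsum("it,jt->ij", filled ** 2 * present, present.astype(float))
    diff2 = sq_shared + sq_shared.T - 2 * filled @ filled.T
    labels = [str(s) for s in traits.index]
    none_shared = (shared == 0) & ~np.eye(len(labels), dtype=bool)
    if none_shared.any():
        i, j = np.argwhere(none_shared)[0]
        raise IncomputableDistanceError(
            f"species {labels[i]!r} and {labels[j]!r} share no non-missing trait")
    with np.errstate(invalid="ignore"):
        dist = np.sqrt(np.maximum(diff2, 0.0) * (n_traits / np.maximum(shared, 1)))
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    return DistanceMatrix(dist, ids=labels)


def upgma(d: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) clustering of a distance matrix into an
    ultrametric rooted dendrogram.

    Node height equals half the average linkage distance at the merge,
    so cophenetic distances of the output reproduce the input whenever
    the input is ultrametric.  Tied merge distances are broken by the
    lexicographically lowest label pair (each cluster represented by its
    smallest member label), making the dendrogram reproducible across
    platforms.
    """
    labels = list(d.ids)
    if len(labels) < 2:
        raise InvalidArgumentError("UPGMA needs at least 2 labels")
    dist = np.array(d.data, dtype=float)
    if not np.all(np.isfinite(dist)):
        raise InvalidArgumentError("non-finite distances")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = {}
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[lab] = node
    # cluster state: key -> (members, size, height, node); key = min label
    clusters = {lab: ([lab], 1, 0.0, nodes[lab]) for lab in labels}
    # working distance dict between cluster keys
    cur = {}
    pos = {lab: i for i, lab in enumerate(labels)}
    keys = sorted(labels)
    for a in keys:
        for b in keys:
            if a < b:
                cur[(a, b)] = dist[pos[a], pos[b]]

    while len(clusters) > 1:
        best = min(cur.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), dmin = best
        mem_a, na, ha, node_a = clusters.pop(a)
        mem_b, nb, hb, node_b = clusters.pop(b)
        height = dmin / 2.0
        parent = dendropy.Node()
        node_a.edge.length = height - ha
        node_b.edge.length = height - hb
        parent.add_child(node_a)
        parent.add_child(node_b)
        new_key = min(a, b)
        # average-linkage update
        for other in list(clusters):
            ka = tuple(sorted((a, other)))
            kb = tuple(sorted((b, other)))
            dnew = (na * cur.pop(ka) + nb * cur.pop(kb)) / (na + nb)
            cur[tuple(sorted((new_key, other)))] = dnew
        cur.pop((a, b), None)
        clusters[new_key] = (mem_a + mem_b, na + nb, height, parent)

    (_, _, _, root) = next(iter(clusters.values()))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def fd(tree: dendropy.Tree, extant) -> float:
    """Functional diversity of an extant species set on a fixed tree.

    Summed branch length of the minimal subtree spanning the extant
    leaves, excluding the path above their MRCA; 0 for zero or one
    species.
    """
    return TreeIndex(tree).fd(extant)


def pd(tree: dendropy.Tree, extant) -> float:
    """Phylogenetic diversity (root path included) of an extant set."""
    return TreeIndex(tree).pd(extant)


def _qe_weights(delta: np.ndarray) -> np.ndarray:
    """Weights on the simplex maximizing the quadratic entropy w'Dw/2.

    Solved as an equality-constrained quadratic program with active-set
    handling of the nonnegativity constraints: solve on the current
    support, drop the most negative weight, re-admit any excluded
    species whose KKT gradient condition is violated.
    """
    n = delta.shape[0]
    support = np.ones(n, dtype=bool)
    tol = 1e-10
    w = np.full(n, 1.0 / n)
    for _ in range(4 * n + 8):
        idx = np.flatnonzero(support)
        k = len(idx)
        if k == 1:
            w = np.zeros(n)
            w[idx] = 1.0
        else:
            sub = delta[np.ix_(idx, idx)]
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = 2 * sub
            kkt[:k, k] = -1.0
            kkt[k, :k] = 1.0
            rhs = np.zeros(k + 1)
            rhs[k] = 1.0
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            w = np.zeros(n)
            w[idx] = sol[:k]
        if w.min() < -tol:
            support[np.argmin(w)] = False
            continue
        # KKT check for excluded species: gradient must not beat the
        # multiplier (maximization), otherwise re-admit the worst violator
        grad = 2 * delta @ np.maximum(w, 0.0)
        nu = grad[support].mean() if support.any() else 0.0
        excluded = ~support
        if excluded.any():
            viol = grad - nu
            viol[support] = -np.inf
            if viol.max() > 1e-8:
                support[int(np.argmax(viol))] = True
                continue
        break
    w = np.maximum(w, 0.0)
    return w / w.sum()


def originality(tree: dendropy.Tree) -> _pandas.Series:
    """Quadratic-entropy-maximizing originality weights of a tree's leaves.

    Computed from the cophenetic distance matrix of the full tree (the
    complete pre-extinction assemblage); nonnegative, summing to 1.
    Non-ultrametric trees trigger a warning but are processed on their
    cophenetic distances as given.
    """
    import warnings

    from .trees import is_ultrametric

    index = TreeIndex(tree)
    if index.n_leaves < 2:
        raise InvalidArgumentError("originality needs at least 2 leaves")
    if not is_ultrametric(tree, rel_tol=1e-6):
        warnings.warn("tree is not ultrametric; originality computed on its "
                      "cophenetic distances as given", stacklevel=2)
    delta = np.array(index.cophenetic().data, dtype=float)
    weights = _qe_weights(delta)
    return _pandas.Series(weights, index=index.labels, name="originality")


def total_originality(orig: _pandas.Series, extant) -> float:
    """Sum of originality weights over the extant species (in [0, 1])."""
    extant = list(extant)
    unknown = set(extant) - set(orig.index)
    if unknown:
        raise InvalidArgumentError(f"labels not in originality vector: {sorted(unknown)}")
    if not extant:
        return 0.0
    return float(orig.loc[extant].sum())
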