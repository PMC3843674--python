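"""Rooted trees with branch lengths and fast tree-metric machinery.

Trees (functional dendrograms and dated phylogenies alike) are held as
:class:`dendropy.Tree` objects.  :class:`TreeIndex` precomputes an
edge-by-leaf incidence structure so that subtree-length diversity
metrics (FD, PD) and cophenetic distances can be evaluated with a few
matrix operations, which matters when scoring tens of thousands of
simulated extinction states.
"""
from __future__ import annotations

import numpy as np
import dendropy
from skbio import DistanceMatrix

from .errors import FormatError, InvalidArgumentError

__all__ = [
    "read_phylogeny",
    "write_newick",
    "prune_tree",
    "leaf_labels",
    "tree_height",
    "is_ultrametric",
    "total_branch_length",
    "TreeIndex",
]


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Leaf taxon labels in tree (leaf-iteration) order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def read_phylogeny(path) -> dendropy.Tree:
    """Read a rooted Newick tree, requiring branch lengths on all edges.

    The root (seed) edge may carry a length or not; every other edge
    must have one.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: cannot parse Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise FormatError(f"{path}: edge above {label} has no branch length")
        if node.edge.length < 0:
            label = node.taxon.label if node.taxon else "<internal>"
            raise FormatError(f"{path}: negative branch length above {label}")
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate leaf labels")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def prune_tree(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Restrict a tree to the leaf set ``keep``.

    Degree-2 internal nodes created by the pruning are collapsed by
    summing adjacent branch lengths.  The path from the original root
    down to the most recent common ancestor of ``keep`` is preserved as
    a root-edge length, so root-inclusive metrics (PD) keep their
    original root convention.
    """
    keep = set(keep)
    if not keep:
        raise InvalidArgumentError("keep must contain at least one leaf label")
    labels = set(leaf_labels(tree))
    unknown = keep - labels
    if unknown:
        raise InvalidArgumentError(f"labels not in tree: {sorted(unknown)}")
    pruned = clone_tree(tree)
    if keep == labels:
        return pruned
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-leaf path length (excluding any root-edge length)."""
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
    height = max(depths)
    if height == 0:
        return True
    return (max(depths) - min(depths)) <= rel_tol * height


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths, including a root-edge length if present."""
    return float(sum(e.length or 0.0 for e in tree.preorder_edge_iter()))


class TreeIndex:
    """Edge-by-leaf incidence index of a rooted tree.

    Attributes
    ----------
    labels : list of str
        Leaf labels; all mask arguments are ordered like this.
    lengths : ndarray of shape (n_edges,)
        Branch length of each indexed edge.  A root-edge length (if the
        tree carries one) is indexed as an edge subtending every leaf.
    incidence : bool ndarray of shape (n_edges, n_leaves)
        ``incidence[e, i]`` is True when leaf ``i`` descends from edge ``e``.
    """

    def __init__(self, tree: dendropy.Tree):
        leaves = list(tree.leaf_node_iter())
        self.labels = [lf.taxon.label for lf in leaves]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        n = len(leaves)
        rows, lengths = [], []
        below: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(n, dtype=bool)
                mask[index[id(node)]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for child in node.child_nodes():
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node is tree.seed_node:
                if node.edge.length:  # explicit root-edge length
                    rows.append(mask)
                    lengths.append(float(node.edge.length))
            else:
                rows.append(mask)
                lengths.append(float(node.edge.length or 0.0))
        self.incidence = np.array(rows, dtype=bool)
        self.lengths = np.asarray(lengths, dtype=float)
        self._label_pos = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def mask(self, extant) -> np.ndarray:
        """Boolean leaf mask for a collection of leaf labels."""
        mask = np.zeros(self.n_leaves, dtype=bool)
        for lab in extant:
            try:
                mask[self._label_pos[lab]] = True
            except KeyError:
                raise InvalidArgumentError(f"unknown leaf label {lab!r}") from None
        return mask

    # --- diversity metrics -------------------------------------------------
    def fd_masks(self, masks: np.ndarray) -> np.ndarray:
        """Functional diversity of each row of ``masks``.

        FD is the summed branch length of the minimal subtree spanning
        the extant leaves, excluding the path above their most recent
        common ancestor; FD of zero or one species is 0.
        """
        masks = np.atleast_2d(np.asarray(masks, dtype=bool))
        counts = self.incidence.astype(np.float64) @ masks.T.astype(np.float64)
        totals = masks.sum(axis=1)[None, :]
        inside = (counts >= 1) & (counts <= totals - 1)
        return self.lengths @ inside

    def pd_masks(self, masks: np.ndarray) -> np.ndarray:
        """Phylogenetic diversity of each row of ``masks``.

        PD is the summed branch length connecting the extant leaves and
        the root (root path included); PD of a single species is its
        root-to-leaf path length, PD of no species is 0.
        """
        masks = np.atleast_2d(np.asarray(masks, dtype=bool))
        counts = self.incidence.astype(np.float64) @ masks.T.astype(np.float64)
        return self.lengths @ (counts >= 1)

    def fd(self, extant) -> float:
        return float(self.fd_masks(self.mask(extant))[0])

    def pd(self, extant) -> float:
        return float(self.pd_masks(self.mask(extant))[0])

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise path-length distances between leaves."""
        weighted = self.incidence * self.lengths[:, None]
        shared = weighted.T @ self.incidence  # shared root-path length
        depth = np.diag(shared)
        dist = depth[:, None] + depth[None, :] - 2 * shared
        dist = np.maximum(dist, 0.0)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        return DistanceMatrix(dist, ids=self.labels)
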