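"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (path
enumeration, exhaustive recursion, dense grids, double loops) and never
calls the implementation paths it is used to check.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
import dendropy


# --- tree metrics by explicit path-union enumeration -----------------------

def _leaf_by_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == label:
            return lf
    raise KeyError(label)


def _path_to_root(node: dendropy.Node, tree: dendropy.Tree):
    """Edges (as node ids with lengths) from node up to and including the
    seed node's own edge when it has a length."""
    edges = []
    cur = node
    while cur is not tree.seed_node:
        edges.append((id(cur), cur.edge.length or 0.0))
        cur = cur.parent_node
    if tree.seed_node.edge.length:
        edges.append((id(tree.seed_node), tree.seed_node.edge.length))
    return edges


def brute_pd(tree: dendropy.Tree, extant) -> float:
    """Union of root paths of the extant leaves."""
    extant = list(extant)
    if not extant:
        return 0.0
    union: dict[int, float] = {}
    for label in extant:
        for key, length in _path_to_root(_leaf_by_label(tree, label), tree):
            union[key] = length
    return sum(union.values())


def brute_fd(tree: dendropy.Tree, extant) -> float:
    """Union of pairwise leaf-to-leaf paths (edge sets up to the MRCA)."""
    extant = list(extant)
    if len(extant) < 2:
        return 0.0
    union: dict[int, float] = {}
    for a, b in itertools.combinations(extant, 2):
        pa = _path_to_root(_leaf_by_label(tree, a), tree)
        pb = _path_to_root(_leaf_by_label(tree, b), tree)
        keys_b = {k for k, _ in pb}
        keys_a = {k for k, _ in pa}
        for key, length in pa:
            if key not in keys_b:
                union[key] = length
        for key, length in pb:
            if key not in keys_a:
                union[key] = length
    return sum(union.values())


# --- quadratic-entropy maximization by dense grid search -------------------

def _simplex_grid(k: int, step: float):
    """All grid points on the (k-1)-simplex with the given step."""
    m = int(round(1.0 / step))
    for combo in itertools.combinations_with_replacement(range(k), m):
        counts = [0] * k
        for c in combo:
            counts[c] += 1
        yield np.array(counts, dtype=float) / m


def grid_qe_argmax(delta: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Dense single-stage grid search of argmax_w w'Dw on the simplex
    (vectorized in chunks; the grid itself is exhaustive)."""
    best, best_val = None, -np.inf
    chunk: list[np.ndarray] = []

    def flush(best, best_val):
        if not chunk:
            return best, best_val
        arr = np.vstack(chunk)
        vals = np.einsum("ni,ij,nj->n", arr, delta, arr)
        top = int(np.argmax(vals))
        if vals[top] > best_val:
            return arr[top], float(vals[top])
        return best, best_val

    for w in _simplex_grid(delta.shape[0], step):
        chunk.append(w)
        if len(chunk) == 200_000:
            best, best_val = flush(best, best_val)
            chunk = []
    best, best_val = flush(best, best_val)
    return best


def grid_qe_argmax_refined(delta: np.ndarray, coarse: float = 0.01,
                           fine: float = 1e-3) -> np.ndarray:
    """Two-stage grid search: dense coarse pass, then a fine pass over the
    coarse optimum's neighbourhood (effective resolution = fine step)."""
    k = delta.shape[0]
    w0 = grid_qe_argmax(delta, step=coarse)
    m = int(round(1.0 / fine))
    base = np.round(w0 * m).astype(int)
    radius = int(round(coarse / fine))
    ranges = [range(max(0, b - radius), min(m, b + radius) + 1) for b in base[:-1]]
    best, best_val = w0, w0 @ delta @ w0
    for combo in itertools.product(*ranges):
        last = m - sum(combo)
        if last < 0 or abs(last - base[-1]) > radius:
            continue
        w = np.array(list(combo) + [last], dtype=float) / m
        val = w @ delta @ w
        if val > best_val:
            best_val, best = val, w
    return best


# --- exact enumeration of one coextinction episode -------------------------

def enumerate_episode_outcomes(counts: np.ndarray, r_plant: float = 1.0,
                               r_animal: float = 1.0) -> dict[frozenset, float]:
    """Exact distribution over surviving-plant index sets after the first
    primary-extinction episode.

    Expands the full probability tree: primary target choice with
    probability proportional to inverse row totals, then alternating
    cascade waves in which every surviving counterpart falls
    independently with probability 1 - prod(1 - R*d) over the wave's
    losses — or exactly R if the wave removed all of its remaining
    partners — with dependences computed from the matrix in which the
    newly lost species were still alive.
    """
    counts = np.asarray(counts, dtype=float)
    npol, npl = counts.shape
    out: dict[frozenset, float] = {}

    def wave(prob, pol_alive, pl_alive, newly, side):
        """newly: indices just lost (still included in the alive sets)."""
        sub = counts.copy()
        sub[[i for i in range(npol) if i not in pol_alive], :] = 0.0
        sub[:, [j for j in range(npl) if j not in pl_alive]] = 0.0
        if side == "pollinator":
            pol_alive = pol_alive - newly
            targets = sorted(pl_alive)
            p_fall = []
            for j in targets:
                tot = sub[:, j].sum()
                lost = sum(sub[i, j] for i in newly)
                if tot > 0 and lost == tot:  # complete partner loss
                    p_fall.append(r_plant)
                    continue
                keep = 1.0
                for i in newly:
                    d = sub[i, j] / tot if tot > 0 else 0.0
                    keep *= 1.0 - r_plant * d
                p_fall.append(1.0 - keep)
        else:
            pl_alive = pl_alive - newly
            targets = sorted(pol_alive)
            p_fall = []
            for i in targets:
                tot = sub[i, :].sum()
                lost = sum(sub[i, j] for j in newly)
                if tot > 0 and lost == tot:  # complete partner loss
                    p_fall.append(r_animal)
                    continue
                keep = 1.0
                for j in newly:
                    d = sub[i, j] / tot if tot > 0 else 0.0
                    keep *= 1.0 - r_animal * d
                p_fall.append(1.0 - keep)
        if not targets:
            out[frozenset(pl_alive)] = out.get(frozenset(pl_alive), 0.0) + prob
            return
        for fallen_flags in itertools.product([False, True], repeat=len(targets)):
            p_branch = prob
            fallen = set()
            for t, flag, pf in zip(targets, fallen_flags, p_fall):
                p_branch *= pf if flag else (1.0 - pf)
                if flag:
                    fallen.add(t)
            if p_branch == 0.0:
                continue
            if not fallen:
                out[frozenset(pl_alive)] = out.get(frozenset(pl_alive), 0.0) + p_branch
            else:
                next_side = "plant" if side == "pollinator" else "pollinator"
                wave(p_branch, frozenset(pol_alive), frozenset(pl_alive),
                     frozenset(fallen), next_side)

    totals = counts.sum(axis=1)
    inv = 1.0 / totals
    probs = inv / inv.sum()
    for primary in range(npol):
        wave(probs[primary], frozenset(range(npol)), frozenset(range(npl)),
             frozenset([primary]), "pollinator")
    return out


# --- exact random-removal reference expectation ----------------------------

def exact_random_reference(tree: dendropy.Tree, labels: list[str],
                           metric: str) -> np.ndarray:
    """Exact expectation of the random removal-order decline curve by
    enumeration of all |labels|! orders; metric computed by the brute
    oracles."""
    n = len(labels)
    fn = brute_fd if metric == "FD" else brute_pd
    total = np.zeros(n + 1)
    n_orders = 0
    for order in itertools.permutations(labels):
        for k in range(n + 1):
            total[k] += fn(tree, order[k:])
        n_orders += 1
    return total / n_orders


# --- Moran's I by direct double loop ---------------------------------------

def brute_morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    n = len(values)
    xbar = sum(values) / n
    num = 0.0
    wsum = 0.0
    for i in range(n):
        for j in range(n):
            num += weights[i, j] * (values[i] - xbar) * (values[j] - xbar)
            wsum += weights[i, j]
    den = sum((v - xbar) ** 2 for v in values)
    return (n / wsum) * num / den


# --- Spearman exact p by enumeration ---------------------------------------

def brute_spearman_exact_p(x, y) -> float:
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    obs = abs(rho(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        if abs(rho(rx, ry[list(perm)])) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
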