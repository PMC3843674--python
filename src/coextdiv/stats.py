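"""Persistence-originality correlations and Moran's I correlograms.

Two questions are addressed after the simulations: (1) do functionally
or phylogenetically original plants persist longer or shorter than
average (Spearman rank tests of mean persistence against originality),
and (2) do functionally or phylogenetically similar plants share a
similar coextinction risk (Moran's I correlograms of persistence over
distance classes of the functional dendrogram and the phylogeny)?  A
phylogenetic correlogram of functional originality serves as the
phylogenetic-signal check that links the two diversity dimensions.

Moran's I per distance class uses binary weights (w_ij = 1 when the
pair's distance falls in the class) with equal-frequency classes, and a
permutation test for significance.  No spatial-autocorrelation package
in the scientific Python stack provides distance-class correlograms on
arbitrary distance matrices, so the statistic is computed directly from
its definition here.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy
from scipy import stats as sps
from skbio import DistanceMatrix

from .errors import InvalidArgumentError
from .trees import TreeIndex

__all__ = [
    "SpearmanResult",
    "CorrelogramResult",
    "spearman_test",
    "cophenetic_distances",
    "morans_correlogram",
    "run_statistics",
]


@dataclass(frozen=True)
class SpearmanResult:
    rs: float
    p: float
    n: int
    method: str  # "exact" or "t-approximation"


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_test(x, y, exact_max_n: int = 10) -> SpearmanResult:
    """Spearman rank correlation with a two-sided significance test.

    Average ranks are used for ties.  For n <= ``exact_max_n`` the
    p-value comes from exhaustive enumeration of all n! pairings of the
    rank vectors; for larger n the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise InvalidArgumentError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidArgumentError("correlation undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    rs = float(rx_c @ ry_c) / denom
    if n <= exact_max_n:
        hits = 0
        total = 0
        chunk = []
        for perm in itertools.permutations(range(n)):
            chunk.append(perm)
            if len(chunk) == 100_000:
                rs_all = (ry_c[np.array(chunk, dtype=np.intp)] @ rx_c) / denom
                hits += int((np.abs(rs_all) >= abs(rs) - 1e-12).sum())
                total += len(chunk)
                chunk = []
        if chunk:
            rs_all = (ry_c[np.array(chunk, dtype=np.intp)] @ rx_c) / denom
            hits += int((np.abs(rs_all) >= abs(rs) - 1e-12).sum())
            total += len(chunk)
        return SpearmanResult(rs=rs, p=hits / total, n=n, method="exact")
    t = rs * math.sqrt((n - 2) / max(1e-300, 1.0 - rs * rs))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rs=rs, p=min(p, 1.0), n=n, method="t-approximation")


def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise path-length distances between the leaves of a tree."""
    index = TreeIndex(tree)
    if index.n_leaves < 2:
        raise InvalidArgumentError("need at least 2 leaves")
    return index.cophenetic()


@dataclass(frozen=True)
class CorrelogramResult:
    """Moran's I per distance class with permutation p-values."""

    lower: np.ndarray
    upper: np.ndarray
    n_pairs: np.ndarray
    morans_i: np.ndarray
    expected_i: float
    p_values: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.lower)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": np.arange(1, self.n_classes + 1),
            "lower": self.lower, "upper": self.upper,
            "n_pairs": self.n_pairs, "I": self.morans_i,
            "expected_I": self.expected_i, "p": self.p_values,
        })


def _distance_classes(dist: np.ndarray, n_classes: int):
    """Equal-frequency class edges over the upper-triangle distances."""
    iu = np.triu_indices_from(dist, k=1)
    pair_d = dist[iu]
    edges = np.quantile(pair_d, np.linspace(0, 1, n_classes + 1))
    # class c covers [edge_c, edge_{c+1}), the last class is closed above;
    # a distance equal to an internal edge goes to the upper class so that
    # heavily tied distance distributions still separate into classes
    labels = np.searchsorted(edges[1:-1], pair_d, side="right")
    return iu, edges, labels


def morans_correlogram(values, d: DistanceMatrix, n_classes: int = 4,
                       n_perm: int = 999, seed: int | None = None
                       ) -> CorrelogramResult:
    """Moran's I of ``values`` within equal-frequency distance classes.

    Per class c, with binary weights w_ij = 1 when d_ij falls in c:
    ``I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``.
    Two-sided significance from ``n_perm`` random permutations of the
    values, with the observed statistic included in the null set:
    ``p = (1 + #{|I_perm| >= |I_obs|}) / (n_perm + 1)``.
    """
    if isinstance(values, pd.Series):
        values = values.reindex(list(d.ids)).to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    n = values.size
    if n != len(d.ids):
        raise InvalidArgumentError("values and distance matrix are misaligned")
    if n_classes < 1:
        raise InvalidArgumentError("n_classes must be >= 1")
    if n_perm < 99:
        raise InvalidArgumentError("n_perm must be >= 99")
    if np.ptp(values) == 0:
        raise InvalidArgumentError("Moran's I undefined for constant values")
    dist = np.array(d.data, dtype=float)
    iu, edges, labels = _distance_classes(dist, n_classes)
    rng = np.random.default_rng(seed)
    perms = np.vstack([np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)])
    x = values - values.mean()
    denom_all = (x @ x)
    lowers, uppers, counts, i_obs, p_vals = [], [], [], [], []
    for c in range(n_classes):
        sel = labels == c
        lowers.append(float(edges[c]))
        uppers.append(float(edges[c + 1]))
        m = int(sel.sum())
        counts.append(m)
        if m == 0:
            i_obs.append(np.nan)
            p_vals.append(np.nan)
            continue
        rows = iu[0][sel]
        cols = iu[1][sel]
        w_total = 2.0 * m  # symmetric weights
        xp = x[perms]  # (n_perm + 1, n)
        cross = 2.0 * (xp[:, rows] * xp[:, cols]).sum(axis=1)
        i_all = (n / w_total) * cross / denom_all
        obs = i_all[0]
        p = float((np.abs(i_all) >= abs(obs) - 1e-12).sum()) / (n_perm + 1)
        i_obs.append(float(obs))
        p_vals.append(p)
    return CorrelogramResult(
        lower=np.array(lowers), upper=np.array(uppers),
        n_pairs=np.array(counts), morans_i=np.array(i_obs),
        expected_i=-1.0 / (n - 1), p_values=np.array(p_vals),
    )


@dataclass(frozen=True)
class StatisticsReport:
    spearman: pd.DataFrame
    correlograms: dict[str, CorrelogramResult]
    degenerate: bool = False
    note: str = ""

    def correlogram_frame(self) -> pd.DataFrame:
        frames = []
        for name, result in self.correlograms.items():
            frame = result.to_frame()
            frame.insert(0, "analysis", name)
            frames.append(frame)
        if not frames:
            return pd.DataFrame(columns=["analysis", "class", "lower", "upper",
                                         "n_pairs", "I", "expected_I", "p"])
        return pd.concat(frames, ignore_index=True)


def run_statistics(mean_persistence: pd.Series, orig_functional: pd.Series,
                   orig_phylogenetic: pd.Series, dendrogram: dendropy.Tree,
                   phylogeny: dendropy.Tree, n_classes: int = 4,
                   n_perm: int = 999, seed: int | None = None
                   ) -> StatisticsReport:
    """Assemble the three post-simulation analyses.

    (1) Spearman tests of mean persistence against functional and
    phylogenetic originality; (2) correlograms of persistence on
    functional and phylogenetic distances; (3) the phylogenetic
    correlogram of functional originality (phylogenetic-signal check).
    Degenerate inputs (constant persistence) are reported as such
    instead of producing numbers.
    """
    plants = list(mean_persistence.index)
    if np.ptp(mean_persistence.to_numpy(dtype=float)) == 0:
        return StatisticsReport(
            spearman=pd.DataFrame(columns=["comparison", "rs", "p", "n"]),
            correlograms={}, degenerate=True,
            note="persistence is identical for all plants; correlations and "
                 "correlograms are undefined")
    d_fun = cophenetic_distances(dendrogram).filter(plants)
    d_phy = cophenetic_distances(phylogeny).filter(plants)
    ss = np.random.SeedSequence(seed).spawn(3)
    rows = []
    for name, orig in (("persistence_vs_functional_originality", orig_functional),
                       ("persistence_vs_phylogenetic_originality", orig_phylogenetic)):
        res = spearman_test(mean_persistence.to_numpy(dtype=float),
                            orig.reindex(plants).to_numpy(dtype=float))
        rows.append({"comparison": name, "rs": res.rs, "p": res.p, "n": res.n})
    correlograms = {
        "persistence_on_functional_distance": morans_correlogram(
            mean_persistence, d_fun, n_classes, n_perm,
            seed=int(ss[0].generate_state(1)[0] % (2 ** 31))),
        "persistence_on_phylogenetic_distance": morans_correlogram(
            mean_persistence, d_phy, n_classes, n_perm,
            seed=int(ss[1].generate_state(1)[0] % (2 ** 31))),
        "functional_originality_on_phylogenetic_distance": morans_correlogram(
            orig_functional.reindex(plants), d_phy, n_classes, n_perm,
            seed=int(ss[2].generate_state(1)[0] % (2 ** 31))),
    }
    return StatisticsReport(spearman=pd.DataFrame(rows),
                            correlograms=correlograms)
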