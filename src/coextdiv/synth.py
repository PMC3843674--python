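"""Synthetic communities with the statistical structure the analysis assumes.

Real inputs to the pipeline are a quantitative visitation matrix, an
LHS trait table and a dated plant phylogeny.  This module generates all
three with controllable structure so every downstream stage can be
exercised and calibrated without external data: sparse bipartite
networks with heavy-tailed (lognormal) visit counts, pure-birth (Yule)
ultrametric phylogenies, and three continuous traits evolving along the
tree by Brownian motion (phylogenetic signal) or drawn independently
per species (no signal).

Traits evolve on the log10 scale — SLA, canopy height and seed mass are
classic log-normally distributed traits — and are mapped to positive
measurement units via trait-specific baselines, so generated tables
satisfy the positivity rules of the on-disk format.  The latent (log)
values are exposed separately for calibration work.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy

from .errors import InvalidArgumentError
from .io import TRAIT_COLUMNS, read_traits, write_traits
from .network import QuantitativeNetwork, read_network, write_network
from .trees import read_phylogeny, write_newick

__all__ = [
    "SynthConfig",
    "simulate_phylogeny",
    "simulate_latent_traits",
    "simulate_traits",
    "simulate_network",
    "FixtureBundle",
    "make_fixture",
]

#: typical magnitudes used to map latent log10 trait values onto
#: measurement units (SLA mm^2/mg, height m, seed mass mg)
TRAIT_BASELINES = {"sla": 20.0, "height": 0.5, "seed_mass": 1.0}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic plant-pollinator community.

    ``count_mu`` / ``count_sigma`` are the log-mean and log-sd of the
    lognormal visit-count law (counts are rounded up to >= 1; with both
    zero the law degenerates to all counts = 1).  ``birth_rate`` is the
    per-lineage speciation rate of the Yule phylogeny, ``trait_sigma``
    the Brownian diffusion (or iid sd) of the latent log10 traits per
    unit branch length.
    """

    n_plants: int = 20
    n_pollinators: int = 30
    connectance: float = 0.2
    count_mu: float = 1.0
    count_sigma: float = 1.0
    birth_rate: float = 1.0
    trait_model: str = "brownian"
    trait_sigma: float = 0.5
    missing_rate: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.n_plants < 1 or self.n_pollinators < 1:
            raise InvalidArgumentError("need at least one species per side")
        if not 0.0 < self.connectance <= 1.0:
            raise InvalidArgumentError("connectance must lie in (0, 1]")
        links = self.connectance * self.n_plants * self.n_pollinators
        if links < max(self.n_plants, self.n_pollinators):
            raise InvalidArgumentError(
                "infeasible connectance: too few links for every species to "
                "receive at least one interaction")
        if self.count_sigma < 0:
            raise InvalidArgumentError("count_sigma must be >= 0")
        if self.birth_rate <= 0:
            raise InvalidArgumentError("birth_rate must be > 0")
        if self.trait_model not in ("brownian", "iid"):
            raise InvalidArgumentError(
                f"trait_model must be 'brownian' or 'iid', got {self.trait_model!r}")
        if self.trait_sigma <= 0:
            raise InvalidArgumentError("trait_sigma must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidArgumentError("missing_rate must lie in [0, 1)")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_phylogeny(n_species: int, birth_rate: float = 1.0,
                       seed=None) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth (Yule) tree.

    The process starts with two lineages at the root; with k lineages
    the next speciation arrives after an Exp(k * birth_rate) waiting
    time on a uniformly chosen lineage.  After the n-th lineage appears
    the tree is extended by a final Exp(n * birth_rate) interval, so no
    terminal branch has zero length.  Leaves are labelled p1..pN in leaf
    order.
    """
    if n_species < 2:
        raise InvalidArgumentError("n_species must be >= 2")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be > 0")
    rng = _as_rng(seed)
    root = dendropy.Node()
    alive: list[tuple[dendropy.Node, float]] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        alive.append((child, t))
    while len(alive) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(alive)))
        idx = int(rng.integers(len(alive)))
        node, born = alive.pop(idx)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            alive.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(alive)))
    for node, born in alive:
        node.edge.length = t - born
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"p{i}")
    return tree


def simulate_latent_traits(tree: dendropy.Tree, model: str = "brownian",
                           sigma: float = 1.0, seed=None) -> pd.DataFrame:
    """Latent (log10-scale) trait values for each leaf, three traits.

    Under ``brownian`` each trait evolves independently along the
    branches from a root value of 0, with increment variance
    ``sigma^2 * branch_length``; under ``iid`` values are N(0, sigma^2)
    per species, independent of the tree.
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be > 0")
    if model not in ("brownian", "iid"):
        raise InvalidArgumentError(f"unknown trait model {model!r}")
    rng = _as_rng(seed)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise InvalidArgumentError("tree must have at least 2 leaves")
    k = len(TRAIT_COLUMNS)
    if model == "iid":
        values = rng.normal(0.0, sigma, size=(len(leaves), k))
        return pd.DataFrame(values, index=pd.Index(leaves, name="species"),
                            columns=list(TRAIT_COLUMNS))
    state: dict[int, np.ndarray] = {}
    rows = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            val = np.zeros(k)
            if node.edge.length:
                val = rng.normal(0.0, sigma * np.sqrt(node.edge.length), size=k)
        else:
            length = node.edge.length or 0.0
            val = state[id(node.parent_node)] + \
                rng.normal(0.0, sigma * np.sqrt(length), size=k)
        state[id(node)] = val
        if node.is_leaf():
            rows[node.taxon.label] = val
    values = np.vstack([rows[lab] for lab in leaves])
    return pd.DataFrame(values, index=pd.Index(leaves, name="species"),
                        columns=list(TRAIT_COLUMNS))


def simulate_traits(tree: dendropy.Tree, model: str = "brownian",
                    sigma: float = 1.0, missing_rate: float = 0.0,
                    seed=None) -> pd.DataFrame:
    """Positive LHS trait table for the tree's leaves.

    Latent log10 values from :func:`simulate_latent_traits` are mapped
    to measurement units as ``baseline * 10**latent``; each value is
    then independently set missing with probability ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise InvalidArgumentError("missing_rate must lie in [0, 1)")
    rng = _as_rng(seed)
    latent = simulate_latent_traits(tree, model=model, sigma=sigma, seed=rng)
    traits = latent.copy()
    for col in TRAIT_COLUMNS:
        traits[col] = TRAIT_BASELINES[col] * np.power(10.0, latent[col])
    if missing_rate > 0:
        mask = rng.random(traits.shape) < missing_rate
        traits = traits.mask(mask)
    return traits


def simulate_network(cfg: SynthConfig, seed=None) -> QuantitativeNetwork:
    """Simulate a sparse quantitative visitation matrix.

    The number of links is fixed at ``round(connectance * cells)``; a
    randomized cyclic covering guarantees every plant and pollinator at
    least one interaction, the remaining links fall on uniformly chosen
    empty cells, and positive counts follow the rounded-up lognormal
    visit-count law.
    """
    rng = _as_rng(cfg.seed if seed is None else seed)
    npl, npol = cfg.n_plants, cfg.n_pollinators
    cells = npl * npol
    m = int(round(cfg.connectance * cells))
    m = max(m, max(npl, npol))
    adj = np.zeros((npol, npl), dtype=bool)
    pol_perm = rng.permutation(npol)
    pla_perm = rng.permutation(npl)
    big = max(npol, npl)
    for k in range(big):
        i = pol_perm[k % npol]
        j = pla_perm[k % npl]
        adj[i, j] = True
    empty = np.flatnonzero(~adj.ravel())
    extra = m - int(adj.sum())
    if extra > 0:
        chosen = rng.choice(empty, size=min(extra, empty.size), replace=False)
        adj.ravel()[chosen] = True
    counts = np.zeros((npol, npl), dtype=np.int64)
    n_links = int(adj.sum())
    draws = np.ceil(rng.lognormal(cfg.count_mu, cfg.count_sigma, size=n_links))
    counts[adj] = draws.astype(np.int64)
    pollinators = tuple(f"a{i+1}" for i in range(npol))
    plants = tuple(f"p{j+1}" for j in range(npl))
    return QuantitativeNetwork(pollinators, plants, counts)


@dataclass
class FixtureBundle:
    """A consistent (network, traits, phylogeny) triple."""

    network: QuantitativeNetwork
    traits: pd.DataFrame
    tree: dendropy.Tree

    def write(self, out_dir) -> dict[str, str]:
        """Serialize to the external-interface formats; returns paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": str(out / "network.csv"),
            "traits": str(out / "traits.csv"),
            "phylogeny": str(out / "phylogeny.nwk"),
        }
        write_network(self.network, paths["network"])
        write_traits(self.traits, paths["traits"])
        write_newick(self.tree, paths["phylogeny"])
        return paths

    @classmethod
    def read(cls, in_dir) -> "FixtureBundle":
        from pathlib import Path

        src = Path(in_dir)
        return cls(network=read_network(src / "network.csv"),
                   traits=read_traits(src / "traits.csv"),
                   tree=read_phylogeny(src / "phylogeny.nwk"))


def make_fixture(cfg: SynthConfig) -> FixtureBundle:
    """Generate a consistent community: the network's plant labels match
    the tree's leaves and the trait table's rows."""
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    tree = simulate_phylogeny(cfg.n_plants, cfg.birth_rate,
                              seed=np.random.default_rng(ss[0]))
    traits = simulate_traits(tree, model=cfg.trait_model, sigma=cfg.trait_sigma,
                             missing_rate=cfg.missing_rate,
                             seed=np.random.default_rng(ss[1]))
    network = simulate_network(cfg, seed=np.random.default_rng(ss[2]))
    return FixtureBundle(network=network, traits=traits, tree=tree)
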