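"""Stochastic coextinction cascades on quantitative bipartite networks.

A single coextinction event is Bernoulli: species *i* goes extinct after
losing mutualistic partner *j* with probability ``P_ij = R_i * d_ij``,
where ``d_ij`` — the dependence of *i* on *j* — is the fraction of *i*'s
current interactions involving *j*, and ``R_i`` is the intrinsic
dependence of *i* on the mutualism (1 = fully dependent).  An extinction
sequence alternates primary pollinator extinctions (targeted with
probability proportional to inverse interaction frequency, a proxy for
rarity) with cascades of secondary extinctions that ripple between the
plant and pollinator sides until no further species fall.  Dependences
are recomputed from the shrinking interaction matrix as the sequence
moves forward; species never form new interactions.

When a wave removes several partners of species *i* at once, the
per-partner hazards combine independently:
``P_i = 1 - prod_j (1 - R_i * d_ij)`` over the wave's losses, which
reduces to ``P_ij`` for a single loss.  One exception: if the wave
removes *all* of species *i*'s remaining partners, the event is the
loss of its entire dependence (d = 1) and the extinction probability is
exactly ``R_i`` — the same value the single-loss rule gives for a sole
surviving partner.  Without this, two simultaneous last-partner losses
would combine to less than ``R_i`` and, at R = 1, could leave species
alive with no partners, contradicting the model's guarantee that fully
dependent communities go extinct completely.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InternalConsistencyError, InvalidArgumentError
from .network import QuantitativeNetwork

__all__ = [
    "SimParams",
    "DependencePair",
    "ExtinctionSequence",
    "EnsembleResult",
    "dependence_matrices",
    "primary_target_probabilities",
    "cascade_wave",
    "simulate_sequence",
    "run_ensemble",
]

PLANT = "plant"
POLLINATOR = "pollinator"


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    ``r_plant`` / ``r_animal`` are the intrinsic mutualism dependences R
    applied to plants and pollinators (default 1: fully dependent).
    ``combine_rule`` names how simultaneous partner losses within one
    cascade wave combine; only the independent-hazard complement product
    is implemented.
    """

    r_plant: float = 1.0
    r_animal: float = 1.0
    n_runs: int = 10_000
    seed: int | None = None
    combine_rule: str = "complement_product"

    def __post_init__(self):
        for name in ("r_plant", "r_animal"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1], got {val}")
        if self.n_runs < 1:
            raise InvalidArgumentError("n_runs must be >= 1")
        if self.combine_rule != "complement_product":
            raise InvalidArgumentError(
                f"unknown combine_rule {self.combine_rule!r}")


@dataclass(frozen=True)
class DependencePair:
    """The two dependence matrices derived from an interaction matrix.

    ``pollinator_on_plant[i, j]`` is pollinator i's dependence on plant j
    and ``plant_on_pollinator[j, i]`` is plant j's dependence on
    pollinator i, each row renormalized over the surviving partners;
    rows of species with no surviving interactions are all zero.
    """

    pollinators: tuple[str, ...]
    plants: tuple[str, ...]
    pollinator_on_plant: np.ndarray = field(repr=False)
    plant_on_pollinator: np.ndarray = field(repr=False)


def _masks(net: QuantitativeNetwork, alive_pollinators, alive_plants):
    if alive_pollinators is None:
        pol = np.ones(net.n_pollinators, dtype=bool)
    else:
        alive = set(alive_pollinators)
        unknown = alive - set(net.pollinators)
        if unknown:
            raise InvalidArgumentError(f"unknown pollinators: {sorted(unknown)}")
        pol = np.array([p in alive for p in net.pollinators])
    if alive_plants is None:
        pla = np.ones(net.n_plants, dtype=bool)
    else:
        alive = set(alive_plants)
        unknown = alive - set(net.plants)
        if unknown:
            raise InvalidArgumentError(f"unknown plants: {sorted(unknown)}")
        pla = np.array([p in alive for p in net.plants])
    return pol, pla


def _dependences(counts: np.ndarray, pol_alive: np.ndarray,
                 pla_alive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = counts * pol_alive[:, None] * pla_alive[None, :]
    row = sub.sum(axis=1, keepdims=True)
    col = sub.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pol_on_pla = np.where(row > 0, sub / np.where(row > 0, row, 1.0), 0.0)
        pla_on_pol = np.where(col > 0, sub / np.where(col > 0, col, 1.0), 0.0).T
    return pol_on_pla, pla_on_pol


def dependence_matrices(net: QuantitativeNetwork, alive_pollinators=None,
                        alive_plants=None) -> DependencePair:
    """Dependence matrices for the surviving community.

    Dead species' rows/columns are zeroed and each surviving species'
    dependences are renormalized over its surviving partners.
    """
    pol, pla = _masks(net, alive_pollinators, alive_plants)
    pol_on_pla, pla_on_pol = _dependences(net.counts.astype(float), pol, pla)
    return DependencePair(net.pollinators, net.plants, pol_on_pla, pla_on_pol)


def primary_target_probabilities(net: QuantitativeNetwork,
                                 alive_pollinators=None) -> pd.Series:
    """Primary-extinction probabilities over the alive pollinators.

    Each alive pollinator is targeted with probability proportional to
    the inverse of its current total interaction frequency (over alive
    plants only).  Rare visitors die first, on average.
    """
    pol, _ = _masks(net, alive_pollinators, None)
    totals = net.counts.sum(axis=1).astype(float)
    alive_idx = np.flatnonzero(pol)
    if alive_idx.size == 0:
        raise InvalidArgumentError("no alive pollinators")
    t = totals[alive_idx]
    if np.any(t <= 0):
        bad = net.pollinators[alive_idx[np.argmin(t)]]
        raise InternalConsistencyError(
            f"alive pollinator {bad!r} has zero interaction frequency")
    inv = 1.0 / t
    return pd.Series(inv / inv.sum(),
                     index=[net.pollinators[i] for i in alive_idx])


def cascade_wave(deps: DependencePair, newly_lost, side: str,
                 alive_targets, params: SimParams, rng) -> list[str]:
    """One cascade wave: the opposite side responds to ``newly_lost``.

    ``deps`` must be the dependence state computed while the newly lost
    species were still alive (the state at the start of the wave).  Each
    surviving target species falls with probability
    ``1 - prod(1 - R * d)`` over the lost partners — or exactly ``R``
    when the wave removes all of its remaining partners (total
    dependence lost = 1) — decided by one uniform draw per species.
    Returns the labels that fell.
    """
    newly_lost = list(newly_lost)
    if not newly_lost:
        raise InvalidArgumentError("newly_lost must be nonempty")
    if side == POLLINATOR:
        lost_idx = [deps.pollinators.index(x) for x in newly_lost]
        dep = deps.plant_on_pollinator[:, lost_idx]  # plants x lost
        r = params.r_plant
        target_labels = deps.plants
    elif side == PLANT:
        lost_idx = [deps.plants.index(x) for x in newly_lost]
        dep = deps.pollinator_on_plant[:, lost_idx]
        r = params.r_animal
        target_labels = deps.pollinators
    else:
        raise InvalidArgumentError(f"side must be plant or pollinator, got {side!r}")
    p_ext = 1.0 - np.prod(1.0 - r * dep, axis=1)
    complete = np.isclose(dep.sum(axis=1), 1.0, atol=1e-12)
    p_ext[complete] = r
    alive = set(alive_targets)
    draws = rng.random(len(target_labels))
    return [lab for lab, p, u in zip(target_labels, p_ext, draws)
            if lab in alive and u < p]


@dataclass
class EpisodeRecord:
    """One primary-extinction episode and its cascade."""

    primary: str
    #: ordered (side, label) secondary losses, in wave order
    losses: list[tuple[str, str]]
    #: boolean mask over the network's plant labels at post-cascade equilibrium
    surviving_plants: np.ndarray


@dataclass
class ExtinctionSequence:
    """One full simulated extinction sequence.

    ``persistence[j]`` is the number of primary-extinction episodes
    completed before plant j was lost (a plant lost during episode k has
    persistence k - 1); plants never lost get the total episode count.
    ``plant_snapshots[k]`` is the surviving-plant mask at equilibrium
    after episode k + 1.
    """

    pollinators: tuple[str, ...]
    plants: tuple[str, ...]
    episodes: list[EpisodeRecord]
    persistence: np.ndarray
    plant_snapshots: np.ndarray

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def plant_losses(self) -> np.ndarray:
        """Cumulative number of plants lost after each episode."""
        return len(self.plants) - self.plant_snapshots.sum(axis=1)

    def persistence_series(self) -> pd.Series:
        return pd.Series(self.persistence, index=list(self.plants),
                         name="persistence")


def simulate_sequence(net: QuantitativeNetwork, params: SimParams,
                      rng: np.random.Generator,
                      record_details: bool = True) -> ExtinctionSequence:
    """Run one extinction sequence until no pollinators remain.

    Each episode removes one primary pollinator (inverse-frequency
    target choice over current totals) and lets cascades alternate
    between sides until a wave yields no extinctions; the community is
    then at equilibrium and the surviving plant set is recorded.  With
    R < 1 a species can survive the loss of its last partner (with
    probability 1 - R); such stranded plants can never again fall to a
    cascade and are recorded as never lost, while stranded pollinators
    (zero current frequency, hence unbounded inverse-frequency weight)
    are deterministically targeted first by subsequent primary
    episodes.  With R = 1 every sequence ends with all species extinct.
    """
    counts = net.counts.astype(float)
    npol, npla = counts.shape
    pol_alive = np.ones(npol, dtype=bool)
    pla_alive = np.ones(npla, dtype=bool)
    persistence = np.full(npla, -1, dtype=np.int64)
    episodes: list[EpisodeRecord] = []
    snapshots: list[np.ndarray] = []
    r_plant, r_animal = params.r_plant, params.r_animal
    episode = 0
    while pol_alive.any():
        episode += 1
        alive_idx = np.flatnonzero(pol_alive)
        totals = (counts[alive_idx] * pla_alive).sum(axis=1)
        stranded = alive_idx[totals == 0]
        if stranded.size:
            primary = int(stranded[rng.integers(stranded.size)])
        else:
            inv = 1.0 / totals
            pick = np.searchsorted(np.cumsum(inv / inv.sum()), rng.random(),
                                   side="right")
            primary = int(alive_idx[min(pick, alive_idx.size - 1)])
        losses: list[tuple[str, str]] = []
        newly = np.array([primary], dtype=np.intp)
        side = POLLINATOR
        while newly.size:
            # dependences from the state in which `newly` were still alive
            if side == POLLINATOR:
                sub = counts * pol_alive[:, None] * pla_alive[None, :]
                denom = sub.sum(axis=0)  # per plant, over alive pollinators
                pol_alive[newly] = False
                with np.errstate(invalid="ignore", divide="ignore"):
                    dep = np.where(denom > 0, sub[newly] / np.where(denom > 0, denom, 1.0), 0.0)
                p_ext = 1.0 - np.prod(1.0 - r_plant * dep, axis=0)
                # complete partner loss: total dependence 1 falls at once
                remaining = (sub.sum(axis=0) - sub[newly].sum(axis=0))
                p_ext[(denom > 0) & (remaining == 0)] = r_plant
                fallen = np.flatnonzero(pla_alive & (rng.random(npla) < p_ext))
                if record_details:
                    losses.extend((PLANT, net.plants[j]) for j in fallen)
                side = PLANT
            else:
                sub = counts * pol_alive[:, None] * pla_alive[None, :]
                denom = sub.sum(axis=1)  # per pollinator, over alive plants
                pla_alive[newly] = False
                persistence[newly] = episode - 1
                with np.errstate(invalid="ignore", divide="ignore"):
                    dep = np.where(denom[:, None] > 0,
                                   sub[:, newly] / np.where(denom[:, None] > 0,
                                                            denom[:, None], 1.0), 0.0)
                p_ext = 1.0 - np.prod(1.0 - r_animal * dep, axis=1)
                remaining = (sub.sum(axis=1) - sub[:, newly].sum(axis=1))
                p_ext[(denom > 0) & (remaining == 0)] = r_animal
                fallen = np.flatnonzero(pol_alive & (rng.random(npol) < p_ext))
                if record_details:
                    losses.extend((POLLINATOR, net.pollinators[i]) for i in fallen)
                side = POLLINATOR
            newly = fallen
        snapshot = pla_alive.copy()
        snapshots.append(snapshot)
        episodes.append(EpisodeRecord(primary=net.pollinators[primary],
                                      losses=losses,
                                      surviving_plants=snapshot))
    persistence[persistence < 0] = episode
    return ExtinctionSequence(
        pollinators=net.pollinators,
        plants=net.plants,
        episodes=episodes,
        persistence=persistence,
        plant_snapshots=(np.vstack(snapshots) if snapshots
                         else np.ones((0, npla), dtype=bool)),
    )


@dataclass
class EnsembleResult:
    """A reproducible ensemble of extinction sequences."""

    network: QuantitativeNetwork
    params: SimParams
    sequences: list[ExtinctionSequence]

    @property
    def n_runs(self) -> int:
        return len(self.sequences)

    @property
    def persistence_matrix(self) -> np.ndarray:
        return np.vstack([s.persistence for s in self.sequences])

    def mean_persistence(self) -> pd.Series:
        return pd.Series(self.persistence_matrix.mean(axis=0),
                         index=list(self.network.plants), name="mean_persistence")

    def sd_persistence(self) -> pd.Series:
        return pd.Series(self.persistence_matrix.std(axis=0, ddof=0),
                         index=list(self.network.plants), name="sd_persistence")

    def persistence_table(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_persistence": self.mean_persistence(),
                             "sd_persistence": self.sd_persistence()})


def run_ensemble(net: QuantitativeNetwork, params: SimParams,
                 record_details: bool = False) -> EnsembleResult:
    """Run ``params.n_runs`` independent extinction sequences.

    Each run draws from its own substream of ``params.seed``, so
    ensembles are reproducible and runs are independent.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_runs)
    sequences = [
        simulate_sequence(net, params, np.random.default_rng(child),
                          record_details=record_details)
        for child in children
    ]
    return EnsembleResult(network=net, params=params, sequences=sequences)
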