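"""Preprocessing: trait-coverage filtering and tree pruning.

Plants with fewer than two non-missing LHS traits cannot be placed in
the functional dendrogram and are removed from the interaction matrix
before any simulation; pollinators left with zero interactions after
that removal are dropped as well.  The same plant set is then pruned
from the phylogeny so that FD and PD are measured on identical
assemblages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .network import QuantitativeNetwork
from .trees import prune_tree  # re-exported for pipeline convenience

__all__ = ["FilterResult", "filter_by_trait_coverage", "prune_tree"]

MIN_TRAITS = 2


@dataclass(frozen=True)
class FilterResult:
    network: QuantitativeNetwork
    removed_plants: frozenset[str]
    removed_pollinators: frozenset[str]
    #: plants absent from the trait table altogether (subset of removed_plants)
    missing_from_traits: frozenset[str] = field(default=frozenset())

    @property
    def fraction_plants_removed(self) -> float:
        total = len(self.network.plants) + len(self.removed_plants)
        return len(self.removed_plants) / total if total else 0.0

    def __iter__(self):
        # allows `net, removed_plants, removed_pollinators = result`
        return iter((self.network, self.removed_plants, self.removed_pollinators))


def filter_by_trait_coverage(net: QuantitativeNetwork,
                             traits: pd.DataFrame) -> FilterResult:
    """Drop plants with <2 non-missing traits, then orphaned pollinators.

    Plants absent from the trait table count as having zero traits and
    are removed with a warning.  Pollinator removal is applied once,
    after plant removal: a pollinator goes only if its remaining row is
    all zero.  Idempotent.
    """
    coverage = traits.notna().sum(axis=1)
    absent = [p for p in net.plants if p not in traits.index]
    if absent:
        warnings.warn(
            f"{len(absent)} plant(s) absent from trait table, treated as "
            f"having no trait data: {absent}", stacklevel=2)
    keep_plants = [p for p in net.plants
                   if p in traits.index and coverage.loc[p] >= MIN_TRAITS]
    removed_plants = frozenset(net.plants) - frozenset(keep_plants)
    reduced = net.subset(plants=keep_plants)
    row_totals = reduced.pollinator_totals
    keep_pols = [pol for pol, tot in zip(reduced.pollinators, row_totals) if tot > 0]
    removed_pols = frozenset(net.pollinators) - frozenset(keep_pols)
    return FilterResult(
        network=reduced.subset(pollinators=keep_pols),
        removed_plants=removed_plants,
        removed_pollinators=removed_pols,
        missing_from_traits=frozenset(absent),
    )
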