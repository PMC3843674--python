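"""Model/Results front end for the whole coextinction analysis.

:class:`CoextinctionModel` bundles the data preparation that the
analysis needs — trait-coverage filtering, tree pruning, functional
dendrogram construction and originality weights — and its :meth:`fit`
runs the stochastic simulations, the reference scenarios and the
post-hoc statistics, returning a :class:`CoextinctionResults` object
with the decline curves, deviations from the random expectation,
per-species persistence and the correlation/correlogram tables.

    >>> model = CoextinctionModel.from_synthetic(SynthConfig(seed=0))
    >>> res = model.fit(n_runs=1000, seed=1)
    >>> print(res.summary())
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

from . import scenarios as scn
from .coextinction import EnsembleResult, SimParams, run_ensemble
from .diversity import originality, trait_distance_matrix, upgma
from .errors import InvalidArgumentError
from .io import read_network, read_phylogeny, read_traits, validate_traits
from .network import QuantitativeNetwork
from .prep import FilterResult, filter_by_trait_coverage, prune_tree
from .stats import StatisticsReport, run_statistics
from .synth import FixtureBundle, SynthConfig, make_fixture

__all__ = ["CoextinctionModel", "CoextinctionResults"]


def _subseed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2 ** 31))


class CoextinctionModel:
    """Plant-pollinator coextinction model for one community.

    Construction applies the preprocessing rules (plants need at least
    two non-missing LHS traits; orphaned pollinators are dropped; the
    phylogeny is pruned to the retained plants), builds the functional
    dendrogram by UPGMA on Euclidean trait distances, and computes the
    functional and phylogenetic originality of every retained plant on
    the complete pre-extinction assemblage.

    Parameters
    ----------
    network : QuantitativeNetwork
        Pollinator x plant visit counts.
    traits : DataFrame
        LHS trait table indexed by species (columns sla, height,
        seed_mass); missing values allowed.
    phylogeny : dendropy.Tree
        Dated phylogeny containing all the network's plants as leaves.
    standardize : bool
        Z-score each trait before computing distances (default True;
        the three traits live on different measurement scales).
    log_traits : sequence of str
        Traits to log10-transform before (optional) standardization.
    """

    def __init__(self, network: QuantitativeNetwork, traits: pd.DataFrame,
                 phylogeny: dendropy.Tree, *, standardize: bool = True,
                 log_traits=()):
        traits = validate_traits(traits)
        self.filter_result: FilterResult = filter_by_trait_coverage(network, traits)
        self.network = self.filter_result.network
        if self.network.n_plants < 2:
            raise InvalidArgumentError(
                "fewer than 2 plants remain after trait-coverage filtering")
        if self.network.n_pollinators < 1:
            raise InvalidArgumentError("no pollinators remain after filtering")
        self.traits = traits.loc[list(self.network.plants)]
        self.phylogeny = prune_tree(phylogeny, self.network.plants)
        self.trait_distances = trait_distance_matrix(
            self.traits, standardize=standardize, log_transform=log_traits)
        self.dendrogram = upgma(self.trait_distances)
        self.functional_originality = originality(self.dendrogram).rename(
            "functional_originality")
        self.phylogenetic_originality = originality(self.phylogeny).rename(
            "phylogenetic_originality")

    # ------------------------------------------------------------------
    @classmethod
    def from_files(cls, network_path, traits_path, phylogeny_path,
                   **kwargs) -> "CoextinctionModel":
        return cls(read_network(network_path), read_traits(traits_path),
                   read_phylogeny(phylogeny_path), **kwargs)

    @classmethod
    def from_synthetic(cls, cfg: SynthConfig | None = None,
                       **kwargs) -> "CoextinctionModel":
        bundle: FixtureBundle = make_fixture(cfg or SynthConfig())
        return cls(bundle.network, bundle.traits, bundle.tree, **kwargs)

    # ------------------------------------------------------------------
    def _metric_context(self, metric: str):
        """(evaluation tree, originality vector) pairing for a metric:
        FD-type metrics use the functional dendrogram and functional
        originality, PD-type metrics the phylogeny and phylogenetic
        originality."""
        if metric in (scn.FD, scn.TOTAL_FUNCTIONAL_ORIGINALITY):
            return self.dendrogram, self.functional_originality
        if metric in (scn.PD, scn.TOTAL_PHYLOGENETIC_ORIGINALITY):
            return self.phylogeny, self.phylogenetic_originality
        raise InvalidArgumentError(f"unknown metric {metric!r}")

    def fit(self, n_runs: int = 10_000, r_plant: float = 1.0,
            r_animal: float = 1.0, seed: int | None = None,
            reference_runs: int | None = None,
            metrics=(scn.FD, scn.PD), n_classes: int = 4,
            n_perm: int = 999) -> "CoextinctionResults":
        """Run the coextinction ensemble, the reference scenarios and
        the statistical analyses.

        ``reference_runs`` defaults to ``n_runs`` and controls the
        random-removal reference ensemble.  All randomness descends
        from ``seed`` through named substreams, so a fit is exactly
        reproducible.
        """
        reference_runs = n_runs if reference_runs is None else reference_runs
        root = np.random.SeedSequence(seed)
        ss_sim, ss_ref, ss_stats = root.spawn(3)
        params = SimParams(r_plant=r_plant, r_animal=r_animal, n_runs=n_runs,
                           seed=_subseed(ss_sim))
        ensemble = run_ensemble(self.network, params)
        curves: dict[tuple[str, str], scn.DeclineCurve] = {}
        deviations: dict[str, np.ndarray] = {}
        ref_children = ss_ref.spawn(len(metrics))
        for metric, child in zip(metrics, ref_children):
            tree, orig = self._metric_context(metric)
            curves[(metric, "coextinction")] = scn.ensemble_decline_curve(
                ensemble, tree, metric, orig=orig)
            for scenario in ("best", "worst"):
                curves[(metric, scenario)] = scn.reference_curve(
                    tree, orig, scenario, metric)
            curves[(metric, "random")] = scn.reference_curve(
                tree, orig, "random", metric, n_runs=reference_runs,
                seed=_subseed(child))
            deviations[metric] = scn.relative_deviation(
                curves[(metric, "coextinction")], curves[(metric, "random")])
        mean_persistence = ensemble.mean_persistence()
        statistics = run_statistics(
            mean_persistence, self.functional_originality,
            self.phylogenetic_originality, self.dendrogram, self.phylogeny,
            n_classes=n_classes, n_perm=n_perm, seed=_subseed(ss_stats))
        return CoextinctionResults(model=self, ensemble=ensemble,
                                   curves=curves, deviations=deviations,
                                   statistics=statistics)


@dataclass
class CoextinctionResults:
    """Results of a fitted coextinction analysis."""

    model: CoextinctionModel
    ensemble: EnsembleResult
    curves: dict[tuple[str, str], scn.DeclineCurve]
    deviations: dict[str, np.ndarray]
    statistics: StatisticsReport
    _dev_at_half: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def metrics(self) -> list[str]:
        return sorted({m for m, _ in self.curves})

    def deviation_at_half(self, metric: str) -> float:
        """Relative deviation (%) from the random scenario at the point
        when 50% of plant species have been lost."""
        if metric not in self._dev_at_half:
            grid = self.curves[(metric, "coextinction")].grid
            self._dev_at_half[metric] = scn.deviation_at_half(
                grid, self.deviations[metric])
        return self._dev_at_half[metric]

    def persistence(self) -> pd.DataFrame:
        return self.ensemble.persistence_table()

    def curves_frame(self) -> pd.DataFrame:
        return pd.concat([c.to_frame() for c in self.curves.values()],
                         ignore_index=True)

    def deviation_frame(self) -> pd.DataFrame:
        frames = []
        for metric, dev in self.deviations.items():
            grid = self.curves[(metric, "coextinction")].grid
            frames.append(pd.DataFrame({"metric": metric, "p": grid,
                                        "deviation_pct": dev}))
        return pd.concat(frames, ignore_index=True)

    def plot_decline(self, metric: str, ax=None):
        """Plot the coextinction decline curve against the best, worst
        and random references for one metric."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        styles = {"coextinction": dict(marker="o", ls="", color="k"),
                  "best": dict(ls="-", color="tab:green"),
                  "worst": dict(ls="-", color="tab:red"),
                  "random": dict(ls=":", color="tab:blue")}
        for scenario, style in styles.items():
            curve = self.curves.get((metric, scenario))
            if curve is not None:
                ax.plot(curve.grid, curve.mean, label=scenario, **style)
        ax.set_xlabel("proportion of plant species lost")
        ax.set_ylabel(metric)
        ax.legend()
        return ax

    def summary(self) -> str:
        model = self.model
        fr = model.filter_result
        lines = []
        lines.append("Plant-pollinator coextinction analysis")
        lines.append("=" * 54)
        lines.append(f"plants (after trait filter): {model.network.n_plants:>6}")
        lines.append(f"pollinators:                 {model.network.n_pollinators:>6}")
        lines.append(f"plants removed (<2 traits):  {len(fr.removed_plants):>6}"
                     f"  ({100 * fr.fraction_plants_removed:.1f}%)")
        lines.append(f"pollinators removed:         {len(fr.removed_pollinators):>6}")
        lines.append(f"connectance:                 {model.network.connectance:>9.3f}")
        lines.append(f"simulation runs:             {self.ensemble.n_runs:>6}"
                     f"   (R_plant={self.ensemble.params.r_plant},"
                     f" R_animal={self.ensemble.params.r_animal})")
        lines.append("-" * 54)
        lines.append("Deviation from random expectation at 50% plant loss:")
        for metric in self.metrics:
            lines.append(f"  {metric:<28} {self.deviation_at_half(metric):+8.1f}%")
        lines.append("-" * 54)
        if self.statistics.degenerate:
            lines.append(f"statistics: {self.statistics.note}")
        else:
            lines.append("Spearman tests (mean persistence vs originality):")
            for _, row in self.statistics.spearman.iterrows():
                kind = "functional" if "functional" in row["comparison"] \
                    else "phylogenetic"
                lines.append(f"  {kind:<14} rs = {row['rs']:+.3f}   "
                             f"p = {row['p']:.3f}   (n = {int(row['n'])})")
            lines.append("Moran's I, first distance class:")
            for name, corr in self.statistics.correlograms.items():
                lines.append(f"  {name:<44} I = {corr.morans_i[0]:+.3f}  "
                             f"p = {corr.p_values[0]:.3f}")
        return "\n".join(lines)
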