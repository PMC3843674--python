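"""Decline curves of diversity versus the proportion of plants lost.

A decline curve tracks a tree-based diversity metric (FD, PD, or a
total-originality variant) as plants disappear, on the common grid
``p_k = k / S`` of proportions of the S plant species lost.  Simulated
coextinction sequences yield right-continuous step curves (plants fall
at irregular, run-specific fractions) that are averaged pointwise over
runs.  Reference scenarios remove plants directly, one per grid step,
with no pollinators involved: *best case* in increasing order of
originality, *worst case* in decreasing order, and *random* as the
average over uniformly random removal orders.  Relative deviations of
the coextinction curve from the random reference express how much
faster or slower diversity is lost than expected by chance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

from .coextinction import EnsembleResult, ExtinctionSequence
from .errors import InvalidArgumentError
from .trees import TreeIndex

__all__ = [
    "FD",
    "PD",
    "TOTAL_FUNCTIONAL_ORIGINALITY",
    "TOTAL_PHYLOGENETIC_ORIGINALITY",
    "METRICS",
    "DeclineCurve",
    "sequence_to_step_curve",
    "ensemble_decline_curve",
    "average_curves",
    "reference_curve",
    "relative_deviation",
    "deviation_at_half",
]

FD = "FD"
PD = "PD"
TOTAL_FUNCTIONAL_ORIGINALITY = "total_functional_originality"
TOTAL_PHYLOGENETIC_ORIGINALITY = "total_phylogenetic_originality"
METRICS = (FD, PD, TOTAL_FUNCTIONAL_ORIGINALITY, TOTAL_PHYLOGENETIC_ORIGINALITY)


@dataclass(frozen=True)
class DeclineCurve:
    """Metric value as a function of the proportion of plants lost."""

    grid: np.ndarray
    mean: np.ndarray
    metric: str
    scenario: str
    sd: np.ndarray | None = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.grid.shape != self.mean.shape:
            raise InvalidArgumentError("grid and mean must have equal length")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"scenario": self.scenario, "metric": self.metric,
                              "p": self.grid, "mean": self.mean})
        frame["sd"] = self.sd if self.sd is not None else np.nan
        return frame

    def value_at(self, p: float) -> float:
        """Value at the smallest grid point >= p (no interpolation)."""
        idx = int(np.searchsorted(self.grid, p - 1e-12))
        return float(self.mean[min(idx, len(self.grid) - 1)])


class _MetricEvaluator:
    """Vectorized metric evaluation over many extant-set masks, all in a
    fixed plant-label order."""

    def __init__(self, metric: str, plants, tree: dendropy.Tree | None = None,
                 orig: pd.Series | None = None):
        if metric not in METRICS:
            raise InvalidArgumentError(f"unknown metric {metric!r}")
        self.metric = metric
        self.plants = list(plants)
        if metric in (FD, PD):
            if tree is None:
                raise InvalidArgumentError(f"{metric} requires a tree")
            self._index = TreeIndex(tree)
            missing = set(self.plants) - set(self._index.labels)
            if missing:
                raise InvalidArgumentError(
                    f"tree lacks leaves for plants: {sorted(missing)}")
            # column permutation: plant order -> tree leaf order
            pos = {lab: i for i, lab in enumerate(self._index.labels)}
            self._perm = np.array([pos[p] for p in self.plants])
            self._n_leaves = self._index.n_leaves
        else:
            if orig is None:
                raise InvalidArgumentError(f"{metric} requires originality weights")
            missing = set(self.plants) - set(orig.index)
            if missing:
                raise InvalidArgumentError(
                    f"originality lacks weights for plants: {sorted(missing)}")
            self._weights = orig.reindex(self.plants).to_numpy(dtype=float)

    def __call__(self, masks: np.ndarray) -> np.ndarray:
        masks = np.atleast_2d(np.asarray(masks, dtype=bool))
        if self.metric in (FD, PD):
            leaf_masks = np.zeros((masks.shape[0], self._n_leaves), dtype=bool)
            leaf_masks[:, self._perm] = masks
            if self.metric == FD:
                return self._index.fd_masks(leaf_masks)
            return self._index.pd_masks(leaf_masks)
        return masks.astype(float) @ self._weights


def _step_values(snapshots: np.ndarray, losses: np.ndarray,
                 evaluate: _MetricEvaluator, n_plants: int) -> np.ndarray:
    """Map per-episode snapshots onto the grid k = 0..S as a
    right-continuous step function of cumulative plant loss."""
    masks = np.vstack([np.ones((1, n_plants), dtype=bool), snapshots])
    values = evaluate(masks)
    cum = np.concatenate(([0], losses))
    ks = np.arange(n_plants + 1)
    idx = np.searchsorted(cum, ks, side="right") - 1
    return values[idx]


def sequence_to_step_curve(seq: ExtinctionSequence, tree: dendropy.Tree,
                           metric: str, orig: pd.Series | None = None
                           ) -> DeclineCurve:
    """Decline curve of one simulated sequence on the grid k/S.

    The metric is evaluated on the surviving-plant set at equilibrium
    after each episode; the value at p = k/S is the metric after the
    last episode at which cumulative plant loss was at most k, with the
    pre-extinction assemblage at p = 0.
    """
    n = len(seq.plants)
    evaluate = _MetricEvaluator(metric, seq.plants, tree=tree, orig=orig)
    values = _step_values(seq.plant_snapshots, seq.plant_losses, evaluate, n)
    return DeclineCurve(grid=np.arange(n + 1) / n, mean=values,
                        metric=metric, scenario="coextinction")


def average_curves(curves) -> DeclineCurve:
    """Pointwise mean and standard deviation of same-grid curves."""
    curves = list(curves)
    if not curves:
        raise InvalidArgumentError("no curves to average")
    first = curves[0]
    for c in curves[1:]:
        if c.metric != first.metric or c.scenario != first.scenario:
            raise InvalidArgumentError("cannot average curves with mixed tags")
        if c.grid.shape != first.grid.shape or not np.allclose(c.grid, first.grid):
            raise InvalidArgumentError("cannot average curves on different grids")
    stack = np.vstack([c.mean for c in curves])
    return DeclineCurve(grid=first.grid, mean=stack.mean(axis=0),
                        sd=stack.std(axis=0, ddof=0), metric=first.metric,
                        scenario=first.scenario)


def ensemble_decline_curve(ensemble: EnsembleResult, tree: dendropy.Tree,
                           metric: str, orig: pd.Series | None = None
                           ) -> DeclineCurve:
    """Average decline curve over an ensemble of coextinction runs."""
    plants = ensemble.network.plants
    n = len(plants)
    evaluate = _MetricEvaluator(metric, plants, tree=tree, orig=orig)
    total = np.zeros(n + 1)
    total_sq = np.zeros(n + 1)
    for seq in ensemble.sequences:
        vals = _step_values(seq.plant_snapshots, seq.plant_losses, evaluate, n)
        total += vals
        total_sq += vals ** 2
    m = ensemble.n_runs
    mean = total / m
    var = np.maximum(total_sq / m - mean ** 2, 0.0)
    return DeclineCurve(grid=np.arange(n + 1) / n, mean=mean, sd=np.sqrt(var),
                        metric=metric, scenario="coextinction")


def _order_masks(order_pos: np.ndarray) -> np.ndarray:
    """Extant masks after k = 0..S removals for a removal order given as
    per-species removal positions."""
    n = order_pos.size
    return order_pos[None, :] >= np.arange(n + 1)[:, None]


def reference_curve(tree: dendropy.Tree | None, orig: pd.Series,
                    scenario: str, metric: str, n_runs: int = 10_000,
                    seed: int | None = None) -> DeclineCurve:
    """Reference decline curve with plants removed directly (one per
    grid step), independently of their pollinators.

    best
        remove plants deterministically in increasing order of
        originality (ties broken lexicographically by label);
    worst
        in decreasing order of originality;
    random
        average (with pointwise sd) over ``n_runs`` uniformly random
        removal orders.
    """
    plants = [str(x) for x in orig.index]
    n = len(plants)
    evaluate = _MetricEvaluator(metric, plants, tree=tree, orig=orig)
    grid = np.arange(n + 1) / n
    if scenario in ("best", "worst"):
        weights = orig.to_numpy(dtype=float)
        sign = 1.0 if scenario == "best" else -1.0
        order = sorted(range(n), key=lambda i: (sign * weights[i], plants[i]))
        pos = np.empty(n, dtype=np.intp)
        pos[np.array(order)] = np.arange(n)
        values = evaluate(_order_masks(pos))
        return DeclineCurve(grid=grid, mean=values, metric=metric,
                            scenario=scenario)
    if scenario != "random":
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    total = np.zeros(n + 1)
    total_sq = np.zeros(n + 1)
    for _ in range(n_runs):
        pos = rng.permutation(n)
        values = evaluate(_order_masks(pos))
        total += values
        total_sq += values ** 2
    mean = total / n_runs
    var = np.maximum(total_sq / n_runs - mean ** 2, 0.0)
    return DeclineCurve(grid=grid, mean=mean, sd=np.sqrt(var), metric=metric,
                        scenario="random")


def relative_deviation(curve: DeclineCurve, random_curve: DeclineCurve
                       ) -> np.ndarray:
    """Percentage deviation ``100 * (curve - random) / random`` per grid
    point; NaN (missing) where the random curve is zero."""
    if curve.metric != random_curve.metric:
        raise InvalidArgumentError("metric mismatch between curves")
    if curve.grid.shape != random_curve.grid.shape or \
            not np.allclose(curve.grid, random_curve.grid):
        raise InvalidArgumentError("grid mismatch between curves")
    ref = random_curve.mean
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = 100.0 * (curve.mean - ref) / ref
    dev = np.where(ref == 0, np.nan, dev)
    return dev


def deviation_at_half(grid: np.ndarray, deviation: np.ndarray) -> float:
    """Deviation at the smallest grid point >= 0.5 (no interpolation)."""
    grid = np.asarray(grid, dtype=float)
    candidates = np.flatnonzero(grid >= 0.5 - 1e-12)
    if candidates.size == 0:
        raise InvalidArgumentError("grid contains no point >= 0.5")
    return float(np.asarray(deviation)[candidates[0]])
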