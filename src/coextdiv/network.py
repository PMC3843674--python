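"""Quantitative bipartite interaction networks.

A quantitative plant-pollinator network is an integer matrix ``a_ij``
counting how many times pollinator (animal) species *i* was recorded
visiting plant species *j*.  Rows are pollinators, columns are plants.
Visit counts double as interaction-frequency estimates, which the
coextinction model uses both to set primary-extinction risk and to
derive mutual dependences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError

__all__ = ["QuantitativeNetwork", "read_network", "write_network"]


@dataclass(frozen=True)
class QuantitativeNetwork:
    """Labelled pollinator x plant visit-count matrix.

    Parameters
    ----------
    pollinators : sequence of str
        Row labels (animal species), unique.
    plants : sequence of str
        Column labels (plant species), unique.
    counts : ndarray of shape (n_pollinators, n_plants)
        Nonnegative integer visit counts.
    """

    pollinators: tuple[str, ...]
    plants: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "pollinators", tuple(str(x) for x in self.pollinators))
        object.__setattr__(self, "plants", tuple(str(x) for x in self.plants))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.pollinators), len(self.plants)):
            raise InvalidArgumentError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.pollinators)} pollinators x {len(self.plants)} plants"
            )
        if len(set(self.pollinators)) != len(self.pollinators):
            raise FormatError("duplicate pollinator labels")
        if len(set(self.plants)) != len(self.plants):
            raise FormatError("duplicate plant labels")
        if not np.issubdtype(counts.dtype, np.number):
            raise FormatError("non-numeric interaction counts")
        if np.any(~np.isfinite(counts.astype(float))):
            raise FormatError("non-finite interaction counts")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at pollinator {self.pollinators[i]!r}, "
                f"plant {self.plants[j]!r}"
            )
        if not np.allclose(counts, np.round(counts.astype(float))):
            i, j = np.argwhere(counts != np.round(counts.astype(float)))[0]
            raise FormatError(
                f"non-integer count at pollinator {self.pollinators[i]!r}, "
                f"plant {self.plants[j]!r}"
            )
        counts = np.round(counts.astype(float)).astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinators)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def pollinator_totals(self) -> np.ndarray:
        """Total interaction frequency of each pollinator (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def plant_totals(self) -> np.ndarray:
        """Total interaction frequency of each plant (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def connectance(self) -> float:
        """Fraction of possible links realized."""
        return float((self.counts > 0).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.pollinators),
                            columns=list(self.plants))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "QuantitativeNetwork":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy())

    def subset(self, pollinators=None, plants=None) -> "QuantitativeNetwork":
        """Restrict to the given label subsets (order preserved)."""
        pol = [p for p in self.pollinators if pollinators is None or p in set(pollinators)]
        pla = [p for p in self.plants if plants is None or p in set(plants)]
        frame = self.to_frame().loc[pol, pla]
        return QuantitativeNetwork.from_frame(frame)

    def has_empty_species(self) -> bool:
        """True if any species has zero interactions."""
        return bool((self.pollinator_totals == 0).any() or (self.plant_totals == 0).any())


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return frame


def read_network(path) -> QuantitativeNetwork:
    """Read an interaction matrix from CSV/TSV.

    First column holds pollinator labels, the header row holds plant
    labels; cells are nonnegative integer visit counts.
    """
    # pandas de-duplicates repeated header names, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    plant_header = header.split(sep)[1:]
    if len(set(plant_header)) != len(plant_header):
        dup = next(x for i, x in enumerate(plant_header) if x in plant_header[:i])
        raise FormatError(f"{path}: duplicate plant label {dup!r}")
    frame = _read_table(path)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate pollinator label {dup!r}")
    values = frame.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        i, j = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at pollinator {frame.index[i]!r}, "
            f"plant {frame.columns[j]!r}"
        )
    try:
        return QuantitativeNetwork.from_frame(values)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_network(net: QuantitativeNetwork, path) -> None:
    """Write an interaction matrix as CSV (round-trips losslessly)."""
    net.to_frame().to_csv(path, index_label="pollinator")
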