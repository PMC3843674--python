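"""Readers/writers for trait tables (plus re-exports of the other formats).

The trait table follows the LHS scheme: specific leaf area (SLA,
mm^2/mg), canopy height (m) and seed mass (mg) — three traits capturing
broad variation in plant ecological strategy.  Missing values are
allowed and are represented by empty cells on disk.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError
from .network import read_network, write_network
from .trees import read_phylogeny, write_newick

__all__ = [
    "TRAIT_COLUMNS",
    "read_traits",
    "write_traits",
    "validate_traits",
    "read_network",
    "write_network",
    "read_phylogeny",
    "write_newick",
]

TRAIT_COLUMNS = ("sla", "height", "seed_mass")


def validate_traits(traits: pd.DataFrame, source: str = "trait table") -> pd.DataFrame:
    """Check a trait table: unique species, the three LHS columns, and
    strictly positive values wherever a value is present."""
    if traits.index.has_duplicates:
        dup = traits.index[traits.index.duplicated()][0]
        raise FormatError(f"{source}: duplicate species {dup!r}")
    missing_cols = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing_cols:
        raise FormatError(f"{source}: missing trait columns {missing_cols}")
    traits = traits[list(TRAIT_COLUMNS)].astype(float)
    for col in TRAIT_COLUMNS:
        vals = traits[col]
        bad = vals.notna() & ~np.isfinite(vals)
        if bad.any():
            raise FormatError(f"{source}: non-finite {col} for {vals.index[bad][0]!r}")
        nonpos = vals.notna() & (vals <= 0)
        if nonpos.any():
            raise FormatError(
                f"{source}: nonpositive {col} for species {vals.index[nonpos][0]!r}"
            )
    traits.index = traits.index.map(str)
    traits.index.name = "species"
    return traits


def read_traits(path) -> pd.DataFrame:
    """Read a trait CSV with columns species, sla, height, seed_mass.

    Empty cells become missing values (NaN), never zero.
    """
    try:
        frame = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return validate_traits(frame, source=str(path))


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="species")
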