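"""Tabular input/output: community tables, plot metadata, species metadata.

File formats (all plain CSV):

* ``composition.csv`` — long format, columns ``plot_id, species_id, census``
  with ``census`` in ``{sown, final}``; one row per occurrence.
* ``plots.csv`` — columns ``plot_id, sown_richness, biomass_year1,
  biomass_year2`` (biomass in g/m^2).
* ``species.csv`` — columns ``species_id, clade_tag, pool`` with
  ``clade_tag`` in ``{grass, legume, other}`` and ``pool`` in
  ``{internal, external}`` (internal = sown experimental pool, external =
  species that only ever arrived as colonists).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import SchemaError

CENSUSES = ("sown", "final")
CLADE_TAGS = ("grass", "legume", "other")
POOLS = ("internal", "external")


@dataclass
class CommunityTable:
    """Plot-by-species presence for one named census, with optional per-plot
    biomass (g/m^2) and sown-richness design metadata."""

    census: str
    matrix: pd.DataFrame  # plots x species, boolean
    biomass: Optional[pd.Series] = None       # indexed by plot_id
    sown_richness: Optional[pd.Series] = None  # indexed by plot_id

    def __post_init__(self):
        self.matrix = self.matrix.astype(bool)
        if self.biomass is not None:
            self.biomass = self.biomass.reindex(self.matrix.index)
        if self.sown_richness is not None:
            self.sown_richness = self.sown_richness.reindex(self.matrix.index)

    @property
    def plot_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)

    def members(self, plot_id: str) -> frozenset[str]:
        row = self.matrix.loc[plot_id]
        return frozenset(row.index[row])

    def richness(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    def to_long(self) -> pd.DataFrame:
        records = [
            {"plot_id": p, "species_id": s, "census": self.census}
            for p in self.plot_ids
            for s in sorted(self.members(p))
        ]
        return pd.DataFrame(records, columns=["plot_id", "species_id", "census"])


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{name}: missing columns {sorted(missing)}")


def load_composition(path, census: str, plots: Optional[pd.DataFrame] = None) -> CommunityTable:
    """Load one census from a long-format composition CSV."""
    if census not in CENSUSES:
        raise SchemaError(f"census must be one of {CENSUSES}, got {census!r}")
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["plot_id", "species_id", "census"], "composition.csv")
    bad = set(df["census"]) - set(CENSUSES)
    if bad:
        raise SchemaError(f"composition.csv: unknown census labels {sorted(bad)}")
    sub = df[df["census"] == census]
    matrix = (
        pd.crosstab(sub["plot_id"], sub["species_id"]).astype(bool)
        if len(sub)
        else pd.DataFrame(dtype=bool)
    )
    # keep every plot that appears in either census (a plot can lose all species)
    all_plots = sorted(set(df["plot_id"]))
    matrix = matrix.reindex(index=all_plots, fill_value=False)
    biomass = sown_richness = None
    if plots is not None:
        col = {"sown": "biomass_year1", "final": "biomass_year2"}[census]
        biomass = plots.set_index("plot_id")[col].astype(float)
        sown_richness = plots.set_index("plot_id")["sown_richness"].astype(int)
    return CommunityTable(census, matrix, biomass=biomass, sown_richness=sown_richness)


def load_plots(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["plot_id", "sown_richness", "biomass_year1", "biomass_year2"], "plots.csv"
    )
    df["plot_id"] = df["plot_id"].astype(str)
    return df


def load_species_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["species_id", "clade_tag", "pool"], "species.csv")
    bad_tag = set(df["clade_tag"]) - set(CLADE_TAGS)
    if bad_tag:
        raise SchemaError(f"species.csv: unknown clade tags {sorted(bad_tag)}")
    bad_pool = set(df["pool"]) - set(POOLS)
    if bad_pool:
        raise SchemaError(f"species.csv: unknown pool labels {sorted(bad_pool)}")
    if df["species_id"].duplicated().any():
        dupes = sorted(df.loc[df["species_id"].duplicated(), "species_id"])
        raise SchemaError(f"species.csv: duplicate species {dupes}")
    return df


def clade_tags_from_metadata(meta: pd.DataFrame) -> dict[str, frozenset[str]]:
    return {row.species_id: frozenset([row.clade_tag]) for row in meta.itertuples()}


def pool_from_metadata(meta: pd.DataFrame, pool: str) -> frozenset[str]:
    if pool == "regional":
        return frozenset(meta["species_id"])
    return frozenset(meta.loc[meta["pool"] == pool, "species_id"])


def write_composition(path, tables: Iterable[CommunityTable]) -> None:
    long = pd.concat([t.to_long() for t in tables], ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    long.to_csv(path, index=False)
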