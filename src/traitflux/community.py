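"""Community time-series container and long-format I/O.

A community is a years x taxa table of densities (fish CPUE per net per
night, or zoobenthos individuals per square metre) for one monitoring area
and one trophic group.  Years that were not sampled are absent from the
table (not zero rows): a zero means "sampled, none caught".
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CommunityTimeSeries", "read_community_csv", "write_community_csv"]


@dataclass(frozen=True)
class CommunityTimeSeries:
    """Density matrix of one area x trophic-group community over time.

    Parameters
    ----------
    density : pandas.DataFrame
        Rows indexed by sampled year (int, strictly increasing), columns
        by unique taxon identifiers; values are non-negative densities.
    area, group : str
        Identifiers for the monitoring area and trophic group
        (conventionally ``"fish"`` or ``"zoobenthos"``).
    missing_years : tuple of int
        Years inside the nominal span that were not sampled.
    """

    density: pd.DataFrame
    area: str = "area"
    group: str = "community"
    missing_years: tuple = field(default_factory=tuple)

    def __post_init__(self):
        idx = self.density.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("years must be strictly increasing and unique")
        if self.density.columns.has_duplicates:
            raise ValueError("taxa must be unique")
        vals = self.density.to_numpy(dtype=float)
        if vals.size and (not np.all(np.isfinite(vals)) or (vals < 0).any()):
            raise ValueError("densities must be finite and non-negative")
        object.__setattr__(self, "missing_years", tuple(int(y) for y in self.missing_years))

    @property
    def years(self) -> np.ndarray:
        return self.density.index.to_numpy()

    @property
    def taxa(self) -> list:
        return list(self.density.columns)

    @property
    def n_sampled_years(self) -> int:
        return len(self.density.index)

    def with_density(self, density: pd.DataFrame) -> "CommunityTimeSeries":
        return replace(self, density=density)

    def full_year_range(self) -> np.ndarray:
        """All calendar years from first to last sampled year inclusive."""
        y = self.years
        return np.arange(int(y[0]), int(y[-1]) + 1)

    def missing_year_mask(self) -> pd.Series:
        """Boolean per calendar year in the full span: True = not sampled."""
        full = self.full_year_range()
        return pd.Series(~np.isin(full, self.years), index=full, name="missing")


def write_community_csv(cts: CommunityTimeSeries, path) -> None:
    """Write the standard long-format table: area, year, taxon, density."""
    long = (
        cts.density.stack()
        .rename("density")
        .rename_axis(["year", "taxon"])
        .reset_index()
    )
    long.insert(0, "area", cts.area)
    long.insert(1, "group", cts.group)
    long.to_csv(path, index=False)


def read_community_csv(path, area=None, group=None) -> CommunityTimeSeries:
    """Read a long-format community CSV (area, group, year, taxon, density).

    If the file holds several area/group combinations, ``area`` and
    ``group`` select one; with a single combination they may be omitted.
    """
    df = pd.read_csv(path)
    required = {"year", "taxon", "density"}
    if not required.issubset(df.columns):
        raise ValueError(f"community CSV must have columns {sorted(required)}")
    if "area" in df.columns and area is not None:
        df = df[df["area"] == area]
    if "group" in df.columns and group is not None:
        df = df[df["group"] == group]
    if df.empty:
        raise ValueError("no rows match the requested area/group")
    area = str(df["area"].iloc[0]) if "area" in df.columns else "area"
    group = str(df["group"].iloc[0]) if "group" in df.columns else "community"
    wide = (
        df.pivot_table(index="year", columns="taxon", values="density", aggfunc="sum")
        .fillna(0.0)
        .sort_index()
    )
    wide.columns.name = None
    years = wide.index.to_numpy()
    full = np.arange(int(years[0]), int(years[-1]) + 1)
    missing = tuple(int(y) for y in full[~np.isin(full, years)])
    return CommunityTimeSeries(density=wide, area=area, group=group, missing_years=missing)
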