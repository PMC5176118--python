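"""Long-format count tables and their conversion to sample series.

The on-disk format is a UTF-8 CSV with header
``population,year,morph,count,total`` and one row per population x
year x morph: ``count`` snails of that morph out of ``total`` snails
scored on that occasion.  ``total`` is the occasion's full sample, so
it repeats across the morph rows of one population-year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from morphsel.likelihood_fit import SampleSeries

__all__ = ["CountTable", "read_counts", "write_counts", "series_to_table"]

REQUIRED_COLUMNS = ("population", "year", "morph", "count", "total")


@dataclass(frozen=True)
class CountTable:
    """Validated long-format phenotype counts."""

    data: pd.DataFrame

    @property
    def populations(self) -> List[str]:
        return sorted(self.data["population"].unique())

    @property
    def morphs(self) -> List[str]:
        return sorted(self.data["morph"].unique())

    def series(self, population: str, morph: str) -> SampleSeries:
        """The (possibly zero-count) time series of one morph in one
        population, with totals taken from that population's samples."""
        sub = self.data[self.data["population"] == population]
        if sub.empty:
            raise KeyError(f"unknown population {population!r}")
        rows = (sub[sub["morph"] == morph].set_index("year")["count"]
                if (sub["morph"] == morph).any() else pd.Series(dtype=int))
        years = sorted(sub["year"].unique())
        totals = sub.groupby("year")["total"].first()
        counts = [int(rows.get(y, 0)) for y in years]
        return SampleSeries.from_counts(population, morph, years, counts,
                                        [int(totals[y]) for y in years])

    def nonfocal_series(self, morph: str, focal_map: Dict[str, str]
                        ) -> List[SampleSeries]:
        """Series of ``morph`` in every population where a different
        morph was the manipulated one."""
        return [self.series(pop, morph) for pop in self.populations
                if focal_map.get(pop) != morph]


def read_counts(path: str | Path) -> CountTable:
    """Read and validate a long-format count CSV.

    Raises ValueError naming the offending row (1-based, excluding the
    header) for counts exceeding totals, negative values or duplicate
    (population, year, morph) keys.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df[list(REQUIRED_COLUMNS)].copy()
    for col in ("year", "count", "total"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"column {col!r} must be integer: {exc}") from None
    for i, row in df.iterrows():
        if row["count"] < 0 or row["total"] < 0:
            raise ValueError(f"row {i + 1}: negative count or total")
        if row["count"] > row["total"]:
            raise ValueError(
                f"row {i + 1}: count {row['count']} exceeds total "
                f"{row['total']} ({row['population']}, {row['year']}, "
                f"{row['morph']})")
    dup = df.duplicated(subset=["population", "year", "morph"])
    if dup.any():
        first = int(dup.idxmax())
        raise ValueError(f"row {first + 1}: duplicate (population, year, "
                         "morph) key")
    bad_tot = df.groupby(["population", "year"])["total"].nunique()
    if (bad_tot > 1).any():
        pop, year = bad_tot[bad_tot > 1].index[0]
        raise ValueError(f"inconsistent totals for ({pop}, {year})")
    return CountTable(df.reset_index(drop=True))


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a CountTable back to CSV (round-trips with read_counts)."""
    table.data.to_csv(path, index=False)


def series_to_table(series_list: Sequence[SampleSeries]) -> CountTable:
    """Assemble focal-morph series into a long-format table.

    Each occasion yields two rows: the focal morph's count and an
    'other' row holding the remainder, so totals are recoverable."""
    rows = []
    for s in series_list:
        for y, k, n in zip(s.years, s.counts, s.totals):
            rows.append((s.population_id, y, s.morph, k, n))
            rows.append((s.population_id, y, "other", n - k, n))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return CountTable(df)
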