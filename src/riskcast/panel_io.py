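"""Multi-region annual panel ingestion, normalization and filtering.

The central container is :class:`Panel`: a wide table of annual rates with one
column per region and one row per year of the common year grid. Gaps are kept
as NaN and are never silently zero-filled — downstream exceedance counting
depends on missing years being genuinely absent, not imputed.

Input is the long-format country–year CSV used by public cause-of-death
exports (columns ``Entity, Code, Year, <value>``); a schema mapping overrides
the column names. The canonical internal unit is percent of local population;
per-100k inputs are converted on load, raw counts are normalized with
:func:`normalize_to_percent`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    IntegrityError,
    ParseError,
    SchemaError,
)

UNITS = ("count", "percent_of_population", "per_100k")

DEFAULT_SCHEMA = {"region": "Entity", "code": "Code", "year": "Year", "value": None}


@dataclass
class RegionSeries:
    """One region's annual series on the panel's year grid.

    ``values`` may contain NaN for years the region was not observed; all
    observed values are non-negative rates (or counts, per the panel units).
    """

    region_id: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or len(self.years) != len(self.values):
            raise ValueError("years and values must be 1-D and equal length")
        if len(self.years) > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError(f"years not strictly increasing for {self.region_id!r}")
        observed = self.values[np.isfinite(self.values)]
        if np.any(observed < 0):
            raise ValueError(f"negative values in series for {self.region_id!r}")

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class Panel:
    """Wide annual panel: ``data`` indexed by year, one column per region."""

    data: pd.DataFrame
    units: str = "percent_of_population"
    scaled: bool = False
    codes: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise IntegrityError(f"duplicate region ids: {dupes}")
        self.data = self.data.sort_index()

    @property
    def region_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=int)

    @property
    def year_range(self) -> tuple:
        return int(self.data.index.min()), int(self.data.index.max())

    def region(self, region_id: str) -> RegionSeries:
        if region_id not in self.data.columns:
            raise KeyError(f"no region {region_id!r} in panel")
        return RegionSeries(region_id, self.years, self.data[region_id].to_numpy(float))

    def __iter__(self):
        for rid in self.data.columns:
            yield self.region(rid)


def load_panel(path, schema: dict | None = None, units: str = "percent_of_population") -> Panel:
    """Read a long-format region–year CSV into a :class:`Panel`.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    schema : dict, optional
        Mapping with keys ``region``, ``year``, optionally ``code`` and
        ``value``, giving the column names to use. When ``value`` is None the
        single remaining column is taken as the value column.
    units : str
        Units of the value column. ``per_100k`` values are converted to
        percent of population (×10⁻³) on load.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    if units not in UNITS:
        raise SchemaError(f"unknown units {units!r}; expected one of {UNITS}")

    df = pd.read_csv(path, dtype=str)
    for key in ("region", "year"):
        col = sch[key]
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} (schema key {key!r}) not in CSV")
    value_col = sch.get("value")
    if value_col is None:
        known = {sch["region"], sch["year"], sch.get("code")}
        rest = [c for c in df.columns if c not in known]
        if len(rest) != 1:
            raise SchemaError(
                f"cannot infer value column: candidates {rest}; pass schema['value']"
            )
        value_col = rest[0]
    elif value_col not in df.columns:
        raise SchemaError(f"value column {value_col!r} not in CSV")

    years = pd.to_numeric(df[sch["year"]], errors="coerce")
    bad = years.isna() & df[sch["year"]].notna()
    if bad.any():
        raise ParseError(f"non-numeric year at row(s) {df.index[bad].tolist()[:5]}")
    values = pd.to_numeric(df[value_col], errors="coerce")
    bad = values.isna() & df[value_col].notna()
    if bad.any():
        raise ParseError(f"non-numeric value at row(s) {df.index[bad].tolist()[:5]}")

    long = pd.DataFrame(
        {
            "region": df[sch["region"]].astype(str),
            "year": years.astype(int),
            "value": values.astype(float),
        }
    )
    dup = long.duplicated(subset=["region", "year"], keep=False)
    if dup.any():
        first = long.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate observation for region {first['region']!r}, year {int(first['year'])}"
        )

    wide = long.pivot(index="year", columns="region", values="value")
    wide.columns.name = None
    wide.index.name = "year"

    codes = {}
    code_col = sch.get("code")
    if code_col and code_col in df.columns:
        codes = (
            df[[sch["region"], code_col]]
            .dropna()
            .drop_duplicates()
            .set_index(sch["region"])[code_col]
            .to_dict()
        )

    if units == "per_100k":
        wide = wide * 1e-3
        units = "percent_of_population"

    return Panel(data=wide, units=units, codes=codes, meta={"source": str(path)})


def write_panel(panel: Panel, path: str) -> None:
    """Serialize a panel back to the long-format CSV plus a JSON sidecar.

    Rows are sorted by region then year and missing years are skipped, so a
    load → write → load cycle is exact and a second write is byte-identical.
    """
    rows = []
    for series in panel:
        mask = series.observed_mask
        for year, value in zip(series.years[mask], series.values[mask]):
            rows.append(
                {
                    "Entity": series.region_id,
                    "Code": panel.codes.get(series.region_id, ""),
                    "Year": int(year),
                    "Value": repr(float(value)),
                }
            )
    out = pd.DataFrame(rows, columns=["Entity", "Code", "Year", "Value"])
    out = out.sort_values(["Entity", "Year"], kind="stable")
    out.to_csv(path, index=False)
    sidecar = {
        "units": panel.units,
        "scaled": panel.scaled,
        "excluded": panel.meta.get("excluded", []),
        "provenance": panel.meta.get("source", ""),
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def normalize_to_percent(panel: Panel, pops: pd.DataFrame) -> Panel:
    """Convert a count panel to percent of local population.

    ``pops`` holds columns ``region_id, year, population`` with positive
    populations and unique (region, year) pairs. Every observed (region, year)
    cell must be covered, otherwise a :class:`CoverageError` lists the missing
    pairs.
    """
    if panel.units != "count":
        raise SchemaError(f"panel units must be 'count', got {panel.units!r}")
    pops = pops.rename(columns=str).copy()
    required = {"region_id", "year", "population"}
    if not required <= set(pops.columns):
        raise SchemaError(f"population table needs columns {sorted(required)}")
    if (pops["population"] <= 0).any():
        raise ValueError("population values must be positive")
    if pops.duplicated(subset=["region_id", "year"]).any():
        raise IntegrityError("duplicate (region_id, year) in population table")

    pop_wide = pops.pivot(index="year", columns="region_id", values="population")
    pop_wide = pop_wide.reindex(index=panel.data.index, columns=panel.data.columns)

    missing = panel.data.notna() & pop_wide.isna()
    if missing.any().any():
        pairs = [
            (region, int(year))
            for region in missing.columns
            for year in missing.index[missing[region]]
        ]
        raise CoverageError(f"population missing for observed pairs: {pairs[:10]}")

    out = 100.0 * panel.data / pop_wide
    return Panel(
        data=out,
        units="percent_of_population",
        scaled=panel.scaled,
        codes=dict(panel.codes),
        meta=dict(panel.meta),
    )


def exclude_regions(panel: Panel, blocklist) -> Panel:
    """Drop listed regions (e.g. outlier nations) from the panel.

    Unknown names in the blocklist produce a warning, never an error. The
    applied exclusions are recorded in the returned panel's metadata; the
    input panel is untouched.
    """
    blocklist = list(blocklist)
    present = [r for r in blocklist if r in panel.data.columns]
    absent = [r for r in blocklist if r not in panel.data.columns]
    if absent:
        warnings.warn(f"blocklist entries not in panel: {absent}", stacklevel=2)
    meta = dict(panel.meta)
    meta["excluded"] = list(meta.get("excluded", [])) + present
    return Panel(
        data=panel.data.drop(columns=present),
        units=panel.units,
        scaled=panel.scaled,
        codes={k: v for k, v in panel.codes.items() if k not in present},
        meta=meta,
    )
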