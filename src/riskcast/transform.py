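"""Hazard-limit scaling, local-maxima extraction and component merging.

A multi-region panel is treated as one multi-degree-of-freedom system whose
components are the per-region series. Each component is made dimensionless by
dividing by its hazard (critical) limit η_r, so every component shares the
failure level 1. The per-component maxima are then merged into a single
time-ordered synthetic series R on which all exceedance statistics are
computed.

Two merge strategies are provided:

* ``merge_interleave`` — interleave all component events in non-decreasing
  time order; events coincident in time collapse to a single event carrying
  the componentwise maximum and all source labels. No input event is lost.
* ``merge_pointwise_max`` — one event per year: the maximum across regions
  observed that year. This is the natural reduction for synchronous annual
  panels and the default in the pipeline.

For annual surveillance data each region contributes exactly one value per
year, so "local maxima" extraction degenerates; mode ``all_values`` (the
default for annual panels) keeps every observation, while ``strict`` keeps
only interior points exceeding both neighbours and is retained for denser
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, LimitsError
from .panel_io import Panel, RegionSeries


@dataclass(frozen=True)
class HazardLimits:
    """Critical level η_r per region, or one scalar for all regions."""

    default: float | None = None
    per_region: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def scalar(cls, value: float) -> "HazardLimits":
        return cls(default=float(value))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "HazardLimits":
        return cls(per_region=dict(mapping))

    def for_region(self, region_id: str) -> float:
        eta = self.per_region.get(region_id, self.default)
        if eta is None:
            raise LimitsError(f"no hazard limit for region {region_id!r}")
        if not (eta > 0):
            raise LimitsError(f"hazard limit for region {region_id!r} must be > 0, got {eta}")
        return float(eta)


@dataclass
class EventList:
    """Time-ordered (time, value) local maxima of one component."""

    region_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"event times not strictly increasing for {self.region_id!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MergedSeries:
    """The synthetic R-vector: merged maxima of all components.

    ``sources[i]`` is the tuple of region labels contributing event i (more
    than one only for time-coincident events collapsed to their maximum).
    """

    times: np.ndarray
    values: np.ndarray
    sources: list
    scaled: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.times) == len(self.values) == len(self.sources)):
            raise ValueError("times, values and sources must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("merged times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def span_years(self) -> float:
        if len(self.times) == 0:
            return 0.0
        return float(self.times[-1] - self.times[0] + 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "value": self.values,
                "sources": [";".join(s) for s in self.sources],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scaled: bool = False) -> "MergedSeries":
        sources = [tuple(str(s).split(";")) if str(s) else () for s in df["sources"]]
        return cls(
            times=df["time"].to_numpy(float),
            values=df["value"].to_numpy(float),
            sources=sources,
            scaled=scaled,
        )


def scale_components(panel: Panel, limits: HazardLimits) -> Panel:
    """Divide each region by its hazard limit; the shared limit becomes 1."""
    etas = {rid: limits.for_region(rid) for rid in panel.region_ids}
    out = panel.data.div(pd.Series(etas), axis="columns")
    return Panel(
        data=out,
        units=panel.units,
        scaled=True,
        codes=dict(panel.codes),
        meta=dict(panel.meta),
    )


def extract_local_maxima(series: RegionSeries, mode: str = "all_values") -> EventList:
    """Per-component event extraction.

    ``all_values`` keeps every observed point; ``strict`` keeps interior
    observed points strictly exceeding both their observed neighbours
    (missing years are skipped, not treated as zeros).
    """
    mask = series.observed_mask
    if not mask.any():
        raise EmptyInputError(f"series {series.region_id!r} has no observed values")
    years = series.years[mask].astype(float)
    vals = series.values[mask]
    if mode == "all_values":
        return EventList(series.region_id, years, vals)
    if mode != "strict":
        raise ValueError(f"unknown maxima mode {mode!r}")
    if len(vals) < 3:
        return EventList(series.region_id, np.empty(0), np.empty(0))
    interior = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    idx = np.flatnonzero(interior) + 1
    return EventList(series.region_id, years[idx], vals[idx])


def merge_interleave(event_lists: Iterable[EventList]) -> MergedSeries:
    """Interleave component events in non-decreasing time order.

    Events sharing a timestamp across components collapse to one event whose
    value is the componentwise maximum and whose sources list every
    contributing component — so every input event remains represented.
    """
    records = []
    for ev in event_lists:
        for t, v in zip(ev.times, ev.values):
            records.append((float(t), float(v), ev.region_id))
    records.sort(key=lambda r: (r[0], r[2]))

    times, values, sources = [], [], []
    for t, v, rid in records:
        if times and t == times[-1]:
            if v > values[-1]:
                values[-1] = v
            sources[-1] = sources[-1] + (rid,)
        else:
            times.append(t)
            values.append(v)
            sources.append((rid,))
    return MergedSeries(np.array(times), np.array(values), sources)


def merge_pointwise_max(panel: Panel) -> MergedSeries:
    """Columnwise maximum per year: R_j = max over regions observed in year j."""
    if panel.n_regions == 0:
        raise EmptyInputError("panel has no regions")
    data = panel.data
    any_obs = data.notna().any(axis=1)
    if not any_obs.any():
        raise EmptyInputError("panel has no observed values")
    sub = data.loc[any_obs]
    values = sub.max(axis=1, skipna=True).to_numpy(float)
    argmax = sub.idxmax(axis=1, skipna=True)
    times = sub.index.to_numpy(float)
    sources = [(str(r),) for r in argmax]
    return MergedSeries(times, values, sources, scaled=panel.scaled)
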