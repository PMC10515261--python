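"""Hazard scaling, local-maxima extraction and the two merge strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskcast import (
    HazardLimits,
    Panel,
    extract_local_maxima,
    merge_interleave,
    merge_pointwise_max,
    scale_components,
)
from riskcast.errors import EmptyInputError, LimitsError
from riskcast.panel_io import RegionSeries
from riskcast.transform import EventList


def panel_from_dict(d, years=None):
    cols = {k: np.asarray(v, dtype=float) for k, v in d.items()}
    n = len(next(iter(cols.values())))
    idx = pd.Index(years if years is not None else range(1990, 1990 + n), name="year")
    return Panel(data=pd.DataFrame(cols, index=idx))


class TestScale:
    def test_divides_by_limit(self):
        panel = panel_from_dict({"A": [0.01, 0.02]})
        out = scale_components(panel, HazardLimits.scalar(0.05))
        np.testing.assert_allclose(out.region("A").values, [0.2, 0.4])
        assert out.scaled

    def test_unit_limit_is_identity(self):
        panel = panel_from_dict({"A": [0.3, 0.7], "B": [0.2, 0.9]})
        out = scale_components(panel, HazardLimits.scalar(1.0))
        np.testing.assert_array_equal(out.data.to_numpy(), panel.data.to_numpy())

    def test_nonpositive_limit_names_region(self):
        panel = panel_from_dict({"A": [0.3], "B": [0.2]})
        limits = HazardLimits(per_region={"A": 1.0, "B": 0.0})
        with pytest.raises(LimitsError, match="B"):
            scale_components(panel, limits)

    def test_missing_limit_names_region(self):
        panel = panel_from_dict({"A": [0.3], "B": [0.2]})
        with pytest.raises(LimitsError, match="B"):
            scale_components(panel, HazardLimits(per_region={"A": 1.0}))


class TestLocalMaxima:
    def test_strict_interior_maxima(self):
        s = RegionSeries("A", range(5), [1, 3, 2, 5, 4])
        ev = extract_local_maxima(s, mode="strict")
        assert ev.values.tolist() == [3.0, 5.0]
        assert ev.times.tolist() == [1.0, 3.0]

    def test_constant_series_has_no_strict_maxima(self):
        ev = extract_local_maxima(RegionSeries("A", range(3), [2, 2, 2]), mode="strict")
        assert len(ev) == 0

    def test_all_values_keeps_every_observation(self):
        s = RegionSeries("A", range(4), [1, 4, 2, 8])
        ev = extract_local_maxima(s, mode="all_values")
        assert ev.values.tolist() == [1, 4, 2, 8]

    def test_missing_years_are_skipped_not_zeroed(self):
        s = RegionSeries("A", range(5), [1, np.nan, 2, np.nan, 3])
        ev = extract_local_maxima(s, mode="all_values")
        assert ev.values.tolist() == [1, 2, 3]
        assert ev.times.tolist() == [0.0, 2.0, 4.0]

    def test_empty_series_raises(self):
        with pytest.raises(EmptyInputError):
            extract_local_maxima(RegionSeries("A", range(2), [np.nan, np.nan]))


class TestInterleave:
    def test_disjoint_times_interleave_fully(self):
        x = EventList("X", [1, 3], [0.5, 0.8])
        y = EventList("Y", [2, 4], [0.6, 0.4])
        merged = merge_interleave([x, y])
        assert merged.times.tolist() == [1, 2, 3, 4]
        assert merged.values.tolist() == [0.5, 0.6, 0.8, 0.4]
        assert len(merged) == 4

    def test_simultaneous_maxima_collapse_to_componentwise_max(self):
        x = EventList("X", [3], [0.8])
        y = EventList("Y", [3], [0.4])
        merged = merge_interleave([x, y])
        assert len(merged) == 1
        assert merged.values[0] == 0.8
        assert set(merged.sources[0]) == {"X", "Y"}

    def test_empty_component_is_neutral(self):
        x = EventList("X", [1, 2], [0.1, 0.2])
        empty = EventList("Z", [], [])
        merged = merge_interleave([x, empty])
        assert merged.values.tolist() == [0.1, 0.2]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_every_event_represented_and_times_sorted(self, data):
        n_comp = data.draw(st.integers(1, 4))
        lists = []
        for i in range(n_comp):
            n = data.draw(st.integers(0, 8))
            times = sorted(
                data.draw(
                    st.lists(st.integers(0, 10), min_size=n, max_size=n, unique=True)
                )
            )
            vals = data.draw(
                st.lists(
                    st.floats(0, 10, allow_nan=False), min_size=n, max_size=n
                )
            )
            lists.append(EventList(f"C{i}", np.array(times, float), np.array(vals)))
        merged = merge_interleave(lists)
        assert np.all(np.diff(merged.times) >= 0)
        # reconstruction: merged value at time t is the max over all input
        # events at t, and every input event's time is present
        by_time = {}
        for ev in lists:
            for t, v in zip(ev.times, ev.values):
                by_time[t] = max(by_time.get(t, -np.inf), v)
        assert dict(zip(merged.times, merged.values)) == by_time
        assert len(merged) == len(by_time)


class TestPointwiseMax:
    def test_columnwise_maximum(self):
        panel = panel_from_dict({"X": [0.1, 0.5], "Y": [0.3, 0.2]}, years=[1990, 1991])
        merged = merge_pointwise_max(panel)
        assert merged.times.tolist() == [1990.0, 1991.0]
        assert merged.values.tolist() == [0.3, 0.5]
        assert merged.sources == [("Y",), ("X",)]

    def test_single_region_is_identity(self):
        panel = panel_from_dict({"X": [0.4, 0.1, 0.9]})
        merged = merge_pointwise_max(panel)
        assert merged.values.tolist() == [0.4, 0.1, 0.9]

    def test_year_with_one_observed_region_uses_it(self):
        panel = panel_from_dict({"X": [0.1, np.nan], "Y": [np.nan, 0.7]})
        merged = merge_pointwise_max(panel)
        assert merged.values.tolist() == [0.1, 0.7]

    def test_year_missing_everywhere_is_dropped(self):
        panel = panel_from_dict({"X": [0.1, np.nan, 0.2], "Y": [0.3, np.nan, np.nan]})
        merged = merge_pointwise_max(panel)
        assert merged.times.tolist() == [1990.0, 1992.0]

    def test_empty_panel_raises(self):
        panel = Panel(data=pd.DataFrame(index=pd.Index([1990], name="year")))
        with pytest.raises(EmptyInputError):
            merge_pointwise_max(panel)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.integers(1, 5),
        st.integers(1, 8),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_bruteforce_columnwise_max(self, n_regions, n_years, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1, size=(n_years, n_regions))
        values[rng.uniform(size=values.shape) < 0.3] = np.nan
        panel = panel_from_dict(
            {f"R{i}": values[:, i] for i in range(n_regions)}
        )
        keep = ~np.all(np.isnan(values), axis=1)
        if not keep.any():
            return
        merged = merge_pointwise_max(panel)
        expected = [max(v for v in row if not np.isnan(v)) for row in values[keep]]
        assert merged.values.tolist() == expected


def test_equal_limits_commute_with_merging():
    rng = np.random.default_rng(1)
    values = rng.uniform(0, 1, size=(6, 3))
    panel = panel_from_dict({f"R{i}": values[:, i] for i in range(3)})
    eta = 0.25
    scaled_first = merge_pointwise_max(scale_components(panel, HazardLimits.scalar(eta)))
    merged_first = merge_pointwise_max(panel)
    np.testing.assert_allclose(scaled_first.values, merged_first.values / eta)
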