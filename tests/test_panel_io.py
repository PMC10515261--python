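"""Panel ingestion, normalization and region filtering."""

import io

import numpy as np
import pandas as pd
import pytest

from riskcast import exclude_regions, load_panel, normalize_to_percent, write_panel
from riskcast.errors import CoverageError, IntegrityError, ParseError, SchemaError

CSV_2X3 = """Entity,Code,Year,Deaths
A,AA,1990,0.01
A,AA,1991,0.02
A,AA,1992,0.03
B,BB,1990,0.04
B,BB,1991,0.05
B,BB,1992,0.06
"""


def test_load_two_regions_three_years():
    panel = load_panel(io.StringIO(CSV_2X3))
    assert panel.n_regions == 2
    assert panel.year_range == (1990, 1992)
    assert panel.region("A").values.tolist() == [0.01, 0.02, 0.03]
    assert panel.codes == {"A": "AA", "B": "BB"}


def test_load_preserves_gap_as_missing():
    csv = "Entity,Code,Year,Deaths\nA,AA,1994,1.0\nA,AA,1996,2.0\nB,BB,1995,3.0\n"
    panel = load_panel(io.StringIO(csv))
    a = panel.region("A")
    assert a.years.tolist() == [1994, 1995, 1996]
    assert np.isnan(a.values[1])  # 1995 missing for A, not zero-filled
    assert not np.isnan(panel.region("B").values[1])


def test_load_duplicate_region_year_is_integrity_error():
    csv = "Entity,Code,Year,Deaths\nA,AA,1990,1.0\nA,AA,1990,2.0\n"
    with pytest.raises(IntegrityError, match=r"'A'.*1990"):
        load_panel(io.StringIO(csv))


def test_load_missing_column_and_bad_cell():
    with pytest.raises(SchemaError, match="Year"):
        load_panel(io.StringIO("Entity,Deaths\nA,1.0\n"))
    with pytest.raises(ParseError, match=r"row"):
        load_panel(io.StringIO("Entity,Code,Year,Deaths\nA,AA,1990,oops\n"))


def test_per_100k_converted_to_percent_on_load():
    csv = "Entity,Code,Year,Rate\nA,AA,1990,50.0\n"
    panel = load_panel(io.StringIO(csv), units="per_100k")
    assert panel.units == "percent_of_population"
    assert panel.region("A").values[0] == pytest.approx(0.05)


def test_roundtrip_is_exact_and_rewrite_is_byte_identical(tmp_path):
    panel = load_panel(io.StringIO(CSV_2X3))
    p1 = tmp_path / "panel.csv"
    write_panel(panel, p1)
    again = load_panel(p1, schema={"value": "Value"})
    pd.testing.assert_frame_equal(panel.data, again.data)
    p2 = tmp_path / "panel2.csv"
    write_panel(again, p2)
    assert p1.read_bytes() == p2.read_bytes()


class TestNormalize:
    def _count_panel(self, rows):
        csv = "Entity,Code,Year,Deaths\n" + "".join(
            f"{r},{r}{r},{y},{v}\n" for r, y, v in rows
        )
        return load_panel(io.StringIO(csv), units="count")

    def test_basic_arithmetic_and_zero(self):
        panel = self._count_panel([("A", 1990, 50), ("A", 1991, 0)])
        pops = pd.DataFrame(
            {"region_id": ["A", "A"], "year": [1990, 1991], "population": [100_000, 100_000]}
        )
        out = normalize_to_percent(panel, pops)
        assert out.units == "percent_of_population"
        assert out.region("A").values.tolist() == [0.05, 0.0]

    def test_missing_population_is_coverage_error(self):
        panel = self._count_panel([("B", 2001, 10)])
        pops = pd.DataFrame({"region_id": ["B"], "year": [2000], "population": [1000]})
        with pytest.raises(CoverageError, match="B"):
            normalize_to_percent(panel, pops)

    def test_population_homogeneity(self):
        # scaling all populations by c divides all rates by c
        panel = self._count_panel([("A", 1990, 30), ("B", 1990, 70)])
        pops = pd.DataFrame(
            {"region_id": ["A", "B"], "year": [1990, 1990], "population": [1000, 2000]}
        )
        base = normalize_to_percent(panel, pops)
        scaled_pops = pops.assign(population=pops["population"] * 4)
        scaled = normalize_to_percent(panel, scaled_pops)
        np.testing.assert_allclose(scaled.data.to_numpy(), base.data.to_numpy() / 4)


class TestExclude:
    def test_removes_listed_regions_only(self):
        panel = load_panel(io.StringIO(CSV_2X3))
        out = exclude_regions(panel, ["A"])
        assert out.region_ids == ["B"]
        assert panel.region_ids == ["A", "B"]  # original untouched
        assert out.meta["excluded"] == ["A"]

    def test_empty_blocklist_is_identity(self):
        panel = load_panel(io.StringIO(CSV_2X3))
        out = exclude_regions(panel, [])
        pd.testing.assert_frame_equal(out.data, panel.data)

    def test_unknown_name_warns_not_errors(self):
        panel = load_panel(io.StringIO(CSV_2X3))
        with pytest.warns(UserWarning, match="Atlantis"):
            out = exclude_regions(panel, ["Atlantis"])
        pd.testing.assert_frame_equal(out.data, panel.data)

    def test_sequential_equals_union(self):
        csv = "Entity,Code,Year,V\n" + "".join(
            f"R{i},C{i},1990,{i}.0\n" for i in range(6)
        )
        panel = load_panel(io.StringIO(csv))
        union = exclude_regions(panel, ["R1", "R2", "R4"])
        seq = exclude_regions(exclude_regions(panel, ["R1", "R2"]), ["R4"])
        assert union.region_ids == seq.region_ids
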