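"""Timescales, range I/O and boundary-crosser bookkeeping."""

import numpy as np
import pytest

from fossilprior.errors import RangeDataError, TimescaleError
from fossilprior.strat import (
    BinCrossingCounts,
    StratBin,
    StratTimescale,
    classify_bin_crossers,
    load_ranges,
    load_timescale,
    oldest_bin_diversity,
    write_ranges,
)

from conftest import make_dataset


class TestTimescale:
    def test_builtin_isc_is_contiguous_and_reaches_present(self, isc):
        assert isc.bins[-1].younger_bound == 0
        for older, younger in zip(isc.bins, isc.bins[1:]):
            assert older.older_bound > older.younger_bound
            assert older.younger_bound == pytest.approx(younger.older_bound)

    def test_builtin_pbdb_bins_are_10ma(self):
        ts = load_timescale("PBDB_10Ma")
        assert all(b.duration == pytest.approx(10.0) for b in ts.bins[:-1])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(TimescaleError, match="unknown scheme"):
            load_timescale("no_such_scheme")

    def test_custom_table(self, tmp_path):
        p = tmp_path / "ts.tsv"
        p.write_text("name\tolder_bound\tyounger_bound\nA\t20\t10\nB\t10\t0\n")
        ts = load_timescale("custom", custom_table_path=p)
        assert len(ts) == 2
        assert [b.duration for b in ts.bins] == [10, 10]

    def test_gap_in_custom_table_rejected(self, tmp_path):
        p = tmp_path / "ts.tsv"
        p.write_text("name\tolder_bound\tyounger_bound\nA\t20\t12\nB\t10\t0\n")
        with pytest.raises(TimescaleError, match="not contiguous"):
            load_timescale("custom", custom_table_path=p)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(TimescaleError):
            StratBin("bad", 10.0, 10.0)

    def test_timescale_must_reach_present(self):
        with pytest.raises(TimescaleError, match="present"):
            StratTimescale("x", (StratBin("A", 20, 10),))

    def test_boundary_age_snaps_to_younger_bin(self, isc):
        # 189.6 Ma is shared by Sinemurian (older) and Pliensbachian (younger)
        assert isc.bin_containing(189.6).name == "Pliensbachian"
        assert isc.bin_containing(0.0).name == "Holocene"
        assert isc.bin_containing(isc.span).name == isc.bins[0].name

    def test_age_outside_span_rejected(self, isc):
        with pytest.raises(RangeDataError):
            isc.bin_containing(1000.0)


class TestRangeIO:
    def test_bin_name_round_trip(self, tmp_path, isc, toy_dataset):
        path = tmp_path / "ranges.tsv"
        write_ranges(toy_dataset, path)
        back = load_ranges(path, isc)
        assert [(r.taxon, r.first_bin.name, r.last_bin.name) for r in back.ranges] == [
            (r.taxon, r.first_bin.name, r.last_bin.name) for r in toy_dataset.ranges
        ]

    def test_numeric_ages_snapped(self, tmp_path, isc):
        path = tmp_path / "ranges.csv"
        path.write_text("taxon,first_ma,last_ma\ng1,172.0,169.0\ng2,189.6,189.6\n")
        ds = load_ranges(path, isc)
        assert ds.ranges[0].first_bin.name == "Aalenian"
        assert ds.ranges[0].last_bin.name == "Bajocian"
        # exact shared boundary goes to the younger bin
        assert ds.ranges[1].first_bin.name == "Pliensbachian"

    def test_singleton_range(self, tmp_path, isc):
        path = tmp_path / "r.tsv"
        path.write_text("taxon\tfirst\tlast\ng1\tToarcian\tToarcian\n")
        ds = load_ranges(path, isc)
        assert ds.ranges[0].first_bin == ds.ranges[0].last_bin

    def test_reversed_range_rejected(self, tmp_path, isc):
        path = tmp_path / "r.tsv"
        path.write_text("taxon\tfirst\tlast\ng1\tBajocian\tToarcian\n")
        with pytest.raises(RangeDataError, match="younger"):
            load_ranges(path, isc)

    def test_unknown_bin_rejected(self, tmp_path, isc):
        path = tmp_path / "r.tsv"
        path.write_text("taxon\tfirst\tlast\ng1\tNowhere\tToarcian\n")
        with pytest.raises(TimescaleError):
            load_ranges(path, isc)

    def test_duplicate_taxa_warn_but_kept(self, tmp_path, isc):
        path = tmp_path / "r.tsv"
        path.write_text(
            "taxon\tfirst\tlast\ng1\tToarcian\tToarcian\ng1\tAalenian\tAalenian\n"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            ds = load_ranges(path, isc)
        assert len(ds) == 2


class TestBinCrossers:
    @pytest.mark.parametrize(
        "rows, bin_name, expect",
        [
            # range spanning the bin crosses both boundaries
            ([("a", "u01", "u03")], "u02", (1, 0, 0, 0)),
            # singleton confined to the bin
            ([("a", "u02", "u02")], "u02", (0, 0, 0, 1)),
            # all four classes at once
            (
                [("a", "u01", "u03"), ("b", "u01", "u02"),
                 ("c", "u02", "u03"), ("d", "u02", "u02")],
                "u02",
                (1, 1, 1, 1),
            ),
            # no intersection
            ([("a", "u05", "u06")], "u02", (0, 0, 0, 0)),
        ],
    )
    def test_four_classes(self, uniform_ts, rows, bin_name, expect):
        ds = make_dataset(uniform_ts, rows)
        c = classify_bin_crossers(ds, uniform_ts.bin_named(bin_name))
        assert (c.n_bt, c.n_bL, c.n_Ft, c.n_FL) == expect

    def test_derived_boundary_counts(self, uniform_ts):
        ds = make_dataset(
            uniform_ts,
            [("a", "u01", "u03"), ("b", "u01", "u02"),
             ("c", "u02", "u03"), ("d", "u02", "u02")],
        )
        c = classify_bin_crossers(ds, uniform_ts.bin_named("u02"))
        assert c.n_b == 2 and c.n_t == 2 and c.total == 4

    def test_classes_partition_intersecting_ranges(self, uniform_ts):
        """For every bin, the four classes partition the intersecting ranges."""
        rng = np.random.default_rng(42)
        n_bins = len(uniform_ts)
        rows = []
        for i in range(40):
            f = int(rng.integers(n_bins))
            l = min(n_bins - 1, f + int(rng.integers(6)))
            rows.append((f"x{i}", uniform_ts.bins[f].name, uniform_ts.bins[l].name))
        ds = make_dataset(uniform_ts, rows)
        first, last = ds.first_last_indices()
        for k in range(n_bins):
            c = classify_bin_crossers(ds, uniform_ts.bins[k])
            assert c.total == int(np.sum((first <= k) & (last >= k)))


class TestOldestBinDiversity:
    def test_single_range(self, uniform_ts):
        ds = make_dataset(uniform_ts, [("a", "u01", "u03")])
        b, n = oldest_bin_diversity(ds)
        assert b.name == "u01" and n == 1

    def test_count_of_ranges_intersecting_oldest_bin(self, uniform_ts):
        ds = make_dataset(
            uniform_ts, [("a", "u01", "u02"), ("b", "u01", "u01"), ("c", "u02", "u03")]
        )
        b, n = oldest_bin_diversity(ds)
        assert b.name == "u01" and n == 2

    def test_all_in_youngest_bin(self, uniform_ts):
        last = uniform_ts.bins[-1].name
        ds = make_dataset(uniform_ts, [("a", last, last), ("b", last, last)])
        b, n = oldest_bin_diversity(ds)
        assert b.name == last and n == 2

    def test_bounds(self, toy_dataset):
        _, n = oldest_bin_diversity(toy_dataset)
        assert 1 <= n <= len(toy_dataset)
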