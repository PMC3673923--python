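"""Clade simulation, preservation degradation, and the two study harnesses."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from fossilprior.simulate import (
    SimClade,
    SimLineage,
    ValidationConfig,
    bin_and_thin,
    run_sensitivity,
    run_validation,
    simulate_clade,
    simulate_occurrences,
    subsample_occurrences,
)
from fossilprior.strat import TaxonRange

from conftest import make_dataset


class TestSimulateClade:
    def test_no_events_single_lineage(self, uniform_ts):
        clade = simulate_clade(200.0, 0.0, 0.0, timescale=uniform_ts, seed=1)
        assert len(clade.lineages) == 1
        ln = clade.lineages[0]
        assert ln.birth_age == 200.0 and ln.extant
        assert clade.extant_count == 1

    def test_seeded_run_is_reproducible(self, uniform_ts):
        a = simulate_clade(150.0, 0.08, 0.05, timescale=uniform_ts, seed=42)
        b = simulate_clade(150.0, 0.08, 0.05, timescale=uniform_ts, seed=42)
        assert a == b

    def test_yule_extant_count_expectation(self, uniform_ts):
        """Pure-birth clades: E[N] = exp(p * origin_age), within 3 SE."""
        p, T = 0.02, 100.0
        counts = [
            simulate_clade(T, p, 0.0, timescale=uniform_ts, seed=s).extant_count
            for s in range(400)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - math.exp(p * T)) < 3 * se

    def test_conditioning_on_min_extant(self, uniform_ts):
        clade = simulate_clade(100.0, 0.05, 0.05, timescale=uniform_ts,
                               seed=3, min_extant=10)
        assert clade.extant_count >= 10

    def test_per_interval_units_need_timescale(self):
        with pytest.raises(ValueError):
            simulate_clade(100.0, 1.0, 0.9, rate_units="per_interval", seed=0)

    def test_extinct_clade_parameters_raise_after_rejections(self, uniform_ts):
        with pytest.raises(RuntimeError, match="survival"):
            simulate_clade(200.0, 0.0, 0.5, timescale=uniform_ts, seed=0,
                           max_rejections=20)


class TestBinAndThin:
    def test_perfect_preservation_keeps_true_binned_ranges(self, uniform_ts):
        clade = simulate_clade(200.0, 0.06, 0.04, timescale=uniform_ts, seed=5)
        ds = bin_and_thin(clade, uniform_ts, 1.0, seed=0)
        assert len(ds) == len(clade.lineages)
        for ln, r in zip(clade.lineages, ds.ranges):
            bins = uniform_ts.bins_overlapping(ln.birth_age, ln.death_age)
            assert r.first_bin == bins[0]
            assert r.last_bin == bins[-1]

    def test_zero_preservation_loses_everything(self, uniform_ts):
        clade = simulate_clade(200.0, 0.06, 0.04, timescale=uniform_ts, seed=5)
        assert bin_and_thin(clade, uniform_ts, 0.0, seed=0) is None

    def test_cell_preservation_frequency_matches_rate(self, uniform_ts):
        # 10^4 single-bin lineages: each occupies one cell, so the fraction
        # preserved estimates the per-cell rate directly
        n = 10_000
        R = 0.37
        mid = uniform_ts.bins[20]
        lineages = tuple(
            SimLineage(mid.older_bound - 1.0, mid.older_bound - 2.0, False)
            for _ in range(n)
        )
        clade = SimClade(300.0, lineages)
        ds = bin_and_thin(clade, uniform_ts, R, seed=8)
        freq = len(ds) / n
        se = math.sqrt(R * (1 - R) / n)
        assert abs(freq - R) < 3 * se

    def test_observed_range_never_longer_than_true(self, uniform_ts):
        clade = simulate_clade(200.0, 0.08, 0.05, timescale=uniform_ts, seed=9)
        ds = bin_and_thin(clade, uniform_ts, 0.5, seed=1)
        name_to_lineage = {f"sim_{i:05d}": ln for i, ln in enumerate(clade.lineages)}
        for r in ds.ranges:
            ln = name_to_lineage[r.taxon]
            true_bins = uniform_ts.bins_overlapping(ln.birth_age, ln.death_age)
            assert uniform_ts.index(r.first_bin) >= uniform_ts.index(true_bins[0])
            assert uniform_ts.index(r.last_bin) <= uniform_ts.index(true_bins[-1])


class TestSimulateOccurrences:
    def test_singleton_gets_at_least_one_occurrence(self, uniform_ts):
        r = TaxonRange("x", uniform_ts.bins[5], uniform_ts.bins[5])
        occ = simulate_occurrences(r, uniform_ts, seed=0)
        assert len(occ.occurrences) >= 1
        assert all(b == uniform_ts.bins[5] for b in occ.occurrences)

    def test_endpoints_always_present(self, uniform_ts):
        r = TaxonRange("x", uniform_ts.bins[5], uniform_ts.bins[9])
        occ = simulate_occurrences(r, uniform_ts, mean_extra=0.01, seed=1)
        names = {b.name for b in occ.occurrences}
        assert uniform_ts.bins[5].name in names
        assert uniform_ts.bins[9].name in names

    def test_occurrences_confined_to_range(self, uniform_ts):
        r = TaxonRange("x", uniform_ts.bins[5], uniform_ts.bins[13])
        occ = simulate_occurrences(r, uniform_ts, mean_extra=30, seed=2)
        idx = [uniform_ts.index(b) for b in occ.occurrences]
        assert min(idx) >= 5 and max(idx) <= 13

    def test_interior_placement_follows_beta(self, uniform_ts):
        """Occupancy of interior bins matches the discretised Beta(2,2) mass."""
        span = 9
        r = TaxonRange("x", uniform_ts.bins[10], uniform_ts.bins[10 + span - 1])
        counts = np.zeros(span)
        rng_ss = np.random.SeedSequence(77)
        from scipy.stats import beta as beta_dist

        for s in rng_ss.spawn(600):
            occ = simulate_occurrences(r, uniform_ts, mean_extra=14, seed=s)
            for b in occ.occurrences:
                counts[uniform_ts.index(b) - 10] += 1
        # subtract the deterministic endpoint occurrences
        counts[0] -= 600
        counts[-1] -= 600
        edges = np.arange(span + 1) / span
        expected_mass = np.diff(beta_dist.cdf(edges, 2, 2))
        total = counts.sum()
        _, p_value = chisquare(counts, expected_mass * total)
        assert p_value > 0.01

    def test_subsample_keeps_rate(self, uniform_ts):
        r = TaxonRange("x", uniform_ts.bins[0], uniform_ts.bins[40])
        occ = simulate_occurrences(r, uniform_ts, mean_extra=300, seed=3)
        kept = subsample_occurrences(occ, 0.6, seed=4)
        n, k = len(occ.occurrences), len(kept.occurrences)
        assert abs(k / n - 0.6) < 3 * math.sqrt(0.6 * 0.4 / n)

    def test_subsample_extremes(self, uniform_ts):
        r = TaxonRange("x", uniform_ts.bins[3], uniform_ts.bins[6])
        occ = simulate_occurrences(r, uniform_ts, seed=5)
        assert subsample_occurrences(occ, 1.0, seed=0) == occ
        assert subsample_occurrences(occ, 0.0, seed=0) is None

    def test_subsampled_range_within_original(self, uniform_ts):
        r = TaxonRange("x", uniform_ts.bins[3], uniform_ts.bins[12])
        occ = simulate_occurrences(r, uniform_ts, mean_extra=5, seed=6)
        kept = subsample_occurrences(occ, 0.4, seed=7)
        if kept is not None:
            rr = kept.to_range(uniform_ts)
            assert uniform_ts.index(rr.first_bin) >= 3
            assert uniform_ts.index(rr.last_bin) <= 12


class TestHarnesses:
    def test_validation_deterministic_and_consistent(self):
        cfg = ValidationConfig(preservation_rates=(0.8,), n_clades=2,
                               thinnings_per_clade=2, seed=123)
        s1 = run_validation(cfg)
        s2 = run_validation(cfg)
        assert s1.rows == s2.rows
        row = s1.arm(0.8)
        tallied = (row["rate_failure"] + row["curve_failure"] + row["below_50"]
                   + row["ge_50"] + row["ge_75"] + row["ge_95"])
        assert tallied == row["total"] == 4

    def test_sensitivity_deterministic_single_row(self, uniform_ts):
        ds = make_dataset(
            uniform_ts,
            [("a", "u02", "u10"), ("b", "u03", "u12"), ("c", "u05", "u11"),
             ("d", "u02", "u06"), ("e", "u07", "u13")],
        )
        f1 = run_sensitivity([ds], [40], rates=(0.6,), reps=1, seed=5)
        f2 = run_sensitivity([ds], [40], rates=(0.6,), reps=1, seed=5)
        assert f1.equals(f2)
        assert len(f1) == 1

    def test_sensitivity_width_shrinks_with_preservation(self, uniform_ts):
        rows = [
            (f"g{i}", f"u{2 + i % 4:02d}", f"u{8 + (i * 3) % 8:02d}")
            for i in range(12)
        ]
        ds = make_dataset(uniform_ts, rows, label="synthetic")
        frame = run_sensitivity([ds], [60], rates=(0.2, 0.8), reps=8, seed=21)
        med = frame.groupby("R")["width"].median()
        assert med[0.8] < med[0.2]
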