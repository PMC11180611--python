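"""Per-barcode QC metrics against hand arithmetic and brute-force scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import brentq

from atacqc import (IntervalSet, compare_fragment_files, fragment_size_stats,
                    frip, per_barcode_stats, tss_enrichment)
from atacqc.sim import LENGTH_BOUNDS, LENGTH_MIXTURE
from conftest import make_fragments


class TestPerBarcodeStats:
    def test_arithmetic(self):
        table = make_fragments([("chr1", 0, 10, "A", 3), ("chr1", 20, 30, "A", 1),
                                ("chr1", 40, 50, "A", 2)])
        stats = per_barcode_stats(table)
        assert stats.loc["A", "total_reads"] == 6
        assert stats.loc["A", "unique_fragments"] == 3
        assert stats.loc["A", "dup_rate"] == pytest.approx(0.5)

    def test_all_singletons_zero_dup(self):
        table = make_fragments([("chr1", i, i + 5, "A", 1) for i in range(0, 50, 10)])
        assert per_barcode_stats(table).loc["A", "dup_rate"] == 0

    def test_matches_per_line_tally(self, default_truth):
        stats = per_barcode_stats(default_truth.fragments)
        tally_total, tally_unique = {}, {}
        for row in default_truth.fragments.itertuples():
            tally_total[row.barcode] = tally_total.get(row.barcode, 0) + row.count
            tally_unique[row.barcode] = tally_unique.get(row.barcode, 0) + 1
        sample = list(tally_total)[::101]
        for bc in sample:
            assert stats.loc[bc, "total_reads"] == tally_total[bc]
            assert stats.loc[bc, "unique_fragments"] == tally_unique[bc]
        assert stats["total_reads"].sum() == default_truth.fragments["count"].sum()


def uniform_insertion_table(tss_pos, window, n_per_pos, barcode="A"):
    """Fragments whose cut sites tile the TSS window uniformly."""
    rows = []
    for offset in range(-window, window + 1, 2):
        # each fragment contributes cut sites at start and end-1
        start = tss_pos + offset
        rows.append(("chr1", start, start + 2, barcode, n_per_pos))
    return make_fragments(rows)


class TestTSSEnrichment:
    def test_uniform_coverage_scores_one(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "position": [5000], "strand": ["+"]})
        table = uniform_insertion_table(5000, 2000, n_per_pos=50)
        scores, profile = tss_enrichment(table, tss, pseudocount=0.0)
        assert scores["A"] == pytest.approx(1.0, abs=0.05)
        assert len(profile) == 4001

    def test_concentrated_insertions_score_much_greater_than_one(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "position": [5000], "strand": ["+"]})
        lo = make_fragments([("chr1", 5000, 5001, "A", 20)])
        hi = make_fragments([("chr1", 5000, 5001, "A", 200)])
        s_lo, _ = tss_enrichment(lo, tss)
        s_hi, _ = tss_enrichment(hi, tss)
        assert s_lo["A"] > 1
        assert s_hi["A"] > s_lo["A"]  # strictly increasing with insertions

    def test_minus_strand_mirror_symmetry(self):
        plus = pd.DataFrame({"chrom": ["chr1"], "position": [5000], "strand": ["+"]})
        minus = pd.DataFrame({"chrom": ["chr1"], "position": [5000], "strand": ["-"]})
        table = make_fragments([("chr1", 5100, 5200, "A", 4),
                                ("chr1", 4000, 4120, "A", 2)])
        reflected_rows = []
        for row in table.itertuples():
            # reflect both cut sites around the TSS: x -> 2*5000 - x
            c1, c2 = 2 * 5000 - row.start, 2 * 5000 - (row.end - 1)
            s, e = min(c1, c2), max(c1, c2) + 1
            reflected_rows.append(("chr1", s, e, "A", row.count))
        reflected = make_fragments(reflected_rows)
        s_plus, _ = tss_enrichment(table, plus)
        s_minus, _ = tss_enrichment(reflected, minus)
        assert s_minus["A"] == pytest.approx(s_plus["A"])

    def test_empty_annotation_raises(self):
        table = make_fragments([("chr1", 0, 10, "A", 1)])
        with pytest.raises(ValueError):
            tss_enrichment(table, pd.DataFrame(columns=["chrom", "position", "strand"]))

    def test_depth_scaling_invariance(self, clean_truth):
        """Multiplying all read counts by a constant leaves scores intact
        (counts enter numerator and flank background proportionally,
        up to the pseudocount)."""
        sub = clean_truth.fragments.head(50_000)
        scaled = sub.copy()
        scaled["count"] = scaled["count"] * 10
        s1, _ = tss_enrichment(sub, clean_truth.tss, pseudocount=0.0)
        s2, _ = tss_enrichment(scaled, clean_truth.tss, pseudocount=0.0)
        mask = s1 > 0
        np.testing.assert_allclose(s2[mask], s1[mask], rtol=1e-9)


class TestFRIP:
    def test_half_in_peaks(self):
        peaks = IntervalSet(pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]}))
        table = make_fragments([("chr1", 90, 110, "A", 1), ("chr1", 150, 160, "A", 1),
                                ("chr1", 300, 310, "A", 1), ("chr1", 400, 410, "A", 1)])
        assert frip(table, peaks)["A"] == pytest.approx(0.5)

    def test_half_open_boundary_no_overlap(self):
        peaks = IntervalSet(pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300]}))
        table = make_fragments([("chr1", 100, 200, "A", 1)])
        assert frip(table, peaks)["A"] == 0.0

    def test_fragment_counted_once_across_peaks(self):
        peaks = IntervalSet(pd.DataFrame({"chrom": ["chr1", "chr1"],
                                          "start": [100, 150], "end": [140, 190]}))
        table = make_fragments([("chr1", 90, 200, "A", 1)])
        assert frip(table, peaks)["A"] == 1.0

    def test_agrees_with_pairwise_scan(self, rng):
        peaks_df = pd.DataFrame({
            "chrom": "chr1",
            "start": (starts := rng.integers(0, 100_000, 80)),
            "end": starts + rng.integers(10, 800, 80)})
        peaks = IntervalSet(peaks_df)
        frag_starts = rng.integers(0, 100_000, 2000)
        table = make_fragments([
            ("chr1", int(s), int(s + l), f"B{i % 7}", 1)
            for i, (s, l) in enumerate(zip(frag_starts, rng.integers(10, 600, 2000)))])
        got = frip(table, peaks)
        plist = list(zip(peaks_df["start"], peaks_df["end"]))
        expected = {}
        for row in table.itertuples():
            hit = any(row.start < pe and row.end > ps for ps, pe in plist)
            n_hit, n_tot = expected.get(row.barcode, (0, 0))
            expected[row.barcode] = (n_hit + hit, n_tot + 1)
        for bc, (h, t) in expected.items():
            assert got[bc] == pytest.approx(h / t)


class TestFragmentSizes:
    def test_simple_median(self):
        table = make_fragments([("chr1", 0, 100, "A", 1), ("chr1", 0, 200, "A", 5),
                                ("chr1", 0, 300, "A", 1)])
        per_bc, pooled, _ = fragment_size_stats(table)
        assert per_bc["A"] == 200          # unique-fragment median, not read-weighted
        assert pooled == 200

    def test_single_fragment(self):
        table = make_fragments([("chr1", 10, 95, "A", 3)])
        per_bc, pooled, _ = fragment_size_stats(table)
        assert per_bc["A"] == 85 and pooled == 85

    def test_pooled_median_matches_mixture_quantile(self, clean_truth):
        """Pooled median tracks the analytic median of the truncated
        gamma mixture used by the generator."""
        (w1, k1, t1), (w2, k2, t2) = LENGTH_MIXTURE
        lo, hi = LENGTH_BOUNDS

        def cdf(x):
            return w1 * sps.gamma.cdf(x, k1, scale=t1) + w2 * sps.gamma.cdf(x, k2, scale=t2)

        # lengths are clipped, not re-drawn; quantile of the clipped mixture
        analytic = brentq(lambda x: cdf(x) - 0.5, lo, hi)
        _, pooled, _ = fragment_size_stats(clean_truth.fragments)
        assert pooled == pytest.approx(analytic, rel=0.05)


class TestCompareFragmentFiles:
    def test_identical_tables(self, clean_truth):
        sub = clean_truth.fragments.head(10_000)
        series, mean = compare_fragment_files(sub, sub)
        assert (series == 1.0).all() and mean == 1.0

    def test_disjoint_tables(self):
        a = make_fragments([("chr1", 0, 10, "A", 1)])
        b = make_fragments([("chr1", 50, 60, "A", 1)])
        series, mean = compare_fragment_files(a, b)
        assert series["A"] == 0.0 and mean == 0.0

    def test_hand_built_jaccard(self):
        shared = [("chr1", i * 10, i * 10 + 5, "A", 1) for i in range(3)]
        a = make_fragments(shared + [("chr2", 0, 5, "A", 1)])
        b = make_fragments(shared + [("chr2", 100, 105, "A", 1)])
        series, mean = compare_fragment_files(a, b)
        assert series["A"] == pytest.approx(3 / 5)
        assert mean == pytest.approx(3 / 5)
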