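"""Saturation-curve fitting, closed-form recovery and the cost model."""

import numpy as np
import pandas as pd
import pytest

from atacqc import (CostInputs, SaturationModel, SimConfig, estimate_cost,
                    fit_saturation, saturation_curve, simulate_experiment)
from atacqc.metrics import per_barcode_stats
from atacqc.sim import expected_unique


def points_from_model(depths, k_dup, u_max, k_l):
    r = np.asarray(depths, dtype=float)
    return pd.DataFrame({"reads_per_cell": r, "dup_rate": r / (k_dup + r),
                         "unique_per_cell": u_max * r / (k_l + r)})


@pytest.fixture(scope="module")
def small_truth():
    return simulate_experiment(SimConfig(
        seed=21, n_cells=60, n_noise_barcodes=0, n_molecules=2000,
        mean_reads_per_cell=5000, read_dispersion=0.0, multiplet_rate=0.0,
        barcode_error_rate=0.0))


class TestSaturationCurve:

    def test_fraction_one_equals_full_stats(self, small_truth):
        stats = per_barcode_stats(small_truth.fragments)
        points = saturation_curve(small_truth.fragments, small_truth.cell_barcodes,
                                  [1.0], seed=3)
        assert points.loc[0, "reads_per_cell"] == pytest.approx(stats["total_reads"].mean())
        assert points.loc[0, "dup_rate"] == pytest.approx(stats["dup_rate"].mean())

    def test_duplication_monotone_in_fraction(self, small_truth):
        points = saturation_curve(small_truth.fragments, small_truth.cell_barcodes,
                                  [0.1, 0.3, 0.5, 0.7, 1.0], seed=3)
        assert (np.diff(points["dup_rate"]) > -1e-6).all()

    def test_points_track_sampling_closed_form(self, small_truth):
        """At fraction f each cell has ~f*r reads from N molecules; the
        mean duplication rate tracks 1 - E[unique]/reads."""
        points = saturation_curve(small_truth.fragments, small_truth.cell_barcodes,
                                  [0.2, 0.5, 1.0], seed=9)
        for row in points.itertuples():
            expect_dup = 1 - expected_unique(2000, row.reads_per_cell) / row.reads_per_cell
            assert row.dup_rate == pytest.approx(expect_dup, abs=0.02)

    def test_empty_cells_error(self, small_truth):
        with pytest.raises(ValueError):
            saturation_curve(small_truth.fragments, frozenset(), [0.5], seed=0)


class TestFit:
    def test_exact_duplication_points_recover_k(self):
        points = points_from_model([2000, 5000, 10000, 20000, 40000],
                                   k_dup=20_000, u_max=8000, k_l=12_000)
        res = fit_saturation(points)
        assert res.k_dup == pytest.approx(20_000, rel=1e-4)
        assert res.saturation_depth == pytest.approx(20_000, rel=1e-4)

    def test_exact_langmuir_points_recover_umax_kl(self):
        points = points_from_model([1000, 3000, 9000, 27000, 81000],
                                   k_dup=15_000, u_max=8000, k_l=12_000)
        res = fit_saturation(points)
        assert res.u_max == pytest.approx(8000, rel=1e-4)
        assert res.k_l == pytest.approx(12_000, rel=1e-4)
        assert res.expected_unique == pytest.approx(8000 * 15000 / (12000 + 15000), rel=1e-3)

    def test_scale_consistency(self):
        base = points_from_model([1000, 2000, 4000, 8000], 5000, 3000, 4000)
        scaled = base.copy()
        scaled["reads_per_cell"] *= 10
        res_a, res_b = fit_saturation(base), fit_saturation(scaled)
        assert res_b.k_dup == pytest.approx(10 * res_a.k_dup, rel=1e-3)
        assert res_b.k_l == pytest.approx(10 * res_a.k_l, rel=1e-3)
        assert res_b.u_max == pytest.approx(res_a.u_max, rel=1e-3)

    def test_too_few_points_rejected(self):
        points = points_from_model([1000, 2000], 5000, 3000, 4000)
        with pytest.raises(ValueError):
            SaturationModel(points)

    def test_summary_mentions_parameters(self):
        res = fit_saturation(points_from_model([1e3, 2e3, 4e3, 8e3], 5000, 3000, 4000))
        text = res.summary()
        assert "K_dup" in text and "saturation depth" in text

    def test_recovers_exact_sampling_saturation_depth(self):
        """Cells with N=10,000 unique molecules: the 50%-duplication depth
        of the exact sampling process is the root of (1-e^-x)/x = 0.5,
        i.e. 1.5936*N reads; the fitted depth lands within 10%."""
        cfg = SimConfig(seed=31, n_cells=60, n_noise_barcodes=0, n_molecules=10_000,
                        mean_reads_per_cell=25_000, read_dispersion=0.0,
                        multiplet_rate=0.0, barcode_error_rate=0.0)
        truth = simulate_experiment(cfg)
        model = SaturationModel.from_fragments(
            truth.fragments, truth.cell_barcodes,
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0], seed=7)
        res = model.fit()
        assert res.saturation_depth == pytest.approx(10_000 * 1.5936, rel=0.10)


class TestCost:
    # printed rows: assay price, recovered cells, saturation depth,
    # cells the sequencing quote covers, sequencing cost, total per cell
    TABLE = [
        ("10x v2", 1565, 5000, 55_000, None, 791, 0.471),
        ("10x multiome", 2843, 5000, 68_000, None, 978, 0.764),
        ("ddSEQ", 1100, 5000, 19_000, None, 273, 0.275),
        ("s3-ATAC", 800, 5760, 1_467_000, 5000, 21_088, 3.80),
        ("HyDrop", 100, 5000, 10_000, None, 144, 0.049),
    ]

    @pytest.mark.parametrize("name,assay,cells,depth,n_seq,seq_cost,total", TABLE)
    def test_published_cost_table(self, name, assay, cells, depth, n_seq, seq_cost, total):
        out = estimate_cost(CostInputs(assay_price=assay, n_cells=cells,
                                       saturation_depth=depth, n_cells_sequenced=n_seq))
        assert out.sequencing_cost == seq_cost
        assert out.total_cost_per_cell == total

    def test_zero_depth(self):
        out = estimate_cost(CostInputs(assay_price=1000, n_cells=4000, saturation_depth=0))
        assert out.sequencing_cost == 0
        assert out.total_cost_per_cell == 0.25

    def test_rounding_half_away_from_zero(self):
        # 977.5 -> 978 at the dollar level
        out = estimate_cost(CostInputs(assay_price=0, n_cells=5000, saturation_depth=68_000))
        assert out.sequencing_cost == 978

    def test_expected_unique_in_peaks(self):
        out = estimate_cost(CostInputs(assay_price=100, n_cells=5000, saturation_depth=10_000,
                                       median_frip=0.38, expected_unique=1884))
        assert out.expected_unique_in_peaks == pytest.approx(1884 * 0.38)

    def test_validation(self):
        with pytest.raises(ValueError):
            CostInputs(assay_price=100, n_cells=0, saturation_depth=100)
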