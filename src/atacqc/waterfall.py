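"""Read-loss waterfall: where the raw sequencing reads end up.

Every raw read lands in exactly one of five disjoint categories, so the
fractions sum to one:

1. lost to barcode correction or alignment/mapping-quality filters
   (reads absent from the fragment table);
2. reads of barcodes not called as cells;
3. duplicate reads within cells (count − 1 per unique fragment; the
   first read of a fragment is the unique one);
4. unique fragments in cells outside peaks;
5. unique fragments in cells inside peaks — the **sequencing
   efficiency**, the fraction of raw reads that carry usable signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalSet

CATEGORIES = ["lost_barcode_or_mapping", "reads_in_noncell_barcodes",
              "duplicate_reads_in_cells", "unique_in_cells_not_in_peaks",
              "unique_in_cells_in_peaks"]


@dataclass(frozen=True)
class WaterfallReport:
    """Fractions of total raw reads per loss category; they sum to 1."""

    lost_barcode_or_mapping: float
    reads_in_noncell_barcodes: float
    duplicate_reads_in_cells: float
    unique_in_cells_not_in_peaks: float
    unique_in_cells_in_peaks: float
    total_raw_reads: int

    @property
    def sequencing_efficiency(self) -> float:
        """Fraction of raw reads that are unique, in cells and in peaks."""
        return self.unique_in_cells_in_peaks

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in CATEGORIES}

    def plot(self, path) -> None:
        """Write a single stacked-bar summary of the read fate."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(3.5, 5))
        bottom = 0.0
        for name in CATEGORIES:
            value = getattr(self, name)
            ax.bar([0], [value], bottom=bottom, label=name.replace("_", " "))
            bottom += value
        ax.set_xticks([])
        ax.set_ylabel("fraction of raw reads")
        ax.legend(fontsize=7, loc="center left", bbox_to_anchor=(1.0, 0.5))
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)


def waterfall(total_raw_reads: int, table: pd.DataFrame, cells,
              peaks: IntervalSet) -> WaterfallReport:
    """Decompose *total_raw_reads* into the five loss categories.

    *table* is the collapsed fragment table that survived barcode
    correction and mapping; *cells* the called cell barcodes; *peaks*
    the peak set used for the in-peak split (any-overlap rule).
    """
    table_reads = int(table["count"].sum())
    if total_raw_reads < table_reads:
        raise ValueError(
            f"total_raw_reads={total_raw_reads} < reads in table ({table_reads})")
    cells = frozenset(cells)
    in_cells = table["barcode"].isin(cells).to_numpy()
    cell_reads = int(table["count"].to_numpy()[in_cells].sum())
    cell_unique = int(in_cells.sum())
    sub = table[in_cells]
    if len(sub) and len(peaks):
        hits = peaks.overlaps(np.asarray(sub["chrom"], dtype=object),
                              sub["start"].to_numpy(), sub["end"].to_numpy())
        unique_in_peaks = int(hits.sum())
    else:
        unique_in_peaks = 0
    total = float(total_raw_reads)
    return WaterfallReport(
        lost_barcode_or_mapping=(total_raw_reads - table_reads) / total,
        reads_in_noncell_barcodes=(table_reads - cell_reads) / total,
        duplicate_reads_in_cells=(cell_reads - cell_unique) / total,
        unique_in_cells_not_in_peaks=(cell_unique - unique_in_peaks) / total,
        unique_in_cells_in_peaks=unique_in_peaks / total,
        total_raw_reads=total_raw_reads,
    )
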