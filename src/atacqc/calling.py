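"""Cell calling: separating real cells from background barcodes.

Real cells sit in a high mode of both unique-fragment count and TSS
enrichment, while ambient-chromatin barcodes form a low mode of each.
Both axes are thresholded with Otsu's method — the exhaustive
between-class-variance maximiser over histogram bin boundaries — and a
barcode is called a cell only if it passes *both* thresholds. Fragment
counts are thresholded on a log10 scale (counts are log-bimodal, as in
the familiar knee plot); TSS enrichment on its natural linear scale.
Barcodes with fewer than ``min_unique_floor`` unique fragments are
dropped before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """Otsu threshold undefined: fewer than two distinct values."""


@dataclass(frozen=True)
class OtsuResult:
    """An Otsu threshold and the histogram it was derived from."""

    threshold: float
    bin_edges: np.ndarray
    between_class_variance: float


@dataclass
class CellCalls:
    """Boolean cell calls plus the thresholds that produced them."""

    is_cell: pd.Series
    threshold_unique: float      # on unique-fragment count (linear scale)
    threshold_tss: float
    min_unique_floor: int
    otsu_unique: OtsuResult
    otsu_tss: OtsuResult

    @property
    def n_cells(self) -> int:
        return int(self.is_cell.sum())


def otsu_threshold(values, n_bins: int = 100) -> OtsuResult:
    """Histogram threshold maximising between-class variance.

    Every interior bin boundary with non-empty classes on both sides is
    scored with the between-class variance ``w0·w1·(μ0 − μ1)²``; the
    returned threshold is the boundary (bin edge) with the maximum, ties
    broken toward the lower edge. The threshold therefore lies strictly
    inside the data range.

    Raises
    ------
    DegenerateInputError
        If the input has fewer than two distinct values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if np.unique(values).size < 2:
        raise DegenerateInputError("Otsu threshold requires >= 2 distinct values")
    counts, edges = np.histogram(values, bins=n_bins)
    # class statistics at every interior boundary t: class0 = bins < t
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    centers = (edges[:-1] + edges[1:]) / 2
    mass = counts * centers
    m0 = np.cumsum(mass)[:-1]
    m1 = mass.sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.full(len(w0), -np.inf)
    var_between[valid] = (w0[valid] * w1[valid]
                          * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
                          / counts.sum() ** 2)
    # ties (e.g. boundaries crossing empty bins) break toward the lower
    # edge; tolerance absorbs float noise between equivalent boundaries
    top = var_between.max()
    best = int(np.flatnonzero(var_between >= top - 1e-9 * abs(top))[0])
    return OtsuResult(threshold=float(edges[best + 1]), bin_edges=edges,
                      between_class_variance=float(var_between[best]))


def call_cells(stats: pd.DataFrame, min_unique_floor: int = 10,
               n_bins: int = 100) -> CellCalls:
    """Dual-Otsu cell calling on unique fragments and TSS enrichment.

    Parameters
    ----------
    stats
        Per-barcode QC table indexed by barcode with columns
        ``unique_fragments`` and ``tss_enrichment``.
    min_unique_floor
        Barcodes below this unique-fragment count are excluded before
        thresholding (and can never be cells).
    n_bins
        Histogram bins for both Otsu runs.
    """
    for col in ("unique_fragments", "tss_enrichment"):
        if col not in stats.columns:
            raise ValueError(f"stats table lacks required column {col!r}")
    above = stats[stats["unique_fragments"] >= min_unique_floor]
    if len(above) < 2:
        raise DegenerateInputError(
            f"fewer than two barcodes with >= {min_unique_floor} unique fragments")
    otsu_unique = otsu_threshold(np.log10(above["unique_fragments"].to_numpy(dtype=float)),
                                 n_bins=n_bins)
    otsu_tss = otsu_threshold(above["tss_enrichment"].to_numpy(dtype=float), n_bins=n_bins)
    threshold_unique = 10 ** otsu_unique.threshold
    threshold_tss = otsu_tss.threshold
    is_cell = (
        (stats["unique_fragments"] >= min_unique_floor)
        & (stats["unique_fragments"] >= threshold_unique)
        & (stats["tss_enrichment"] >= threshold_tss)
    ).rename("is_cell")
    return CellCalls(is_cell=is_cell, threshold_unique=threshold_unique,
                     threshold_tss=threshold_tss, min_unique_floor=min_unique_floor,
                     otsu_unique=otsu_unique, otsu_tss=otsu_tss)
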