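"""Per-barcode and per-sample quality metrics for fragment tables.

The metrics mirror the standard scATAC-seq QC vocabulary:

* **total reads** — the sum of read counts of a barcode's fragments;
* **unique fragments** — its number of distinct (chrom, start, end)
  records; **duplication rate** = 1 − unique/total;
* **TSS enrichment** — read depth of Tn5 insertion (cut) sites in the
  centre of a ±2,000 bp window around transcription start sites,
  normalised to the depth in the outermost window flanks. Each fragment
  contributes both of its cut sites (positions ``start`` and
  ``end − 1``), weighted by read count; offsets are strand-oriented;
* **FRIP** — fraction of unique fragments with any overlap with a peak
  set (a fragment counts once however many peaks it touches);
* **fragment-length statistics** — medians over unique fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalSet

STATS_COLUMNS = ["barcode", "total_reads", "unique_fragments", "dup_rate",
                 "tss_enrichment", "frip", "median_fragment_length", "is_cell"]


def per_barcode_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Counting statistics per barcode (TSS/FRIP left unset).

    Returns a DataFrame indexed by barcode with columns ``total_reads``,
    ``unique_fragments`` and ``dup_rate = 1 − unique/total``; the sum of
    ``total_reads`` equals the sum of the table's counts.
    """
    g = table.groupby("barcode", observed=True)["count"]
    out = pd.DataFrame({"total_reads": g.sum(), "unique_fragments": g.size()})
    out["dup_rate"] = 1.0 - out["unique_fragments"] / out["total_reads"]
    return out


def tss_enrichment(table: pd.DataFrame, tss: pd.DataFrame, window: int = 2000,
                   flank: int = 100, center: int = 50, pseudocount: float = 0.1):
    """Per-barcode TSS enrichment scores and the pooled insertion profile.

    For every TSS, cut sites within ``position ± window`` are binned by
    their strand-oriented offset; a cut site inside several TSS windows
    contributes to each. Per barcode, the score is the mean depth over
    the central ``±center`` bp divided by (mean depth over the outermost
    ``flank`` bp of each window end + *pseudocount*). The pooled profile
    is normalised so its flank mean is 1.

    Returns
    -------
    (scores, profile)
        *scores*: float Series indexed by barcode. *profile*: DataFrame
        with columns ``offset`` (−window..window) and ``norm_depth``.
    """
    if len(tss) == 0:
        raise ValueError("TSS annotation is empty")
    width = 2 * window + 1
    codes, barcodes = pd.factorize(table["barcode"].to_numpy())
    counts = table["count"].to_numpy(dtype=np.int64)
    central_sum = np.zeros(len(barcodes), dtype=np.int64)
    flank_sum = np.zeros(len(barcodes), dtype=np.int64)
    profile = np.zeros(width, dtype=np.int64)

    chrom_arr = np.asarray(table["chrom"], dtype=object)
    for chrom, tss_sub in tss.groupby("chrom", sort=False):
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        starts = table["start"].to_numpy()[mask]
        ends = table["end"].to_numpy()[mask] - 1
        cuts = np.concatenate([starts, ends])
        cut_codes = np.tile(codes[mask], 2)
        cut_counts = np.tile(counts[mask], 2)
        order = np.argsort(cuts, kind="mergesort")
        cuts, cut_codes, cut_counts = cuts[order], cut_codes[order], cut_counts[order]
        positions = tss_sub["position"].to_numpy()
        minus = (tss_sub["strand"] == "-").to_numpy()
        lo = np.searchsorted(cuts, positions - window, side="left")
        hi = np.searchsorted(cuts, positions + window, side="right")
        for pos, is_minus, a, b in zip(positions, minus, lo, hi):
            if a == b:
                continue
            offsets = cuts[a:b] - pos
            if is_minus:
                offsets = -offsets
            np.add.at(profile, offsets + window, cut_counts[a:b])
            in_center = np.abs(offsets) <= center
            in_flank = np.abs(offsets) > window - flank
            if in_center.any():
                np.add.at(central_sum, cut_codes[a:b][in_center], cut_counts[a:b][in_center])
            if in_flank.any():
                np.add.at(flank_sum, cut_codes[a:b][in_flank], cut_counts[a:b][in_flank])

    n_center = 2 * center + 1
    n_flank = 2 * flank
    background = flank_sum / n_flank + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = pd.Series((central_sum / n_center) / background,
                           index=barcodes, name="tss_enrichment")

    flank_mask = np.abs(np.arange(-window, window + 1)) > window - flank
    flank_mean = profile[flank_mask].mean() if profile[flank_mask].sum() else np.nan
    norm = profile / flank_mean if flank_mean and not np.isnan(flank_mean) else profile.astype(float)
    profile_df = pd.DataFrame({"offset": np.arange(-window, window + 1), "norm_depth": norm})
    return scores, profile_df


def frip(table: pd.DataFrame, peaks: IntervalSet) -> pd.Series:
    """Fraction of each barcode's unique fragments overlapping any peak."""
    hits = peaks.overlaps(np.asarray(table["chrom"], dtype=object),
                          table["start"].to_numpy(), table["end"].to_numpy())
    df = pd.DataFrame({"barcode": table["barcode"].to_numpy(), "hit": hits})
    g = df.groupby("barcode", observed=True)["hit"]
    return (g.sum() / g.size()).rename("frip")


def fragment_size_stats(table: pd.DataFrame):
    """Fragment-length medians over unique fragments (not read-weighted).

    Returns (per-barcode median Series, pooled median, pooled length counts).
    """
    lengths = table["end"].to_numpy() - table["start"].to_numpy()
    per_barcode = (
        pd.DataFrame({"barcode": table["barcode"].to_numpy(), "length": lengths})
        .groupby("barcode", observed=True)["length"].median()
        .rename("median_fragment_length")
    )
    pooled_median = float(np.median(lengths)) if len(lengths) else float("nan")
    pooled_counts = pd.Series(lengths).value_counts().sort_index()
    return per_barcode, pooled_median, pooled_counts


def compare_fragment_files(a: pd.DataFrame, b: pd.DataFrame):
    """Per-barcode Jaccard agreement between two collapsed fragment tables.

    For every barcode present in either table, the Jaccard index of its
    (chrom, start, end) sets; the summary is the mean weighted by the
    barcode's union fragment count. Used to quantify how closely two
    processing routes agree on the same data.

    Returns (per-barcode Series, weighted mean).
    """
    def keyed(t):
        return pd.DataFrame({
            "barcode": t["barcode"].to_numpy(),
            "key": list(zip(np.asarray(t["chrom"], dtype=object),
                            t["start"].to_numpy(), t["end"].to_numpy())),
        })

    sets_a = keyed(a).groupby("barcode", observed=True)["key"].apply(set)
    sets_b = keyed(b).groupby("barcode", observed=True)["key"].apply(set)
    barcodes = sorted(set(sets_a.index) | set(sets_b.index))
    jac, weights = [], []
    for bc in barcodes:
        sa = sets_a.get(bc, set())
        sb = sets_b.get(bc, set())
        union = len(sa | sb)
        jac.append(len(sa & sb) / union if union else 1.0)
        weights.append(union)
    series = pd.Series(jac, index=barcodes, name="jaccard", dtype=float)
    weights = np.asarray(weights, dtype=float)
    weighted_mean = float((series.to_numpy() * weights).sum() / weights.sum()) if weights.sum() else 1.0
    return series, weighted_mean


def compute_qc(table: pd.DataFrame, peaks: IntervalSet | None = None,
               tss: pd.DataFrame | None = None, **tss_kwargs) -> pd.DataFrame:
    """Assemble the per-barcode QC table (``is_cell`` left False).

    Convenience wrapper combining :func:`per_barcode_stats`,
    :func:`tss_enrichment`, :func:`frip` and
    :func:`fragment_size_stats`.
    """
    stats = per_barcode_stats(table)
    if tss is not None:
        scores, _ = tss_enrichment(table, tss, **tss_kwargs)
        stats["tss_enrichment"] = scores.reindex(stats.index).fillna(0.0)
    else:
        stats["tss_enrichment"] = np.nan
    if peaks is not None:
        stats["frip"] = frip(table, peaks).reindex(stats.index)
    else:
        stats["frip"] = np.nan
    medians, _, _ = fragment_size_stats(table)
    stats["median_fragment_length"] = medians.reindex(stats.index)
    stats["is_cell"] = False
    return stats
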