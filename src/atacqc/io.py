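"""Readers and writers for the plain-text formats the toolkit touches.

All genomic coordinates are 0-based, half-open (BED convention). Fragment
files follow the de-facto 10x/pycisTopic dialect: five tab-separated
columns (chrom, start, end, barcode, count), optionally gzip-compressed,
with ``#``-prefixed comment lines permitted. Any Tn5-shift correction is
assumed to have been applied upstream; this toolkit never re-shifts
coordinates.

The in-memory representation of a fragment table is a plain
:class:`pandas.DataFrame` with columns ``chrom, start, end, barcode,
count``, *collapsed* so that no two rows share the same
(chrom, start, end, barcode); duplicate reads of one fragment are summed
into ``count``. TSS annotations are DataFrames with columns
``chrom, position, strand``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]

_BASES = frozenset("ACGT")


class ParseError(ValueError):
    """A malformed record in an input file; carries the offending line number."""


def _find_bad_line(path, predicate, min_fields):
    """Scan *path* to locate the first line failing *predicate* (error path only)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_fields or not predicate(fields):
                return lineno
    return None


def _coords_ok(fields):
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        return False
    return 0 <= start < end


def collapse_fragments(table: pd.DataFrame) -> pd.DataFrame:
    """Sum read counts over rows identical in (chrom, start, end, barcode).

    Idempotent, and conserves the total read count. The result is sorted
    by (chrom, start, end, barcode).
    """
    if len(table) == 0:
        return table.reindex(columns=FRAGMENT_COLUMNS)
    out = (
        table.groupby(["chrom", "start", "end", "barcode"], observed=True, sort=True)["count"]
        .sum()
        .reset_index()
    )
    return out[FRAGMENT_COLUMNS]


def read_fragments(path, min_count_filter: int | None = None) -> pd.DataFrame:
    """Read a fragments file into a collapsed fragment table.

    Both dialects are accepted: pre-collapsed files with a count column,
    and one-line-per-read files (count 1 everywhere or a missing fifth
    column); rows are collapsed on read either way.

    Parameters
    ----------
    path
        Tab-separated file with >=4 columns (chrom, start, end, barcode
        [, count]), optionally gzip-compressed.
    min_count_filter
        If given, drop collapsed rows whose count is below this value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str, 3: str},
            compression="infer",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    if raw.shape[1] < 4:
        raise ParseError(f"{path}: expected >=4 tab-separated columns, found {raw.shape[1]}")
    raw = raw.iloc[:, :5]
    if raw.shape[1] == 4:
        raw[4] = 1
    raw.columns = FRAGMENT_COLUMNS
    for col in ("start", "end", "count"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any():
            lineno = _find_bad_line(path, _coords_ok, 4)
            raise ParseError(f"{path}: non-integer value in column '{col}' (line {lineno})")
        raw[col] = vals.astype(np.int64)
    bad = (raw["start"] < 0) | (raw["start"] >= raw["end"])
    if bad.any():
        lineno = _find_bad_line(path, _coords_ok, 4)
        raise ParseError(f"{path}: start/end do not satisfy 0 <= start < end (line {lineno})")
    if (raw["count"] < 1).any():
        raise ParseError(f"{path}: read counts must be >= 1")
    table = collapse_fragments(raw)
    if min_count_filter is not None:
        table = table[table["count"] >= min_count_filter].reset_index(drop=True)
    return table


def write_fragments(table: pd.DataFrame, path) -> None:
    """Write a fragment table, sorted by (chrom, start, end, barcode).

    Gzip-compressed when *path* ends in ``.gz`` (with a zeroed mtime so
    identical tables give byte-identical files). No header line is
    written, for compatibility with downstream fragments-file consumers.
    """
    path = Path(path)
    out = table[FRAGMENT_COLUMNS].sort_values(
        ["chrom", "start", "end", "barcode"], kind="mergesort"
    )
    text = out.to_csv(sep="\t", header=False, index=False)
    if str(path).endswith(".gz"):
        # empty filename + zero mtime keep the gzip header reproducible
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write(text.encode())
    else:
        path.write_text(text)


class IntervalSet:
    """A queryable set of genomic intervals (0-based, half-open).

    Overlap queries are vectorised against per-chromosome merged interval
    arrays: a query [s, e) overlaps the set iff it overlaps the merged
    cover, which is equivalent for any-overlap membership.
    """

    def __init__(self, frame: pd.DataFrame):
        cols = ["chrom", "start", "end"] + (["name"] if "name" in frame.columns else [])
        frame = frame.reindex(columns=cols)
        if len(frame) and ((frame["start"] < 0) | (frame["start"] >= frame["end"])).any():
            raise ParseError("intervals must satisfy 0 <= start < end")
        self._frame = frame.reset_index(drop=True)
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self._frame.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts, kind="mergesort")
            starts, ends = starts[order], ends[order]
            m_starts, m_ends = [], []
            for s, e in zip(starts, ends):
                if m_ends and s <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            self._merged[chrom] = (np.asarray(m_starts), np.asarray(m_ends))

    def __len__(self) -> int:
        return len(self._frame)

    def to_dataframe(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def total_width(self) -> int:
        return int(sum((e - s).sum() for s, e in self._merged.values()))

    def overlaps(self, chrom, starts, ends) -> np.ndarray:
        """Boolean array: does each query interval overlap any set member?

        *chrom* may be a scalar (applied to all queries) or an array.
        """
        starts = np.atleast_1d(np.asarray(starts))
        ends = np.atleast_1d(np.asarray(ends))
        if np.isscalar(chrom) or isinstance(chrom, str):
            chrom = np.full(len(starts), chrom, dtype=object)
        else:
            chrom = np.asarray(chrom, dtype=object)
        out = np.zeros(len(starts), dtype=bool)
        for c in pd.unique(chrom):
            if c not in self._merged:
                continue
            m_starts, m_ends = self._merged[c]
            mask = chrom == c
            s, e = starts[mask], ends[mask]
            # first merged interval whose end exceeds the query start
            idx = np.searchsorted(m_ends, s, side="right")
            hit = (idx < len(m_starts)) & (m_starts[np.minimum(idx, len(m_starts) - 1)] < e)
            out[mask] = hit
        return out


def read_intervals(path) -> IntervalSet:
    """Read a BED3(+name) file of intervals (peaks, blacklist regions, ...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", compression="infer")
    except pd.errors.EmptyDataError:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    if raw.shape[1] < 3:
        raise ParseError(f"{path}: BED requires >=3 columns")
    frame = raw.iloc[:, :4] if raw.shape[1] >= 4 else raw.iloc[:, :3]
    frame.columns = ["chrom", "start", "end", "name"][: frame.shape[1]]
    for col in ("start", "end"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
        if frame[col].isna().any():
            raise ParseError(f"{path}: non-integer {col} coordinate")
        frame[col] = frame[col].astype(np.int64)
    if ((frame["start"] < 0) | (frame["start"] >= frame["end"])).any():
        lineno = _find_bad_line(path, _coords_ok, 3)
        raise ParseError(f"{path}: interval with start >= end (line {lineno})")
    return IntervalSet(frame)


def write_intervals(intervals: IntervalSet, path) -> None:
    intervals.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


def read_tss(path) -> pd.DataFrame:
    """Read a tab-separated TSS annotation (chrom, position, strand).

    A header row naming the columns is accepted; identical rows are
    deduplicated.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "position": pd.Series(dtype=np.int64),
                             "strand": pd.Series(dtype=str)})
    if raw.shape[1] < 3:
        raise ParseError(f"{path}: TSS table requires columns chrom, position, strand")
    raw = raw.iloc[:, :3]
    raw.columns = ["chrom", "position", "strand"]
    if len(raw) == 0:
        raw["position"] = raw["position"].astype(np.int64)
        return raw
    if str(raw.iloc[0]["position"]).lstrip("-").isdigit() is False:
        raw = raw.iloc[1:]  # header row
    raw["position"] = pd.to_numeric(raw["position"], errors="coerce")
    if raw["position"].isna().any() or (raw["position"] < 0).any():
        raise ParseError(f"{path}: TSS positions must be non-negative integers")
    raw["position"] = raw["position"].astype(np.int64)
    bad = ~raw["strand"].isin(["+", "-"])
    if bad.any():
        raise ParseError(f"{path}: strand must be '+' or '-', got {raw.loc[bad.idxmax(), 'strand']!r}")
    return raw.drop_duplicates().reset_index(drop=True)


def write_tss(tss: pd.DataFrame, path) -> None:
    tss.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class BarcodeWhitelist:
    """A validated set of equal-length barcodes over {A, C, G, T}."""

    barcodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "barcodes", frozenset(self.barcodes))
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError(f"whitelist barcodes have mixed lengths {sorted(lengths)}")
        for b in self.barcodes:
            if not set(b) <= _BASES:
                raise ValueError(f"barcode {b!r} contains non-ACGT characters")

    @property
    def length(self) -> int:
        if not self.barcodes:
            raise ValueError("empty whitelist has no barcode length")
        return len(next(iter(self.barcodes)))

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    def __iter__(self):
        return iter(sorted(self.barcodes))


def read_whitelist(path) -> BarcodeWhitelist:
    """Read a one-barcode-per-line whitelist; duplicates collapse silently."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return BarcodeWhitelist(frozenset(ln for ln in lines if ln))


def write_whitelist(whitelist: BarcodeWhitelist, path) -> None:
    Path(path).write_text("".join(f"{b}\n" for b in whitelist))
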