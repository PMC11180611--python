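"""Whitelist correction of observed cell barcodes at Hamming distance <= 1.

A barcode is kept if it matches the whitelist exactly, or if exactly one
whitelist entry lies at Hamming distance 1 from it. When two or more
entries are one substitution away the observation is ambiguous and left
uncorrected — a deterministic, conservative rule (no quality-weighted
tie-break). Lookup is O(1) per read via a precomputed hash of every
single-substitution neighbourhood of the whitelist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BarcodeWhitelist, collapse_fragments

EXACT = "exact"
CORRECTED = "corrected"
AMBIGUOUS = "ambiguous"
UNCORRECTABLE = "uncorrectable"

_AMBIG = object()  # sentinel in the neighbourhood map


@dataclass(frozen=True)
class Correction:
    """Outcome of correcting one observed barcode."""

    observed: str
    corrected: str | None
    status: str


@dataclass
class CorrectionSummary:
    """Read counts per correction status; conserves the input total."""

    exact: int = 0
    corrected: int = 0
    ambiguous: int = 0
    uncorrectable: int = 0

    @property
    def total(self) -> int:
        return self.exact + self.corrected + self.ambiguous + self.uncorrectable

    @property
    def valid(self) -> int:
        return self.exact + self.corrected

    def as_dict(self) -> dict:
        return {s: getattr(self, s) for s in (EXACT, CORRECTED, AMBIGUOUS, UNCORRECTABLE)}


class BarcodeCorrector:
    """Precomputed Hamming-1 neighbourhood index over a whitelist."""

    def __init__(self, whitelist: BarcodeWhitelist):
        if len(whitelist) == 0:
            raise ValueError("cannot correct against an empty whitelist")
        self.whitelist = whitelist
        self.length = whitelist.length
        self._exact = set(whitelist.barcodes)
        neighbours: dict[str, object] = {}
        for entry in whitelist.barcodes:
            for i in range(self.length):
                for base in "ACGT":
                    if base == entry[i]:
                        continue
                    mutated = entry[:i] + base + entry[i + 1:]
                    prev = neighbours.get(mutated)
                    if prev is None:
                        neighbours[mutated] = entry
                    elif prev is not entry and prev != entry:
                        neighbours[mutated] = _AMBIG
        self._neighbours = neighbours

    def correct(self, observed: str) -> Correction:
        if len(observed) != self.length:
            raise ValueError(
                f"observed barcode length {len(observed)} != whitelist length {self.length}")
        if observed in self._exact:
            return Correction(observed, observed, EXACT)
        hit = self._neighbours.get(observed)
        if hit is None:
            return Correction(observed, None, UNCORRECTABLE)
        if hit is _AMBIG:
            return Correction(observed, None, AMBIGUOUS)
        return Correction(observed, hit, CORRECTED)


def correct_barcode(observed: str, whitelist: BarcodeWhitelist) -> Correction:
    """Correct a single barcode (convenience wrapper; builds the index)."""
    return BarcodeCorrector(whitelist).correct(observed)


def correct_table(reads: pd.DataFrame, whitelist: BarcodeWhitelist):
    """Correct every read's barcode and collapse the valid reads.

    Parameters
    ----------
    reads
        One row per read with columns ``chrom, start, end, barcode``
        (observed barcode).
    whitelist
        Barcodes to correct against.

    Returns
    -------
    (fragments, summary)
        *fragments* is the collapsed fragment table of exact/corrected
        reads under their corrected barcodes; ambiguous and
        uncorrectable reads are counted in *summary* but excluded.
    """
    corrector = BarcodeCorrector(whitelist)
    codes, uniques = pd.factorize(np.asarray(reads["barcode"], dtype=object))
    results = [corrector.correct(b) for b in uniques]
    status_per_unique = np.array([r.status for r in results], dtype=object)
    corrected_per_unique = np.array(
        [r.corrected if r.corrected is not None else "" for r in results], dtype=object)

    per_read_status = status_per_unique[codes]
    summary = CorrectionSummary(
        exact=int((per_read_status == EXACT).sum()),
        corrected=int((per_read_status == CORRECTED).sum()),
        ambiguous=int((per_read_status == AMBIGUOUS).sum()),
        uncorrectable=int((per_read_status == UNCORRECTABLE).sum()),
    )
    keep = (per_read_status == EXACT) | (per_read_status == CORRECTED)
    valid = pd.DataFrame({
        "chrom": np.asarray(reads["chrom"], dtype=object)[keep],
        "start": np.asarray(reads["start"])[keep],
        "end": np.asarray(reads["end"])[keep],
        "barcode": corrected_per_unique[codes[keep]],
        "count": 1,
    })
    return collapse_fragments(valid), summary
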