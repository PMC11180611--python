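"""Seeded downsampling of reads in fragment tables.

Reads are thinned by independent Bernoulli retention (each unit of each
row's count kept with probability *p*), matching the behaviour of
read-level FASTQ subsamplers and making the operation order-independent:
thinning then collapsing is distributionally the same as collapsing then
thinning. Two modes: a raw fraction, or a target mean reads-per-cell
over a given cell set, from which one global fraction is derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DownsampleSpec:
    """Either ``fraction`` in [0, 1] or ``target_reads_per_cell`` (with
    the cell set over which the current mean depth is measured)."""

    fraction: float | None = None
    target_reads_per_cell: float | None = None
    cells: frozenset | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.fraction is None) == (self.target_reads_per_cell is None):
            raise ValueError("specify exactly one of fraction / target_reads_per_cell")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.target_reads_per_cell is not None:
            if self.target_reads_per_cell <= 0:
                raise ValueError("target_reads_per_cell must be positive")
            if not self.cells:
                raise ValueError("target mode requires a non-empty cell set")


def downsample_reads(table: pd.DataFrame, spec: DownsampleSpec) -> pd.DataFrame:
    """Binomially thin each row's read count; drop rows thinned to zero.

    In target mode the retention probability is
    ``target · n_cells / current_cell_reads`` and must be <= 1 (no
    upsampling). Identical spec (including seed) gives identical output.
    """
    if spec.fraction is not None:
        p = spec.fraction
    else:
        in_cells = table["barcode"].isin(spec.cells)
        current = table.loc[in_cells, "count"].sum()
        wanted = spec.target_reads_per_cell * len(spec.cells)
        if wanted > current:
            raise ValueError(
                f"target depth needs {wanted:.0f} cell reads but only {current} available")
        p = wanted / current
    if p >= 1.0:
        return table.reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)
    kept = rng.binomial(table["count"].to_numpy(), p)
    out = table.copy()
    out["count"] = kept
    return out[out["count"] > 0].reset_index(drop=True)
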