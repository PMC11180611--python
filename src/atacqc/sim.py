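"""Fragment-level scATAC-seq simulator with known ground truth.

The generator emulates the statistical structure of a droplet scATAC-seq
experiment at the fragments-file level:

* each cell owns a finite pool of ``n_molecules`` unique tagmented
  fragments (its library complexity); sequencing reads are drawn from the
  pool *with replacement*, so the expected number of distinct molecules
  seen after ``r`` reads is ``N * (1 - (1 - 1/N)**r)`` — the mechanism
  behind PCR-duplicate accumulation and the saturation curves;
* a molecule falls inside a peak with probability ``target_frip``, starts
  near a transcription start site with probability ``tss_fraction``, and
  otherwise lands uniformly on the genome;
* fragment lengths follow a two-component gamma mixture (sub-nucleosomal
  and mono-nucleosomal), truncated to [20, 1000] bp;
* ambient (noise) barcodes receive a handful of reads drawn from the
  pooled molecules of all cells, mimicking cell-free ambient chromatin;
* a fraction of cells are bead multiplets whose reads are split across
  ``k`` distinct bead barcodes;
* observed barcodes carry independent per-base substitution errors.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BarcodeWhitelist,
    IntervalSet,
    collapse_fragments,
    write_fragments,
    write_intervals,
    write_tss,
    write_whitelist,
)

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")

READ_COLUMNS = ["chrom", "start", "end", "barcode"]

# fragment-length mixture: (weight, gamma shape, gamma scale); means 80 / 200 bp
LENGTH_MIXTURE = ((0.6, 4.0, 20.0), (0.4, 16.0, 12.5))
LENGTH_BOUNDS = (20, 1000)


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults describe a small droplet experiment: 200 cells of library
    complexity 5,000 unique molecules sequenced to ~10,000 reads each
    (≈46% duplicates), an in-peak probability of 0.6 (the FRIP regime of
    a good PBMC run), 2,000 ambient barcodes averaging 30 reads, a 5%
    bead-multiplet rate and a 0.5% per-base barcode error rate.
    """

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    n_tss: int = 200
    n_peaks: int = 500
    peak_width: int = 500
    tss_in_peak_fraction: float = 0.3
    n_cells: int = 200
    n_noise_barcodes: int = 2000
    barcode_length: int = 16
    whitelist_size: int = 8192
    mean_reads_per_cell: float = 10_000
    read_dispersion: float = 0.3
    n_molecules: int = 5000
    target_frip: float = 0.6
    tss_fraction: float = 0.15
    tss_jitter_sd: float = 50.0
    ambient_mean_reads: float = 30.0
    multiplet_rate: float = 0.05
    multiplet_k: int = 2
    barcode_error_rate: float = 0.005
    peak_cut_grid: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("target_frip", "tss_fraction", "multiplet_rate",
                     "barcode_error_rate", "tss_in_peak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.target_frip + self.tss_fraction > 1.0:
            raise ValueError("target_frip + tss_fraction must not exceed 1")
        for name in ("n_tss", "peak_width", "n_cells", "barcode_length",
                     "whitelist_size", "n_molecules", "multiplet_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_peaks", "n_noise_barcodes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mean_reads_per_cell <= 0 or self.ambient_mean_reads < 0:
            raise ValueError("read budgets must be positive")
        if not self.chrom_sizes or any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chrom_sizes must be positive")
        n_beads = self.n_cells + round(self.multiplet_rate * self.n_cells) * (self.multiplet_k - 1)
        if n_beads + self.n_noise_barcodes > self.whitelist_size:
            raise ValueError("whitelist too small for requested bead + noise barcodes")
        if self.n_peaks * self.peak_width > 0.8 * sum(self.chrom_sizes.values()):
            raise ValueError("requested peaks exceed genome capacity")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    tss: pd.DataFrame
    peaks: IntervalSet
    whitelist: BarcodeWhitelist
    fragments: pd.DataFrame            # collapsed, error-free true barcodes
    reads: pd.DataFrame                # one row per read, observed barcodes
    cell_barcodes: frozenset           # all bead barcodes belonging to cells
    multiplet_groups: list             # list of frozensets of bead barcodes, size >= 2
    molecules_per_cell: dict           # cell index -> pool size N

    def write(self, outdir) -> None:
        """Emit the experiment and its truth as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        reads = self.reads.copy()
        reads["count"] = 1
        write_fragments(reads, outdir / "reads.tsv.gz")
        write_fragments(self.fragments, outdir / "fragments.tsv.gz")
        write_intervals(self.peaks, outdir / "peaks.bed")
        write_tss(self.tss, outdir / "tss.tsv")
        write_whitelist(self.whitelist, outdir / "whitelist.txt")
        (outdir / "cell_barcodes.txt").write_text(
            "".join(f"{b}\n" for b in sorted(self.cell_barcodes)))
        with open(outdir / "multiplet_groups.tsv", "w") as fh:
            for group in sorted(tuple(sorted(g)) for g in self.multiplet_groups):
                fh.write("\t".join(group) + "\n")
        (outdir / "config.json").write_text(self.config.to_json() + "\n")


def _random_barcodes(rng, n, length):
    """n distinct ACGT strings of the given length."""
    seen: set[bytes] = set()
    out = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=((n - len(out)) + 8, length))
        for row in _BASE_ARR[draw]:
            b = row.tobytes()
            if b not in seen:
                seen.add(b)
                out.append(b.decode())
                if len(out) == n:
                    break
    return out


def _disjoint_intervals(rng, size, n, width):
    """n sorted non-overlapping width-bp intervals inside [0, size)."""
    slack = size - n * width
    if slack < 0:
        raise ValueError("requested features exceed genome capacity")
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    starts = gaps + width * np.arange(n)
    return starts, starts + width


def simulate_reference(config: SimConfig, rng=None):
    """Generate the genome annotation: TSS table and disjoint peak set.

    A ``tss_in_peak_fraction`` of TSSs sit at peak centres (promoter
    peaks); the rest are uniform. Strands are random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    # allocate peaks per chromosome proportionally to length
    alloc = np.floor(config.n_peaks * sizes / sizes.sum()).astype(int)
    for i in range(config.n_peaks - alloc.sum()):
        alloc[i % len(alloc)] += 1
    peak_rows = []
    for chrom, n in zip(chroms, alloc):
        if n == 0:
            continue
        starts, ends = _disjoint_intervals(rng, config.chrom_sizes[chrom], n, config.peak_width)
        for s, e in zip(starts, ends):
            peak_rows.append((chrom, int(s), int(e)))
    peaks = IntervalSet(pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]))

    n_promoter = int(round(config.tss_in_peak_fraction * config.n_tss)) if peak_rows else 0
    tss_rows = []
    if n_promoter:
        picks = rng.choice(len(peak_rows), size=n_promoter, replace=False)
        for i in picks:
            chrom, s, e = peak_rows[i]
            tss_rows.append((chrom, (s + e) // 2))
    for _ in range(config.n_tss - n_promoter):
        ci = rng.integers(0, len(chroms))
        tss_rows.append((chroms[ci], int(rng.integers(0, config.chrom_sizes[chroms[ci]]))))
    strands = np.where(rng.random(config.n_tss) < 0.5, "+", "-")
    tss = pd.DataFrame(
        {"chrom": [r[0] for r in tss_rows],
         "position": [r[1] for r in tss_rows],
         "strand": strands}
    ).drop_duplicates().reset_index(drop=True)
    return tss, peaks


def _sample_lengths(rng, n):
    comp = rng.random(n) < LENGTH_MIXTURE[0][0]
    out = np.empty(n)
    for is_first, (_, shape, scale) in zip((True, False), LENGTH_MIXTURE):
        mask = comp if is_first else ~comp
        out[mask] = rng.gamma(shape, scale, size=mask.sum())
    lo, hi = LENGTH_BOUNDS
    return np.clip(np.round(out), lo, hi).astype(np.int64)


def _sample_molecules(rng, n, config, chroms, chrom_sizes, peaks_df, tss_nonpeak):
    """Draw n unique molecules: (chrom_idx, start, end) arrays."""
    lengths = _sample_lengths(rng, n)
    u = rng.random(n)
    in_peak = u < config.target_frip
    near_tss = (~in_peak) & (u < config.target_frip + config.tss_fraction) & (len(tss_nonpeak) > 0)
    background = ~(in_peak | near_tss)

    chrom_idx = np.empty(n, dtype=np.int64)
    start = np.empty(n, dtype=np.int64)

    k = int(in_peak.sum())
    if k:
        if len(peaks_df) == 0:
            # no peaks to land in: fall back to background placement
            background |= in_peak
            in_peak[:] = False
        else:
            pick = rng.integers(0, len(peaks_df), size=k)
            chrom_idx[in_peak] = peaks_df["chrom_idx"].to_numpy()[pick]
            # Tn5 prefers discrete cut positions within open chromatin; a
            # coarse grid reproduces the low rate of exact fragment
            # collisions between unrelated barcodes seen in real data
            grid = max(config.peak_cut_grid, 1)
            offs = rng.integers(0, config.peak_width // grid, size=k) * grid
            start[in_peak] = peaks_df["start"].to_numpy()[pick] + offs

    k = int(near_tss.sum())
    if k:
        pick = rng.integers(0, len(tss_nonpeak), size=k)
        jit = np.round(rng.normal(0, config.tss_jitter_sd, size=k)).astype(np.int64)
        chrom_idx[near_tss] = tss_nonpeak["chrom_idx"].to_numpy()[pick]
        start[near_tss] = tss_nonpeak["position"].to_numpy()[pick] + jit

    k = int(background.sum())
    if k:
        sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=k, p=sizes / sizes.sum())
        chrom_idx[background] = ci
        pos = (rng.random(k) * sizes[ci]).astype(np.int64)
        start[background] = pos

    bounds = np.array([chrom_sizes[c] for c in chroms])[chrom_idx]
    start = np.clip(start, 0, np.maximum(bounds - lengths - 1, 0))
    end = np.minimum(start + lengths, bounds)
    end = np.maximum(end, start + 1)
    return chrom_idx, start, end


def simulate_experiment(config: SimConfig) -> SimTruth:
    """Run the full generative model and return data plus ground truth."""
    rng = np.random.default_rng(config.seed)
    tss, peaks = simulate_reference(config, rng)
    chroms = list(config.chrom_sizes)
    chrom_pos = {c: i for i, c in enumerate(chroms)}

    peaks_df = peaks.to_dataframe()
    peaks_df["chrom_idx"] = peaks_df["chrom"].map(chrom_pos)
    tss_aug = tss.copy()
    tss_aug["chrom_idx"] = tss_aug["chrom"].map(chrom_pos)
    if len(peaks_df):
        inpk = peaks.overlaps(tss_aug["chrom"].to_numpy(),
                              tss_aug["position"].to_numpy(),
                              tss_aug["position"].to_numpy() + 1)
    else:
        inpk = np.zeros(len(tss_aug), dtype=bool)
    tss_nonpeak = tss_aug[~inpk].reset_index(drop=True)

    whitelist = BarcodeWhitelist(frozenset(
        _random_barcodes(rng, config.whitelist_size, config.barcode_length)))
    wl_sorted = sorted(whitelist.barcodes)

    n_multiplets = int(round(config.multiplet_rate * config.n_cells))
    n_beads = config.n_cells + n_multiplets * (config.multiplet_k - 1)
    picks = rng.choice(len(wl_sorted), size=n_beads + config.n_noise_barcodes, replace=False)
    bead_barcodes = [wl_sorted[i] for i in picks[:n_beads]]
    noise_barcodes = [wl_sorted[i] for i in picks[n_beads:]]

    # assign bead barcodes to cells; the first n_multiplets cells get k beads
    beads_per_cell: list[list[str]] = []
    cursor = 0
    for ci in range(config.n_cells):
        k = config.multiplet_k if ci < n_multiplets else 1
        beads_per_cell.append(bead_barcodes[cursor:cursor + k])
        cursor += k
    multiplet_groups = [frozenset(b) for b in beads_per_cell if len(b) > 1]
    cell_barcodes = frozenset(b for group in beads_per_cell for b in group)

    # per-cell read budgets: gamma-Poisson (negative binomial) unless dispersion 0
    if config.read_dispersion > 0:
        shape = 1.0 / config.read_dispersion ** 2
        lam = rng.gamma(shape, config.mean_reads_per_cell / shape, size=config.n_cells)
        reads_per_cell = rng.poisson(lam)
    else:
        reads_per_cell = np.full(config.n_cells, int(round(config.mean_reads_per_cell)))
    reads_per_cell = np.maximum(reads_per_cell, 1)

    chrom_parts, start_parts, end_parts, bc_parts = [], [], [], []
    pool_chrom, pool_start, pool_end = [], [], []
    molecules_per_cell = {}

    for ci in range(config.n_cells):
        n_mol = config.n_molecules
        molecules_per_cell[ci] = n_mol
        m_chrom, m_start, m_end = _sample_molecules(
            rng, n_mol, config, chroms, config.chrom_sizes, peaks_df, tss_nonpeak)
        pool_chrom.append(m_chrom)
        pool_start.append(m_start)
        pool_end.append(m_end)
        r = int(reads_per_cell[ci])
        draws = rng.integers(0, n_mol, size=r)
        chrom_parts.append(m_chrom[draws])
        start_parts.append(m_start[draws])
        end_parts.append(m_end[draws])
        beads = beads_per_cell[ci]
        if len(beads) == 1:
            bc_parts.append(np.full(r, beads[0], dtype=object))
        else:
            split = rng.integers(0, len(beads), size=r)
            bc_parts.append(np.array(beads, dtype=object)[split])

    # ambient pool: union of all cell molecules
    if config.n_noise_barcodes:
        pc = np.concatenate(pool_chrom)
        ps = np.concatenate(pool_start)
        pe = np.concatenate(pool_end)
        amb_reads = np.maximum(rng.poisson(config.ambient_mean_reads,
                                           size=config.n_noise_barcodes), 1)
        total_amb = int(amb_reads.sum())
        draws = rng.integers(0, len(pc), size=total_amb)
        chrom_parts.append(pc[draws])
        start_parts.append(ps[draws])
        end_parts.append(pe[draws])
        bc_parts.append(np.repeat(np.array(noise_barcodes, dtype=object), amb_reads))

    chrom_idx = np.concatenate(chrom_parts)
    starts = np.concatenate(start_parts)
    ends = np.concatenate(end_parts)
    true_bc = np.concatenate(bc_parts)

    observed = _inject_barcode_errors(rng, true_bc, config.barcode_error_rate)

    chrom_names = pd.Categorical.from_codes(chrom_idx, categories=chroms)
    reads = pd.DataFrame({"chrom": chrom_names, "start": starts, "end": ends,
                          "barcode": observed})
    true_frags = pd.DataFrame({"chrom": np.asarray(chroms, dtype=object)[chrom_idx],
                               "start": starts, "end": ends,
                               "barcode": true_bc, "count": 1})
    fragments = collapse_fragments(true_frags)

    return SimTruth(config=config, tss=tss, peaks=peaks, whitelist=whitelist,
                    fragments=fragments, reads=reads,
                    cell_barcodes=cell_barcodes,
                    multiplet_groups=multiplet_groups,
                    molecules_per_cell=molecules_per_cell)


def _inject_barcode_errors(rng, barcodes, error_rate):
    """Substitute bases independently at *error_rate* per position."""
    if error_rate <= 0:
        return barcodes.copy()
    L = len(barcodes[0])
    n_err = rng.binomial(L, error_rate, size=len(barcodes))
    out = barcodes.copy()
    hit = np.flatnonzero(n_err)
    for i in hit:
        b = list(out[i])
        pos = rng.choice(L, size=n_err[i], replace=False)
        for p in pos:
            choices = [c for c in "ACGT" if c != b[p]]
            b[p] = choices[rng.integers(0, 3)]
        out[i] = "".join(b)
    return out


def expected_unique(n_molecules: float, n_reads: float) -> float:
    """E[distinct molecules] after sampling *n_reads* with replacement from
    a pool of *n_molecules*: ``N * (1 - (1 - 1/N)**r)``."""
    return n_molecules * (1.0 - (1.0 - 1.0 / n_molecules) ** n_reads)
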