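"""Sequencing-saturation curves and per-cell cost modelling.

Repeatedly subsampling a deeply sequenced library and recording the mean
duplication rate and mean unique-fragment yield per cell traces two
saturating curves in reads-per-cell ``r``:

* duplication rate, fitted with a Michaelis–Menten hyperbola with the
  asymptote pinned at 1: ``dup(r) = r / (K_dup + r)`` — duplication must
  approach 100% at infinite depth, and the 50%-duplication *saturation
  depth* is then exactly ``K_dup``;
* unique fragments per cell, fitted with a Langmuir isotherm
  ``U(r) = U_max · r / (K_L + r)``, whose value at the saturation depth
  gives the expected unique fragments per cell.

The two curves are fitted independently by nonlinear least squares
(initialised from double-reciprocal linearisations). The cost model then
prices an experiment: sequencing cost = cells × saturation depth ×
price per million reads, and total cost per cell adds the assay price.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .depth import DownsampleSpec, downsample_reads
from .metrics import per_barcode_stats

POINT_COLUMNS = ["fraction", "reads_per_cell", "dup_rate", "unique_per_cell"]

#: NovaSeq S2-era sequencing price, USD per million reads
DEFAULT_PRICE_PER_MILLION = 2.875


class FitError(RuntimeError):
    """Saturation fit failed to converge; carries the residuals if any."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


def saturation_curve(table: pd.DataFrame, cells, fractions, seed: int = 0) -> pd.DataFrame:
    """Mean depth/duplication/unique-yield at each subsampling fraction.

    The table is restricted to *cells*; each fraction in (0, 1] is drawn
    independently with a seed derived from *seed*, and summarised as the
    mean over barcodes present after thinning. Fraction 1 reproduces the
    full-data statistics exactly.
    """
    cells = frozenset(cells)
    if not cells:
        raise ValueError("empty cell set")
    fractions = sorted(float(f) for f in fractions)
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    sub = table[table["barcode"].isin(cells)].reset_index(drop=True)
    rows = []
    for i, f in enumerate(fractions):
        if f == 1.0:
            thinned = sub
        else:
            thinned = downsample_reads(sub, DownsampleSpec(fraction=f, seed=seed + i))
        stats = per_barcode_stats(thinned)
        rows.append((f, float(stats["total_reads"].mean()),
                     float(stats["dup_rate"].mean()),
                     float(stats["unique_fragments"].mean())))
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


@dataclass
class SaturationResults:
    """Fitted saturation parameters, uncertainties and derived quantities."""

    k_dup: float
    u_max: float
    k_l: float
    bse: dict = field(default_factory=dict)
    points: pd.DataFrame | None = None

    @property
    def saturation_depth(self) -> float:
        """Reads per cell at which the fitted duplication rate is 50%."""
        return self.k_dup

    @property
    def expected_unique(self) -> float:
        """Fitted unique fragments per cell at the saturation depth."""
        return self.predict_unique(self.saturation_depth)

    def predict_dup(self, reads_per_cell):
        r = np.asarray(reads_per_cell, dtype=float)
        return r / (self.k_dup + r)

    def predict_unique(self, reads_per_cell):
        r = np.asarray(reads_per_cell, dtype=float)
        return float(self.u_max * r / (self.k_l + r)) if r.ndim == 0 else \
            self.u_max * r / (self.k_l + r)

    def summary(self) -> str:
        lines = [
            "Sequencing saturation fit",
            "=" * 41,
            f"{'parameter':<22}{'estimate':>12} {'se':>6}",
            "-" * 41,
        ]
        for name, value in (("K_dup (reads/cell)", self.k_dup),
                            ("U_max (fragments)", self.u_max),
                            ("K_L (reads/cell)", self.k_l)):
            key = {"K_dup (reads/cell)": "k_dup", "U_max (fragments)": "u_max",
                   "K_L (reads/cell)": "k_l"}[name]
            se = self.bse.get(key, float("nan"))
            lines.append(f"{name:<22}{value:>12.1f} {se:>6.1f}")
        lines += [
            "-" * 41,
            f"saturation depth (50% dup): {self.saturation_depth:,.0f} reads/cell",
            f"expected unique fragments:  {self.expected_unique:,.0f} per cell",
        ]
        return "\n".join(lines)


class SaturationModel:
    """Fits the duplication and unique-yield saturation curves.

    Parameters
    ----------
    points
        DataFrame with columns ``reads_per_cell``, ``dup_rate``,
        ``unique_per_cell`` (as produced by :func:`saturation_curve`);
        at least three distinct depths are required.
    """

    def __init__(self, points: pd.DataFrame):
        required = {"reads_per_cell", "dup_rate", "unique_per_cell"}
        missing = required - set(points.columns)
        if missing:
            raise ValueError(f"points table lacks columns {sorted(missing)}")
        if points["reads_per_cell"].nunique() < 3:
            raise ValueError("need >= 3 points with distinct depths")
        self.points = points.sort_values("reads_per_cell").reset_index(drop=True)

    @classmethod
    def from_fragments(cls, table: pd.DataFrame, cells, fractions,
                       seed: int = 0) -> "SaturationModel":
        """Build the subsampling points from a fragment table, then model them."""
        return cls(saturation_curve(table, cells, fractions, seed=seed))

    def fit(self, xtol: float = 1e-8) -> SaturationResults:
        r = self.points["reads_per_cell"].to_numpy(dtype=float)
        dup = self.points["dup_rate"].to_numpy(dtype=float)
        uniq = self.points["unique_per_cell"].to_numpy(dtype=float)

        # double-reciprocal starting values
        pos = dup > 0
        k0 = float(np.median(r[pos] * (1 - dup[pos]) / dup[pos])) if pos.any() else float(np.median(r))
        try:
            (k_dup,), pcov_d = curve_fit(lambda x, k: x / (k + x), r, dup,
                                         p0=[max(k0, 1e-9)], xtol=xtol, maxfev=10000)
        except RuntimeError as exc:
            raise FitError(f"duplication fit failed: {exc}") from exc

        slope, intercept = np.polyfit(1.0 / r, 1.0 / np.maximum(uniq, 1e-12), 1)
        u0 = 1.0 / intercept if intercept > 0 else float(uniq.max()) * 2
        kl0 = slope * u0 if slope > 0 and u0 > 0 else float(np.median(r))
        try:
            (u_max, k_l), pcov_u = curve_fit(
                lambda x, um, kl: um * x / (kl + x), r, uniq,
                p0=[max(u0, 1.0), max(kl0, 1.0)], xtol=xtol, maxfev=10000)
        except RuntimeError as exc:
            residuals = uniq - u0 * r / (kl0 + r)
            raise FitError(f"unique-yield fit failed: {exc}", residuals) from exc

        for name, value in (("K_dup", k_dup), ("U_max", u_max), ("K_L", k_l)):
            if not np.isfinite(value) or value <= 0:
                raise FitError(f"non-physical fitted parameter {name}={value}")
        bse = {"k_dup": float(np.sqrt(pcov_d[0, 0])),
               "u_max": float(np.sqrt(pcov_u[0, 0])),
               "k_l": float(np.sqrt(pcov_u[1, 1]))}
        return SaturationResults(k_dup=float(k_dup), u_max=float(u_max),
                                 k_l=float(k_l), bse=bse, points=self.points)


def fit_saturation(points: pd.DataFrame) -> SaturationResults:
    """Functional wrapper: ``SaturationModel(points).fit()``."""
    return SaturationModel(points).fit()


def _round_half_away(value: float, ndigits: int) -> float:
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(value)).quantize(quantum, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class CostInputs:
    """Inputs of the experiment cost model.

    ``n_cells`` is the number of recovered cells the total is spread
    over; ``n_cells_sequenced`` (defaulting to ``n_cells``) is the cell
    count the sequencing cost is quoted for — platforms whose unit of
    purchase recovers more cells than the standard 5,000-cell experiment
    keep the sequencing quote at the standard size.
    """

    assay_price: float
    n_cells: int
    saturation_depth: float
    price_per_million_reads: float = DEFAULT_PRICE_PER_MILLION
    median_frip: float | None = None
    expected_unique: float | None = None
    n_cells_sequenced: int | None = None

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for name in ("assay_price", "saturation_depth", "price_per_million_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CostBreakdown:
    """Priced experiment: sequencing cost (USD, nearest dollar), total
    cost per cell (USD, 3 decimals), and expected unique fragments in
    peaks per cell when FRIP and the unique yield are supplied."""

    sequencing_cost: float
    total_cost_per_cell: float
    expected_unique_in_peaks: float | None = None


def estimate_cost(inputs: CostInputs) -> CostBreakdown:
    """Price an experiment from assay price, cell count and saturation depth.

    ``sequencing_cost = n_cells_sequenced · depth · price/10⁶`` rounded to
    the nearest dollar; ``total_cost_per_cell = (assay + sequencing) /
    n_cells`` rounded to 3 decimals; both half-away-from-zero.
    """
    n_seq = inputs.n_cells_sequenced if inputs.n_cells_sequenced is not None else inputs.n_cells
    raw_seq = n_seq * inputs.saturation_depth * inputs.price_per_million_reads / 1e6
    sequencing_cost = _round_half_away(raw_seq, 0)
    total = _round_half_away((inputs.assay_price + sequencing_cost) / inputs.n_cells, 3)
    in_peaks = None
    if inputs.median_frip is not None and inputs.expected_unique is not None:
        in_peaks = inputs.expected_unique * inputs.median_frip
    return CostBreakdown(sequencing_cost=sequencing_cost, total_cost_per_cell=total,
                         expected_unique_in_peaks=in_peaks)
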