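"""Bead-multiplet detection by fragment-coordinate Jaccard similarity.

Droplet platforms (notably Bio-Rad ddSEQ) can load several barcoded
beads into one droplet, so a single nucleus is split across multiple
barcodes whose fragment sets overlap almost perfectly. Detection works
on collapsed fragment tables:

1. restrict to barcodes with at least ``min_unique`` unique fragments;
2. score every pair of barcodes that share at least ``min_shared``
   exact (chrom, start, end) coordinates, via an inverted
   coordinate -> barcodes index (never all-pairs set intersection);
3. threshold the pair Jaccard indices with Otsu's method on a log10
   scale (the background/multiplet bimodality lives in log space);
4. merge connected components of above-threshold pairs; a merged
   identity is the underscore-join of its sorted member barcodes.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import collapse_fragments

PAIR_COLUMNS = ["barcode_a", "barcode_b", "n_shared", "unique_a", "unique_b", "jaccard"]


class DegenerateThresholdError(ValueError):
    """All candidate scores identical; no threshold separates two classes."""


@dataclass
class MergeMap:
    """A partition of barcodes into merged identities.

    Barcodes absent from the mapping are implicitly singletons mapped to
    themselves.
    """

    mapping: dict = field(default_factory=dict)
    threshold: float | None = None

    def __getitem__(self, barcode: str) -> str:
        return self.mapping.get(barcode, barcode)

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def groups(self) -> list:
        """Multi-barcode groups as sorted tuples."""
        by_merged: dict[str, list] = {}
        for bc, merged in self.mapping.items():
            by_merged.setdefault(merged, []).append(bc)
        return sorted(tuple(sorted(v)) for v in by_merged.values() if len(v) > 1)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.mapping.items())
        return pd.DataFrame(rows, columns=["barcode", "merged"])


def candidate_pairs(table: pd.DataFrame, min_unique: int = 1000,
                    min_shared: int = 5) -> pd.DataFrame:
    """Score barcode pairs sharing exact fragment coordinates.

    Only barcodes with >= *min_unique* unique fragments are eligible
    (low-count barcodes cannot be scored reliably); only pairs sharing
    >= *min_shared* coordinates are reported. Returns a DataFrame with
    columns ``barcode_a, barcode_b, n_shared, unique_a, unique_b,
    jaccard`` where ``jaccard = shared / (unique_a + unique_b - shared)``.
    """
    unique_counts = table.groupby("barcode", observed=True).size()
    eligible = unique_counts[unique_counts >= min_unique]
    if len(eligible) < 2:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    sub = table[table["barcode"].isin(eligible.index)]

    # invert: coordinate -> list of barcode codes, then count co-occurrences
    codes, barcodes = pd.factorize(sub["barcode"].to_numpy())
    coord_ids = pd.factorize(
        pd.util.hash_pandas_object(sub[["chrom", "start", "end"]], index=False))[0]
    order = np.argsort(coord_ids, kind="mergesort")
    coord_sorted = coord_ids[order]
    code_sorted = codes[order]
    boundaries = np.flatnonzero(np.diff(coord_sorted)) + 1
    shared: Counter = Counter()
    for group in np.split(code_sorted, boundaries):
        if len(group) < 2:
            continue
        for a, b in itertools.combinations(sorted(set(group.tolist())), 2):
            shared[(a, b)] += 1

    rows = []
    for (a, b), n in shared.items():
        if n < min_shared:
            continue
        bca, bcb = sorted((barcodes[a], barcodes[b]))
        ua, ub = int(eligible[bca]), int(eligible[bcb])
        rows.append((bca, bcb, n, ua, ub, n / (ua + ub - n)))
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return out.sort_values("jaccard", ascending=False).reset_index(drop=True)


def detect_multiplets(pairs: pd.DataFrame, n_bins: int = 100,
                      log_scale: bool = True,
                      min_separation: float = 1.0) -> MergeMap:
    """Threshold pair scores with Otsu's method and merge components.

    Above-threshold pairs define edges of a graph; each connected
    component becomes one merged identity (the underscore-join of its
    lexicographically sorted members). With no pairs, or a degenerate
    score distribution, the identity map is returned (with a warning in
    the degenerate case).

    Otsu always produces a split, even inside a single mode; a split is
    only *accepted* if the two classes are at least ``min_separation``
    decades apart in mean log10 Jaccard. Genuine bead multiplets share
    most of their fragments (Jaccard of order 0.1–1) while coincidental
    coordinate collisions sit orders of magnitude lower, so a split
    without a decade of separation indicates structure within the
    background class and nothing is merged.
    """
    from .calling import otsu_threshold

    if len(pairs) == 0:
        return MergeMap({})
    scores = pairs["jaccard"].to_numpy(dtype=float)
    if np.unique(scores).size < 2:
        warnings.warn("all candidate-pair Jaccard values identical; "
                      "no multiplets merged", stacklevel=2)
        return MergeMap({}, threshold=None)
    values = np.log10(scores) if log_scale else scores
    otsu = otsu_threshold(values, n_bins=n_bins)
    threshold = 10 ** otsu.threshold if log_scale else otsu.threshold

    log_scores = np.log10(scores)
    above_mask = scores >= threshold
    separation = log_scores[above_mask].mean() - log_scores[~above_mask].mean()
    if separation < min_separation:
        return MergeMap({}, threshold=threshold)

    graph = nx.Graph()
    above = pairs[above_mask]
    graph.add_edges_from(zip(above["barcode_a"], above["barcode_b"]))
    mapping = {}
    for component in nx.connected_components(graph):
        members = sorted(component)
        merged = "_".join(members)
        for bc in members:
            mapping[bc] = merged
    return MergeMap(mapping, threshold=threshold)


def apply_merge(table: pd.DataFrame, merge_map: MergeMap) -> pd.DataFrame:
    """Rewrite barcodes to merged identities and re-collapse.

    Total read count is conserved; the unique-fragment count of a merged
    group equals the size of the union of its members' fragment sets.
    """
    if len(merge_map) == 0:
        return collapse_fragments(table)
    out = table.copy()
    out["barcode"] = [merge_map[b] for b in out["barcode"]]
    return collapse_fragments(out)
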