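"""Shared fixtures: small simulated experiments with known ground truth.

Session-scoped so the heavier generative runs happen once per test
session; tests must not mutate fixture tables in place.
"""

import numpy as np
import pandas as pd
import pytest

from atacqc import SimConfig, simulate_experiment
from atacqc.io import FRAGMENT_COLUMNS


def make_fragments(rows):
    """Build a fragment table from (chrom, start, end, barcode, count) tuples."""
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


@pytest.fixture(scope="session")
def default_truth():
    """A small default experiment: 200 cells, ambient noise, 5% bead
    doublets, 0.5% barcode errors."""
    return simulate_experiment(SimConfig(seed=1))


@pytest.fixture(scope="session")
def clean_truth():
    """Error-free, multiplet-free experiment with fixed read budgets,
    matching the closed-form duplication expectation exactly."""
    return simulate_experiment(SimConfig(
        seed=2, barcode_error_rate=0.0, multiplet_rate=0.0, read_dispersion=0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
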