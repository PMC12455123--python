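"""Shared fixtures: small deterministic matrices and a desk-scale simulated
experiment reused across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dialop import ReplicateMatrix, SimConfig, SpatialDataset, simulate_experiment


def make_matrix(values, fractions=None, proteins=None, replicate=1):
    """Build a ReplicateMatrix from a nested list (None/np.nan = missing)."""
    arr = np.asarray(values, dtype=float)
    n_rows, n_cols = arr.shape
    fractions = list(fractions) if fractions is not None else list(range(1, n_cols + 1))
    index = [f"prec{i}" for i in range(n_rows)]
    if proteins is None:
        proteins = [f"PROT{i}" for i in range(n_rows)]
    frame = pd.DataFrame(arr, index=index, columns=fractions)
    return ReplicateMatrix(frame, pd.Series(proteins, index=index), replicate)


def random_missing_matrix(seed, n_rows=30, n_cols=8, missing_frac=0.25):
    """Positive random matrix with missing cells; every row keeps >= 2 and
    every column >= 1 observed values."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(8, 1, (n_rows, n_cols))
    mask = rng.random((n_rows, n_cols)) < missing_frac
    for i in range(n_rows):  # keep rows imputable
        while mask[i].sum() > n_cols - 2:
            mask[i, rng.integers(n_cols)] = False
    for j in range(n_cols):
        if mask[:, j].all():
            mask[rng.integers(n_rows), j] = False
    values[mask] = np.nan
    return make_matrix(values)


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured experiment: 5 compartments, 8 fractions,
    2 replicates, ~50 proteins."""
    cfg = SimConfig(
        n_classes=5,
        n_fractions=8,
        n_replicates=2,
        proteins_per_class=10,
        precursor_lambda=2.0,
        marker_fraction=0.5,
        seed=7,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def separable_dataset():
    """Two well-separated profile classes with markers and unlabeled rows."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.03, (24, 6)) + np.array([0.6, 0.25, 0.1, 0.03, 0.01, 0.01])
    b = rng.normal(0, 0.03, (24, 6)) + np.array([0.01, 0.01, 0.03, 0.1, 0.25, 0.6])
    profiles = pd.DataFrame(
        np.abs(np.vstack([a, b])), index=[f"p{i}" for i in range(48)]
    )
    profiles.columns = [f"rep1_frac{j + 1:02d}" for j in range(6)]
    marker_idx = [f"p{i}" for i in list(range(12)) + list(range(24, 36))]
    markers = pd.Series(["early"] * 12 + ["late"] * 12, index=marker_idx)
    truth = pd.Series(
        ["early"] * 24 + ["late"] * 24, index=profiles.index, name="true_class"
    )
    return SpatialDataset(profiles, markers), truth
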