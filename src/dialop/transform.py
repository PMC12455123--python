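"""Normalization, protein-level aggregation and cross-replicate assembly.

The fixed order is impute -> sum-normalize -> aggregate.  Sum normalization
divides each feature row by its row total so profiles describe the relative
distribution of a feature across fractions; protein-level aggregation is the
per-column median over a protein's features (DIA branch) or a robust two-way
fit (DDA branch).  Per-protein profiles are then concatenated replicate-major
into a :class:`~dialop.containers.SpatialDataset`, keeping only proteins
found in all replicates.

Medians of sum-normalized rows do not themselves sum to 1, so by default each
per-replicate protein block is re-sum-normalized before concatenation
(switchable off via ``renormalize_blocks``).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ReplicateMatrix, SpatialDataset
from .errors import ValidationError


def sum_normalize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its row sum; rows then sum to 1 (within 1e-9).

    Requires a complete matrix (run imputation first) with strictly positive
    row sums; a zero or negative sum raises, naming the offending feature.
    """
    if matrix.isna().to_numpy().any():
        raise ValidationError("matrix contains missing cells; impute first")
    sums = matrix.sum(axis=1)
    bad = sums <= 0
    if bad.any():
        raise ValidationError(
            f"non-positive row sum for feature {matrix.index[bad][0]!r}"
        )
    return matrix.div(sums, axis=0)


def aggregate_median(matrix: pd.DataFrame, proteins: pd.Series) -> pd.DataFrame:
    """Per-protein, per-column median over that protein's features.

    ``proteins`` maps each feature (matrix row) to its protein accession.
    Single-feature proteins pass through unchanged.
    """
    if not matrix.index.equals(proteins.index):
        proteins = proteins.reindex(matrix.index)
    if proteins.isna().any():
        raise ValidationError("feature->protein mapping incomplete")
    out = matrix.groupby(proteins, sort=True).median()
    out.index.name = None
    return out


def _robust_column_effects(
    block: np.ndarray, c: float, max_iter: int, tol: float
) -> np.ndarray:
    """Fit cell = column_effect + feature_effect by Huber IRLS and return the
    estimated column effects (reference-feature parameterization)."""
    m, ncol = block.shape
    y = block.ravel()
    x_col = np.tile(np.eye(ncol), (m, 1))
    x_feat = np.repeat(np.eye(m)[:, 1:], ncol, axis=0)
    design = np.hstack([x_col, x_feat])
    model = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=c))
    result = model.fit(maxiter=max_iter, tol=tol)
    return np.asarray(result.params[:ncol])


def aggregate_robust(
    matrix: pd.DataFrame,
    proteins: pd.Series,
    c: float = 1.345,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Robust summarization: per protein, fit the additive model
    cell = column_effect + feature_effect with Huber weights and return the
    column effects.

    Single-feature proteins pass through; a failed fit falls back to the
    median with a warning.
    """
    if not matrix.index.equals(proteins.index):
        proteins = proteins.reindex(matrix.index)
    rows = {}
    for accession, block in matrix.groupby(proteins, sort=True):
        values = block.to_numpy(dtype=float)
        if values.shape[0] == 1:
            rows[accession] = values[0]
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows[accession] = _robust_column_effects(values, c, max_iter, tol)
        except Exception:  # noqa: BLE001 - singular fits fall back to median
            warnings.warn(
                f"robust summarization failed for {accession!r}; using median"
            )
            rows[accession] = np.median(values, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)


def profile_columns(replicate: int, fractions: Sequence[int]) -> list[str]:
    """Column names for one replicate's block of a spatial dataset."""
    return [f"rep{replicate}_frac{int(f):02d}" for f in fractions]


def combine_replicates(
    protein_matrices: Sequence[pd.DataFrame],
    replicates: Sequence[int] | None = None,
    markers: pd.Series | None = None,
    renormalize_blocks: bool = True,
    provenance: dict | None = None,
) -> SpatialDataset:
    """Assemble per-replicate protein matrices into a spatial dataset.

    Proteins are inner-joined across replicates — only proteins found in all
    replicates are retained — and the fraction columns are concatenated
    replicate-major.  Marker labels are attached where accessions match.
    """
    if not protein_matrices:
        raise ValidationError("no replicate matrices supplied")
    if replicates is None:
        replicates = list(range(1, len(protein_matrices) + 1))
    common = protein_matrices[0].index
    for mat in protein_matrices[1:]:
        common = common.intersection(mat.index)
    common = common.sort_values()
    if len(common) == 0:
        warnings.warn("no protein is present in all replicates; dataset is empty")
    blocks = []
    for rep, mat in zip(replicates, protein_matrices):
        block = mat.loc[common].copy()
        if renormalize_blocks and len(block):
            block = sum_normalize_rows(block)
        block.columns = profile_columns(rep, block.columns)
        blocks.append(block)
    profiles = pd.concat(blocks, axis=1)
    if markers is not None:
        markers = markers[markers.index.isin(profiles.index)]
    else:
        markers = pd.Series(dtype=object)
    return SpatialDataset(profiles, markers, provenance or {})


def normalize_and_aggregate(
    matrix: ReplicateMatrix, method: str = "median"
) -> pd.DataFrame:
    """Sum-normalize a complete replicate matrix and aggregate to protein
    level (``median`` or ``robust``)."""
    normalized = sum_normalize_rows(matrix.values)
    if method == "median":
        return aggregate_median(normalized, matrix.proteins)
    if method == "robust":
        return aggregate_robust(normalized, matrix.proteins)
    raise ValueError(f"unknown aggregation method {method!r}")
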