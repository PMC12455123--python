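"""Map-resolution metrics and low-dimensional coordinates.

QSep quantifies how well a spatial map separates its marker clusters: entry
(i, j) of the raw matrix is the mean Euclidean distance between the full
profiles of clusters i and j (mean over distinct pairs when i = j), and each
row is divided by its diagonal within-cluster distance, so normalized
off-diagonal entries express between-cluster distance in units of
within-cluster spread.  The summary statistic is the median of off-diagonal
normalized entries, per cluster row and globally; higher is better resolved.
Because normalization is row-wise, the normalized matrix is asymmetric.

PCA coordinates are for display: points in the extreme top/bottom tail of PC1
or PC2 are flagged as display outliers (default tail 0.01%) but never removed
from the dataset, and the trimming never feeds classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA

from .containers import ResolutionReport, SpatialDataset
from .errors import ValidationError


def qsep(dataset: SpatialDataset) -> ResolutionReport:
    """QSep cluster-distance matrices for a marker-annotated dataset.

    Requires at least two marker classes, each with at least two members
    (the within-cluster distance of a singleton is undefined).
    """
    markers = dataset.markers
    classes = sorted(markers.unique())
    if len(classes) < 2:
        raise ValidationError("QSep needs >= 2 marker classes")
    blocks = {}
    for cls in classes:
        members = markers.index[markers == cls]
        if len(members) < 2:
            raise ValidationError(
                f"marker class {cls!r} has a single member; QSep undefined"
            )
        blocks[cls] = dataset.profiles.loc[members].to_numpy(dtype=float)
    k = len(classes)
    raw = np.zeros((k, k))
    for i, ci in enumerate(classes):
        raw[i, i] = pdist(blocks[ci]).mean()
        for j in range(i + 1, k):
            raw[i, j] = raw[j, i] = cdist(blocks[ci], blocks[classes[j]]).mean()
    raw_frame = pd.DataFrame(raw, index=classes, columns=classes)
    normalized = raw_frame.div(np.diag(raw), axis=0)
    off_diag = normalized.where(~np.eye(k, dtype=bool))
    class_medians = off_diag.median(axis=1)
    class_medians.name = "median_qsep"
    global_median = float(np.median(off_diag.to_numpy()[~np.eye(k, dtype=bool)]))
    return ResolutionReport(raw_frame, normalized, class_medians, global_median)


def marker_profile_summary(
    dataset: SpatialDataset,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class median profile and its standard error per column.

    SE = sd / sqrt(n) with the sample (ddof=1) standard deviation; a
    single-member class gets SE = 0 by convention.
    """
    markers = dataset.markers
    profiles = dataset.profiles.loc[markers.index]
    grouped = profiles.groupby(markers, sort=True)
    medians = grouped.median()
    counts = grouped.size()
    se = grouped.std(ddof=1).div(np.sqrt(counts), axis=0).fillna(0.0)
    medians.index.name = se.index.name = None
    return medians, se


@dataclass
class PcaMap:
    """PCA display coordinates with outlier flags."""

    coords: pd.DataFrame
    explained_variance_ratio: np.ndarray
    outliers: pd.Series  # boolean, flagged for display trimming only


def pca_map(
    dataset: SpatialDataset,
    trim_frac: float = 1e-4,
    n_components: int = 2,
    scale: bool = False,
) -> PcaMap:
    """Column-mean-centered PCA of the profiles.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making coordinates reproducible across runs.  The ``trim_frac``
    top and bottom tails of PC1 and of PC2 are flagged as display outliers
    (ceil(n * trim_frac) points per tail per component); flagged points stay
    in the dataset.
    """
    x = dataset.profiles.to_numpy(dtype=float)
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, min(x.shape))
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(x)
    for comp in range(n_components):
        loading = model.components_[comp]
        if loading[np.argmax(np.abs(loading))] < 0:
            model.components_[comp] *= -1
            coords[:, comp] *= -1
    frame = pd.DataFrame(
        coords,
        index=dataset.profiles.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    outliers = pd.Series(False, index=frame.index)
    if trim_frac > 0:
        k = math.ceil(len(frame) * trim_frac)
        for col in frame.columns[: min(2, n_components)]:
            order = frame[col].sort_values()
            outliers.loc[order.index[:k]] = True
            outliers.loc[order.index[-k:]] = True
    outliers.name = "display_outlier"
    return PcaMap(frame, model.explained_variance_ratio_, outliers)


def tsne_map(
    dataset: SpatialDataset, perplexity: float = 30.0, seed: int = 0
) -> pd.DataFrame:
    """Optional t-SNE pass-through for visualization; no metric is derived
    from these coordinates."""
    from sklearn.manifold import TSNE

    coords = TSNE(
        n_components=2,
        perplexity=min(perplexity, max((len(dataset.profiles) - 1) / 3, 1.0)),
        random_state=seed,
        init="pca",
    ).fit_transform(dataset.profiles.to_numpy(dtype=float))
    return pd.DataFrame(
        coords, index=dataset.profiles.index, columns=["tSNE1", "tSNE2"]
    )
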