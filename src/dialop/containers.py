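"""Core in-memory containers shared across the pipeline.

The pipeline moves data through three shapes:

* a long-format precursor table (one row per run x precursor observation),
* one :class:`ReplicateMatrix` per replicate (precursors x fractions, with
  missing cells), and
* a :class:`SpatialDataset` (proteins x concatenated fraction profiles across
  all replicates) that feeds classification and resolution metrics.

All tabular data is held in pandas objects; containers are thin dataclasses
that add validation and provenance on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

#: The 13 subcellular compartments used as the marker vocabulary.
MARKER_CLASSES: tuple[str, ...] = (
    "cytosol",
    "mitochondrion",
    "nucleus",
    "chromatin",
    "plasma membrane",
    "endoplasmic reticulum",
    "Golgi apparatus",
    "endosome",
    "lysosome",
    "peroxisome",
    "proteasome",
    "ribosome 40S",
    "ribosome 60S",
)

#: Secretory-pathway compartments: the classes whose membranes behave most
#: alike under detergent solubilization and are hardest to tell apart there.
SECRETORY_CLASSES: tuple[str, ...] = (
    "endoplasmic reticulum",
    "Golgi apparatus",
    "endosome",
    "lysosome",
)

#: Label used for proteins whose top score falls below the class threshold.
UNKNOWN_LABEL = "unknown"


@dataclass(frozen=True)
class RunDesign:
    """Mapping of MS run identifiers to (replicate, fraction) coordinates.

    Replicate and fraction indices are 1-based.  The mapping must be injective
    on (replicate, fraction): two runs may not quantify the same fraction of
    the same replicate.
    """

    runs: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], str] = {}
        for run_id, (rep, frac) in self.runs.items():
            if rep < 1 or frac < 1:
                raise ValidationError(
                    f"run {run_id!r}: replicate/fraction indices are 1-based, "
                    f"got ({rep}, {frac})"
                )
            if (rep, frac) in seen:
                raise ValidationError(
                    f"runs {seen[(rep, frac)]!r} and {run_id!r} both map to "
                    f"replicate {rep}, fraction {frac}"
                )
            seen[(rep, frac)] = run_id

    @property
    def n_replicates(self) -> int:
        return max(rep for rep, _ in self.runs.values())

    @property
    def n_fractions(self) -> int:
        return max(frac for _, frac in self.runs.values())

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(sorted({rep for rep, _ in self.runs.values()}))

    def fractions(self, replicate: int) -> tuple[int, ...]:
        """Sorted fraction indices available for one replicate."""
        fracs = sorted(f for r, f in self.runs.values() if r == replicate)
        if not fracs:
            raise ValidationError(f"replicate {replicate} not present in design")
        return tuple(fracs)

    def run_map(self, replicate: int) -> dict[str, int]:
        """run_id -> fraction index for one replicate."""
        return {rid: f for rid, (r, f) in self.runs.items() if r == replicate}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RunDesign":
        for col in ("run", "replicate", "fraction"):
            if col not in frame.columns:
                raise ValidationError(f"run design table lacks column {col!r}")
        runs = {
            str(row.run): (int(row.replicate), int(row.fraction))
            for row in frame.itertuples()
        }
        if len(runs) != len(frame):
            raise ValidationError("duplicate run ids in design table")
        return cls(runs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"run": rid, "replicate": rep, "fraction": frac}
            for rid, (rep, frac) in self.runs.items()
        ]
        return pd.DataFrame(rows).sort_values(["replicate", "fraction"]).reset_index(drop=True)


@dataclass
class ReplicateMatrix:
    """One replicate's features x fractions intensity matrix.

    ``values`` is indexed by feature (precursor or PSM) id with integer
    fraction columns; missing cells are NaN.  ``proteins`` maps each feature to
    its protein group and is index-aligned with ``values``.
    """

    values: pd.DataFrame
    proteins: pd.Series
    replicate: int

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.proteins.index):
            raise ValidationError(
                "feature->protein mapping is not aligned with the matrix rows"
            )

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    @property
    def n_observed(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def copy(self) -> "ReplicateMatrix":
        return ReplicateMatrix(
            self.values.copy(), self.proteins.copy(), self.replicate
        )


@dataclass
class QcStage:
    """Accounting record for one filtering stage: in = out + removed."""

    name: str
    n_in: int
    n_removed: int
    detail: str = ""

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class QcReport:
    """Per-stage record counts plus any fraction columns dropped."""

    stages: list[QcStage] = field(default_factory=list)
    dropped_fractions: dict[int, list[int]] = field(default_factory=dict)

    def add(self, name: str, n_in: int, n_removed: int, detail: str = "") -> None:
        if n_removed < 0 or n_removed > n_in:
            raise ValidationError(
                f"stage {name!r}: removed {n_removed} of {n_in} records"
            )
        self.stages.append(QcStage(name, n_in, n_removed, detail))

    def extend(self, other: "QcReport") -> None:
        self.stages.extend(other.stages)
        for rep, fracs in other.dropped_fractions.items():
            self.dropped_fractions.setdefault(rep, []).extend(fracs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_removed": s.n_removed,
                    "n_out": s.n_out,
                    "detail": s.detail,
                }
                for s in self.stages
            ]
        )


@dataclass
class SpatialDataset:
    """Proteins x concatenated fraction profiles across replicates.

    ``profiles`` is indexed by protein accession; columns are named
    ``rep{r}_frac{f:02d}`` and ordered replicate-major.  ``markers`` maps a
    subset of accessions to curated compartment labels.
    """

    profiles: pd.DataFrame
    markers: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profiles.isna().to_numpy().any():
            raise ValidationError("spatial dataset profiles contain missing cells")
        stray = self.markers.index.difference(self.profiles.index)
        if len(stray):
            raise ValidationError(
                f"marker accessions absent from the dataset: {sorted(stray)[:5]}"
            )

    @property
    def marker_classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.markers.unique()))

    @property
    def unlabeled(self) -> pd.Index:
        return self.profiles.index.difference(self.markers.index)

    def subset_columns(self, columns: Sequence[str]) -> "SpatialDataset":
        """Dataset restricted to a subset of profile columns (e.g. fewer
        fractions); marker labels and provenance carried over."""
        return SpatialDataset(
            self.profiles.loc[:, list(columns)].copy(),
            self.markers.copy(),
            dict(self.provenance),
        )


@dataclass
class ClassificationResult:
    """Outcome of marker-based classification with per-class thresholds.

    ``assignments`` has one row per protein with columns ``marker`` (curated
    label or NaN), ``predicted`` (argmax class), ``score`` (winning calibrated
    score) and ``assignment`` (class or :data:`UNKNOWN_LABEL`; markers keep
    their curated label).  ``scores`` holds the full per-class score vectors.
    """

    assignments: pd.DataFrame
    scores: pd.DataFrame
    thresholds: pd.Series
    f1_per_class: pd.DataFrame | None = None
    best_params: dict | None = None

    def n_assigned(self, cls: str | None = None) -> int:
        """Number of non-marker proteins assigned (to ``cls`` if given)."""
        nonmarker = self.assignments["marker"].isna()
        assigned = self.assignments["assignment"] != UNKNOWN_LABEL
        if cls is not None:
            assigned &= self.assignments["assignment"] == cls
        return int((nonmarker & assigned).sum())


@dataclass
class ResolutionReport:
    """QSep cluster-distance matrices and their summaries.

    ``raw[i, j]`` is the mean pairwise Euclidean distance between full
    profiles of marker clusters i and j (distinct pairs when i == j); the
    normalized matrix divides each row by its diagonal (within-cluster)
    distance, so the diagonal is identically 1 and larger off-diagonal values
    mean better separation.  Normalization is row-wise, so the normalized
    matrix is in general asymmetric.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    class_medians: pd.Series
    global_median: float
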