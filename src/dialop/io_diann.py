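"""Reading and writing the tabular formats the pipeline touches.

Inputs are plain UTF-8 TSV: DIA-NN-style precursor reports, PSM-level TMT
exports, marker annotation tables, contaminant lists and run designs.  Column
names for the precursor report follow the DIA-NN defaults but are overridable
via :class:`ReportDialect`, since report dialects drift between DIA-NN
versions.  Missing cells are serialized as empty strings; zero intensities are
coerced to missing on ingest (an MS intensity of zero is a non-detection), with
a dialect switch to keep them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ClassificationResult, ReplicateMatrix, RunDesign, SpatialDataset
from .errors import FormatError, ParseError, ValidationError

_PROFILE_COL = r"^rep(\d+)_frac(\d+)$"


@dataclass(frozen=True)
class ReportDialect:
    """Column naming for a DIA-NN-style precursor report.

    ``intensity_cols`` is tried in order; the first column present in the file
    is used.  The default prefers the normalised quantity and falls back to
    the raw one.
    """

    run_col: str = "Run"
    protein_col: str = "Protein.Group"
    precursor_col: str = "Precursor.Id"
    intensity_cols: tuple[str, ...] = ("Precursor.Normalised", "Precursor.Quantity")
    zero_as_missing: bool = True


DEFAULT_DIALECT = ReportDialect()


@dataclass(frozen=True)
class PsmDialect:
    """Column naming for a PSM-level TMT export."""

    psm_col: str = "PSM.Id"
    protein_col: str = "Protein.Group"
    sn_col: str = "Average.SN"
    coisolation_col: str = "Coisolation.Pct"
    sps_col: str = "SPS.Match.Pct"
    reporter_prefix: str = "Abundance."


DEFAULT_PSM_DIALECT = PsmDialect()


def _parse_intensity(raw: pd.Series, path: str) -> pd.Series:
    """Parse an intensity column, reporting the 1-based file line of any
    non-numeric cell (header is line 1)."""
    stripped = raw.fillna("").astype(str).str.strip()
    empty = stripped == ""
    values = pd.to_numeric(stripped.where(~empty), errors="coerce")
    bad = values.isna() & ~empty
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(
            f"{path}: non-numeric intensity {stripped[bad].iloc[0]!r} on line {line}"
        )
    neg = values < 0
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 2
        raise ParseError(f"{path}: negative intensity on line {line}")
    return values.astype(float)


def read_precursor_report(
    path: str | Path,
    design: RunDesign,
    dialect: ReportDialect = DEFAULT_DIALECT,
) -> pd.DataFrame:
    """Read a long-format precursor report into a tidy PrecursorTable.

    Returns a DataFrame with columns ``run_id``, ``protein_group``,
    ``precursor_id`` and ``intensity`` (NaN = missing).  Every run in the file
    must appear in ``design``; unmatched runs raise a :class:`ValidationError`
    naming them.
    """
    path = str(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.run_col, dialect.protein_col, dialect.precursor_col):
        if col not in raw.columns:
            raise FormatError(f"{path}: required column {col!r} not found")
    icol = next((c for c in dialect.intensity_cols if c in raw.columns), None)
    if icol is None:
        raise FormatError(
            f"{path}: no intensity column found (tried {list(dialect.intensity_cols)})"
        )
    intensity = _parse_intensity(raw[icol], path)
    if dialect.zero_as_missing:
        intensity = intensity.where(intensity != 0.0)
    table = pd.DataFrame(
        {
            "run_id": raw[dialect.run_col],
            "protein_group": raw[dialect.protein_col],
            "precursor_id": raw[dialect.precursor_col],
            "intensity": intensity,
        }
    )
    unknown = sorted(set(table["run_id"]) - set(design.runs))
    if unknown:
        raise ValidationError(
            f"{path}: runs absent from the run design: {', '.join(unknown)}"
        )
    return table


def pivot_replicate(
    table: pd.DataFrame, design: RunDesign, replicate: int
) -> ReplicateMatrix:
    """Pivot one replicate's records into a precursors x fractions matrix.

    Rows are precursors observed (positive intensity) in at least one fraction
    of the replicate; columns are that replicate's fractions in order; absent
    or missing observations are NaN.  A duplicate (precursor, fraction) record
    is ambiguous quantification and raises.
    """
    run_map = design.run_map(replicate)
    sub = table[table["run_id"].isin(run_map)].copy()
    sub["fraction"] = sub["run_id"].map(run_map)
    dup = sub.duplicated(subset=["precursor_id", "fraction"], keep=False)
    if dup.any():
        key = sub.loc[dup, ["precursor_id", "fraction"]].iloc[0]
        raise ValidationError(
            f"replicate {replicate}: duplicate record for precursor "
            f"{key.precursor_id!r} in fraction {int(key.fraction)}"
        )
    values = sub.pivot(index="precursor_id", columns="fraction", values="intensity")
    values = values.reindex(columns=list(design.fractions(replicate)))
    values = values.dropna(how="all")
    values.columns.name = None
    proteins = (
        sub.drop_duplicates("precursor_id")
        .set_index("precursor_id")["protein_group"]
        .reindex(values.index)
    )
    proteins.name = "protein_group"
    return ReplicateMatrix(values, proteins, replicate)


def read_psm_table(
    path: str | Path, plex: int, dialect: PsmDialect = DEFAULT_PSM_DIALECT
) -> pd.DataFrame:
    """Read a PSM-level TMT export.

    Returns a DataFrame with columns ``psm_id``, ``protein_group``,
    ``avg_sn``, ``coisolation_pct``, ``sps_match_pct`` and ``reporter_1`` ..
    ``reporter_{plex}``.  The number of reporter columns in the file must
    equal ``plex``.
    """
    path = str(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (
        dialect.psm_col,
        dialect.protein_col,
        dialect.sn_col,
        dialect.coisolation_col,
        dialect.sps_col,
    ):
        if col not in raw.columns:
            raise FormatError(f"{path}: required column {col!r} not found")
    reporter_cols = [c for c in raw.columns if c.startswith(dialect.reporter_prefix)]
    if len(reporter_cols) != plex:
        raise FormatError(
            f"{path}: found {len(reporter_cols)} reporter columns, expected "
            f"plex={plex}"
        )
    out = pd.DataFrame(
        {
            "psm_id": raw[dialect.psm_col],
            "protein_group": raw[dialect.protein_col],
            "avg_sn": _parse_intensity(raw[dialect.sn_col], path),
            "coisolation_pct": pd.to_numeric(raw[dialect.coisolation_col]),
            "sps_match_pct": pd.to_numeric(raw[dialect.sps_col]),
        }
    )
    for i, col in enumerate(reporter_cols, start=1):
        out[f"reporter_{i}"] = _parse_intensity(raw[col], path)
    return out


def write_precursor_report(
    table: pd.DataFrame, path: str | Path, dialect: ReportDialect = DEFAULT_DIALECT
) -> None:
    """Write a tidy PrecursorTable back to DIA-NN-dialect TSV."""
    out = pd.DataFrame(
        {
            dialect.run_col: table["run_id"],
            dialect.protein_col: table["protein_group"],
            dialect.precursor_col: table["precursor_id"],
            dialect.intensity_cols[0]: table["intensity"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_spatial_map(
    dataset: SpatialDataset,
    path: str | Path,
    result: ClassificationResult | None = None,
) -> None:
    """Write one row per protein: accession, profile columns, marker label
    (blank for non-markers) and, when a classification result is supplied,
    the predicted class, per-class scores and final assignment.

    Profile values are written with full float repr so that re-reading
    reproduces them bit-exactly.
    """
    out = dataset.profiles.copy()
    out["marker"] = dataset.markers.reindex(out.index)
    if result is not None:
        out["predicted"] = result.assignments["predicted"].reindex(out.index)
        out["assignment"] = result.assignments["assignment"].reindex(out.index)
        for cls in result.scores.columns:
            out[f"score_{cls}"] = result.scores[cls].reindex(out.index)
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def read_spatial_map(path: str | Path) -> SpatialDataset:
    """Read a spatial map written by :func:`write_spatial_map`; only the
    profile columns and marker labels are reconstructed."""
    raw = pd.read_csv(str(path), sep="\t", index_col="accession")
    raw.index.name = None
    profile_cols = [c for c in raw.columns if pd.Series([c]).str.match(_PROFILE_COL)[0]]
    profiles = raw[profile_cols].astype(float)
    if "marker" in raw.columns:
        markers = raw["marker"].dropna()
    else:
        markers = pd.Series(dtype=object)
    return SpatialDataset(profiles, markers)


def read_marker_table(
    path: str | Path, allowed_classes: Sequence[str] | None = None
) -> pd.Series:
    """Read a two-column TSV (accession, marker_class) into a Series.

    Each accession must map to exactly one class; duplicates raise.  When
    ``allowed_classes`` is given, labels outside it raise.
    """
    frame = pd.read_csv(str(path), sep="\t", dtype=str)
    for col in ("accession", "marker_class"):
        if col not in frame.columns:
            raise FormatError(f"{path}: required column {col!r} not found")
    dup = frame["accession"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{path}: accession {frame.loc[dup, 'accession'].iloc[0]!r} has "
            "multiple marker annotations"
        )
    if allowed_classes is not None:
        bad = set(frame["marker_class"]) - set(allowed_classes)
        if bad:
            raise ValidationError(f"{path}: unknown marker classes {sorted(bad)}")
    markers = frame.set_index("accession")["marker_class"]
    markers.index.name = None
    markers.name = "marker_class"
    return markers


def write_marker_table(markers: pd.Series, path: str | Path) -> None:
    frame = markers.rename("marker_class").rename_axis("accession").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_contaminants(path: str | Path) -> frozenset[str]:
    """Read a contaminant accession list: one accession (or prefix) per line,
    '#' comments allowed."""
    entries = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            entries.append(line)
    return frozenset(entries)


def read_run_design(path: str | Path) -> RunDesign:
    return RunDesign.from_frame(pd.read_csv(str(path), sep="\t", dtype=str))


def write_run_design(design: RunDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def write_replicate_matrix(matrix: ReplicateMatrix, path: str | Path) -> None:
    """Serialize a replicate matrix: precursor, protein group, then one column
    per fraction (missing cells empty)."""
    out = matrix.values.copy()
    out.columns = [f"frac{int(c):02d}" for c in out.columns]
    out.insert(0, "protein_group", matrix.proteins)
    out.index.name = "precursor_id"
    out.to_csv(path, sep="\t")


def read_replicate_matrix(path: str | Path, replicate: int) -> ReplicateMatrix:
    raw = pd.read_csv(str(path), sep="\t", index_col="precursor_id")
    frac_cols = [c for c in raw.columns if c.startswith("frac")]
    values = raw[frac_cols].astype(float)
    values.columns = [int(c[4:]) for c in frac_cols]
    return ReplicateMatrix(values, raw["protein_group"], replicate)
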