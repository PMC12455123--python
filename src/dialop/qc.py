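"""Quality-control filtration for precursor matrices and PSM tables.

The DIA branch applies, in this fixed order:

1. removal of contaminant and ambiguous (multi-accession) protein groups,
2. an intensity high-pass (off by default),
3. removal of fractions (columns) with missing data for over 70% of
   precursors, and
4. removal of precursors (rows) with fewer than two quantitative values
   across the remaining fractions.

The column filter must precede the row filter because row support is counted
over the fractions that survive.  "Over 70%" and "fewer than two" are read
strictly: a column at exactly 70% missing and a row with exactly two values
survive.  Both thresholds are configurable.

The DDA branch filters PSMs on average reporter signal-to-noise (< 10
removed), co-isolation interference (75% or above removed) and SPS mass-match
percentage.  The SPS threshold default (65%) is a common community choice, not
a value asserted by any upstream protocol; set it deliberately.

Every filter only removes rows/columns or blanks cells — no value is ever
altered otherwise — and each returns a :class:`~dialop.containers.QcReport`
with conservative per-stage accounting (in = out + removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import QcReport, ReplicateMatrix


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for both QC branches; see module docstring for semantics."""

    max_column_missing_frac: float = 0.70
    min_row_values: int = 2
    min_intensity: float = 0.0
    contaminant_accessions: frozenset[str] = frozenset()
    contaminant_prefix: str | None = "Cont_"
    dda_min_sn: float = 10.0
    dda_max_coisolation_pct: float = 75.0
    dda_min_sps_pct: float = 65.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_column_missing_frac <= 1.0:
            raise ValueError("max_column_missing_frac must lie in [0, 1]")
        if self.min_row_values < 1:
            raise ValueError("min_row_values must be >= 1")
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be non-negative")


def _is_contaminant(group: str, cfg: QcConfig) -> bool:
    accessions = group.split(";")
    if cfg.contaminant_prefix and any(
        a.startswith(cfg.contaminant_prefix) for a in accessions
    ):
        return True
    return any(a in cfg.contaminant_accessions for a in accessions)


def remove_contaminants_and_ambiguous(
    matrix: ReplicateMatrix, cfg: QcConfig
) -> tuple[ReplicateMatrix, QcReport]:
    """Drop rows whose protein group is a contaminant or contains more than
    one accession (';'-separated)."""
    groups = matrix.proteins.astype(str)
    ambiguous = groups.str.contains(";")
    contaminant = groups.map(lambda g: _is_contaminant(g, cfg)) & ~ambiguous
    keep = ~(ambiguous | contaminant)
    report = QcReport()
    report.add(
        "contaminants_ambiguous",
        len(groups),
        int((~keep).sum()),
        f"ambiguous={int(ambiguous.sum())}, contaminant={int(contaminant.sum())}",
    )
    out = ReplicateMatrix(
        matrix.values.loc[keep], matrix.proteins.loc[keep], matrix.replicate
    )
    if out.values.empty and not matrix.values.empty:
        warnings.warn("contaminant/ambiguous filter removed every feature")
    return out, report


def filter_intensity_highpass(
    matrix: ReplicateMatrix, cfg: QcConfig
) -> tuple[ReplicateMatrix, QcReport]:
    """Blank cells below ``min_intensity`` and drop rows left with no
    observed cell.  With the default threshold of 0 this is the identity."""
    values = matrix.values.copy()
    blanked = int((values < cfg.min_intensity).to_numpy().sum())
    values = values.where(~(values < cfg.min_intensity))
    keep = values.notna().any(axis=1)
    report = QcReport()
    report.add(
        "intensity_highpass",
        len(values),
        int((~keep).sum()),
        f"cells_blanked={blanked}, threshold={cfg.min_intensity}",
    )
    out = ReplicateMatrix(
        values.loc[keep], matrix.proteins.loc[keep], matrix.replicate
    )
    return out, report


def filter_columns_by_missingness(
    matrix: ReplicateMatrix, cfg: QcConfig
) -> tuple[ReplicateMatrix, QcReport]:
    """Drop fraction columns whose missing-cell proportion exceeds (strictly)
    ``max_column_missing_frac``; a column at exactly the threshold survives."""
    values = matrix.values
    if values.empty:
        return matrix.copy(), QcReport()
    missing_frac = values.isna().mean(axis=0)
    drop = missing_frac > cfg.max_column_missing_frac
    dropped = [int(c) for c in values.columns[drop]]
    report = QcReport()
    report.add(
        "column_missingness",
        values.shape[1],
        len(dropped),
        f"dropped_fractions={dropped}",
    )
    if dropped:
        report.dropped_fractions[matrix.replicate] = dropped
    out = ReplicateMatrix(
        values.loc[:, ~drop.to_numpy()].copy(), matrix.proteins.copy(), matrix.replicate
    )
    return out, report


def filter_rows_min_values(
    matrix: ReplicateMatrix, cfg: QcConfig
) -> tuple[ReplicateMatrix, QcReport]:
    """Drop rows with fewer than ``min_row_values`` observed cells across the
    remaining fractions.  Must run after the column filter."""
    observed = matrix.values.notna().sum(axis=1)
    keep = observed >= cfg.min_row_values
    report = QcReport()
    report.add("row_min_values", len(observed), int((~keep).sum()))
    out = ReplicateMatrix(
        matrix.values.loc[keep], matrix.proteins.loc[keep], matrix.replicate
    )
    return out, report


def run_dia_qc(
    matrix: ReplicateMatrix, cfg: QcConfig
) -> tuple[ReplicateMatrix, QcReport]:
    """Full DIA-branch QC in the fixed order documented above."""
    report = QcReport()
    for step in (
        remove_contaminants_and_ambiguous,
        filter_intensity_highpass,
        filter_columns_by_missingness,
        filter_rows_min_values,
    ):
        matrix, stage_report = step(matrix, cfg)
        report.extend(stage_report)
    return matrix, report


def filter_psms(psms: pd.DataFrame, cfg: QcConfig) -> tuple[pd.DataFrame, QcReport]:
    """DDA-branch PSM filter: keep records with average S/N >= ``dda_min_sn``,
    co-isolation strictly below ``dda_max_coisolation_pct`` and SPS match
    percentage >= ``dda_min_sps_pct``."""
    keep = (
        (psms["avg_sn"] >= cfg.dda_min_sn)
        & (psms["coisolation_pct"] < cfg.dda_max_coisolation_pct)
        & (psms["sps_match_pct"] >= cfg.dda_min_sps_pct)
    )
    report = QcReport()
    report.add(
        "psm_filter",
        len(psms),
        int((~keep).sum()),
        f"sn<{cfg.dda_min_sn}, coiso>={cfg.dda_max_coisolation_pct}, "
        f"sps<{cfg.dda_min_sps_pct}",
    )
    return psms.loc[keep].copy(), report
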