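"""End-to-end orchestration: precursor table -> spatial dataset.

Each replicate is processed independently (pivot -> QC -> imputation ->
sum-normalization -> protein aggregation) and the per-replicate protein
matrices are then inner-joined into a :class:`~dialop.containers.SpatialDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import QcReport, ReplicateMatrix, RunDesign, SpatialDataset
from .imputation import ImputationConfig, impute
from .io_diann import pivot_replicate
from .qc import QcConfig, run_dia_qc
from .transform import combine_replicates, normalize_and_aggregate


@dataclass(frozen=True)
class PipelineConfig:
    """Stage configurations for the DIA branch."""

    qc: QcConfig = field(default_factory=QcConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    aggregation: str = "median"
    renormalize_blocks: bool = True


def process_replicate(
    table: pd.DataFrame,
    design: RunDesign,
    replicate: int,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, QcReport, pd.Series]:
    """One replicate end to end; returns the protein-level matrix, the QC
    report and the per-row missingness labels from imputation."""
    matrix = pivot_replicate(table, design, replicate)
    matrix, report = run_dia_qc(matrix, cfg.qc)
    matrix, labels = impute(matrix, cfg.imputation)
    protein = normalize_and_aggregate(matrix, cfg.aggregation)
    return protein, report, labels


def build_spatial_dataset(
    table: pd.DataFrame,
    design: RunDesign,
    markers: pd.Series | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[SpatialDataset, dict[int, QcReport]]:
    """Process every replicate in the design and combine the results.

    Only proteins found in all replicates are retained.  QC stage counts and
    the imputation mode are recorded in the dataset's provenance.
    """
    matrices, reports = [], {}
    replicates = design.replicates
    for rep in replicates:
        protein, report, _ = process_replicate(table, design, rep, cfg)
        matrices.append(protein)
        reports[rep] = report
    provenance = {
        "imputation_mode": cfg.imputation.mode,
        "aggregation": cfg.aggregation,
        "renormalize_blocks": cfg.renormalize_blocks,
        "qc_stages": {rep: rpt.to_frame().to_dict("records") for rep, rpt in reports.items()},
    }
    dataset = combine_replicates(
        matrices,
        replicates=replicates,
        markers=markers,
        renormalize_blocks=cfg.renormalize_blocks,
        provenance=provenance,
    )
    return dataset, reports
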