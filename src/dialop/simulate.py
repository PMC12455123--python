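"""Synthetic fractionation experiments with known ground truth.

The generator emulates the premise of correlation profiling: proteins of one
compartment co-distribute across biochemical fractions.  Each compartment k
has a fixed fractionation profile w_k — a Gaussian bump over the fraction
index (center mu_k, width sigma_k, additive baseline b) normalized to sum to
1 — and the pre-censoring intensity of precursor j of protein i (class k) in
fraction f is

    I = A_i * e_ij * w_k[f] * eps,

with protein abundance A_i ~ LogNormal, precursor response e_ij ~ LogNormal
and per-cell multiplicative noise eps ~ LogNormal.  Missingness is generated
mechanistically rather than by pattern copying, so the imputation module's
MNAR/MAR rule can be scored against true mechanisms: a cell first goes
missing-MNAR with probability logistic((LOD - log I) * slope) — a
left-censoring detection limit — and a surviving cell goes missing-MAR with
a Bernoulli dropout rate p.  MAR dropout can act per cell (``mar_unit =
"cell"``, the default) or per protein-run (``"protein-run"``): in the latter
case a dropout event strikes a protein in one fraction of one replicate and
silences each of its precursors there with probability
``mar_event_completeness``, emulating run-level detection failures
(alignment/RT drift, ionization competition) that hit a protein's co-eluting
peptides together but not identically.  Such correlated events make
missing-at-random damage coherent enough to survive protein aggregation —
unlike independent cell dropout, which the median absorbs.  Only surviving
cells are written to the
emitted DIA-NN-dialect report, one table per replicate; the full truth
(class labels, pre-censoring intensities, per-cell mechanisms) is returned
alongside.

Protein identities (class, abundance, precursor responses) are drawn once
per experiment; noise and missingness are drawn from per-replicate
sub-streams derived deterministically from the experiment seed, so
replicates share biology but not measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import MARKER_CLASSES, RunDesign
from .io_diann import (
    write_marker_table,
    write_precursor_report,
    write_run_design,
)


@dataclass(frozen=True)
class SimConfig:
    """Fully determines one synthetic experiment (including the seed).

    Defaults describe a well-resolved 13-compartment, 10-fraction,
    3-replicate experiment: compartment profile centers evenly spaced across
    the fraction range with widths cycling through (0.6, 0.9, 1.2) fractions,
    log-intensity detection limit 10 (natural log of arbitrary MS intensity
    units, roughly the low tail of simulated cell intensities) with logistic
    censoring slope 1.5, and 5% random dropout.
    """

    n_classes: int = 13
    n_fractions: int = 10
    n_replicates: int = 3
    proteins_per_class: int = 40
    precursor_lambda: float = 4.0
    profile_centers: tuple[float, ...] | None = None
    profile_widths: tuple[float, ...] | None = None
    profile_baseline: float = 0.01
    abundance_meanlog: float = 14.0
    abundance_sdlog: float = 1.0
    response_sdlog: float = 0.3
    noise_sdlog: float = 0.15
    lod_log_intensity: float = 10.0
    lod_slope: float = 1.5
    mar_rate: float = 0.05
    mar_unit: str = "cell"  # "cell" or "protein-run"
    mar_event_completeness: float = 0.7  # P(precursor silenced | protein-run event)
    marker_fraction: float = 0.4
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("need at least 2 fractions")
        if not 0.0 <= self.mar_rate <= 1.0:
            raise ValueError("mar_rate must lie in [0, 1]")
        if self.mar_unit not in ("cell", "protein-run"):
            raise ValueError("mar_unit must be 'cell' or 'protein-run'")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ValueError("marker_fraction must lie in [0, 1]")

    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            if len(self.class_names) != self.n_classes:
                raise ValueError("class_names length must equal n_classes")
            return self.class_names
        names = list(MARKER_CLASSES[: self.n_classes])
        names += [f"class_{i + 1}" for i in range(len(names), self.n_classes)]
        return tuple(names)

    def resolved_centers(self) -> np.ndarray:
        if self.profile_centers is not None:
            return np.asarray(self.profile_centers, dtype=float)
        return np.linspace(1.0, float(self.n_fractions), self.n_classes)

    def resolved_widths(self) -> np.ndarray:
        if self.profile_widths is not None:
            widths = np.asarray(self.profile_widths, dtype=float)
        else:
            cycle = (0.6, 0.9, 1.2)
            widths = np.array([cycle[k % 3] for k in range(self.n_classes)])
        if len(widths) != self.n_classes:
            raise ValueError("profile_widths length must equal n_classes")
        return widths


def class_profiles(cfg: SimConfig) -> pd.DataFrame:
    """Per-class fractionation profiles (rows sum to 1)."""
    fractions = np.arange(1, cfg.n_fractions + 1, dtype=float)
    centers = cfg.resolved_centers()
    widths = cfg.resolved_widths()
    bump = cfg.profile_baseline + np.exp(
        -((fractions[None, :] - centers[:, None]) ** 2) / (2.0 * widths[:, None] ** 2)
    )
    bump /= bump.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        bump, index=list(cfg.resolved_class_names()), columns=fractions.astype(int)
    )


#: Per-cell mechanism labels in the truth table.
OBSERVED = "observed"
MNAR_CELL = "MNAR"
MAR_CELL = "MAR"


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    classes: pd.Series  # protein accession -> true compartment
    cells: pd.DataFrame  # replicate, precursor_id, fraction, intensity, mechanism


@dataclass
class SimExperiment:
    """A simulated experiment: per-replicate DIA-NN-dialect report tables,
    the run design, curated-marker subset and full ground truth."""

    config: SimConfig
    tables: list[pd.DataFrame]
    design: RunDesign
    markers: pd.Series
    truth: SimTruth
    profiles: pd.DataFrame = field(repr=False, default=None)

    def combined_table(self) -> pd.DataFrame:
        """All replicates' records in one long table."""
        return pd.concat(self.tables, ignore_index=True)


def _run_id(replicate: int, fraction: int) -> str:
    return f"rep{replicate}_frac{fraction:02d}"


def simulate_experiment(cfg: SimConfig = SimConfig()) -> SimExperiment:
    """Generate one experiment; deterministic given ``cfg`` (incl. seed)."""
    names = cfg.resolved_class_names()
    profiles = class_profiles(cfg)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates + 1)
    grng = np.random.default_rng(seeds[0])

    accessions, prot_class, prot_index = [], [], []
    for k, name in enumerate(names):
        for i in range(cfg.proteins_per_class):
            accessions.append(f"P{k:02d}{i:04d}")
            prot_class.append(name)
    classes = pd.Series(prot_class, index=accessions, name="true_class")

    n_prec = 1 + grng.poisson(cfg.precursor_lambda, size=len(accessions))
    abundance = grng.lognormal(cfg.abundance_meanlog, cfg.abundance_sdlog, len(accessions))
    prec_ids, prec_protein, prec_base = [], [], []
    for p_idx, acc in enumerate(accessions):
        w = profiles.loc[classes.iloc[p_idx]].to_numpy()
        responses = grng.lognormal(0.0, cfg.response_sdlog, n_prec[p_idx])
        for j in range(n_prec[p_idx]):
            prec_ids.append(f"{acc}_PEP{j:02d}2")
            prec_protein.append(acc)
            prec_base.append(abundance[p_idx] * responses[j] * w)
    base = np.vstack(prec_base)  # precursors x fractions, pre-noise
    prec_protein = np.asarray(prec_protein, dtype=object)
    acc_pos = {acc: i for i, acc in enumerate(accessions)}
    prec_prot_idx = np.array([acc_pos[a] for a in prec_protein])

    runs = {
        _run_id(r, f): (r, f)
        for r in range(1, cfg.n_replicates + 1)
        for f in range(1, cfg.n_fractions + 1)
    }
    design = RunDesign(runs)

    tables, truth_frames = [], []
    fractions = np.arange(1, cfg.n_fractions + 1)
    for r in range(1, cfg.n_replicates + 1):
        rng = np.random.default_rng(seeds[r])
        eps = rng.lognormal(0.0, cfg.noise_sdlog, base.shape)
        intensity = base * eps
        with np.errstate(divide="ignore"):
            p_mnar = expit((cfg.lod_log_intensity - np.log(intensity)) * cfg.lod_slope)
        mnar = rng.random(base.shape) < p_mnar
        if cfg.mar_unit == "protein-run":
            events = rng.random((len(accessions), cfg.n_fractions)) < cfg.mar_rate
            struck = events[prec_prot_idx, :] & (
                rng.random(base.shape) < cfg.mar_event_completeness
            )
            mar = ~mnar & struck
        else:
            mar = ~mnar & (rng.random(base.shape) < cfg.mar_rate)
        observed = ~mnar & ~mar
        mechanism = np.where(mnar, MNAR_CELL, np.where(mar, MAR_CELL, OBSERVED))

        rows, cols = np.nonzero(observed)
        tables.append(
            pd.DataFrame(
                {
                    "run_id": [_run_id(r, int(fractions[c])) for c in cols],
                    "protein_group": prec_protein[rows],
                    "precursor_id": np.asarray(prec_ids, dtype=object)[rows],
                    "intensity": intensity[rows, cols],
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "replicate": r,
                    "precursor_id": np.repeat(prec_ids, cfg.n_fractions),
                    "fraction": np.tile(fractions, len(prec_ids)),
                    "intensity": intensity.ravel(),
                    "mechanism": mechanism.ravel(),
                }
            )
        )

    n_markers = int(round(cfg.marker_fraction * cfg.proteins_per_class))
    marker_acc = [
        acc
        for k in range(cfg.n_classes)
        for acc in accessions[
            k * cfg.proteins_per_class : k * cfg.proteins_per_class + n_markers
        ]
    ]
    markers = classes.loc[marker_acc].copy()
    markers.name = "marker_class"

    truth = SimTruth(classes, pd.concat(truth_frames, ignore_index=True))
    return SimExperiment(cfg, tables, design, markers, truth, profiles)


def scenario_presets() -> dict[str, SimConfig]:
    """Named scenarios used throughout testing.

    - ``dialop-like``: the default well-resolved design — 13 compartments,
      10 fractions, 3 replicates, profile centers spread across the gradient.
    - ``detergent-like``: 6 fractions with the four secretory compartments
      (ER, Golgi, endosome, lysosome) centered within one fraction of each
      other and broadened — detergent solubilization separates these
      membranes poorly.
    - ``fraction-dropout``: identical design to ``dialop-like``; downstream
      analyses subset its fractions to study resolution loss.
    - ``mechanism-mix``: both mechanisms material — a shallower detection
      limit (LOD 8.5, so roughly a quarter of cells are left-censored rather
      than half) plus coherent protein-run MAR dropout (10% event rate), the
      regime in which the blind spot of each global imputation strategy
      shows; >= 500 proteins.
    """
    base = SimConfig(seed=101)
    # 6-fraction centers: secretory classes piled between fractions 3.2-4.1,
    # the other nine spread over the remaining range.
    spread = np.concatenate([np.linspace(1.0, 2.8, 5), np.linspace(4.6, 6.0, 4)])
    secretory = {"endoplasmic reticulum": 3.2, "Golgi apparatus": 3.5,
                 "endosome": 3.8, "lysosome": 4.1}
    centers, widths, spread_iter = [], [], iter(spread)
    for name in SimConfig(n_fractions=6).resolved_class_names():
        if name in secretory:
            centers.append(secretory[name])
            widths.append(1.2)
        else:
            centers.append(float(next(spread_iter)))
            widths.append(0.8)
    detergent = replace(
        base,
        n_fractions=6,
        profile_centers=tuple(centers),
        profile_widths=tuple(widths),
        seed=102,
    )
    return {
        "dialop-like": base,
        "detergent-like": detergent,
        "fraction-dropout": replace(base, seed=103),
        "mechanism-mix": replace(
            base,
            mar_rate=0.10,
            mar_unit="protein-run",
            lod_log_intensity=8.5,
            seed=104,
        ),
    }


def write_simulation(experiment: SimExperiment, out_dir: str | Path) -> None:
    """Write an experiment to disk: one DIA-NN-dialect report per replicate,
    the run design, marker table and ground truth, all as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r, table in enumerate(experiment.tables, start=1):
        write_precursor_report(table, out / f"report_rep{r}.tsv")
    write_run_design(experiment.design, out / "design.tsv")
    write_marker_table(experiment.markers, out / "markers.tsv")
    experiment.truth.classes.rename("true_class").rename_axis("accession").reset_index().to_csv(
        out / "truth_classes.tsv", sep="\t", index=False
    )
    experiment.truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
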