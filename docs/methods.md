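# Methods

## The pipeline model

`dialop` implements correlation-profiling spatial proteomics for
differential-centrifugation (DC) fractionation read out by DIA mass
spectrometry. The unit of quantification is the precursor (modified peptide
sequence + charge); one MS run quantifies one fraction of one replicate, and
the run→(replicate, fraction) design is always supplied explicitly, never
inferred from file names. Zero intensities are coerced to missing on ingest
(an MS zero is a non-detection), switchable off per dialect.

### Quality control

The DIA branch runs four filters in a fixed order: contaminant/ambiguous
removal → intensity high-pass → fraction (column) filter → precursor (row)
filter. The order matters because the row filter counts support "across the
remaining fractions". Thresholds are read strictly: a fraction with *over*
70% missing precursors is dropped (exactly 70% survives) and a precursor
with *fewer than two* values is dropped (exactly two survives). The
high-pass default is 0 (off): no principled default exists, so users must
set it deliberately. The DDA/TMT branch keeps PSMs with average reporter
S/N ≥ 10, co-isolation interference strictly below 75%, and SPS mass-match
percentage ≥ 65% — the SPS default is a common community choice, not a value
with independent authority; it is config-exposed like every other threshold.

### Mixed imputation

Each replicate is imputed independently; replicates never share
information, so a profile shift in one replicate cannot contaminate
another. Rows are labeled by their own missingness count: more than 2
missing values → MNAR, 1–2 → MAR, 0 → COMPLETE. The count rule is used as
an absolute count, not a proportion; with 10 fractions it coincides with a
20% proportion, and a proportional mode exists for other designs but is
never applied silently. MNAR rows are filled with the *global* observed
minimum of the replicate matrix (the classic "min" left-censor method; a
per-column variant is available), computed before any imputation. MAR rows
are filled by k-NN: distance between rows is the Euclidean distance over
mutually observed columns scaled by √(total columns / shared columns), and
a missing cell becomes the mean of that column over the k = 10 nearest rows
observed there (scikit-learn's `KNNImputer` implements exactly these
semantics). The donor pool is all rows, pre-imputation, including MNAR
rows. Ties are broken deterministically; no default path uses randomness.

Global MinDet (per-column 1% linear-interpolation quantile for every
missing cell) and global k-NN are provided as the cautionary baselines: a
left-censor method wrongly zeroes missing cells that carried real signal,
and a hot-deck method wrongly pulls censored cells up toward donor means.

### Normalization, aggregation, assembly

Order is fixed: impute → sum-normalize → aggregate. Sum normalization
divides each precursor row by its total so rows sum to 1 (± 1e-9 enforced).
DIA aggregation is the per-column median over a protein's precursors; the
DDA branch instead fits cell = column_effect + feature_effect per protein by
iteratively reweighted least squares with Huber weights (tuning constant
1.345, ≤ 20 iterations, tolerance 1e-6; statsmodels RLM), returning the
column effects and falling back to the median on a failed fit. Because
medians of normalized rows do not sum to 1, each per-replicate protein block
is re-sum-normalized by default before concatenation (switchable; PCA and
SVM results are then on a [0, 1] profile scale). Only proteins present in
every replicate enter the spatial dataset.

### Classification

Markers for 13 compartments (cytosol, mitochondrion, nucleus, chromatin,
plasma membrane, ER, Golgi, endosome, lysosome, peroxisome, proteasome, 40S
and 60S ribosomes) train an RBF SVM with inverse-class-frequency weights.
Assessment: `outer_rounds` stratified 80/20 splits (default 100, 10 for
desk-scale runs); per round, C ∈ 2⁻⁴..2⁴ and γ ∈ 10⁻³..10² are selected by
5-fold cross-validated macro-F1 on the 80%, and per-class F1 is recorded on
the 20%. Every marker class must have ≥ 6 members. Scores are
probability-calibrated by pairwise coupling so they sum to 1 and thresholds
share a [0, 1] scale. Per-organelle thresholds are, by default, the median
(q configurable) of the winning scores achieved by *correct* held-out
marker predictions — a reproducible stand-in for the manual per-organelle
tailoring practitioners perform; explicit per-class thresholds can be
supplied, and the thresholds actually applied are always recorded in the
result rather than claimed to match any external choice. Markers always
keep their curated labels.

### Resolution metrics

QSep: entry (i, j) of the raw matrix is the mean Euclidean distance between
full profiles of marker clusters i and j (distinct pairs on the diagonal);
each row is divided by its diagonal, so the normalized matrix has unit
diagonal, is scale-invariant, and is asymmetric (row normalization — this
follows the metric's published form). The summary is the median of
off-diagonal normalized entries per row and globally. PCA coordinates are
column-mean-centered (unit-variance scaling optional, off by default since
profiles are already on a common scale); component signs are fixed by
making the largest-magnitude loading positive. The top and bottom
`trim_frac` (default 0.01%) of points by PC1 and by PC2 are *flagged* as
display outliers — flagged points are never removed from the dataset and
trimming never feeds classification. t-SNE is a pass-through convenience
with no metric derived from it.

## The synthetic generator

`simulate_experiment` draws, per experiment: a profile w_k per class — a
Gaussian bump over fraction index (centers default to an even spread over
the fraction range; widths cycle 0.6/0.9/1.2 fractions; baseline 0.01)
normalized to sum to 1 — protein abundances A_i ~ LogNormal(meanlog 14,
sdlog 1), precursor counts 1 + Poisson(4), precursor responses
e_ij ~ LogNormal(0, 0.3). Per replicate it draws multiplicative cell noise
ε ~ LogNormal(0, 0.15) and missingness: a cell first goes missing-MNAR with
probability logistic((LOD − log I)·slope) (defaults LOD = 10 on the
natural-log intensity scale, slope 1.5 — deep enough that profile tails
censor, as expected when a separation gradient depletes a compartment from
most fractions), then missing-MAR with dropout rate p (default 5%). MAR
dropout is per-cell by default; a "protein-run" mode instead draws dropout
events per (protein, fraction, replicate) and silences each of the
protein's precursors with probability 0.7, emulating run-level detection
failures that hit co-eluting peptides of a protein together. Protein
identities are drawn once; noise and missingness come from per-replicate
sub-streams spawned deterministically from the experiment seed, so
replicates share biology but not measurement error, and equal seeds give
bit-identical output tables.

Scenario presets fix full configurations including seeds: `dialop-like`
(13 classes × 10 fractions × 3 replicates, 40 proteins/class, 40% markers),
`detergent-like` (6 fractions; ER/Golgi/endosome/lysosome centers within
one fraction of each other and broadened, since detergent solubilization
separates those membranes poorly), `fraction-dropout` (as dialop-like;
downstream analyses subset its fractions), and `mechanism-mix` (LOD 8.5 so
roughly a quarter of cells censor, plus protein-run MAR at a 10% event
rate — a regime where both mechanisms are material).

### What the generator does and does not emulate

It generates missingness mechanistically (censoring + dropout), so the
MNAR/MAR row rule can be scored against true mechanisms, and it reproduces
the qualitative structure of fractionation data: class-specific profiles,
heavy intensity dynamic range, left-censored tails. It does not emulate
correlated biological replicates drifting in fractionation efficiency,
multi-localized proteins, isobaric interference, retention-time structure,
or search-engine FDR behavior. Passing tests therefore demonstrate that the
pipeline's operations are correct and that its directional claims hold in a
controlled world — not that real-data resolution numbers transfer.

One honest caveat surfaced by this controlled world: the advantage of the
mixed strategy over a *global MinDet* baseline, measured as downstream
marker macro-F1, is small and draw-dependent here. Median aggregation over
several precursors absorbs most of the damage an indiscriminate left-censor
fill does, and k-NN repair of MAR cells is imperfect because nearest
neighbours in raw intensity space are abundance-matched rather than
shape-matched (sparse rows with few shared columns are over-favoured by the
√(total/shared) rescaling). The advantage over *global k-NN* is large and
robust. The package reports both comparisons as computed rather than
asserting a fixed ordering.

## Numerical and design choices

- DIA-NN dialect defaults: columns `Run`, `Protein.Group`, `Precursor.Id`,
  intensity from `Precursor.Normalised` with fallback `Precursor.Quantity`;
  all overridable (report dialects drift between versions).
- MinDet quantile uses the linear-interpolation convention
  (`numpy.quantile` default); q → 0 approaches the column minimum.
- Robust summarization estimates column effects in a reference-feature
  parameterization; effects are defined up to an additive constant, which
  the DDA branch's subsequent sum normalization removes.
- Best SVM hyperparameters across outer rounds are the modal (C, γ) pair,
  ties broken toward smaller values.
- A marker class never correctly predicted during cross-validation gets
  threshold 1.0 under the quantile rule (nothing is assigned to it).
- Degenerate inputs raise typed errors naming the offender: runs missing
  from the design, duplicate (precursor, fraction) records, all-missing
  columns at imputation time, non-positive row sums at normalization,
  singleton marker clusters in QSep, undersized marker classes at training.

## Problem sizes

Desk-scale defaults are used throughout testing: presets simulate 520
proteins (≈ 2 600 precursors) over 10 fractions × 3 replicates, and
cross-validation uses 10 outer rounds; the full acceptance computation runs
in a few minutes on one CPU. The assessment protocol itself defaults to 100
rounds for production use.
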