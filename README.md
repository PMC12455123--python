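# dialop

Subcellular spatial proteomics from biochemical fractionation profiles.

When a cell lysate is separated by differential ultracentrifugation into a
series of fractions, proteins of one compartment co-distribute: the relative
intensity of a protein across fractions traces a profile characteristic of
its organelle (the correlation-profiling / De Duve principle). `dialop` turns
a precursor-level quantification report (one MS run per fraction per
replicate, DIA-NN-style TSV) into a classified subcellular map:

1. **QC** — removal of contaminant and ambiguous protein groups, an optional
   intensity high-pass, then missing-value filtration: fractions missing for
   over 70% of precursors are dropped, and precursors with fewer than two
   quantitative values across the remaining fractions are removed.
2. **Mixed MNAR/MAR imputation, per replicate** — each precursor row is
   assigned a missingness mechanism from its own profile: rows missing more
   than 2 values are treated as missing-not-at-random (left-censored, below
   the detection limit) and filled with the minimum observed value of the
   replicate matrix; the remaining incomplete rows are missing-at-random and
   filled by k-nearest-neighbour averaging (k = 10, Euclidean distance on
   mutually observed columns rescaled by √(total/shared)). Global MinDet and
   global k-NN are included as cautionary baselines.
3. **Normalization and aggregation** — precursor rows are sum-normalized
   (each row sums to 1), aggregated to protein level by per-column median
   (or robust Huber summarization for the TMT/DDA branch), and the
   per-replicate protein profiles are concatenated replicate-major, keeping
   only proteins found in all replicates.
4. **Marker-based SVM localization** — curated markers for 13 compartments
   train an RBF-kernel SVM (class weights inverse to class size). Over
   stratified 80/20 outer rounds, hyperparameters are picked by 5-fold
   cross-validated macro-F1 and held-out per-class F1 distributions are
   recorded (F1 = 2PR/(P+R)). Calibrated scores are thresholded per
   organelle; proteins below threshold stay "unknown".
5. **Resolution metrics** — QSep (mean within- vs between-cluster Euclidean
   distance of full profiles, row-normalized so the diagonal is 1) and
   per-class F1 distributions; PCA map coordinates with tail-outlier
   flagging (display only).

A fully parameterized synthetic-experiment generator (`dialop.simulate`)
emulates organelle profiles, protein/precursor hierarchies, lognormal noise,
logistic intensity censoring (MNAR) and random dropout (MAR) with complete
ground truth, so the whole pipeline is testable without any download.

## Worked example

```python
import dialop as dl

exp = dl.simulate_experiment(dl.scenario_presets()["dialop-like"])
dataset, reports = dl.build_spatial_dataset(
    exp.combined_table(), exp.design, markers=exp.markers
)
print(dataset.profiles.shape)

result, cv = dl.classify(dataset, dl.SvmConfig(outer_rounds=10, seed=42))
print(cv.median_f1().median(), cv.best_params)

unlabeled = dataset.unlabeled
truth = exp.truth.classes.loc[unlabeled]
print((result.assignments.loc[unlabeled, "predicted"] == truth).mean())
```

prints

```
(518, 30)
1.0 {'C': 0.25, 'gamma': 1.0}
1.0
```

i.e. 518 of 520 simulated proteins survive QC in all three replicates
(30 profile columns = 10 fractions × 3 replicates), the median held-out F1
across the 13 marker classes is 1.0 with the selected RBF hyperparameters,
and 100% of the unlabeled proteins are returned to their true compartment.

The same flow is available from the shell:

```bash
dialop simulate --preset dialop-like --out sim/
dialop ingest --report sim/report_rep1.tsv --report sim/report_rep2.tsv \
              --report sim/report_rep3.tsv --design sim/design.tsv --out matrices/
dialop qc --in matrices/ --out qced/ --report qc_report.tsv
dialop impute --in qced/ --mode mixed --out imputed/
dialop aggregate --in imputed/ --markers sim/markers.tsv --out dataset.tsv
dialop classify --dataset dataset.tsv --rounds 10 --out map.tsv
dialop qsep --dataset dataset.tsv --out qsep.tsv
```

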