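# neurofuse

Multidimensional resting-state EEG analysis in one reusable pipeline:

- **Temporal**: Lempel-Ziv complexity (exhaustive-history LZ76 phrase count of
  median-binarized epochs), broadband and per frequency band.
- **Spectral**: individualized frequency-band detection by generalized
  eigendecomposition (GED) of narrowband-vs-broadband covariances across a
  frequency sweep, eigenvector-similarity clustering (DBSCAN or peak/trough),
  and Welch band power over each subject's own intervals.
- **Spatial**: directed nonlinear connectivity via ordinal-pattern
  symbolization and Gaussian-kernel Granger causality, gated against IAAFT
  surrogate nulls with an exact one-sided Wilcoxon signed-rank test; weighted
  graph metrics (clustering coefficient, characteristic path length, global
  and local efficiency, plus nodal variants).
- **Statistics**: normality screening (Lilliefors) with log-transform
  fallback, Welch t / Mann-Whitney routing, Benjamini-Hochberg FDR within
  feature families, Cohen's d.
- **Classification**: per-subject fusion of temporal (4 bands x 8 channels),
  spectral (4 x 8), and spatial (8 x 7 x 4 connectivity + 8 nodal metrics
  x 4 x 4) features — 416 columns — evaluated with a subject-level,
  stratified, 5-repetition 10-fold cross-validated SVM-RBF (C = 1).

Because no public recordings ship with the method, a first-class
`synthetic_data` module generates EEG-like cohorts with known ground truth:
Gaussian-spectral-filtered noise oscillations with per-subject peak
frequencies and bandwidths, 1/f background, planted directed lagged
couplings, and two groups with configurable effect directions. Every
downstream stage is validated by parameter recovery against what was planted.

## Command line

```bash
neurofuse simulate --preset paper_like --n-per-group 20 --seed 1 --out data/
neurofuse preprocess --in data/ --out pre/ --notch 50 --band 0.5 45
neurofuse features lzc --in pre/ --bands canonical --out lzc.tsv
neurofuse features gedbounds --in pre/ --out bounds.tsv powers.tsv
neurofuse features gsngc --in pre/ --seed 1 --out conn/
neurofuse features graph --conn conn/ --mode weighted --out graph.tsv
neurofuse classify --features features.tsv --blocks T,F,S --seed 1 --out cv.json report.tsv
```

or everything at once from a YAML config (any `PipelineConfig` field):

```bash
neurofuse run --config cfg.yaml        # simulate -> ... -> classify
```

Re-running skips completed stages whose outputs match the config hash in
`manifest.yaml`; pass `--force` to recompute.

## Acceptance

`tests/test_acceptance.py` implements the acceptance criteria (oracle
equivalence for LZ76, BH-FDR and the graph metrics; IAAFT and Wilcoxon-gate
exactness; planted-band, coupling-direction and group-effect recovery; null
calibration; end-to-end direction fidelity). The acceptance report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a deterministic self-check and writes the (empty) numeric target map —
the source study's headline numbers were computed on private clinical data
and are not reproducible offline, so acceptance is property-based.

## Layout

| module | contents |
| --- | --- |
| `neurofuse.synthetic_data` | cohort/subject/coupled-pair generators, ground truth |
| `neurofuse.io_preprocess` | Recording/EpochSet, EDF+TSV I/O, zero-phase filters, epoching |
| `neurofuse.edfio` | minimal 16-bit EDF reader/writer |
| `neurofuse.complexity` | median binarization, LZ76, normalized LZC features |
| `neurofuse.gedbounds` | GED sweep, similarity clustering, band assignment, band power |
| `neurofuse.gsngc` | symbolization, IAAFT surrogates, kernel GC, surrogate gate |
| `neurofuse.network_metrics` | weighted/binary graph metrics, metric tables |
| `neurofuse.group_stats` | normality routing, tests, BH-FDR, effect sizes |
| `neurofuse.classification` | feature assembly, repeated subject-level CV, ablation |
| `neurofuse.pipeline_cli` | config, orchestration, provenance, click CLI |
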