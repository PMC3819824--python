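# chromaccess

Quantitative modeling of chromatin accessibility within DNase I
hypersensitive sites (DHSs) from histone-modification (HM) and
transcription-factor (TF) ChIP-seq signals.

The package implements the full analysis pipeline as reusable, tested
components:

- **`chromaccess.genomic`** — 0-based half-open genomic intervals, peak sets,
  and piecewise-constant signal tracks (BED / bedGraph / wiggle readers and
  writers), with per-region `max`/`avg` aggregation and binary-search
  interval overlap.
- **`chromaccess.localization`** — per-feature percentage of peaks located in
  open chromatin (any ≥1 bp overlap with a DHS counts as presence), with
  unweighted HM/TF class means.
- **`chromaccess.feature_matrix`** — the regions × features aggregated-signal
  matrix plus the DNase target vector, region subsampling, TSV round-trip.
- **`chromaccess.modeling`** — epsilon-SVR (RBF kernel, libsvm-style
  defaults: cost 1, epsilon 0.1, gamma 1/n_features, train-fold
  standardization of features and target) and ordinary least squares, under
  10-fold cross-validation with pooled out-of-fold predictions. Prediction
  power `R` is the positive square root of the squared Pearson correlation
  between pooled predictions and observations. A four-way model comparison
  (SVR/LM × max/avg aggregation, per HM/TF/HM+TF feature set) is included.
- **`chromaccess.combinatorics`** — exhaustive evaluation of all k-feature
  models (shared fold partition across subsets), top-combination selection
  at a relative-power threshold, upper-tail hypergeometric feature
  enrichment with Benjamini–Hochberg adjustment, and the sample-size curve.
- **`chromaccess.synthetic`** — a fully deterministic generator of DHS
  regions, peak sets and signal tracks: a latent per-region accessibility
  value drives the DNase signal and, through monotone (power / saturating)
  noisy links, a configurable set of redundant informative features plus
  pure-noise features. Signal bumps are discretized triangles with exactly
  known max and mean, so aggregation behavior is testable in closed form.
- **`chromaccess.pipeline` / `chromaccess.cli`** — end-to-end orchestration
  with a single master seed feeding named per-stage substreams.

## CLI

```bash
# generate the default 33-feature (10 HM + 23 TF) synthetic dataset
chromaccess simulate --seed 1 --out data/

# percentage of each feature's peaks inside DHSs
chromaccess localize --dhs data/dhs.bed --manifest manifest.tsv --out localization.tsv

# build the (sampled) signal matrix, then cross-validate a model
chromaccess matrix --dhs data/dhs.bed --dnase data/DNase.bedGraph \
    --manifest manifest.tsv --aggregation max --sample-n 5000 --out matrix.tsv
chromaccess model --matrix matrix.tsv --algorithm svr --folds 10

# exhaustive k-feature evaluation, top set, enrichment, sample-size curve
chromaccess combos --matrix matrix.tsv -k 3 --algorithm lm --out combos.tsv
chromaccess enrich --combinations combos.tsv --matrix matrix.tsv \
    --r-full 0.80 --threshold 0.9 --out enrichment.tsv
chromaccess sample-size --matrix matrix.tsv --sizes 200,500,1000,2000 --reps 500 \
    --out curve.tsv

# everything in one go, on freshly simulated data
chromaccess run-all --simulate --seed 1 --out run/
```

Feature manifests are TSV files with columns `name`, `class` (HM|TF),
`track_path`, and optionally `peak_path` and `dialect`, resolved relative to
the manifest location. All outputs are plain tab-separated tables; rerunning
with the same seed reproduces them byte for byte.

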