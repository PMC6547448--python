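# tfscribe

Predictive modeling of gene transcript levels from quantitative transcription
factor (TF) binding signal, built for ChIP-exo-style coverage data paired
with condition-matched RNA-seq.

Chromatin-immunoprecipitation studies usually reduce TF binding to called
peaks and ask which genes are "targets". This package follows a different
route: it quantifies the **total ChIP-exo read count in each gene's promoter
window** (TSS −500 to +500 bp) and treats that number as a quantitative
covariate in transparent regression models of expression,

```
Y_i = β0 + β1·X_1i + … + βk·X_ki + ε_i
```

where `Y_i` is the FPKM of gene *i* and `X_ki` the promoter binding signal of
TF *k*. On top of ordinary least squares it implements **multivariate
adaptive regression splines (MARS)** from scratch: an additive model of
linear and hinge terms `max(0, x − t)` grown by a greedy forward pass (knots
restricted by an endspan rule) and pruned backward under generalized
cross-validation,

```
GCV(M) = (RSS/n) / (1 − C(M)/n)²,   C(M) = #coefficients + penalty·#knots,
```

with repeated k-fold refits to retain only TFs and spline shapes that recur
across folds. A hinge knot has a direct reading: a binding threshold below
which a TF has no predicted effect.

Around that core the package provides the full analysis cycle:

- **chip**: WIG coverage I/O, replicate averaging, promoter sums, a naive
  SNR-thresholded peak caller, peak→gene annotation, peak-window sums, and
  per-condition target-set overlaps — the three binding representations the
  models compare.
- **expression**: count filtering (≥1 read in every sample), FPKM, replicate
  averaging, sum-of-squares (unit-norm) normalization of cross-condition
  profiles.
- **mars**: the spline engine (`ols_fit`, `mars_forward`, `mars_prune`,
  `cv_select`, `relative_importance`).
- **regulatory**: signed TF importance (R² × relative importance × sign),
  binding collinearity with product-moment significance, substitution tests
  for collinear TFs, additive-vs-multiplicative pair interactions, promoter
  segment scans and symmetric region-extension scans, coordinated-trio
  detection.
- **clustering**: BIC-selected k-means on normalized expression,
  hypergeometric gene-set enrichment with Benjamini–Hochberg control,
  per-cluster linear models.
- **synthetic / scenarios**: a generator of ground-truth binding matrices,
  expression responses, pseudo-counts and raw-style coverage tracks, plus
  planted-truth benchmark scenarios, so that every claim the pipeline makes
  is testable against a known answer.
- **pipeline / cli**: a YAML-configured end-to-end run (`tfscribe run`) with
  a deterministic seed fan-out and a self-contained demo (`tfscribe demo`).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
with known generative truth (850 genes × 21 TFs × 4 conditions; six
activating TFs, most behind a binding threshold; one collinear pair at
ρ = 0.9; one multiplicative pair):

```bash
python analysis/01_simulate_study_data.py
python analysis/02_fit_expression_models.py
```

prints, among other lines:

```
nitrogen_lim: R2 = 0.309; selected ['TF00', 'TF02', 'TF05', 'TF08', 'TF12', 'TF16']
anaerobic:    R2 = 0.454; selected ['TF00', 'TF02', 'TF05', 'TF08', 'TF12', 'TF16']
variance explained: 0.31-0.45 (mean 0.37)
planted drivers recovered: ['TF00', 'TF02', 'TF05', 'TF08', 'TF12', 'TF16'] of [...]
```

i.e. the cross-validated spline models explain 31–45% of expression variance
at the calibrated noise level and recover exactly the six planted drivers —
no false TF enters any condition's model. `03_collinearity_and_interactions.py`
then reports the planted ρ = 0.9 pair as substitutable in every condition
(`[('TF02', 'TF03')]`): dropping the selected member of the pair pulls its
partner into the selection, the signature of redundant binding.
`05_promoter_geometry.py` compares binding representations on tracks where
sub-threshold binding drives expression:

```
promoter_sum: 0.882    peak_window: 0.503    peak_signal: 0.091
segment scan: max signed r^2 0.99 at -363 bp (causal region planted at -450..-250)
region extension: plateau at +/-250 bp (causal peak planted at -200, width 10)
```

— summing the whole promoter beats peak-based quantification exactly when
real but weak binding escapes the peak caller, and the segment/extension
scans localize the planted causal region. `06_benchmark_recovery.py` prints
seeded recovery rates (hinge knots, substitution, interaction flags, BIC
cluster count).

A self-contained small run of the full pipeline, from WIG tracks to cluster
models:

```bash
tfscribe demo --seed 7 --out demo
tfscribe run --config demo/run.yaml
```

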