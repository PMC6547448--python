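# Methods

## Signal quantification

Coverage tracks are dense per-base read counts, 1-based inclusive (the WIG
convention). The promoter window is TSS −500 to +500 bp and therefore spans
1001 bases. Windows are strand-mirrored by default so that "upstream" is 5′
of the gene; because it is not obvious that every published processing chain
did this, `promoter_sum(..., mirror_strand=False)` reproduces the
strand-agnostic alternative. Replicates are averaged at the track level
(per-base arithmetic mean) before any quantification.

Three representations of promoter binding are produced:

* **promoter_sum** — total coverage in the window;
* **peak_window** — coverage summed ±50 bp around detected peaks annotated
  to the gene (overlapping windows count each base once);
* **peak_signal** — summit signal of SNR-passing peaks.

The peak caller is deliberately naive plumbing, not a reimplementation of a
model-based event caller: smoothed local maxima (5 bp moving average,
plateau midpoints included), local noise estimated as the median coverage in
2 kb flanks excluding the peak span (the contiguous region at ≥ half the
summit height, capped at ±500 bp so a high background cannot swallow the
chromosome), and a strict `signal/noise > 2` retention rule. Peaks are
annotated to the nearest TSS within 500 bp, ties broken by lexicographic
gene id for determinism; each peak is assigned to at most one gene.

## Expression processing

Genes are kept only if every sample (all conditions × replicates) has at
least 1 read; the filter runs before library sizes are computed, so library
size is the column sum over retained genes. FPKM is
`count · 10⁹ / (libsize · length)`, averaged over replicates per condition.
No compositional normalization (e.g. TMM) is applied — plain FPKM keeps the
response interpretable and the regressions operate on the natural FPKM
scale; a `log2(FPKM+1)` transform exists but is off by default. For
cross-condition clustering each gene's condition vector is scaled to unit
Euclidean norm ("sum-of-squares normalization"), which removes absolute
expression level and keeps only the relative pattern.

## The MARS engine

The model is additive, degree 1: an intercept plus linear terms and hinge
pairs `max(0, x−t)` / `max(0, t−x)` on single predictors.

**Forward pass.** At each step the candidate set is, per predictor, a linear
term plus a mirrored hinge pair at each admissible knot; the addition with
the largest RSS reduction wins (ties: lowest variable index, then lowest
knot). Knots are observed data values with at least `endspan` observations
strictly below and above (default 100, suppressing boundary knots); when the
admissible set is large it is thinned to at most `max_knot_candidates`
(default 64) evenly spaced order statistics — a cost cap that leaves knot
resolution at a fraction of a percent of the data range at study scale,
while small problems keep every observed value. Screening uses an
incrementally updated orthonormal basis, so each step only projects
candidates onto the newly added direction. The pass stops at `max_terms`
(default `min(21, n/10)`) or when the relative RSS improvement falls below
1e−6.

**Pruning.** Backward deletion under
`GCV(M) = (RSS/n)/(1 − C(M)/n)²` with `C(M) = #coefficients + penalty·#knots`
(penalty 2, the additive-model convention; a mirrored pair sharing one knot
counts one knot). Each step removes the term whose removal minimizes the
GCV of the refitted remainder, and the model along the path with minimal GCV
is returned. For small candidate sets (≤ 8 terms) all subsets are
enumerated instead, which removes the occasional suboptimality of the greedy
path at negligible cost; the greedy deletion trace is still recorded.

**Cross-validated structure selection** (`cv_select`). MARS is refitted on
each fold-complement of repeated shuffled k-fold splits; a predictor is
retained if selected in more than half of the fits, and its hinge form if a
hinge on it appeared in more than half of the fits (final knot = median of
the per-fit knots). The retained structure is refitted on all data, useless
hinge sides are dropped (GCV deletion restricted so no retained predictor
disappears), and finally any predictor whose terms are jointly insignificant
in a partial F-test (α = 0.01) is eliminated. The last step matters: fold
refits share the dataset, so a chance correlation is selected *consistently*
and recurrence alone cannot reject it; the F-filter is what makes pure-noise
inputs return intercept-only models reliably. The whole scheme is this
package's reconstruction of "conservative selection by cross-validation";
every knob (folds, repeats, retention fraction, α) is exposed.

**Importance.** Relative importance of a selected predictor is the GCV
increase when all of its terms are removed (with refit), normalized to sum
to 1. The signed importance score is `R² × relative importance × sign`,
with the sign taken from the net slope (coefficient × average basis slope
over the data) of the predictor's terms — positive means activation,
negative repression. By construction |score| ≤ R² and the scores of one
model sum in absolute value to at most R².

## Regulatory statistics

* **Collinearity**: pairwise Pearson r between TF binding columns;
  two-sided p from `t = r·√((n−2)/(1−r²))` against t(n−2); stars at 0.05 /
  0.01 / 0.001; zero-variance columns recorded as missing.
* **Substitution**: for each selected TF *t* and each significantly
  correlated (p < 0.05) unselected TF *u*, the selection is refitted with
  *t* removed from the candidates; (t, u) is substitutable if *u* enters.
  Only one TF is excluded at a time — the question is replaceability, not
  combinatorial search.
* **Interactions**: for every significantly correlated pair, OLS of
  `y ~ x_a + x_b` versus `y ~ x_a + x_b + x_a·x_b` (raw, uncentered products;
  a centering flag exists for diagnostics). The improvement ratio is
  `(ΔR² + R²_add)/R²_add`; a pair is flagged when `R²_add > 0.1` and the
  ratio is ≥ 1.10 (a 1e−12 slack keeps the boundary robust to float
  rounding). ΔR² ≥ 0 always (nested models).
* **Segment scan**: the ±1000 bp promoter range is tiled by 75 bp segments
  (final partial segment dropped); per TF and segment a simple OLS of
  expression on the segment's coverage sum yields a signed profile
  (r² × sign of slope) over segment midpoints.
* **Region extension**: symmetric windows grown in 50 bp half-width steps;
  per width, a linear-only selected regression's R² is recorded; the
  plateau is the smallest half-width within 1% of the curve maximum.
* **Trio detection**: genes are split by 2-means on the standardized joint
  profile (3 binding columns + expression). A "coordinated repression" call
  requires, in the high-binding group, mean pairwise binding correlation
  > 0.2 and a significantly negative (p < 0.01) correlation between mean
  binding and expression. The thresholds exist because 2-means grouping
  itself induces mild within-group correlations in random data.

## Clustering

k-means (k-means++ initialization, best of ≥10 restarts) on unit-norm
expression profiles. The cluster count is selected by the BIC of a
spherical Gaussian mixture fitted per candidate k. A hard-assignment k-means
BIC (`n·d·ln(WCSS/(n·d)) + k·d·ln(n)`, also available per-cluster-variance)
is provided for diagnostics but is *not* the default: under hard
assignments, splitting any Gaussian blob reduces within-cluster variance by
a scale-free factor (≈ 1 − (2/π)/d along the split axis), so the likelihood
term grows linearly in n and always beats the log-n penalty — the criterion
over-splits by construction. The soft mixture likelihood gains only O(log n)
from extra components on well-separated data, and the penalty decides; on
planted 4-cluster mixtures the default recovers k = 4 essentially always.

Enrichment: one-sided hypergeometric p for each cluster × gene-set overlap,
background = the clustered genes (the relevant universe for "relatively
enriched"), Benjamini–Hochberg across the full cluster × set grid (stricter
than per-cluster adjustment). Per-cluster models use linear-only `cv_select`
(splines are unstable in ~50-gene clusters), skip clusters under 10 genes,
and exclude zero-variance TF columns per cluster.

## Synthetic data: what it emulates and what it does not

`SyntheticTruth` holds the generative parameters: per-TF effects that are
linear, hinge (a binding threshold `t` below which the TF does nothing), or
saturating (a second threshold above which the effect plateaus); an optional
multiplicative pair `γ·x_a·x_b`; designated collinear pairs; Gaussian
expression noise; a seed.

* Binding marginals are log-normal (meanlog 2, sdlog 1), matching
  heavy-tailed promoter read-count sums. Collinear pairs are induced by a
  Gaussian copula on the log scale whose correlation is solved so the
  **natural-scale** Pearson correlation lands on the target ρ
  (`ρ_z = ln(1 + ρ(e^{σ²}−1))/σ²`); strongly negative targets are not
  reachable under log-normal marginals and are clipped with a warning.
* Expression noise is additive Gaussian on the FPKM scale (matching direct
  FPKM regressions), negative values clipped to zero. The default noise
  (sd 46 at study scale) is calibrated once so the generating model explains
  a realistic minority share (~1/3 to ~1/2) of expression variance.
* Pseudo-counts invert the FPKM formula at library size 10⁷ with gene
  lengths uniform in [500, 5000] bp, identical across replicates — the
  expression noise already lives in the response, and exact inversion keeps
  the counts→FPKM path testable to 1e−9.
* Coverage tracks are rectangular read pileups of stated height/width at
  stated TSS offsets over Poisson background — enough to exercise WIG I/O,
  peak calling, and window quantification analytically.
* All randomness fans out from one seed through fixed counter-based child
  streams (stream × condition × replicate), so identical truth gives a
  bit-identical bundle and pipeline reruns are byte-identical.

Deliberately **not** modeled: exonuclease footprint shape, fragment-length
distributions, nucleosome occupancy, motif content, cross-condition
persistence of binding (each condition's binding matrix is an independent
draw — so the synthetic data has no planted discrete cluster structure, and
cluster-count recovery is validated on planted mixtures instead), and
count-level overdispersion. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
robustness to every property of real ChIP-exo data.

## Benchmark scenarios and sizes

The planted scenarios (in `tfscribe.scenarios`) fix study conditions with
known answers:

* **Hinge recovery**: one TF, knot at 8 (near the binding median), noise
  0.2·sd(signal), n = 850, endspan 100. Success = a recovered knot within 5%
  of the data range of the truth and positive above-threshold slopes (the
  true below-knot slope is zero, so only coefficients with a nonzero true
  counterpart are sign-checked).
* **Substitution**: a dominant driver (β = 1.0) with a ρ = 0.95 co-driver
  whose effect (β = 0.15) was sized, by a conditional-t design calculation,
  to sit below the stable-selection threshold at noise sd 40 while keeping
  its marginal signal strong — the redundancy regime the test is about.
  19 inert decoys ride along.
* **Interaction**: a ρ = 0.6 pair with additive effects plus γ = 0.05
  product term, sized (population R² calculation at large n) so the
  multiplicative share is decisively above the 10%-improvement flag; the
  additive control sets γ = 0.
* **Cluster recovery**: 4 spherical Gaussian clusters, n = 800, d = 4,
  centers ≥ 6 within-cluster sd apart, nonnegative profiles.
* **Promoter geometry**: causal coverage confined to a stated window
  (segment scan: −450..−250; extension scan: a peak at −200), with a
  near-constant detectable peak plus broad sub-SNR pileups carrying the
  expression signal for the representation comparison.

Cross-validation in the benchmark runners uses 5 folds × 2 repeats (10
refits per selection) and the study-scale problems use n = 850, p = 21 —
sizes chosen so a full benchmark sweep completes in minutes on one CPU while
keeping every per-fit sample size in the regime the endspan-100 rule
presumes.

## Known limitations

* The forward pass adds hinge pairs only (single-sided entry happens via
  pruning), and degree-2 interactions inside MARS are out of scope —
  multiplicative effects are tested explicitly in the regulatory layer.
* GCV-based selection at penalty 2 is liberal for linear terms; the
  stabilized selector compensates with the CV-recurrence and F-filter steps,
  so single `fit_mars` calls overfit more than `cv_select` results.
* The peak caller is a stand-in adequate for rectangular synthetic pileups;
  it makes no claim of matching model-based event callers on real data.
* `region_extension_scan` and `segment_scan` refit per window
  independently; no multiplicity control is applied across segments, as the
  profiles are descriptive.
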