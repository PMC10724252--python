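# Methods

This note documents the models and procedures `cfnet` implements, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the bundled simulator does and does not emulate.

## Preprocessing

MaxQuant `proteinGroups.txt`-dialect tables are cleaned in a fixed order:
(1) rows flagged `Reverse`, `Potential contaminant`, or `Only identified by
site` are removed (absent flag columns remove nothing, with a warning);
(2) zeros are converted to missing for this dialect (MaxQuant writes 0 for
"not quantified"; the generic TSV dialect and the simulator keep an explicit
missing marker, so 0 remains a numeric zero there — `zeros_are_missing`
controls this); (3) protein groups are collapsed to gene symbols, keeping the
chromatogram with the fewest missing values per gene — ties broken by larger
summed intensity, then lexicographic group id, so the result is independent
of input row order; (4) proteins quantified in fewer than `min_fractions`
fractions (default 4, inclusive boundary) are dropped. A provenance log
guarantees `rows_in − rows_out = Σ per-rule removals`. Whether the
minimum-fraction filter should run before or after gene collapsing is
underdetermined; collapsing first is this package's choice and keeps the
fewest-missing rule operating on raw group chromatograms.

## Co-elution measures

All measures operate on one experiment's chromatograms and are symmetric in
their arguments. Each is bound to a missing-value strategy; the binding is
enforced by `MeasureSpec` and cannot be mixed arbitrarily.

* **Distance correlation** (zeros imputation). Székely's statistic from
  doubly-centered pairwise-distance matrices; 0 when either distance
  variance vanishes. The all-pairs path computes the flattened centered
  distance matrices once per protein and obtains all pairwise distance
  covariances as a single Gram product; it is numerically identical to the
  scalar path (tested to 1e-10 against a loop-based oracle).
* **Weighted cross-correlation** (zeros imputation). Over lags `−L..L` with
  triangular weights `w_k = 1 − |k|/(L+1)`:
  `WCC = Σ w_k c_k(x,y) / sqrt(Σ w_k c_k(x,x) · Σ w_k c_k(y,y))`, where
  `c_k` is the raw cross-covariance of the mean-centered vectors. `L = 1` by
  default (one-fraction peak shifts are common in SEC data); the form
  reduces to the Pearson correlation at `L = 0`. The exact functional form
  used by prior CF-MS toolkits is not published; this triangular-weight form
  is this package's own, exposed as configuration. A vanishing denominator
  (constant chromatogram) yields 0 with a warning rather than an error.
* **Cosine similarity** (near-zero-noise imputation). Missing values are
  replaced by half-normal draws scaled to `σ · max(x)` with `σ = 1e-4`. The
  noise stream is keyed by (configuration seed, experiment, protein), so the
  feature is deterministic end-to-end for a fixed seed while remaining
  independent across proteins. Noise, rather than zeros, prevents shared
  missingness patterns from manufacturing similarity.
* **Mutual information** (pairwise-complete). Plug-in estimate in nats over
  a `B×B` equal-width joint histogram of the pairwise-complete positions
  (`B = 10` default; the estimator choice is this package's own). Fewer than
  `B` complete positions yields the missing-feature marker rather than an
  unstable estimate.
* **Pearson correlation** (pairwise-complete, ≥3 shared positions) is
  provided for evaluation uses (coexpression, colocalization), not as a
  classifier feature.

The feature tier rule assigns measures per experiment by corpus size:
`>10` experiments → distance correlation only; `6–10` → + weighted
cross-correlation; `≤5` → + cosine and mutual information, in descending
order of how well each measure separates labeled pairs in large-scale
benchmarks. The pair universe of a multi-experiment feature table is the
union over experiments; a pair absent from an experiment carries the
missing-feature marker there, and markers are zero-filled immediately before
model fitting (consistent with the zero-imputation semantics of the dominant
measures; median-fill is available behind a flag). A test asserts no marker
ever reaches the learner.

## Gold standard and cross-validation

Positives are intra-complex pairs; negatives are pairs of catalog proteins
never co-complexed; a pair positive anywhere is never negative. Catalogs are
deduplicated (identical member sets merged) and complexes below two members
dropped. For non-model species the catalog is projected through a strictly
one-to-one ortholog map (rows violating bidirectional injectivity are
dropped at read time); members without an ortholog vanish and complexes
shrinking below two members are dropped, with attrition counted.

Cross-validation folds are assigned at the complex level: complexes are
permuted into `k` folds (default 5) and a positive pair inherits the fold of
its lexicographically smallest source complex; negatives are spread
uniformly. This prevents two pairs from one complex straddling the
train/test boundary, the standard anti-leakage construction for
complex-derived labels. Training uses all labeled pairs (no class
rebalancing by default; a negative-subsampling ratio is available).

## Classifier, ranking, thresholding

Per fold, a 100-tree random forest (scikit-learn defaults otherwise,
recorded in the audit metadata) is trained on out-of-fold labeled pairs and
scores the pairs of its fold; unlabeled pairs are scored by the mean over
fold models (variance-reducing; the choice is this package's own). The
ranking is by descending score with ties broken by alphabetized pair order,
making the output invariant to input order. Cumulative precision is defined
over labeled pairs only and is undefined (NaN) before the first labeled
pair. `threshold_network` keeps the top `k` ranks where `k` is the deepest
rank whose cumulative precision meets the target (default 50%), returning an
empty network if it is never met; `threshold_topk` keeps a fixed count.

The *within-prefix precision* summary reported by the acceptance script is
the median cumulative precision over the labeled ranks inside the
thresholded prefix. At the threshold rank itself the cumulative precision
equals the target by construction (~0.5), so that point value carries no
information about ranking quality; the labeled-rank median is 1.0 for a
perfect ranking, ~0.5 for one that barely clears the threshold, and
summarizes how sharply true pairs concentrate at the top of the recovered
network.

## Augmentation and transfer

**Augmentation** addresses targets with few labeled pairs.
`floor(proportion × n)` external labeled pairs (default proportion 0.33,
`n` = labeled pairs present in the target feature table) are sampled without
replacement from an external pool; each external experiment is mapped
uniformly at random onto a target experiment column, and an injected pair's
row takes each column's value from the external experiments mapped to it
(seeded scan; measures the pool lacks stay missing and are zero-filled, with
fill counts audited). Injected rows carry namespaced identifiers, join every
fold's training set, and are never scored — the ranked list and its
precision are identical with and without augmentation.

**Transfer** trains entirely on external labels: every external labeled pair
is assigned a seeded tuple of `R` external experiments (matching the
target's replicate count; with-replacement fallback plus warning when fewer
experiments exist) supplying its feature vector, and the resulting forest
scores the target pairs. Because labeled pairs are typically too few in such
targets for a stable precision curve, evaluation uses the rank-based
(Mann–Whitney, midrank ties) AUROC over all scored labeled pairs.

## Network evaluation

Neighbor voting follows the guilt-by-association convention: for each term
(annotation sets of 10–100 proteins by default; no size filter for disease
gene sets), annotated proteins are split into three seeded folds; per fold
the members' labels are hidden and every network protein is scored by the
fraction of its neighbors annotated among the non-hidden; the AUC contrasts
hidden positives against proteins never annotated with the term, and the
term AUC is the fold mean. Proteins whose neighbors are all hidden score 0
(not missing), keeping the ROC well-defined. The exact rank-based AUC is
used rather than a trapezoidal approximation. Evidence-code filtering of GO
annotations is an input-preparation concern (a flag on the GMT consumer),
off by default.

Saturation analysis shuffles experiment order (10 seeded repeats), records
cumulative proteins detected in ≥1 fraction, and fits `count = a + b·ln(step)`
by least squares over all repeats for projection.

## Phosphosites

Site identity across experiments is (protein, position, residue).
`n_fractions` sums non-missing intensity cells over experiments;
aggregate-only quantifications (e.g. TMT) count as one experiment and zero
fractions. Prioritization keeps sites with `n_fractions ≥ 5` (inclusive) — a
deliberately simple heuristic; detection by CF-MS is not direct evidence of
function. Kinase-substrate enrichment uses the upper-tail hypergeometric
probability with population = background sites, successes = the kinase's
substrates in the background, draws = |foreground|; Benjamini–Hochberg
q-values are reported alongside raw p-values (the correction is this
package's addition). Stoichiometry chromatograms divide site by parent
intensity where both are quantified; the peak-assignment flag smooths the
parent with a 3-point moving average, takes local maxima with prominence
≥10% of the smoothed maximum (both configurable), and assigns the site to
the nearest parent peak by its own intensity maximum.

## Simulator

Each complex draws one co-elution center per experiment, uniform over the
interior fractions; members get Gaussian profiles with center jitter
(sd 0.75 fractions), width `2.5 ± 0.5` fractions, and log-normal amplitudes
(σ = 0.5 around 1e5). Monomers (50% of proteins by default) elute
independently. Multiplicative log-normal noise (σ = 0.3) is applied, then
missingness: values below the 0.6 quantile of the experiment's intensities
are unobserved (the detection-limit/abundance bias of CF-MS) plus 10%
uniform dropout. Defaults — 200 proteins, 20 complexes (geometric sizes
2–8, mean 4), 3 experiments × 50 fractions — were chosen once as a small but
realistic SEC-like regime in which proteins are detected in roughly 20 of 50
fractions and co-elution is clear but noisy. Phosphosite tables attach
Poisson-distributed sites per protein whose intensity tracks one parent peak
scaled by a per-site stoichiometry, with heavier missingness and a
configurable (pS, pT, pY) simplex.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: peptide-level identification and protein-group
ambiguity, correlated (batch) noise across proteins, asymmetric or tailing
peak shapes, partially assembled complexes and condition-specific membership,
incomplete/erroneous complex catalogs (truth and labels coincide exactly),
and cross-species divergence beyond namespace disjointness (external studies
share the generative process, so transfer results are a best case).

## Numerical conventions

Missing is NaN throughout and is distinct from zero. All randomness
(imputation noise, fold splits, forest seeds, augmentation sampling,
pseudo-replicate assignment, simulation) derives from a single root seed via
CRC-keyed child streams, so every pipeline output is bit-reproducible for a
fixed seed. Degenerate inputs prefer defined values over errors where a
convention exists (constant chromatograms → 0 for distance correlation and
WCC; empty edge-list union → Jaccard 0, logged) and errors where silence
would corrupt results (zero-norm cosine, all-missing near-zero-noise
imputation, single-class training folds, foreground not a subset of
background in enrichment).

## Problem sizes

Tests and the acceptance script run studies of 60–200 proteins, 8–20
complexes, 3 experiments of 50 fractions, and external pools of 30
experiments, with 10-seed medians for stochastic claims — sizes chosen so
the full pipeline exercises every code path while an entire run completes
in minutes on one CPU.
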