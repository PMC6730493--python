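# Methods

This note documents the models, conventions and numerical choices behind
`cytodx`, and what the synthetic-cohort experiments do and do not show.

## Problem setting

Common variable immunodeficiency (CVID) is a primary antibody deficiency
(PAD) diagnosed by exclusion. Flow-cytometric immunophenotyping measures
per-cell marker expression across several staining panels; traditionally
populations are gated by hand in nested 2-D plots and a clinician reasons
over population percentages. `cytodx` automates the full chain: event-level
preprocessing, self-organizing-map (SOM) gating, cluster-feature
extraction, age normalization against healthy controls (HC), optional
feature selection, and classification of each sample as CVID vs
non-CVID (or CVID / other PAD / HC), validated by leaving whole
acquisition days out.

## Preprocessing

**Compensation.** Spectral spillover is removed linearly:
`true = observed · S⁻¹` on the channels named in the spillover matrix
(`$SPILLOVER` keyword or a delimited sidecar). A singular matrix raises
with channel diagnostics.

**Logicle transform.** Fluorescence channels use the logicle
(inverse-biexponential) scale with parameters (T, M, W, A). The forward
biexponential is `S(y) = a·e^{by} − c·e^{−dy} + f` with coefficients
solved so `S(x1) = 0` and `S(1) = T`; the decay constant `d` solves
`2(ln d − ln b) + w(b + d) = 0` by Brent's method. The data → scale
direction is inverted by vectorized bisection on a bracket widened as
needed; `S` is strictly increasing (`S' > 0` everywhere), so bisection is
unconditionally convergent; 52 halvings resolve y far below the 1e−9
target. Parameters are estimated per channel as: T = instrument range
(`$PnR`, else observed max), M = 4.5 decades, A = 0, and
`W = max(0, (M − log10(T/|r|))/2)` with r the 5th percentile of the
channel's negative values, defaulting to W = 0.5 for channels without
negatives (the behavior of the widely used estimator this mirrors).
W is additionally capped at M/2, its admissible maximum.

**Output scale.** Transformed values are normalized to `y = decades /
(M + A)` so that intensity T maps to 1. Clustering is scale sensitive,
so one convention is fixed throughout. Scatter channels (FSC*/SSC*) are
not logicle-transformed; they are divided by their instrument range so
that all clustering inputs live on a comparable [0, 1] scale. Time
channels are never transformed.

**Quality control.** Three filters only ever clear the per-event keep
mask; values are never modified, and kept + removed always equals the
input count.

* Range filter: on untransformed data, any fluorescence value ≤ 0 or
  ≥ T marks the event unreliable.
* Time-anomaly filter: kept events are binned into `n_bins = 100`
  equal-width acquisition windows; a bin is flagged when its event count
  or any channel's median deviates from the across-bin median by more
  than `mad_factor = 5` times that statistic's median absolute
  deviation (MAD). When the MAD of a statistic is exactly 0 the
  statistic is perfectly flat and nothing is flagged on it — this keeps
  the null case (stationary run) clean instead of flagging numerical
  dust. This is a deliberately simple, self-contained stand-in for
  dedicated signal-QC packages; it detects rate bursts and level shifts
  but not gradual drifts or changepoint structure.
* Pregating: live-single selection is consumed as per-event labels
  (null/"debris"/"doublet"/"dead" are dropped; unknown categories pass
  through with a log message). Gating is not recomputed — upstream
  manual pregates are authoritative.

## SOM gating

**Training.** An online SOM on a fixed rectangular grid (default
10 × 10). The codebook is initialized from K distinct random events;
for `rlen = 10` shuffled passes each event pulls its best-matching unit
(nearest row, squared Euclidean; ties to the lowest node id) and all
nodes within the current neighborhood radius toward itself by
`α(t)·(x − w)`. α decays linearly 0.05 → 0.01 over all steps; the
radius decays linearly from the upper quartile of the grid-distance
distribution to 0 (bubble neighborhood). Training is bit-reproducible
for a fixed seed; the inner loop is compiled with numba.

**Aggregation.** Per panel, ceil(total_n / n_files) kept events are
drawn uniformly without replacement from each file and concatenated
with a 1-based source-file index channel. The default budget is
`min(3 000 000, 10 000 × n_files)` so that cohort-scale runs use the
full 3M-cell aggregate while desk-scale synthetic runs stay fast.

**Metaclustering.** Nodes are grouped into k metaclusters (k = 14 for
the PBMC panel, 18 for the B- and T-cell panels) by average-linkage
agglomerative clustering of the codebook rows on Euclidean distance,
cut at k. This deterministic mode is the default; a consensus mode (100
average-linkage runs on 90 % node subsamples, consensus matrix
re-clustered at k, seeded) is available behind a flag since reference
implementations favor consensus clustering. Labels are renumbered 1..k
by decreasing node count.

**Tree layout.** The minimum spanning tree of the complete Euclidean
graph over codebook rows, by Prim's algorithm on the dense distance
matrix (trivial at K = 100); equal weights break lexicographically.

**Mapping.** New samples are assigned by nearest codebook row; mapping
is a pure function of the events and the codebook, so event order only
permutes the output.

## Features and normalization

Per sample, five blocks: cluster percentages (K), metacluster
percentages (k), each cluster's share of its metacluster (K), and
median fluorescence intensities per cluster (K·m) and per metacluster
(k·m) — `K + k + K + K·m + k·m` features, e.g. 1,696 for
(K, k, m) = (100, 14, 13). Percentages are of kept events and sum to
100 within their block; empty clusters get zero-imputed MFIs so feature
vectors stay aligned across samples. Note the printed feature total for
the B-cell panel (1,162) matches this formula only with m = 8 although
that panel clusters 9 markers; the formula is kept and the discrepancy
recorded rather than resolved.

Age-linked immune variation is removed by z-scoring each feature
against healthy controls per age group (8 strata):
`z = (x − μ_age)/σ_age`, with μ, σ estimated from the HC samples of the
training partition only (sample SD, n − 1). Age groups with fewer than
two training HCs fall back to pooled all-HC statistics with a logged
warning. σ = 0 maps to z = 0 so constant features stay inert instead of
producing NaNs.

## Feature selection

Features are ranked by two-sided Wilcoxon rank-sum p-values (two
classes) or Kruskal–Wallis (three classes); exact enumeration is used
for tie-free groups of ≤ 10 samples, otherwise the midrank
approximation with tie-corrected variance. A feature constant across
all samples gets p = 1 by convention. The two smallest p-values are
always selected; remaining features join in p-order iff their absolute
Pearson correlation with every selected feature is below 0.2.
"Correlation lower than 0.2" is read as |r| < 0.2 — a strongly
anti-correlated feature is just as redundant. Constant features have
r defined as 0 and never block. Ties in p break by feature name, making
selection deterministic. Inside cross-validation both the ranking and
the correlations use training samples only.

## Classification and validation

Random forest (500 trees, default split criterion) and linear
soft-margin SVM (C = 1, one-vs-one for three classes), on the z-scored
features without further rescaling or class weighting. Balanced
accuracy — the mean of per-class recalls, `(TP/P + TN/N)/2` for two
classes and macro-averaged recall for three — is the headline metric
because CVID samples are heavily outnumbered. SVM feature importance is
the maximum absolute hyperplane coefficient across class pairs; random
forests use mean impurity decrease.

Validation is leave-one-experiment-day-out: per fold, the aggregate,
SOM, metaclustering, z-scoring and (optionally) selection are rebuilt
from the training days only, then every file is mapped and the held-out
day predicted. Folds whose training partition lacks a class are skipped
with a warning rather than imputed. All per-fold seeds derive
deterministically from (master seed, fold index). Balanced accuracy is
reported both per fold (mean ± SD) and pooled over all out-of-fold
predictions; the pooled figure is the headline number because single
days hold few samples, sometimes of one class only.

## Synthetic cohorts

**Model.** Each panel is a Gaussian mixture with diagonal covariance in
transformed marker space. The three default panels use the study's
marker lists (13/9/9 markers) with 10–12 populations each, placed at
canonical expression levels (negative ≈ 0.22, low 0.38, mid 0.55, high
0.75, very high 0.88 on the unit logicle scale; SD 0.05), so adjacent
populations are ≥ 4 population-SD apart on at least one marker. Per
sample, population frequencies are Dirichlet-distributed around class-
and age-adjusted baselines (concentration 500 — roughly the
sample-to-sample frequency variability of a stable population panel),
events are drawn from the mixture, and intensities are mapped to the
raw instrument scale through the inverse logicle (T = 262 144, W = 0.5;
scatter channels linearly), with a Time channel of unit-rate arrivals.

**Effects.** The default B-cell-panel disease effect mirrors the CVID
immunophenotype, which reshapes the whole memory/antibody-secreting
compartment rather than a single subset: switched-memory B cells of
both isotypes halved, plasmablasts and plasma cells halved, marginal-
zone-like B cells at 0.7×, CD21low B cells doubled, CD21⁻CD38⁺ and
transitional B cells expanded, together with expression shifts (CD27
and surface IgG/IgA −1 SD on switched-memory cells, IgM/IgD reduced on
MZ-like and naive cells, CD24 up on CD21low cells). Other-PAD samples
get intermediate multipliers. Two populations follow a monotone age
trend across the 8 age groups (e.g. naive B 1.25× → 0.8×), which the
HC z-scoring must absorb.

Two nuisance variance components complete the donor model. Every donor
carries idiosyncratic population-mean shifts, N(0, 0.01) per population
and marker in transformed units (~0.2 population-SD) — without this
inter-individual variability, median-intensity features would have
essentially zero between-sample variance and the healthy-control σ used
for z-scoring would degenerate to the batch SD. Each experiment day
adds a N(0, 0.005) offset per channel: day-to-day drift at half the
donor variability, the regime a bead-calibrated clinical cytometer is
maintained in, and small enough that a day-out-validated model can
generalize while naive same-day validation still benefits from shared
within-day structure. Acquisition days are assigned by stratified
accrual (each diagnosis group spread across all days, as in a
prospective cohort), so no training fold is drained of a class. A
"null" variant keeps age and batch effects but removes all diagnosis
effects.

**Manual baseline.** The generator's own mixture components double as
the "manual gating": per-event population labels, plus a per-sample
47-column table (population percentages padded with per-population
marker MFIs) reproducing the size and spirit of a hand-gated feature
baseline, not its exact columns.

**What the synthetic experiments show — and don't.** Default-effect
cohorts (60 samples over 6 days, 20 000 events per sample) run through
the full day-out protocol with the total feature set and a linear SVM
reach mean balanced accuracy ≥ 0.9 across master seeds, and null
cohorts stay at chance — i.e., the pipeline recovers a planted,
realistic-sized signal and does not hallucinate one. These cohorts are
idealized: unimodal symmetric populations, no spillover error, no
spectral overlap physics, no debris/doublets, no gradual acquisition
drift, and effect sizes that are known and homogeneous within class.
Passing here demonstrates correctness of the machinery, not clinical
performance on patient data, which varies with panel quality and cohort
composition. Problem sizes in the tests (2 000-event samples, 4×4–10×10
grids) were chosen as the smallest that leave each statistical check
well-powered.

## Known limitations

* The FCS layer writes float32 FCS 3.1 single-dataset files and reads
  FCS 3.0/3.1 with linear amplification only ($PnE = 0,0); legacy
  log-amplified or multi-dataset files are out of scope.
* The time-anomaly filter is a robust rate/level screen, not a
  changepoint detector.
* The online-SOM quantization error is not strictly monotone across
  passes (stochastic updates); it is monotone up to a small tolerance
  once converged, and tested as such.
* The F1 matching between manual populations and metaclusters (greedy,
  one metacluster per population, event-weighted aggregate) is one of
  several defensible conventions; a pooled (micro) aggregate is also
  provided.
* `fcluster(..., criterion="maxclust")` can return fewer than k groups
  on degenerate codebooks with many exactly tied merge heights; with
  continuous data this does not occur.
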