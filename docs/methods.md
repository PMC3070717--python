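# Methods

This note documents the statistical model behind `xplatde`, the choices
made where the design was genuinely open, and what the synthetic studies
do and do not establish about real data.

## Preprocessing model (single-channel raw spots)

Each array provides per spot a signal `S`, a local background `B_L`, the
SD of the local background `σ_BL`, and one global background median
`B_G` per array.

* **Flagging.** A spot is flagged `low_signal` when `S < B_L + k·σ_BL`.
  The multiplier `k` is the conventional CodeLink threshold-flag rule;
  we default to `k = 1.5` and expose it (`PreprocessConfig.k_sigma`)
  because scanner-software conventions differ and the exact constant
  matters near the detection limit.
* **Background correction.** The default reading subtracts the array-wide
  offset between local and global background from every signal:
  `S' = max(floor, S − (median(B_L) − B_G))`. An alternative reading —
  subtracting each spot's own `B_L` — is available via
  `background_mode="local"`. Both are monotone in `S`; the positive
  `floor` (default 1.0) keeps downstream logs finite.
* **Intensity cutoff.** Spots with corrected signal below
  `cutoff_fold × median(B_L)` (default fold 2) are flagged
  `below_cutoff`. A spot exactly at the threshold is **retained**; the
  boundary had to be fixed one way for determinism and we read
  "at least twice the background" inclusively. The design is
  single-channel (one Cy5-like intensity), so "any channel" collapses to
  that one value.
* **Normalization and ratios.** Each array is divided by the median of
  its analyzable (unflagged) spots, making that median exactly 1.
  Expression is then `log2(x / mean of control arrays)` per gene; the
  control mean is arithmetic on the intensity scale. Entries with masked
  or non-positive operands stay masked. Multiple probes per Gene ID are
  collapsed by the **median** log-ratio after ratio computation —
  robust, order-independent, and insensitive to a single bad probe.

The stage order flag → correct → cutoff → normalize → ratios is fixed;
scale tags (`intensity` vs `log2ratio`) prevent re-running a stage on
already-processed data.

## Harmonization

Platforms are joined on NCBI Gene IDs; only genes measured on **every**
platform (the common gene list, sorted ascending) are analyzed. All
samples — controls included, each expressed as a log2 ratio against its
own platform's control mean — are then quantile cross-normalized: every
column is replaced by the mean-of-sorted-columns reference mapped back
through its ranks. Normalizing on the log2-ratio scale (rather than raw
intensities) was an open choice; ratios already cancel per-platform
location effects, so the quantile step only has to reconcile scale and
tail shape. Ties receive the mean of the reference values over the tied
rank span; columns with masked entries are mapped through interpolated
quantiles, so the identical-sorted-multiset guarantee is exact only for
complete columns. The operation is idempotent (to 1e-9) in the absence
of ties and preserves within-sample rank order exactly.

## Differential expression

* **Group contrasts** use the pooled-variance two-sample *t* (df
  `nA+nB−2`), the era-typical default for microarray work; Welch's
  correction is a flag, not hidden. Direction is the sign of
  (group mean − control mean). Zero pooled variance with equal means
  yields `t=0, p=1` by convention; with unequal means the gene is
  flagged in-band as `t=±inf, p=0` rather than raising, so vectorized
  call tables stay usable.
* **Intra-experimental z**: within one sample's column, each gene is
  standardized against the mean and SD over genes (`z = (x−μ_s)/σ_s`).
  The alternative reading — standardizing against control replicate
  variance — is not what the within-experiment description supports, so
  the across-genes reading is implemented.
* **Inter-experimental z**: within one gene's row, each sample is
  standardized against the gene's mean and SD across samples. A constant
  row is "inter-unchanged" (`z=0, p=1` everywhere).
* The sample SD uses the n−1 denominator everywhere. Significance is
  strict (`p < α`, default α = 0.05), two-tailed from the Student/normal
  distribution as appropriate. "Unchanged" in a mode means `p ≥ α` in
  every unit of that mode, the definition the combined intra/inter case
  logic requires.
* **FDR** is Storey's: `π0(λ) = #{p>λ}/(m(1−λ))` with fixed λ = 0.5
  (no bootstrap λ selection — the simplest faithful estimator),
  `π0` clamped to `(1/m, 1]`, and the step-down rule
  `q(p_(i)) = min_{j≥i} π0·m·p_(j)/j` clamped to `[p, 1]`. q-values are
  computed **per comparison family** (one run per sample or per
  contrast), matching per-group FDR reporting.

## Commonality rules

All rules are pure set algebra over call tables and are invariant to row
order and unit relabeling. A gene unmeasured in some unit counts as
not-DE for intersections and is listed separately in the report's
provenance, keeping "simultaneously in all units" strict but
transparent. The final cross-platform report is the intersection over
platforms of per-platform directional calls on the harmonized matrix
(each platform's tumors against the pooled controls). This follows the
two-stage design the pipeline targets — per-platform evidence first,
then intersection — and, unlike requiring per-sample significance in
all ~129 tumors simultaneously, it has non-trivial power at moderate
effect sizes: a per-sample z of ~2 (a 2-noise-SD effect) passes any one
sample only about half the time, so a 129-fold simultaneity rule
retains essentially nothing; the per-sample rules remain available for
the large-effect regime they suit.

## Structure and annotation

Hierarchical clustering is UPGMA on Euclidean distances
(`scipy.cluster.hierarchy`; its deterministic tie ordering is the tie
rule). k-means uses k-means++ with an explicit seed and best-of-10
restarts; the published cluster counts (49, 81, 100, 24) are presets,
not derived. PCA is the centered full SVD; variance fractions sum to 1.
Masked entries are mean-imputed per gene **only** for distance-based
methods (clustering, PCA, correlation maps), never for statistics.
Chromosome summaries use plain membership labels (1–22, X, Y, MT) with
no coordinates. Over-representation is the inclusive upper tail
`P[X ≥ k]` of the hypergeometric distribution (over-representation
only, matching the class of tools this analysis style uses); terms with
fewer than two genes inside the universe are skipped; the universe
defaults to the common gene list.

## Synthetic studies: what they emulate

The generator's defaults are the study conditions: three platforms
(5+10, 9+60, 3+59 control+tumor arrays; 17 controls and 129 tumors in
total), 11 tumor stage/grade groups assigned cyclically, a 2000-gene
universe with log-normal baseline (log2 mean 8, SD 1), platform
location/scale effects, log2 noise SD 0.5, and planted truth: 30 genes
up- and 80 down-regulated in every tumor by 1.0 log2 units (= 2 noise
SDs), plus 5 group-specific genes per group. Platform probe subsets
(95%, 90%, 90% of the universe) are drawn without replacement so the
common gene list is a strict subset of the universe; planted genes are
always retained on every platform — otherwise recovery against ground
truth would be bounded by the product of subset fractions rather than
by statistical power, and the benchmark would measure probe content,
not the method. One seed-sequence tree per configuration gives
byte-identical regeneration and keeps the annotation/term generator
consistent with the expression generator.

What passing these benchmarks does **not** show: real cross-platform
data have probe-sequence-specific biases, intensity-dependent variance,
correlated genes and batch structure that the independent log-normal
noise model lacks; quantile normalization removes distributional but not
covariance-level platform effects. Recovery rates on the synthetic
design are therefore an upper bound on what the same pipeline achieves
on real pooled series.

## Problem sizes and numerics

Tests and the acceptance script run the full design (2000 genes ×
146 samples × 3 platforms), which completes in seconds; oracle-
equivalence checks use 50×10 instances where brute force is exact.
Normalization invariants are asserted to 1e-12 (global median) and 1e-9
(quantile); statistic oracles to 1e-12; hypergeometric tails against
rational enumeration for universes ≤ 15. Ties in quantile normalization
break idempotence by construction (the tie-averaged values re-enter the
reference); this is inherent to the tie convention and is documented
rather than patched. All outputs are written with `%.17g` so float
round trips are exact and runs are byte-reproducible.

## Known limitations

* The raw-spot layer models background channels phenomenologically
  (normal backgrounds, planted sub-threshold fraction); it validates the
  filtering logic, not scanner physics.
* No batch-effect regression beyond quantile normalization, no
  moderated-variance statistics, no permutation nulls, no meta-analytic
  effect pooling — commonality is by set intersection only, by design.
* GO/pathway handling is flat (no DAG topology); motif tables are
  consumed, never computed from promoter sequence.
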