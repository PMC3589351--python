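# Methods

## The directional-consistency model

For one modality (expression, methylation or copy number) and one cancer
type, two independent cancer-vs-normal cohorts each yield a set of
differential genes with a direction. Let `N` be the number of genes in the
comparison set and `m` the number whose directions agree. Under the null
that each gene's pair of directions matches by chance with probability
`P_r = 0.5`, the significance of at least `m` agreements is the upper
binomial tail `p = Σ_{k=m}^{N} C(N,k) P_r^k (1−P_r)^{N−k}`.

The tail is evaluated exactly at `P_r = 0.5` with Python big integers
(`Σ C(N,k) / 2^N` as a rational number) and in log space
(`gammaln` + `logsumexp`) for other `P_r`. Exactness matters because the
regime of interest — thousands of agreeing genes — puts the tail at
10⁻¹⁰⁰⁰ and below, far outside double precision; every report therefore
carries an exact `log10_p_value` next to the (possibly underflowed) float.
The big-integer log10 is computed by bit-shifting the integer into float
range, which is exact to well below the 1e-12 comparison tolerance used in
tests.

Comparison-set variants:

- **shared** — genes called in both cohorts; agreement = same direction.
  This is the headline rate (`m/N`, reported as a percentage with `N` in
  parentheses).
- **union** — genes called in at least one cohort. A gene called in only
  one cohort is consistent iff its direction matches the sign of its
  (possibly non-significant) effect in the other cohort. A zero effect in
  the reference cohort counts as *inconsistent* — the conservative
  resolution of an undefined sign.
- **marginal** — calls from one cohort restricted to genes with two-sided
  p < 0.1 (configurable) in the other; the marginal p is a Welch t-test on
  the reference cohort, chosen over the pooled test because the reference
  cohort's variances are not part of the calling model.
- **third_dataset** — calls unique to one cohort scored against calls in
  an independent third cohort.

Downstream analyses use the **merged** list: the union of both cohorts'
calls minus genes called in both with opposite directions. Reports with
`N = 0` carry no p-value (they are flagged empty) rather than a vacuous
p = 1.

## Differential callers

**Expression (SAM-style).** Per gene, `d = (x̄₁ − x̄₂)/(s + s₀)` with `s`
the pooled standard error `sqrt((1/n₁ + 1/n₂)(SS₁ + SS₂)/(n₁ + n₂ − 2))`.
With `s₀ = 0` and any group sizes, `d` is exactly the pooled-variance
two-sample t statistic; `s₀ > 0` damps low-variance genes. The default
`s₀` search evaluates candidates at every 5th percentile of the `s`
distribution and picks the one minimizing the coefficient of variation,
across ten `s`-quantile bins, of the within-bin median absolute deviation
of `d`; when the surface is flat (one variance class) it falls back to
`median(s)`. The null is built from group-label permutations (all distinct
relabelings when fewer than requested, otherwise seed-controlled balanced
draws). At a threshold on `|d|` — up and down thresholded jointly — the
estimated FDR is `median(null count)/observed count`, with the true-null
proportion fixed at 1 (conservative; no π₀ estimator is assumed). Per-gene
q-values are the running minimum of estimated FDR from the most extreme
gene outward, which makes the call set monotone in the target: lowering
the FDR target can only remove genes. Genes with `s + s₀ = 0` are
degenerate and excluded from calling rather than assigned an arbitrary
direction.

**Methylation.** Probe beta-values `β = M/(U + M + 100)`; the +100
regularizer bounds β strictly below 1 and stabilizes low-intensity probes.
Probes are aggregated to genes by mean beta (mirroring mean-intensity
probe aggregation on the expression side), then tested gene-level by a
pooled-variance Student's t (Welch available as a flag) with
Benjamini–Hochberg adjustment (statsmodels). Direction +1 means
hypermethylated in cancer. Genes with zero variance in both groups have an
undefined statistic and are excluded with a warning. Probe-level testing
before gene mapping would be a defensible alternative; gene-level testing
after aggregation is the documented choice here.

**Copy number.** Marker-level G-scores: for amplification,
`f` = fraction of samples with log2 ratio above a noise threshold
(default 0.1, the conventional array noise floor; configurable),
`ā` = mean ratio over those samples, `G = f·ā`; deletions are scored on
the negated matrix, so the two analyses are exact mirrors. The null
permutes marker values *within each sample*, preserving each sample's
amplitude distribution while destroying marker identity, and pools null
scores across markers and permutations for resolution; observed markers
get add-one-corrected empirical p-values, BH q-values, and maximal
contiguous runs of significant markers become regions. A gene overlapping
both an amplification and a deletion region in one dataset is ambiguous
and excluded from direction events (with a logged count). This is a
deliberate simplification of full GISTIC — no segmentation of raw arrays,
no arm-level peel-off, no focal/broad distinction — adequate for
direction-of-change analysis, not for precise peak localization.

## Candidate-gene analysis

An **event** is one catalogued candidate gene (oncogene or TSG for a
specific cancer type) appearing in the merged consistent-direction list of
its own cancer type, for one modality; distinct genes count once per
(cancer, modality). The direction-bias test of a gene class is the same
binomial upper tail applied to favored-direction events out of total
events at 0.5. Stability TSGs (genome-integrity genes: DNA repair,
cell-cycle checkpoint, DNA-damage response) are flagged from an externally
supplied annotation table and analyzed separately from other TSGs, since
their loss acts through instability and their wild-type copies tend to
respond to it. "Average frequency" over cancer types is ambiguous between
pooling events and averaging per-cancer rates; both are computed and
reported side by side, with the pooled value as the headline. Background
frequencies — the direction rates of *all* merged differential genes per
cancer and modality — are attached so a candidate class can be compared
with what any differential gene would show.

## Mutation-stratified testing

Cancer samples are stratified by a gene's annotated mutation class
(activating, inactivating, undetermined, wild-type; unannotated samples
are excluded, never defaulted) and each stratum is tested against the
normal controls with a two-tailed two-sample t-test (pooled by default,
matching the plain t-test convention; Welch as a flag). Strata with fewer
than two samples are reported untested. No multiple-testing correction is
applied across the handful of strata; the raw p-values are reported and
the choice is noted in the output. A *reversal* flags two strata
significant in opposite directions at a configurable α — the signature of
a mutant deregulated unlike its wild-type counterpart. When no sample is
mutated, the wild-type stratum test reduces exactly to the plain
cancer-vs-normal comparison.

## Synthetic data: what it emulates and what it does not

The generators produce the statistical structure the analysis assumes, not
realistic microarrays. Expression: per-gene baselines `N(8, 2²)` on the
log2 scale, i.i.d. Gaussian noise (default sd 0.5 log2 units, a typical
between-sample spread), a planted fraction of differential genes (default
10%) shifted by ±effect size (default 1.0; the examples use 1.5 for a
clearly powered design), and a per-gene probability (default 0.95) that
the planted sign agrees between the two cohorts — flips are independent
per gene, exactly the binomial null's alternative. Methylation: the same
design on the beta scale (base beta uniform 0.15–0.85, shifts like ±0.2,
noise sd 0.05), converted to U/M intensities around a fixed total of 2000
so that `M/(U+M+100)` reproduces the betas; betas clip at the attainable
range, so shifts planted near the boundary are attenuated by design.
Copy number: marker noise sd 0.1 (typical SNP-array log2-ratio noise),
planted contiguous segments of ~25 markers covering `frac_de` of the
genome, each carried by 40% of samples (default) at ±0.8 — which makes
the expected marker G-score `0.4 × 0.8 = 0.32` plus a small background
exceedance term. Mutations: per candidate gene and cancer sample, mutated
with the catalog's rate, class uniform over
activating/inactivating/undetermined, with class-specific expression
shifts (defaults +2/−2/0 log2; wild-type configurable).

Truth tables (planted gene → direction per cohort, sample → mutation
class, segment coordinates) are emitted alongside the data, and recovery
tests always compare against them rather than re-inferring truth. What the
generators deliberately omit: probe-level artifacts, batch and platform
effects, correlated genes, realistic genome coordinates, copy-number
segmentation noise. Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated under its own model —
not that real cohorts of a given size would achieve any particular
agreement rate.

## Numerical and design choices

- All randomness flows from `numpy.random.default_rng` seeds; pipeline
  stages derive seeds as `SeedSequence([root, crc32(stage path)])`, so
  adding a stage never perturbs another stage's stream and runs are
  byte-identical at fixed config+seed.
- Fractional planted counts round to the nearest integer; a spec with
  `frac_de > 0` but fewer than one plantable gene is rejected rather than
  silently null.
- Problem sizes in the test suite (≈500–2000 genes, 15–40 samples per
  group, 50–150 permutations, 20 null replicates for FDR calibration) are
  chosen so the full statistical battery — permutation FDR, null
  calibration, recovery, end-to-end reproducibility — runs comfortably on
  one CPU core while keeping every binomial comparison in its
  well-powered regime.
- Exact reference tails asserted in tests: `p(23,23) = 2⁻²³ ≈ 1.19×10⁻⁷`,
  `p(27,14) = 0.5` (odd-N symmetry), `p(20,15) = 21700/2²⁰`, and
  brute-force enumeration over all `2^N` agreement patterns for every
  `N ≤ 20`.

## Known limitations

- The SAM caller implements symmetric |d| thresholding only (no
  asymmetric Δ, paired designs or multi-class variants) and fixes π₀ = 1,
  which is conservative when many genes are differential.
- The CNA null assumes exchangeable markers within a sample; long-range
  waves or arm-level biases would inflate significance and are not
  modeled.
- Gene-level methylation aggregation discards probe heterogeneity within
  a gene (e.g. island vs shore probes).
- The union-variant direction rule for singly-called genes (score against
  the other cohort's raw effect sign) is one reasonable reading of that
  comparison; rank-based or effect-pooled alternatives are out of scope.
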