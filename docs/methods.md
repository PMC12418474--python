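# Methods

## The model

For each protein assayed in matched serum and plasma aliquots of the same
subjects, `npxfactor` fits the simple linear regression of plasma NPX on
serum NPX over complete pairs (pairs with either side missing are excluded
protein-wise). The slope is the candidate transformation factor; the
intercept absorbs cohort-specific offsets and is stored for provenance but
never used for conversion, so applying a factor is the single multiplication
`plasma_hat = slope * serum_NPX`. Because NPX is a log2-scale unit, this
multiplication corresponds to a power-law relation between the two media's
linear-scale concentrations; no linear-scale mode is offered, deliberately.

Regression orientation is a genuine choice — the relation could equally be
fitted serum-on-plasma. We fix plasma as the response so the catalogued
slope converts serum into plasma-equivalent NPX, the direction in which
pooled analyses usually need to move (plasma panels dominate). The inverse
conversion divides by the slope; `TransformationFactor.direction` records
which way a catalog points.

### Tiered fitting and Cook's distance

A protein is *modelable* when some tier's fit reaches R² ≥ 0.5:

* **Tier 1**: all n complete pairs;
* **Tier 2**: remove the ⌈0.10 n⌉ samples with the largest Cook's
  distances under the Tier-1 fit, refit;
* **Tier 3**: remove the top ⌈0.15 n⌉ (a superset of Tier 2's), refit.

At n = 19 the removals are 2 and 3 samples. Removal counts default to
fractions of n so the scheme scales to other cohort sizes; a fixed-count
mode ({0, 2, 3}) is available. Cook's distance is computed from the closed
form `D_i = e_i² h_ii / (2 s² (1−h_ii)²)` (2 estimated parameters,
`s² = SSE/(n−2)`), which the test suite verifies against the brute-force
leave-one-out definition to 1 × 10⁻¹⁰ relative. Ranking all removals on
the *Tier-1* distances makes the scheme deterministic and the Tier-3
removal set a superset of Tier-2's; a re-rank-per-tier variant
(`TierScheme(rerank_per_tier=True)`) recomputes distances on the Tier-2 fit
for the additional Tier-3 removal. Ties in the ranking break by subject
order, deterministically. A protein that fails all three tiers is reported
with its Tier-1 fit and `tier=None`.

The Pearson screen (signed r ≥ 0.5 over complete pairs) is descriptive
only — every protein enters tiered fitting regardless — because the R²
threshold, not the screen, defines modelability. The threshold is on signed
r: a strongly anti-correlated protein is not a candidate for a positive
scaling factor.

### Confidence gate

The precision of an accepted slope is summarised by the half-width of its
95% t-interval, `t(1−α/2, n_used−2) · SE(slope)` with α = 0.05. Only
modelable fits with half-width ≤ 0.3 (inclusive) enter a factor catalog.
The 0.3 bound is motivated by the sensitivity analysis below: group
comparisons on rescaled data remain largely intact while the applied factor
is within ±0.3–0.4 of truth, and degrade quickly beyond.

### DEA sensitivity sweep

To quantify how factor error propagates into scientific conclusions, a
two-group differential expression analysis is run on an NPX matrix, the
matrix is rescaled by each factor in {0.6, …, 1.4} (step 0.1), the analysis
re-run, and each protein classified: **TP** (significant in both runs, same
direction), **FP** (significant only after rescaling, or direction
flipped), **FN** (original finding lost; a direction flip counts as both FP
and FN, so TP + FN always equals the original significant count and
retention = TP/(TP+FN) is well defined). The test statistic is Welch's
two-sample t with Benjamini–Hochberg adjustment across scored proteins
(a rank-sum variant is selectable); significance is the compound rule
adjusted p ≤ 0.05 **and** |group mean difference| ≥ 1 NPX (NPX is log2, so
1 NPX is a two-fold change). Both thresholds are inclusive. Note that
rescaling a protein multiplies its mean difference but leaves its t
statistic — and hence its p-value — unchanged; under this test the sweep
moves findings across the *effect* gate only. A test whose statistic is not
scale-invariant would also move p-values; the pluggable test seam exists
for that reason.

### Cross-cohort validation and final selection

Catalogued proteins are refitted (same tier scheme) in an independent
matched cohort; proteins the cohort does not measure are reported
untestable. A factor is *concordant* when both cohorts call the protein
modelable and |Δslope| ≤ 0.3 (inclusive; the tolerance deliberately reuses
the gate magnitude). Proteins modelable in only one cohort are annotated
with per-medium variances — loss of modelability in a more homogeneous
cohort is typically a low-variance effect — but no automatic variance
cutoff is applied. The accepted-tier slope of each cohort is compared
(not the Tier-1 slope). When several cohorts model a protein, the final
catalog keeps the factor from the highest-R² model, ties falling to the
larger cohort and then to the earlier-listed one.

## Synthetic data: what it emulates, what it does not

The generator mirrors the structure of a small matched pediatric cohort:
19 subjects by default, 200 proteins, true slopes uniform on [0.6, 1.3]
(the range where most real cross-medium slopes concentrate), serum means
uniform on [2, 10] NPX, per-protein serum SD uniform on [0.5, 1.5] with a
15% near-zero-variance stratum (SD 0.02–0.10), zero intercepts, Gaussian
residuals on the NPX scale. The residual SD defaults to
`max(slope·serum_sd/2, 0.2)`: the proportional term gives a typical
modelable protein an expected R² near 0.8, and the 0.2 NPX floor models
technical assay noise that does not shrink with biological variance — it is
exactly this floor that makes the low-variance stratum non-modelable, as in
real panels. 10% of proteins receive two +8 NPX plasma-side outlier
samples (gross handling artefacts); outliers are planted in the response
because that is what Cook's distance on a plasma-on-serum regression
detects (a serum-side leverage-outlier mode is a config switch away). The
two-group generator spikes 30 of 200 proteins at ±1.2 NPX against a
within-group SD of 0.3 at 20 subjects per group.

Not emulated: Olink plate/batch effects, LOD censoring, panel bridging,
correlated proteins, non-Gaussian heavy tails. Passing tests therefore
demonstrate the pipeline's statistical correctness under a clean linear
data-generating process, not robustness to those artefacts; on real data
the modelable fraction and concordance will be lower.

Because every spiked effect in the two-group study has the same magnitude
(±1.2 NPX), the sweep's retention curve is step-like: all findings survive
until the rescaled effect crosses the 1-NPX gate (at factor ≈ 0.83 in the
negative direction) and then all are lost at once. Real cohorts, with a
continuum of effect sizes, show the gradual retention decay instead; the
step is the correct behaviour under the simulated conditions, not an
artefact.

## Numerical choices and edge cases

* OLS via `scipy.stats.linregress` plus closed-form leverages; slope SE is
  `s/√Sxx`. Constant serum (zero predictor variance) raises a degenerate-
  fit error inside the fitter and yields a flagged non-modelable call from
  `tiered_fit`; constant plasma returns slope 0, R² 0, flagged.
* Leverage 1 (only possible in pathological two-point clusters) maps to an
  infinite Cook's distance rather than NaN.
* All boundary comparisons (R² ≥ 0.5, r ≥ 0.5, half-width ≤ 0.3,
  |Δslope| ≤ 0.3, adjusted p ≤ 0.05, |effect| ≥ 1) are inclusive.
* Histogram bins for slope summaries are left-closed/right-open with a
  both-closed final bin; the conventional [0.75, 1] interval count uses
  closed bounds at both ends (`count_in_interval`).
* Factor tables serialise floats at 10 significant digits; write→read is
  value-identical at that precision.
* Identical input and scheme produce bit-identical fit collections; the
  generators are `numpy.random.default_rng`-seeded and bit-reproducible.

## Known limitations

* **Cook's-distance masking.** Two outliers displaced in the same
  direction tilt the Tier-1 fit toward themselves; occasionally a clean
  high-leverage sample then outranks the second outlier in the Tier-1
  ranking, so Tier-2 removal misses it and the protein is rescued only at
  Tier 3 (whose larger removal set catches both). Under the default
  generator this affects roughly 5% of outlier-carrying proteins. The
  re-rank-per-tier mode mitigates but does not eliminate it.
* A Tier-1 fit can reach R² ≥ 0.5 *because of* aligned outliers and accept
  a biased slope; the scheme has no goodness-of-fit check beyond R².
* The CI gate presumes approximately Gaussian residuals; heavy-tailed noise
  widens true uncertainty beyond the t-interval.
* Retention/FP statistics depend on the chosen DEA test; only Welch-t and
  rank-sum are provided, no moderated-variance (limma-style) test.
* Acceptance and test problem sizes (200–2000 proteins, 19–40 subjects,
  200 Cook's instances) were chosen as the smallest sizes at which the
  checked proportions are statistically stable.
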