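# Methods

This note documents the models, defaults and design choices behind
`crisprgi`, in the spirit of a statistical-methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pooled-growth model and fitness estimation

Strains grow in serial batch culture: each cycle the pool grows to
saturation and is diluted 1:D, so a cycle spans G = log₂ D generations
(G = 2 for 1:4 every 24 h, G = 3 for 1:8 every 48 h). If strain *i* has
relative fitness w_i per generation, its pool frequency obeys

    ln f_i(g) = const + g·ln w_i − ln Z(g),

with Z(g) the pool normalizer. We estimate ln w_i as the OLS slope of
ln(f_i/f_ctrl) on generations, where f_ctrl is the **summed** frequency of
the no-knockdown control strains (true w = 1 by construction). Dividing by
the control trajectory cancels Z exactly, so on noiseless data the estimator
is exact for any subset of timepoints — the basis of the noiseless recovery
test, which demands agreement with truth to ≥6 decimals. Fitness is thereby
anchored at wildtype = 1, which the multiplicative GI expectation requires.

Measurability: a timepoint is used for a strain only if its (corrected)
count is ≥ `min_count` (default 10 reads); a strain needs a passing t0 and
≥2 usable timepoints, and a replicate-mean is reported only when all
required replicates (default 3) are measurable. The exact count floor in the
original assays lives in unavailable supplementary material; here it is an
explicit parameter, not a claim.

## Chimera model

Each read is chimeric with probability ρ; a chimera draws its guide and
barcode independently from the marginal template frequencies (uniform
junction model — the standard model for template-switching artifacts).
Absent combinations then receive expected count ρ·N·p_g·p_b, giving the
pooled estimator

    ρ̂ = Σ_absent n_gb / (N · Σ_absent p_g·p_b),  clipped to [0, 1].

Correction subtracts ρ̂·N·p_g·p_b from every combination, clamped at zero,
recomputing marginals from the corrected counts and repeating (default 2
iterations — marginals are themselves contaminated, and two passes suffice
for ρ ≤ 0.1). Corrected counts are real-valued and never exceed the raw
counts; with ρ̂ = 0 the operation is the identity. The exact correction used
by the original pipeline is in supplementary material citing prior work; the
marginal-product model here is this package's stated reconstruction and is
the same model the generator uses, which is what makes the ±0.01 recovery
test well-posed.

## GI scores

For each query guide and condition, observed double-mutant fitness w_ab is
regressed (OLS) on the starting-guide single fitness w_a over all double
mutants of that query (minimum 30 points by default; degenerate or sparse
fits fall back to the multiplicative expectation with a warning). The
residual is the GI score. Suppressor-like queries are listed manually
(mirroring the judgment call such data demand); a lack-of-fit diagnostic
(R², slope sign) only warns. z-scores divide by the SD (ddof = 1) of all
scores pooled over all pairs and conditions; the center is 0 by default
since linear residuals are centered by construction (`center="mean"` is
available — whether the original analysis centered on the global mean is not
stated, and with residual-dominated scores the two differ negligibly).
Whether σ_global should exclude suppressor-query records is likewise
unstated; we include them.

Condition specificity requires a z in **all** conditions under
consideration; the rule (|z| > 2 in exactly one, |z| < 1 in each other) is
implemented vectorized and verified against a literal transcription on the
full 7⁵ grid {0, ±0.9, ±1.1, ±2.1}⁵. Gene pairs aggregate the z values of
≥3 replicate guide combinations with a Student-t 95% CI (n is 3–10, so a
normal CI would be anti-conservative); significance means the CI lies
entirely outside ±1.

## Profiles, classification, networks

Profile similarity is Spearman's ρ on pairwise-complete entries (midranks
for ties; pandas' `corr(method="spearman", min_periods=...)`, matching R's
`cor(use="pairwise.complete.obs")`), requiring ≥3 shared entries. ROC curves
sweep ρ thresholds −1…1 in steps of 0.05, counting a pair as called when
ρ ≥ θ (deterministic tie handling); AUC integrates TPR over FPR by the
trapezoid rule traversed in threshold order, which equals the
ties-at-half rank statistic whenever the grid resolves the distinct values.
Precision–recall AUC integrates defined points only (no calls → undefined
precision). The negative class for same-gene classification is **all**
non-same-gene pairs, including same-bioprocess pairs: the task is same-gene
prediction, and same-bioprocess similarity is reported descriptively.
Permutation nulls shuffle each (query, condition) column independently,
preserving column score distributions while destroying row structure.
Condition subsets are enumerated exhaustively; measurement subsets are
random with 8 replicate draws per size by default.

Profile networks drop guides with >25% missing entries first (whether the
original rule applied before or after thresholding is unstated;
filter-first is the default here), then choose the smallest θ on a 0.01
grid (the original selection granularity is unstated) such that strictly
fewer than `max_fpr` (default 0.5%) of different-target pairs pass. The
degenerate request `max_fpr ≥ 1` returns the grid minimum. The achieved
rate is recorded on the graph. Layout is out of scope; graphs export to
GraphML/TSV.

## GFP knockdown

The baseline is a tricube-weighted local-linear (loess) regression of
fluorescence on forward scatter fit to the uninduced sample
(`statsmodels` lowess; span default 0.75 — the original span is unstated and
exposed as a parameter), with linear extrapolation beyond the observed FSC
range. Knockdown is the t-test on induced vs uninduced residuals
(equal-variance Student by default, Welch optional — which was used
originally is unstated). Events come from TSV/DataFrames; FCS parsing is
deliberately out of core.

## Synthetic data generator

The generator emulates the study conditions: five growth conditions (one on
the 1:8/48 h scheme), triplicate cultures, three timepoints after t0, one
shared physical pool with lognormal abundance spread (σ = 0.65, chosen to
reproduce a ≈2.4-fold Q3/Q1 coverage spread), growth by w^G per cycle, a
multinomial bottleneck of 10⁷ cells at each dilution, multinomial read
sampling (default 100 reads/strain), and chimeras at a tunable per-read
rate drawn from marginal frequencies (so absent combinations receive reads).
Ground truth composes double fitness as w_ab = (β₀ + β₁·w_a)(1 + ε): the
per-query line models the positive bias from the multiplicative expectation
and is exactly the scoring model, making recovery tests well-posed; ε is the
true GI on the fitness scale, nonzero for a `gi_density` fraction of
(guide, query, condition) triples with magnitude U(0.15, 0.35) and random
sign. Non-suppressor query lines pass through (1, w_q), so a nontargeting
starting partner recovers the query single fitness; β₀ ~ U(0.02, 0.12).
Suppressor queries draw β₀ ~ U(0.35, 0.45), β₁ ~ U(0.5, 0.7), pulling
baselines toward wildtype. Single fitness defaults: targeting starting
guides U(0.5, 1.1), targeting queries U(0.5, 1.0) (partial CRISPRi
knockdowns with mostly moderate defects), nontargeting exactly 1.

What the generator does **not** model: PCR amplification bias, sequence
errors beyond chimeras, de novo suppressor mutations, lag phases,
frequency-dependent fitness, or gene-level (as opposed to guide-level)
interaction sharing. Passing tests therefore demonstrate correctness of the
estimators under the stated statistical model, not robustness to every
artifact of real screens.

## Problem sizes and numerical choices

The validation suite runs a ~1,000-strain pool for fitness recovery, a
~3,600-strain pool (700 targeting guides × 4 targeting queries, 5
conditions × 3 replicates at 10⁶ reads/sample) for null calibration of the
z-scores (>13,000 scored pairs), 20 seeds × 3 rates for chimera recovery,
and 20-seed profile fixtures (80–600 guides) for the classification and
network properties; these sizes give stable statistics while keeping the
whole suite fast on one CPU. Ties in Spearman use midranks; ROC calls use
ρ ≥ θ; corrected counts clamp at 0; σ_global = 0 and all-zero timepoints are
hard errors rather than silent NaNs. Master seeds fan out to per-sample
substreams via numpy `SeedSequence` lists, so any sample is reproducible in
isolation.

## Known limitations

- The per-query line is fit on estimated (noisy) single fitness, i.e. an
  errors-in-variables regression; at screen-scale depths the attenuation is
  negligible but it is not corrected.
- Guide-level GI truth dilutes gene-pair aggregates (replicate strains of a
  gene pair do not share ε), so gene-pair significance on synthetic screens
  is conservative.
- The z-score null calibration inherits mild heteroscedasticity across
  strains (fitness-dependent counts), giving slightly heavy tails relative
  to a single normal; the null |z| > 2 rate runs a few tenths of a
  percentage point above the 4.55% normal tail at the tested depths.
- The FDR-based alternative caller is out of scope (an extension hook at
  `standardize_and_call` is the natural place for it).
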