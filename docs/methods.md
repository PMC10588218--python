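# Methods

This note documents the quantitative procedures implemented in `tdpfly`,
their assumptions, the defaults that matter, and the design choices made
where conventions were genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Spontaneous alternation (ymaze)

A fly in a symmetric three-arm maze produces an ordered sequence of arm
entries per one-minute trial (ten trials per fly by default). Every window
of three consecutive entries within a trial is an *alternation attempt*
(A_max); an attempt is an *alternation* (N_alt) iff its three entries are
pairwise distinct. Windows slide by one entry and never span trial
boundaries.

* **Per-trial aggregation.** Counts are summed within each trial, the
  per-trial ratio N_alt/A_max is formed, and the fly's score is the mean of
  per-trial ratios over trials with at least one attempt. A pooled mode
  (total N_alt / total A_max) is also reported; the two differ when trials
  have unequal attempt counts. Flies with no attempt in any trial have no
  score and are excluded from score statistics (flagged, not silently
  dropped).
* **Re-entries.** Same-arm re-entries are recorded as entries. They can only
  break alternations, since an alternation requires three distinct arms;
  nothing justifies deduplicating them.
* **Arm bias.** Per-fly entry fractions per arm are tested across the cohort
  against the unbiased null 1/3 with a two-sided Wilcoxon signed-rank test.
* **Distance scaling.** Total alternations divided by total distance moved
  (per mm) controls for locomotor differences between genotypes; undefined
  at zero distance.
* **Entry detection.** From a timestamped (x, y) trajectory, an entry is
  recorded when the position passes from the central zone into an arm beyond
  a *debounce depth* of 10% of the arm length (default; unstated in source
  protocols, chosen to suppress boundary jitter). Consecutive samples in the
  same arm are one entry; a new entry (same arm or not) requires an
  intervening center visit.
* **Group comparisons.** With multiple biological replicates the parametric
  path is used: a fixed-effects linear model (replicate as a fixed effect)
  with ANOVA and Tukey HSD. With a single replicate the nonparametric
  cascade is used. Sexes are always analyzed separately. The source
  convention mentions a mixed-effects fit with replicate "as a fixed
  effect"; a fixed effect inside a mixed-model call is operationally a
  fixed-effects linear model, which is what we fit.

## Sleep from activity monitors (sleepdam)

Monitor files are tab-delimited, one row per minute: record index, date,
time, a status field, six unused fields, then 32 channel counts. Rows with a
non-OK status are dropped; a single missing minute is imputed with the
neighbour maximum (so a zero-run survives only if both neighbours were at
zero); longer gaps are rejected because bout segmentation assumes contiguous
minutes.

Sleep is a maximal run of ≥ 5 consecutive zero-count minutes. Analysis
starts at the first midnight after recording begins (everything earlier is
loading/acclimation). Conventions:

* A bout spanning the day/night boundary contributes its minutes to each
  phase's sleep proportion but counts once, in the phase holding the
  majority of its minutes (ties: the phase of the bout's first minute).
  This conserves total sleep time exactly.
* Bouts touching the trace edges are kept and flagged; dropping them would
  bias bout length downward.
* The activity-to-sleep-bout-length ratio is defined as (mean counts per
  waking minute) / (mean sleep bout length in minutes). The upstream tool
  this summary imitates does not publish its exact formula; ours is declared
  in the summary metadata rather than asserted to be identical.

## Lifespan (lifespan)

Cohorts are censused every other day to a 100-day horizon, so event times
live on a 2-day grid and ties are common; at tied times deaths precede
censorings. The Kaplan–Meier product-limit estimate, Greenwood variance,
log-log (exponential Greenwood) pointwise CIs — which respect the [0, 1]
bounds — and the median (first time Ŝ ≤ 0.5) with a CI from intersecting
the pointwise band with 0.5 are computed via lifelines; a hand-rolled
product over risk sets serves as the independent oracle in tests. Log-rank
(two-group, or chi-square for k groups) compares genotypes; sexes are
pooled for survival.

## Confocal quantification (imagequant)

* **Nuclear ratio.** Mean tagged-protein intensity inside the nucleus mask
  (drawn on the DNA-dye channel) divided by the mean over the whole-cell
  mask (traced around the full extent of tagged signal). Near 1 when the
  protein fills the cell, < 1 under nuclear depletion, slightly > 1 for
  punctate nuclear signal. Invariant to global intensity scaling. Manual
  masks take precedence; Otsu-based automation is provided for synthetic
  stacks.
* **Nucleus counting.** Every ⌈spacing/z-step⌉-th optical section (2 µm
  spacing by default) is thresholded and its 2-D connected components
  counted; the total is summed over sections. If a component re-appears at
  the same (y, x) position in consecutive selected sections the count is
  flagged as a possible overcount (nucleus diameter exceeding the spacing).
* **Lobe intensity.** Over ≥ 3 sections, either integrated density minus
  (background mean × lobe area) ("subtract") or lobe mean / background mean
  ("ratio") — both modes exist because the source protocols used both
  conventions and do not state whether integrated density was divided by
  area before subtraction. Values are normalized to the young-group mean of
  the same genotype and lobe, so the young group's normalized mean is
  exactly 1.
* **Contrast enhancement.** Clip at the (f/2, 1 − f/2) quantiles with
  f = 0.3% total saturation split across tails, then rescale to [0, 1].
* **Bernsen thresholding.** Per pixel, local max/min over a circular window
  (radius 25–50 px in practice; any radius ≥ 1 accepted). High-contrast
  pixels are foreground when ≥ the local mid-gray; low-contrast
  neighbourhoods (max − min < contrast threshold, default 15) are classified
  wholesale by whether their mid-gray exceeds the global mid-intensity
  (dark-background convention; configurable). The contrast threshold is
  configuration, not a constant, because the source protocol does not state
  it.
* **Particle analysis.** 8-connected components; area = pixel count × pixel
  area; perimeter by clockwise Moore-neighbour boundary tracing with unit
  steps for 4-neighbour moves and √2 for diagonals (1-pixel-wide regions
  trace out and back, so a 1×n line has perimeter 2(n−1); a single pixel
  has no trace and gets circularity 1 by convention); circularity = 4πA/P²
  clamped at 1. Filters are inclusive at the bounds: 0.25 ≤ area ≤ 3.0 µm²,
  0.25 ≤ circularity ≤ 1.0. Mean particle size per lobe averages per-section
  means over ≥ 3 sections.

## RNA-IP enrichment (ripenrich)

* **Normalization.** Median-of-ratios size factors against a geometric-mean
  reference, over genes with nonzero counts in all samples.
* **Enrichment test.** Per-gene log-ratio of normalized condition means
  (IP vs input) with a moderated pseudo-count (0.5) and a delta-method
  standard error using negative-binomial variance,
  Var(x̄_c) = (x̄_c·E[1/s] + α·x̄_c²)/n. The dispersion α is
  method-of-moments per gene, averaged across the two conditions and floored
  at the across-gene median so three-replicate dispersion collapse cannot
  manufacture significance. p-values are two-sided normal, BH-adjusted
  across tested genes; all-zero genes are excluded and reported as NaN.
  This test is deliberately simple and is **not** numerically identical to
  shrinkage-based DE tools; externally produced DE tables (gene_id, log2FC,
  padj) can be ingested directly to bypass it.
* **Control subtraction.** adjusted_log2FC = log2FC − yfp_log2FC, matched by
  gene; genes absent from the tag-only control table get 0 (absence of
  evidence of nonspecific binding) and a flag. Candidate selection defaults
  to filtering on the model's own adjusted p while using the subtracted
  log2FC for ranking; filtering on the subtracted value is available, since
  the order of operations is a genuine convention choice.
* **Thresholds.** Strict inequalities (log2FC > 1, p_adj < 0.05), read
  literally: a gene at exactly log2FC = 1 is not a candidate.
* **Overlap, qPCR, orthologs, patient nuclei.** Exact set algebra with
  integer-rounded percentages for display (full precision retained);
  2^(−ΔΔCt) with triplicate wells averaged before differencing (so
  log2 FC = −ΔΔCt exactly); many-to-many ortholog joins preserved with an
  optional best-score filter; cryptic-vs-canonical nuclei compared with a
  pooled-variance independent t-test by default (the cited function's
  default), Welch available.

## Statistical conventions (statcore)

All tests are two-sided. The nonparametric cascade is Kruskal–Wallis
followed by all pairwise Wilcoxon rank-sum tests with Benjamini–Hochberg
adjustment applied jointly to the pairwise family. Rank tests use exact
enumeration for small tie-free samples and the tie-corrected normal
approximation otherwise (scipy's automatic switch, which changes over at
sample sizes compatible with the cohorts analyzed here). The signed-rank
test discards observations equal to the null value and errors when none
remain.

## Synthetic data: what it emulates, and what it does not

Generators are bit-reproducible given (params, seed); a master seed plus
fixed per-generator offsets feed independent SeedSequence streams.

* **Arm entries** follow a first-order Markov choice: re-enter the current
  arm with probability p_reentry, otherwise choose between the two other
  arms such that the window-completing arm is taken with probability
  p_alternate. The unbiased null (p_alternate = 0.5, p_reentry = 0) has
  E[score] = 0.5 and per-arm entry fractions of 1/3. An optional per-arm
  weight vector plants arm bias (weights (4.5, 1, 1) give a stationary
  fraction of 0.45 for the favored arm). Distance is entries ×
  distance_rate (5 mm per entry by default). Not emulated: locomotor
  dynamics, pausing, wall-following.
* **Activity traces** are a two-state per-minute Markov chain with
  phase-dependent transition rates chosen to hit the stationary sleep
  probabilities (0.4 day / 0.7 night by default) and geometric mean bout
  lengths (20 min day / 60 min night). Wake minutes emit zero-truncated
  Poisson counts (rate 2/min) so wakefulness always registers on the beam —
  the assumption that makes the 5-minute rule well-posed; a flag enables
  untruncated emission to study misclassification. The 5-minute rule
  reclassifies sub-5-minute sleep episodes as wake, which at the default
  bout means biases recovered sleep fractions down by ~1–2% — within the
  ±0.03 recovery tolerance used in tests. Not emulated: circadian ramping,
  startle responses, arousal thresholds.
* **Survival** draws Weibull (shape, scale) or Gompertz (a, b) death times,
  rounds UP to the 2-day census grid (a death is discovered at the next
  count) and right-censors at day 100. Note that ceil-rounding shifts the
  large-sample median up by up to one census interval; estimator-validation
  tests therefore use a 1-day census, while the 2-day convention is tested
  as such.
* **Cell stacks** are spheres (nuclei, radius 1.5 µm) with concentric rims
  (0.5 µm) on a flat background with Gaussian noise; the depletion
  parameter moves tagged signal from nucleus to rim while conserving the
  whole-cell mean, so the expected nuclear ratio is exactly 1 − depletion.
  No optical PSF, no z-attenuation, no overlapping cells.
* **Puncta images** render ellipses of requested area and eccentricity on a
  noisy background. No texture correlation or uneven illumination.
* **Count tables** are negative binomial (dispersion 0.05) around lognormal
  baseline means (floored at 20) with three replicates per condition;
  planted targets carry log2FC = 3 in the TDP-43 IP only, and "nonspecific"
  genes are enriched in both the TDP-43 and tag-only IPs so that control
  subtraction cancels them. No GC/length bias, no batch structure.

Passing recovery tests on these generators demonstrates that the
quantification code inverts its own generative assumptions at the stated
sample sizes; it does not certify performance on real microscopy or
sequencing artifacts (bleed-through, ambient RNA, alignment error), which
are out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use cohort sizes chosen to make Monte-Carlo error
small relative to the asserted tolerances on one CPU: 500 flies for the
Y-maze nulls, 100 flies × 3 days for sleep recovery (±0.03), 10⁴ flies for
the KM closed-form check (2% band), 2000 genes for enrichment calibration
and sensitivity, 2000 replicates for cascade null calibration. Tolerances on
stochastic checks are 3× the Monte-Carlo standard error unless a wider
engineering tolerance is stated inline. Degenerate inputs (empty masks,
all-censored cohorts, all-zero genes, zero distance) raise errors or return
flagged undefined values rather than NaNs propagating silently.
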