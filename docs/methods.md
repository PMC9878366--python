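# Methods

This note documents the models, conventions and design choices behind
`tatexpo`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Exposure model

A participant's tattoo-ink exposure is summarized by four quantities: total
tattooed skin area (cm²), the black/gray area, the colored area (every
canonical color other than black/gray, white included), and coverage — the
area-weighted fraction of tattoo outlines that is actually inked, on the
categorical scale {10, 25, 50, 75, 100} %.

Two measurement routes produce these quantities:

**Self-report.** Three questionnaire dialects express tattoo extent per
body part and color. *Hand surface* and *credit card* are unit counts:
reported magnitude × unit area, where the unit is the respondent's measured
hand (length × width; a 17.5 × 9.5 cm surgical mask, 166.25 cm², stands in
when the hand was not measured) or a 30 cm² credit card. *Body schemes* is
categorical: the tattooed fraction of each body part is one of
{10, 25, 50, 75, 100} %, multiplied by the part's skin area; per-color
5-point Likert proportions split the part total across colors. The Likert
proportions are normalized within each part before splitting, so per-color
areas sum exactly to the part total — without normalization, independent
Likert answers could not satisfy the conservation invariant that per-color
and per-part areas each sum to the participant total (enforced at 10⁻⁶
relative tolerance on every estimate).

**Validation.** Trained-staff measurements describe each tattoo by its
optically closest geometric shape(s) — square l², rectangle l×w, circle
πr², oval πr₁r₂, additive combinations (a bold word is measured as the
enclosing shape of the whole word) — plus a coverage category and visually
estimated per-color shares that must sum to 1.

Coverage of an estimate with zero tattooed area is *undefined* (`None`),
never 0; coercing it to 0 would drag agreement statistics toward
disagreement for untattooed participants.

Gray and gray wash (diluted-black shading) merge into a single `black_gray`
class at ingest because respondents routinely report shading as black; all
other colors, including white, count as "colored".

## Anthropometry

Body surface area uses sex-stratified power laws (weight in kg, height in
cm, output m²): 0.000975482·w^0.46·h^1.08 for women and
0.000579479·w^0.38·h^1.24 for men — the only unit combination that yields
plausible adult BSA (~1.5–2 m²). Per-part areas are BSA × 10⁴ × partition
fraction. The shipped partition is the standard rule of nines (head/neck
0.09, each arm 0.09, anterior and posterior trunk 0.18 each, each leg 0.18,
perineum 0.01); burn-medicine variants differ in detail, so the partition
is a YAML-configurable table rather than a constant. Plausibility gates at
ingest (height ∈ (50, 250) cm, weight ∈ (20, 300) kg, hand dimensions both
present or both absent) reject malformed rows before any arithmetic.

## Agreement battery

For each questionnaire arm × outcome, self-assessed (x) and validation (y)
values are paired by participant and passed through:

* paired t: t = mean(d)/(sd(d)/√n) with d = x − y, two-tailed p from
  Student t with n−1 df; all-zero differences give (t, p) = (0, 1) and
  zero-variance nonzero differences give a flagged infinite t;
* ICC from two-way ANOVA mean squares with k = 2 fixed raters:
  ICC(C,1) = (MSR−MSE)/(MSR+MSE) and
  ICC(A,1) = (MSR−MSE)/(MSR+MSE+(2/n)(MSC−MSE)) — the single-measurement
  forms matching the "consistency" vs "absolute agreement" vocabulary.
  ICC(A,1) ≤ ICC(C,1) whenever MSC ≥ MSE, i.e. whenever a systematic rater
  offset exists; with no offset the ordering can invert by sampling noise,
  which is why the package does not enforce it as a construction invariant;
* Kendall τ-b (tie-corrected; ties among tattoo sizes are common), flagged
  undefined when either side is constant;
* Bland–Altman series with abscissa (x+y)/2 and ordinate y − x, so
  overestimation by self-report appears as negative bias; limits of
  agreement are bias ± 1.96 sd. The pair mean is the conventional and
  intended abscissa for relating disagreement to tattoo size;
* average ranks per side for rank scatterplots.

p-values carry no multiple-testing adjustment; none is part of the battery.
Statistics are always computed on the raw scale — log scaling is a plotting
concern only (the plot-series export carries raw values).

Color outcomes include a participant when *either* measure records that
color group, so a missed color degrades agreement instead of shrinking the
sample. Arms or outcomes with n < 3 are skipped with a logged reason, and
every input participant lands either in a result's n or in the exclusion
log (asserted in tests).

### Display rounding

Report tables round percentages to one decimal. The cohort-composition
summary prints integer percentages; for the mutually exclusive color groups
these use largest-remainder (Hamilton) apportionment so the three shares
sum to exactly 100 — with plain rounding, 22/24/51 of 97 would print
23/25/53 = 101 %. Multi-select rows (tattoo-age bands, artist expertise)
round plainly since they need not sum to 100.

## Image surface analysis

A photograph is calibrated by a known distance (pixels / cm). The 8-bit
grayscale is thresholded at three cutoffs {auto−δ, auto, auto+δ} (δ = 10
levels by default) and the ink area — pixels at or below the cutoff, ink
being darker than skin; a flag inverts the convention — is the mean of the
three, in px²/scale². The automatic cutoff maximizes Otsu's between-class
variance, computed in-package so that ties resolve to the *midpoint* of the
maximizing plateau: on a clean two-level image every cutoff between the
modes maximizes the criterion, and picking the lowest (as common library
implementations do) would place cutoff−δ below the ink intensity and
silently drop a third of the area from the average.

Color-resolved areas assign every pixel to the perceptually nearest
prototype in CIELAB among the canonical ink colors plus skin/background
prototypes; background classes are discarded. This replaces interactive
machine-learning segmentation with a deterministic classifier having the
same output contract (per-class areas). White ink on a white background is
inherently ambiguous for this classifier; prototypes are configurable per
image. Perspective correction is out of scope (photographs are assumed
captured at 90°).

Accuracy on analytic fixtures is limited by pixelation: the error scales
with perimeter/scale, verified at two resolutions in the tests, and a
5 cm-radius disk at 10 px/cm is recovered within 2 %.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
tested. Defaults emulate a young, two-thirds-female tattooed volunteer
population: heights/weights normal per sex (women 164.5 ± 7 cm, 66 ± 12 kg;
men 177.5 ± 7 cm, 80 ± 12 kg, truncated to plausible ranges); hand measured
with probability 0.78; tattoo counts negative binomial (mean 6, size 1.5,
conditioned ≥ 1, matching a median of ~5 with IQR ~2–9); per-tattoo areas
log-normal on cm² with μ = 3.9, σ = 1.5 (median ≈ 49 cm², strongly
right-skewed); placement weighted toward arms and the back; palettes
per participant (23 % black-only, 25 % black+gray shading, 52 % including
other colors); coverage categories with a broad central mode. These
marginals are seeds for realism, not calibration targets — no test asserts
exact agreement with any published table. Tattoo draws are capped so the
cumulative inked area of a body part cannot exceed 95 % of that part's
skin: without the cap a single log-normal draw can exceed the whole part,
which no physical tattoo can, and the body-schemes scenario ceiling would
systematically under-report such cohorts.

One integer seed governs everything; participant i draws from a dedicated
sub-stream keyed (seed, i), so regenerating any participant is stable under
cohort-size changes.

### Reporting-bias model

Self-reports distort truth in four ways:

1. **Multiplicative size-dependent error.** Each reported (part, color)
   area is the true area times a log-normal factor with median
   b₀·size^(−γ) and log-sd σ_b. γ > 0 reproduces the observed pattern that
   small tattoos are relatively more overestimated while large tattoos
   carry the biggest absolute overestimation. The default
   (b₀ = 2·49^0.25, γ = 0.25, σ_b = 0.5) puts the median factor at 2 for a
   median-sized (49 cm²) entry. A steeper γ that would make the smallest
   quartile a full 4× would push large tattoos below factor 1
   (under-estimation), contradicting the qualitative pattern, so the
   default keeps both facts qualitatively rather than matching both
   numbers exactly. Errors are independent across body-part entries; no
   within-person error correlation is modeled (a documented assumption).
2. **Quantization.** Magnitudes are rounded to the dialect's reporting
   grid — half-unit steps for hand/credit counts, the
   {0, 10, 25, 50, 75, 100} % scenario categories for body schemes — by
   *randomized rounding*: round up with probability equal to the
   fractional position between the bracketing grid points. Across a cohort
   respondents round in different directions; randomized rounding captures
   that heterogeneity and is mean-unbiased by construction, whereas
   deterministic nearest-rounding of a left-skewed size distribution would
   inject a systematic truncation bias (small entries always collapse to
   zero) that is a statement about the rounding rule, not about
   respondents. The worst-case per-entry error is one grid step (half a
   unit × unit area for the unit dialects; one category gap × part area
   for schemes), asserted in tests. `quantize=False` yields the continuum
   limit, where unit-dialect conversion reproduces truth exactly.
3. **Coverage confusion.** The reported coverage category passes through a
   5×5 row-stochastic confusion matrix. The default (0.65 stay, 0.30 one
   category up, 0.05 down) is calibrated to a ~5 percentage-point
   systematic coverage overestimate, the magnitude seen when respondents
   judge coverage diagrams.
4. **Gray→black misreporting.** With probability 0.30 a participant labels
   all gray shading as black. Because analysis merges the two classes this
   does not move area totals; it models the raw-label confusion that
   motivates the merge.

### Bias recovery

With the multiplicative model, E[log(self/validation)] = log b₀ − γ·log
size, so OLS of the participant-level log ratio on log validated size
gives γ̂ = −slope. The regressor is centered at the geometric-mean size
and b₀ is reported *at that reference size*: extrapolating the intercept
to 1 cm² (≈ 6.5 log-units away) would multiply slope noise into the
estimate. At γ = 0 the reference choice is immaterial; `b0_at_unit`
exposes the size-1 extrapolation when wanted. Pairs with a non-positive
total on either side are excluded and counted; at least 50 usable pairs
are required. Recovery experiments use the credit-card dialect: its fine
grid (15 cm² steps) keeps quantization inside the multiplicative model,
whereas the coarse hand unit (~160 cm²) can round a small participant's
whole report to zero, and excluding those pairs selects upward-rounded
small totals, biasing γ̂ upward by ~0.06.

## Problem sizes and numerical choices

The test suite exercises cohorts of 60–500 participants and estimates
stochastic pipeline properties by Monte Carlo: the null-bias sanity check
uses 100 cohorts of 200 participants per arm (paired-t p-value behavior)
with ICC means over the first 10; oracle-equivalence checks run 1000 random
samples at n ∈ [3, 50] against brute-force implementations (agreement to
1e-10 for ICC, 1e-12 for τ). The acceptance script mirrors these at the
same sizes (40 cohorts for the null-bias block). Tolerances on analytic
image fixtures are 2 %, dominated by pixelation. Degenerate inputs resolve
explicitly: constant paired tables → undefined ICC (NaN, flagged), all-tied
rank inputs → undefined τ, empty exposure → undefined coverage, constant
images → named threshold error.

## Known limitations

* The rule-of-nines partition is an approximation; the "modified" burn
  partitions used in practice differ in detail, hence the configurable
  table.
* Passing tests on synthetic cohorts demonstrates internal consistency of
  the pipeline under the stated bias model — not that real respondents
  follow a log-normal multiplicative error, that their rounding is
  unbiased, or that real color confusion is limited to gray/black.
* The per-color Likert normalization assumes respondents' color
  proportions are relatively, not absolutely, meaningful.
* Validation measurements are treated as error-free references; the image
  stage exists precisely to audit that assumption on photographed subsets.
* The nearest-prototype color classifier has no notion of lighting or skin
  tone variation beyond its fixed prototypes; real photographs need
  per-image prototype tuning.
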