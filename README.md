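# tatexpo

Questionnaire-based assessment of tattoo-ink exposure for epidemiological
research.

Tattoo inks can carry carcinogens (metals, polycyclic aromatic hydrocarbons,
primary aromatic amines), yet large cohort studies of their long-term health
effects need a way to quantify each participant's exposure without physically
examining tens of thousands of people. The practical instrument is a
self-report questionnaire: respondents describe how much of their skin is
tattooed, in which colors, and how densely inked ("coverage"). `tatexpo`
implements the quantitative machinery such an instrument needs:

* **Unit conversion** — self-reports in three measurement-unit dialects are
  turned into absolute tattooed skin areas (cm²): counts of the respondent's
  own *hand surface* (length × width, or a 17.5 cm × 9.5 cm surgical-mask
  fallback), counts of a standard *credit card* (30 cm²), or per-body-part
  *body schemes* (tattooed-fraction scenarios of 10/25/50/75/100 %).
* **Anthropometry** — body-scheme conversion needs each body part's skin
  area, derived from sex-stratified power-law body surface area (BSA)
  formulas, BSA = c·w^a·h^b (c = 0.000975482, a = 0.46, b = 1.08 for women;
  c = 0.000579479, a = 0.38, b = 1.24 for men; weight in kg, height in cm,
  BSA in m²), partitioned by the rule of nines.
* **Validation measurements** — physically measured tattoos described by
  their optically closest geometric shapes (square l², rectangle l×w, circle
  πr², oval πr₁r₂, and sums thereof), per-color area shares, and coverage
  categories, aggregated to the same per-participant exposure estimates.
* **Agreement battery** — paired t tests, intraclass correlation in both the
  absolute-agreement ICC(A,1) and consistency ICC(C,1) forms, tie-corrected
  Kendall τ-b, paired ranks, and Bland–Altman bias with 95 % limits of
  agreement, computed per questionnaire arm and outcome (total size,
  black/gray area, colored area, coverage).
* **Digital surface analysis** — tattoo areas from calibrated photographs:
  pixels-per-cm scale from a known in-image distance, three-threshold
  averaged binary segmentation, and per-color areas by nearest-prototype
  classification in CIELAB.
* **Synthetic cohorts** — a generator that emulates a tattooed study
  population (skewed log-normal tattoo sizes, black/gray-dominant palettes,
  five-category coverage) and distorts truth into self-reports through a
  configurable bias model: a multiplicative log-normal error with median
  b₀·size^(−γ), grid/category quantization, coverage-category confusion and
  gray→black misreporting. `recover_bias` closes the loop by re-estimating
  (b₀, γ) from paired totals.

## Worked example

`examples/05_simulate_validation_study.py` simulates a 300-participant
validation study with the default ~2× overestimation bias and runs the full
per-arm analysis:

```
cohort: 300 participants, 1907 tattoos

arm            outcome      n   self-mean  valid-mean      p   AA-ICC  CA-ICC   tau
body_schemes   total_size  100       1176         718   0.000    0.77    0.84   0.75
credit_card    total_size  100       1347         877   0.000    0.83    0.89   0.82
hand_surface   total_size   99       1418         899   0.000    0.82    0.88   0.79

recovered bias: median factor 1.73 at 508 cm^2, size exponent gamma = 0.20 (94 pairs, 5 excluded)
```

Self-assessed mean areas are roughly double the validated ones (the p column
is the paired t test of that difference); consistency ICC stays higher than
absolute-agreement ICC because the overestimation is systematic rather than
random; and the regression of log(self/validation) on log size recovers a
median factor near 2 that shrinks with tattoo size (γ > 0: small tattoos are
relatively more overestimated). The other scripts in `examples/` each
demonstrate one capability (BSA, dialect conversion, the agreement battery,
image-based areas).

A thin CLI mirrors the pipeline: `tatexpo simulate | convert | validate |
image-area | report` (see `tatexpo --help`).

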