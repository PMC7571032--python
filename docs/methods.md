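# Methods

## Scope and data model

`aarisk` implements a deterministic survey-to-risk pipeline for a process
contaminant (acrylamide, AA) in baked products: per-sample occurrence
records are summarized per product, screened against regulatory benchmark
levels, compared inferentially across products, and propagated into a
daily-intake and margin-of-exposure (MOE) grid. All concentrations are in
µg/kg (≡ ng/g), consumption in g/day, body weight in kg, daily intake in
ng/kg bw/day and BMDL10 values in mg/kg bw/day; the single 10⁶ (mg → ng)
conversion lives inside `exposure.margin_of_exposure` so the unit chain is
explicit and tested in one place.

The package ships a calibrated default study (`aarisk.defaults`): the
observed summary statistics, recipe ranges, benchmark levels and published
intake grid of a 200-sample market survey of ten Italian baked products
(five bread-type, five sweets; 102 + 98 samples). Raw samples, consumption
extracts and body weights of that survey are not published, so the raw
data layer is synthetic (below) and the published tables serve as
calibration inputs and as a regression surface.

## Occurrence summaries

Per product: mean, sample sd (n − 1 denominator), median, 95th percentile,
min, max. Percentiles interpolate linearly between order statistics
(numpy's default, the "type 7" rule); on n ≈ 20 samples the 95th
percentile is method-sensitive, so the method is a parameter rather than a
constant. A single observation yields sd = 0 with a warning instead of an
error, keeping tiny-fixture pipelines alive. Rounding (to integers, as
survey tables print) is presentation-only; every computation runs at full
precision.

Censored records (below the limit of quantification, LOQ) carry the LOQ in
their concentration field and are substituted before aggregation by one of
three conventional policies: 0, LOQ/2 or LOQ (default LOQ 25 µg/kg, the
reference method's value). The calibrated survey quantified AA in every
sample, so censoring only arises with user data. Left-censored maximum
likelihood estimators (Kaplan–Meier, ROS) are out of scope.

## Benchmark screening

Benchmark levels are mitigation triggers, read as "should not exceed":
a value exactly at the benchmark is compliant, exceedance is strict. Both
a summary-statistic screen (flag + signed margin in µg/kg) and a
per-sample exceedance fraction are provided. Benchmarks are configuration
data, not hard-coded regulation text.

## Comparative statistics

* **ANOVA / Tukey HSD.** Classical fixed-effects one-way ANOVA
  (scipy `f_oneway`) and all-pairs Tukey HSD with the Tukey–Kramer
  unequal-n correction (scipy `tukey_hsd`). Default α = 0.01, the
  convention of the calibrated survey's letter display. Zero within-group
  variance with differing means is flagged degenerate (F = ∞, p reported
  as 0, pairs with differing means significant); all observations
  identical is an error (F is 0/0).
* **Compact letter display.** Insert-and-absorb: start from one class
  holding every group; each significant pair splits every class containing
  both members into two copies (one without each member); classes that are
  subsets of another are absorbed. Letters are assigned to classes ordered
  by their first group in input order. The defining property — two groups
  share a letter iff not significantly different — holds exactly and is
  verified exhaustively over every significance pattern on up to five
  groups.
* **Spearman correlation.** Average ranks for ties; two-sided p by the
  t approximation (adequate at the n ≈ 66 soft-bread samples of the
  intended use), with an exact permutation option for n ≤ 10.
* **Smoother.** Locally weighted linear regression (tricube kernel,
  span-fraction nearest-neighbour bandwidth, default span 0.75). At each
  grid point the fit is a linear combination l(x₀)·y, so the pointwise
  95% band is ±1.96 σ̂ ‖l(x₀)‖ with σ̂² the residual variance of the
  smoother at the data points (df = n − tr L). Extrapolation beyond the
  data range is refused. The smoother is presentation-layer: it shows the
  curvilinear moisture–AA shape (sharp rise below ~43% dough moisture) and
  is excluded from any numeric acceptance surface.

## Exposure and risk characterization

The intake grid crosses {median, p95 consumer} × {BS: C = median,
WS: C = 95th percentile} × age groups × products — four DI values per
product and age group. MOE = BMDL10·10⁶/DI, classified per endpoint:
neurotoxic (BMDL10 0.43 mg/kg bw/day) low concern at MOE ≥ 125
(inclusive), carcinogenic (0.17 mg/kg bw/day) low concern strictly above
10,000. Threshold comparisons always use unrounded values; display
rounding is half away from zero. DI = 0 makes the MOE "not computable"
rather than infinite, so sentinel infinities never reach reports.

## Synthetic data generator

The generator fabricates the raw layer the calibrated survey does not
publish:

* **Concentrations** are drawn by rejection from the parent normal
  N(mean, sd) restricted to the product's observed [min, max]. The
  configured mean/sd parametrize the *parent*, not the truncated,
  distribution; in the default calibration the bounds sit within ~1.5 sd,
  so acceptance is high. Empirical moments therefore match the
  truncated-normal moments (checked against an independent quadrature
  oracle, within 2% at large n), not the configured parameters.
* **Recipe attributes** (moisture, sugars, salt %) are uniform within each
  product's recipe range. No moisture–concentration correlation is
  induced: generated data reproduce marginal structure only, so the
  survey's observed negative moisture correlation (ρ ≈ −0.44) is *not* a
  property of the synthetic data and is not an acceptance quantity —
  passing tests show the correlation/smoother machinery works, not that
  the generator reproduces that field correlation.
* **Consumption** profiles are inverted from the published best-scenario
  intakes: Q = DI_BS · BW / C_median per (product, age group), separately
  for median-consumer and p95-consumer tables. This makes every published
  BS intake an exact fixed point of the pipeline. Without targets, median
  consumption is uniform in 40–160 g/day (the realistic span of staple
  bread consumption) with the p95 consumer at 1.5–3.5× the median.
* **Body weights** are nominal Italian anthropometrics: 55 kg adolescents,
  70 kg for adults and the elderly (the survey used one weight for both
  older groups); fully overridable.
* **Determinism.** One seed drives everything; each generator call derives
  an independent stream, split per product in declaration order, so output
  is byte-stable and adding products never perturbs earlier draws.

### Reconstruction fidelity and a known anomaly

Reconstructing worst-scenario intakes as WS = BS · C_p95/C_median
reproduces the published WS cells only to ±1 ng/kg bw/day in general,
because the published BS values are themselves rounded. One published cell
is inconsistent with its own concentration ratio: wholemeal Friselle,
adolescents, median consumers prints 50–70, while 50 · (450/375) = 60.
The package reproduces the printed 50 (BS) and computes 60; the
discrepancy is documented rather than resolved, and that cell is excluded
from the WS regression test. Similarly, the published extreme MOEs
484–3967 and 1225–10,033 derive from the authors' unrounded minimum intake
(≈ 42.86 vs the printed 43); applying the MOE formula to the published
intake table reproduces 484 and 1225 exactly, while the grid recomputed
from calibrated inputs gives a minimum carcinogenic MOE of 483.

## Method QC

Calibration is an ordinary least-squares line of response (analyte /
internal-standard peak-area ratio) on concentration; σ is the residual sd
(n − 2). LOD = 3.3 σ/S and LOQ = 3·LOD — note 3 × 8 = 24 while the
reference method reports LOQ 25 µg/kg, a rounding inconsistency that is
preserved rather than hidden: computation is full-precision, presentation
separate. σ may alternatively be supplied directly (e.g. sd of blank
responses). Recovery is 100 · measured/true; precision is the mean
within-day RSD and the RSD of daily means. When the pipeline has no QC
input files it generates a seeded synthetic demonstration set (linear
calibration over the 25–2000 µg/kg working range with σ/S matching an LOD
of 8 µg/kg, 92–97% recoveries, 7 × 5 replicates at ~5% scatter), labelled
`synthetic_inputs: true` in the report.

## Numerical and design choices

* Strict inequalities for benchmark exceedance; boundary equality
  compliant. Inclusive neurotoxic / strict carcinogenic MOE thresholds.
* `q_p95 < q_median` in a consumption file is a hard validation failure,
  never silently reordered — it signals corrupted quantile extraction.
* CSV dialect fixed (UTF-8, comma, "." decimal, header mandatory);
  en-dash "31–90" ranges are normalized only in the range-parsing helper.
* Test problem sizes: parameter recovery draws 20,000 samples per product,
  at which the 2% moment band is a ≈ 4σ test of the sampler; the
  full-grid fidelity checks use the calibrated study's own sizes
  (n = 18–22 per product, 200 total).

## Limitations

Exposure is deterministic: no Monte Carlo intake distributions and no
quantitative uncertainty propagation. The consumption profiles are an
algebraic inversion, not the original dietary-database extractions, so
age-group contrasts beyond the published grid carry no information. Sweets
are summarized and screened but excluded from exposure (no reliable
consumption rates). The generator assumes independent truncated-normal
concentrations within products — no batch effects, no manufacturer
clustering, no recipe–concentration coupling — so inferential results on
synthetic data validate machinery, not biology.
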