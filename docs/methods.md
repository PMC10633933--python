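# Methods

## Data model and ingestion

A record is one individual's Hb measurement (g/dL) with survey, group
(child 6–59 mo / non-pregnant WRA 15–49 y), and site metadata. Ingestion
keeps every input row: unparseable Hb becomes a missing value on a
retained record, so row counts always reconcile. Validity is the device
reporting range 0–25.6 g/dL, inclusive at both ends (the range of the
HemoCue-class photometers these surveys use). Exact duplicate rows (all
fields equal) collapse to the first occurrence; rows sharing a record id
but differing in any field are both kept with a logged warning, because
silently dropping measurements would alter the distribution shape this
analysis exists to examine. Pregnant WRA records are dropped at assembly
(the reference cutoffs apply to non-pregnant women); a missing pregnancy
flag counts as non-pregnant and is logged. A survey enters analysis only
if at least 30% of sampled individuals have valid Hb; when the input
carries no subsampling metadata the denominator defaults to the row count,
making the rule vacuous — stated in the CLI help. Whether the 30% should
be assessed against eligible individuals or households is left to the
caller via the explicit `n_sampled` input.

## Per-survey statistics

All moments, the median, and anemia prevalence are computed on valid
values inside the plausibility window (default 4.0–18.0 g/dL, endpoints
kept, exclusion strict beyond); the implausible-value percentage
(`flag_pct`) is computed on valid values *before* that exclusion.
Skewness and excess kurtosis use the bias-corrected G1/G2 estimators
(unbiased under normality; G2 is centered at zero for a normal
distribution). Skewness requires n ≥ 3, kurtosis n ≥ 4, both a
non-degenerate sample; otherwise the statistic is NaN and the rule engine
returns an "insufficient data" verdict. Quantiles (and the median) use a
configurable order-statistic definition, defaulting to linear
interpolation (Hyndman–Fan type 7); reference analyses used statistical
packages whose exact percentile algorithm is unstated, and corpus-level
tolerances absorb the difference. Values are analyzed as recorded at 0.1
g/dL device precision; no unrounding or dithering is applied.

## Outlier tabulation

Record-level outlier percentages pool all records with equal weight
(not survey-weighted); survey-level prevalence is categorized as
none (exactly 0%), 0–1% (interpreted as the half-open interval (0, 1],
so the three categories partition surveys), and > 1%. Comparisons are
strict inequalities on both sides, matching the window semantics.

## Anemia and altitude

Total anemia is Hb < 11.0 g/dL (children) and < 12.0 g/dL (non-pregnant
WRA), strict comparison at the cutoff. Field data normally arrive
altitude-adjusted; when they do not, the CDC polynomial correction
(−0.032·A + 0.022·A², A in thousands of feet) is subtracted, floored at
zero so low altitudes never inflate Hb. Agencies publish tabulated
variants of the same curve, so the adjustment function is swappable.
Severity strata and smoking adjustment are out of scope.

## QC rule set

Flags: G1 > +0.2, G2 < −0.5, SD outside 1.1–1.55 g/dL (child) or 1.1–1.65
g/dL (WRA), flag_pct > 1% (using the combined below-4-or-above-18
percentage). Boundary semantics are strict: a statistic exactly at a
threshold passes, following the "above"/"below" wording of the proposed
rules. Rules are evaluated independently and reported as a flag set, not a
composite score; flagged surveys prompt investigation, never automatic
exclusion from corpus summaries. `derive_thresholds` recomputes SD bounds
as the P2.5/P90 of survey-level SDs (after an optional subgroup
exclusion), each rounded to the nearest 0.05 g/dL with ties away from zero
(the rounding convention is otherwise unspecified); it refuses below a
configurable floor of 20 surveys per group. The default lower bound 1.1
g/dL is retained from the proposed rule set rather than derived — the
empirical P2.5 of survey-level SD (≈ 1.09–1.12) motivates but does not
formalize it.

## Corpus analysis

The corpus summary treats each survey as one observation and reports
mean, SD, and the quantile ladder {min, P2.5, P10, P25, P50, P75, P90,
P97.5, max} for each survey-level statistic, with optional
subgroup-exclusion variants driven by a generic predicate (country, site,
year — not hard-coded to any country). The paired child/WRA comparison
matches surveys on survey id and uses a paired t interval on the
differences (child − WRA); the presentation of the reference results
("difference (95% CI)") is consistent with a paired t, but the method is
configurable (Wilcoxon signed-rank as alternative) since it is not named.
Spearman correlations use mid-ranks for ties with the t-approximation
p-value on n − 2 df. Figures are emitted as tidy CSV tables rather than
rendered plots.

## Synthetic data generator

The generator stands in for restricted field microdata. Per-survey
targets (mean, SD, G1, G2) are drawn from normal hyper-distributions
whose defaults are the across-survey mean/SD of the reference corpus:
children (11.1 ± 0.50, 1.39 ± 0.21, −0.37 ± 0.26, 0.54 ± 0.67), WRA
(12.6 ± 0.57, 1.47 ± 0.23, −0.53 ± 0.36, 1.15 ± 1.17). A Gaussian copula
couples a survey's mean and SD at rank correlation −0.33 and the child
and WRA SDs of one site at +0.52, the correlations observed in the
reference corpus. Per-survey sample sizes are uniform over the reference
5th–95th percentile ranges (children 175–649, median ≈ 400; WRA 99–406,
median ≈ 226). Gross-error contamination replaces each record with
probability 0.0008 (child) / 0.0014 (WRA) — chosen to emulate the observed
0.08% / 0.14% of records outside 4.0–18.0 g/dL — by a uniform draw from
[1.0, 4.0) or (18.0, 25.6], sides equiprobable. Values are rounded to 0.1
g/dL (photometer display precision) and clipped to 0–25.6.

Record values come from the Fleishman power method: X = a + bZ + cZ² + dZ³
with Z standard normal and a = −c, coefficients solved numerically
(residual < 1e−9) for unit variance and the target third/fourth
standardized moments. The family cannot reach excess kurtosis below
roughly −1.1513 + 1.7·skew²; the package treats that slightly conservative
curve as its supported region (the solver is verified to converge
everywhere on or above it) and raises an explicit infeasibility error
below it. Hyper-draws of (skew, kurtosis) are clamped to the region with a
0.05 margin, which truncates the lower kurtosis tail of the
hyper-distribution slightly.

Because reference summary statistics are computed on plausibility-trimmed
values, the generator's targets are defined on the same support: a damped
fixed-point iteration adjusts the raw location, scale, and family shape
parameters until the *trimmed* population moments match the targets
(kurtosis especially needs this — a 1e−4 tail mass at 5 SD carries visible
fourth-moment weight). For extreme draws whose trimmed shape is outside
the family's reach, the match is best-effort: location and scale still
match, shape gets as close as the region allows. Setting
`target_window=None` targets the untrimmed distribution instead.

What the generator does *not* emulate: cluster/household sampling
structure and design effects, seasonality, covariates, team- or
device-level error clustering, digit preference, and overdispersed
contamination (a few very bad surveys rather than a uniform low rate).
Passing tests therefore show that the analysis pipeline is correct and
well-calibrated on distributions with realistic moments, coupling, and
contamination — not that the QC thresholds would reproduce exactly on any
particular real survey program.

## Numerical choices

Moment solver: hybrid Powell root-finder from three fixed starting points,
accepted at residual < 1e−9; the sign-symmetric solution branch is
normalized to increasing b. Trimmed-moment quadrature: 4001-point grid on
z ∈ [−8, 8] under the Gaussian weight (tail mass beyond is ~1e−15).
Rounding to threshold steps uses floor(|x|/step + 0.5 + 1e−9) to keep
decimal ties (e.g. 1.525) from landing below the tie point after binary
representation error. Paired differences with sample SD below 1e−10
(relative) are treated as constant: degenerate CI, p unavailable, warning.
Corpus problem sizes in tests and the acceptance script (400 sites,
one-million-record recovery runs) were chosen to keep hyper-sampling noise
well inside the stated tolerances.

## Known limitations

* The 30%-valid inclusion rule is inert without subsampling metadata.
* Threshold derivation assumes the corpus is itself mostly sound; deriving
  percentile bounds from a heavily contaminated corpus bakes the
  contamination into the thresholds (mitigated by the subgroup-exclusion
  sensitivity path).
* G1/G2 are unbiased only under normality; at field sample sizes their
  small-sample bias on skewed parents slightly attenuates corpus-level
  shape summaries.
* The rule engine treats thresholds as exact constants; it does not model
  sampling uncertainty of a survey's SD or shape statistics.
* The polynomial family matches four moments, not tail quantiles: in
  generated corpora the implausible-value rate runs somewhat above the
  configured contamination rate, because surveys drawn with wide SD or
  heavy kurtosis carry genuine family tail mass beyond the 4.0–18.0
  window (most visibly in the WRA upper tail).
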