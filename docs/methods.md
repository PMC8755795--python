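# Methods

## Exposure model

Chronic daily exposure follows the standard USEPA ingestion formulation.
For a chemical at concentration *C* (mg/kg) in the berries:

    EXPO        = C · d · DI · EF · ED / (BW · AT),  AT = ED · 365 day/yr
    EXPO_cancer = C · d · DI · EF · ED / (BW · LT · 365)

`d` is an optional dissolution fraction for berries brewed in tea or water
(default 1.0, i.e. direct consumption; surveys of brewing report at most
~30% extraction, so `d=0.3` is the natural setting for tea-only consumers).
Units are fixed by convention: concentrations are mg/kg (≡ µg/g)
everywhere in storage and I/O, so that C·DI is already µg/day and EXPO
comes out in µg/(kg·day) with no conversion factor. The single µg→mg
conversion the cancer slope factor needs is owned by one function
(`exposure_engine.ug_to_mg`); it is applied exactly once, inside
`carcinogenic_risk`. ED cancels algebraically in the non-carcinogenic
formula; it is retained in the expression for traceability and the
cancellation is asserted in tests.

Risk characterization: HQ = EXPO/ADI per chemical, HI = ΣHQ partitioned by
chemical class (HI_P pesticides, HI_M metals; additivity and the
share_P + share_M = 100 identity are exact and asserted on every run),
R = SF·EXPO_cancer. Thresholds: 1 for HQ/HI; 10⁻⁶ (negligible) and 10⁻⁴
(maximum acceptable) for R, with the boundary value classified into the
more severe grade. Rankings sort by HQ descending with lexicographic
tie-breaks so output is deterministic.

Interactions between chemicals are not modelled (dose additivity), and
exposure from other foods is out of scope.

## Censored (below-LOD) data

A record below the limit of detection is left-censored. Summaries
substitute ND records according to a policy — `zero` (default), `half_lod`
or `lod` — before computing mean/SD/min/max over all n samples; the
detection rate (percent of samples at or above the LOD) is independent of
the policy. The published summary tables this package targets are
numerically consistent with ND→0, which is why `zero` is the default; the
mean is monotone non-decreasing across the three policies, a property the
suite tests. SD is the sample (n−1) standard deviation. The MRL screen
compares the summarized mean against the maximum residue limit with a
strict inequality.

## Distribution fitting and selection

The probabilistic stage replaces a proprietary spreadsheet batch-fit.
Eleven candidate families are supported; continuous families are fit by
maximum likelihood through `scipy.stats`, with three conventions:

* the lognormal is the 3-parameter form with a free location shift;
* bounded families (beta, uniform, triangular) are rescaled to the
  observed data range padded by 1% of the range on each side, which avoids
  likelihood singularities when observations sit on the boundary;
* the discrete geometric family (used for day-count variables such as
  exposure frequency) is fit by method of moments and sampled clipped to
  the physical support [1, 365].

Goodness of fit is scored three ways: the Anderson–Darling statistic
computed from the fitted CDF, a chi-square statistic on k = max(5, ⌊n/5⌋)
equiprobable cells of the probability-integral transform, and the
Kolmogorov–Smirnov distance. Selection minimizes the Anderson–Darling
statistic, breaking ties by chi-square and then by parameter count, and is
therefore invariant to candidate order up to those tie-breaks. Fits
require at least 15 observations (`InsufficientDataError` below that,
matching the study's refusal to fit a residue detected in only eight
samples) and non-degenerate variance. No attempt is made to reproduce the
spreadsheet tool's proprietary critical values or ranking weights.

## Monte Carlo propagation

Each model input — one concentration per chemical, plus DI, EF, ED, BW —
is a sampler: a fitted distribution, a censored mixture, an empirical
resample, or a fixed scalar. Concentration inputs built from data use the
detected values only for the parametric fit and mix it with the ND
substitute at the observed detection rate, which preserves both the
detection rate and the overall mean of censored data; chemicals with fewer
than 15 detects fall back to empirical resampling of the full column, and
all-ND chemicals are fixed at the substitute. Exposure-factor inputs are
fitted to the chronic-valid survey records.

Inputs are sampled independently — the study reports no correlation
structure, so none is induced; this is a documented limitation, since
rank-correlated inputs (e.g. DI with BW) would widen or narrow the output
distribution. Truncation: concentration draws are floored at 0, EF is
clipped to [1, 365] day/yr, and BW is floored at a tiny positive value as
a guard on the dose denominator. Output trials are never truncated, and
output distributions re-fit with the same selection machinery may carry
negative location shifts. Default iteration count is 10,000 with a
mandatory seed; identical seed and configuration give bitwise-identical
trial matrices. Every run also computes the deterministic chain from the
input means and checks that it falls between the lowest and highest
requested percentile (10th/90th by default) of each output.

## Sensitivity

Contribution to variance is the normalized squared Spearman rank
correlation between each input column and the output trials:
share_i = 100·ρ_i²/Σρ_j². This mirrors the convention of spreadsheet
Monte Carlo tools, keeps shares non-negative and summing to exactly 100,
and makes them invariant under strictly monotone transforms of any input.
Signed correlations are reported separately for tornado plots. Constant
inputs get share 0; if no input varies the decomposition is undefined and
an error is raised. Signed shares were rejected because they break the
Σ = 100 identity.

## Synthetic data

The generator emulates the study conditions so the whole chain is testable
without any deposited data.

**Concentrations.** Each chemical × source carries a target mean, SD,
range, detection rate and LOD taken from the published summary table, plus
a detected-value family (for plantation metals the families the study
itself reports: beta for Pb, Cd and As, normal for Cu, maximum extreme
value for Ni, lognormal for Zn; pesticides, for which no family is
published, use lognormal — the conventional choice for residue data).
Censoring is a structural mixture: exactly `round(rate·n)` samples are
detected (randomly placed), the rest are ND, so detection rates are
reproducible at any n. Detected-value moments are solved from the target
overall moments (mixture inversion: µ_d = µ/p,
σ_d² = (σ² − p(1−p)µ_d²)/p, with σ_d set to µ_d/2 when the printed SD is
too small to be consistent with the censoring mass); beta parameters come
from method of moments on the printed range. Detected draws are clipped
into [max(LOD, printed min), printed max] to keep detection semantics and
ranges physical; the clipping bias is far inside the 3-standard-error
fidelity band at the study's sample sizes, with one exception: the
published Cd row is internally inconsistent (mean below its own printed
LOD at the supermarket source), so the supermarket Cd mean generates high.
The plantation scenario, on which fidelity is asserted, is unaffected.

**Survey.** Chronic-valid respondents draw DI from a beta on
[0.05, 10] g/day with mean 1.37, EF as 52 + a geometric day count clipped
at 365 whose unclipped mean is solved numerically so the clipped mean is
exactly 145.7, ED from a lognormal with mean 5.93 yr floored at the
3-month inclusion boundary, and BW from a beta on [40, 100] kg with mean
64.81 — the families the study reports for these factors. The published
means fix the location of each factor but not its spread; the SDs
(DI 0.6 g/day, ED 4 yr, BW 10 kg) were chosen once as realistic for an
adult consumer population and so that the factors' relative variability is
consistent with the study's sensitivity ranking, in which exposure
frequency contributes about twice the variance share of daily intake.
Exactly `round(n·401/558)` records satisfy the chronic-consumer rule
(≥ 52 day/yr for ≥ 0.25 yr); the remainder are corrupted to fail it.

What the generator does *not* emulate: spatial structure across
plantations, inter-chemical correlation, reporting/recall error in the
questionnaire, and the analytical-chemistry error of the instruments.
Passing tests therefore show the pipeline's correctness under the study's
statistical structure, not robustness to those real-data features.

Under these defaults the plantation sensitivity ranking puts the As
concentration first (~48%) ahead of EF and DI: the 43% non-detection rate
makes the As input's variance larger than any survey factor's. The
supermarket scenario reproduces the published EF > DI > As ordering. In
both scenarios EF outranks DI and {EF, DI, As} is the top-3 set, which is
what the acceptance suite asserts.

## Numerical and reporting conventions

* Survey sample size n = u²·P(1−P)/E² is rounded half-up (the published
  worked example 384.16 → 384); a `ceil` flag provides the conservative
  convention.
* "Once a week" maps to 52 day/yr and "three months" to 0.25 yr, both
  boundaries inclusive.
* Empirical percentiles interpolate linearly between order statistics.
* Display rounding (4 decimals for HQ/HI, 2-significant-digit scientific
  notation for R) exists only in rendered `display` columns; every
  numeric column and every inter-stage hand-off stays at full precision,
  and a test asserts no rounded value feeds back into computation.
* All randomness flows through `numpy.random.Generator` seeded from the
  run configuration; pipeline runs over multiple sources derive per-source
  seeds by offsetting the configured seed.

## Problem sizes

The test suite exercises the chain at the study's own scales (n = 37 and
n = 80 samples, 558 survey respondents) with 10³–2×10⁴ Monte Carlo
iterations for property checks, 10⁵ draws for the variance-share oracle,
and 100 seeded replicates for family-selection consistency; the
convergence check contrasts 5×10⁴ against 10⁵ iterations. These sizes
give comfortable margins on every stochastic tolerance while keeping the
default run fast on a single CPU.

## Known limitations

* Independent sampling of inputs (no rank correlation), as noted above.
* The published pesticide HQs imply unrounded concentration means, so
  exact reproduction from the printed two-decimal summaries alone is
  impossible; deterministic reproductions are asserted within the 5%
  slack the printed rounding induces.
* The medicine-use setting (ADI scaled to 1% for medicinal consumption)
  and multi-food aggregate exposure are out of scope.
* The geometric family is fit by moments, not MLE, and its GOF statistics
  treat the CDF as if continuous; adequate for day-count screening, not
  for formal discrete inference.
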