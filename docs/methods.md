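# Methods

## MPN estimation

Each Quanti-Tray partitions a fixed volume of assay fluid into two well
classes (default preset `quanti_tray_2000`: 49 × 1.86 mL large wells
and 48 × 0.186 mL small wells, total 100.07 mL ≈ the 100 mL reference
volume). Under the standard serial-dilution assay model — organisms
Poisson-distributed in the fluid, wells seeded independently — the
number of positive wells per class is binomial with success probability
1 − e^(−λv). The per-tray concentration estimate is the maximizer of
the resulting log-likelihood, rescaled to MPN per 100 mL.

The score function is strictly decreasing in λ, so the MLE is the
unique root of the score equation. It is found with Brent's method on
the bracket [10⁻⁹, 10³] per mL (widened adaptively if a custom geometry
requires it) at relative tolerance 10⁻¹⁰ — deterministic, no seeds.
This reproduces the manufacturer's lookup table within rounding; the
table itself is not a dependency. A tray with zero positive wells
(non-detect) or all wells positive (over-range) has no interior
maximum and is returned as a censored status with no numeric MPN —
numeric substitution is deliberately left to the pipeline so that
estimation and censoring policy stay separate. With a single well
class the MLE reduces to the closed form −ln((n−p)/n)/v, which the
tests use as an exact oracle; two-class trays are checked against an
independent grid-search maximizer.

Confidence intervals are profile-likelihood sets
{λ : 2(ℓ(λ̂) − ℓ(λ)) ≤ χ²₁(level)}. They are asymmetric, respect the
positivity constraint, and degenerate to the MLE at level 0. Censored
trays admit only a one-sided bound and are rejected with an error
rather than returning a misleading two-sided interval.

## Dilution-series aggregation and censoring

Each sample is assayed at one to three fold-dilutions D of its assay
fluid (tray MPN × D estimates the undiluted concentration). The
aggregation rules, applied verbatim to however many dilutions were
assayed:

* all trays non-detect → value 0.5 × D_min, left-censored ("use the
  lowest diluted sample");
* all trays over-range → value 2419.6 × D_max, right-censored ("use
  the highest dilution");
* otherwise → arithmetic mean of mpn × D over the quantifiable trays,
  censored trays ignored.

The substitution constants (0.5, 2419.6) and every dilution scheme are
configuration, not code (`RunConfig`). Averaging is arithmetic on the
MPN scale by default — matching how multi-dilution concentrations were
averaged in the study this package replicates — with a `geometric`
switch for sensitivity analyses. Two degenerate patterns are handled
explicitly: a non-detect at a *lower* dilution than a quantifiable tray
is logically inconsistent but still follows the averaging rule, flagged
`nondetect_below_quantifiable`; a series mixing non-detects and
over-range trays with nothing quantifiable (essentially impossible
under any sane scheme) substitutes both limits, averages, and is
flagged `inconsistent_censoring`.

## Unit normalization

The aggregated value refers to 100 mL of undiluted assay fluid. Matrix
reporting units are reconstructed from the processing volumes:

| matrix | assay fluid | conversion to reporting unit |
|---|---|---|
| water (6 types) | the sample itself | identity, MPN/100 mL |
| latrine swab | 14 mL PBST eluate | × 14/100 → MPN/swab |
| produce | 500 mL PBST rinse | × 500/100 → MPN/serving |
| street food | 10 g in 90 mL water | × (100/100)/10 g → MPN/gram |
| soil | 10 g in 20 mL PBST | × (20/100)/10 g → MPN/gram |

All volumes are configurable per sample (`MatrixMetadata`). The soil
aliquot's own water content would enlarge the eluate; with no moisture
data collected, `soil_water_fraction` defaults to 0. Swab
concentrations below ~7 MPN/100 mL of eluate give negative log₁₀
values per swab (e.g. the substituted non-detect, 0.5 × 10 / 100 × 14
= 0.7/swab, log₁₀ ≈ −0.15); this is expected and preserved.

## Comparison statistics

Per-sample log₁₀ concentrations are summarized per (sample type ×
stratum) as mean, sample SD (a singleton stratum reports SD 0), and
percent positive (share not left-censored). Two-stratum contrasts are
fitted as `log10 ~ 1 + indicator` by OLS — the Gaussian identity-link
linear model, the only family consistent with reporting symmetric CIs
around mean differences — so the coefficient equals mean_A − mean_B
exactly and the 95% CI is ±1.96·SE (model-based SE; a Student-t
multiplier switch exists, differing by <2% of SE at the study's 40–50
samples per stratum). The model p-value is t-based, so for very small
strata a difference can have a z-based CI that just excludes zero
while p ≥ 0.05; at study-scale n the two agree. No multiple-testing
correction is applied, matching the analysis being replicated;
significance markers annotate 0.05/0.01/0.001 tiers. The soil
feces-proximity comparison runs both the pooled two-sample t-test and
the Wilcoxon rank-sum (Mann–Whitney) test with tie correction.

## Synthetic-study generator

Contamination is modeled per (sample type × stratum) as log₁₀-normal —
the minimal model consistent with stratum means/SDs of log₁₀ values —
with no spatial correlation. The packaged calibration
(`data/calibration.csv`) carries the observed overall and
per-category means/SDs of the 2017 Dhaka campaign in reporting units.
To simulate a sample, a true log₁₀ concentration is drawn, converted
back to assay-fluid concentration by inverting the unit normalization,
and each well at each dilution turns positive independently with
probability 1 − e^(−(λ/D)v) — exactly the model under which the MPN is
the MLE, with no overdispersion or inhibition. True values below the
scheme's band produce honest non-detects, exercising the left-censoring
rule. The overall-row SDs mix between- and within-neighborhood
variance; they are used where a single pooled stratum is simulated,
while the category rows drive the default neighborhood-level study (a
cell's profile is looked up neighborhood → category → overall).

Seeding: a study seed feeds `numpy.random.SeedSequence.spawn`, which
deterministically derives one child seed per sample in design order, so
any subset is reproducible and two runs with the same seed are
byte-identical.

What the generator does not emulate: spatial/temporal correlation
between nearby samples, within-tray overdispersion, matrix inhibition
and recovery efficiency, QC blanks, and covariates (turbidity,
chlorine). Passing recovery tests therefore demonstrate the internal
consistency of the estimation chain under the assay's own model, not
field accuracy of any real campaign.

## Validation scale and numerical choices

The recovery checks use 100 samples per sample type (matching the
10-neighborhood × 10-sample design cell count for one matrix): at the
drain-water calibration (mean 6.91, SD 0.92 log₁₀) the mean of 100
draws has a sampling SD of ~0.09 log₁₀, so the ±0.15 recovery
tolerance is a meaningful end-to-end check while the estimator's own
systematic error, measured at large n with the draw noise removed, is
below 0.02 log₁₀. Property suites cap hypothesis examples (≤60) and
oracle grids (~10³ points coarse + refinement) so the whole suite runs
in seconds. Default dilution schemes place each calibrated mean well
inside the quantifiable band (e.g. drain water: band 5.0–9.38 log₁₀
at dilutions 10⁵/10⁶ vs mean 6.91), keeping censoring fractions at the
few-percent level, as in the field data.

## Known limitations

* The per-gram/per-swab/per-serving conversion factors are
  reconstructed from the stated processing volumes; a study may have
  scaled differently (every factor is configurable, and ingesting a
  deposited dataset via `read_stata_samples` allows confirming them).
* One tray per dilution is assumed; replicate-tray designs are out of
  scope.
* Left-/right-censored samples carry substituted constants, so stratum
  means inherit the substitution convention rather than a likelihood
  treatment of censoring.
* Comparisons are unadjusted two-stratum contrasts; no mixed-effects
  or spatial modeling.
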