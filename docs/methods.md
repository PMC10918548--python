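# Methods

## Model

The analysis models a monthly indicator series `Y_t` (percent of that month's
opioid users) as segmented-linear with two interruptions:

```
Y_t = b0 + b1*t + b2*I1_t + b3*C1_t + b4*I2_t + b5*C2_t + e_t,   t = 1..n
```

with level indicators `I_k = [t >= m_k]` and post-interruption clocks
`C_k = max(0, t - (m_k - 1))`, so each clock equals 1 in its interruption
month.  On the default Jan 2016 - Dec 2020 grid the interruptions are months
29 (May 2018) and 50 (February 2020).  A single-interruption variant simply
omits the `I2`/`C2` columns; it is a configuration switch
(`interruption_months` with one entry, or `build_design(n, m1)`), not a
separate code path.

Estimation is the standard two-step rule: fit OLS; compute the Durbin-Watson
statistic `d = sum((e_t - e_{t-1})^2) / sum(e_t^2)` of the OLS residuals; if
serial correlation is significant at `alpha` (default 0.05), refit by exact
Gaussian maximum likelihood with stationary AR(1) errors.  The reported
Durbin-Watson always describes the OLS residuals (the conventional
presentation); an AR(1)-ML fit also carries its own residual statistic in
`dw_final`.

### Durbin-Watson significance

The test's null distribution depends on the design matrix, and no single
convention exists for a p-value.  The package uses a normal approximation
with the *exact* first two null moments of `d` given the design: with
`M = I - X(X'X)^{-1}X'` and `A` the differencing quadratic-form matrix,
`E[d] = tr(MA)/(n-k)` and
`Var[d] = 2*(tr((MA)^2) - tr(MA)^2/(n-k)) / ((n-k)(n-k+2))`, and a two-sided
normal p-value.  A Monte-Carlo option (`method="bootstrap"`, Gaussian errors
projected through `M`) is available as a cross-check; without a design the
cruder `N(2, 4/n)` reference is used.  At n = 60 with the 6-column design the
moment-based test selects OLS in about 97% of independent-noise simulations
at alpha 0.05, i.e. its size is close to nominal.

### AR(1) maximum likelihood

The exact stationary-AR(1) Gaussian likelihood is maximized by profiling:
for a candidate `rho`, the Prais-Winsten transform (first row scaled by
`sqrt(1-rho^2)`, subsequent rows quasi-differenced) makes the errors white;
`beta` and `sigma` then have closed-form GLS/ML solutions, leaving a
one-dimensional profile log-likelihood
`l(rho) = -n/2*(log(2*pi*sigma_hat^2) + 1) + 1/2*log(1 - rho^2)`
maximized by bounded L-BFGS-B from `rho = 0` on `[-0.99, 0.99]`.  Coefficient
covariance is the GLS covariance at `rho_hat` with the ML innovation
variance; p-values use the large-sample normal reference (the fit does not
adjust degrees of freedom for the estimated `rho`).  Tests verify the
implementation against `statsmodels` ARIMA(1,0,0)-with-exogenous exact MLE;
at n = 200 the estimator's well-known small-sample downward bias in `rho_hat`
is about 0.04 at `rho = 0.5` — a property of exact ML itself, reproduced by
the reference implementation.

Missing months are dropped listwise with a warning; retained rows keep their
true calendar `t`, so the design is never re-indexed.  Rank-deficient designs
raise an error naming the collinear columns.

## Indicators

All four indicators share the denominator: unique patients with at least one
catalog-opioid fill *starting* in the month (claims are dispensing events, so
a fill belongs to its start month; fills spanning into later months still
contribute drug exposure there, but do not place the patient in later
denominators).

- **High dose.** A patient is high-dose when the summed daily dose over all
  fills covering a day reaches the threshold (default 100 MME/day, boundary
  inclusive) on at least one day of the month.  Daily dose is
  `units_per_day * unit_strength_mg * mme_factor` summed over active fills.
  The maximum-over-days statistic is the stricter, widely used monitoring
  convention; a mean-over-covered-days variant is available by configuration.
- **Multiple providers.** At least 2 distinct prescriber ids among the
  month's fills, regardless of institution.
- **Overlap.** Per patient, days covered by >= 2 fills divided by days
  covered by >= 1 fill, with intervals clipped to the month; the monthly
  value is the mean of these ratios times 100.  Because period summaries of
  this indicator are sometimes presented instead as the share of patients
  with *any* overlapping day, both aggregations are computed
  (`overlap_value` / `overlap_alt_value`) and neither is asserted to be the
  other; the primary mode is configurable.
- **Naloxone.** Share of the month's opioid users with a naloxone record
  (reserved drug code `NALOXONE`) in the month — a proxy for overdose events.

Percentages in the series are exact (`100 * num / den`); presentation tables
round half-up to 2 decimals.

### MME conversion factors

The catalog ships CDC-2018-style defaults (morphine 1, oxycodone 1.5,
hydromorphone 4, hydrocodone 1, codeine 0.15, dihydrocodeine 0.25,
tapentadol 0.4).  For the two transdermal products the published factors are
per mcg/hr of labeled patch delivery (buprenorphine 12.6, fentanyl 2.4), so
patch strength is recorded in mcg/hr in the strength column.  The table is
data (`opioid_catalog.csv`), not code, and fully replaceable; oral morphine
must keep factor 1.

## Cohort selection

Retained patients have >= 1 diagnosis with an include prefix (default the
ICD-10 M chapter), none with an exclude prefix (default C, i.e. a cancer code
at any time in the window — the conservative reading, since claims do not
date diagnoses reliably), age >= 20 in the year of their first in-window
outpatient opioid fill (claims carry birth year only, so age is year
arithmetic), and >= 1 such fill.  Naloxone rows of retained patients are
carried alongside.  Morbidity classes within the M chapter are arthropathies
M00-M25, dorsopathies M40-M54, soft-tissue M60-M79, all else "others"; a
patient with codes in several classes is assigned by the lexicographically
first code — an arbitrary but deterministic tie-break.  MedAid and PVI
insurance are collapsed into one reporting stratum.

## Synthetic data

The generator defines the conditions under which the pipeline is validated.

**Series tier.** `simulate_series` draws `Y_t = X beta + e_t` with `e_t`
stationary Gaussian AR(1) (marginal SD `noise_sd`, autocorrelation
`ar1_rho`) — exactly the error structure the estimators assume.  Values are
not clipped to [0, 100]; configuration is rejected up front if the *mean*
leaves that range.  Defaults: 60 months, interruptions (29, 50), true
coefficients equal to the published two-interruption fits for the four
indicators, `noise_sd = 0.25` percentage points (chosen once to resemble the
observed monthly scatter of such series; the source tables report only
period SDs of 0.16-0.42 which include trend variation), `ar1_rho = 0`
(reported Durbin-Watson statistics for these outcomes are all near 2).

**Record tier.** `simulate_claims` emits a fresh monthly cohort of
`patients_per_month` (default 800) schema-valid adult outpatients with one
musculoskeletal diagnosis sampled from the class mix, demographics matching
the study totals (60.9% female; age groups 12.5/33.1/34.6/19.8%; 9.1%
MedAid-or-PVI).  Every patient gets a base opioid fill (< 50 MME/day) fully
inside the month; with the month's model-implied probability a patient is
independently made high-dose (a 120 MME/day fill), multi-provider (a second
fill from a distinct prescriber on disjoint days), overlapping (an exact
duplicate of the base fill, overlap ratio 1) or a naloxone recipient.  The
templates are arranged so flags never interact (a duplicated base fill peaks
at 90 MME/day, below the threshold), which makes the planted monthly
numerators exact ground truth — tests require the indicator stage to recover
them bit-for-bit.  Residual noise at this tier is binomial, not Gaussian:
SD approx `sqrt(p*(100-p)/n)` percentage points, and flags are independent
across patients and indicators.

What the record tier deliberately does **not** emulate: drug-level market
shares, within-patient persistence across months (each month's cohort is
fresh), seasonality, dose titration, or correlated misuse behaviors.
Passing tests therefore demonstrate the pipeline's arithmetic and the
estimators' statistical properties under the assumed model — not
epidemiological realism of Korean prescribing.

A `decoys_per_month` option adds under-age, cancer-diagnosed and
inpatient-only patients that cohort selection must remove, to exercise the
exclusion rules end to end.

## Reporting

Period summaries default to the study calendar: months 1-28, 29-49, 50-60
(the interruption months belong to the post periods).  The outcome block
reports both the mean (SD) of monthly percentages and the pooled
numerator/denominator proportion per period, because the two presentations
need not agree and sources mix them.  The coefficient table prints estimates
to 4 decimals and p-values in the `.48` / `.004` / `<.001` style.  Figures
are written as SVG (with hashed ids salted and date metadata stripped, so
output is byte-stable for fixed inputs) plus a PNG sibling.
`run_pipeline` writes a manifest (config echo, seed, library versions,
output list) sufficient to reproduce every output bit-identically; on a
stage failure, partial outputs are removed and the error names the stage.

## Problem sizes used in validation

Simulation-based checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances while keeping the default suite quick: CI
coverage over 1,000 simulated 60-month series (OLS path, per-coefficient
coverage required within [90%, 99%]); AR(1) `rho` recovery over 500
replicates at n = 200 (mean within 0.05 of 0.5); series-tier coefficient
recovery over 500 replicates at `rho` in {0, 0.3} (bias within 2 Monte-Carlo
SEs); record-level sign recovery of an injected level change equal to 3
binomial residual SDs over 200 replicates at 150 patients/month (correct
sign required in >= 95%).

## Known limitations

- AR(1)-ML inference is large-sample; at n = 60 its p-values are mildly
  anti-conservative compared to a degrees-of-freedom-adjusted reference.
- The Durbin-Watson normal approximation is a choice, not a canon; the
  bootstrap option exists for sensitivity analysis.
- The overlap indicator's two aggregations can differ materially when
  overlaps are short; consumers must pick one explicitly.
- Age arithmetic by calendar year misclassifies patients around birthdays by
  at most one year, as is inherent to birth-year-only claims.
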