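# Methods

## The problem

Spontaneous reporting systems such as the FDA Adverse Event Reporting System
(FAERS) collect voluntary reports of suspected adverse drug reactions. They
have no denominator — nobody knows how many patients took each drug — so the
standard screening approach is *disproportionality analysis*: for a target
drug and an adverse-event preferred term (PT), compare the event's share of
the drug's reports with its share of all other drugs' reports. `faersig`
implements that screen for FAERS-style quarterly extracts, together with the
surrounding ETL (parsing, deduplication, primary-suspect selection),
descriptive tabulation, and a Weibull model of time to onset. The worked
application is pegvaliase (Palynziq), an enzyme-substitution therapy for
phenylketonuria whose immunogenic adverse events — arthralgia, injection-site
reactions, hypersensitivity — dominate its post-market safety profile.

## Data model and ETL

FAERS quarterly ASCII files are dollar-sign-delimited with one header line;
the reader also accepts comma/tab dialects. Files are decoded as Latin-1
(FAERS is not UTF-8 clean). Closed vocabularies are enforced at parse time:
drug role codes {PS, SS, C, I} and outcome codes {DE, LT, HO, DS, CA, RI,
OT}; rows violating them are rejected and counted, so that rows read plus
rows rejected always equals the data lines in the file.

**Partial dates.** FAERS dates may be `YYYYMMDD`, `YYYYMM` or `YYYY`. They
are stored as a timestamp floored to the period start *plus a precision tag*
(`day`/`month`/`year`). Any computation that needs day precision (time to
onset) treats non-day dates as missing. Silent imputation would bias onset
estimates downward toward period starts, so it is never done.

**Ages** are converted to years via the unit code (DEC×10, YR×1, MON÷12,
WK÷52.14, DY÷365.25); unknown codes become missing rather than guessed.

**Deduplication** follows the FDA-recommended rule: among reports sharing a
CASEID keep the one with the largest FDA receipt date, breaking ties by the
largest numeric PRIMARYID. The implementation is a stable two-key sort and
is idempotent and invariant to input row order. Non-numeric PRIMARYIDs fall
back to width-padded lexicographic comparison with a warning.

**Case selection.** Target-drug reports are found by case-insensitive
substring match of user-supplied keywords (e.g. `pegvaliase`, `palynziq`)
against both the verbatim drug name and the active-ingredient field —
FAERS drug names are free text with dose suffixes, so exact matching is not
viable. Reports are kept when the target drug appears with the requested
role (primary suspect by default), the receipt date falls in the configured
window (receipt date, because quarterly files are organized by receipt), and
the report carries at least one reaction PT. "Monotherapy" is read as *the
target is the only primary-suspect drug in the report*; an optional strict
mode additionally drops reports carrying any secondary-suspect drug. Every
filter stage logs its surviving count to a provenance table.

**PT normalization**: trim, collapse internal whitespace, title-case. A PT
repeated within one report counts once (report-level counting throughout).
PT→SOC mapping is supplied by the user as a two-column table (MedDRA is
licensed and cannot be bundled); lookups are normalized, conflicts are
fatal, and unknown PTs map to the sentinel `Unmapped`.

## The disproportionality screen

Each PT occurring in the target case set is cross-classified against the
background (all other deduplicated reports in the window):

|              | target PT | other PTs |
|--------------|-----------|-----------|
| target drug  | a         | b         |
| other drugs  | c         | d         |

Four statistics are computed per table (n = a+b+c+d):

- **ROR** = ad/(bc), with 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
- **PRR** = [a/(a+b)] / [c/(c+d)], with the Pearson χ² =
  (ad−bc)²·n / [(a+b)(c+d)(a+c)(b+d)] (no continuity correction).
- **IC** = log₂[a·n/((a+c)(a+b))], the information component, with lower
  bound IC025 = IC − 2·√V(IC). V(IC) is the delta-method variance
  (1/ln 2)²·(1/a − 1/(a+b) − 1/(a+c) + 1/n); in the rare finite-sample
  corner where that expression is non-positive it is clamped at zero. The
  full Bayesian BCPNN posterior interval is deliberately out of scope; the
  variance function is isolated so it could be swapped.
- **EBGM**, here the *crude* observed/expected relative reporting ratio
  a·n/((a+c)(a+b)) — algebraically 2^IC, an identity the implementation
  preserves exactly by computing both from one ratio — with lower bound
  EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)). No gamma-Poisson
  (MGPS) shrinkage is applied; the statistic implemented is exactly the
  crude form above, and the name EBGM is kept only because that is the
  label this quantity carries in the screening-rule literature.

**Joint screening criteria** (a PT is a signal only if all four hold):
ROR 95% lower bound > 1 and a ≥ 3; PRR ≥ 2 and χ² ≥ 4 and a ≥ 3;
IC025 > 0; EBGM05 > 2. Inequalities are applied exactly as written — strict
for the interval bounds, non-strict for PRR/χ²/N — and the boundary cases
are pinned by tests. All thresholds are configurable (`CriteriaConfig`).

**Zero cells.** A table with any zero cell gets the Haldane–Anscombe
correction (+0.5 to all four cells, that table only) and a `corrected`
flag; the raw case count still drives the N ≥ 3 criteria. With the
correction disabled, zero-cell tables yield NaN statistics and can never be
flagged.

**Ranking** is deterministic: descending case count, then descending ROR,
then PT lexicographically. Ranking by strength orders by ROR first.

The model/results surface (`DisproportionalityAnalysis(...).fit() →
DisproportionalityResults`) computes all PTs vectorized; the scalar
functions (`ror`, `prr`, `bcpnn_ic`, `ebgm`) implement the identical
formulas one table at a time and the two paths are tested against each
other and against an independent rational-arithmetic evaluation.

## Descriptives and time to onset

The characteristics table reports counts and percentages for sex, age bins,
report year, reporter occupation, country, outcomes and onset bins.
Denominators: total reports for every block except outcomes, where the
denominator is total outcome *entries* (a report can carry several outcome
codes; one with none contributes a single "Not Specified" entry) — this is
how published FAERS characteristics tables make the outcome block sum to
100%. Percentages round half-up to one decimal. Two age-bin presets exist
(<18 / 18–45 / 45–65 / ≥65 for the characteristics table; <18 / 18–65 / ≥65
for subgroup runs); both are configuration.

**Time to onset** is event date minus the earliest *day-precise* therapy
start date of the target drug's rows in the report. Reports with a partial
or missing date on either side, or a negative difference, are excluded and
counted as missing. Bins are closed day intervals (0–30, 31–60, …,
181–360, >360) plus missing; bins + missing conserve the report total.
The median and quartiles use linear interpolation (the inclusive
convention); the min–max range is reported alongside and labelled as a
range, not an IQR.

**Weibull shape-parameter (WSP) analysis.** Usable onsets are fitted to a
two-parameter Weibull distribution by maximum likelihood: the shape β
solves the standard profile score equation by bracketed root finding
(Brent, bracket grown geometrically), and the scale α follows in closed
form. 95% CIs come from the observed Fisher information on (ln β, ln α)
(central-difference Hessian of the negative log-likelihood, normal
approximation, exponentiated), which keeps bounds positive. Zero-day
onsets are shifted +0.5 day for fitting only (positive support); binning
uses raw integers. Classification by the CI of β: entirely below 1 →
"early failure" (decreasing hazard, events cluster after treatment start);
containing 1 → "random" (constant hazard, as for drug-unrelated events);
entirely above 1 → "wear-out". Fewer than 10 usable onsets or degenerate
(all-equal) data raise an error rather than returning a sham fit. The fit
is cross-checked in tests against `scipy.stats.weibull_min.fit(floc=0)`.

**Subgroups** (sex, age bins, reporter class) rerun the full screen within
each stratum with the background restricted to the *same* stratum, so
stratum RORs are internally comparable; per-stratum onset medians and
quartiles are reported. Strata partition the non-missing reports, so case
counts conserve.

## Synthetic data and what it does (not) show

The generator emulates the statistical structure the pipeline assumes:
cases with a primary-suspect drug (target share 10% by default, so the
default and study-scale corpora have target case counts in the thousands,
the scale of a single-drug pharmacovigilance study); a Zipf-weighted PT
vocabulary (rank j gets background per-report mention probability
min(3·w_j, 0.9) with w_j ∝ 1/(j+1)); planted drug–PT associations at
relative risks 2, 5 and 10 on mid-frequency PTs (report-level planting:
target reports mention a planted PT with probability min(ρ·p_bg, 0.9),
matching the 2×2 counting); ~5% duplicate cases with 1–2 extra report
versions whose receipt dates and report ids increase, so the true survivor
is known; early-failure Weibull onsets (β = 0.6, α = 27 days, median ≈ 15
days) with half of therapy dates missing and a few percent of event dates
degraded to month/year precision; and categorical demographics (sex, age,
reporter occupation, country, outcomes) with realistic missingness.
Randomness is Philox counter-based with an independent spawned substream
per concern, so adding fields never perturbs earlier draws and a fixed
seed yields byte-identical files.

What passing tests on this corpus *show*: the dedup rule, case assembly,
contingency counting, the four statistics, the joint criteria, and the
Weibull machinery are implemented correctly and recover planted truth.
What they *do not* show: real FAERS marginal frequencies, free-text drug
name noise beyond simple variants, correlated PT co-reporting, reporting
waves, or MedDRA versioning effects — conclusions about real corpora still
require the real download.

### Calibration results and a structural limit

Validation runs the real pipeline on generated corpora: planted-signal
sensitivity at n = 50,000 cases over 50 seeds, a 200-seed null calibration
at n = 20,000 (the null corpus size is a package choice: large enough that
PT counts are informative, small enough to keep hundreds of replicates
cheap), exact dedup checks over 20 seeds, and Weibull recovery at 1,000
onsets. Relative risks 5 and 10 are recovered by the joint flag at
sensitivity ≈ 1, and the null flags essentially nothing (the joint screen
is conservative).

Relative risk 2, however, is *structurally undetectable* by the joint
screen at high sensitivity, for any sample size: with target share s, the
population value of the crude EBGM at relative risk ρ is ρ/(1 + s(ρ−1)),
which for ρ = 2 is below 2 for every s > 0 — so the strict criterion
EBGM05 > 2 fails asymptotically — and the population PRR sits exactly on
the non-strict threshold PRR ≥ 2. This is a property of the screening
rules, not of the implementation; the ROR criterion alone detects ρ = 2
with high power. The validation suite asserts sensitivity per planted ρ
and the ρ = 2 assertion documents this limit by failing.

## Numerical choices

- Contingency cells are held as floats to keep (ad−bc)²·n out of integer
  overflow at large n.
- Statistics are computed vectorized with divide-by-zero silenced and then
  masked; undefined tables (zero cells with correction off) are NaN and
  excluded from ranking.
- Percentages use decimal half-up rounding (banker's rounding would turn
  41.15 into 41.1).
- CSV output uses RFC-4180 quoting and 12-significant-digit floats, so
  numeric tables round-trip to working precision.
- Weibull root bracketing starts at [1e-3, 1] and doubles the upper end
  until the score changes sign (capped at 1e3).

## Problem sizes used in validation

Formula-oracle comparisons use 1,000 random tables with cells in
[1, 10⁵]; signal recovery uses 50 corpora of 50,000 cases; the null uses
200 corpora of 20,000 cases; dedup checks use 20 corpora of 2,000 cases at
25% duplication; Weibull recovery uses 1,000 draws per shape. These sizes
are the package's chosen validation conditions and are stated here so the
reported rates can be interpreted.

## Known limitations

- The EBGM implemented is the crude relative reporting ratio; corpora
  dominated by very small counts would benefit from real MGPS shrinkage,
  which is out of scope.
- The BCPNN interval is a delta-method approximation, not the posterior.
- The Weibull fit ignores censoring; reports without onset dates are
  simply excluded, which biases toward reported-onset events.
- No multiple-comparison adjustment is applied across PTs (none is used in
  the screening-rule tradition implemented here); the joint criteria are
  the only false-positive control.
- Country normalization covers only the handful of codes common in this
  kind of corpus; everything else passes through verbatim.
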