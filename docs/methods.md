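# Methods

## Data model and cleaning

The unit of analysis is the safety report. Quarterly "$"-delimited ASCII
tables are mapped onto typed records: DEMO (one row per report version:
CASEID, PRIMARYID, FDA receipt date, event date, sex, age with unit code,
reporter occupation, country), DRUG (one row per reported drug with a role
code — PS primary suspect, SS secondary suspect, C concomitant, I
interacting), REAC (one MedDRA preferred term per row), THER (therapy
start dates linked to drug rows), OUTC (outcome codes) and DELE (caseids
nullified by the FDA). The dialect has no quoting; an embedded "$" is
replaced by a space on write and logged. All identifiers are strings.

Cleaning order is fixed: DELE removal first, then deduplication over the
full database, then drug screening. For each CASEID the surviving version
is the one with the largest FDA_DT, ties broken by the largest PRIMARYID
(numeric comparison when all-digit, else lexicographic). An unparseable
FDA_DT sorts lowest, so versions with valid dates are preferred.
Deduplication is idempotent and its output is sorted by CASEID. Whether
deletion should precede or follow deduplication is not observable from
the published flow; removing deleted cases first is marginally more
conservative (a deleted case can never resurrect an older version) and is
what the pipeline tests pin down.

Target-drug screening is case-insensitive substring matching on DRUGNAME
and PROD_AI. The role restriction applies to the matching drug row
itself: a report whose only keyword hit is a concomitant row is not a
target when the screen demands primary-suspect rows. Screening is
monotone in the keyword list.

## Counting unit

All four statistics are computed over unique (report, normalized PT)
pairs: PT strings are trimmed, whitespace-collapsed and case-folded for
matching (FAERS capitalization drifts across quarters), and a report
listing the same PT twice contributes one pair. A report with several PTs
contributes to cell a (its target PT) and to cell b (its other PTs)
simultaneously; n is the total number of pairs. This matches the
convention in which a cohort of ~46k reports yields ~146k "cases" of
adverse events. Because the choice is not unambiguous, a `unit="report"`
switch computes the report-level table instead (margins a+b and c+d are
then report counts). Pair-level is the default everywhere.

## Statistics

With cells a, b, c, d and n = a+b+c+d:

- ROR = ad/bc; 95% CI = exp(ln ROR ± 1.96·s), s = √(1/a+1/b+1/c+1/d).
- PRR = a(c+d)/(c(a+b)); χ² is the uncorrected Pearson statistic
  (ad−bc)²·n/((a+b)(c+d)(a+c)(b+d)) — no Yates continuity correction.
- IC = log₂(a·n/((a+c)(a+b))).
- EBGM = a·n/((a+c)(a+b)); its 95% interval reuses the ROR's log-scale
  SE, as the source tables print it. No Gamma-mixture (DuMouchel)
  shrinkage is applied: this "EBGM" is the plain observed/expected pair
  ratio, and consequently IC = log₂(EBGM) exactly and
  ln(EBGM95/EBGM05) = ln(ROR hi/lo). Both identities are enforced by
  tests and hold in the published tables this implementation mirrors
  (e.g. an EBGM of 232.15 printed beside an IC of 7.86 = log₂ 232.15).

Criteria: ROR — a ≥ 3 and CI lower bound > 1 (strict); PRR — a ≥ 3,
PRR ≥ 2, χ² ≥ 4 (both inclusive); BCPNN — IC025 > 0 (strict); MGPS —
EBGM05 > 2 (strict). A "signal" PT passes all four. Intensity grades on
IC025: (0, 1.5] weak (+), (1.5, 3.0] medium (++), > 3.0 high (+++).

### The IC interval

The source prints "E(IC) ± 2·V(IC)^0.5" without defining V(IC), and its
printed IC025 values are not consistent with any single simple variance
(the implied SD does not scale as 1/√a across rows). Two documented
approximations are therefore provided and the printed intervals are not
promised to be reproduced:

- `mcmc-dirichlet` (default): each cell probability gets an independent
  Gamma(cell + 0.5, 1) posterior — jointly Dirichlet after normalisation,
  a Jeffreys-style prior — IC is evaluated on each draw, and the
  2.5/97.5 percentiles of 100,000 seeded draws form the interval. Valid
  for zero cells.
- `bate1998`: the closed-form moment approximation of the original BCPNN
  publication, with priors α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1 and γ chosen
  so the prior IC expectation is zero.

Both agree closely for large cells (tested); the Monte-Carlo interval is
wider for tiny ones. Heavy batch runs (the recovery studies) use
`bate1998` since it is deterministic and a few hundred times faster.

### Zero cells

Any zero cell makes the ROR/PRR/EBGM formulas undefined. The default is
to report the statistics as undefined (NaN plus a reason), which fails
every criterion — never a crash, never a silent fill. An optional
Haldane–Anscombe flag adds 0.5 to all four cells instead (applied to all
printed statistics; the a ≥ 3 case-count conditions always use the raw
a). The a ≥ 3 filter makes zero-a irrelevant in ranked output, but b, c
or d can still be zero in small strata.

### Monotonicity caveat

ROR and PRR increase strictly in a (b, c, d held fixed). EBGM and IC are
monotone only while the signal cell does not dominate its own margins:
on degenerate tables such as (1,1,1,6) → (2,1,1,6) the observed/expected
ratio dips because the increment inflates both margins faster than the
numerator. For b, c ≥ a + 1 — the spontaneous-reporting regime — strict
monotonicity is provable and property-tested.

## Time to onset

TTO = event date − earliest exact therapy-start date among the report's
*matching* (target-drug) THER rows, in whole days. Exclusions, in
precedence order: missing event date, missing start dates, partial
(6-digit YYYYMM or 4-digit YYYY) dates on either side, negative
intervals. Day 0 is included (event on the start day). Partial dates are
excluded rather than imputed by default — imputing month starts biases
onsets downward — with an `impute_partial="month_start"` option. Onset
bins are closed on both ends (0–30, 31–60, …, 181–360, >360) and,
together with the exclusion bucket, partition the cohort exactly.
Summaries use linear-interpolation (type-7) quantiles. Bin percentages
use the whole cohort as denominator, which is how a descriptive table
whose "missing or outlier" row carries ~80% reads.

## Subgroups

Sex imbalance: among the target drug's pairs only, each PT gets the 2×2
(female with PT, female other PTs; male with PT, male other PTs), with
unknown sex excluded from both margins. The F:M ROR uses the same
log-scale CI as above; direction is "female" when the lower bound
exceeds 1 and "male" when the upper bound is below 1, in both cases
requiring at least 3 combined cases. Swapping the sex labels inverts the
ROR exactly (property-tested).

Age strata: <18, 18–64, ≥65 and unknown, with 18.0 and 65.0 assigned to
the older bin. Ages are normalised to years (YR ×1, DEC ×10, MON ÷12,
WK ÷52.18, DY ÷365.25, HR ÷8766); missing or invalid values go to the
unknown stratum, which is analysed like any other rather than dropped.
Stratified tables rebuild the contingency cells entirely within each
stratum — the comparator is the rest of the database *in the same
stratum* — so age is not confounded with drug exposure.

## Ranking and aggregation

Ranked output keeps PTs passing all four criteria with a strictly
greater than the case-count floor (default 30), sorts by EBGM05
descending — the most conservative of the four statistics — with ties
broken by larger a then PT name, and truncates to the top N (default
100). SOC aggregation needs a user-supplied two-column PT→SOC TSV
(MedDRA is licensed and not bundled; the synthetic generator emits its
own map); unmapped PTs land in an explicit UNMAPPED class so totals are
conserved.

## Synthetic data generator

The generator emulates the mechanics of a spontaneous-reporting database
rather than its clinical content. Per base report: one primary-suspect
drug drawn from a configurable distribution, a Poisson number of distinct
concomitant drugs (mean 0.5) with non-PS roles; each (report, PT) event
is an independent Bernoulli draw at the PT's baseline probability,
multiplied by the planted ratio (capped at 1) when the report's PS drug
carries a planted signal. Reporting artefacts are layered on top, with
defaults shaped like the public database's descriptive tables: sex
F/M/unknown 0.47/0.32/0.21; age strata 4/18/6/72% (<18/18–64/≥65/
unknown); reporters predominantly consumers; country mix dominated by
one territory; outcome-code marginals of the usual order (hospitalisation
0.28, death 0.10, …). Onset days are lognormal (median 150 d, σ = 1.5
log-units — wide, like real onset distributions), 2% of reports get a
negative interval, event/start dates go missing at 0.5/0.3 and partial
(YYYYMM) at 0.1. Duplicates copy a case under a new PRIMARYID with FDA_DT
either bumped upward or left equal (both tie kinds emitted, so both
halves of the dedup rule are observable); DELE lists a configurable
fraction of caseids. One PCG64 stream keyed by the config seed makes
output byte-identical across runs.

`expected_counts` returns the analytic expectation of each planted
signal's 2×2 cells before duplicate/deletion injection, serving as the
independent oracle for the analysis stages.

What the generator does **not** emulate: drug co-prescription structure,
MedDRA hierarchy beyond a flat PT→SOC map, country- or time-varying
reporting patterns, schema drift across quarters, and correlated events
within a report. Passing tests therefore demonstrate correctness of the
counting and statistics, not robustness to real-world coding noise.

### Recovery study conditions

The planted-ratio recovery configuration (20,000 reports, ratios 5 and
20) has to contend with a structural property of pair-level
disproportionality: the planted cell a inflates both of its margins, so

EBGM/ρ = (β_s(1+ε) + T) / ((1+ε)(ρβ_s + T)),

where ρ is the planted report-level ratio, β_s the signal PT's baseline,
ε = s(ρ−1) with s the target drug's PS share, and T the expected
background events per report. EBGM approaches ρ only when s is small
(little margin inflation) and T large (the signal PT is a small part of
the drug's row margin). The study conditions fix s = 0.26%, β_s = 0.9/ρ
(so the elevated probability is 0.9 and the signal cell expectation is
~47), and 500 null PTs at baseline 0.1 (T = 50), giving an expected
EBGM/ρ of 0.94–0.98. Duplicates (5%) and deletions (2%) stay on, since
the cleaning stages run as part of the measured pipeline. Under these
conditions the recovered EBGM falls within ±20% of the planted ratio in
≥90% of seeds and the planted PT passes all four criteria while null PTs
essentially never do; tests and the acceptance script run 20 seeds per
ratio, about 4 s each on one CPU.

## Numerical conventions

- Displayed values round half-up to 2 decimals (decimal arithmetic, not
  banker's rounding); internal computation keeps full precision.
- The normal quantile is 1.959963984540054; checks against tables printed
  with 1.96 use tolerances far above the 4th-decimal difference.
- Deterministic ordering everywhere: signal tables by EBGM05 desc / a
  desc / PT name, undefined rows last; dedup output by CASEID.
- Malformed input lines are skipped and counted, never guessed at;
  orphan REAC rows (no surviving DEMO version) are dropped and logged;
  the run log's funnel (raw − deleted − duplicates = cohort) is asserted
  at run time.

## Limitations

- The published database-wide results (46,316 reports, 461 signal PTs,
  median onset 159 d, 51 sex-imbalanced PTs) require the full
  multi-gigabyte quarterly archive and are out of desk-scale scope; what
  is reproduced are the internally recomputable quantities and the
  method's behaviour under controlled ground truth.
- "EBGM" here is the unshrunk observed/expected ratio as printed in the
  tables this package mirrors; a true Gamma-Poisson shrinker would pull
  small-count PTs toward 1 and rank them lower.
- The printed IC intervals are approximated, not reproduced (see above).
- Drug screening is substring-based; no RxNorm/fuzzy normalisation.
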