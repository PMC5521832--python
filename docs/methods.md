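# Methods

## Data model

The package operates on four relational CSV tables shaped like the public
JADER extract: `demo` (case id, sex, decade age band, report year),
`drug` (case id, non-proprietary drug name, role code, start/end dates),
`reac` (case id, 8-digit MedDRA preferred-term code and name, onset date,
outcome) and `hist` (case id, primary-disease/history term). Loading
joins them into one `CaseReport` per case id. Three conventions matter:

- **The report is the counting unit.** Case counts, totals and non-case
  counts are counts of reports, never of drug–event pairs. A report with
  several matching event terms is one case; a report naming a drug twice
  is one exposure.
- **Only `suspected` drug records are exposures** for the
  disproportionality and time-to-onset statistics. A report carrying a
  study drug only as concomitant is treated as non-exposed for that drug.
  Rule mining, by contrast, deliberately uses drugs of *all* role codes:
  risk-factor antecedents are typically co-medications.
- **Partial dates are first class.** ISO dates may be truncated to year
  or month; every date carries its precision and downstream statistics
  decide exclusion (time-to-onset uses day-precision dates only).

Orphan child rows (case ids absent from `demo`) are kept on stub reports
and counted, so every loaded row remains auditable. Duplicate demo rows
keep the first occurrence and are counted. Drug names are normalized by
whitespace collapsing and case folding, with an optional alias map for
combination-product naming.

Event cases are defined by standardized MedDRA queries: the packaged
thromboembolism definition is the union of three SMQs — embolic and
thrombotic events, arterial (20000082), vessel type unspecified and mixed
(20000083), and venous (20000084) — 317 preferred terms in total, shipped
as `datasets/smq_thromboembolism.csv`.

## Disproportionality

From the 2×2 table (a, b, c, d; n = a+b+c+d):

- ROR = ad/bc, CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- PRR = [a/(a+b)] / [c/(c+d)].
- χ² with Yates continuity correction,
  n(|ad−bc| − n/2)² / [(a+b)(c+d)(a+c)(b+d)], clamped to 0 when the
  correction overshoots.

Three conventions here are **reproduction-driven** choices, fixed by
replaying the published CEP–TE screen from its printed count margins:

1. **PRR confidence interval.** The CI uses the ROR-style standard error
   √(1/a+1/b+1/c+1/d). The textbook PRR standard error
   √(1/a − 1/(a+b) + 1/c − 1/(c+d)) gives (15.1–16.3) for the combined
   row where the published table prints (13.8–17.6); the ROR-style SE
   reproduces every printed PRR interval to ±0.1. Users needing the
   asymptotically correct PRR variance should treat these intervals as
   what they are: the replayed table's convention.
2. **Continuity correction.** The uncorrected χ² for the combined row is
   ≈ 10,060.6 against a printed 10,046.1; the Yates-corrected statistic
   matches to 0.1. Correction is therefore always applied.
3. **Stratified comparator.** Age-stratified rows take a and b from the
   stratum but c and d from the entire remaining database (all ages).
   Replaying the printed 10–19 and 40–49 rows confirms this; a
   within-stratum comparator gives visibly different values.

One further textual conflict is worth recording: the PRR is sometimes
written [a/(a+c)] / [b/(b+d)] with rows and columns transposed relative
to the layout used here. Under this package's table layout that formula
does not reproduce the published values; the row-proportion form
[a/(a+b)] / [c/(c+d)] does, and is the only one offered.

Signal criteria: ROR — at least 2 cases and lower CI bound > 1;
PRR — at least 3 cases, PRR ≥ 2, χ² ≥ 4. Zero cells are suppressed with
a marker (mirroring published dashes) rather than Haldane-corrected:
fewer than 2 cases suppresses the ROR, fewer than 3 suppresses PRR and
χ², and b = 0 (no non-case) suppresses everything. Report output rounds
half-up to 1 decimal; internal values are never rounded.

## Time-to-onset

Durations are onset minus the earliest day-precision start date of the
specific suspected drug ("first prescription" is read as the first record
of that drug, not of any drug). Records with missing dates,
month/year-precision dates, or negative differences are excluded and
tallied by reason. Quartiles interpolate order statistics at the p(n+1)
positions, which yields the fractional quartiles (e.g. 8.8 days) that
small published samples show.

The Weibull fit maximises the complete-data likelihood in
(log α, log β) — an SRS contains only reports where the event occurred,
so there is no censoring model. Start values come from log-moments
(Var(log T) = π²/(6β²)); BFGS with analytic gradient, gradient tolerance
1e-8. Zero durations are shifted to 0.5 day (the Weibull support is
positive); shift counts are reported. 95% CIs are Wald intervals on the
log-parameter scale from the numerically evaluated observed information.
Profile-likelihood intervals would differ slightly in small samples;
published tables fitted with commercial software may therefore not match
the third decimal even on identical data. Degenerate samples (all values
equal, or n below a configurable minimum of 10) return quartiles only,
flagged indeterminate.

Hazard classification: early failure if β < 1 and the CI excludes 1,
wear-out if β > 1 and the CI excludes 1, random otherwise; unconverged
fits are indeterminate. Subgroup tables (indication × drug, indications
mapped from history terms) suppress the Weibull fit below the minimum n
and omit empty cells.

A faithful re-analysis of the original database's onset table is not
possible from printed summaries alone — it requires the raw reports.
The time-to-onset stage is therefore validated by parameter recovery on
synthetic data (truth inside both 95% CIs in ≥ 90% of seeded
replicates), closed-form quantile checks, CI-coverage simulation, an
independent-MLE cross-check, and hazard classification of published
(β, CI) triplets.

## Association-rule mining

A from-scratch level-wise apriori: candidate k-itemsets join (k−1)-sets
sharing a (k−1)-prefix in lexicographic order, are pruned by downward
closure, and counted by intersecting per-item transaction-id sets.
Downward closure of the output is asserted on every run, and the miner
is tested for exact equivalence with exhaustive powerset enumeration on
randomized transaction sets. Rules are restricted to the event-flag
consequent, filtered at min confidence, and sorted by support desc,
confidence desc, then lexicographic antecedent (the tie-break within
equal support is otherwise arbitrary). Metrics are computed in exact
rational arithmetic; display rounds support to 6 decimals and
confidence/lift to 2 (half-up). A confidence-1 rule's lift is exactly
n_total/n_rhs — with 14,593 event transactions in 338,224 that is 23.18.
Age-band items are config-gated and off by default; top published rules
contain none.

## Synthetic generator

`simulate_tables` draws, per report: independent per-drug exposure
(Bernoulli at the configured prevalence), an event flag with odds
(background odds × product of the odds multipliers of exposed drugs),
age bands (a background mix skewed to older patients, overridable per
drug for its exposed reports), one suspected background drug from a
small pool plus a ~30% chance of a concomitant record, history terms at
configured prevalences, and dates uniform over the study window with a
configurable fraction truncated to month/year precision (defaults 7%
and 3%) to exercise partial-date exclusion. Event cases exposed to a
study drug receive onset = start + round(Weibull(α, β)) days. The
manifest records configured parameters and realized counts; tests verify
that manifest counts equal recounts from the emitted CSVs and that a
fixed seed gives byte-identical files.

Under independent exposure the population odds ratio of a drug equals
its configured multiplier, so recovery is a closed-loop test: with
multiplier 1 and 200,000 reports, the 95% ROR CI covers 1 in ≥ 90% of
50 seeds. Default sizes used by the test-suite simulations (200,000
reports for null-effect coverage, 1,000 durations for Weibull recovery,
2,000 tables for CI calibration) keep Monte-Carlo error well below the
asserted bands.

What the generator does **not** emulate: drug co-prescription
correlation structure, duplicate or follow-up reports, reporting-year
drift, realistic event-term co-occurrence, or under-reporting biases.
Passing closed-loop tests therefore demonstrates the statistics are
computed correctly under the stated sampling model, not that the model
captures real reporting behaviour.

## Planted transactions

`plant_transactions` lays out a transaction database with exact
co-occurrence counts: the first n_te transactions carry the event item,
and each planted antecedent occupies its own disjoint block (n_with_te
ids inside the event region). Antecedents that are subsets of one
another are rejected, since they would contaminate each other's counts.
This is how full-size (338,224-transaction) worked examples are
reconstructed for the miner without any external data.

## Known limitations

- Disproportionality measures quantify reporting, not risk; no
  confounder adjustment (e.g. logistic regression) is offered.
- The PRR interval convention is reproduction-driven (above).
- Weibull CIs are Wald-on-log-scale; no interval censoring, truncation
  or competing risks.
- The loader targets the package's own CSV dialect, not the PMDA's
  Shift-JIS file layout; MedDRA navigation is flat PT-set membership.
- Duplicate-report detection across case ids is out of scope.
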