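# Methods

This note records how `trialaudit` defines, computes and validates its
measurements, and which choices were genuinely open.

## Cohort screening

Trials enter the analysis cohort when they completed within a configured
window (default 2009–2017), carry a registry status "considered as
complete", and are interventional. The completeness status set defaults to
{Completed, Terminated, Suspended, Unknown status} and is a configuration
knob, since registries revise their status vocabularies. Filters apply in
a fixed order — completion window, status, study type, optionally a
present start date (used for prospective-registration samples) — and each
excluded trial is tallied under the *first* reason that fires, so the
exclusion tally always conserves the input count. Trials with no
completion date cannot be placed in the window and are excluded under the
window reason, with a log entry.

Cross-registrations (the same trial registered in both ClinicalTrials.gov
and DRKS) are detected symmetrically: a pair exists when either record's
secondary identifiers contain the other's registration number after
normalization (uppercase, internal whitespace/hyphens stripped). The
ClinicalTrials.gov member is retained because it carries the structured
summary-results field used downstream; the union of both records'
references is merged onto it, and it remembers the partner identifier so
either number counts as evidence of linkage in publications. Chains longer
than two records collapse to one retained record with a warning.

## Partial dates

Registry dates arrive at day, month or year resolution and the resolution
is tracked, never imputed away. The prospective-registration rule is
month-granular: a trial is prospectively registered when the registration
month is the same as or earlier than the start month; if either date lacks
a month the trial leaves that denominator. For "within N years" arithmetic,
month-resolved dates are imputed to the first of the month *before* adding
whole years, and the comparison is ≤ at day resolution — a deterministic,
conservative convention. February 29 anniversaries land on February 28 in
non-leap years.

## Denominator discipline

Every metric flag is ternary (True / False / absent). Absent means the
trial is outside that metric's sample definition: no PubMed identifier for
the abstract metric, no retrieved full text for the full-text metric, no
DOI or PMID for the registry-link metric, no DOI or dated open-access
record for the OA metric, dissertations for every publication-based
metric, and an unclosed follow-up window for the timeliness metrics.
Aggregation counts only present flags in denominators, so "absent" can
never deflate a rate.

Timeliness follow-up windows close against two observation dates: the
registry download date (default 2022-11-01) for the summary-results route
and the manual publication search date for the publication route; the
either-route metric requires both windows closed. The publication search
date defaults to 2021-09-01 — an assumption, since search campaigns for
multi-year cohorts have per-tranche cutoffs that are configuration, not
derivable from the records. Both dates are run-config keys.

EUCTR summary-results rates are pass-through from EU Trials Tracker
history rows — validated (reported ≤ due), with the percentage recomputed
from counts when absent — and are never recomputed from trial records,
mirroring how such tracker data is sourced. When several tracker sponsor
names correspond to one center, the sponsor with the most trials
represents it; ties break lexicographically and are logged.

## Open access

Each publication's Unpaywall-style locations map to candidate statuses
(publisher-hosted in an OA journal → gold; publisher-hosted with an open
license → hybrid; repository-hosted → green; publisher-hosted otherwise →
bronze) and the publication receives the highest candidate in the
descending hierarchy gold > hybrid > green > bronze; no locations means
closed. Classification is order-insensitive in the evidence list. A
precomputed status column, when supplied, is accepted verbatim.

## Confidence intervals

Grouped proportions carry two-sided Wilson score intervals with continuity
correction (Newcombe 1998), z = 1.959964 at the default 95% level, with
the boundary fixes L = 0 at x = 0 and U = 1 at x = n and the radicand
clamped at 0 against floating-point dips at the boundaries. The z value is
frozen to six decimals so integer-percent rounding is platform-stable; any
other confidence level derives z from the normal quantile. Percentages are
printed as integers rounded half away from zero (half-even rounding cannot
be distinguished from dashboard-style printed values; the choice is
asserted in tests). Zero denominators yield an explicitly undefined
proportion rather than an error-free zero, and such groups are emitted
with the undefined marker so report views can show gaps.

Cross-center spread is summarised by the median, sample standard deviation
(n−1), minimum and maximum of per-center point estimates; centers with
empty denominators are excluded and counted separately. A single defined
center yields SD 0 (degenerate, flagged by the count).

## Synthetic cohorts

The generator samples truth first — every behavior flag and delay per
trial — and then renders records that realize those flags, so pipeline
tallies must equal truth tallies *exactly*, not statistically; the
end-to-end tests assert precisely that, per metric and per denominator
rule. Sampling uses Python's seeded Mersenne Twister over integers only,
so output is byte-identical across platforms for a fixed seed.

Default conditions emulate a national cohort of UMC-led trials:
35 centers × 80 trials, 78% registered in ClinicalTrials.gov, completion
years 2009–2017, prospective registration 55%, publication rate 65%, TRN
in abstract 38% / full text 60%, registry link 58%, summary results 8%
(ctgov) and 3% (DRKS), 46% of publications closed access, and a 3%
cross-registration rate. The timeliness knob is conditional —
P(earliest report within 24 months | the trial reports at all) = 0.62 —
which implies a marginal 2-year either-route rate near 41%. Report delays
are sampled in month ranges (2–23, 25–59, 61–84 months) chosen to keep
realized dates on the intended side of the 2- and 5-year deadlines
regardless of day-level imputation. ClinicalTrials.gov-style records carry
day-resolved dates and DRKS-style records month-resolved dates, so both
branches of the month comparison are exercised. Denominator conditions
(missing start date, PMID, full text, DOI, open-access date; dissertations)
are independently toggleable rates, and unrelated registry identifiers are
planted as decoys to exercise detector precision.

What the generator does *not* emulate: real registry prose (texts are
templates sufficient for the identifier scanner), multi-center trials
(each synthetic trial has one lead center), registry status churn, or
biased missingness (all toggles are independent Bernoulli draws). Passing
tests therefore demonstrate correctness of the measurement logic under
clean conditions, not robustness to the messiness of real registry
exports — the dialect readers and the configurable keyword/pattern
inventories are the intended adaptation points for that.

## Problem sizes

The test suite runs the exact-truth check at 35 × 80 trials and the
statistical demonstration at ~3,000 trials (35 × 86), the scale at which
each configured rate is recovered within its binomial 95% sampling
interval; both finish in seconds on one core. The exhaustive interval-
containment sweep covers every x for all n ≤ 500.

## Known limitations

- Full-text matching is plain substring over extracted text; PDF
  conversion is out of scope.
- The registry-link metric matches normalized DOIs and exact PMIDs only;
  titles are not fuzzy-matched.
- "Due" for registry summary-results rates is every cohort trial; no
  grace-period modeling for ClinicalTrials.gov or DRKS (the EU 12-month
  deadline enters only through the tracker pass-through).
- The dashboard is a static site: the three views and absolute-number
  tooltips are preserved, interactivity beyond that is not.
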