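# trialaudit

`trialaudit` audits registered clinical trials against transparency
practices and builds institutional dashboards from the results. It is
aimed at meta-researchers and research-integrity teams who track, at the
level of a university medical center (UMC), whether the trials an
institution leads are registered and reported responsibly.

## What it measures

Starting from flat-file registry exports (ClinicalTrials.gov and DRKS
dialects), publication metadata with abstracts and full texts, Unpaywall-
style open-access evidence and EU Trials Tracker history, the pipeline
screens trials into an analysis cohort (completion window, completeness
status, interventional design; cross-registered ctgov/DRKS pairs collapsed
to one trial) and assesses each trial against seven practices:

1. **Prospective registration** — registered in the same or a previous
   month to the trial start date (month-granular comparison of partial
   dates).
2. **TRN in the abstract** and 3. **TRN in the full text** — the trial
   registration number detected by registry-specific regular expressions
   (`NCT\d{8}`, `DRKS\d{8}`, `ISRCTN\d{8}`, EudraCT `\d{4}-\d{6}-\d{2}`,
   tolerant of case and a single space/hyphen).
4. **Publication link in the registry** — the earliest results publication
   linked from the registration by DOI or PMID.
5. **Summary results in the registry** — the structured results field
   (ClinicalTrials.gov) or keyword-detected results reports (DRKS).
6. **Timely reporting** — results disseminated within 2 (or 5) years of
   completion, by summary results, manuscript publication, or either
   route, counting only trials whose follow-up window closed before the
   observation dates.
7. **Open access** — one status per publication by the descending
   hierarchy gold > hybrid > green > bronze > closed.

Each flag is ternary: trials outside a metric's sample definition are
*absent* from its denominator, never counted as failures.

Grouped results are reported as proportions x/n with two-sided 95%
confidence intervals from the **Wilson score interval with continuity
correction** (Newcombe), with z = 1.959964:

    L = max(0, [2x + z² − 1 − z·√(z² − 2 − 1/n + 4p(nq + 1))] / (2(n + z²)))
    U = min(1, [2x + z² + 1 + z·√(z² + 2 − 1/n + 4p(nq − 1))] / (2(n + z²)))

with L = 0 at x = 0 and U = 1 at x = n. This interval stays inside [0, 1]
and remains informative at the tiny denominators and extreme rates that
per-UMC breakdowns produce.

A seeded synthetic-cohort generator (`trialaudit.synthetic`) emulates all
input record shapes with configurable per-behavior rates and an explicit
truth table, so the whole pipeline is testable end to end without any
registry downloads.

## Worked example

```
$ python examples/01_wilson_intervals.py
   0/44    =   0%  (95% CI 0% to 10%)  DRKS trials started 2006-2008, prospectively registered
  19/24    =  79%  (95% CI 57% to 92%)  DRKS trials started 2017, prospectively registered
  58/178   =  33%  (95% CI 26% to 40%)  ClinicalTrials.gov trials started 2006, prospectively registered
 714/1895  =  38%  (95% CI 35% to 40%)  publications reporting the TRN in the abstract
```

The 0/44 row shows why the continuity-corrected interval matters: zero
observed events still leave a 10-point upper bound of uncertainty, where
a naive interval would collapse to a point.

An end-to-end audit of a synthetic cohort (`examples/03_synthetic_audit.py`)
prints each practice's pooled tally next to the generator's truth, e.g.:

```
screened 410 records -> 400 trials (10 cross-registrations removed)

practice                           pipeline      truth
prospective_registration            222/384    222/384
trn_in_abstract                      94/241     94/241
...
```

The two columns agree exactly because every pipeline stage is
deterministic; denominators differ per practice because each metric only
counts the trials its sample definition covers.

The same pipeline is scriptable from a shell:

```
trialaudit simulate --seed 7 --out fixtures/
trialaudit audit --trials fixtures/ctgov_trials.jsonl --trials fixtures/drks_trials.jsonl \
    --publications fixtures/publications.jsonl --links fixtures/links.csv \
    --oa fixtures/oa.jsonl --tracker fixtures/tracker.csv --out audit/
trialaudit report --dataset audit/dashboard.json --out site/
```

`report` renders a self-contained static site with the three dashboard
views (all centers pooled, comparison between centers, one page per
center); absolute numbers appear as hover tooltips, and every percentage
shown is drawn from the tidy `summaries.csv` export.

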