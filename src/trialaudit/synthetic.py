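"""Seeded synthetic trial cohorts with known per-behavior truth.

The generator emulates the record shapes the audit consumes — registry
exports in the ClinicalTrials.gov and DRKS dialects, publication metadata
with abstract/full texts, Unpaywall-style open-access evidence, the
trial↔publication mapping, and EU Trials Tracker history — with every
transparency behavior sampled first as an explicit truth flag and the
records then rendered to realize it. Because every downstream classifier
is deterministic, pipeline tallies on a synthetic cohort must equal the
truth-table tallies exactly, which is what the end-to-end tests assert.

Truth flags are derived here with the generator's own plain-tuple date
arithmetic, independent of the metric implementations they validate.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .metrics import DEFAULT_CONTEXT, FollowupContext, HostType, OAEvidence, OARecord, OAStatus
from .partialdates import PartialDate
from .registry_io import CTGOV, DRKS, EuctrTrackerRow, RegistryReference, TrialRecord
from .trn_linkage import Publication

#: Per-behavior sampling rates; the defaults approximate the pooled rates
#: observed across German university medical centers (prospective ≈ 55%,
#: TRN in abstract ≈ 38%, registry link ≈ 58%, ClinicalTrials.gov summary
#: results ≈ 8%, ≈ 54% of publications openly accessible).
DEFAULT_RATES: dict[str, float] = {
    "prospective": 0.55,
    "has_publication": 0.65,
    "dissertation": 0.03,
    "trn_in_abstract": 0.38,
    "trn_in_full_text": 0.60,
    "link_in_registry": 0.58,
    "summary_results_ctgov": 0.08,
    "summary_results_drks": 0.03,
    "cross_registration": 0.03,
    # P(earliest report within 24 months | the trial reports at all); with
    # has_publication 0.65 this yields a marginal 2-year either-route rate
    # near 41%
    "timely_report_2y": 0.62,
    # P(report within 5 years | report later than 2 years)
    "late_within_5y": 0.75,
    # denominator toggles
    "missing_start_date": 0.03,
    "missing_pmid": 0.05,
    "missing_full_text": 0.15,
    "missing_doi": 0.04,
    "missing_unpaywall_date": 0.03,
    # probability of planting an unrelated registry id in a text
    "decoy_trn": 0.10,
}

#: Mix of open-access statuses among assessed publications (closed ≈ 46%).
DEFAULT_OA_MIX: dict[str, float] = {
    "gold": 0.18,
    "hybrid": 0.08,
    "green": 0.12,
    "bronze": 0.16,
    "closed": 0.46,
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_umcs: int = 35
    trials_per_umc: int = 80
    registry_mix: float = 0.78  # fraction of trials registered in ClinicalTrials.gov
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    oa_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OA_MIX))
    completion_window: tuple[int, int] = (2009, 2017)

    def __post_init__(self) -> None:
        rates = dict(DEFAULT_RATES)
        rates.update(self.rates)
        self.rates = rates
        for key, p in self.rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate {key!r} out of [0, 1]: {p}")
        if not 0.0 <= self.registry_mix <= 1.0:
            raise ValueError(f"registry_mix out of [0, 1]: {self.registry_mix}")
        total = sum(self.oa_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"oa_mix must sum to 1, got {total}")
        lo, hi = self.completion_window
        if not (1990 <= lo <= hi <= 2100):
            raise ValueError(f"implausible completion window: {self.completion_window}")


def paper_shaped_config(seed: int = 0, n_umcs: int = 35, trials_per_umc: int = 86) -> SyntheticConfig:
    """A configuration whose pooled rates mirror the audited cohort.

    At ~3,000 trials the pipeline recovers each configured rate within its
    binomial sampling error, which makes for a realistic demonstration run.
    """
    return SyntheticConfig(seed=seed, n_umcs=n_umcs, trials_per_umc=trials_per_umc)


@dataclass
class SyntheticCohort:
    """Everything one audit run consumes, plus the generator's truth table."""

    trials: list[TrialRecord]  # pre-dedup; includes cross-registration partners
    publications: dict[str, Publication]
    links: dict[str, str]  # trn -> pub_id (earliest results publication)
    oa_records: dict[str, OARecord]
    tracker: list[EuctrTrackerRow]
    truth: pd.DataFrame  # one row per unique trial, post-dedup
    config: SyntheticConfig
    ctx: FollowupContext


# ---------------------------------------------------------------------------
# Generator-side date arithmetic (plain tuples; independent of partialdates)


def _add_months(year: int, month: int, k: int) -> tuple[int, int]:
    idx = year * 12 + (month - 1) + k
    return idx // 12, idx % 12 + 1


ABSTRACT_TEMPLATE = (
    "Background: a randomised controlled study at a university medical center. "
    "{TRN_SLOT}Outcomes were assessed at follow-up. "
    "Conclusion: findings warrant confirmation."
)
FULL_TEXT_TEMPLATE = (
    "Introduction. This report describes an interventional study.\n"
    "Methods. {TRN_SLOT}Participants were randomised; analysis was prespecified.\n"
    "Results. Outcomes are reported per protocol.\nDiscussion. See registry entry."
)

TRN_STYLES = ("plain", "spaced", "lowercase")


def embed_trn(template: str, trn: str, style: str = "plain") -> tuple[str, int]:
    """Render a text containing exactly one TRN in the requested style.

    The template must carry a single ``{TRN_SLOT}`` placeholder. Returns
    the text and the character offset of the embedded TRN (the offset a
    detector should report).
    """
    if style not in TRN_STYLES:
        raise ValueError(f"unknown style: {style!r}")
    if style == "spaced":
        head = trn.rstrip("0123456789")
        rendered = f"{head} {trn[len(head):]}"
    elif style == "lowercase":
        rendered = trn.lower()
    else:
        rendered = trn
    fragment = f"The trial was registered ({rendered}). "
    offset_in_fragment = fragment.index(rendered)
    before, _, _after = template.partition("{TRN_SLOT}")
    text = template.replace("{TRN_SLOT}", fragment)
    return text, len(before) + offset_in_fragment


def generate_cohort(
    config: SyntheticConfig, ctx: FollowupContext = DEFAULT_CONTEXT
) -> SyntheticCohort:
    """Generate one seeded cohort; byte-identical for a fixed seed."""
    rng = random.Random(config.seed)
    rates = config.rates
    oa_labels = list(config.oa_mix)
    oa_weights = [config.oa_mix[k] for k in oa_labels]
    download = ctx.registry_download_date.as_date()
    search = ctx.publication_search_date.as_date()

    trials: list[TrialRecord] = []
    publications: dict[str, Publication] = {}
    links: dict[str, str] = {}
    oa_records: dict[str, OARecord] = {}
    truth_rows: list[dict] = []

    nct_counter = 10000000
    drks_counter = 20000000
    pub_counter = 1
    pmid_counter = 30000000

    for umc_idx in range(config.n_umcs):
        umc = f"UMC {umc_idx + 1:02d}"
        for _ in range(config.trials_per_umc):
            is_ctgov = rng.random() < config.registry_mix
            registry = CTGOV if is_ctgov else DRKS
            if is_ctgov:
                trn = f"NCT{nct_counter:08d}"
                nct_counter += 1
            else:
                trn = f"DRKS{drks_counter:08d}"
                drks_counter += 1

            # --- dates -------------------------------------------------
            comp_year = rng.randint(*config.completion_window)
            comp_month = rng.randint(1, 12)
            comp_day = rng.randint(1, 28) if is_ctgov else None
            duration = rng.randint(12, 36)  # months from start to completion
            start_year, start_month = _add_months(comp_year, comp_month, -duration)
            start_day = rng.randint(1, 28) if is_ctgov else None

            missing_start = rng.random() < rates["missing_start_date"]
            prospective_flag = rng.random() < rates["prospective"]
            if prospective_flag:
                reg_year, reg_month = _add_months(start_year, start_month, -rng.randint(0, 2))
            else:
                reg_year, reg_month = _add_months(start_year, start_month, rng.randint(1, 6))
            reg_day = rng.randint(1, 28) if is_ctgov else None

            # --- reporting behaviors ------------------------------------
            summary_rate = rates["summary_results_ctgov" if is_ctgov else "summary_results_drks"]
            has_summary = rng.random() < summary_rate
            has_pub = rng.random() < rates["has_publication"]
            timely_flag = rng.random() < rates["timely_report_2y"]
            # delay (months after completion) of the earliest report; kept
            # clear of the day-resolution boundary so realized dates match
            # the sampled flag regardless of imputation
            if timely_flag:
                delay = rng.randint(2, 23)
            elif rng.random() < rates["late_within_5y"]:
                delay = rng.randint(25, 59)
            else:
                delay = rng.randint(61, 84)

            summary_date: Optional[PartialDate] = None
            if has_summary:
                sy, sm = _add_months(comp_year, comp_month, delay + rng.randint(0, 2))
                summary_date = PartialDate(sy, sm, rng.randint(1, 28))

            references: list[RegistryReference] = []
            if has_summary and not is_ctgov:
                references.append(
                    RegistryReference(title="Ergebnisbericht (PDF)", is_results_reference=True)
                )

            # --- publication --------------------------------------------
            pub: Optional[Publication] = None
            dissertation = False
            has_pmid = has_doi = has_full_text = False
            abstract_flag = fulltext_flag = link_flag = None
            oa_label: Optional[str] = None
            has_unpaywall_date = False
            pub_year_month_day: Optional[tuple[int, int, int]] = None
            cross_flag = is_ctgov and rng.random() < rates["cross_registration"]
            partner_trn = f"DRKS{drks_counter:08d}" if cross_flag else None
            if cross_flag:
                drks_counter += 1

            if has_pub:
                pub_id = f"pub{pub_counter:06d}"
                pub_counter += 1
                py, pm = _add_months(comp_year, comp_month, delay)
                pd_day = rng.randint(1, 28)
                pub_year_month_day = (py, pm, pd_day)
                dissertation = rng.random() < rates["dissertation"]
                has_pmid = rng.random() >= rates["missing_pmid"]
                has_doi = rng.random() >= rates["missing_doi"]
                has_full_text = rng.random() >= rates["missing_full_text"]
                pmid = str(pmid_counter) if has_pmid else None
                pmid_counter += 1
                doi = f"10.5555/synth.{pub_id}" if has_doi else None

                abstract_flag = None if (dissertation or not has_pmid) else (
                    rng.random() < rates["trn_in_abstract"]
                )
                fulltext_flag = None if (dissertation or not has_full_text) else (
                    rng.random() < rates["trn_in_full_text"]
                )
                link_flag = None if (dissertation or not (has_pmid or has_doi)) else (
                    rng.random() < rates["link_in_registry"]
                )

                # the embedded identifier may be the cross-registered one:
                # either id evidences the same study
                text_trn = partner_trn if (cross_flag and rng.random() < 0.5) else trn
                abstract = ABSTRACT_TEMPLATE.replace("{TRN_SLOT}", "")
                if abstract_flag:
                    abstract, _ = embed_trn(ABSTRACT_TEMPLATE, text_trn, rng.choice(TRN_STYLES))
                full_text = None
                if has_full_text:
                    full_text = FULL_TEXT_TEMPLATE.replace("{TRN_SLOT}", "")
                    if fulltext_flag:
                        full_text, _ = embed_trn(
                            FULL_TEXT_TEMPLATE, text_trn, rng.choice(TRN_STYLES)
                        )
                if rng.random() < rates["decoy_trn"]:
                    decoy = f"ISRCTN{rng.randint(0, 99999999):08d}"
                    abstract += f" (companion study {decoy})"

                pub = Publication(
                    pub_id=pub_id,
                    doi=doi,
                    pmid=pmid,
                    publication_date=PartialDate(py, pm, pd_day),
                    is_dissertation=dissertation,
                    abstract=abstract,
                    full_text=full_text,
                )
                publications[pub_id] = pub
                links[trn] = pub_id

                if link_flag:
                    references.append(
                        RegistryReference(
                            title=f"Results article for {trn}", doi=doi, pmid=pmid
                        )
                    )
                elif rng.random() < 0.3:
                    # background reference that must not count as a link
                    references.append(
                        RegistryReference(title="Protocol paper", doi=f"10.5555/proto.{pub_id}")
                    )

                # --- open access ---------------------------------------
                if not dissertation and has_doi:
                    has_unpaywall_date = rng.random() >= rates["missing_unpaywall_date"]
                    oa_label = rng.choices(oa_labels, weights=oa_weights, k=1)[0]
                    oa_records[pub_id] = OARecord(
                        pub_id=pub_id,
                        unpaywall_date=(
                            PartialDate(2022, 11, 1) if has_unpaywall_date else None
                        ),
                        evidence=_evidence_for(oa_label, rng),
                    )

            # --- registry records ---------------------------------------
            secondary_ids: list[str] = []
            partner_secondary: list[str] = []
            if cross_flag:
                side = rng.choice(("ctgov", "drks", "both"))
                if side in ("ctgov", "both"):
                    secondary_ids.append(partner_trn)
                if side in ("drks", "both"):
                    partner_secondary.append(trn)

            trial = TrialRecord(
                trn=trn,
                registry=registry,
                lead_umcs=[umc],
                start_date=None
                if missing_start
                else PartialDate(start_year, start_month, start_day),
                completion_date=PartialDate(comp_year, comp_month, comp_day),
                registration_date=PartialDate(reg_year, reg_month, reg_day),
                status="Completed",
                study_type="interventional",
                has_structured_summary_results=has_summary and is_ctgov,
                summary_results_date=summary_date,
                references=references,
                secondary_ids=secondary_ids,
            )
            trials.append(trial)
            if cross_flag:
                trials.append(
                    TrialRecord(
                        trn=partner_trn,
                        registry=DRKS,
                        lead_umcs=[umc],
                        start_date=None
                        if missing_start
                        else PartialDate(start_year, start_month),
                        completion_date=PartialDate(comp_year, comp_month),
                        registration_date=PartialDate(reg_year, reg_month),
                        status="Completed",
                        study_type="interventional",
                        references=[],
                        secondary_ids=partner_secondary,
                    )
                )

            # --- truth row ----------------------------------------------
            truth_rows.append(
                _truth_row(
                    trn=trn,
                    umc=umc,
                    registry=registry,
                    start=(None if missing_start else (start_year, start_month)),
                    completion=(comp_year, comp_month, comp_day),
                    prospective=None if missing_start else prospective_flag,
                    has_summary=has_summary,
                    summary_date=summary_date,
                    pub_date=pub_year_month_day,
                    dissertation=dissertation,
                    abstract_flag=abstract_flag,
                    fulltext_flag=fulltext_flag,
                    link_flag=link_flag,
                    oa_label=oa_label if has_unpaywall_date else None,
                    download=download,
                    search=search,
                    cross_registered=cross_flag,
                )
            )

    tracker = _make_tracker(config, rng)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        trials=trials,
        publications=publications,
        links=links,
        oa_records=oa_records,
        tracker=tracker,
        truth=truth,
        config=config,
        ctx=ctx,
    )


def _evidence_for(label: str, rng: random.Random) -> list[OAEvidence]:
    """Unpaywall-style locations whose hierarchy classification is `label`."""
    gold = OAEvidence(HostType.PUBLISHER, journal_is_oa=True, license_open=True)
    hybrid = OAEvidence(HostType.PUBLISHER, journal_is_oa=False, license_open=True)
    green = OAEvidence(HostType.REPOSITORY)
    bronze = OAEvidence(HostType.PUBLISHER, journal_is_oa=False, license_open=False)
    base = {
        "gold": [gold],
        "hybrid": [hybrid],
        "green": [green],
        "bronze": [bronze],
        "closed": [],
    }[label]
    # lower-ranked extra locations must not change the classification
    extras = {"gold": [hybrid, green, bronze], "hybrid": [green, bronze], "green": [], "bronze": [], "closed": []}
    evidence = list(base)
    for ev in extras[label]:
        if rng.random() < 0.3:
            evidence.append(ev)
    rng.shuffle(evidence)
    return evidence


def _truth_row(
    *,
    trn,
    umc,
    registry,
    start,
    completion,
    prospective,
    has_summary,
    summary_date,
    pub_date,
    dissertation,
    abstract_flag,
    fulltext_flag,
    link_flag,
    oa_label,
    download: _dt.date,
    search: _dt.date,
    cross_registered: bool,
) -> dict:
    comp_year, comp_month, comp_day = completion
    comp_date = _dt.date(comp_year, comp_month, comp_day or 1)
    summary_tuple = (
        (summary_date.year, summary_date.month, summary_date.day) if summary_date else None
    )
    pub_counts = pub_date is not None and not dissertation

    def deadline(years: int) -> _dt.date:
        return _dt.date(comp_date.year + years, comp_date.month, comp_date.day)

    def timely(route: str, years: int) -> Optional[bool]:
        dl = deadline(years)
        if route == "summary":
            if dl > download:
                return None
            return has_summary and summary_tuple is not None and _dt.date(*summary_tuple) <= dl
        if route == "publication":
            if dl > search:
                return None
            return pub_counts and _dt.date(*pub_date) <= dl
        if dl > download or dl > search:
            return None
        s = has_summary and summary_tuple is not None and _dt.date(*summary_tuple) <= dl
        p = pub_counts and _dt.date(*pub_date) <= dl
        return s or p

    both = (abstract_flag and fulltext_flag) if (abstract_flag is not None and fulltext_flag is not None) else None
    return {
        "trn": trn,
        "umc": umc,
        "registry": registry,
        "start_year": start[0] if start else None,
        "completion_year": comp_year,
        "publication_year": pub_date[0] if pub_counts else None,
        "prospective_registration": prospective,
        "summary_results": has_summary,
        "trn_in_abstract": abstract_flag,
        "trn_in_full_text": fulltext_flag,
        "trn_in_both": both,
        "publication_link_in_registry": link_flag,
        "oa_status": oa_label,
        "open_access": (oa_label != "closed") if oa_label is not None else None,
        "timely_2y_summary": timely("summary", 2),
        "timely_2y_publication": timely("publication", 2),
        "timely_2y_either": timely("either", 2),
        "timely_5y_summary": timely("summary", 5),
        "timely_5y_publication": timely("publication", 5),
        "timely_5y_either": timely("either", 5),
        "cross_registered": cross_registered,
    }


def _make_tracker(config: SyntheticConfig, rng: random.Random) -> list[EuctrTrackerRow]:
    rows = []
    for umc_idx in range(config.n_umcs):
        sponsor = f"UMC {umc_idx + 1:02d} (EUCTR sponsor)"
        due = rng.randint(5, 30)
        early = rng.randint(0, due)
        late = rng.randint(early, due)
        for (year, month), reported in (((2020, 12), early), ((2022, 10), late)):
            rows.append(
                EuctrTrackerRow(
                    sponsor_name=sponsor,
                    snapshot_date=PartialDate(year, month, 1),
                    total_due=due,
                    total_reported=reported,
                    percent_reported=100.0 * reported / due,
                )
            )
    return rows


# ---------------------------------------------------------------------------
# Fixture export in the dialects the readers consume


def write_cohort(cohort: SyntheticCohort, outdir: Path | str) -> dict[str, Path]:
    """Write a cohort as the flat files the audit pipeline reads.

    Emits ``ctgov_trials.jsonl`` / ``drks_trials.jsonl`` (dialect column
    names), ``publications.jsonl`` with full texts as referenced plain-text
    files, ``links.csv``, ``oa.jsonl``, ``tracker.csv`` and ``truth.csv``.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "fulltext").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    from .registry_io import DIALECT_PROFILES

    for registry, fname in ((CTGOV, "ctgov_trials.jsonl"), (DRKS, "drks_trials.jsonl")):
        prof = DIALECT_PROFILES[registry]
        lines = []
        for t in cohort.trials:
            if t.registry != registry:
                continue
            row = {
                prof["trn"]: t.trn,
                prof["registration_date"]: t.registration_date.isoformat() if t.registration_date else None,
                prof["start_date"]: t.start_date.isoformat() if t.start_date else None,
                prof["completion_date"]: t.completion_date.isoformat() if t.completion_date else None,
                prof["status"]: t.status,
                prof["study_type"]: t.study_type,
                prof["lead_umcs"]: t.lead_umcs,
                prof["has_structured_summary_results"]: t.has_structured_summary_results,
                prof["summary_results_date"]: t.summary_results_date.isoformat() if t.summary_results_date else None,
                prof["references"]: [
                    {
                        "title": r.title,
                        "doi": r.doi,
                        "pmid": r.pmid,
                        "is_results_reference": r.is_results_reference,
                    }
                    for r in t.references
                ],
                prof["secondary_ids"]: t.secondary_ids,
            }
            lines.append(json.dumps(row, ensure_ascii=False))
        path = outdir / fname
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        paths[registry] = path

    pub_lines = []
    for pub in cohort.publications.values():
        ft_path = None
        if pub.full_text is not None:
            ft_path = f"fulltext/{pub.pub_id}.txt"
            (outdir / ft_path).write_text(pub.full_text, encoding="utf-8")
        pub_lines.append(
            json.dumps(
                {
                    "pub_id": pub.pub_id,
                    "doi": pub.doi,
                    "pmid": pub.pmid,
                    "publication_date": pub.publication_date.isoformat() if pub.publication_date else None,
                    "is_dissertation": pub.is_dissertation,
                    "abstract_text": pub.abstract,
                    "full_text_path": ft_path,
                },
                ensure_ascii=False,
            )
        )
    paths["publications"] = outdir / "publications.jsonl"
    paths["publications"].write_text("\n".join(pub_lines) + ("\n" if pub_lines else ""), encoding="utf-8")

    links_df = pd.DataFrame(sorted(cohort.links.items()), columns=["trn", "pub_id"])
    paths["links"] = outdir / "links.csv"
    links_df.to_csv(paths["links"], index=False)

    oa_lines = []
    for rec in cohort.oa_records.values():
        oa_lines.append(
            json.dumps(
                {
                    "pub_id": rec.pub_id,
                    "unpaywall_date": rec.unpaywall_date.isoformat() if rec.unpaywall_date else None,
                    "locations": [
                        {
                            "host_type": ev.host_type.value,
                            "journal_is_oa": ev.journal_is_oa,
                            "license_open": ev.license_open,
                        }
                        for ev in rec.evidence
                    ],
                }
            )
        )
    paths["oa"] = outdir / "oa.jsonl"
    paths["oa"].write_text("\n".join(oa_lines) + ("\n" if oa_lines else ""), encoding="utf-8")

    tracker_df = pd.DataFrame(
        {
            "sponsor": [r.sponsor_name for r in cohort.tracker],
            "date": [r.snapshot_date.isoformat() for r in cohort.tracker],
            "total_due": [r.total_due for r in cohort.tracker],
            "total_reported": [r.total_reported for r in cohort.tracker],
        }
    )
    paths["tracker"] = outdir / "tracker.csv"
    tracker_df.to_csv(paths["tracker"], index=False)

    paths["truth"] = outdir / "truth.csv"
    cohort.truth.to_csv(paths["truth"], index=False)
    return paths


def read_oa_records(path: Path | str) -> dict[str, OARecord]:
    """Read open-access evidence from JSON-lines (one element per location)."""
    import json

    from .registry_io import _as_date

    records: dict[str, OARecord] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        row = json.loads(line)
        status = row.get("oa_status")
        records[str(row["pub_id"])] = OARecord(
            pub_id=str(row["pub_id"]),
            unpaywall_date=_as_date(row.get("unpaywall_date")),
            evidence=[
                OAEvidence(
                    host_type=HostType(loc["host_type"]),
                    journal_is_oa=bool(loc.get("journal_is_oa", False)),
                    license_open=bool(loc.get("license_open", False)),
                )
                for loc in row.get("locations", [])
            ],
            precomputed_status=OAStatus[status.upper()] if status else None,
        )
    return records
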