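"""Registry-record input: parsing, cohort filters, cross-registration dedup.

Trial registrations arrive as flat-file exports in two dialects — a
ClinicalTrials.gov-shaped one and a DRKS-shaped one — with different column
names for the same concepts. A dialect profile maps source columns onto the
canonical :class:`TrialRecord`. Cohort inclusion follows the fixed filter
order (completion window, completeness status, study type, optionally a
start date for the prospective-registration sample) with every exclusion
tallied under the first reason that fires, and cross-registered ctgov/DRKS
pairs are collapsed to the ClinicalTrials.gov member.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .partialdates import PartialDate, parse_partial_date

logger = logging.getLogger(__name__)

CTGOV = "ctgov"
DRKS = "drks"

#: Registry statuses treated as "considered as complete". Overridable via
#: :class:`CohortCriteria` so a different status inventory can be supplied.
DEFAULT_COMPLETE_STATUSES = frozenset(
    {"Completed", "Terminated", "Suspended", "Unknown status"}
)

_TRN_SHAPE = {
    CTGOV: re.compile(r"^NCT\d{8}$"),
    DRKS: re.compile(r"^DRKS\d{8}$"),
}


def normalize_trn(text: str) -> str:
    """Canonicalize a registration number: uppercase, strip spaces/hyphens."""
    return re.sub(r"[\s\-]+", "", str(text)).upper()


@dataclass(frozen=True)
class RegistryReference:
    """One reference attached to a registration (citation or results link)."""

    title: Optional[str] = None
    doi: Optional[str] = None
    pmid: Optional[str] = None
    is_results_reference: bool = False

    def __post_init__(self) -> None:
        if not (self.title or self.doi or self.pmid):
            raise ValueError("reference needs at least one of title/doi/pmid")


@dataclass
class TrialRecord:
    """One trial registration, normalized across registry dialects."""

    trn: str
    registry: str
    lead_umcs: list[str] = field(default_factory=list)
    start_date: Optional[PartialDate] = None
    completion_date: Optional[PartialDate] = None
    registration_date: Optional[PartialDate] = None
    status: str = ""
    study_type: str = "interventional"
    has_structured_summary_results: bool = False
    summary_results_date: Optional[PartialDate] = None
    references: list[RegistryReference] = field(default_factory=list)
    secondary_ids: list[str] = field(default_factory=list)
    cross_registered_trns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trn = normalize_trn(self.trn)
        shape = _TRN_SHAPE.get(self.registry)
        if shape is not None and not shape.match(self.trn):
            raise ValueError(f"TRN {self.trn!r} does not match {self.registry} format")


@dataclass(frozen=True)
class CohortCriteria:
    """Inclusion/exclusion rules for the audited cohort."""

    completion_from: int = 2009
    completion_to: int = 2017
    complete_statuses: frozenset[str] = DEFAULT_COMPLETE_STATUSES
    require_interventional: bool = True
    require_start_date: bool = False

    def __post_init__(self) -> None:
        if self.completion_from > self.completion_to:
            raise ValueError("completion_from must be <= completion_to")


#: Ordered exclusion reasons; each trial is counted under the first that fires.
REASON_COMPLETION = "completion_outside_window"
REASON_STATUS = "status_not_complete"
REASON_TYPE = "not_interventional"
REASON_START = "missing_start_date"


@dataclass
class ExclusionTally:
    """Bookkeeping of the screening flow; conserves the input count."""

    input_count: int
    excluded_by_reason: dict[str, int]
    duplicates_removed: int
    included_count: int

    def check(self) -> None:
        total = self.included_count + self.duplicates_removed + sum(
            self.excluded_by_reason.values()
        )
        if total != self.input_count:
            raise AssertionError(
                f"tally does not conserve counts: {self.input_count} != {total}"
            )


@dataclass(frozen=True)
class EuctrTrackerRow:
    """One historical snapshot of a sponsor's EUCTR reporting rate."""

    sponsor_name: str
    snapshot_date: PartialDate
    total_due: int
    total_reported: int
    percent_reported: float

    def __post_init__(self) -> None:
        if self.total_reported > self.total_due:
            raise ValueError(
                f"tracker row for {self.sponsor_name!r} at {self.snapshot_date}: "
                f"reported ({self.total_reported}) exceeds due ({self.total_due})"
            )


# ---------------------------------------------------------------------------
# Dialect profiles

#: Column-name mappings from source exports onto TrialRecord fields.
DIALECT_PROFILES: dict[str, dict[str, str]] = {
    CTGOV: {
        "trn": "nct_id",
        "registration_date": "first_submitted_date",
        "start_date": "start_date",
        "completion_date": "completion_date",
        "status": "overall_status",
        "study_type": "study_type",
        "lead_umcs": "lead_umcs",
        "has_structured_summary_results": "has_summary_results",
        "summary_results_date": "summary_results_date",
        "references": "references",
        "secondary_ids": "secondary_ids",
    },
    DRKS: {
        "trn": "drks_id",
        "registration_date": "registration_date",
        "start_date": "start_date",
        "completion_date": "completion_date",
        "status": "recruitment_status",
        "study_type": "study_type",
        "lead_umcs": "lead_umcs",
        "has_structured_summary_results": "has_summary_results",
        "summary_results_date": "summary_results_date",
        "references": "references",
        "secondary_ids": "secondary_ids",
    },
}


def _as_list(value) -> list:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    if isinstance(value, list):
        return value
    s = str(value).strip()
    if not s:
        return []
    if s.startswith("["):
        return json.loads(s)
    return [part.strip() for part in s.split(";") if part.strip()]


def _as_date(value) -> Optional[PartialDate]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, PartialDate):
        return value
    s = str(value).strip()
    if not s or s.lower() in {"nan", "none", "na"}:
        return None
    return parse_partial_date(s)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in {"true", "1", "yes", "y"}


def record_from_row(row: dict, registry: str, profile: Optional[dict[str, str]] = None) -> TrialRecord:
    """Build a :class:`TrialRecord` from one raw row using a dialect profile."""
    prof = profile or DIALECT_PROFILES[registry]

    def get(field_name):
        col = prof.get(field_name, field_name)
        return row.get(col)

    refs = []
    for item in _as_list(get("references")):
        if isinstance(item, str):
            item = json.loads(item)
        refs.append(
            RegistryReference(
                title=item.get("title"),
                doi=item.get("doi"),
                pmid=str(item["pmid"]) if item.get("pmid") else None,
                is_results_reference=bool(item.get("is_results_reference", False)),
            )
        )
    trn_value = get("trn")
    if trn_value is None:
        raise KeyError(prof.get("trn", "trn"))
    return TrialRecord(
        trn=str(trn_value),
        registry=registry,
        lead_umcs=[str(u) for u in _as_list(get("lead_umcs"))],
        start_date=_as_date(get("start_date")),
        completion_date=_as_date(get("completion_date")),
        registration_date=_as_date(get("registration_date")),
        status=str(get("status") or ""),
        study_type=str(get("study_type") or "").strip().lower() or "other",
        has_structured_summary_results=_as_bool(get("has_structured_summary_results")),
        summary_results_date=_as_date(get("summary_results_date")),
        references=refs,
        secondary_ids=[str(s) for s in _as_list(get("secondary_ids"))],
    )


def read_trials(
    path: Union[str, Path],
    registry: str,
    profile: Optional[dict[str, str]] = None,
) -> list[TrialRecord]:
    """Read trial registrations from CSV or JSON-lines in a registry dialect."""
    path = Path(path)
    if path.suffix in {".jsonl", ".ndjson", ".json"}:
        rows = [json.loads(line) for line in path.read_text(encoding="utf-8").splitlines() if line.strip()]
    else:
        rows = pd.read_csv(path, dtype=str).to_dict(orient="records")
    return [record_from_row(row, registry, profile) for row in rows]


# ---------------------------------------------------------------------------
# Cohort screening


def apply_cohort_filters(
    trials: Sequence[TrialRecord], criteria: CohortCriteria
) -> tuple[list[TrialRecord], ExclusionTally]:
    """Apply the cohort inclusion rules in fixed order, tallying exclusions.

    Order: (1) completion year outside the window (missing completion dates
    are excluded here and logged), (2) status not considered complete,
    (3) study type not interventional, (4) optionally a missing start date.
    Each trial is counted under the first reason that excludes it, so the
    tally conserves the input count.
    """
    reasons = [REASON_COMPLETION, REASON_STATUS, REASON_TYPE]
    if criteria.require_start_date:
        reasons.append(REASON_START)
    excluded = {r: 0 for r in reasons}
    included: list[TrialRecord] = []
    for trial in trials:
        reason = _first_exclusion_reason(trial, criteria)
        if reason is None:
            included.append(trial)
        else:
            excluded[reason] += 1
    tally = ExclusionTally(
        input_count=len(trials),
        excluded_by_reason=excluded,
        duplicates_removed=0,
        included_count=len(included),
    )
    tally.check()
    for reason, count in excluded.items():
        logger.info("cohort filter %s excluded %d trials", reason, count)
    return included, tally


def _first_exclusion_reason(trial: TrialRecord, criteria: CohortCriteria) -> Optional[str]:
    if trial.completion_date is None:
        logger.info("trial %s: missing completion date, excluded", trial.trn)
        return REASON_COMPLETION
    if not criteria.completion_from <= trial.completion_date.year <= criteria.completion_to:
        return REASON_COMPLETION
    if trial.status not in criteria.complete_statuses:
        return REASON_STATUS
    if criteria.require_interventional and trial.study_type != "interventional":
        return REASON_TYPE
    if criteria.require_start_date and trial.start_date is None:
        return REASON_START
    return None


def deduplicate_cross_registrations(
    trials: Sequence[TrialRecord],
) -> tuple[list[TrialRecord], int, list[tuple[str, str]]]:
    """Collapse ctgov/DRKS cross-registrations to a single trial.

    A pair is a cross-registration when either record's secondary IDs
    contain the other's TRN (after normalization) — detection is symmetric.
    The ClinicalTrials.gov member is retained (it carries the structured
    summary-results field used downstream) with the union of references
    from both records, and it remembers its partner's TRN so either
    identifier counts as a TRN match in publications. Chains of more than
    two records collapse to one retained record with a warning.

    Returns (retained trials, number removed, pair log of (kept, removed)).
    """
    by_trn = {t.trn: t for t in trials}
    # union-find over trials connected by secondary-id references
    parent: dict[str, str] = {t.trn: t.trn for t in trials}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for trial in trials:
        for sec in trial.secondary_ids:
            other = normalize_trn(sec)
            if other in by_trn and other != trial.trn:
                union(trial.trn, other)

    groups: dict[str, list[TrialRecord]] = {}
    for trial in trials:
        groups.setdefault(find(trial.trn), []).append(trial)

    retained: list[TrialRecord] = []
    pair_log: list[tuple[str, str]] = []
    removed = 0
    for members in groups.values():
        if len(members) == 1:
            retained.append(members[0])
            continue
        if len(members) > 2:
            logger.warning(
                "cross-registration chain of %d records collapsed: %s",
                len(members),
                [m.trn for m in members],
            )
        keep = next((m for m in members if m.registry == CTGOV), members[0])
        dropped = [m for m in members if m is not keep]
        merged_refs = list(keep.references)
        seen = {(r.title, r.doi, r.pmid) for r in merged_refs}
        for other in dropped:
            for ref in other.references:
                key = (ref.title, ref.doi, ref.pmid)
                if key not in seen:
                    merged_refs.append(ref)
                    seen.add(key)
        keep = replace(
            keep,
            references=merged_refs,
            cross_registered_trns=sorted(
                set(keep.cross_registered_trns) | {m.trn for m in dropped}
            ),
        )
        retained.append(keep)
        for other in dropped:
            pair_log.append((keep.trn, other.trn))
        removed += len(dropped)
    # preserve input order of the retained records
    order = {t.trn: i for i, t in enumerate(trials)}
    retained.sort(key=lambda t: order[t.trn])
    return retained, removed, pair_log


def screen_cohort(
    trials: Sequence[TrialRecord], criteria: CohortCriteria
) -> tuple[list[TrialRecord], ExclusionTally]:
    """Full screening: inclusion filters then cross-registration dedup."""
    included, tally = apply_cohort_filters(trials, criteria)
    deduped, removed, pairs = deduplicate_cross_registrations(included)
    tally = ExclusionTally(
        input_count=tally.input_count,
        excluded_by_reason=tally.excluded_by_reason,
        duplicates_removed=removed,
        included_count=len(deduped),
    )
    tally.check()
    for kept, dropped in pairs:
        logger.info("cross-registration: kept %s, removed %s", kept, dropped)
    return deduped, tally


# ---------------------------------------------------------------------------
# EU Trials Tracker


def read_euctr_tracker_history(
    source: Union[str, Path, pd.DataFrame, Iterable[dict]],
) -> list[EuctrTrackerRow]:
    """Read EU Trials Tracker history rows, sorted by snapshot date.

    Expects columns sponsor, date (ISO-8601), total_due, total_reported;
    percent_reported is recomputed from the counts when absent. A row with
    more reported than due trials is a validation error naming the row.
    """
    if isinstance(source, pd.DataFrame):
        rows = source.to_dict(orient="records")
    elif isinstance(source, (str, Path)):
        rows = pd.read_csv(source).to_dict(orient="records")
    else:
        rows = list(source)
    out = []
    for row in rows:
        sponsor = str(row.get("sponsor") or row.get("sponsor_name"))
        due = int(row["total_due"])
        reported = int(row["total_reported"])
        pct = row.get("percent_reported")
        if pct is None or (isinstance(pct, float) and pd.isna(pct)):
            pct = 100.0 * reported / due if due else 0.0
        out.append(
            EuctrTrackerRow(
                sponsor_name=sponsor,
                snapshot_date=_as_date(row.get("date") or row.get("snapshot_date")),
                total_due=due,
                total_reported=reported,
                percent_reported=float(pct),
            )
        )
    out.sort(key=lambda r: (r.snapshot_date.as_date(), r.sponsor_name))
    return out


def select_sponsor_for_umc(candidates: Sequence[tuple[str, int]]) -> str:
    """Pick the EUCTR sponsor name to represent a UMC.

    The sponsor with the most trials wins; ties break lexicographically by
    name (and are logged, since the choice is then arbitrary).
    """
    if not candidates:
        raise ValueError("no sponsor candidates for UMC")
    best_count = max(count for _, count in candidates)
    tied = sorted(name for name, count in candidates if count == best_count)
    if len(tied) > 1:
        logger.warning("sponsor tie at %d trials among %s; taking %s", best_count, tied, tied[0])
    return tied[0]
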