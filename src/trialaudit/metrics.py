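"""Per-trial transparency outcomes.

Seven practices are assessed per trial: prospective registration (month-
level rule), TRN in the publication abstract and full text, a publication
link in the registration, summary results in the registry, timely reporting
within 2 and 5 years of completion (by summary-results route, publication
route, or either), and the open-access status of the results publication.

Every metric is ternary: True/False when the trial is in the metric's
denominator, ``None`` when it is not — missing flags are never coerced to
False, so group denominators count exactly the eligible trials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Optional, Sequence

from .partialdates import MonthOrder, PartialDate, compare_month
from .registry_io import CTGOV, DRKS, TrialRecord
from .trn_linkage import LinkAssessment, Publication

#: Reference titles that mark a DRKS summary-results ("results report") entry.
DEFAULT_SUMMARY_KEYWORDS = ("ergebnisbericht", "abschlussbericht")

ROUTE_SUMMARY = "summary"
ROUTE_PUBLICATION = "publication"
ROUTE_EITHER = "either"
ROUTES = (ROUTE_SUMMARY, ROUTE_PUBLICATION, ROUTE_EITHER)


@dataclass(frozen=True)
class FollowupContext:
    """Observation dates that bound the timely-reporting denominators.

    A trial only enters the N-year timeliness denominator when at least N
    years elapsed between its completion and the date we could last have
    observed a report: the registry download date for summary results, the
    manual publication search date for publications, and both for the
    either-route metric.
    """

    registry_download_date: PartialDate
    publication_search_date: PartialDate

    def __post_init__(self) -> None:
        for name, d in (
            ("registry_download_date", self.registry_download_date),
            ("publication_search_date", self.publication_search_date),
        ):
            if d.day is None:
                raise ValueError(f"{name} must be day-resolved, got {d}")


#: Defaults mirror the study snapshot: registry data pulled 2022-11-01; the
#: manual publication search predates it (assumption documented in docs).
DEFAULT_CONTEXT = FollowupContext(
    registry_download_date=PartialDate(2022, 11, 1),
    publication_search_date=PartialDate(2021, 9, 1),
)


class HostType(str, enum.Enum):
    PUBLISHER = "publisher"
    REPOSITORY = "repository"


@dataclass(frozen=True)
class OAEvidence:
    """One open-access location for a publication (Unpaywall-style)."""

    host_type: HostType
    journal_is_oa: bool = False
    license_open: bool = False


@total_ordering
class OAStatus(enum.Enum):
    """Open-access status, ordered by the assignment hierarchy (descending
    gold > hybrid > green > bronze > closed)."""

    CLOSED = 0
    BRONZE = 1
    GREEN = 2
    HYBRID = 3
    GOLD = 4

    def __lt__(self, other):
        if isinstance(other, OAStatus):
            return self.value < other.value
        return NotImplemented

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def is_open(self) -> bool:
        return self is not OAStatus.CLOSED


@dataclass
class OARecord:
    """Open-access evidence for one publication, with the lookup date."""

    pub_id: str
    unpaywall_date: Optional[PartialDate] = None
    evidence: list[OAEvidence] = field(default_factory=list)
    #: precomputed status accepted verbatim when the input supplies one
    precomputed_status: Optional[OAStatus] = None


def is_prospectively_registered(trial: TrialRecord) -> Optional[bool]:
    """Was the trial registered in the same or a previous month to its start?

    ``None`` (outside the denominator) when either the start date or the
    registration date lacks a month.
    """
    order = compare_month(trial.registration_date, trial.start_date)
    if order is MonthOrder.UNDETERMINED:
        return None
    return order in (MonthOrder.BEFORE, MonthOrder.SAME)


def has_summary_results(
    trial: TrialRecord, keywords: Sequence[str] = DEFAULT_SUMMARY_KEYWORDS
) -> bool:
    """Does the registration carry summary results?

    ClinicalTrials.gov exposes a structured summary-results field; DRKS has
    none, so a results report is recognised by keywords (case-insensitive
    substring, e.g. "Ergebnisbericht") in any reference title.
    """
    if trial.registry == CTGOV:
        return trial.has_structured_summary_results
    if trial.registry == DRKS:
        lowered = [kw.lower() for kw in keywords]
        return any(
            ref.title and any(kw in ref.title.lower() for kw in lowered)
            for ref in trial.references
        )
    return trial.has_structured_summary_results


def route_report_date(
    trial: TrialRecord,
    pub: Optional[Publication],
    route: str,
    keywords: Sequence[str] = DEFAULT_SUMMARY_KEYWORDS,
) -> Optional[PartialDate]:
    """Date the trial's results first appeared via the given route.

    Summary route: the registry summary-results date (when results exist).
    Publication route: the publication date of the earliest linked
    non-dissertation results publication. Either: the earlier of the two
    defined dates. ``None`` when the route has no report.
    """
    if route == ROUTE_SUMMARY:
        return trial.summary_results_date if has_summary_results(trial, keywords) else None
    if route == ROUTE_PUBLICATION:
        if pub is None or pub.is_dissertation:
            return None
        return pub.publication_date
    if route == ROUTE_EITHER:
        dates = [
            d
            for d in (
                route_report_date(trial, pub, ROUTE_SUMMARY, keywords),
                route_report_date(trial, pub, ROUTE_PUBLICATION, keywords),
            )
            if d is not None
        ]
        return min(dates, key=lambda d: d.as_date()) if dates else None
    raise ValueError(f"unknown route: {route!r}")


def is_eligible_for_followup(
    trial: TrialRecord, route: str, years: int, ctx: FollowupContext
) -> bool:
    """Has the route's follow-up window closed for this trial?

    Completion + N years must not extend past the route's reference date
    (registry download for summary, publication search for publications,
    both for either). Month-resolved completion dates are imputed to the
    first of the month before adding whole years.
    """
    if trial.completion_date is None or trial.completion_date.month is None:
        return False
    deadline = trial.completion_date.add_years(years).as_date()
    if route == ROUTE_SUMMARY:
        return deadline <= ctx.registry_download_date.as_date()
    if route == ROUTE_PUBLICATION:
        return deadline <= ctx.publication_search_date.as_date()
    if route == ROUTE_EITHER:
        return is_eligible_for_followup(
            trial, ROUTE_SUMMARY, years, ctx
        ) and is_eligible_for_followup(trial, ROUTE_PUBLICATION, years, ctx)
    raise ValueError(f"unknown route: {route!r}")


def reported_within(
    trial: TrialRecord,
    route: str,
    years: int,
    pub: Optional[Publication],
    ctx: FollowupContext,
    keywords: Sequence[str] = DEFAULT_SUMMARY_KEYWORDS,
) -> Optional[bool]:
    """Did the trial report results via the route within N years of completion?

    ``None`` when the trial's follow-up window has not closed (outside the
    denominator); otherwise True iff a report date exists and is no later
    than completion + N years.
    """
    if not is_eligible_for_followup(trial, route, years, ctx):
        return None
    report = route_report_date(trial, pub, route, keywords)
    if report is None:
        return False
    deadline = trial.completion_date.add_years(years).as_date()
    return report.as_date() <= deadline


def classify_oa_status(evidence: Sequence[OAEvidence]) -> OAStatus:
    """Assign one OA status from all locations via the descending hierarchy.

    Candidates: publisher-hosted in an OA journal → gold; publisher-hosted
    with an open license → hybrid; repository-hosted → green; publisher-
    hosted otherwise → bronze. The highest candidate wins; no locations →
    closed.
    """
    best = OAStatus.CLOSED
    for ev in evidence:
        if ev.host_type == HostType.PUBLISHER:
            if ev.journal_is_oa:
                cand = OAStatus.GOLD
            elif ev.license_open:
                cand = OAStatus.HYBRID
            else:
                cand = OAStatus.BRONZE
        else:
            cand = OAStatus.GREEN
        best = max(best, cand)
    return best


def oa_metric_sample(pub: Optional[Publication], oa: Optional[OARecord]) -> Optional[OAStatus]:
    """OA status within the metric's denominator, else ``None``.

    Denominator: a non-dissertation publication with a DOI and a dated
    open-access record.
    """
    if pub is None or pub.is_dissertation or not pub.doi:
        return None
    if oa is None or oa.unpaywall_date is None:
        return None
    if oa.precomputed_status is not None:
        return oa.precomputed_status
    return classify_oa_status(oa.evidence)


# ---------------------------------------------------------------------------
# Composition


@dataclass
class TrialAssessment:
    """All per-trial transparency outcomes, each under its own denominator."""

    trn: str
    umcs: list[str]
    registry: str
    start_year: Optional[int]
    completion_year: Optional[int]
    publication_year: Optional[int]
    prospective: Optional[bool]
    summary_results: bool
    timely: dict[tuple[str, int], Optional[bool]]  # (route, years) -> flag
    trn_in_abstract: Optional[bool]
    trn_in_full_text: Optional[bool]
    trn_in_both: Optional[bool]
    publication_link_in_registry: Optional[bool]
    oa: Optional[OAStatus]

    def metric_flag(self, metric: str) -> Optional[bool]:
        """Ternary flag for a named metric (used by the aggregator)."""
        if metric == "prospective_registration":
            return self.prospective
        if metric == "summary_results":
            return self.summary_results
        if metric.startswith("timely_"):
            _, years, route = metric.split("_", 2)
            return self.timely[(route, int(years.rstrip("y")))]
        if metric == "trn_in_abstract":
            return self.trn_in_abstract
        if metric == "trn_in_full_text":
            return self.trn_in_full_text
        if metric == "trn_in_both":
            return self.trn_in_both
        if metric == "publication_link_in_registry":
            return self.publication_link_in_registry
        if metric == "open_access":
            return self.oa.is_open if self.oa is not None else None
        raise KeyError(f"unknown metric: {metric!r}")


#: Metric identifiers the aggregator understands, with their year axis.
METRIC_YEAR_AXIS = {
    "prospective_registration": "start_year",
    "trn_in_abstract": "completion_year",
    "trn_in_full_text": "completion_year",
    "trn_in_both": "completion_year",
    "publication_link_in_registry": "completion_year",
    "summary_results": "completion_year",
    "timely_2y_summary": "completion_year",
    "timely_2y_publication": "completion_year",
    "timely_2y_either": "completion_year",
    "timely_5y_summary": "completion_year",
    "timely_5y_publication": "completion_year",
    "timely_5y_either": "completion_year",
    "open_access": "publication_year",
}

ALL_METRICS = tuple(METRIC_YEAR_AXIS)


def assess_trial(
    trial: TrialRecord,
    link: Optional[LinkAssessment],
    pub: Optional[Publication],
    oa: Optional[OARecord],
    ctx: FollowupContext = DEFAULT_CONTEXT,
    keywords: Sequence[str] = DEFAULT_SUMMARY_KEYWORDS,
) -> TrialAssessment:
    """Compose every metric for one trial; deterministic for fixed inputs."""
    if link is not None and link.trial_trn != trial.trn:
        raise ValueError(
            f"link assessment for {link.trial_trn} passed with trial {trial.trn}"
        )
    if pub is not None and oa is not None and oa.pub_id != pub.pub_id:
        raise ValueError(f"OA record for {oa.pub_id} passed with publication {pub.pub_id}")
    timely = {
        (route, years): reported_within(trial, route, years, pub, ctx, keywords)
        for route in ROUTES
        for years in (2, 5)
    }
    return TrialAssessment(
        trn=trial.trn,
        umcs=list(trial.lead_umcs),
        registry=trial.registry,
        start_year=trial.start_date.year if trial.start_date else None,
        completion_year=trial.completion_date.year if trial.completion_date else None,
        publication_year=(
            pub.publication_date.year
            if pub is not None and not pub.is_dissertation and pub.publication_date
            else None
        ),
        prospective=is_prospectively_registered(trial),
        summary_results=has_summary_results(trial, keywords),
        timely=timely,
        trn_in_abstract=link.trn_in_abstract if link else None,
        trn_in_full_text=link.trn_in_full_text if link else None,
        trn_in_both=link.trn_in_both if link else None,
        publication_link_in_registry=link.publication_linked_in_registry if link else None,
        oa=oa_metric_sample(pub, oa),
    )
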