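"""End-to-end orchestration: screen → link → assess → aggregate."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .aggregation import GroupSummary, aggregate_metric
from .metrics import (
    ALL_METRICS,
    DEFAULT_CONTEXT,
    DEFAULT_SUMMARY_KEYWORDS,
    FollowupContext,
    OARecord,
    TrialAssessment,
    assess_trial,
)
from .registry_io import CohortCriteria, ExclusionTally, TrialRecord, screen_cohort
from .trn_linkage import Publication, assess_links


@dataclass
class AuditResult:
    """Everything one audit run produces before report rendering."""

    assessments: list[TrialAssessment]
    tally: ExclusionTally
    screened_trials: list[TrialRecord]
    summaries: dict[str, list[GroupSummary]] = field(default_factory=dict)


def _find_publication(
    trial: TrialRecord,
    links: Mapping[str, str],
    publications: Mapping[str, Publication],
) -> Optional[Publication]:
    # the earliest-results mapping may be keyed by either identifier of a
    # deduplicated cross-registered pair
    for trn in (trial.trn, *trial.cross_registered_trns):
        pub_id = links.get(trn)
        if pub_id is not None:
            return publications.get(pub_id)
    return None


def audit_cohort(
    trials: Sequence[TrialRecord],
    publications: Mapping[str, Publication],
    links: Mapping[str, str],
    oa_records: Mapping[str, OARecord],
    criteria: CohortCriteria = CohortCriteria(),
    ctx: FollowupContext = DEFAULT_CONTEXT,
    keywords: Sequence[str] = DEFAULT_SUMMARY_KEYWORDS,
    metrics: Sequence[str] = ALL_METRICS,
    ci_level: float = 0.95,
) -> AuditResult:
    """Run the full audit over parsed inputs.

    Applies the cohort filters and cross-registration dedup, assesses every
    retained trial against each transparency practice, and aggregates
    per-UMC group summaries (pooled summary first) for every metric.
    """
    screened, tally = screen_cohort(trials, criteria)
    assessments = []
    for trial in screened:
        pub = _find_publication(trial, links, publications)
        link = assess_links(trial, pub)
        oa = oa_records.get(pub.pub_id) if pub is not None else None
        assessments.append(assess_trial(trial, link, pub, oa, ctx, keywords))
    summaries = {
        metric: aggregate_metric(assessments, metric, group_by="umc", level=ci_level)
        for metric in metrics
    }
    return AuditResult(
        assessments=assessments,
        tally=tally,
        screened_trials=screened,
        summaries=summaries,
    )
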