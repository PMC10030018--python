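"""Run configuration: a flat YAML document covering cohort criteria,
follow-up dates, keyword lists and the confidence level."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .metrics import DEFAULT_CONTEXT, DEFAULT_SUMMARY_KEYWORDS, FollowupContext
from .partialdates import parse_partial_date
from .registry_io import DEFAULT_COMPLETE_STATUSES, CohortCriteria


@dataclass
class RunConfig:
    criteria: CohortCriteria = field(default_factory=CohortCriteria)
    ctx: FollowupContext = DEFAULT_CONTEXT
    summary_keywords: tuple[str, ...] = DEFAULT_SUMMARY_KEYWORDS
    ci_level: float = 0.95


def load_run_config(path: Optional[Path | str] = None) -> RunConfig:
    """Load a run configuration; missing keys fall back to the defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    criteria = CohortCriteria(
        completion_from=int(data.get("completion_from", 2009)),
        completion_to=int(data.get("completion_to", 2017)),
        complete_statuses=frozenset(data.get("complete_statuses", DEFAULT_COMPLETE_STATUSES)),
        require_interventional=bool(data.get("require_interventional", True)),
        require_start_date=bool(data.get("require_start_date", False)),
    )
    ctx = FollowupContext(
        registry_download_date=parse_partial_date(
            str(data.get("registry_download_date", "2022-11-01"))
        ),
        publication_search_date=parse_partial_date(
            str(data.get("publication_search_date", "2021-09-01"))
        ),
    )
    keywords: Sequence[str] = data.get("summary_keywords", list(DEFAULT_SUMMARY_KEYWORDS))
    return RunConfig(
        criteria=criteria,
        ctx=ctx,
        summary_keywords=tuple(str(k) for k in keywords),
        ci_level=float(data.get("ci_level", 0.95)),
    )
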