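"""Dashboard dataset assembly and static report rendering.

The report mirrors an institutional transparency dashboard with three
views — pooled assessment across all centers, a comparative view between
centers, and one page per center — rendered as a self-contained static
site (inline CSS bar charts, absolute numbers as hover tooltips, and a
methods/limitations panel beside each metric). Every number shown in HTML
is taken from the same tidy table exported as CSV, which is the single
source of truth.
"""

from __future__ import annotations

import hashlib
import html
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .aggregation import CI, GroupSummary, Proportion, percent_round, summaries_to_frame
from .registry_io import EuctrTrackerRow

#: Short description and limitation note shown beside each metric's plot.
METRIC_INFO: dict[str, tuple[str, str]] = {
    "prospective_registration": (
        "Trials registered in the same or a previous month to the trial start date.",
        "Month-level comparison; trials without a start or registration month are excluded.",
    ),
    "trn_in_abstract": (
        "Results publications reporting the trial registration number in the abstract.",
        "Only publications with a PubMed identifier and an abstract are assessed.",
    ),
    "trn_in_full_text": (
        "Results publications reporting the trial registration number in the full text.",
        "Only publications with a retrievable full text are assessed.",
    ),
    "trn_in_both": (
        "Publications reporting the registration number in both abstract and full text.",
        "Requires both the abstract and the full-text denominators to apply.",
    ),
    "publication_link_in_registry": (
        "Registrations linking their results publication by DOI or PMID.",
        "Only publications carrying a DOI or PMID are assessed.",
    ),
    "summary_results": (
        "Trials with summary results posted in the registry.",
        "Structured field for ClinicalTrials.gov; keyword-detected results reports for DRKS.",
    ),
    "timely_2y_summary": (
        "Summary results posted within 2 years of trial completion.",
        "Only trials with 2 years of follow-up before the registry download are included.",
    ),
    "timely_2y_publication": (
        "Results published as a manuscript within 2 years of completion.",
        "Only trials with 2 years of follow-up before the publication search are included.",
    ),
    "timely_2y_either": (
        "Results reported by either route within 2 years of completion.",
        "Requires 2-year follow-up to both observation dates; dissertations excluded.",
    ),
    "timely_5y_summary": (
        "Summary results posted within 5 years of trial completion.",
        "Only trials with 5 years of follow-up before the registry download are included.",
    ),
    "timely_5y_publication": (
        "Results published as a manuscript within 5 years of completion.",
        "Only trials with 5 years of follow-up before the publication search are included.",
    ),
    "timely_5y_either": (
        "Results reported by either route within 5 years of completion.",
        "Requires 5-year follow-up to both observation dates; dissertations excluded.",
    ),
    "open_access": (
        "Results publications openly accessible (gold, hybrid, green or bronze).",
        "Assigned from open-access evidence by a descending hierarchy; needs a DOI and a dated record.",
    ),
}


@dataclass
class ReportConfig:
    output_dir: Path
    formats: tuple[str, ...] = ("csv", "json", "html")
    include_absolute_numbers: bool = True

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not self.formats:
            raise ValueError("at least one output format required")
        unknown = set(self.formats) - {"csv", "json", "html"}
        if unknown:
            raise ValueError(f"unknown formats: {sorted(unknown)}")


@dataclass
class DashboardDataset:
    """All data behind the three report views."""

    metrics: dict[str, list[GroupSummary]]
    euctr_series: dict[str, list[EuctrTrackerRow]]
    provenance: dict

    @property
    def umcs(self) -> list[str]:
        names = {s.group for rows in self.metrics.values() for s in rows if s.group_type == "umc"}
        return sorted(names)


def build_dashboard_dataset(
    summaries: dict[str, list[GroupSummary]],
    tracker_rows: Sequence[EuctrTrackerRow] = (),
    provenance: Optional[dict] = None,
) -> DashboardDataset:
    """Assemble the dataset feeding the three dashboard views.

    Pure in its inputs: identical summaries and tracker rows produce an
    identical dataset. Provenance (config snapshot, input digests, dates)
    is carried through to every export.
    """
    if not summaries:
        raise ValueError("no summaries to build a dashboard from")
    series: dict[str, list[EuctrTrackerRow]] = {}
    for row in tracker_rows:
        series.setdefault(row.sponsor_name, []).append(row)
    for rows in series.values():
        rows.sort(key=lambda r: r.snapshot_date.as_date())
    return DashboardDataset(
        metrics={m: list(rows) for m, rows in summaries.items()},
        euctr_series=series,
        provenance=dict(provenance or {}),
    )


# ---------------------------------------------------------------------------
# JSON serialization (round-trip stable)


def _prop_to_obj(p: Proportion) -> dict:
    return {
        "x": p.x,
        "n": p.n,
        "ci": None
        if p.ci is None
        else {"lower": p.ci.lower, "upper": p.ci.upper, "level": p.ci.level, "z": p.ci.z},
    }


def _prop_from_obj(obj: dict) -> Proportion:
    ci = obj.get("ci")
    return Proportion(
        x=obj["x"],
        n=obj["n"],
        ci=None if ci is None else CI(lower=ci["lower"], upper=ci["upper"], level=ci["level"], z=ci["z"]),
    )


def dataset_to_json(ds: DashboardDataset) -> str:
    obj = {
        "metrics": {
            m: [
                {
                    "metric": s.metric,
                    "group_type": s.group_type,
                    "group": s.group,
                    "prop": _prop_to_obj(s.prop),
                    "by_year": {str(y): _prop_to_obj(p) for y, p in sorted(s.by_year.items())},
                }
                for s in rows
            ]
            for m, rows in ds.metrics.items()
        },
        "euctr_series": {
            sponsor: [
                {
                    "date": r.snapshot_date.isoformat(),
                    "total_due": r.total_due,
                    "total_reported": r.total_reported,
                    "percent_reported": r.percent_reported,
                }
                for r in rows
            ]
            for sponsor, rows in ds.euctr_series.items()
        },
        "provenance": ds.provenance,
    }
    return json.dumps(obj, indent=1, sort_keys=True)


def dataset_from_json(text: str) -> DashboardDataset:
    from .partialdates import parse_partial_date

    obj = json.loads(text)
    metrics = {
        m: [
            GroupSummary(
                metric=s["metric"],
                group_type=s["group_type"],
                group=s["group"],
                prop=_prop_from_obj(s["prop"]),
                by_year={int(y): _prop_from_obj(p) for y, p in s["by_year"].items()},
            )
            for s in rows
        ]
        for m, rows in obj["metrics"].items()
    }
    series = {
        sponsor: [
            EuctrTrackerRow(
                sponsor_name=sponsor,
                snapshot_date=parse_partial_date(r["date"]),
                total_due=r["total_due"],
                total_reported=r["total_reported"],
                percent_reported=r["percent_reported"],
            )
            for r in rows
        ]
        for sponsor, rows in obj["euctr_series"].items()
    }
    return DashboardDataset(metrics=metrics, euctr_series=series, provenance=obj["provenance"])


def input_digest(path: Path | str) -> str:
    """SHA-256 of an input file, for the provenance block."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Static site rendering


_PAGE = """<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
.bar-bg {{ background:#e8e8e8; width: 24em; height: 1em; display:inline-block; }}
.bar {{ background:#2c7fb8; height: 1em; display:inline-block; }}
.metric {{ margin-bottom: 2em; border-bottom: 1px solid #ccc; padding-bottom: 1em; }}
.note {{ color:#555; font-size: 0.9em; }}
table {{ border-collapse: collapse; }} td, th {{ padding: 0.2em 0.8em; text-align:left; }}
nav a {{ margin-right: 1em; }}
</style></head><body>
<nav><a href="index.html">All centers</a><a href="compare.html">Compare centers</a></nav>
<h1>{title}</h1>
{body}
<footer class="note"><p>{provenance}</p></footer>
</body></html>
"""


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-")


def _bar(prop: Proportion, include_numbers: bool) -> str:
    if not prop.defined:
        return '<span class="note">no data</span>'
    pct = percent_round(prop.p)
    tooltip = f"{prop.x}/{prop.n}" if include_numbers else f"{pct}%"
    return (
        f'<span class="bar-bg" title="{tooltip}">'
        f'<span class="bar" style="width:{pct * 0.24:.2f}em"></span></span> '
        f"{pct}% <span class=\"note\">({prop.x}/{prop.n})</span>"
    )


def _metric_panel(metric: str, prop: Proportion, include_numbers: bool, extra: str = "") -> str:
    desc, limits = METRIC_INFO.get(metric, (metric, ""))
    return (
        f'<div class="metric"><h2>{html.escape(metric)}</h2>'
        f"<p>{_bar(prop, include_numbers)}</p>{extra}"
        f'<p class="note">{html.escape(desc)}<br>Limitations: {html.escape(limits)}</p></div>'
    )


def _year_table(summary: GroupSummary, include_numbers: bool) -> str:
    if not summary.by_year:
        return ""
    rows = "".join(
        f"<tr><td>{year}</td><td>{_bar(summary.by_year[year], include_numbers)}</td></tr>"
        for year in sorted(summary.by_year)
    )
    return f"<table><tr><th>Year</th><th>Rate</th></tr>{rows}</table>"


def render_static_site(ds: DashboardDataset, cfg: ReportConfig) -> list[Path]:
    """Render the dataset as a static file tree; returns written paths.

    Deterministic: identical datasets produce identical files.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    frame = summaries_to_frame([s for rows in ds.metrics.values() for s in rows])
    provenance_line = html.escape(json.dumps(ds.provenance, sort_keys=True))

    if "csv" in cfg.formats:
        path = out / "summaries.csv"
        frame.to_csv(path, index=False)
        written.append(path)
    if "json" in cfg.formats:
        path = out / "dashboard.json"
        path.write_text(dataset_to_json(ds), encoding="utf-8")
        written.append(path)
    if "html" not in cfg.formats:
        return written

    inc = cfg.include_absolute_numbers

    # view (a): pooled assessment across all centers
    panels = []
    for metric, rows in ds.metrics.items():
        pooled = next((s for s in rows if s.group_type == "all"), None)
        if pooled is None:
            panels.append(
                f'<div class="metric"><h2>{html.escape(metric)}</h2>'
                '<p class="note">no data</p></div>'
            )
            continue
        panels.append(_metric_panel(metric, pooled.prop, inc, _year_table(pooled, inc)))
    if ds.euctr_series:
        rows_html = "".join(
            f"<tr><td>{html.escape(sponsor)}</td><td>{r.snapshot_date}</td>"
            f'<td title="{r.total_reported}/{r.total_due}">{r.percent_reported:.1f}%</td></tr>'
            for sponsor, series in sorted(ds.euctr_series.items())
            for r in series
        )
        panels.append(
            '<div class="metric"><h2>EUCTR summary results (tracker)</h2>'
            f"<table><tr><th>Sponsor</th><th>Date</th><th>Reported</th></tr>{rows_html}</table>"
            '<p class="note">Reporting rates for due trials in the EU registry, as published '
            "by the EU Trials Tracker; shown as provided, never recomputed from trial records.</p></div>"
        )
    page = out / "index.html"
    page.write_text(
        _PAGE.format(title="Clinical trial transparency — all centers", body="".join(panels), provenance=provenance_line),
        encoding="utf-8",
    )
    written.append(page)

    # view (b): comparative assessment between centers
    panels = []
    for metric, rows in ds.metrics.items():
        per_umc = [s for s in rows if s.group_type == "umc"]
        if not per_umc:
            continue
        table = "".join(
            f"<tr><td><a href=\"umc-{_slug(s.group)}.html\">{html.escape(s.group)}</a></td>"
            f"<td>{_bar(s.prop, inc)}</td></tr>"
            for s in sorted(per_umc, key=lambda s: s.group)
        )
        desc, limits = METRIC_INFO.get(metric, (metric, ""))
        panels.append(
            f'<div class="metric"><h2>{html.escape(metric)}</h2>'
            f"<table><tr><th>Center</th><th>Rate</th></tr>{table}</table>"
            f'<p class="note">{html.escape(desc)}<br>Limitations: {html.escape(limits)}</p></div>'
        )
    page = out / "compare.html"
    page.write_text(
        _PAGE.format(title="Clinical trial transparency — comparison", body="".join(panels), provenance=provenance_line),
        encoding="utf-8",
    )
    written.append(page)

    # view (c): one page per center
    for umc in ds.umcs:
        panels = []
        for metric, rows in ds.metrics.items():
            mine = next((s for s in rows if s.group_type == "umc" and s.group == umc), None)
            if mine is None:
                panels.append(
                    f'<div class="metric"><h2>{html.escape(metric)}</h2>'
                    '<p class="note">no data</p></div>'
                )
            else:
                panels.append(_metric_panel(metric, mine.prop, inc, _year_table(mine, inc)))
        page = out / f"umc-{_slug(umc)}.html"
        page.write_text(
            _PAGE.format(title=f"Clinical trial transparency — {umc}", body="".join(panels), provenance=provenance_line),
            encoding="utf-8",
        )
        written.append(page)
    return written
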