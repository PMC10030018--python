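"""Grouped proportions with continuity-corrected Wilson intervals.

The binomial interval used throughout is the Wilson score interval with
continuity correction (Newcombe 1998), with the conventional boundary
fixes L=0 at x=0 and U=1 at x=n. With z = 1.959964 this reproduces, after
integer-percent rounding, every 95% interval the audited dashboards print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .metrics import METRIC_YEAR_AXIS, OAStatus, TrialAssessment

#: Two-sided 95% critical value, frozen to six decimals so printed
#: percentages round identically across platforms.
Z_95 = 1.959964


@dataclass(frozen=True)
class CI:
    lower: float
    upper: float
    level: float = 0.95
    z: float = Z_95
    method: str = "wilson_cc"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")


@dataclass(frozen=True)
class Proportion:
    """x successes out of n, with its confidence interval."""

    x: int
    n: int
    ci: Optional[CI]

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")

    @property
    def defined(self) -> bool:
        return self.n > 0

    @property
    def p(self) -> float:
        if self.n == 0:
            raise ZeroDivisionError("proportion undefined for n = 0")
        return self.x / self.n

    @property
    def q(self) -> float:
        return 1.0 - self.p


class UndefinedProportionError(ZeroDivisionError):
    pass


def wilson_cc_interval(x: int, n: int, level: float = 0.95, z: Optional[float] = None) -> CI:
    """Two-sided Wilson score interval with continuity correction.

    L = max(0, [2x + z² − 1 − z·sqrt(z² − 2 − 1/n + 4p(nq + 1))] / (2(n + z²)))
    U = min(1, [2x + z² + 1 + z·sqrt(z² + 2 − 1/n + 4p(nq − 1))] / (2(n + z²)))
    with L = 0 when x = 0 and U = 1 when x = n.
    """
    if n < 1:
        raise UndefinedProportionError("interval undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if z is None:
        z = Z_95 if level == 0.95 else float(norm.ppf(0.5 + level / 2.0))
    p = x / n
    q = 1.0 - p
    denom = 2.0 * (n + z * z)
    # the radicand can dip just below zero at the boundaries; clamp
    rad_l = max(0.0, z * z - 2.0 - 1.0 / n + 4.0 * p * (n * q + 1.0))
    rad_u = max(0.0, z * z + 2.0 - 1.0 / n + 4.0 * p * (n * q - 1.0))
    lower = (2.0 * x + z * z - 1.0 - z * math.sqrt(rad_l)) / denom
    upper = (2.0 * x + z * z + 1.0 + z * math.sqrt(rad_u)) / denom
    if x == 0:
        lower = 0.0
    if x == n:
        upper = 1.0
    return CI(lower=max(0.0, lower), upper=min(1.0, upper), level=level, z=z)


def percent_round(p: float) -> int:
    """Fraction → integer percent, halves rounded away from zero."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"fraction out of [0, 1]: {p}")
    return int(math.floor(100.0 * p + 0.5))


def proportion(x: int, n: int, level: float = 0.95) -> Proportion:
    return Proportion(x=x, n=n, ci=wilson_cc_interval(x, n, level) if n > 0 else None)


# ---------------------------------------------------------------------------
# Grouping


@dataclass
class GroupSummary:
    """One metric's proportion within one group, with a per-year series."""

    metric: str
    group_type: str  # "all" | "umc" | "registry" | "year"
    group: str
    prop: Proportion
    by_year: dict[int, Proportion] = field(default_factory=dict)


@dataclass
class DistributionStats:
    """Spread of per-UMC rates for one metric."""

    median: float
    sd: float
    min: float
    max: float
    n_umcs: int
    n_umcs_undefined: int = 0


def _year_of(assessment: TrialAssessment, metric: str) -> Optional[int]:
    return getattr(assessment, METRIC_YEAR_AXIS[metric])


def _tally(pairs: Sequence[tuple[Optional[bool], Optional[int]]], level: float) -> tuple[Proportion, dict[int, Proportion]]:
    defined = [(flag, yr) for flag, yr in pairs if flag is not None]
    x = sum(1 for flag, _ in defined if flag)
    n = len(defined)
    years = sorted({yr for _, yr in defined if yr is not None})
    by_year = {}
    for yr in years:
        sub = [flag for flag, y in defined if y == yr]
        by_year[yr] = proportion(sum(sub), len(sub), level)
    return proportion(x, n, level), by_year


def aggregate_metric(
    assessments: Sequence[TrialAssessment],
    metric: str,
    group_by: str = "umc",
    level: float = 0.95,
) -> list[GroupSummary]:
    """Grouped proportions for one metric.

    Denominators count only trials whose flag is present (True or False);
    numerators count True. The result holds one pooled "all" summary first,
    then one summary per group value in deterministic (sorted) order. For
    ``group_by="umc"`` a trial led by several UMCs counts once per UMC in
    the group slices but once overall in the pooled summary.
    """
    if metric not in METRIC_YEAR_AXIS:
        raise KeyError(f"unknown metric: {metric!r}")
    if group_by not in {"umc", "registry", "year", "all"}:
        raise ValueError(f"unknown grouping: {group_by!r}")

    pooled_pairs = [(a.metric_flag(metric), _year_of(a, metric)) for a in assessments]
    pooled_prop, pooled_years = _tally(pooled_pairs, level)
    out = [GroupSummary(metric, "all", "all", pooled_prop, pooled_years)]
    if group_by == "all":
        return out

    groups: dict[str, list[tuple[Optional[bool], Optional[int]]]] = {}
    for a in assessments:
        pair = (a.metric_flag(metric), _year_of(a, metric))
        if group_by == "umc":
            for umc in a.umcs:
                groups.setdefault(umc, []).append(pair)
        elif group_by == "registry":
            groups.setdefault(a.registry, []).append(pair)
        else:  # year
            yr = _year_of(a, metric)
            if yr is not None:
                groups.setdefault(str(yr), []).append(pair)
    for key in sorted(groups):
        prop, by_year = _tally(groups[key], level)
        out.append(GroupSummary(metric, group_by, key, prop, by_year))
    return out


def oa_status_counts(assessments: Sequence[TrialAssessment]) -> dict[str, int]:
    """Counts of each OA status among trials in the OA denominator."""
    counts = {status.label: 0 for status in sorted(OAStatus, reverse=True)}
    for a in assessments:
        if a.oa is not None:
            counts[a.oa.label] += 1
    return counts


def umc_distribution(summaries: Sequence[GroupSummary]) -> DistributionStats:
    """Median, sample SD (n−1), min and max of per-UMC point estimates.

    UMCs with a zero denominator are excluded from the statistics and
    counted in ``n_umcs_undefined``. A single defined UMC yields SD 0.
    """
    per_umc = [s for s in summaries if s.group_type == "umc"]
    defined = [s.prop.p for s in per_umc if s.prop.defined]
    undefined = len(per_umc) - len(defined)
    if not defined:
        raise ValueError("no per-UMC summary with a defined proportion")
    rates = np.asarray(defined, dtype=float)
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    return DistributionStats(
        median=float(np.median(rates)),
        sd=sd,
        min=float(rates.min()),
        max=float(rates.max()),
        n_umcs=int(rates.size),
        n_umcs_undefined=undefined,
    )


def summaries_to_frame(summaries: Sequence[GroupSummary]):
    """Flatten group summaries to the tidy export table.

    Columns: metric, group_type, group, year, x, n, percent, ci_low, ci_high.
    Group-level rows carry year = "" ; per-year series rows follow them.
    """
    import pandas as pd

    rows = []

    def row(s: GroupSummary, year, prop: Proportion):
        rows.append(
            {
                "metric": s.metric,
                "group_type": s.group_type,
                "group": s.group,
                "year": "" if year is None else int(year),
                "x": prop.x,
                "n": prop.n,
                "percent": percent_round(prop.p) if prop.defined else None,
                "ci_low": prop.ci.lower if prop.ci else None,
                "ci_high": prop.ci.upper if prop.ci else None,
            }
        )

    for s in summaries:
        row(s, None, s.prop)
        for year in sorted(s.by_year):
            row(s, year, s.by_year[year])
    return pd.DataFrame(
        rows,
        columns=["metric", "group_type", "group", "year", "x", "n", "percent", "ci_low", "ci_high"],
    )
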