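"""Period x subgroup metric tables, disparity gaps and gain decompositions.

The table layout mirrors the standard presentation of multistate health
expectancies: one row per (period, subgroup) with total life expectancy
(TLE), CVD-free and CVD expectancies, the percentage of remaining life spent
CVD-free, lifetime risk, mean onset age and conditional TLE at 65.

A packaged fixture ships published register-based reference estimates for
Finland 1996-2020 (lifetime risk and expectancies at age 40 per period,
gender and education), so the reporting arithmetic — gender/education gaps,
the decomposition of TLE gains into CVD-free and CVD years — is testable as
worked examples independently of any estimation run.

Display rounding follows the reference precision: years to one decimal,
percentages to whole points; unrounded values are retained internally.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import pandas as pd

from .estimation import TransitionProbs
from .markov import metrics_row

__all__ = [
    "MetricsTable",
    "DisparityReport",
    "build_metrics_table",
    "disparity_gap",
    "disparity_report",
    "decompose_tle_gain",
    "percent_cvd_free",
    "load_reference_tables",
    "plot_metric_trend",
]

KEY_COLUMNS = ("period", "subgroup")
#: metrics reported on a percent scale (gap rounding: whole points)
PERCENT_METRICS = frozenset({"pct_free", "lifetime_risk_pct"})

Decomposition = namedtuple("Decomposition", "d_tle d_free d_cvd pct_free_of_gain")


@dataclass
class MetricsTable:
    """Collection of metric rows keyed by (period, subgroup)."""

    df: pd.DataFrame
    scheme: str = ""
    standardized: bool = False

    def __post_init__(self) -> None:
        for col in KEY_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"metrics table lacks key column {col!r}")
        dup = self.df.duplicated(list(KEY_COLUMNS))
        if dup.any():
            keys = self.df.loc[dup, list(KEY_COLUMNS)].values.tolist()
            raise ValueError(f"duplicate (period, subgroup) keys: {keys}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def row(self, period: str, subgroup: str) -> pd.Series:
        m = (self.df["period"] == period) & (self.df["subgroup"] == subgroup)
        if not m.any():
            raise KeyError(f"no row for period={period!r}, subgroup={subgroup!r}")
        return self.df[m].iloc[0]

    def value(self, metric: str, period: str, subgroup: str) -> float:
        row = self.row(period, subgroup)
        if metric not in row.index:
            raise KeyError(f"unknown metric {metric!r}")
        return float(row[metric])

    @property
    def periods(self) -> list[str]:
        return list(dict.fromkeys(self.df["period"]))

    @property
    def subgroups(self) -> list[str]:
        return list(dict.fromkeys(self.df["subgroup"]))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "MetricsTable":
        return cls(pd.read_csv(path), **kw)


def build_metrics_table(
    probs_by_context, scheme: str = "", standardized: bool = False
) -> MetricsTable:
    """One metric row per transition-probability context.

    ``probs_by_context`` is a mapping (period, subgroup) -> TransitionProbs
    or an iterable of TransitionProbs (contexts read off the objects).
    Duplicate contexts raise. Deterministic: rows equal the individual
    matrix-functional calls on the same probabilities.
    """
    if isinstance(probs_by_context, dict):
        items = []
        for key, tp in probs_by_context.items():
            period, subgroup = key
            if (tp.period, tp.subgroup) != (period, subgroup):
                tp = TransitionProbs(tp.array, tp.ages, period=period, subgroup=subgroup)
            items.append(tp)
    else:
        items = list(probs_by_context)
    seen = set()
    rows = []
    for tp in items:
        key = (tp.period, tp.subgroup)
        if key in seen:
            raise ValueError(f"duplicate context {key}")
        seen.add(key)
        r = metrics_row(tp)
        d = r.to_dict()
        d["lifetime_risk_pct"] = 100.0 * r.lifetime_risk
        rows.append(d)
    return MetricsTable(pd.DataFrame(rows), scheme=scheme, standardized=standardized)


def _round_gap(value: float, metric: str) -> float:
    if metric in PERCENT_METRICS:
        return float(round(value))
    return round(value, 1)


def disparity_gap(
    table: MetricsTable,
    metric: str,
    group_a: str,
    group_b: str,
    period: str,
    rounded: bool = True,
) -> float:
    """metric(group_a) - metric(group_b) in one period, on the native scale.

    Antisymmetric in the group arguments; zero for a group against itself.
    Rounded to one decimal for year-scale metrics and to whole points for
    percent-scale metrics (set ``rounded=False`` for the raw difference).
    """
    gap = table.value(metric, period, group_a) - table.value(metric, period, group_b)
    return _round_gap(gap, metric) if rounded else gap


@dataclass
class DisparityReport:
    """Per-period gaps in one metric between two groups, plus their change."""

    metric: str
    group_a: str
    group_b: str
    gaps: dict[str, float] = field(default_factory=dict)

    @property
    def change(self) -> float:
        """Last-period gap minus first-period gap."""
        vals = list(self.gaps.values())
        return round(vals[-1] - vals[0], 10)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "group_a": self.group_a,
                "group_b": self.group_b,
                "period": list(self.gaps),
                "gap": list(self.gaps.values()),
            }
        )


def disparity_report(
    table: MetricsTable,
    metric: str,
    group_a: str,
    group_b: str,
    periods: list[str] | None = None,
    rounded: bool = True,
) -> DisparityReport:
    periods = periods or table.periods
    gaps = {
        p: disparity_gap(table, metric, group_a, group_b, p, rounded=rounded)
        for p in periods
    }
    return DisparityReport(metric=metric, group_a=group_a, group_b=group_b, gaps=gaps)


def decompose_tle_gain(
    table: MetricsTable, group: str, first_period: str, last_period: str
) -> Decomposition:
    """Split a group's TLE change between two periods into CVD-free/CVD years.

    Returns (d_tle, d_free, d_cvd, pct_free_of_gain) where the share is
    100 * d_free / d_tle rounded to the nearest percent. A zero TLE change
    leaves the share undefined (NaN, with a warning).
    """
    a = table.row(first_period, group)
    b = table.row(last_period, group)
    d_tle = round(float(b["tle"] - a["tle"]), 10)
    d_free = round(float(b["e_free"] - a["e_free"]), 10)
    d_cvd = round(float(b["e_cvd"] - a["e_cvd"]), 10)
    if d_tle == 0.0:
        warnings.warn("TLE unchanged: share of gain undefined", RuntimeWarning)
        share = math.nan
    else:
        share = float(round(100.0 * d_free / d_tle))
    return Decomposition(d_tle, d_free, d_cvd, share)


def percent_cvd_free(e_free: float, tle: float, rounded: bool = True) -> float:
    """Share of total life expectancy spent CVD-free, in percent."""
    if tle <= 0:
        raise ValueError("tle must be positive")
    pct = 100.0 * e_free / tle
    return float(round(pct)) if rounded else pct


# --------------------------------------------------------------------------
# reference fixture and plotting
# --------------------------------------------------------------------------


def load_reference_tables() -> MetricsTable:
    """Published register-based reference estimates for Finland 1996-2020.

    Lifetime risk (percent) and expectancies at age 40 per period, gender and
    education, at printed precision. Useful for worked examples and for
    regression-testing the reporting arithmetic.
    """
    pkg = importlib.resources.files("cvdms") / "data"
    exp = pd.read_csv(pkg / "finland_reference_expectancies.csv")
    ltr = pd.read_csv(pkg / "finland_reference_lifetime_risk.csv")
    df = exp.merge(ltr, on=["period", "subgroup"], how="outer")
    return MetricsTable(df, scheme="reference")


def plot_metric_trend(
    table: MetricsTable, metric: str, subgroups: list[str] | None = None, ax=None
):
    """Line plot of one metric across periods, one line per subgroup."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for sg in subgroups or table.subgroups:
        sub = table.df[table.df["subgroup"] == sg]
        ax.plot(sub["period"], sub[metric], marker="o", label=sg)
    ax.set_xlabel("period")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=30)
    return ax
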