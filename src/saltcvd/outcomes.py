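"""Aggregate run results into reported outcome metrics.

Headline quantities: annual average event counts over an analysis window
(default 2013-2043), rates per 10,000 persons aged 40-69 (denominator: the
mean living population over the window), events averted by an intervention
relative to the baseline run, percent rate changes between two calendar
years, and subgroup decompositions of averted events by location and
gender. "Incident MI/stroke" pools new and recurrent events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import cohort_multiindex
from .engine import RunResult
from .errors import DomainError

#: derived metrics -> the engine tallies they pool
METRIC_SERIES = {
    "mi": ("new_mi", "recurrent_mi"),
    "stroke": ("new_stroke", "recurrent_stroke"),
    "cvd_deaths": ("mi_deaths", "stroke_deaths"),
    "other_deaths": ("other_deaths",),
}

DEFAULT_WINDOW = (2013, 2043)


def _window_mask(result: RunResult, window: tuple[int, int]) -> np.ndarray:
    years = result.month_years()
    lo, hi = window
    if lo > hi:
        raise DomainError(f"empty analysis window {window}")
    mask = (years >= lo) & (years <= hi)
    if not mask.any():
        raise DomainError(f"window {window} lies outside the simulated horizon")
    return mask


def _metric_monthly(result: RunResult, metric: str) -> np.ndarray:
    if metric not in METRIC_SERIES:
        raise DomainError(f"unknown metric {metric!r}; choose from {sorted(METRIC_SERIES)}")
    return sum(result.series[s] for s in METRIC_SERIES[metric])


def annual_average(
    result: RunResult,
    metric: str,
    window: tuple[int, int] = DEFAULT_WINDOW,
    per_cohort: bool = False,
):
    """Mean events per year over the window (total events / years spanned)."""
    mask = _window_mask(result, window)
    monthly = _metric_monthly(result, metric)[mask]
    n_years = mask.sum() / 12.0
    per = monthly.sum(axis=0) / n_years
    if per_cohort:
        return pd.Series(per, index=cohort_multiindex(), name=metric)
    return float(per.sum())


def mean_population(
    result: RunResult, window: tuple[int, int] = DEFAULT_WINDOW, per_cohort: bool = False
):
    """Mean living population aged 40-69 over the window."""
    mask = _window_mask(result, window)
    per = result.alive[mask].mean(axis=0)
    if per_cohort:
        return pd.Series(per, index=cohort_multiindex(), name="population")
    return float(per.sum())


def rate_per_10k(
    result: RunResult, metric: str, window: tuple[int, int] = DEFAULT_WINDOW
) -> float:
    """Annual events per 10,000 persons aged 40-69 over the window."""
    pop = mean_population(result, window)
    if pop <= 0:
        raise DomainError("population is zero over the analysis window")
    return 10_000.0 * annual_average(result, metric, window) / pop


def rate_per_10k_in_year(result: RunResult, metric: str, year: int) -> float:
    """Annual event rate per 10,000 within a single calendar year."""
    return rate_per_10k(result, metric, (year, year))


@dataclass
class OutcomeSummary:
    """Baseline-vs-intervention comparison over an analysis window."""

    window: tuple[int, int]
    per_cohort: pd.DataFrame  # cohort-indexed metrics
    overall: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.per_cohort.copy()
        overall = self.overall.reindex(out.columns)
        out.loc[("all", "all", "all"), :] = overall.to_numpy()
        return out


def averted(
    baseline: RunResult,
    intervention: RunResult,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> OutcomeSummary:
    """Events averted by the intervention: baseline minus intervention.

    Both runs must share the bundle, horizon and demographic stream; this is
    checked via the entrant/initial-population series.
    """
    if baseline.n_months != intervention.n_months:
        raise DomainError("baseline and intervention runs cover different horizons")
    if not np.array_equal(baseline.entrants, intervention.entrants) or (
        baseline.initial_total != intervention.initial_total
    ):
        raise DomainError("runs do not share a demographic stream")

    idx = cohort_multiindex()
    cols = {}
    for metric in ("mi", "stroke", "cvd_deaths"):
        base = annual_average(baseline, metric, window, per_cohort=True)
        intv = annual_average(intervention, metric, window, per_cohort=True)
        cols[f"baseline_{metric}"] = base
        cols[f"intervention_{metric}"] = intv
        cols[f"averted_{metric}"] = base - intv
    per_cohort = pd.DataFrame(cols, index=idx)

    pop_base = mean_population(baseline, window)
    overall = per_cohort.sum(axis=0)
    for metric in ("mi", "stroke", "cvd_deaths"):
        overall[f"baseline_rate_{metric}"] = 10_000.0 * overall[f"baseline_{metric}"] / pop_base
        pop_intv = mean_population(intervention, window)
        overall[f"intervention_rate_{metric}"] = (
            10_000.0 * overall[f"intervention_{metric}"] / pop_intv
        )
        overall[f"averted_rate_{metric}"] = (
            overall[f"baseline_rate_{metric}"] - overall[f"intervention_rate_{metric}"]
        )
        base_total = overall[f"baseline_{metric}"]
        overall[f"pct_averted_{metric}"] = (
            100.0 * overall[f"averted_{metric}"] / base_total if base_total > 0 else np.nan
        )
    return OutcomeSummary(window, per_cohort, overall)


def subgroup_shares(averted_per_cohort: pd.Series) -> dict:
    """Fractions of averted events by location and by gender.

    Raises :class:`DomainError` when the total is zero (undefined shares).
    """
    total = float(averted_per_cohort.sum())
    if total == 0:
        raise DomainError("subgroup shares undefined: zero total averted events")
    by_loc = averted_per_cohort.groupby(level="location").sum() / total
    by_gender = averted_per_cohort.groupby(level="gender").sum() / total
    return {
        "rural": float(by_loc.get("rural", 0.0)),
        "urban": float(by_loc.get("urban", 0.0)),
        "female": float(by_gender.get("female", 0.0)),
        "male": float(by_gender.get("male", 0.0)),
    }


def pct_rate_change(
    baseline: RunResult,
    intervention: RunResult,
    metric: str,
    year_a: int = 2013,
    year_b: int = 2043,
) -> float:
    """Growth (percentage points) of the relative rate reduction between two years.

    Returns 100 x [(base_b - int_b)/base_b - (base_a - int_a)/base_a]: how
    much larger, in percent of the baseline rate, the intervention's rate
    reduction is at ``year_b`` than at ``year_a``. Zero when the
    intervention has no effect.
    """
    out = 0.0
    for year, sign in ((year_b, 1.0), (year_a, -1.0)):
        base = rate_per_10k_in_year(baseline, metric, year)
        if base == 0:
            raise DomainError(f"baseline {metric} rate is zero in {year}; undefined")
        intv = rate_per_10k_in_year(intervention, metric, year)
        out += sign * 100.0 * (base - intv) / base
    return out
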