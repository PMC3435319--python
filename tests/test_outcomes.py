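"""Outcome aggregation: annual averages, rates, averted events, shares."""

import numpy as np
import pandas as pd
import pytest

from saltcvd import (
    EngineParams,
    Scenario,
    annual_average,
    averted,
    pct_rate_change,
    rate_per_10k,
    run,
    subgroup_shares,
)
from saltcvd.cohorts import N_COHORTS, cohort_multiindex
from saltcvd.engine import EVENT_METRICS, RunResult, StateVector
from saltcvd.errors import DomainError
from saltcvd.outcomes import mean_population


def synthetic_result(monthly_events, population, n_months=636, start_year=1998):
    """Hand-built RunResult with flat or per-month event series."""
    series = {m: np.zeros((n_months, N_COHORTS)) for m in EVENT_METRICS}
    ev = np.asarray(monthly_events, dtype=float)
    if ev.ndim == 0:
        ev = np.full(n_months, float(ev))
    series["new_mi"][:, 0] = ev
    alive = np.full((n_months, N_COHORTS), 0.0)
    alive[:, 0] = population
    params = EngineParams(start_year=start_year, end_year=start_year + n_months // 12 - 1)
    return RunResult(
        scenario=Scenario.baseline(),
        params=params,
        series=series,
        alive=alive,
        aged_out=np.zeros((n_months, N_COHORTS)),
        entrants=np.zeros((n_months, N_COHORTS)),
        initial_total=float(population),
        final_state=StateVector.zeros(),
    )


class TestAnnualAverage:
    def test_constant_events(self):
        r = synthetic_result(100.0, 1e5)
        assert annual_average(r, "mi", (2013, 2043)) == pytest.approx(1200.0)

    def test_zero_events(self):
        r = synthetic_result(0.0, 1e5)
        assert annual_average(r, "stroke", (2013, 2043)) == 0.0

    def test_linear_growth_equals_midpoint(self):
        n = 636
        r = synthetic_result(np.linspace(0, 100, n), 1e5)
        window = (1998, 2050)
        # arithmetic series: mean annual value = 12 x mean monthly value
        assert annual_average(r, "mi", window) == pytest.approx(12 * 50.0, rel=1e-3)

    def test_empty_window_rejected(self):
        r = synthetic_result(1.0, 1e5)
        with pytest.raises(DomainError):
            annual_average(r, "mi", (2045, 2043))
        with pytest.raises(DomainError):
            annual_average(r, "mi", (2100, 2110))


class TestRatePer10k:
    def test_paper_style_definition(self):
        # 1,969 events/year in 100,000 persons -> 196.9 per 10,000
        r = synthetic_result(1969.0 / 12.0, 1e5)
        assert rate_per_10k(r, "mi", (2013, 2043)) == pytest.approx(196.9)

    def test_population_scaling(self):
        r1 = synthetic_result(100.0, 1e5)
        r2 = synthetic_result(100.0, 2e5)
        assert rate_per_10k(r1, "mi") == pytest.approx(2 * rate_per_10k(r2, "mi"))

    def test_zero_population_rejected(self):
        r = synthetic_result(1.0, 0.0)
        with pytest.raises(DomainError):
            rate_per_10k(r, "mi")


class TestAverted:
    def test_identical_runs_avert_nothing(self, baseline_run):
        s = averted(baseline_run, baseline_run)
        assert np.all(s.per_cohort.filter(like="averted_").to_numpy() == 0.0)

    def test_hand_arithmetic(self):
        base = synthetic_result(200.0 / 12.0, 1e5)
        intv = synthetic_result(150.0 / 12.0, 1e5)
        s = averted(base, intv)
        assert s.overall["averted_mi"] == pytest.approx(50.0)
        assert s.overall["pct_averted_mi"] == pytest.approx(25.0)

    def test_dose_monotonicity_per_cohort(self, calibrated_bundle, baseline_run):
        one = run(calibrated_bundle, Scenario.preset("1g30y"))
        three = run(calibrated_bundle, Scenario.preset("3g30y"))
        a1 = averted(baseline_run, one).per_cohort["averted_mi"]
        a3 = averted(baseline_run, three).per_cohort["averted_mi"]
        assert (a3 > a1).all()

    def test_decomposition_sums_exactly(self, baseline_run, intervention_run):
        s = averted(baseline_run, intervention_run)
        for metric in ("mi", "stroke", "cvd_deaths"):
            assert s.overall[f"averted_{metric}"] == pytest.approx(
                s.per_cohort[f"averted_{metric}"].sum(), rel=1e-12
            )

    def test_rate_count_consistency(self, baseline_run, intervention_run):
        s = averted(baseline_run, intervention_run)
        pop_b = mean_population(baseline_run)
        pop_i = mean_population(intervention_run)
        for metric in ("mi", "stroke"):
            reconstructed = (
                s.overall[f"baseline_rate_{metric}"] * pop_b
                - s.overall[f"intervention_rate_{metric}"] * pop_i
            ) / 10_000.0
            assert reconstructed == pytest.approx(s.overall[f"averted_{metric}"], rel=1e-9)

    def test_mismatched_horizons_rejected(self, bundle, baseline_run):
        short = run(bundle, Scenario.baseline(), EngineParams(end_year=2020))
        with pytest.raises(DomainError):
            averted(baseline_run, short, (2013, 2020))


class TestSubgroupShares:
    def _series(self, values):
        return pd.Series(values, index=cohort_multiindex())

    def test_all_rural(self):
        v = [10.0 if c[2] == "rural" else 0.0 for c in cohort_multiindex()]
        shares = subgroup_shares(self._series(v))
        assert shares["rural"] == 1.0 and shares["urban"] == 0.0

    def test_partition_sums_to_one(self, baseline_run, intervention_run):
        s = averted(baseline_run, intervention_run)
        shares = subgroup_shares(s.per_cohort["averted_mi"])
        assert shares["rural"] + shares["urban"] == pytest.approx(1.0)
        assert shares["male"] + shares["female"] == pytest.approx(1.0)

    def test_worked_partition(self):
        v = [0.0] * 12
        idx = list(cohort_multiindex())
        rural_i = [i for i, c in enumerate(idx) if c[2] == "rural"]
        urban_i = [i for i, c in enumerate(idx) if c[2] == "urban"]
        v[rural_i[0]] = 27.0
        v[urban_i[0]] = 73.0
        shares = subgroup_shares(self._series(v))
        assert shares["rural"] == pytest.approx(0.27)
        assert shares["urban"] == pytest.approx(0.73)

    def test_zero_total_undefined(self):
        with pytest.raises(DomainError):
            subgroup_shares(self._series([0.0] * 12))


class TestPctRateChange:
    def test_null_intervention_is_zero(self, baseline_run):
        assert pct_rate_change(baseline_run, baseline_run, "mi") == 0.0

    def test_hand_arithmetic(self):
        base = synthetic_result(100.0, 1e5)
        intv_events = np.full(636, 100.0)
        years = 1998 + np.arange(636) // 12
        intv_events[years == 2043] = 92.0  # 8% lower rate in 2043 only
        intv = synthetic_result(intv_events, 1e5)
        assert pct_rate_change(base, intv, "mi") == pytest.approx(8.0)

    def test_cohort_homogeneity_under_uniform_slopes(
        self, baseline_run, intervention_run
    ):
        """With one RR slope family across cohorts, percent declines cluster.

        Echoes the property that all subgroups land within a few percentage
        points of each other.
        """
        pcts = []
        for metric in ("stroke",):
            base = baseline_run
            intv = intervention_run
            # per-cohort percent averted over the window
            s = averted(base, intv)
            pct = (
                100.0
                * s.per_cohort[f"averted_{metric}"]
                / s.per_cohort[f"baseline_{metric}"]
            )
            pcts.extend(pct.tolist())
        assert max(pcts) - min(pcts) <= 3.0
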