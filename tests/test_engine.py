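"""Markov engine: probability plumbing, stepping, aging, full runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltcvd import (
    DoseResponseParams,
    EngineParams,
    Scenario,
    StateVector,
    competing_split,
    rate_to_monthly_prob,
    run,
)
from saltcvd.cohorts import ALL_COHORTS, N_COHORTS, CohortKey
from saltcvd.engine import AMI, AST, DCVD, DOTH, PMI, PST, W, _RunContext, age_and_enter, step
from saltcvd.errors import DomainError


class TestRateConversion:
    def test_closed_form(self):
        assert rate_to_monthly_prob(0.0) == 0.0
        assert rate_to_monthly_prob(0.12) == pytest.approx(1 - math.exp(-0.01))

    @given(rate=st.floats(1e-6, 0.1))
    @settings(max_examples=50, derandomize=True)
    def test_small_rate_taylor_bound(self, rate):
        p = rate_to_monthly_prob(rate)
        assert p == pytest.approx(rate / 12.0, rel=0.01)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            rate_to_monthly_prob(-0.1)


class TestCompetingSplit:
    def test_closed_form_two_causes(self):
        p = competing_split([0.03, 0.01])
        total = 1 - math.exp(-0.04 / 12)
        assert p.sum() == pytest.approx(total)
        assert p[0] == pytest.approx(total * 0.75)
        assert p[1] == pytest.approx(total * 0.25)
        assert p[0] == pytest.approx(0.0024958, abs=1e-7)
        assert p[1] == pytest.approx(0.0008319, abs=1e-7)

    def test_equal_rates_split_equally(self):
        p = competing_split([0.02, 0.02])
        assert p[0] == pytest.approx(p[1])

    def test_single_cause_reduces_to_rate_conversion(self):
        p = competing_split([0.05])
        assert p[0] == pytest.approx(rate_to_monthly_prob(0.05))

    def test_zero_rates_give_zero(self):
        assert np.all(competing_split([0.0, 0.0]) == 0.0)
        assert competing_split([]).size == 0

    @given(rates=st.lists(st.floats(0.0, 2.0), min_size=1, max_size=5))
    @settings(max_examples=100, derandomize=True)
    def test_total_probability_identity(self, rates):
        p = competing_split(rates)
        assert p.sum() == pytest.approx(1 - math.exp(-sum(rates) / 12.0))
        assert np.all(p >= 0)


def _ctx(bundle, params=None, scenario=None):
    params = params or EngineParams(end_year=1999)
    return _RunContext.build(bundle, scenario or Scenario.baseline(), params)


class TestStep:
    def test_zero_rates_are_null_dynamics(self, bundle):
        zeroed = bundle.copy()
        zeroed.rates.iloc[:, :7] = 0.0
        ctx = _ctx(zeroed)
        state = StateVector.zeros()
        state.counts[:, W] = 500.0
        state.counts[:, PMI] = 100.0
        new, tallies = step(state, 0, ctx)
        np.testing.assert_array_equal(new.counts, state.counts)
        assert all(np.all(v == 0) for v in tallies.values())

    def test_mass_conservation_without_entrants(self, bundle):
        ctx = _ctx(bundle)
        state = StateVector.zeros()
        state.counts[:, W] = 1000.0
        state.counts[:, AMI] = 30.0
        state.counts[:, PST] = 70.0
        new, _ = step(state, 5, ctx)
        assert new.total == pytest.approx(state.total, rel=1e-12)

    @given(
        counts=st.lists(st.floats(0.0, 1e6), min_size=5, max_size=5),
        month=st.integers(0, 23),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mass_conservation_property(self, bundle, counts, month):
        ctx = _ctx(bundle)
        state = StateVector.zeros()
        state.counts[:, :5] = np.array(counts)[None, :]
        new, _ = step(state, month, ctx)
        assert new.total == pytest.approx(state.total, rel=1e-12, abs=1e-9)

    def test_two_month_toy_matches_transition_matrix(self, bundle):
        """Hand-specified rates: engine tallies equal a transition-matrix product.

        The matrix is built here from first principles (1-exp conversions and
        competing-risks shares) as an independent expression of the same
        dynamics.
        """
        toy = bundle.copy()
        r_mi, r_st, r_rmi, r_rst, cf_mi, cf_st, r_bg = (
            0.06, 0.02, 0.2, 0.15, 0.3, 0.4, 0.04,
        )
        toy.rates["first_mi_rate"] = r_mi
        toy.rates["first_stroke_rate"] = r_st
        toy.rates["recurrent_mi_rate"] = r_rmi
        toy.rates["recurrent_stroke_rate"] = r_rst
        toy.rates["mi_case_fatality"] = cf_mi
        toy.rates["stroke_case_fatality"] = cf_st
        toy.rates["background_mortality_rate"] = r_bg
        toy.rates[["trend_mi", "trend_stroke", "trend_background"]] = 1.0

        # transition matrix rows: from-state, columns: to-state
        T = np.zeros((7, 7))
        tot_w = r_mi + r_st + r_bg
        p_exit_w = 1 - math.exp(-tot_w / 12)
        p_mi = p_exit_w * r_mi / tot_w
        p_st = p_exit_w * r_st / tot_w
        p_bg = p_exit_w * r_bg / tot_w
        T[W] = [1 - p_exit_w, p_mi, p_st, 0, 0, 0, p_bg]
        T[AMI] = [0, 0, 0, 1 - cf_mi, 0, cf_mi, 0]
        T[AST] = [0, 0, 0, 0, 1 - cf_st, cf_st, 0]
        tot_pmi = r_rmi + r_bg
        p_exit_pmi = 1 - math.exp(-tot_pmi / 12)
        T[PMI] = [0, p_exit_pmi * r_rmi / tot_pmi, 0, 1 - p_exit_pmi, 0, 0,
                  p_exit_pmi * r_bg / tot_pmi]
        tot_pst = r_rst + r_bg
        p_exit_pst = 1 - math.exp(-tot_pst / 12)
        T[PST] = [0, 0, p_exit_pst * r_rst / tot_pst, 0, 1 - p_exit_pst, 0,
                  p_exit_pst * r_bg / tot_pst]
        T[DCVD, DCVD] = 1.0
        T[DOTH, DOTH] = 1.0

        v = np.zeros(7)
        v[W], v[PMI] = 1000.0, 200.0

        ctx = _ctx(toy)
        state = StateVector.zeros()
        state.counts[:] = v[None, :]
        expected = v.copy()
        for month in range(2):
            state, tallies = step(state, month, ctx)
            new_mi_expected = expected[W] * p_mi
            rec_mi_expected = expected[PMI] * p_exit_pmi * r_rmi / tot_pmi
            mi_deaths_expected = expected[AMI] * cf_mi
            expected = expected @ T
            assert tallies["new_mi"][0] == pytest.approx(new_mi_expected, rel=1e-12)
            assert tallies["recurrent_mi"][0] == pytest.approx(rec_mi_expected, rel=1e-12)
            assert tallies["mi_deaths"][0] == pytest.approx(mi_deaths_expected, rel=1e-12)
            np.testing.assert_allclose(state.counts[0], expected, rtol=1e-12)


class TestAging:
    def test_no_aging_no_entrants_is_identity(self, small_closed_bundle):
        state = StateVector.zeros()
        state.counts[:, W] = 800.0
        new, out, ent = age_and_enter(
            state, 1998, small_closed_bundle.population, aging=False
        )
        np.testing.assert_array_equal(new.counts, state.counts)
        assert np.all(out == 0) and np.all(ent == 0)

    def test_steady_state_band_size(self, bundle):
        """Constant entrants E/month with no mortality: 40-49 band -> 120 E."""
        from conftest import closed_population

        zeroed = closed_population(bundle, 0.0)  # empty start, entrants only
        zeroed.rates.iloc[:, :7] = 0.0
        params = EngineParams(start_year=1998, end_year=2050)
        zeroed.population.entrants.loc[:, :] = 1200.0  # 100 persons/month
        result = run(zeroed, Scenario.baseline(), params)
        band40 = [
            result.alive[-1, i]
            for i, c in enumerate(ALL_COHORTS)
            if c.age_band == "40-49"
        ]
        # geometric approach to 120 x 100 persons; 53 years ~ 5.3 mean residence times
        assert all(abs(b - 12000.0) / 12000.0 < 0.02 for b in band40)

    def test_terminal_band_decays_without_inflow(self, small_closed_bundle):
        zeroed = small_closed_bundle.copy()
        zeroed.rates.iloc[:, :7] = 0.0
        result = run(zeroed, Scenario.baseline(), EngineParams(end_year=2007))
        i60 = [i for i, c in enumerate(ALL_COHORTS) if c.age_band == "60-69"][0]
        series = result.alive[:, i60]
        assert np.all(np.diff(series) <= 1e-9)
        assert series[-1] < series[0]


class TestRun:
    def test_null_dose_response_equals_baseline(self, bundle):
        params = EngineParams(
            end_year=2020,
            dose_response=DoseResponseParams(
                dsbp_hypertensive_per3g=0.0, dsbp_normotensive_per3g=0.0
            ),
        )
        base = run(bundle, Scenario.baseline(), params)
        intv = run(bundle, Scenario.preset("3g30y"), params)
        for k in base.series:
            np.testing.assert_array_equal(base.series[k], intv.series[k])

    def test_intervention_events_never_exceed_baseline(
        self, calibrated_bundle, baseline_run, intervention_run
    ):
        for metric in ("new_mi", "recurrent_mi", "new_stroke", "recurrent_stroke"):
            base_cum = baseline_run.series[metric].sum(axis=0)
            intv_cum = intervention_run.series[metric].sum(axis=0)
            assert np.all(intv_cum <= base_cum + 1e-9)

    def test_deterministic(self, bundle):
        a = run(bundle, Scenario.preset("3g30y"), EngineParams(end_year=2015))
        b = run(bundle, Scenario.preset("3g30y"), EngineParams(end_year=2015))
        for k in a.series:
            np.testing.assert_array_equal(a.series[k], b.series[k])

    def test_tidy_export_schema(self, bundle):
        result = run(bundle, Scenario.baseline(), EngineParams(end_year=1998))
        df = result.to_frame()
        assert list(df.columns) == [
            "year", "month", "gender", "age_band", "location", "metric", "value",
        ]
        assert set(df["metric"]) >= {"new_mi", "alive", "other_deaths"}
        assert len(df[df.metric == "alive"]) == 12 * N_COHORTS
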