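"""Open-cohort Markov engine: twelve cohorts, seven states, monthly steps.

States per cohort: well (no MI/stroke history), acute MI (this month),
acute stroke (this month), post-MI, post-stroke, and the two absorbing
death states (cardiovascular, other causes). Each monthly cycle:

* occupants of an acute state resolve — they die with the case-fatality
  probability or move to the corresponding post-event state;
* well occupants face competing risks of a first MI, a first stroke and
  non-CVD death; post-event occupants face recurrence and non-CVD death;
* annual secular trend multipliers compound at calendar-year boundaries and
  scale the underlying rates; a salt-reduction scenario scales first and
  recurrent event rates by the lagged relative risks;
* one-twelfth-of-a-decade (1/120 per month) of every living state flows to
  the next age band (memoryless aging); occupants of 60-69 exit the model;
  census-style new entrants are added to the well state of the 40-49 band.

The simulation is an expected-value (cohort) calculation on real-valued
counts: deterministic given its inputs. Mass is conserved exactly — persons
in = alive + cumulative deaths + cumulative aged-out, every month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import AGING_CHAINS, ALL_COHORTS, GENDERS, LOCATIONS, N_COHORTS
from .errors import ConfigurationError, DomainError, EngineError
from .exposure import (
    DoseResponseParams,
    ExposureEffect,
    LagKernel,
    RiskEquationParams,
    Scenario,
    exposure_effect,
)
from .inputs import InputBundle, validate_bundle

STATE_NAMES = (
    "well",
    "acute_mi",
    "acute_stroke",
    "post_mi",
    "post_stroke",
    "cvd_death",
    "other_death",
)
W, AMI, AST, PMI, PST, DCVD, DOTH = range(7)

LIVING = slice(W, PST + 1)  # states subject to aging

EVENT_METRICS = (
    "new_mi",
    "recurrent_mi",
    "new_stroke",
    "recurrent_stroke",
    "mi_deaths",
    "stroke_deaths",
    "other_deaths",
)


# --------------------------------------------------------------------------
# probability plumbing


def rate_to_monthly_prob(annual_rate):
    """Actuarial conversion of an annual rate to a monthly probability.

    p = 1 - exp(-rate/12); valid for any non-negative rate.
    """
    r = np.asarray(annual_rate, dtype=float)
    if np.any(r < 0):
        raise DomainError("annual rate must be non-negative")
    p = -np.expm1(-r / 12.0)
    return float(p) if np.isscalar(annual_rate) else p


def competing_split(cause_rates) -> np.ndarray:
    """Allocate one monthly exit probability across competing causes.

    Total monthly probability is 1 - exp(-sum(rates)/12); cause *i* receives
    the share rate_i / sum(rates). All-zero (or empty) rates give all-zero
    probabilities. With a single cause this reduces to
    :func:`rate_to_monthly_prob`.
    """
    rates = np.asarray(cause_rates, dtype=float)
    if np.any(rates < 0):
        raise DomainError("cause rates must be non-negative")
    total = rates.sum(axis=0)
    p_total = -np.expm1(-np.asarray(total) / 12.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(total > 0, rates / np.where(total > 0, total, 1.0), 0.0)
    return shares * p_total


# --------------------------------------------------------------------------
# run configuration and results


@dataclass(frozen=True)
class EngineParams:
    start_year: int = 1998
    end_year: int = 2050  # last simulated calendar year (inclusive)
    dose_response: DoseResponseParams = field(default_factory=DoseResponseParams)
    risk: RiskEquationParams = field(default_factory=RiskEquationParams)
    kernel: LagKernel = field(default_factory=LagKernel)
    #: allow post-MI occupants to suffer first strokes and vice versa
    cross_morbidity: bool = False
    #: monthly 1/120 flow between age bands (off only for reduced test setups)
    aging: bool = True

    @property
    def n_months(self) -> int:
        return (self.end_year - self.start_year + 1) * 12


@dataclass
class StateVector:
    """Counts (real-valued persons) per cohort per state, shape (12, 7)."""

    counts: np.ndarray

    @staticmethod
    def zeros() -> "StateVector":
        return StateVector(np.zeros((N_COHORTS, 7)))

    @property
    def alive(self) -> np.ndarray:
        return self.counts[:, LIVING].sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class RunResult:
    """Monthly event tallies and population series for one scenario run."""

    scenario: Scenario
    params: EngineParams
    series: dict  # metric -> (n_months, 12) array
    alive: np.ndarray  # (n_months, 12), end-of-month living persons
    aged_out: np.ndarray  # (n_months, 12), persons exiting past 60-69
    entrants: np.ndarray  # (n_months, 12), persons entering 40-49
    initial_total: float
    final_state: StateVector

    @property
    def n_months(self) -> int:
        return self.alive.shape[0]

    def month_years(self) -> np.ndarray:
        return self.params.start_year + np.arange(self.n_months) // 12

    def mass_balance_residual(self) -> np.ndarray:
        """Relative conservation residual per month (should be ~1e-15)."""
        cum_deaths = np.cumsum(
            self.series["mi_deaths"].sum(axis=1)
            + self.series["stroke_deaths"].sum(axis=1)
            + self.series["other_deaths"].sum(axis=1)
        )
        cum_out = np.cumsum(self.aged_out.sum(axis=1))
        cum_in = np.cumsum(self.entrants.sum(axis=1))
        balance = self.alive.sum(axis=1) + cum_deaths + cum_out - cum_in
        return (balance - self.initial_total) / self.initial_total

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: year, month, gender, age_band, location, metric, value."""
        n = self.n_months
        years = np.repeat(self.month_years(), N_COHORTS)
        months = np.repeat(np.arange(n) % 12 + 1, N_COHORTS)
        genders = np.tile([c.gender for c in ALL_COHORTS], n)
        bands = np.tile([c.age_band for c in ALL_COHORTS], n)
        locs = np.tile([c.location for c in ALL_COHORTS], n)
        metrics = dict(self.series)
        metrics["alive"] = self.alive
        frames = [
            pd.DataFrame(
                {
                    "year": years,
                    "month": months,
                    "gender": genders,
                    "age_band": bands,
                    "location": locs,
                    "metric": name,
                    "value": arr.ravel(),
                }
            )
            for name, arr in metrics.items()
        ]
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# precomputed per-run arrays


@dataclass
class _RunContext:
    first_mi: np.ndarray
    first_stroke: np.ndarray
    rec_mi: np.ndarray
    rec_stroke: np.ndarray
    cf_mi: np.ndarray
    cf_stroke: np.ndarray
    background: np.ndarray
    trend_mi: np.ndarray
    trend_stroke: np.ndarray
    trend_background: np.ndarray
    effect: ExposureEffect
    params: EngineParams
    entrants_monthly: np.ndarray  # (n_months, 12)

    @staticmethod
    def build(bundle: InputBundle, scenario: Scenario, params: EngineParams) -> "_RunContext":
        r = bundle.rates.loc[[c.as_tuple() for c in ALL_COHORTS]]
        prevalence = np.array(
            [float(bundle.hypertension.loc[c.as_tuple()]) for c in ALL_COHORTS]
        )
        effect = exposure_effect(
            scenario,
            prevalence,
            params.dose_response,
            params.risk,
            params.kernel,
            params.start_year,
            params.n_months,
        )

        years = np.arange(params.start_year, params.end_year + 1)
        ent_df = bundle.population.entrants
        missing = [int(y) for y in years if y not in ent_df.index]
        if missing:
            raise ConfigurationError(f"no entrant projection for year {missing[0]}")
        ent_year = np.zeros((len(years), N_COHORTS))
        pairs = [(g, loc) for g in GENDERS for loc in LOCATIONS]
        for (g, loc), (i40, _, _) in zip(pairs, AGING_CHAINS):
            ent_year[:, i40] = ent_df.loc[years, (g, loc)].to_numpy()
        entrants_monthly = ent_year[np.arange(params.n_months) // 12] / 12.0

        return _RunContext(
            first_mi=r["first_mi_rate"].to_numpy(),
            first_stroke=r["first_stroke_rate"].to_numpy(),
            rec_mi=r["recurrent_mi_rate"].to_numpy(),
            rec_stroke=r["recurrent_stroke_rate"].to_numpy(),
            cf_mi=r["mi_case_fatality"].to_numpy(),
            cf_stroke=r["stroke_case_fatality"].to_numpy(),
            background=r["background_mortality_rate"].to_numpy(),
            trend_mi=r["trend_mi"].to_numpy(),
            trend_stroke=r["trend_stroke"].to_numpy(),
            trend_background=r["trend_background"].to_numpy(),
            effect=effect,
            params=params,
            entrants_monthly=entrants_monthly,
        )

    def all_probs(self) -> dict:
        """Cause-specific monthly probabilities, vectorized over all months.

        The cycle probabilities are state-independent, so they are computed
        once per run. Returns arrays shaped (causes, n_months, n_cohorts).
        """
        n = self.params.n_months
        yi = np.arange(n) // 12  # whole years since baseline; trends step yearly
        tm = self.trend_mi[None, :] ** yi[:, None]
        ts = self.trend_stroke[None, :] ** yi[:, None]
        tb = self.trend_background[None, :] ** yi[:, None]
        rr_mi = self.effect.rr["mi"]
        rr_st = self.effect.rr["stroke"]

        r_mi = self.first_mi[None, :] * tm * rr_mi
        r_st = self.first_stroke[None, :] * ts * rr_st
        r_bg = self.background[None, :] * tb
        p_w = competing_split(np.stack([r_mi, r_st, r_bg]))

        zeros = np.zeros_like(r_bg)
        if self.params.cross_morbidity:
            # post-event occupants may also suffer the other first event,
            # at first-event rates
            cross_pmi, cross_pst = r_st, r_mi
        else:
            cross_pmi, cross_pst = zeros, zeros
        p_pmi = competing_split(
            np.stack([self.rec_mi[None, :] * tm * rr_mi, cross_pmi, r_bg])
        )
        p_pst = competing_split(
            np.stack([self.rec_stroke[None, :] * ts * rr_st, cross_pst, r_bg])
        )
        return {
            "well": p_w,  # rows: first MI, first stroke, other death
            "post_mi": p_pmi,  # rows: recurrent MI, cross stroke, other death
            "post_stroke": p_pst,  # rows: recurrent stroke, cross MI, other death
            "cf_mi": self.cf_mi,
            "cf_stroke": self.cf_stroke,
        }

    def monthly_probs(self, month: int) -> dict:
        """Per-cohort cause-specific monthly probabilities for one cycle."""
        probs = getattr(self, "_probs_cache", None)
        if probs is None:
            probs = self.all_probs()
            self._probs_cache = probs
        return {
            "well": probs["well"][:, month],
            "post_mi": probs["post_mi"][:, month],
            "post_stroke": probs["post_stroke"][:, month],
            "cf_mi": self.cf_mi,
            "cf_stroke": self.cf_stroke,
        }


# --------------------------------------------------------------------------
# single step


def step(
    state: StateVector, month: int, ctx: _RunContext
) -> tuple[StateVector, dict]:
    """Advance one monthly cycle. Returns the new state and event tallies.

    Mass-conserving by construction: every flow is subtracted from its
    source and added to exactly one destination.
    """
    c = state.counts
    probs = ctx.monthly_probs(month)
    p_mi, p_st, p_bg = probs["well"]
    p_recmi, p_cross_st, p_bg_pmi = probs["post_mi"]
    p_recst, p_cross_mi, p_bg_pst = probs["post_stroke"]

    well = c[:, W]
    new_mi = well * p_mi
    new_st = well * p_st
    well_d = well * p_bg

    mi_d = c[:, AMI] * probs["cf_mi"]
    ami_surv = c[:, AMI] - mi_d
    st_d = c[:, AST] * probs["cf_stroke"]
    ast_surv = c[:, AST] - st_d

    rec_mi = c[:, PMI] * p_recmi
    cross_st = c[:, PMI] * p_cross_st  # first stroke among MI survivors
    pmi_d = c[:, PMI] * p_bg_pmi
    rec_st = c[:, PST] * p_recst
    cross_mi = c[:, PST] * p_cross_mi  # first MI among stroke survivors
    pst_d = c[:, PST] * p_bg_pst

    out = np.empty_like(c)
    out[:, W] = well - new_mi - new_st - well_d
    out[:, AMI] = new_mi + rec_mi + cross_mi
    out[:, AST] = new_st + rec_st + cross_st
    out[:, PMI] = c[:, PMI] - rec_mi - cross_st - pmi_d + ami_surv
    out[:, PST] = c[:, PST] - rec_st - cross_mi - pst_d + ast_surv
    out[:, DCVD] = c[:, DCVD] + mi_d + st_d
    out[:, DOTH] = c[:, DOTH] + well_d + pmi_d + pst_d

    if np.any(out < -1e-9):
        i, j = np.argwhere(out < -1e-9)[0]
        raise EngineError(
            f"negative count in state {STATE_NAMES[j]} of cohort "
            f"{ALL_COHORTS[i]} at month {month}"
        )

    tallies = {
        "new_mi": new_mi + cross_mi,
        "recurrent_mi": rec_mi,
        "new_stroke": new_st + cross_st,
        "recurrent_stroke": rec_st,
        "mi_deaths": mi_d,
        "stroke_deaths": st_d,
        "other_deaths": well_d + pmi_d + pst_d,
    }
    return StateVector(out), tallies


def age_and_enter(
    state: StateVector,
    year: int,
    population,
    aging: bool = True,
) -> tuple[StateVector, np.ndarray, np.ndarray]:
    """Monthly aging flow (1/120 per band) plus new 40-49 entrants.

    Returns (new state, aged-out persons per cohort, entrants per cohort).
    """
    c = state.counts.copy()
    aged_out = np.zeros(N_COHORTS)
    if aging:
        for i40, i50, i60 in AGING_CHAINS:
            f40 = c[i40, LIVING] / 120.0
            f50 = c[i50, LIVING] / 120.0
            f60 = c[i60, LIVING] / 120.0
            c[i40, LIVING] -= f40
            c[i50, LIVING] += f40 - f50
            c[i60, LIVING] += f50 - f60
            aged_out[i60] = f60.sum()

    entrants = np.zeros(N_COHORTS)
    if population is not None:
        e = population.entrants_for(year)
        for (g, loc), (i40, _, _) in zip(
            ((g, loc) for g in GENDERS for loc in LOCATIONS), AGING_CHAINS
        ):
            monthly = float(e[(g, loc)]) / 12.0
            c[i40, W] += monthly
            entrants[i40] = monthly
    return StateVector(c), aged_out, entrants


# --------------------------------------------------------------------------
# full run


def run(
    bundle: InputBundle,
    scenario: Scenario,
    params: EngineParams | None = None,
    validate: bool = True,
) -> RunResult:
    """Simulate the full horizon under one scenario. Deterministic."""
    params = params or EngineParams()
    if validate:
        validate_bundle(bundle)
    if scenario.target_g > 0 and scenario.start_year > params.end_year:
        raise ConfigurationError("scenario starts after the simulation horizon ends")

    ctx = _RunContext.build(bundle, scenario, params)
    n = params.n_months

    state = StateVector.zeros()
    init = np.array(
        [float(bundle.population.initial.loc[c.as_tuple()]) for c in ALL_COHORTS]
    )
    state.counts[:, W] = init
    initial_total = float(init.sum())

    series = {m: np.zeros((n, N_COHORTS)) for m in EVENT_METRICS}
    alive = np.zeros((n, N_COHORTS))
    aged_out = np.zeros((n, N_COHORTS))
    entrants = np.zeros((n, N_COHORTS))

    for m in range(n):
        state, tallies = step(state, m, ctx)
        c = state.counts
        if params.aging:
            for i40, i50, i60 in AGING_CHAINS:
                f40 = c[i40, LIVING] / 120.0
                f50 = c[i50, LIVING] / 120.0
                f60 = c[i60, LIVING] / 120.0
                c[i40, LIVING] -= f40
                c[i50, LIVING] += f40 - f50
                c[i60, LIVING] += f50 - f60
                aged_out[m, i60] = f60.sum()
        ent = ctx.entrants_monthly[m]
        c[:, W] += ent
        entrants[m] = ent
        for k, v in tallies.items():
            series[k][m] = v
        alive[m] = state.alive

    return RunResult(
        scenario=scenario,
        params=params,
        series=series,
        alive=alive,
        aged_out=aged_out,
        entrants=entrants,
        initial_total=initial_total,
        final_state=state,
    )
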