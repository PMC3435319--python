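"""Synthetic input bundles: stratified rate tables, demographics, prevalence.

The model consumes four stratified tables — event/mortality rates with
secular trends, population projections, hypertension prevalence, and
province-level iodization — whose real-world counterparts come from WHO and
census sources. Those source values are not redistributable here, so this
module generates statistically structured synthetic stand-ins: event rates
rise with age, MI rates are highest among urban men, secular trends drift
multiplicatively, and hypertension prevalence sits in the 10-40% range,
higher in urban and older cohorts. A calibration helper then scales event
rates so the baseline run reproduces stated aggregate totals, which is the
supported route to India-like magnitudes.

All rates are stored as *annual* rates (events per person-year); conversion
to monthly probabilities is done once, inside the engine.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import ALL_COHORTS, GENDERS, LOCATIONS, cohort_multiindex
from .errors import CalibrationError, ConfigurationError, FormatError
from .iodine import IodineInputs, IodineStratum

GENERATOR_VERSION = "1.0"

RATE_COLUMNS = [
    "first_mi_rate",
    "first_stroke_rate",
    "recurrent_mi_rate",
    "recurrent_stroke_rate",
    "mi_case_fatality",
    "stroke_case_fatality",
    "background_mortality_rate",
    "trend_mi",
    "trend_stroke",
    "trend_background",
]

_RATE_COLS_NONNEG = RATE_COLUMNS[:4] + ["background_mortality_rate"]
_PROB_COLS = ["mi_case_fatality", "stroke_case_fatality"]
_TREND_COLS = ["trend_mi", "trend_stroke", "trend_background"]


# --------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PopulationProjection:
    """Initial cohort sizes plus yearly new entrants to the 40-49 band.

    ``initial`` is a Series over the 12-cohort MultiIndex; ``entrants`` is a
    DataFrame indexed by calendar year with MultiIndex columns
    (gender, location) giving persons entering the 40-49 band that year.
    """

    initial: pd.Series
    entrants: pd.DataFrame

    def entrants_for(self, year: int) -> pd.Series:
        if year not in self.entrants.index:
            raise ConfigurationError(f"no entrant projection for year {year}")
        return self.entrants.loc[year]


@dataclass
class InputBundle:
    """Everything one simulation run consumes."""

    rates: pd.DataFrame  # 12 cohorts x RATE_COLUMNS
    population: PopulationProjection
    hypertension: pd.Series  # prevalence per cohort
    iodine: IodineInputs
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "InputBundle":
        return InputBundle(
            rates=self.rates.copy(),
            population=PopulationProjection(
                self.population.initial.copy(), self.population.entrants.copy()
            ),
            hypertension=self.hypertension.copy(),
            iodine=self.iodine,
            metadata=dict(self.metadata),
        )

    def equals(self, other: "InputBundle") -> bool:
        return (
            self.rates.equals(other.rates)
            and self.population.initial.equals(other.population.initial)
            and self.population.entrants.equals(other.population.entrants)
            and self.hypertension.equals(other.hypertension)
            and self.iodine == other.iodine
        )


# --------------------------------------------------------------------------
# generator configuration


def _rng_range(name: str, lo: float, hi: float) -> tuple[float, float]:
    if lo > hi:
        raise ConfigurationError(f"range {name}: min {lo} > max {hi}")
    return (lo, hi)


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling ranges for the synthetic tables.

    Base rates apply to the rural-female 40-49 cohort; gradients/factors are
    multiplicative. Defaults give order-of-magnitude plausible Indian adult
    values; calibration is the route to exact aggregate magnitudes.
    """

    # first-event rates, events/person-year at the reference cohort
    first_mi_base: tuple[float, float] = (0.004, 0.008)
    mi_age_gradient: tuple[float, float] = (1.6, 2.2)  # per decade of age
    mi_male_factor: tuple[float, float] = (1.4, 1.8)
    mi_urban_factor: tuple[float, float] = (1.3, 1.7)
    first_stroke_base: tuple[float, float] = (0.0008, 0.0016)
    stroke_age_gradient: tuple[float, float] = (1.8, 2.4)
    stroke_male_factor: tuple[float, float] = (1.1, 1.4)
    stroke_urban_factor: tuple[float, float] = (0.85, 1.1)
    # recurrence among survivors, as a multiple of the first-event rate
    recurrent_mi_multiplier: tuple[float, float] = (3.0, 5.0)
    recurrent_stroke_multiplier: tuple[float, float] = (3.0, 5.0)
    # case fatality per acute event-month
    mi_case_fatality_base: tuple[float, float] = (0.15, 0.25)
    stroke_case_fatality_base: tuple[float, float] = (0.20, 0.35)
    case_fatality_age_gradient: tuple[float, float] = (1.1, 1.3)
    # non-MI/non-stroke mortality, deaths/person-year at reference cohort
    background_base: tuple[float, float] = (0.004, 0.007)
    background_age_gradient: tuple[float, float] = (2.2, 2.8)
    background_male_factor: tuple[float, float] = (1.1, 1.3)
    background_urban_factor: tuple[float, float] = (0.85, 1.0)
    # multiplicative annual secular trends
    trend_mi: tuple[float, float] = (1.005, 1.02)
    trend_stroke: tuple[float, float] = (1.000, 1.015)
    trend_background: tuple[float, float] = (0.985, 0.998)
    # hypertension prevalence (additive construction, clipped)
    htn_base: tuple[float, float] = (0.10, 0.18)  # rural 40-49
    htn_age_step: tuple[float, float] = (0.04, 0.08)  # per decade
    htn_urban_shift: tuple[float, float] = (0.08, 0.15)
    # demographics
    total_population: float = 2.0e8  # persons aged 40-69 at start
    rural_share: tuple[float, float] = (0.62, 0.68)
    male_share: tuple[float, float] = (0.50, 0.53)
    age_shares: tuple[float, float, float] = (0.45, 0.33, 0.22)
    entrants_per_year: tuple[float, float] = (1.2e7, 1.8e7)
    entrant_growth: tuple[float, float] = (1.000, 1.008)  # per year
    # cohort-level multiplicative jitter (lognormal sigma)
    jitter_sd: float = 0.05
    # iodine side-model: most provinces adequately iodized (headroom under a
    # few-gram cut), a couple with poor iodized-salt access, and a small
    # low-content mixture share in each
    n_provinces: int = 8
    n_low_access_provinces: int = 2
    province_salt_mean: tuple[float, float] = (8.0, 12.0)
    province_salt_sd: tuple[float, float] = (0.8, 1.5)
    iodine_coverage: tuple[float, float] = (0.80, 0.95)
    iodine_coverage_low_access: tuple[float, float] = (0.10, 0.40)
    iodine_content_adequate: tuple[float, float] = (35.0, 50.0)
    iodine_content_low: tuple[float, float] = (5.0, 12.0)
    iodine_low_content_fraction: tuple[float, float] = (0.0, 0.15)
    # timeline covered by the entrant projection
    start_year: int = 1998
    end_year: int = 2050

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple) and len(v) == 2 and all(isinstance(x, float) for x in v):
                _rng_range(f.name, v[0], v[1])
        if self.total_population <= 0:
            raise ConfigurationError("total_population must be positive")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be non-negative")


# --------------------------------------------------------------------------
# generation


def _u(rng: np.random.Generator, rr: tuple[float, float]) -> float:
    return float(rng.uniform(*rr))


def _jitter(rng: np.random.Generator, sd: float, n: int = 1) -> np.ndarray:
    if sd == 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, sd, size=n))


def generate_inputs(seed: int, config: GeneratorConfig | None = None) -> InputBundle:
    """Generate a complete synthetic :class:`InputBundle`.

    Pure function of ``(seed, config)``: identical arguments give a
    bit-identical bundle.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    idx = cohort_multiindex()

    mi_base = _u(rng, cfg.first_mi_base)
    mi_grad = _u(rng, cfg.mi_age_gradient)
    mi_male = _u(rng, cfg.mi_male_factor)
    mi_urban = _u(rng, cfg.mi_urban_factor)
    st_base = _u(rng, cfg.first_stroke_base)
    st_grad = _u(rng, cfg.stroke_age_gradient)
    st_male = _u(rng, cfg.stroke_male_factor)
    st_urban = _u(rng, cfg.stroke_urban_factor)
    rec_mi = _u(rng, cfg.recurrent_mi_multiplier)
    rec_st = _u(rng, cfg.recurrent_stroke_multiplier)
    cf_mi_base = _u(rng, cfg.mi_case_fatality_base)
    cf_st_base = _u(rng, cfg.stroke_case_fatality_base)
    cf_grad = _u(rng, cfg.case_fatality_age_gradient)
    bg_base = _u(rng, cfg.background_base)
    bg_grad = _u(rng, cfg.background_age_gradient)
    bg_male = _u(rng, cfg.background_male_factor)
    bg_urban = _u(rng, cfg.background_urban_factor)

    rows = []
    for c in ALL_COHORTS:
        j = _jitter(rng, cfg.jitter_sd, 7)
        male = c.gender == "male"
        urban = c.location == "urban"
        a = c.age_index
        f_mi = mi_base * mi_grad**a * (mi_male if male else 1.0) * (mi_urban if urban else 1.0)
        f_st = st_base * st_grad**a * (st_male if male else 1.0) * (st_urban if urban else 1.0)
        bg = bg_base * bg_grad**a * (bg_male if male else 1.0) * (bg_urban if urban else 1.0)
        rows.append(
            {
                "first_mi_rate": f_mi * j[0],
                "first_stroke_rate": f_st * j[1],
                "recurrent_mi_rate": f_mi * rec_mi * j[2],
                "recurrent_stroke_rate": f_st * rec_st * j[3],
                "mi_case_fatality": min(cf_mi_base * cf_grad**a * j[4], 0.95),
                "stroke_case_fatality": min(cf_st_base * cf_grad**a * j[5], 0.95),
                "background_mortality_rate": bg * j[6],
                "trend_mi": _u(rng, cfg.trend_mi),
                "trend_stroke": _u(rng, cfg.trend_stroke),
                "trend_background": _u(rng, cfg.trend_background),
            }
        )
    rates = pd.DataFrame(rows, index=idx, columns=RATE_COLUMNS)

    # hypertension prevalence
    htn_base = _u(rng, cfg.htn_base)
    htn_step = _u(rng, cfg.htn_age_step)
    htn_urban = _u(rng, cfg.htn_urban_shift)
    prev = []
    for c in ALL_COHORTS:
        p = htn_base + htn_step * c.age_index + (htn_urban if c.location == "urban" else 0.0)
        p += float(rng.uniform(-0.02, 0.02))
        prev.append(float(np.clip(p, 0.02, 0.8)))
    hypertension = pd.Series(prev, index=idx, name="prevalence")

    # demographics
    rural = _u(rng, cfg.rural_share)
    male_share = _u(rng, cfg.male_share)
    age_sh = np.asarray(cfg.age_shares, dtype=float)
    age_sh = age_sh / age_sh.sum()
    sizes = []
    for c in ALL_COHORTS:
        share = (
            (male_share if c.gender == "male" else 1 - male_share)
            * age_sh[c.age_index]
            * (rural if c.location == "rural" else 1 - rural)
        )
        sizes.append(cfg.total_population * share)
    initial = pd.Series(sizes, index=idx, name="initial_size")

    years = np.arange(cfg.start_year, cfg.end_year + 1)
    entr0 = _u(rng, cfg.entrants_per_year)
    growth = _u(rng, cfg.entrant_growth)
    cols = pd.MultiIndex.from_product([GENDERS, LOCATIONS], names=["gender", "location"])
    young = initial.xs("40-49", level="age_band")
    young_share = young / young.sum()
    entr = pd.DataFrame(
        np.outer(entr0 * growth ** (years - cfg.start_year), young_share[cols].to_numpy()),
        index=pd.Index(years, name="year"),
        columns=cols,
    )
    population = PopulationProjection(initial, entr)

    # iodine strata: deficiency is mostly an access problem, so most
    # provinces iodize adequately (headroom under a few-gram cut) while a
    # minority lack iodized-salt access; a small share of salt is iodized
    # at low content, which is where salt reduction can create new cases
    strata = []
    prov_pops = rng.uniform(2e7, 1.2e8, size=cfg.n_provinces)
    low_access = rng.choice(
        cfg.n_provinces, size=min(cfg.n_low_access_provinces, cfg.n_provinces),
        replace=False,
    )
    for i in range(cfg.n_provinces):
        low_frac = _u(rng, cfg.iodine_low_content_fraction)
        levels = (
            (low_frac, _u(rng, cfg.iodine_content_low)),
            (1.0 - low_frac, _u(rng, cfg.iodine_content_adequate)),
        )
        coverage = _u(
            rng,
            cfg.iodine_coverage_low_access if i in low_access else cfg.iodine_coverage,
        )
        strata.append(
            IodineStratum(
                province=f"province_{i + 1:02d}",
                population=float(prov_pops[i]),
                salt_mean=_u(rng, cfg.province_salt_mean),
                salt_sd=_u(rng, cfg.province_salt_sd),
                coverage=coverage,
                content_levels=levels,
            )
        )
    iodine = IodineInputs(tuple(strata))

    meta = {
        "seed": int(seed),
        "generator_version": GENERATOR_VERSION,
        "calibration": None,
    }
    bundle = InputBundle(rates, population, hypertension, iodine, meta)
    validate_bundle(bundle)
    return bundle


# --------------------------------------------------------------------------
# validation


def validate_bundle(bundle: InputBundle) -> None:
    """Schema/domain validation shared by the generator and the loader."""
    idx = cohort_multiindex()
    for name, table in (("rates", bundle.rates), ("hypertension", bundle.hypertension.to_frame())):
        missing = idx.difference(table.index)
        if len(missing):
            g, a, loc = missing[0]
            raise FormatError(f"{name} table is missing cohort row {g}/{a}/{loc}")
    missing_cols = [c for c in RATE_COLUMNS if c not in bundle.rates.columns]
    if missing_cols:
        raise FormatError(f"rates table is missing columns {missing_cols}")
    r = bundle.rates
    if (r[_RATE_COLS_NONNEG] < 0).any().any():
        raise FormatError("rates table contains negative rates")
    if ((r[_PROB_COLS] < 0) | (r[_PROB_COLS] > 1)).any().any():
        raise FormatError("case fatalities must lie in [0,1]")
    if (r[_TREND_COLS] <= 0).any().any():
        raise FormatError("trend factors must be positive")
    if ((bundle.hypertension < 0) | (bundle.hypertension > 1)).any():
        raise FormatError("hypertension prevalence must lie in [0,1]")
    missing_pop = idx.difference(bundle.population.initial.index)
    if len(missing_pop):
        g, a, loc = missing_pop[0]
        raise FormatError(f"population table is missing cohort row {g}/{a}/{loc}")
    if (bundle.population.initial < 0).any():
        raise FormatError("initial population counts must be non-negative")
    if (bundle.population.entrants < 0).any().any():
        raise FormatError("entrant counts must be non-negative")


# --------------------------------------------------------------------------
# serialization (UTF-8 CSV, one row per cohort, + JSON metadata sidecar)


def save_bundle(bundle: InputBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.rates.reset_index().to_csv(path / "rates.csv", index=False)

    pop_rows = bundle.population.initial.reset_index()
    pop_rows.columns = ["gender", "age_band", "location", "value"]
    pop_rows.insert(0, "kind", "initial")
    pop_rows["year"] = ""
    entr = bundle.population.entrants.stack(["gender", "location"], future_stack=True)
    entr = entr.reset_index()
    entr.columns = ["year", "gender", "location", "value"]
    entr.insert(0, "kind", "entrants")
    entr["age_band"] = "40-49"
    pop = pd.concat([pop_rows, entr], ignore_index=True)[
        ["kind", "gender", "age_band", "location", "year", "value"]
    ]
    pop.to_csv(path / "population.csv", index=False)

    bundle.hypertension.reset_index().to_csv(path / "hypertension.csv", index=False)
    bundle.iodine.to_frame().to_csv(path / "iodine.csv", index=False)
    meta = dict(bundle.metadata)
    meta["iodine_requirement_ug"] = bundle.iodine.requirement_ug
    meta["iodine_requirement_upper_ug"] = bundle.iodine.requirement_upper_ug
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_bundle(path: str | Path) -> InputBundle:
    path = Path(path)
    for fname in ("rates.csv", "population.csv", "hypertension.csv", "iodine.csv"):
        if not (path / fname).exists():
            raise FormatError(f"bundle at {path} is missing {fname}")

    rates = pd.read_csv(path / "rates.csv", float_precision="round_trip").set_index(["gender", "age_band", "location"])
    rates = _reindex_cohorts(rates, "rates.csv")[RATE_COLUMNS]

    pop = pd.read_csv(path / "population.csv", float_precision="round_trip")
    init_rows = pop[pop["kind"] == "initial"].set_index(["gender", "age_band", "location"])
    initial = _reindex_cohorts(init_rows, "population.csv")["value"].rename("initial_size")
    entr_rows = pop[pop["kind"] == "entrants"].copy()
    entr_rows["year"] = entr_rows["year"].astype(int)
    entrants = entr_rows.pivot_table(
        index="year", columns=["gender", "location"], values="value", aggfunc="sum"
    )
    cols = pd.MultiIndex.from_product([GENDERS, LOCATIONS], names=["gender", "location"])
    entrants = entrants.reindex(columns=cols)
    if entrants.isna().any().any():
        raise FormatError("population.csv entrant rows do not cover all gender/location strata")
    entrants.index.name = "year"

    htn = pd.read_csv(path / "hypertension.csv", float_precision="round_trip").set_index(["gender", "age_band", "location"])
    htn = _reindex_cohorts(htn, "hypertension.csv")["prevalence"]

    meta = {}
    meta_path = path / "metadata.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    iodine = IodineInputs.from_frame(
        pd.read_csv(path / "iodine.csv", float_precision="round_trip"),
        requirement_ug=float(meta.get("iodine_requirement_ug", 150.0)),
        requirement_upper_ug=float(meta.get("iodine_requirement_upper_ug", 250.0)),
    )
    meta = {k: v for k, v in meta.items() if not k.startswith("iodine_requirement")}

    bundle = InputBundle(rates, PopulationProjection(initial, entrants), htn, iodine, meta)
    validate_bundle(bundle)
    return bundle


def _reindex_cohorts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    idx = cohort_multiindex()
    missing = idx.difference(df.index)
    if len(missing):
        g, a, loc = missing[0]
        raise FormatError(f"{source} is missing cohort row {g}/{a}/{loc}")
    return df.loc[idx]


# --------------------------------------------------------------------------
# calibration


_EVENT_SCALE_COLS = {
    "mi": ["first_mi_rate", "recurrent_mi_rate"],
    "stroke": ["first_stroke_rate", "recurrent_stroke_rate"],
}


def calibrate_to_totals(
    bundle: InputBundle,
    targets: dict[str, float],
    window: tuple[int, int] = (2013, 2043),
    rel_tol: float = 0.01,
    max_iter: int = 40,
) -> InputBundle:
    """Uniformly scale event rates/case fatalities so the baseline run hits targets.

    ``targets`` may contain ``mi`` (annual new+recurrent MIs), ``stroke``
    (annual new+recurrent strokes) and ``deaths`` (annual MI+stroke deaths),
    averaged over ``window``. Iterative proportional fitting: each pass runs
    the baseline scenario, compares annual averages against targets, and
    scales the relevant columns by the ratio. Raises
    :class:`CalibrationError` with residuals on non-convergence.
    """
    from .engine import EngineParams, run
    from .exposure import Scenario
    from .outcomes import annual_average

    for k, v in targets.items():
        if k not in ("mi", "stroke", "deaths"):
            raise ConfigurationError(f"unknown calibration target {k!r}")
        if v <= 0:
            raise ConfigurationError(f"calibration target {k} must be positive, got {v}")

    work = bundle.copy()
    params = EngineParams()
    baseline = Scenario.baseline()
    residuals: dict[str, float] = {}
    factors_applied: dict[str, float] = {k: 1.0 for k in targets}

    for _ in range(max_iter):
        result = run(work, baseline, params)
        current = {
            "mi": annual_average(result, "mi", window),
            "stroke": annual_average(result, "stroke", window),
            "deaths": annual_average(result, "cvd_deaths", window),
        }
        residuals = {k: current[k] / targets[k] - 1.0 for k in targets}
        if all(abs(r) <= rel_tol for r in residuals.values()):
            work.metadata = dict(work.metadata)
            work.metadata["calibration"] = {
                "targets": {k: float(v) for k, v in targets.items()},
                "window": list(window),
                "factors": {k: float(f) for k, f in factors_applied.items()},
                "residuals": {k: float(r) for k, r in residuals.items()},
            }
            return work
        for k in targets:
            if current[k] <= 0:
                raise CalibrationError(
                    f"baseline run produces zero {k}; cannot scale to a positive target",
                    residuals,
                )
            f = targets[k] / current[k]
            if k in _EVENT_SCALE_COLS:
                work.rates[_EVENT_SCALE_COLS[k]] *= f
            else:  # deaths: scale both case fatalities
                scaled = work.rates[_PROB_COLS] * f
                if (scaled > 0.99).any().any():
                    raise CalibrationError(
                        "deaths target requires case fatality above 0.99", residuals
                    )
                work.rates[_PROB_COLS] = scaled
            factors_applied[k] *= f

    raise CalibrationError(
        f"calibration did not converge within {max_iter} iterations", residuals
    )
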