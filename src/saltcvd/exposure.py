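"""Salt-reduction exposure chain: scenario -> ΔSBP -> lagged relative risks.

The effect of a salt-reduction scenario on event rates is computed in two
stages. First, the achieved reduction in daily salt intake is mapped to a
reduction in systolic blood pressure (ΔSBP) via meta-analysis coefficients:
3.6 mmHg per 3 g/day among hypertensive persons (95% CI 2.8-4.4) and
1.8 mmHg (1.0-2.6) among normotensive persons, mixed by cohort hypertension
prevalence. Second, ΔSBP is mapped to relative risks of MI and stroke via a
log-linear hazard relation RR = exp(-slope x ΔSBP) with age-band-specific
slopes.

Benefit does not arrive instantly: risk reduction phases in through a lag
kernel — linearly over 3 years for stroke; for MI, two-thirds of the
benefit linearly over the first 3 years and the remainder linearly over the
next 7. A gradual ramp is handled by convolving monthly ΔSBP increments
with the kernel, which is exact for the linear chain used here.

An optimistic, age-dependent alternative maps salt directly to ΔSBP as
0.0598 mmHg per mmol salt (17.1 mmol/g) plus 0.0431 mmHg per year of age
above 48 (clamped at zero below 48).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np

from .cohorts import AGE_BANDS, ALL_COHORTS, CohortKey
from .errors import ConfigurationError, DomainError

MMOL_PER_GRAM_SALT = 17.1

ENDPOINTS = ("mi", "stroke")


# --------------------------------------------------------------------------
# scenario


@dataclass(frozen=True)
class Scenario:
    """A linear salt-reduction trajectory.

    The reduction ramps from 0 at ``start_year`` at ``ramp_g_per_year``
    until it reaches ``target_g``, and stays capped there.
    """

    target_g: float
    ramp_g_per_year: float
    start_year: float = 2013.0
    end_year: float = 2043.0
    name: str = ""

    def __post_init__(self):
        if self.target_g < 0:
            raise ConfigurationError("target_g must be non-negative")
        if self.ramp_g_per_year < 0:
            raise ConfigurationError("ramp_g_per_year must be non-negative")
        if self.end_year < self.start_year:
            raise ConfigurationError("end_year must be >= start_year")
        if self.target_g > 0:
            reach = self.ramp_g_per_year * (self.end_year - self.start_year)
            if reach + 1e-9 < self.target_g:
                raise ConfigurationError(
                    f"target {self.target_g} g not reachable at "
                    f"{self.ramp_g_per_year} g/yr over {self.end_year - self.start_year} yr"
                )

    @staticmethod
    def baseline() -> "Scenario":
        return Scenario(0.0, 0.0, name="baseline")

    @staticmethod
    def preset(name: str) -> "Scenario":
        presets = {
            "baseline": Scenario(0.0, 0.0, name="baseline"),
            "1g30y": Scenario(1.0, 1.0 / 30.0, name="1g30y"),
            "3g30y": Scenario(3.0, 0.1, name="3g30y"),
            "4g30y": Scenario(4.0, 4.0 / 30.0, name="4g30y"),
        }
        if name not in presets:
            raise ConfigurationError(
                f"unknown scenario preset {name!r}; choose from {sorted(presets)}"
            )
        return presets[name]


def salt_trajectory(scenario: Scenario, year: float) -> float:
    """Achieved salt reduction (g/day) at a (possibly fractional) calendar year."""
    elapsed = year - scenario.start_year
    if elapsed <= 0:
        return 0.0
    return min(scenario.ramp_g_per_year * elapsed, scenario.target_g)


# --------------------------------------------------------------------------
# dose-response parameters


@dataclass(frozen=True)
class DoseResponseParams:
    """Salt -> ΔSBP coefficients (mmHg per 3 g/day salt reduction)."""

    dsbp_hypertensive_per3g: float = 3.6
    dsbp_normotensive_per3g: float = 1.8
    hypertensive_ci: tuple[float, float] = (2.8, 4.4)
    normotensive_ci: tuple[float, float] = (1.0, 2.6)
    #: sensitivity lever: fraction of the hypertensive benefit retained
    #: (1.0 = achieved benefit equals the full epidemiological benefit)
    hypertensive_benefit_fraction: float = 1.0
    #: switch to the optimistic age-dependent salt->SBP formula
    age_dependent: bool = False

    def __post_init__(self):
        if self.dsbp_hypertensive_per3g < 0 or self.dsbp_normotensive_per3g < 0:
            raise DomainError("dose-response coefficients must be non-negative")
        if self.dsbp_hypertensive_per3g < self.dsbp_normotensive_per3g:
            raise DomainError("hypertensive coefficient must be >= normotensive")


def _default_slopes() -> dict[str, dict[str, float]]:
    # halving of risk per 20 mmHg at 40-49, attenuated 20% per decade;
    # approximate, overridable
    base = log(2.0) / 20.0
    return {
        ep: {band: base * 0.8**i for i, band in enumerate(AGE_BANDS)} for ep in ENDPOINTS
    }


@dataclass(frozen=True)
class RiskEquationParams:
    """ΔSBP -> relative-risk slopes and optimistic-formula coefficients."""

    slopes: dict = field(default_factory=_default_slopes)  # per endpoint, per age band
    c_mmol: float = 0.0598  # mmHg per mmol/day salt reduction
    c_age: float = 0.0431  # mmHg per year of age above 48
    mmol_per_gram_salt: float = MMOL_PER_GRAM_SALT
    #: sensitivity lever: multiplies every log-hazard slope
    slope_multiplier: float = 1.0

    def slope(self, endpoint: str, age_band: str) -> float:
        if endpoint not in self.slopes:
            raise DomainError(f"unknown endpoint {endpoint!r}")
        if age_band not in self.slopes[endpoint]:
            raise DomainError(f"unknown age band {age_band!r}")
        s = self.slopes[endpoint][age_band] * self.slope_multiplier
        if s < 0:
            raise DomainError("RR slope must be non-negative")
        return s


# --------------------------------------------------------------------------
# ΔSBP operations


def sbp_reduction_individual(
    delta_salt: float, hypertensive: bool, params: DoseResponseParams | None = None
) -> float:
    """ΔSBP (mmHg) for one person from a ``delta_salt`` g/day reduction."""
    params = params or DoseResponseParams()
    if delta_salt < 0:
        raise DomainError("delta_salt must be non-negative")
    per3g = (
        params.dsbp_hypertensive_per3g * params.hypertensive_benefit_fraction
        if hypertensive
        else params.dsbp_normotensive_per3g
    )
    return (delta_salt / 3.0) * per3g


def sbp_reduction_cohort(
    delta_salt: float, prevalence: float, params: DoseResponseParams | None = None
) -> float:
    """Prevalence-weighted cohort mean ΔSBP (mmHg)."""
    params = params or DoseResponseParams()
    if not 0.0 <= prevalence <= 1.0:
        raise DomainError(f"prevalence must be in [0,1], got {prevalence}")
    return prevalence * sbp_reduction_individual(delta_salt, True, params) + (
        1.0 - prevalence
    ) * sbp_reduction_individual(delta_salt, False, params)


def sbp_reduction_optimistic(
    delta_salt: float, age: float, params: RiskEquationParams | None = None
) -> float:
    """Age-dependent ΔSBP (mmHg): 0.0598/mmol salt + 0.0431/yr above age 48."""
    params = params or RiskEquationParams()
    if delta_salt < 0:
        raise DomainError("delta_salt must be non-negative")
    if delta_salt == 0:
        return 0.0
    mmol = delta_salt * params.mmol_per_gram_salt
    return params.c_mmol * mmol + params.c_age * max(age - 48.0, 0.0)


def rr_from_sbp(
    delta_sbp: float, endpoint: str, age_band: str, params: RiskEquationParams | None = None
) -> float:
    """Relative risk exp(-slope x ΔSBP), in (0, 1] for ΔSBP >= 0."""
    params = params or RiskEquationParams()
    if delta_sbp < 0:
        raise DomainError("delta_sbp must be non-negative")
    return float(np.exp(-params.slope(endpoint, age_band) * delta_sbp))


# --------------------------------------------------------------------------
# lag kernel


@dataclass(frozen=True)
class LagKernel:
    """Piecewise-linear phase-in of benefit after an exposure change.

    ``breakpoints`` per endpoint: ordered (months, cumulative fraction)
    pairs; fraction is 0 at month 0 and linear between breakpoints, reaching
    1 at the final breakpoint.
    """

    breakpoints: dict = field(
        default_factory=lambda: {
            "stroke": ((36.0, 1.0),),
            "mi": ((36.0, 2.0 / 3.0), (120.0, 1.0)),
        }
    )

    def __post_init__(self):
        for ep, bps in self.breakpoints.items():
            months = [m for m, _ in bps]
            fracs = [f for _, f in bps]
            if sorted(months) != list(months) or sorted(fracs) != list(fracs):
                raise ConfigurationError(f"{ep} kernel breakpoints must be non-decreasing")
            if abs(fracs[-1] - 1.0) > 1e-12:
                raise ConfigurationError(f"{ep} kernel must reach 1.0 at its final breakpoint")

    def max_months(self, endpoint: str) -> int:
        return int(np.ceil(self.breakpoints[endpoint][-1][0]))


def phase_in_fraction(
    endpoint: str, months_since_change: float, kernel: LagKernel | None = None
) -> float:
    """Fraction of the full benefit realized ``months_since_change`` after a change."""
    kernel = kernel or LagKernel()
    if endpoint not in kernel.breakpoints:
        raise DomainError(f"unknown endpoint {endpoint!r}")
    if months_since_change < 0:
        raise DomainError("months_since_change must be non-negative")
    m = months_since_change
    prev_m, prev_f = 0.0, 0.0
    for bm, bf in kernel.breakpoints[endpoint]:
        if m <= bm:
            if bm == prev_m:
                return bf
            return prev_f + (bf - prev_f) * (m - prev_m) / (bm - prev_m)
        prev_m, prev_f = bm, bf
    return 1.0


# --------------------------------------------------------------------------
# per-cohort effect series


@dataclass
class ExposureEffect:
    """Monthly exposure-effect series for all cohorts.

    Arrays are shaped (n_months, n_cohorts) in canonical cohort order;
    ``salt_reduction`` is (n_months,) — the trajectory is population-wide.
    """

    months: np.ndarray  # month index 0..n-1
    years: np.ndarray  # fractional calendar year per month
    salt_reduction: np.ndarray
    effective_dsbp: dict  # endpoint -> (n_months, n_cohorts)
    rr: dict  # endpoint -> (n_months, n_cohorts)

    def for_cohort(self, cohort: CohortKey) -> dict:
        i = ALL_COHORTS.index(cohort)
        return {
            "salt_reduction": self.salt_reduction,
            "dsbp_mi": self.effective_dsbp["mi"][:, i],
            "dsbp_stroke": self.effective_dsbp["stroke"][:, i],
            "rr_mi": self.rr["mi"][:, i],
            "rr_stroke": self.rr["stroke"][:, i],
        }


def _kernel_vector(endpoint: str, kernel: LagKernel, n_months: int) -> np.ndarray:
    horizon = min(kernel.max_months(endpoint), n_months)
    return np.array(
        [phase_in_fraction(endpoint, m, kernel) for m in range(horizon + 1)], dtype=float
    )


def exposure_effect(
    scenario: Scenario,
    prevalence: np.ndarray,
    params: DoseResponseParams,
    risk: RiskEquationParams,
    kernel: LagKernel,
    start_year: int,
    n_months: int,
    cohort_ages: np.ndarray | None = None,
) -> ExposureEffect:
    """Build the full lagged exposure-effect series for all cohorts.

    For each month, the effective ΔSBP is the convolution of monthly
    increments in the achieved cohort ΔSBP with the endpoint's phase-in
    kernel; relative risks follow from the log-linear relation. A
    zero-reduction scenario yields RR identically 1.
    """
    months = np.arange(n_months)
    years = start_year + months / 12.0
    salt = np.array([salt_trajectory(scenario, y) for y in years])

    prevalence = np.asarray(prevalence, dtype=float)
    if cohort_ages is None:
        cohort_ages = np.array([c.mid_age for c in ALL_COHORTS])

    # full (un-lagged) cohort ΔSBP per month per cohort
    if params.age_dependent:
        full_dsbp = np.array(
            [[sbp_reduction_optimistic(s, a, risk) for a in cohort_ages] for s in salt]
        )
    else:
        full_dsbp = np.array(
            [[sbp_reduction_cohort(s, p, params) for p in prevalence] for s in salt]
        )

    increments = np.diff(full_dsbp, axis=0, prepend=np.zeros((1, full_dsbp.shape[1])))

    eff_dsbp: dict[str, np.ndarray] = {}
    rr: dict[str, np.ndarray] = {}
    slopes = {
        ep: np.array([risk.slope(ep, c.age_band) for c in ALL_COHORTS]) for ep in ENDPOINTS
    }
    for ep in ENDPOINTS:
        kv = _kernel_vector(ep, kernel, n_months)
        if len(kv) < n_months:
            # contributions older than the kernel horizon are fully phased in
            kv = np.concatenate([kv, np.ones(n_months - len(kv))])
        eff = np.empty_like(full_dsbp)
        for j in range(full_dsbp.shape[1]):
            eff[:, j] = np.convolve(increments[:, j], kv)[:n_months]
        eff_dsbp[ep] = eff
        rr[ep] = np.exp(-slopes[ep][None, :] * eff)

    return ExposureEffect(months, years, salt, eff_dsbp, rr)


def effective_rr_series(
    scenario: Scenario,
    cohort: CohortKey,
    bundle,
    params: DoseResponseParams | None = None,
    risk: RiskEquationParams | None = None,
    kernel: LagKernel | None = None,
    horizon_months: int | None = None,
    start_year: int = 1998,
) -> dict:
    """Exposure-effect series for a single cohort (thin wrapper over all-cohort calc)."""
    params = params or DoseResponseParams()
    risk = risk or RiskEquationParams()
    kernel = kernel or LagKernel()
    if horizon_months is None:
        horizon_months = (2051 - start_year) * 12
    if start_year + horizon_months / 12.0 <= scenario.start_year and scenario.target_g > 0:
        raise ConfigurationError("horizon ends before the scenario starts")
    prevalence = np.array(
        [float(bundle.hypertension.loc[c.as_tuple()]) for c in ALL_COHORTS]
    )
    eff = exposure_effect(
        scenario, prevalence, params, risk, kernel, start_year, horizon_months
    )
    return eff.for_cohort(cohort)
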