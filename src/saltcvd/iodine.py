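"""Iodine-deficiency side model.

Salt is the main iodine vehicle in India, so a population-wide reduction in
salt intake can in principle push people whose daily iodine intake sits just
above the requirement below it. This module counts those threshold
crossings per province stratum.

Daily iodine intake for a person consuming ``s`` g salt/day of which a
fraction ``c`` is iodized at ``q`` ug iodine per g salt is ``s * c * q``.
Within a stratum, salt intake is heterogeneous and modelled as a normal
distribution truncated at zero and at +-6 SD, discretized on a fine grid so
threshold counting is exact for the discretized distribution. A province may carry a
mixture of iodization levels (fractions of the population receiving salt
iodized at different contents).

Two assumption sets are supported:

``central``
    the salt reduction comes proportionally from iodized and non-iodized
    salt, and the adult requirement (default 150 ug/day) is used;
``pessimistic``
    the entire reduction is taken from the iodized share of salt, and the
    upper requirement bound (default 250 ug/day, pregnancy-level need) is
    used — a deliberate worst case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

IODINE_COLUMNS = [
    "province",
    "population",
    "salt_mean_g_per_day",
    "salt_sd_g_per_day",
    "iodized_coverage",
    "iodine_content_ug_per_g",
    "content_fraction",
]


def iodine_intake(salt_g_per_day: float, coverage: float, content_ug_per_g: float) -> float:
    """Daily iodine intake (ug/day) = salt x iodized coverage x content."""
    if salt_g_per_day < 0 or coverage < 0 or content_ug_per_g < 0:
        raise DomainError("iodine_intake arguments must be non-negative")
    return salt_g_per_day * coverage * content_ug_per_g


@dataclass(frozen=True)
class IodineStratum:
    """One province-level stratum, possibly with a mixture of iodization levels.

    ``content_levels`` is a list of (population_fraction, ug iodine per g salt)
    pairs; fractions must sum to 1.
    """

    province: str
    population: float
    salt_mean: float  # g/day
    salt_sd: float  # g/day
    coverage: float  # fraction of an individual's salt that is iodized
    content_levels: tuple[tuple[float, float], ...] = ((1.0, 15.0),)

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise DomainError(f"coverage must be in [0,1], got {self.coverage}")
        if self.population < 0 or self.salt_mean < 0 or self.salt_sd < 0:
            raise DomainError("population and salt parameters must be non-negative")
        fracs = sum(f for f, _ in self.content_levels)
        if abs(fracs - 1.0) > 1e-6:
            raise DomainError(f"content_level fractions must sum to 1, got {fracs}")
        if any(q < 0 or f < 0 for f, q in self.content_levels):
            raise DomainError("content levels must be non-negative")


@dataclass(frozen=True)
class IodineInputs:
    strata: tuple[IodineStratum, ...]
    requirement_ug: float = 150.0
    requirement_upper_ug: float = 250.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            for frac, content in s.content_levels:
                rows.append(
                    {
                        "province": s.province,
                        "population": s.population,
                        "salt_mean_g_per_day": s.salt_mean,
                        "salt_sd_g_per_day": s.salt_sd,
                        "iodized_coverage": s.coverage,
                        "iodine_content_ug_per_g": content,
                        "content_fraction": frac,
                    }
                )
        return pd.DataFrame(rows, columns=IODINE_COLUMNS)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        requirement_ug: float = 150.0,
        requirement_upper_ug: float = 250.0,
    ) -> "IodineInputs":
        strata = []
        for prov, grp in df.groupby("province", sort=False):
            levels = tuple(
                (float(r.content_fraction), float(r.iodine_content_ug_per_g))
                for r in grp.itertuples()
            )
            first = grp.iloc[0]
            strata.append(
                IodineStratum(
                    province=str(prov),
                    population=float(first["population"]),
                    salt_mean=float(first["salt_mean_g_per_day"]),
                    salt_sd=float(first["salt_sd_g_per_day"]),
                    coverage=float(first["iodized_coverage"]),
                    content_levels=levels,
                )
            )
        return cls(tuple(strata), requirement_ug, requirement_upper_ug)


@dataclass
class IodineResult:
    per_stratum: pd.DataFrame  # province, baseline_deficient, post_deficient, excess_cases
    assumptions: str
    delta_salt: float

    @property
    def total_excess(self) -> float:
        return float(self.per_stratum["excess_cases"].sum())

    @property
    def worst_province(self) -> str | None:
        if self.per_stratum.empty or self.per_stratum["excess_cases"].max() <= 0:
            return None
        return str(self.per_stratum.loc[self.per_stratum["excess_cases"].idxmax(), "province"])


def _salt_grid(mean: float, sd: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Discretize the within-stratum salt distribution: grid values + weights.

    Normal, truncated at zero and at mean +- 6 SD (so implausibly extreme
    intakes carry exactly zero mass rather than ~1e-10 tail remnants).
    """
    if sd == 0:
        return np.array([mean]), np.array([1.0])
    lo, hi = max(0.0, mean - 6 * sd), mean + 6 * sd
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    edges = np.linspace(lo, hi, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    weights = np.diff(dist.cdf(edges))
    total = weights.sum()
    if total > 0:
        weights = weights / total
    return mids, weights


def _deficient_fraction(
    salt: np.ndarray,
    weights: np.ndarray,
    coverage: float,
    content: float,
    delta: float,
    requirement: float,
    pessimistic: bool,
) -> float:
    """Fraction of a subgroup with daily iodine intake below the requirement."""
    if pessimistic:
        # entire reduction taken out of the iodized share of salt
        iodized_g = np.maximum(salt * coverage - delta, 0.0)
        intake = iodized_g * content
    else:
        reduced = np.maximum(salt - delta, 0.0)
        intake = reduced * coverage * content
    return float(weights[intake < requirement].sum())


def deficiency_cases(
    inputs: IodineInputs,
    delta_salt: float,
    assumptions: str = "central",
    grid_points: int = 4001,
) -> IodineResult:
    """Count new iodine-deficiency cases induced by a ``delta_salt`` g/day reduction.

    Per stratum and iodization level, persons are deficient when intake falls
    below the requirement; ``excess_cases = max(post - baseline, 0)``.
    """
    if delta_salt < 0:
        raise DomainError("delta_salt must be non-negative")
    if assumptions not in ("central", "pessimistic"):
        raise DomainError(f"unknown assumption set {assumptions!r}")
    pessimistic = assumptions == "pessimistic"
    requirement = inputs.requirement_upper_ug if pessimistic else inputs.requirement_ug

    rows = []
    for s in inputs.strata:
        salt, w = _salt_grid(s.salt_mean, s.salt_sd, grid_points)
        base = post = 0.0
        for frac, content in s.content_levels:
            subpop = s.population * frac
            base += subpop * _deficient_fraction(
                salt, w, s.coverage, content, 0.0, requirement, pessimistic
            )
            post += subpop * _deficient_fraction(
                salt, w, s.coverage, content, delta_salt, requirement, pessimistic
            )
        rows.append(
            {
                "province": s.province,
                "baseline_deficient": base,
                "post_deficient": post,
                "excess_cases": max(post - base, 0.0),
            }
        )
    return IodineResult(pd.DataFrame(rows), assumptions, delta_salt)
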