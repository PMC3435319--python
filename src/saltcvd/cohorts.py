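"""The twelve demographic cohorts of the model.

The simulated population is stratified by gender, ten-year age band
(40-49, 50-59, 60-69) and location (urban/rural), giving exactly twelve
cohorts. All rate, prevalence and population tables are keyed by these
cohorts, and the engine orders its state arrays by :data:`ALL_COHORTS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GENDERS = ("male", "female")
AGE_BANDS = ("40-49", "50-59", "60-69")
LOCATIONS = ("urban", "rural")

#: representative age used where a formula needs a scalar age for a band
AGE_MIDPOINTS = {"40-49": 45.0, "50-59": 55.0, "60-69": 65.0}


@dataclass(frozen=True, order=True)
class CohortKey:
    gender: str
    age_band: str
    location: str

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")

    @property
    def age_index(self) -> int:
        return AGE_BANDS.index(self.age_band)

    @property
    def mid_age(self) -> float:
        return AGE_MIDPOINTS[self.age_band]

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.gender, self.age_band, self.location)

    def __str__(self) -> str:  # used in error messages
        return f"{self.gender}/{self.age_band}/{self.location}"


#: canonical ordering: gender-major, then age band, then location
ALL_COHORTS: tuple[CohortKey, ...] = tuple(
    CohortKey(g, a, loc) for g in GENDERS for a in AGE_BANDS for loc in LOCATIONS
)

N_COHORTS = len(ALL_COHORTS)  # 12

COHORT_INDEX: dict[CohortKey, int] = {c: i for i, c in enumerate(ALL_COHORTS)}


def cohort_multiindex() -> pd.MultiIndex:
    """MultiIndex (gender, age_band, location) in canonical cohort order."""
    return pd.MultiIndex.from_tuples(
        [c.as_tuple() for c in ALL_COHORTS], names=["gender", "age_band", "location"]
    )


#: for each (gender, location): cohort indices ordered 40-49 -> 50-59 -> 60-69,
#: used by the aging flow (occupants of 60-69 exit the model)
AGING_CHAINS: tuple[tuple[int, int, int], ...] = tuple(
    (
        COHORT_INDEX[CohortKey(g, "40-49", loc)],
        COHORT_INDEX[CohortKey(g, "50-59", loc)],
        COHORT_INDEX[CohortKey(g, "60-69", loc)],
    )
    for g in GENDERS
    for loc in LOCATIONS
)
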