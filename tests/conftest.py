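import numpy as np
import pandas as pd
import pytest

from saltcvd import EngineParams, Scenario, calibrate_to_totals, generate_inputs, run
from saltcvd.cohorts import GENDERS, LOCATIONS, cohort_multiindex
from saltcvd.inputs import InputBundle, PopulationProjection


@pytest.fixture(scope="session")
def bundle():
    return generate_inputs(1)


@pytest.fixture(scope="session")
def calibrated_bundle(bundle):
    """Bundle scaled so the baseline run matches India-scale annual totals."""
    return calibrate_to_totals(
        bundle, {"mi": 8.3e6, "stroke": 8.3e5, "deaths": 2.0e6}
    )


@pytest.fixture(scope="session")
def baseline_run(calibrated_bundle):
    return run(calibrated_bundle, Scenario.baseline())


@pytest.fixture(scope="session")
def intervention_run(calibrated_bundle):
    return run(calibrated_bundle, Scenario.preset("3g30y"))


def closed_population(bundle, n_per_cohort: float) -> InputBundle:
    """Replace demographics: n_per_cohort in every cohort, zero entrants."""
    out = bundle.copy()
    idx = cohort_multiindex()
    initial = pd.Series(float(n_per_cohort), index=idx, name="initial_size")
    years = out.population.entrants.index
    cols = pd.MultiIndex.from_product([GENDERS, LOCATIONS], names=["gender", "location"])
    entrants = pd.DataFrame(0.0, index=years, columns=cols)
    out.population = PopulationProjection(initial, entrants)
    return out


@pytest.fixture(scope="session")
def small_closed_bundle(bundle):
    return closed_population(bundle, 1000.0)


@pytest.fixture(scope="session")
def short_params():
    """Three-year horizon for fast engine tests."""
    return EngineParams(start_year=1998, end_year=2000)
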