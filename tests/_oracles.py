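"""Independent stochastic oracle: individual-level microsimulation.

Simulates every person's monthly transitions by multinomial/binomial
sampling with the same cause-specific monthly probabilities the cohort
engine uses. The expected value of this process is exactly the cohort
(expected-value) engine, so engine tallies must sit within Monte-Carlo
error of microsimulation means. Counts are integers throughout; sampling a
multinomial per state aggregate is distributionally identical to sampling
each individual independently.
"""

from __future__ import annotations

import numpy as np

from saltcvd.cohorts import AGING_CHAINS, N_COHORTS
from saltcvd.engine import (
    AMI,
    AST,
    DCVD,
    DOTH,
    EVENT_METRICS,
    LIVING,
    PMI,
    PST,
    W,
    EngineParams,
    _RunContext,
)


def microsim_run(bundle, scenario, params: EngineParams, rng: np.random.Generator):
    """One stochastic replicate. Returns dict metric -> (n_months, 12) int arrays.

    Demographics must be closed (zero entrants); initial cohort sizes are
    rounded to integers.
    """
    ctx = _RunContext.build(bundle, scenario, params)
    if np.any(ctx.entrants_monthly != 0):
        raise ValueError("microsim oracle requires a closed population")
    n = params.n_months

    counts = np.zeros((N_COHORTS, 7), dtype=np.int64)
    from saltcvd.cohorts import ALL_COHORTS

    counts[:, W] = np.round(
        [float(bundle.population.initial.loc[c.as_tuple()]) for c in ALL_COHORTS]
    ).astype(np.int64)

    series = {m: np.zeros((n, N_COHORTS), dtype=np.int64) for m in EVENT_METRICS}

    for m in range(n):
        probs = ctx.monthly_probs(m)
        new = np.zeros_like(counts)
        tallies = {k: np.zeros(N_COHORTS, dtype=np.int64) for k in EVENT_METRICS}

        for i in range(N_COHORTS):
            # well: competing first MI / first stroke / other death / stay
            p = probs["well"][:, i]
            stay = max(1.0 - p.sum(), 0.0)
            n_mi, n_st, n_d, n_stay = rng.multinomial(
                counts[i, W], [p[0], p[1], p[2], stay]
            )
            new[i, W] += n_stay
            new[i, AMI] += n_mi
            new[i, AST] += n_st
            new[i, DOTH] += n_d
            tallies["new_mi"][i] += n_mi
            tallies["new_stroke"][i] += n_st
            tallies["other_deaths"][i] += n_d

            # acute states resolve: case fatality or post-event
            d_mi = rng.binomial(counts[i, AMI], probs["cf_mi"][i])
            new[i, PMI] += counts[i, AMI] - d_mi
            new[i, DCVD] += d_mi
            tallies["mi_deaths"][i] += d_mi
            d_st = rng.binomial(counts[i, AST], probs["cf_stroke"][i])
            new[i, PST] += counts[i, AST] - d_st
            new[i, DCVD] += d_st
            tallies["stroke_deaths"][i] += d_st

            # post-MI: recurrence / cross stroke / other death / stay
            p = probs["post_mi"][:, i]
            stay = max(1.0 - p.sum(), 0.0)
            n_rec, n_cross, n_d, n_stay = rng.multinomial(
                counts[i, PMI], [p[0], p[1], p[2], stay]
            )
            new[i, PMI] += n_stay
            new[i, AMI] += n_rec
            new[i, AST] += n_cross
            new[i, DOTH] += n_d
            tallies["recurrent_mi"][i] += n_rec
            tallies["new_stroke"][i] += n_cross
            tallies["other_deaths"][i] += n_d

            # post-stroke: recurrence / cross MI / other death / stay
            p = probs["post_stroke"][:, i]
            stay = max(1.0 - p.sum(), 0.0)
            n_rec, n_cross, n_d, n_stay = rng.multinomial(
                counts[i, PST], [p[0], p[1], p[2], stay]
            )
            new[i, PST] += n_stay
            new[i, AST] += n_rec
            new[i, AMI] += n_cross
            new[i, DOTH] += n_d
            tallies["recurrent_stroke"][i] += n_rec
            tallies["new_mi"][i] += n_cross
            tallies["other_deaths"][i] += n_d

        counts = new

        if params.aging:
            for i40, i50, i60 in AGING_CHAINS:
                move40 = rng.binomial(counts[i40, LIVING], 1.0 / 120.0)
                move50 = rng.binomial(counts[i50, LIVING], 1.0 / 120.0)
                move60 = rng.binomial(counts[i60, LIVING], 1.0 / 120.0)
                counts[i40, LIVING] -= move40
                counts[i50, LIVING] += move40 - move50
                counts[i60, LIVING] += move50 - move60
                # move60 exits the model

        for k in EVENT_METRICS:
            series[k][m] = tallies[k]

    return series
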