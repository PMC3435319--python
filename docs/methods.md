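# Methods

## Model structure

The population is an open cohort of Indian adults aged 40–69, split into
twelve strata by gender, ten-year age band and urban/rural location, and
advanced in monthly cycles from January 1998 through December 2050. The
early years act as a burn-in so that by the intervention start (2013) the
post-event pools and secular trends have evolved from their 1998 state.

Seven states per cohort: well, acute MI, acute stroke, post-MI,
post-stroke, CVD death, other-cause death. Dynamics per cycle:

- **Competing risks.** Annual cause-specific rates `r_i` convert jointly to
  monthly probabilities: total exit `1 − exp(−Σr_i/12)`, shared among
  causes in proportion to `r_i`. This is the single point where rates
  become probabilities; all tables store annual rates.
- **Acute states** last exactly one month and resolve to CVD death (case
  fatality, a per-event-month probability) or the post-event state. Case
  fatalities carry no secular trend.
- **Post-event states** face recurrence (at recurrent-event rates, scaled
  by the same relative risks as first events) and background mortality.
  Cross-morbidity transitions (post-MI → first stroke and vice versa) are
  off by default and can be enabled (`EngineParams(cross_morbidity=True)`),
  in which case they use first-event rates.
- **Trends** compound annually (`trend^(year − 1998)`) and change at
  calendar-year boundaries.
- **Aging** is a memoryless 1/120-per-month flow between bands — the
  standard treatment for ten-year-band cohort models; it preserves band
  sizes against projection-style inputs without tracking single-year ages.
  Occupants leaving 60–69 exit the model. Entrants join the well state of
  the 40–49 band at one-twelfth of the annual projection.

The simulation is expected-value (real-valued counts), matching the use
case of deterministic central estimates with parameter-uncertainty
intervals. An individual-level stochastic microsimulation with identical
monthly probabilities lives in the test suite as an oracle; the engine's
tallies are its exact expectation.

Mass is conserved by construction: every flow is subtracted from its
source and added to one destination, so `initial + entrants = alive +
deaths + aged-out` holds to floating-point round-off (~1e-15 relative)
every month.

## Exposure chain

Scenarios are linear ramps: zero before `start_year`, rising at
`ramp_g_per_year` until `target_g`, capped thereafter. Presets: 1 g, 3 g
and 4 g over 30 years (2013–2043).

Stage one maps salt to systolic pressure: 3.6 mmHg per 3 g/day among
hypertensive persons (95% CI 2.8–4.4), 1.8 (1.0–2.6) among normotensive,
linear in dose and mixed by cohort hypertension prevalence. The binary
hypertensive/normotensive split is all the underlying meta-analysis
distinguishes, so no continuous blood-pressure distribution is carried.
An optimistic, age-dependent alternative (`age_dependent=True`) computes
ΔSBP = 0.0598 mmHg/mmol × 17.1 mmol/g × Δsalt + 0.0431 mmHg per year of
age over 48; the age term is clamped at zero below 48 to avoid sign
reversal, and band midpoints (45/55/65) stand in for individual ages.

Stage two maps ΔSBP to relative risk, `RR = exp(−β·ΔSBP)`, for both first
and recurrent events. The exact age-specific slopes used by the original
risk equations are not publicly printed, so the defaults are an explicit,
overridable approximation: `β = ln(2)/20` per mmHg (risk halves per
20 mmHg sustained difference) at 40–49, attenuated by 0.8 per decade of
age, identical for MI and stroke. Every slope is configuration
(`RiskEquationParams.slopes`); conclusions that depend on absolute slope
values should supply their own.

Benefit lags the exposure change. The phase-in kernel rises linearly to 1
over 36 months for stroke; for MI it reaches 2/3 at 36 months and 1 at
120. A gradual ramp is handled by convolving monthly ΔSBP *increments*
with the kernel — exact for this linear chain, and order-independent,
unlike applying the kernel to RR (non-additive; differs only at second
order but has no clean superposition).

## Synthetic inputs and calibration

The generator emulates the schema and qualitative structure of the
stratified tables such models consume: first-event MI/stroke rates rising
with age (multiplicative gradient per decade), male and urban excess for
MI, recurrence at 3–5× first-event rates, case fatalities of 15–35%
rising with age, background mortality with its own age gradient and a
declining secular trend (epidemiological transition: CVD rates drift up,
other-cause mortality down), hypertension prevalence built additively from
a rural-40s base plus age and urban increments (≈10–40%), and India-scale
demographics (~2×10⁸ persons aged 40–69, ~1.2–1.8×10⁷ entrants/year,
~65% rural). Each cohort value carries a 5% lognormal jitter, small
enough that the structural orderings (age monotonicity, urban-male MI
excess) survive sampling. All draws are a pure function of
`(seed, config)`.

These defaults are order-of-magnitude plausible, not estimates. The
supported route to realistic magnitudes is `calibrate_to_totals`:
iterative proportional fitting that uniformly scales first+recurrent MI
rates, stroke rates, and case fatalities until the baseline run's
2013–2043 annual averages match given totals (default tolerance 1%,
typically 4–6 passes; fails loudly with residuals if case fatality would
need to exceed 0.99).

Iodine strata default to the structure in which most deficiency is an
*access* problem: most provinces adequately iodized (35–50 µg/g, 80–95%
coverage — headroom under a few-gram cut), two with poor access (10–40%
coverage, deficient regardless of salt intake), and a 0–15% share of salt
iodized at low content (5–12 µg/g) — the only place where salt reduction
creates new deficiency. Within-stratum salt intake is normal, truncated at
zero and ±6 SD, discretized on a fine grid so threshold counting is exact
for the discretized distribution. Absolute synthetic case counts are
illustrative only; the real-world analogue depends on provincial data the
generator does not attempt to estimate. "Pessimistic" assumptions take the
entire reduction from the iodized share of salt and use the upper
requirement bound (250 µg/day, pregnancy-level need, vs the 150 µg/day
adult default). Note that *excess* cases are not monotone in iodine
content: at very low content nearly everyone is already deficient at
baseline, so there is nobody left to cross the threshold.

## Uncertainty and sensitivity

The PSA draws dose-response coefficients from normals with
SD = CI width/3.92 truncated at zero, and lognormal multipliers
(default σ = 0.10) on the RR slopes and on the MI/stroke rate columns.
Draw *i* seeds its own RNG from `(seed, i)`, so results are independent of
execution order and reproducible byte-for-byte. Summaries report both
mean ± 2 SD and 2.5/97.5 percentiles; with degenerate (zero-variance)
distributions the PSA reproduces the deterministic pipeline exactly.

Two named sensitivity scenarios:

- `lower_rr_benefit` — lowering a *hypertensive* person's blood pressure
  confers only two-thirds of the benefit of always having had the lower
  pressure. This is implemented as a 2/3 factor on the hypertensive ΔSBP
  contribution (normotensive benefit unchanged); at ~25–30% prevalence the
  population-level benefit falls to ≈85% of the main simulation. Scaling
  *all* log-RR by 2/3 would instead cut benefits by a third, which is not
  what the assumption describes.
- `age_dependent_sbp` — switches to the optimistic salt→SBP formula above,
  which yields several-fold larger ΔSBP and correspondingly larger
  benefits.

## Problem sizes and numerical choices

Default runs cover 636 months × 12 cohorts (~50 ms). The test suite uses
1,000-person closed cohorts over 24 months for the microsimulation
comparison (200 replicates; agreement judged at 3 Monte-Carlo SE with a
Poisson floor `√(μ/n)` on the SE for tallies too rare to appear in any
replicate), 100 seeded bundles for the conservation sweep, and 500 draws
for PSA reproducibility. Calibration and scenario comparisons in tests use
India-scale totals (8.3 M MIs / 830 k strokes / 2.0 M CVD deaths per year).

Degenerate inputs are handled explicitly: zero rates give zero
probabilities (not NaN) in the competing-risks split; zero-reduction
scenarios produce RR ≡ 1 and runs bit-identical to baseline; subgroup
shares and percent changes raise a domain error on zero denominators
rather than returning NaN silently.

## Limitations

- Synthetic inputs reproduce structure, not levels; only calibrated
  aggregates are meaningful in absolute terms, and per-cohort splits
  remain generator-dependent.
- RR slopes are an explicit approximation (see above); MI and stroke share
  default slopes even though the literature suggests steeper stroke
  gradients.
- No urban↔rural migration beyond what entrant projections imply; no
  cross-morbidity by default; acute states cannot suffer the other event
  in their resolution month; no salt effects outside the blood-pressure
  pathway; no non-linear salt–BP relationship; ages <40 and >69, renal and
  gastric endpoints, and economic outcomes are out of scope.
- Passing tests demonstrate internal consistency (conservation, oracle
  agreement, monotonicity, reproducibility), not predictive validity for
  India: that would require the confidential stratified input tables.
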