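"""Generate a synthetic input bundle, calibrate it, and compare scenarios.

Builds an India-scale synthetic population (12 cohorts, ~200M adults aged
40-69), scales its event rates so the baseline run produces 8.3M MIs,
830k strokes and 2.0M CVD deaths per year over 2013-2043, then runs a
3 g/day salt-reduction ramp (0.1 g/yr over 30 years) against baseline.
"""

from saltcvd import (
    Scenario,
    annual_average,
    averted,
    calibrate_to_totals,
    generate_inputs,
    rate_per_10k,
    run,
    subgroup_shares,
)

bundle = generate_inputs(seed=1)
bundle = calibrate_to_totals(
    bundle, {"mi": 8.3e6, "stroke": 8.3e5, "deaths": 2.0e6}
)

baseline = run(bundle, Scenario.baseline())
intervention = run(bundle, Scenario.preset("3g30y"))

print("Baseline, annual averages 2013-2043 (calibration targets):")
for metric, label in (("mi", "MIs"), ("stroke", "strokes"), ("cvd_deaths", "CVD deaths")):
    print(f"  {label:>10}: {annual_average(baseline, metric):12,.0f}  "
          f"({rate_per_10k(baseline, metric):6.1f} per 10,000)")

summary = averted(baseline, intervention)
print("\n3 g/day over 30 years, events averted per year:")
for metric, label in (("mi", "MIs"), ("stroke", "strokes"), ("cvd_deaths", "CVD deaths")):
    o = summary.overall
    print(f"  {label:>10}: {o[f'averted_{metric}']:10,.0f}  "
          f"({o[f'pct_averted_{metric}']:.1f}% of baseline, "
          f"{o[f'averted_rate_{metric}']:.1f} per 10,000)")

shares = subgroup_shares(summary.per_cohort["averted_stroke"])
print(f"\nOf averted strokes, {shares['rural']:.0%} are rural and "
      f"{shares['female']:.0%} are among women — the benefit is not an "
      "urban-male phenomenon.")
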