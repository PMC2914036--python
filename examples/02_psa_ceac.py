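"""Probabilistic sensitivity analysis and acceptability curve.

Draws 1,000 joint parameter sets (beta for utilities/probabilities,
gamma for costs, normal-on-coefficient for the survival parameters),
re-runs both arms per draw for a one-year-old starting related
transplantation, and prints the probability that transplantation is
cost-effective at the Thai willingness-to-pay thresholds of 100,000 and
300,000 THB per QALY.  The probability is the fraction of draws with
positive incremental net monetary benefit.
"""

from thalcea import ModelConfig, ceac, default_registry, run_psa

registry = default_registry()
psa = run_psa(
    registry, "related_hsct", "bt_ict", ModelConfig(start_age=1),
    n_iter=1000, seed=42,
)
print(f"mean incremental cost: {psa.delta_cost.mean() / 1e6:.2f} million THB")
print(f"mean incremental QALY: {psa.delta_qaly.mean():.2f}")
for pt in ceac(psa, [100_000, 300_000]):
    print(
        f"P(cost-effective at WTP {pt.wtp:>9,.0f} THB/QALY) = "
        f"{pt.probability_cost_effective:.1%}"
    )
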