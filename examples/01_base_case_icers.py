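"""Base-case cost-utility table: ICER of transplantation versus
transfusion-and-chelation by age at treatment start.

For each starting age both arms are run with point-estimate inputs over
a 99-year horizon at 3% discounting (societal perspective), and the
incremental cost (million THB), incremental QALYs and ICER (THB/QALY)
are printed.  "Dominated" marks ages where transplantation costs more
yet yields fewer lifetime QALYs than continued transfusion care.
"""

from thalcea import ModelConfig, default_registry, icer, run_cohort

point = default_registry().point_estimate()

for arm in ("related_hsct", "unrelated_hsct"):
    print(f"\n{arm.replace('_', ' ')} vs BT-ICT")
    print(f"{'age':>4} {'dCost (M THB)':>14} {'dQALY':>8} {'ICER (THB/QALY)':>16}")
    for age in (1, 5, 10, 15, 17, 18, 19, 20, 25, 28):
        cfg = ModelConfig(start_age=age)
        res = icer(
            run_cohort(arm, cfg, point, collect_trace=False),
            run_cohort("bt_ict", cfg, point, collect_trace=False),
        )
        print(
            f"{age:>4} {res.delta_cost / 1e6:>14.2f} {res.delta_qaly:>8.2f} "
            f"{res.label:>16}"
        )
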