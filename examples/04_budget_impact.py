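"""Governmental budget impact of funding 200 related transplants per year.

Stacks a new cohort of 200 patients (entry ages 1-10, uniform) each
fiscal year 2008-2022 and compares direct medical expenditure under
continued transfusion care versus providing related transplantation,
discounted at 3% to 2008.  The incremental column is the extra annual
budget the payer would need; it shrinks over time as transplant
follow-up costs fade while the transfusion cohort keeps accumulating.
"""

from thalcea import BudgetConfig, budget_frame, default_registry, run_budget

rows = run_budget(BudgetConfig(), default_registry().point_estimate())
print(budget_frame(rows).round(0).to_string(index=False))
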