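"""Incremental cost-effectiveness ratios, dominance and net monetary benefit."""

from __future__ import annotations

from dataclasses import dataclass

from .markov import ArmResult

__all__ = ["CEAResult", "NMBValue", "icer", "nmb", "round_sig"]


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator.

    ``verdict`` is one of:

    * ``"icer"`` — more costly and more effective; the ratio is meaningful;
    * ``"dominated"`` — more costly, no more effective;
    * ``"dominant"`` — no more costly, more effective;
    * ``"cost_saving"`` — no more costly, no more effective (south-west
      quadrant, including the null comparison).
    """

    delta_cost: float
    delta_qaly: float
    verdict: str
    icer: float | None = None

    @property
    def label(self) -> str:
        if self.verdict == "icer":
            return f"{round_sig(self.icer):,.0f}"
        return self.verdict.replace("_", " ").capitalize()


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (table presentation)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def icer(intervention: ArmResult, comparator: ArmResult) -> CEAResult:
    """Incremental cost per QALY gained, with dominance handling.

    The ratio is computed only when the intervention is strictly more
    costly and strictly more effective; a zero QALY gain at positive
    extra cost counts as dominated (no division by zero).
    """
    d_cost = intervention.lifetime_cost - comparator.lifetime_cost
    d_qaly = intervention.lifetime_qaly - comparator.lifetime_qaly
    if d_cost > 0 and d_qaly > 0:
        return CEAResult(d_cost, d_qaly, "icer", d_cost / d_qaly)
    if d_cost > 0:
        return CEAResult(d_cost, d_qaly, "dominated")
    if d_qaly > 0:
        return CEAResult(d_cost, d_qaly, "dominant")
    return CEAResult(d_cost, d_qaly, "cost_saving")


@dataclass(frozen=True)
class NMBValue:
    """Net monetary benefit at one willingness-to-pay ceiling ratio."""

    wtp: float
    nmb: float


def nmb(arm: ArmResult, wtp: float) -> NMBValue:
    """NMB = WTP x QALYs - cost (THB); linear in the ceiling ratio."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return NMBValue(wtp=wtp, nmb=wtp * arm.lifetime_qaly - arm.lifetime_cost)
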