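"""One-way deterministic sensitivity analysis (tornado) and probabilistic
sensitivity analysis with cost-effectiveness acceptability curves.

The PSA draws every non-degenerate parameter jointly from its
moment-matched distribution and re-evaluates both arms with the *same*
sampled set (common random parameters), because the uncertainty being
propagated is parameter uncertainty, not stochastic patient variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import icer
from .markov import ModelConfig, run_cohort, run_cohort_vectorized
from .params import ParameterRegistry, ParameterSet

__all__ = [
    "TornadoEntry",
    "CEACPoint",
    "PSAResult",
    "one_way_dsa",
    "default_dsa_ranges",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

#: 0 to 500k THB per QALY in 10k steps, covering the 100k-300k decision band
DEFAULT_WTP_GRID = tuple(range(0, 500_001, 10_000))

_DISCOUNT_NAMES = ("discount_rate_costs", "discount_rate_outcomes")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float | None
    icer_at_high: float | None
    swing: float


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


@dataclass(frozen=True)
class PSAResult:
    """Per-draw discounted (cost, QALY) for intervention and comparator."""

    intervention: str
    comparator: str
    cost_intervention: np.ndarray
    qaly_intervention: np.ndarray
    cost_comparator: np.ndarray
    qaly_comparator: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.cost_intervention)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_intervention - self.qaly_comparator

    def to_frame(self) -> pd.DataFrame:
        n = self.n_draws
        return pd.DataFrame(
            {
                "iteration": np.tile(np.arange(n), 2),
                "arm": [self.intervention] * n + [self.comparator] * n,
                "cost": np.concatenate([self.cost_intervention, self.cost_comparator]),
                "qaly": np.concatenate([self.qaly_intervention, self.qaly_comparator]),
            }
        )


def default_dsa_ranges(
    registry: ParameterRegistry,
    se_multiplier: float = 1.0,
    seless_fraction: float = 0.25,
    discount_range: tuple[float, float] = (0.0, 0.06),
) -> dict[str, tuple[float, float]]:
    """Default one-way ranges: mean +- 1 SE clipped to the parameter's
    domain; the printed 0-6% range for the discount rate (both rates
    moved together under the key ``"discount_rate"``); +-25% for
    probabilities published without an SE."""
    ranges: dict[str, tuple[float, float]] = {"discount_rate": discount_range}
    for spec in registry:
        if spec.group == "discount":
            continue
        if spec.se > 0:
            lo = spec.mean - se_multiplier * spec.se
            hi = spec.mean + se_multiplier * spec.se
        else:
            lo = spec.mean * (1.0 - seless_fraction)
            hi = spec.mean * (1.0 + seless_fraction)
        if spec.family == "beta":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        elif spec.family == "gamma":
            lo = max(lo, 0.0)
        ranges[spec.name] = (lo, hi)
    return ranges


def _icer_value(
    intervention: str, comparator: str, config: ModelConfig, params: ParameterSet
) -> float | None:
    res = icer(
        run_cohort(intervention, config, params, collect_trace=False),
        run_cohort(comparator, config, params, collect_trace=False),
    )
    return res.icer


def one_way_dsa(
    base_params: ParameterSet,
    ranges: dict[str, tuple[float, float]],
    intervention: str,
    comparator: str,
    config: ModelConfig,
) -> list[TornadoEntry]:
    """Re-run the comparison with one parameter at a time at its low and
    high value, all others at base; entries sorted by descending ICER
    swing for tornado display.  The pseudo-parameter ``"discount_rate"``
    moves both the cost and outcome rates together via the config."""
    entries = []
    for name, (lo, hi) in ranges.items():
        if name == "discount_rate":
            icer_lo = _icer_value(
                intervention,
                comparator,
                config.replace(discount_costs=lo, discount_outcomes=lo),
                base_params,
            )
            icer_hi = _icer_value(
                intervention,
                comparator,
                config.replace(discount_costs=hi, discount_outcomes=hi),
                base_params,
            )
        else:
            icer_lo = _icer_value(
                intervention, comparator, config, base_params.replace(**{name: lo})
            )
            icer_hi = _icer_value(
                intervention, comparator, config, base_params.replace(**{name: hi})
            )
        if icer_lo is None or icer_hi is None:
            swing = float("inf")  # dominance flip: maximal qualitative swing
        else:
            swing = abs(icer_hi - icer_lo)
        entries.append(TornadoEntry(name, lo, hi, icer_lo, icer_hi, swing))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )


def run_psa(
    registry: ParameterRegistry,
    intervention: str,
    comparator: str,
    config: ModelConfig,
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Second-order Monte Carlo: ``n_iter`` joint parameter draws, both
    arms evaluated per draw; reproducible given ``seed``."""
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    arrays = registry.sample_arrays(seed, n_iter)
    ci, qi, _, _, _ = run_cohort_vectorized(intervention, config, arrays, n=n_iter)
    cc, qc, _, _, _ = run_cohort_vectorized(comparator, config, arrays, n=n_iter)
    return PSAResult(
        intervention=intervention,
        comparator=comparator,
        cost_intervention=ci,
        qaly_intervention=qi,
        cost_comparator=cc,
        qaly_comparator=qc,
        seed=seed,
    )


def ceac(psa: PSAResult, wtp_grid=DEFAULT_WTP_GRID) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve.

    At each ceiling ratio the probability is the fraction of draws with
    strictly positive incremental net monetary benefit (ties count as
    not cost-effective).
    """
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ValueError("wtp_grid must not be empty")
    d_cost = psa.delta_cost
    d_qaly = psa.delta_qaly
    return [
        CEACPoint(
            wtp=float(w),
            probability_cost_effective=float(np.mean(w * d_qaly - d_cost > 0)),
        )
        for w in wtp_grid
    ]


def ceac_frame(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wtp": [p.wtp for p in points],
            "probability_cost_effective": [
                p.probability_cost_effective for p in points
            ],
        }
    )
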