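"""Five-state Markov cohort engine for transplant versus transfusion care.

States: first transplant year, second transplant year, post-transplant
(successful graft), transfusion-and-chelation (BT-ICT, also the
destination of graft failures), and death.  Cycles are one year; the
horizon (default 99 cycles) covers the maximum lifetime.

Transition structure per cycle, for a cohort that started treatment at
``start_age``:

* occupants of the three transplant states face a death probability from
  the Weibull death model (age-at-start covariate, clock = time since
  transplant) and, among survivors, a graft-failure probability from the
  Weibull failure model (donor-type covariate);
* graft failures move to BT-ICT permanently (or, with
  ``max_transplants=2``, receive one repeat transplant with a reset
  transplant clock and full first-year payoffs);
* BT-ICT occupants die with the age-band annual probability at their
  attained age;
* with ``background_mortality="post_hsct"`` (the default), occupants of
  the post-transplant state additionally face the age-band probability
  as a competing risk, so a cured cohort is not effectively immortal
  when the fitted transplant hazard (shape < 1) fades over a 99-year
  extrapolation.

Death is evaluated before failure within a cycle, so probability mass is
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .params import ParameterSet
from .survival import (
    WeibullCoefficients,
    cycle_transition_probability,
    scale_lambda,
)

__all__ = [
    "HealthState",
    "AgeBandTable",
    "ModelConfig",
    "StatePayoffs",
    "CohortTrace",
    "ArmResult",
    "ARMS",
    "btict_death_probability",
    "build_cycle_transitions",
    "run_cohort",
    "run_cohort_vectorized",
    "microsimulate",
]

ARMS = ("related_hsct", "unrelated_hsct", "bt_ict")

_OCCUPANCY_TOL = 1e-8


class HealthState(IntEnum):
    HSCT_YEAR1 = 0
    HSCT_YEAR2 = 1
    POST_HSCT = 2
    BT_ICT = 3
    DEAD = 4


_BAND_PARAMS = (
    (0, 1, "btict_death_age_0_1"),
    (2, 5, "btict_death_age_2_5"),
    (6, 10, "btict_death_age_6_10"),
    (11, 15, "btict_death_age_11_15"),
    (16, 20, "btict_death_age_16_20"),
    (21, 30, "btict_death_age_21_30"),
    (31, None, "btict_death_age_31_plus"),
)


@dataclass(frozen=True)
class AgeBandTable:
    """Contiguous integer age bands with annual death probabilities.

    Upper bounds are inclusive (age 10 falls in the 6-10 band); ages
    beyond the last band keep its probability indefinitely.
    """

    bands: tuple[tuple[int, int | None, float], ...]

    def __post_init__(self) -> None:
        prev_hi = -1
        for lo, hi, p in self.bands:
            if lo != prev_hi + 1:
                raise ValueError("age bands must be contiguous from 0")
            if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > 1):
                raise ValueError(f"band probability {p} outside [0, 1]")
            prev_hi = hi if hi is not None else lo
            if hi is None:
                break

    @classmethod
    def from_parameter_set(cls, params: ParameterSet | Mapping) -> "AgeBandTable":
        get = params.__getitem__
        return cls(tuple((lo, hi, get(name)) for lo, hi, name in _BAND_PARAMS))

    def probability(self, age: float):
        if age < 0:
            raise ValueError("age must be >= 0")
        age = int(age)
        for lo, hi, p in self.bands:
            if hi is None or lo <= age <= hi:
                return p
        return self.bands[-1][2]


def btict_death_probability(age: float, table: AgeBandTable):
    """Annual death probability under transfusion care at integer ``age``."""
    return table.probability(age)


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration for one cohort simulation."""

    start_age: int = 1
    horizon: int = 99
    discount_costs: float = 0.03
    discount_outcomes: float = 0.03
    perspective: str = "societal"
    max_transplants: int = 1
    cycle_days: float = 365.0
    accrual_timing: str = "cycle_start"
    background_mortality: str = "post_hsct"
    hsct_year12_cost_split: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.start_age <= 28:
            raise ValueError("start_age must be between 1 and 28 years")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 cycle")
        for r in (self.discount_costs, self.discount_outcomes):
            if not 0.0 <= r <= 0.06:
                raise ValueError("discount rates must lie in [0, 0.06]")
        if self.perspective not in ("societal", "governmental"):
            raise ValueError("perspective must be societal or governmental")
        if self.max_transplants not in (1, 2):
            raise ValueError("max_transplants must be 1 or 2")
        if self.accrual_timing not in ("cycle_start", "half_cycle"):
            raise ValueError("accrual_timing must be cycle_start or half_cycle")
        if self.background_mortality not in ("none", "post_hsct"):
            raise ValueError("background_mortality must be none or post_hsct")
        if not 0.0 <= self.hsct_year12_cost_split <= 1.0:
            raise ValueError("hsct_year12_cost_split must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class StatePayoffs:
    """Per-cycle cost (THB) and utility by health state for one arm.

    Arrays broadcast over PSA draws; the dead state pays nothing.
    """

    cost: tuple  # indexed by HealthState
    utility: tuple


def state_payoffs(arm: str, config: ModelConfig, p: Mapping) -> StatePayoffs:
    """Assemble state payoffs for ``arm`` under the configured perspective.

    Societal costs are direct medical + direct non-medical + productivity
    losses; the governmental perspective keeps direct medical costs only.
    The survey totals for transplant non-medical and productivity costs
    cover the first two years jointly and are split between year 1 and
    year 2 by ``hsct_year12_cost_split`` (fraction allocated to year 1).
    Cured patients are assumed to incur BT-ICT-level non-medical and
    productivity costs.  Utilities: transfusion-level (0.61 base case) in
    the BT-ICT state and both transplant years, near-healthy (0.93) after
    a successful transplant; death pays zero.
    """
    unrelated = arm == "unrelated_hsct"
    pre = "cost_unrelated_hsct" if unrelated else "cost_related_hsct"
    med1, med2, medf = p[f"{pre}_year1"], p[f"{pre}_year2"], p[f"{pre}_following"]
    zero = 0.0 * np.asarray(p["cost_btict_annual"])
    if config.perspective == "societal":
        two_year_extra = p["cost_nonmedical_hsct_year12"] + p["cost_productivity_hsct_year12"]
        split = config.hsct_year12_cost_split
        extra1 = split * two_year_extra
        extra2 = (1.0 - split) * two_year_extra
        extraf = p["cost_nonmedical_btict_annual"] + p["cost_productivity_btict_annual"]
    else:
        extra1 = extra2 = extraf = zero
    cost = (
        med1 + extra1,
        med2 + extra2,
        medf + extraf,
        p["cost_btict_annual"] + extraf,
        zero,
    )
    utility = (
        p["utility_hsct_year12"],
        p["utility_hsct_year12"],
        p["utility_hsct_post"],
        p["utility_btict"],
        zero,
    )
    for c in cost:
        if np.any(np.asarray(c) < 0):
            raise ValueError("state costs must be >= 0")
    for uv in utility:
        arr = np.asarray(uv)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("state utilities must lie in [0, 1]")
    return StatePayoffs(cost=cost, utility=utility)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted/undiscounted payoff increments."""

    occupancy: np.ndarray  # (horizon, 5)
    cost: np.ndarray  # undiscounted, (horizon,)
    cost_discounted: np.ndarray
    qaly: np.ndarray
    qaly_discounted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.occupancy, columns=[s.name.lower() for s in HealthState]
        )
        frame.insert(0, "cycle", np.arange(1, len(frame) + 1))
        frame["cost"] = self.cost
        frame["cost_discounted"] = self.cost_discounted
        frame["qaly"] = self.qaly
        frame["qaly_discounted"] = self.qaly_discounted
        return frame


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime totals for one arm, with the full trace."""

    arm: str
    lifetime_cost: float
    lifetime_qaly: float
    lifetime_cost_undiscounted: float
    lifetime_qaly_undiscounted: float
    trace: CohortTrace | None = None


def _weibull_tp(p: Mapping, model: str, covariates: Mapping, t: float, u: float):
    coeffs = WeibullCoefficients.from_parameter_set(p, model)  # type: ignore[arg-type]
    lam = scale_lambda(coeffs, covariates)
    return cycle_transition_probability(lam, coeffs.shape, t, u)


def _vector_weibull_tp(p: Mapping, model: str, cov_value: float, t: float, u: float):
    """Vectorized tp over PSA draws (parameters may be arrays)."""
    if model == "death":
        lam = np.exp(p["death_constant"] + p["death_age_coefficient"] * cov_value)
        gamma = np.exp(p["death_ancillary"])
    else:
        lam = np.exp(
            p["failure_constant"] + p["failure_donor_type_coefficient"] * cov_value
        )
        gamma = np.exp(p["failure_ancillary"])
    return cycle_transition_probability(lam, gamma, t, u)


def build_cycle_transitions(
    arm: str, cycle_index: int, config: ModelConfig, params: ParameterSet
) -> dict[HealthState, dict[HealthState, float]]:
    """Transition probabilities out of each state for one cycle.

    The transplant clock is ``cycle_index`` cycles since the (first)
    transplant; BT-ICT mortality is looked up at the attained age
    ``start_age + cycle_index - 1``.  Death is resolved before failure,
    so each row sums to one exactly.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    S = HealthState
    u = config.cycle_days
    t = cycle_index * u
    age = config.start_age + cycle_index - 1
    table = AgeBandTable.from_parameter_set(params)
    pb = float(btict_death_probability(age, table))
    rows: dict[HealthState, dict[HealthState, float]] = {
        S.BT_ICT: {S.DEAD: pb, S.BT_ICT: 1.0 - pb},
        S.DEAD: {S.DEAD: 1.0},
    }
    if arm == "bt_ict":
        return rows
    donor = 1.0 if arm == "unrelated_hsct" else 0.0
    pdw = float(
        _weibull_tp(params, "death", {"age_at_start_years": config.start_age}, t, u)
    )
    pfw = float(_weibull_tp(params, "failure", {"donor_type": donor}, t, u))
    fail_dest = S.HSCT_YEAR1 if config.max_transplants > 1 else S.BT_ICT
    for state, nxt in (
        (S.HSCT_YEAR1, S.HSCT_YEAR2),
        (S.HSCT_YEAR2, S.POST_HSCT),
        (S.POST_HSCT, S.POST_HSCT),
    ):
        pd_ = pdw
        if state is S.POST_HSCT and config.background_mortality == "post_hsct":
            pd_ = 1.0 - (1.0 - pdw) * (1.0 - pb)
        pf = (1.0 - pd_) * pfw
        row = {S.DEAD: pd_, fail_dest: pf, nxt: 1.0 - pd_ - pf}
        if not all(0.0 <= v <= 1.0 for v in row.values()):
            raise ValueError(f"transition probability outside [0, 1]: {row}")
        rows[state] = row
    return rows


def run_cohort_vectorized(
    arm: str,
    config: ModelConfig,
    p: Mapping[str, np.ndarray | float],
    n: int | None = None,
    collect_trace: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, CohortTrace | None]:
    """Run the cohort model with (possibly array-valued) parameters.

    Returns ``(cost_disc, qaly_disc, cost_undisc, qaly_undisc, trace)``;
    the first four broadcast over PSA draws.  Occupancy is tracked per
    transplant epoch so a repeat transplant restarts the Weibull clock.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if n is None:
        n = max(
            np.size(v) for v in p.values()
        )
    shape = (n,)
    pay = state_payoffs(arm, config, p)
    scost = [np.broadcast_to(np.asarray(c, dtype=float), shape) for c in pay.cost]
    sutil = [np.broadcast_to(np.asarray(uv, dtype=float), shape) for uv in pay.utility]
    u = config.cycle_days
    donor = 1.0 if arm == "unrelated_hsct" else 0.0
    table = AgeBandTable.from_parameter_set(p)
    S = HealthState
    # occupancy keyed by (state, transplant-start cycle, transplant count)
    if arm == "bt_ict":
        occ: dict[tuple[int, int, int], np.ndarray] = {
            (S.BT_ICT, 0, 0): np.ones(shape)
        }
    else:
        occ = {(S.HSCT_YEAR1, 1, 1): np.ones(shape)}
    bg_post = config.background_mortality == "post_hsct"
    cost_d = np.zeros(shape)
    qaly_d = np.zeros(shape)
    cost_u = np.zeros(shape)
    qaly_u = np.zeros(shape)
    trace_occ = np.zeros((config.horizon, 5)) if collect_trace else None
    trace_cols = np.zeros((config.horizon, 4)) if collect_trace else None
    half = config.accrual_timing == "half_cycle"

    def payoff(occupancy: dict) -> tuple[np.ndarray, np.ndarray]:
        c = np.zeros(shape)
        q = np.zeros(shape)
        for (state, _, _), v in occupancy.items():
            c += v * scost[state]
            q += v * sutil[state]
        return c, q

    for k in range(1, config.horizon + 1):
        age = config.start_age + k - 1
        pb = np.asarray(table.probability(age), dtype=float)
        new: dict[tuple[int, int, int], np.ndarray] = {}

        def add(key, v):
            if key in new:
                new[key] = new[key] + v
            else:
                new[key] = v

        for (state, tx0, ntx), v in occ.items():
            if state == S.DEAD:
                add((S.DEAD, 0, 0), v)
                continue
            if state == S.BT_ICT:
                add((S.DEAD, 0, 0), v * pb)
                add((S.BT_ICT, 0, 0), v * (1.0 - pb))
                continue
            t = (k - tx0 + 1) * u  # cycles since this transplant
            pdw = _vector_weibull_tp(p, "death", config.start_age, t, u)
            pfw = _vector_weibull_tp(p, "failure", donor, t, u)
            pd_ = (
                1.0 - (1.0 - pdw) * (1.0 - pb)
                if (state == S.POST_HSCT and bg_post)
                else pdw
            )
            pf = (1.0 - pd_) * pfw
            add((S.DEAD, 0, 0), v * pd_)
            if ntx < config.max_transplants:
                add((S.HSCT_YEAR1, k + 1, ntx + 1), v * pf)
            else:
                add((S.BT_ICT, 0, 0), v * pf)
            nxt = S.HSCT_YEAR2 if state == S.HSCT_YEAR1 else S.POST_HSCT
            add((nxt, tx0, ntx), v * (1.0 - pd_ - pf))

        total = sum(new.values())
        if np.any(np.abs(total - 1.0) > _OCCUPANCY_TOL):
            raise RuntimeError(
                f"occupancy leak at cycle {k}: max |1 - total| = "
                f"{float(np.max(np.abs(total - 1.0))):.2e}"
            )
        c_start, q_start = payoff(occ)
        if half:
            c_end, q_end = payoff(new)
            c_acc = 0.5 * (c_start + c_end)
            q_acc = 0.5 * (q_start + q_end)
        else:
            c_acc, q_acc = c_start, q_start
        dc = (1.0 + config.discount_costs) ** -(k - 1)
        dq = (1.0 + config.discount_outcomes) ** -(k - 1)
        cost_u += c_acc
        qaly_u += q_acc
        cost_d += dc * c_acc
        qaly_d += dq * q_acc
        if collect_trace:
            for (state, _, _), v in occ.items():
                trace_occ[k - 1, state] += float(np.mean(v))
            trace_cols[k - 1] = (
                float(np.mean(c_acc)),
                float(np.mean(dc * c_acc)),
                float(np.mean(q_acc)),
                float(np.mean(dq * q_acc)),
            )
        occ = new

    trace = None
    if collect_trace:
        trace = CohortTrace(
            occupancy=trace_occ,
            cost=trace_cols[:, 0],
            cost_discounted=trace_cols[:, 1],
            qaly=trace_cols[:, 2],
            qaly_discounted=trace_cols[:, 3],
        )
    return cost_d, qaly_d, cost_u, qaly_u, trace


def run_cohort(
    arm: str, config: ModelConfig, params: ParameterSet, collect_trace: bool = True
) -> ArmResult:
    """Run one arm with a single realized parameter set."""
    cost_d, qaly_d, cost_u, qaly_u, trace = run_cohort_vectorized(
        arm, config, params.values, n=1, collect_trace=collect_trace
    )
    return ArmResult(
        arm=arm,
        lifetime_cost=float(cost_d[0]),
        lifetime_qaly=float(qaly_d[0]),
        lifetime_cost_undiscounted=float(cost_u[0]),
        lifetime_qaly_undiscounted=float(qaly_u[0]),
        trace=trace,
    )


def microsimulate(
    arm: str,
    config: ModelConfig,
    params: ParameterSet,
    n_individuals: int = 100_000,
    seed: int = 0,
) -> dict[str, float]:
    """First-order (individual-level) Monte Carlo using the same per-cycle
    probabilities as the cohort engine; an independent cross-check.

    Returns mean discounted cost/QALY per individual and their Monte
    Carlo standard errors.  Supports ``max_transplants=1`` only.
    """
    if config.max_transplants != 1:
        raise NotImplementedError("microsimulation supports max_transplants=1")
    rng = np.random.default_rng(seed)
    p = params.values
    pay = state_payoffs(arm, config, p)
    scost = np.array([float(c) for c in pay.cost])
    sutil = np.array([float(uv) for uv in pay.utility])
    table = AgeBandTable.from_parameter_set(params)
    u = config.cycle_days
    donor = 1.0 if arm == "unrelated_hsct" else 0.0
    S = HealthState
    state = np.full(
        n_individuals, S.BT_ICT if arm == "bt_ict" else S.HSCT_YEAR1, dtype=np.int8
    )
    cost = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)
    half = config.accrual_timing == "half_cycle"
    for k in range(1, config.horizon + 1):
        age = config.start_age + k - 1
        pb = float(table.probability(age))
        t = k * u
        pdw = float(_vector_weibull_tp(p, "death", config.start_age, t, u))
        pfw = float(_vector_weibull_tp(p, "failure", donor, t, u))
        start_state = state.copy()
        draw = rng.random(n_individuals)
        draw2 = rng.random(n_individuals)
        new = state.copy()
        for s in (S.HSCT_YEAR1, S.HSCT_YEAR2, S.POST_HSCT):
            mask = state == s
            if not mask.any():
                continue
            pd_ = (
                1.0 - (1.0 - pdw) * (1.0 - pb)
                if (s == S.POST_HSCT and config.background_mortality == "post_hsct")
                else pdw
            )
            dies = mask & (draw < pd_)
            fails = mask & ~dies & (draw2 < pfw)
            moves = mask & ~dies & ~fails
            new[dies] = S.DEAD
            new[fails] = S.BT_ICT
            new[moves] = S.HSCT_YEAR2 if s == S.HSCT_YEAR1 else S.POST_HSCT
        mask = state == S.BT_ICT
        dies = mask & (draw < pb)
        new[dies] = S.DEAD
        dc = (1.0 + config.discount_costs) ** -(k - 1)
        dq = (1.0 + config.discount_outcomes) ** -(k - 1)
        if half:
            cost += dc * 0.5 * (scost[start_state] + scost[new])
            qaly += dq * 0.5 * (sutil[start_state] + sutil[new])
        else:
            cost += dc * scost[start_state]
            qaly += dq * sutil[start_state]
        state = new
    return {
        "cost": float(cost.mean()),
        "qaly": float(qaly.mean()),
        "cost_se": float(cost.std(ddof=1) / np.sqrt(n_individuals)),
        "qaly_se": float(qaly.std(ddof=1) / np.sqrt(n_individuals)),
    }
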