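"""Decision-tree entry pathways and the lifetime Markov cohort engine.

The comparison is between two strategies for patients with spontaneous
subarachnoid hemorrhage whose initial CTA + DSA was negative:

* ``no_repeat`` — discharge without further imaging; patients with an
  occult aneurysm remain at risk of re-bleeding.
* ``repeat_cta`` — a repeat CTA seven days after the initial imaging
  (in-hospital wait), DSA confirmation of positives, and elective
  treatment of confirmed aneurysms.

Each strategy's decision tree produces an :class:`EntryProfile` — an
upfront cost at time zero and a distribution over the four Markov
states — which the cohort engine then propagates through one-year
cycles until age ``stop_age``, accruing discounted costs and QALYs.

Accounting conventions: state rewards accrue at the end of each cycle
(discount exponent equals the cycle index, first cycle t = 1); upfront
decision-tree costs sit at t = 0 undiscounted; a re-bleed's emergency
treatment cost is discounted at the cycle in which it occurs, while the
survivors' outcome-state rewards start the following cycle (a one-cycle
zero-reward tunnel; ``ParameterSet.rebleed_reward_same_cycle`` restores
same-cycle accrual).  Half-cycle correction is off by default and can
be enabled via ``ParameterSet.half_cycle_correction``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import LifeTable, ParameterSet, RebleedSchedule, SIMPLEX_TOL

__all__ = [
    "HealthState",
    "EntryProfile",
    "TransitionModel",
    "Trace",
    "StrategyResult",
    "CEComparison",
    "ARMS",
    "discount_factor",
    "combine_hazards",
    "elective_treatment_cost",
    "rebleed_resolution",
    "short_term_pathway",
    "run_cohort",
    "evaluate_strategy",
    "incremental_analysis",
]

ARMS = ("no_repeat", "repeat_cta")
MIN_LIVING_MASS = 1e-9


class HealthState(IntEnum):
    """Markov states; long-term outcomes follow the modified Rankin Scale."""

    AT_RISK = 0      # occult aneurysm, no re-bleed yet
    FAVORABLE = 1    # mRS 0-2
    UNFAVORABLE = 2  # mRS 3-5
    DEAD = 3         # mRS 6, absorbing


_OUTCOME_STATES = (HealthState.FAVORABLE, HealthState.UNFAVORABLE, HealthState.DEAD)


@dataclass(frozen=True)
class EntryProfile:
    """Time-zero result of a strategy's decision tree."""

    upfront_cost: float
    entry_mass: np.ndarray  # over (AT_RISK, FAVORABLE, UNFAVORABLE, DEAD)
    branch_log: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        mass = np.asarray(self.entry_mass, dtype=float)
        if mass.shape != (4,):
            raise ValueError("entry_mass must have one component per health state")
        if abs(mass.sum() - 1.0) > SIMPLEX_TOL:
            raise ValueError(f"entry_mass sums to {mass.sum()}, not 1")
        if self.upfront_cost < 0:
            raise ValueError("upfront_cost must be nonnegative")
        if any(not (0.0 <= v <= 1.0) for v in self.branch_log.values()):
            raise ValueError("branch_log probabilities must lie in [0, 1]")
        object.__setattr__(self, "entry_mass", mass)


@dataclass(frozen=True)
class TransitionModel:
    """Per-cycle movement rules among the four states.

    Post-treatment outcome-state transitions come either from
    ``ParameterSet.state_mortality`` (default: annual death probability
    from the favorable and unfavorable states, no moves between them) or
    from an explicit 3x3 ``outcome_matrix`` over (favorable,
    unfavorable, dead), e.g. loaded from a from/to/prob CSV.  Background
    mortality from the life table combines with state-specific risk as
    independent hazards: survivors of background mortality distribute
    per the state row, so P(death) = 1 - (1 - row_death)(1 - qx).
    """

    life_table: LifeTable
    rebleed_schedule: RebleedSchedule
    outcome_matrix: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.outcome_matrix is not None:
            m = np.asarray(self.outcome_matrix, dtype=float)
            if m.shape != (3, 3):
                raise ValueError("outcome_matrix must be 3x3 over (favorable, unfavorable, dead)")
            if np.any(m < -SIMPLEX_TOL) or np.any(m > 1 + SIMPLEX_TOL):
                raise ValueError("outcome_matrix entries must lie in [0, 1]")
            bad = np.abs(m.sum(axis=1) - 1.0) > SIMPLEX_TOL
            if bad.any():
                names = np.array(["favorable", "unfavorable", "dead"])[bad]
                raise ValueError(f"outcome_matrix rows {list(names)} do not sum to 1")
            if abs(m[2, 2] - 1.0) > SIMPLEX_TOL:
                raise ValueError("outcome_matrix dead row must be absorbing")
            object.__setattr__(self, "outcome_matrix", m)

    def outcome_rows(self, p: ParameterSet) -> np.ndarray:
        """2x3 rows (from favorable, from unfavorable) over (fav, unfav, dead)."""
        if self.outcome_matrix is not None:
            return self.outcome_matrix[:2].copy()
        mf, mu = p.state_mortality[0], p.state_mortality[1]
        return np.array([[1.0 - mf, 0.0, mf], [0.0, 1.0 - mu, mu]])


@dataclass
class Trace:
    """Per-cycle state occupancy and discounted accruals for one cohort run."""

    start_age: float
    cycles: np.ndarray            # 1..T
    ages: np.ndarray              # age during each cycle
    occupancy: np.ndarray         # (T, 4), end-of-cycle
    cost_accrual: np.ndarray      # discounted GBP per cycle
    qaly_accrual: np.ndarray      # discounted QALYs per cycle

    @property
    def total_cost(self) -> float:
        return float(self.cost_accrual.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_accrual.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy, columns=[s.name.lower() for s in HealthState]
        )
        df.insert(0, "cycle", self.cycles)
        df.insert(1, "age", self.ages)
        df["discounted_cost"] = self.cost_accrual
        df["discounted_qaly"] = self.qaly_accrual
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime expected discounted cost and QALYs for one strategy."""

    strategy: str
    expected_cost: float
    expected_qaly: float
    entry: EntryProfile
    trace: Trace

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "expected_cost": self.expected_cost,
            "expected_qaly": self.expected_qaly,
            "upfront_cost": self.entry.upfront_cost,
        }


@dataclass(frozen=True)
class CEComparison:
    """Pairwise incremental comparison (comparator vs reference)."""

    reference: StrategyResult
    comparator: StrategyResult
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]   # GBP per QALY; None when delta_qaly == 0
    label: str              # "icer", "dominant", "dominated" or "undefined"
    wtp: float
    nmb: float              # wtp * delta_qaly - delta_cost

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "reference": self.reference.to_dict(),
            "comparator": self.comparator.to_dict(),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "label": self.label,
            "wtp": self.wtp,
            "nmb": self.nmb,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Elemental operations
# ---------------------------------------------------------------------------


def discount_factor(cycle: int, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** -cycle``."""
    if rate <= -1:
        raise ValueError(f"discount rate must exceed -1, got {rate}")
    return (1.0 + rate) ** (-cycle)


def combine_hazards(p_state: float, q_age: float) -> float:
    """Combine two annual death probabilities as independent hazards.

    ``1 - (1 - p_state)(1 - q_age)``; symmetric and never below either
    input.
    """
    for name, v in (("p_state", p_state), ("q_age", q_age)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    # p + q - pq form keeps precision when one input is tiny
    return min(1.0, p_state + q_age - p_state * q_age)


def elective_treatment_cost(p: ParameterSet) -> float:
    """Elective repair cost under the coiling/clipping mix."""
    return (
        p.coiling_fraction * p.cost_elective_coiling
        + (1.0 - p.coiling_fraction) * p.cost_elective_clipping
    )


def rebleed_resolution(p: ParameterSet) -> tuple[float, np.ndarray]:
    """Emergency treatment cost and outcome split after a re-bleed.

    The outcome distribution's death share subsumes death before or
    during emergency treatment.
    """
    cost = (
        p.coiling_fraction * p.cost_emergency_coiling
        + (1.0 - p.coiling_fraction) * p.cost_emergency_clipping
    )
    return cost, np.asarray(p.outcome_rebleed, dtype=float)


# ---------------------------------------------------------------------------
# Decision-tree pathways
# ---------------------------------------------------------------------------


def short_term_pathway(arm: str, p: ParameterSet) -> EntryProfile:
    """Resolve a strategy's decision tree into an :class:`EntryProfile`.

    ``no_repeat``: no upfront cost; patients with an occult aneurysm
    (prevalence) enter AT_RISK, the rest split per the no-aneurysm
    outcome distribution.

    ``repeat_cta``: everyone pays the 7-day hospital stay plus the CTA.
    True positives add a confirmatory DSA and elective treatment and
    enter per the elective outcome split; false negatives stay AT_RISK;
    false positives add a DSA (DSA itself has 100% specificity, so none
    are treated) and, like true negatives, follow the no-aneurysm split.
    """
    prev = p.prevalence_aneurysm
    no_an = np.asarray(p.outcome_no_aneurysm, dtype=float)
    mass = np.zeros(4)

    if arm == "no_repeat":
        mass[HealthState.AT_RISK] = prev
        for s, share in zip(_OUTCOME_STATES, no_an):
            mass[s] += (1.0 - prev) * share
        return EntryProfile(
            upfront_cost=0.0,
            entry_mass=mass,
            branch_log={"aneurysm": prev, "no_aneurysm": 1.0 - prev},
        )

    if arm != "repeat_cta":
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")

    tp = prev * p.cta_sensitivity
    fn = prev * (1.0 - p.cta_sensitivity)
    tn = (1.0 - prev) * p.cta_specificity
    fp = (1.0 - prev) * (1.0 - p.cta_specificity)

    stay_cost = p.los_days * p.cost_hospital_day + p.cost_cta
    upfront = stay_cost + (tp + fp) * p.cost_dsa + tp * elective_treatment_cost(p)

    mass[HealthState.AT_RISK] = fn
    elective = np.asarray(p.outcome_elective, dtype=float)
    for s, share in zip(_OUTCOME_STATES, elective):
        mass[s] += tp * share
    for s, share in zip(_OUTCOME_STATES, no_an):
        mass[s] += (tn + fp) * share

    return EntryProfile(
        upfront_cost=upfront,
        entry_mass=mass,
        branch_log={
            "true_positive": tp,
            "false_negative": fn,
            "true_negative": tn,
            "false_positive": fp,
        },
    )


# ---------------------------------------------------------------------------
# Cohort engine
# ---------------------------------------------------------------------------


def run_cohort(
    entry: EntryProfile,
    tm: TransitionModel,
    p: ParameterSet,
    start_age: float | None = None,
    stop_age: float | None = None,
) -> Trace:
    """Propagate the cohort through one-year cycles until ``stop_age``.

    Per cycle: AT_RISK patients re-bleed with the schedule probability
    for that year since presentation (splitting per
    :func:`rebleed_resolution`, with the emergency cost accrued,
    discounted, on the moving mass) or face background mortality;
    favorable/unfavorable patients transition per the outcome rows
    combined with background mortality; DEAD absorbs.  QALY accrual per
    cycle is end-of-cycle state mass times state utility times the
    discount factor; cost accrual is the annual nursing cost on the
    unfavorable mass plus the discounted re-bleed event cost.  The run
    ends at ``stop_age`` (the terminal cycle forces qx = 1) or when
    living mass is exhausted.
    """
    start_age = p.start_age if start_age is None else start_age
    stop_age = p.stop_age if stop_age is None else stop_age
    if start_age >= stop_age:
        raise ValueError(f"start_age {start_age} must be below stop_age {stop_age}")
    n_cycles = int(np.ceil(stop_age - start_age))

    utilities = np.array(
        [p.utility_no_rebleed, p.utility_favorable, p.utility_unfavorable, p.utility_dead]
    )
    annual_costs = np.array([0.0, 0.0, p.cost_nursing_unfavorable_annual, 0.0])
    emergency_cost, rebleed_outcome = rebleed_resolution(p)
    rows = tm.outcome_rows(p)

    dq = 1.0 / (1.0 + p.discount_qaly)
    dc = 1.0 / (1.0 + p.discount_cost)

    occ = entry.entry_mass.astype(float).copy()
    cycles, ages, occs, costs, qalys = [], [], [], [], []

    for t in range(1, n_cycles + 1):
        age = start_age + t - 1
        qx = 1.0 if t == n_cycles else tm.life_table.qx_at(age)
        r = tm.rebleed_schedule.prob_at(t)

        new = np.zeros(4)
        # occult aneurysm: re-bleed, else background mortality, else stay
        ar = occ[HealthState.AT_RISK]
        rebleed_mass = ar * r
        new[HealthState.AT_RISK] += ar * (1.0 - r) * (1.0 - qx)
        new[HealthState.DEAD] += ar * (1.0 - r) * qx
        for s, share in zip(_OUTCOME_STATES, rebleed_outcome):
            new[s] += rebleed_mass * share
        # post-event outcome states: state row x background survival
        for i, s in enumerate((HealthState.FAVORABLE, HealthState.UNFAVORABLE)):
            m = occ[s]
            living = rows[i, :2] * (1.0 - qx)
            new[HealthState.FAVORABLE] += m * living[0]
            new[HealthState.UNFAVORABLE] += m * living[1]
            new[HealthState.DEAD] += m * (1.0 - living.sum())
        new[HealthState.DEAD] += occ[HealthState.DEAD]

        # reward-bearing occupancy: same-cycle re-bleed survivors sit in
        # a zero-reward tunnel unless rebleed_reward_same_cycle is set
        reward_occ = new.copy()
        if not p.rebleed_reward_same_cycle:
            reward_occ[HealthState.FAVORABLE] -= rebleed_mass * rebleed_outcome[0]
            reward_occ[HealthState.UNFAVORABLE] -= rebleed_mass * rebleed_outcome[1]
        weights = 0.5 * (occ + reward_occ) if p.half_cycle_correction else reward_occ
        qaly = dq**t * float(weights @ utilities)
        cost = dc**t * (float(weights @ annual_costs) + rebleed_mass * emergency_cost)

        cycles.append(t)
        ages.append(age)
        occs.append(new)
        costs.append(cost)
        qalys.append(qaly)
        occ = new
        if 1.0 - occ[HealthState.DEAD] < MIN_LIVING_MASS:
            break

    return Trace(
        start_age=start_age,
        cycles=np.asarray(cycles, dtype=int),
        ages=np.asarray(ages, dtype=float),
        occupancy=np.asarray(occs, dtype=float),
        cost_accrual=np.asarray(costs, dtype=float),
        qaly_accrual=np.asarray(qalys, dtype=float),
    )


def evaluate_strategy(arm: str, p: ParameterSet, tm: TransitionModel) -> StrategyResult:
    """Decision tree plus lifetime cohort run for one strategy."""
    entry = short_term_pathway(arm, p)
    trace = run_cohort(entry, tm, p)
    return StrategyResult(
        strategy=arm,
        expected_cost=entry.upfront_cost + trace.total_cost,
        expected_qaly=trace.total_qaly,
        entry=entry,
        trace=trace,
    )


def incremental_analysis(
    ref: StrategyResult, comp: StrategyResult, wtp: float = 20_000.0
) -> CEComparison:
    """Incremental cost, incremental QALYs, ICER/dominance and NMB."""
    delta_cost = comp.expected_cost - ref.expected_cost
    delta_qaly = comp.expected_qaly - ref.expected_qaly
    icer = delta_cost / delta_qaly if delta_qaly != 0.0 else None
    if delta_qaly > 0 and delta_cost < 0:
        label = "dominant"
    elif delta_qaly < 0 and delta_cost > 0:
        label = "dominated"
    elif delta_qaly == 0.0:
        label = "undefined"
    else:
        label = "icer"
    return CEComparison(
        reference=ref,
        comparator=comp,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        label=label,
        wtp=wtp,
        nmb=wtp * delta_qaly - delta_cost,
    )
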