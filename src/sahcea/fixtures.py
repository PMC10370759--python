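"""Synthetic stand-ins for inputs the published tables do not print,
plus an individual-level microsimulation oracle for engine validation.

Three tabular inputs of the model come from supplementary or external
sources that are not shipped here: the background-mortality life table,
the annual re-bleed probability schedule (a 10-year UK aneurysm
cohort), and the post-treatment outcome-state transition probabilities
(ISAT 10-year follow-up).  This module synthesizes documented
placeholders for each — every generated file is labelled
``source: fixture`` — and users replicating against the real tables can
pass their own CSVs to the same loaders.

The microsimulation oracle re-implements the model at the individual
level by direct sampling of every decision-tree branch and Markov
transition, under the same accounting conventions as the cohort
engine.  It shares no propagation code with the engine, so agreement
between the two (within Monte-Carlo error) is an end-to-end check of
the deterministic implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    HealthState,
    TransitionModel,
    elective_treatment_cost,
    rebleed_resolution,
    short_term_pathway,
)
from .parameters import (
    ConfigFormatError,
    LifeTable,
    ParameterSet,
    RebleedSchedule,
    default_parameters,
    write_parameters,
)

__all__ = [
    "GompertzSpec",
    "gompertz_life_table",
    "default_life_table",
    "default_rebleed_schedule",
    "load_outcome_matrix",
    "outcome_matrix_to_csv",
    "default_transition_fixture",
    "MicrosimResult",
    "microsim_oracle",
    "write_fixture_files",
]

FIXTURE_HEADER = (
    "source: fixture — synthetic stand-in generated by sahcea.fixtures; "
    "not data from the published study or its supplement"
)


# ---------------------------------------------------------------------------
# Background mortality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz mortality shape: ``qx(age) = min(1, a * exp(b * age))``.

    ``a`` is the baseline annual death probability at age 0 and ``b``
    the log-increase per year of age.  The defaults give an
    adult-mortality shape of the right order for a high-income
    population; this is a documented fixture, not a national life
    table.
    """

    a: float = 2.3e-5
    b: float = 0.095
    cap: int = 110

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("baseline rate a must be positive")
        if self.b < 0:
            raise ValueError("age slope b must be nonnegative")
        if self.cap < 1:
            raise ValueError("cap age must be at least 1")


def gompertz_life_table(spec: GompertzSpec = GompertzSpec()) -> LifeTable:
    """Life table from a Gompertz hazard, closed with qx = 1 at the cap age."""
    ages = np.arange(0, spec.cap + 1)
    qx = np.minimum(1.0, spec.a * np.exp(spec.b * ages))
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def default_life_table() -> LifeTable:
    return gompertz_life_table()


# ---------------------------------------------------------------------------
# Re-bleed schedule
# ---------------------------------------------------------------------------

# Placeholder 10-year annual re-bleed probabilities for an untreated
# occult aneurysm after presentation: front-loaded first year, geometric
# decline to a constant floor, constant tail thereafter.  The shape was
# calibrated once against the published base-case cost/QALY table (see
# docs/methods.md); these are NOT the supplementary cohort values, which
# are not shipped.
_REBLEED_PROBS = (
    0.58, 0.4872, 0.4092, 0.3438, 0.2888, 0.2426, 0.2038, 0.1712, 0.16, 0.16,
)


def default_rebleed_schedule() -> RebleedSchedule:
    """Packaged placeholder re-bleed schedule (front-loaded, declining)."""
    years = np.arange(1, len(_REBLEED_PROBS) + 1)
    return RebleedSchedule(years, np.array(_REBLEED_PROBS), tail="constant")


# ---------------------------------------------------------------------------
# Outcome-state transition matrix (matrix mode)
# ---------------------------------------------------------------------------

_STATE_NAMES = ("favorable", "unfavorable", "dead")


def load_outcome_matrix(path: str | Path) -> np.ndarray:
    """Load a from/to/prob CSV into a 3x3 outcome transition matrix.

    Rows and columns are ordered (favorable, unfavorable, dead);
    unlisted entries default to 0 and each row must sum to 1.
    """
    df = pd.read_csv(path, comment="#")
    if not {"from", "to", "prob"} <= set(df.columns):
        raise ConfigFormatError(f"{path}: transition matrix needs columns from,to,prob")
    m = np.zeros((3, 3))
    index = {name: i for i, name in enumerate(_STATE_NAMES)}
    for _, row in df.iterrows():
        try:
            i, j = index[str(row["from"]).strip()], index[str(row["to"]).strip()]
        except KeyError as e:
            raise ConfigFormatError(
                f"{path}: unknown state {e.args[0]!r}; expected one of {_STATE_NAMES}"
            ) from e
        m[i, j] = float(row["prob"])
    bad = np.abs(m.sum(axis=1) - 1.0) > 1e-9
    if bad.any():
        names = [n for n, b in zip(_STATE_NAMES, bad) if b]
        raise ConfigFormatError(f"{path}: rows {names} do not sum to 1")
    return m


def outcome_matrix_to_csv(m: np.ndarray, path: str | Path, header: str | None = None) -> Path:
    rows = [
        {"from": _STATE_NAMES[i], "to": _STATE_NAMES[j], "prob": m[i, j]}
        for i in range(3)
        for j in range(3)
        if m[i, j] != 0.0
    ]
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    return path


def default_outcome_matrix(p: ParameterSet | None = None) -> np.ndarray:
    """Default-mode matrix implied by ``state_mortality`` (no fav<->unfav moves)."""
    p = p or default_parameters()
    mf, mu = p.state_mortality[0], p.state_mortality[1]
    return np.array([[1 - mf, 0.0, mf], [0.0, 1 - mu, mu], [0.0, 0.0, 1.0]])


def default_transition_fixture(
    life_table: LifeTable | None = None,
    rebleed_schedule: RebleedSchedule | None = None,
    outcome_matrix: np.ndarray | None = None,
) -> TransitionModel:
    """The packaged :class:`TransitionModel` (fixture life table and schedule).

    In default mode (``outcome_matrix=None``) outcome-state movement
    comes from ``ParameterSet.state_mortality`` at evaluation time.
    """
    return TransitionModel(
        life_table=life_table or default_life_table(),
        rebleed_schedule=rebleed_schedule or default_rebleed_schedule(),
        outcome_matrix=outcome_matrix,
    )


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimate of one strategy's expected cost and QALYs."""

    strategy: str
    n: int
    expected_cost: float
    expected_qaly: float
    se_cost: float
    se_qaly: float


def _sample_categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    """Vectorized categorical draw: n indices from a probability row."""
    edges = np.cumsum(probs)
    return np.searchsorted(edges, rng.random(n) * edges[-1], side="right").clip(
        0, len(probs) - 1
    )


def microsim_oracle(
    arm: str,
    p: ParameterSet,
    tm: TransitionModel,
    n_individuals: int,
    seed: int,
) -> MicrosimResult:
    """Individual-level Monte-Carlo estimate of a strategy's totals.

    Samples every decision-tree branch (aneurysm presence, test result,
    outcome split) and every yearly transition for ``n_individuals``
    independent trajectories, accruing discounted costs and QALYs under
    the cohort engine's accounting conventions.  Uses its own RNG
    stream, independent of the PSA sampler.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_individuals

    prev = p.prevalence_aneurysm
    no_an = np.asarray(p.outcome_no_aneurysm, dtype=float)
    elective = np.asarray(p.outcome_elective, dtype=float)
    emergency_cost, rebleed_outcome = rebleed_resolution(p)
    outcome_states = np.array(
        [HealthState.FAVORABLE, HealthState.UNFAVORABLE, HealthState.DEAD], dtype=int
    )

    cost = np.zeros(n)
    state = np.empty(n, dtype=int)
    has_aneurysm = rng.random(n) < prev

    if arm == "no_repeat":
        state[has_aneurysm] = HealthState.AT_RISK
        idx = ~has_aneurysm
        state[idx] = outcome_states[_sample_categorical(rng, no_an, int(idx.sum()))]
    elif arm == "repeat_cta":
        cost += p.los_days * p.cost_hospital_day + p.cost_cta
        test_pos = np.where(
            has_aneurysm,
            rng.random(n) < p.cta_sensitivity,
            rng.random(n) < 1.0 - p.cta_specificity,
        )
        tp = has_aneurysm & test_pos
        fn = has_aneurysm & ~test_pos
        fp = ~has_aneurysm & test_pos
        tn = ~has_aneurysm & ~test_pos
        cost[tp | fp] += p.cost_dsa
        cost[tp] += elective_treatment_cost(p)
        state[fn] = HealthState.AT_RISK
        state[tp] = outcome_states[_sample_categorical(rng, elective, int(tp.sum()))]
        neg = tn | fp
        state[neg] = outcome_states[_sample_categorical(rng, no_an, int(neg.sum()))]
    else:
        raise ValueError(f"unknown arm {arm!r}")

    utilities = np.array(
        [p.utility_no_rebleed, p.utility_favorable, p.utility_unfavorable, p.utility_dead]
    )
    annual_costs = np.array([0.0, 0.0, p.cost_nursing_unfavorable_annual, 0.0])
    rows = tm.outcome_rows(p)
    dq = 1.0 / (1.0 + p.discount_qaly)
    dc = 1.0 / (1.0 + p.discount_cost)
    n_cycles = int(np.ceil(p.stop_age - p.start_age))

    qaly = np.zeros(n)
    for t in range(1, n_cycles + 1):
        age = p.start_age + t - 1
        qx = 1.0 if t == n_cycles else tm.life_table.qx_at(age)
        r = tm.rebleed_schedule.prob_at(t)

        prev_state = state
        new = prev_state.copy()
        tunnel = np.zeros(n, dtype=bool)  # same-cycle re-bleed survivors

        ar = prev_state == HealthState.AT_RISK
        n_ar = int(ar.sum())
        if n_ar:
            rebleeds = rng.random(n_ar) < r
            dies_bg = rng.random(n_ar) < qx
            dest = np.full(n_ar, HealthState.AT_RISK, dtype=int)
            dest[~rebleeds & dies_bg] = HealthState.DEAD
            if rebleeds.any():
                dest[rebleeds] = outcome_states[
                    _sample_categorical(rng, rebleed_outcome, int(rebleeds.sum()))
                ]
                idx_reb = np.flatnonzero(ar)[rebleeds]
                cost[idx_reb] += dc**t * emergency_cost
                if not p.rebleed_reward_same_cycle:
                    tunnel[idx_reb[dest[rebleeds] != HealthState.DEAD]] = True
            new[ar] = dest

        for i, s in enumerate((HealthState.FAVORABLE, HealthState.UNFAVORABLE)):
            mask = prev_state == s
            m = int(mask.sum())
            if not m:
                continue
            living = rows[i, :2] * (1.0 - qx)
            probs = np.array([living[0], living[1], 1.0 - living.sum()])
            new[mask] = np.array(
                [HealthState.FAVORABLE, HealthState.UNFAVORABLE, HealthState.DEAD]
            )[_sample_categorical(rng, probs, m)]

        u_new = utilities[new]
        c_new = annual_costs[new]
        u_new[tunnel] = 0.0
        c_new[tunnel] = 0.0
        if p.half_cycle_correction:
            u_cycle = 0.5 * (utilities[prev_state] + u_new)
            c_cycle = 0.5 * (annual_costs[prev_state] + c_new)
        else:
            u_cycle = u_new
            c_cycle = c_new
        qaly += dq**t * u_cycle
        cost += dc**t * c_cycle
        state = new
        if np.all(state == HealthState.DEAD):
            break

    return MicrosimResult(
        strategy=arm,
        n=n,
        expected_cost=float(cost.mean()),
        expected_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
    )


# ---------------------------------------------------------------------------
# Fixture file emission
# ---------------------------------------------------------------------------


def write_fixture_files(directory: str | Path) -> dict[str, Path]:
    """Write the four packaged input files into ``directory``.

    Emits ``defaults.yaml``, ``life_table.csv``, ``rebleed_schedule.csv``
    and ``transitions.csv``; idempotent (identical bytes on re-run).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create fixture directory {directory}: {e}") from e

    paths = {}
    paths["defaults"] = write_parameters(
        default_parameters(),
        directory / "defaults.yaml",
        header="sahcea base-case parameters (published point estimates)",
    )
    paths["life_table"] = default_life_table().to_csv(
        directory / "life_table.csv", header=FIXTURE_HEADER
    )
    paths["rebleed_schedule"] = default_rebleed_schedule().to_csv(
        directory / "rebleed_schedule.csv", header=FIXTURE_HEADER
    )
    paths["transitions"] = outcome_matrix_to_csv(
        default_outcome_matrix(),
        directory / "transitions.csv",
        header=FIXTURE_HEADER + "\nderived from the base-case state_mortality values",
    )
    return paths
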