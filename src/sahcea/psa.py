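"""Probabilistic sensitivity analysis and cost-effectiveness
acceptability curves.

Each Monte-Carlo iteration draws one parameter set from the per-field
distributions (independently across fields, jointly within each
Dirichlet simplex), evaluates both strategies on the same draw, and
records the (cost, QALY) pair per strategy.  The draws are consumed
from a single seeded generator in a fixed field order, so a given seed
reproduces the result bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ARMS, TransitionModel, evaluate_strategy
from .parameters import DistSpec, ParameterSet

__all__ = [
    "PSAResult",
    "CEACCurve",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "psa_summary",
    "default_wtp_grid",
]

# Documented draw order: one generator stream, fields consumed in this
# sequence, so results are stable across runs and platforms.
_FIELD_ORDER = (
    "prevalence_aneurysm",
    "outcome_rebleed",
    "outcome_elective",
    "outcome_no_aneurysm_favorable",
    "outcome_no_aneurysm_unfavorable",
    "state_mortality",
    "cta_sensitivity",
    "cta_specificity",
    "cost_cta",
    "cost_dsa",
    "cost_hospital_stay_block",
    "cost_elective_coiling",
    "cost_elective_clipping",
    "cost_emergency_coiling",
    "cost_emergency_clipping",
    "cost_nursing_unfavorable_annual",
    "utility_favorable",
    "utility_unfavorable",
)


def default_wtp_grid() -> np.ndarray:
    """£0 to £50,000 per QALY in £1,000 steps (covers the NICE band)."""
    return np.arange(0, 50_001, 1_000, dtype=float)


def _draw(spec: DistSpec, rng: np.random.Generator):
    if spec.family == "point":
        return spec.params[0]
    if spec.family == "beta":
        return float(rng.beta(*spec.params))
    if spec.family == "gamma":
        shape, rate = spec.params
        return float(rng.gamma(shape, 1.0 / rate))
    return tuple(float(x) for x in rng.dirichlet(spec.params))


def sample_parameter_set(p: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: every field with a ``DistSpec`` is resampled.

    Fields without a spec keep their base value.  The 7-day hospital
    stay is drawn as a block and divided by the length of stay; the two
    no-aneurysm outcome probabilities are drawn as independent Betas
    and rescaled in the (vanishingly rare) case their sum exceeds 1.
    """
    kwargs = {}
    for name in _FIELD_ORDER:
        spec = p.dist.get(name)
        if spec is None:
            continue
        value = _draw(spec, rng)
        if name == "cost_hospital_stay_block":
            kwargs["cost_hospital_day"] = value / max(p.los_days, 1)
        else:
            kwargs[name] = value
    f = kwargs.get("outcome_no_aneurysm_favorable", p.outcome_no_aneurysm_favorable)
    u = kwargs.get("outcome_no_aneurysm_unfavorable", p.outcome_no_aneurysm_unfavorable)
    if f + u > 1.0:
        kwargs["outcome_no_aneurysm_favorable"] = f / (f + u)
        kwargs["outcome_no_aneurysm_unfavorable"] = u / (f + u)
    return replace(p, **kwargs)


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration (cost, QALY) pairs for both strategies."""

    n_iterations: int
    seed: int
    strategies: tuple[str, str]
    costs: np.ndarray  # (n, 2), column order = strategies
    qalys: np.ndarray  # (n, 2)

    def scatter_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iteration": np.arange(1, self.n_iterations + 1)})
        for j, s in enumerate(self.strategies):
            df[f"cost_{s}"] = self.costs[:, j]
            df[f"qaly_{s}"] = self.qalys[:, j]
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.scatter_frame().to_csv(path, index=False)
        return path


def run_psa(
    p: ParameterSet, tm: TransitionModel, n: int, seed: int
) -> PSAResult:
    """``n`` Monte-Carlo iterations; the same draw feeds both strategies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    costs = np.empty((n, 2))
    qalys = np.empty((n, 2))
    for i in range(n):
        draw = sample_parameter_set(p, rng)
        try:
            for j, arm in enumerate(ARMS):
                res = evaluate_strategy(arm, draw, tm)
                costs[i, j] = res.expected_cost
                qalys[i, j] = res.expected_qaly
        except Exception as e:
            digest = {
                k: getattr(draw, k)
                for k in ("prevalence_aneurysm", "cta_sensitivity", "state_mortality")
            }
            raise RuntimeError(f"PSA draw {i} failed ({digest}): {e}") from e
    return PSAResult(
        n_iterations=n, seed=seed, strategies=ARMS, costs=costs, qalys=qalys
    )


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is cost-effective across a WTP grid."""

    wtp: np.ndarray
    probability: np.ndarray  # (len(wtp), 2), columns follow PSAResult.strategies
    strategies: tuple[str, str]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wtp": self.wtp})
        for j, s in enumerate(self.strategies):
            df[f"p_{s}"] = self.probability[:, j]
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame().to_csv(path, index=False)
        return path

    def at(self, wtp: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.wtp - wtp)))
        return self.probability[i]


def ceac(r: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Fraction of iterations in which each strategy has the larger NMB.

    Ties (equal net monetary benefit) are split equally, so the two
    probabilities sum to 1 at every threshold.
    """
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    prob = np.empty((grid.size, 2))
    for i, w in enumerate(grid):
        nmb = w * r.qalys - r.costs
        diff = nmb[:, 1] - nmb[:, 0]
        p1 = float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0))
        prob[i] = (1.0 - p1, p1)
    return CEACCurve(wtp=grid, probability=prob, strategies=r.strategies)


def psa_summary(r: PSAResult, wtp: float = 20_000.0) -> dict:
    """Single-threshold CEAC read-out plus means and 95% credible intervals."""
    point = ceac(r, np.array([wtp]))
    out = {
        "n_iterations": r.n_iterations,
        "seed": r.seed,
        "wtp": wtp,
        "probability_cost_effective": {
            s: float(point.probability[0, j]) for j, s in enumerate(r.strategies)
        },
    }
    for j, s in enumerate(r.strategies):
        lo_c, hi_c = np.percentile(r.costs[:, j], [2.5, 97.5])
        lo_q, hi_q = np.percentile(r.qalys[:, j], [2.5, 97.5])
        out[s] = {
            "mean_cost": float(r.costs[:, j].mean()),
            "cost_ci95": [float(lo_c), float(hi_c)],
            "mean_qaly": float(r.qalys[:, j].mean()),
            "qaly_ci95": [float(lo_q), float(hi_q)],
        }
    out["mean_delta_cost"] = float((r.costs[:, 1] - r.costs[:, 0]).mean())
    out["mean_delta_qaly"] = float((r.qalys[:, 1] - r.qalys[:, 0]).mean())
    return out


def summary_to_json(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2))
    return path
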