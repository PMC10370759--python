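"""Deterministic sensitivity analysis: one-way sweeps, tornado ordering,
and willingness-to-pay threshold search.

Every sweepable quantity is registered by name with its valid domain,
its published (or ±25% fallback) one-way range, and a pure applier that
returns a modified :class:`ParameterSet`.  Components of an outcome
simplex are swept with complementary renormalization: the swept share
is set and the remaining shares are rescaled proportionally so the row
stays on the simplex.  Sweeping ``start_age`` shifts both the
life-table lookup and the remaining horizon, which is the only
mechanism through which age affects the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CEComparison,
    TransitionModel,
    evaluate_strategy,
    incremental_analysis,
)
from .parameters import ParameterSet

__all__ = [
    "SweepParameter",
    "SweepResult",
    "TornadoBar",
    "ThresholdResult",
    "registry",
    "one_way",
    "tornado",
    "threshold_search",
]


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepParameter:
    """A registered scalar knob for deterministic sensitivity analysis."""

    name: str
    bounds: tuple[float, float]
    default_range: Callable[[ParameterSet], tuple[float, float]]
    get: Callable[[ParameterSet], float]
    apply: Callable[[ParameterSet, float], ParameterSet]


def _scalar(name: str, bounds, rng) -> SweepParameter:
    if callable(rng):
        default_range = rng
    else:
        default_range = lambda p, rng=rng: rng
    return SweepParameter(
        name=name,
        bounds=bounds,
        default_range=default_range,
        get=lambda p: float(getattr(p, name)),
        apply=lambda p, v: replace(p, **{name: v}),
    )


def _pm25(name: str, bounds=(0.0, np.inf)) -> SweepParameter:
    """±25% of the current base value (the fallback one-way range)."""
    return _scalar(
        name,
        bounds,
        lambda p: (0.75 * getattr(p, name), 1.25 * getattr(p, name)),
    )


def _set_simplex_component(simplex: Sequence[float], i: int, v: float) -> tuple:
    """Set component ``i`` to ``v``, rescaling the others onto 1 - v."""
    s = np.asarray(simplex, dtype=float)
    if v == s[i]:  # keep base-case evaluations bit-identical
        return tuple(s)
    rest = np.delete(s, i)
    total = rest.sum()
    if total > 0:
        rest = rest * (1.0 - v) / total
    else:
        rest = np.full(rest.size, (1.0 - v) / rest.size)
    out = np.insert(rest, i, v)
    return tuple(out)


def _simplex(field: str, label: str, i: int) -> SweepParameter:
    name = f"{field}_{label}"

    def get(p):
        return float(getattr(p, field)[i])

    def apply(p, v):
        return replace(p, **{field: _set_simplex_component(getattr(p, field), i, v)})

    def default_range(p):
        base = get(p)
        return (max(0.0, 0.75 * base), min(1.0, 1.25 * base))

    return SweepParameter(name, (0.0, 1.0), default_range, get, apply)


def registry() -> dict[str, SweepParameter]:
    """All registered sweep parameters, keyed by name.

    Published one-way ranges are used where they exist (age 50-80,
    prevalence 5-35%, CTA sensitivity 20-99% and specificity 20-100%,
    the no-aneurysm outcome shares, and the three utilities); all cost
    parameters and simplex shares default to ±25% of base.
    """
    params = [
        _scalar("start_age", (18.0, 99.0), (50.0, 80.0)),
        _scalar("prevalence_aneurysm", (0.0, 1.0), (0.05, 0.35)),
        _scalar("cta_sensitivity", (0.0, 1.0), (0.20, 0.99)),
        _scalar("cta_specificity", (0.0, 1.0), (0.20, 1.00)),
        _scalar("outcome_no_aneurysm_favorable", (0.0, 1.0), (0.8030, 0.9160)),
        _scalar("outcome_no_aneurysm_unfavorable", (0.0, 1.0), (0.0791, 0.0793)),
        _pm25("cost_cta"),
        _pm25("cost_dsa"),
        _pm25("cost_hospital_day"),
        _pm25("cost_elective_coiling"),
        _pm25("cost_elective_clipping"),
        _pm25("cost_emergency_coiling"),
        _pm25("cost_emergency_clipping"),
        _pm25("cost_nursing_unfavorable_annual"),
        _scalar("utility_favorable", (0.0, 1.0), (0.60, 1.00)),
        _scalar("utility_unfavorable", (0.0, 1.0), (0.11, 0.71)),
        _scalar("utility_no_rebleed", (0.0, 1.0), (0.41, 0.72)),
        _scalar("utility_dead", (0.0, 1.0), (0.0, 0.0)),  # pinned at 0
        _scalar("coiling_fraction", (0.0, 1.0), (0.0, 1.0)),
    ]
    for field in ("outcome_rebleed", "outcome_elective"):
        for i, label in enumerate(("favorable", "unfavorable", "dead")):
            params.append(_simplex(field, label, i))
    for i, label in enumerate(("favorable", "unfavorable")):
        params.append(_simplex("state_mortality", label, i))
    return {sp.name: sp for sp in params}


def _lookup(name: str) -> SweepParameter:
    reg = registry()
    if name not in reg:
        raise KeyError(
            f"unknown sweep parameter {name!r}; registered names: {sorted(reg)}"
        )
    return reg[name]


# ---------------------------------------------------------------------------
# One-way sweeps
# ---------------------------------------------------------------------------


def _evaluate_pair(p: ParameterSet, tm: TransitionModel, wtp: float) -> CEComparison:
    ref = evaluate_strategy("no_repeat", p, tm)
    comp = evaluate_strategy("repeat_cta", p, tm)
    return incremental_analysis(ref, comp, wtp=wtp)


@dataclass
class SweepResult:
    """Grid evaluation of both strategies along one parameter."""

    parameter: str
    records: pd.DataFrame  # value, costs/QALYs per strategy, deltas, icer, label

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False)
        return path


def one_way(
    param: str,
    low: float,
    high: float,
    n_points: int,
    p: ParameterSet,
    tm: TransitionModel,
    wtp: float = 20_000.0,
) -> SweepResult:
    """Evaluate both strategies along a grid of one parameter's values.

    All other parameters stay at base case.  ``low == high`` is allowed
    as a degenerate sweep (all records identical).
    """
    if low > high:
        raise ValueError(f"low {low} must not exceed high {high}")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    sp = _lookup(param)
    lo_b, hi_b = sp.bounds
    if low < lo_b or high > hi_b:
        raise ValueError(
            f"range [{low}, {high}] outside {param} domain [{lo_b}, {hi_b}]"
        )
    values = np.linspace(low, high, n_points)
    rows = []
    for v in values:
        cmp_ = _evaluate_pair(sp.apply(p, float(v)), tm, wtp)
        rows.append(
            {
                "parameter": param,
                "value": float(v),
                "cost_no_repeat": cmp_.reference.expected_cost,
                "qaly_no_repeat": cmp_.reference.expected_qaly,
                "cost_repeat_cta": cmp_.comparator.expected_cost,
                "qaly_repeat_cta": cmp_.comparator.expected_qaly,
                "delta_cost": cmp_.delta_cost,
                "delta_qaly": cmp_.delta_qaly,
                "icer": cmp_.icer if cmp_.label == "icer" else np.nan,
                "label": cmp_.label,
            }
        )
    return SweepResult(parameter=param, records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Tornado
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoBar:
    """ICER swing of one parameter between its range endpoints."""

    parameter: str
    low: float
    high: float
    icer_low: float      # raw delta_cost/delta_qaly at the low end (nan if undefined)
    icer_high: float
    label_low: str
    label_high: str
    span: float          # |icer_high - icer_low|


def _raw_icer(cmp_: CEComparison) -> float:
    return np.nan if cmp_.icer is None else float(cmp_.icer)


def tornado(
    params_with_ranges: Iterable[tuple[str, float, float]] | dict[str, tuple[float, float]],
    p: ParameterSet,
    tm: TransitionModel,
    wtp: float = 20_000.0,
) -> list[TornadoBar]:
    """One bar per parameter from endpoint evaluations, widest first.

    A dominant/dominated endpoint keeps its raw cost/QALY ratio for the
    span computation but carries its dominance label, so reports can
    suppress the number while the ordering stays defined.  Bars whose
    span is undefined (a zero incremental-QALY endpoint) sort last.
    """
    if isinstance(params_with_ranges, dict):
        items = [(k, lo, hi) for k, (lo, hi) in params_with_ranges.items()]
    else:
        items = list(params_with_ranges)
    if not items:
        raise ValueError("tornado needs at least one parameter/range pair")
    bars = []
    for name, lo, hi in items:
        sp = _lookup(name)
        cmp_lo = _evaluate_pair(sp.apply(p, float(lo)), tm, wtp)
        cmp_hi = _evaluate_pair(sp.apply(p, float(hi)), tm, wtp)
        icer_lo, icer_hi = _raw_icer(cmp_lo), _raw_icer(cmp_hi)
        bars.append(
            TornadoBar(
                parameter=name,
                low=float(lo),
                high=float(hi),
                icer_low=icer_lo,
                icer_high=icer_hi,
                label_low=cmp_lo.label,
                label_high=cmp_hi.label,
                span=abs(icer_hi - icer_lo),
            )
        )
    return sorted(bars, key=lambda b: (np.isnan(b.span), -b.span))


def tornado_frame(bars: Sequence[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in bars])


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a WTP-crossing search along one parameter."""

    parameter: str
    wtp: float
    crossing: Optional[float]       # None when no crossing exists in the bracket
    multiple: bool                  # more than one sign change on the scan grid
    bracket: tuple[float, float]
    n_evaluations: int
    cost_effective_above: Optional[bool]  # comparator cost-effective for values above the crossing

    @property
    def found(self) -> bool:
        return self.crossing is not None


def threshold_search(
    param: str,
    wtp: float,
    bracket: tuple[float, float],
    p: ParameterSet,
    tm: TransitionModel,
    tol: float = 1e-4,
    n_scan: int = 33,
) -> ThresholdResult:
    """Find where the comparator stops being cost-effective at ``wtp``.

    Bisects ``g(x) = delta_cost(x) - wtp * delta_qaly(x)`` (the negated
    net monetary benefit), whose root coincides with ICER = wtp whenever
    incremental QALYs are nonzero, and whose sign encodes dominance
    consistently (dominant => g < 0, dominated => g > 0).  A coarse scan
    locates sign changes first; with several, the crossing nearest the
    base-case value is refined and flagged.  The bisection stops when
    the interval shrinks below ``tol`` relative to the parameter scale.
    """
    sp = _lookup(param)
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo >= hi:
        raise ValueError(f"bracket [{lo}, {hi}] must be increasing")
    lo_b, hi_b = sp.bounds
    if lo < lo_b or hi > hi_b:
        raise ValueError(f"bracket [{lo}, {hi}] outside {param} domain [{lo_b}, {hi_b}]")

    evaluations = 0

    def g(x: float) -> float:
        nonlocal evaluations
        evaluations += 1
        cmp_ = _evaluate_pair(sp.apply(p, x), tm, wtp)
        return cmp_.delta_cost - wtp * cmp_.delta_qaly

    xs = np.linspace(lo, hi, n_scan)
    gs = np.array([g(x) for x in xs])
    signs = np.sign(gs)
    flips = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    exact = np.flatnonzero(gs == 0.0)

    if flips.size == 0 and exact.size == 0:
        return ThresholdResult(param, wtp, None, False, (lo, hi), evaluations, None)

    base = sp.get(p)
    multiple = (flips.size + exact.size) > 1
    if exact.size and (
        flips.size == 0
        or min(abs(xs[exact] - base)) <= min(abs(0.5 * (xs[flips] + xs[flips + 1]) - base))
    ):
        i = exact[np.argmin(abs(xs[exact] - base))]
        crossing = float(xs[i])
        g_above = g(min(hi, crossing + (hi - lo) / (n_scan - 1) / 2))
        return ThresholdResult(
            param, wtp, crossing, multiple, (lo, hi), evaluations, bool(g_above < 0)
        )

    mids = 0.5 * (xs[flips] + xs[flips + 1])
    k = flips[np.argmin(abs(mids - base))]
    a, b = float(xs[k]), float(xs[k + 1])
    ga, gb = gs[k], gs[k + 1]
    width_tol = tol * max(abs(lo), abs(hi), 1.0)
    while b - a > width_tol:
        m = 0.5 * (a + b)
        gm = g(m)
        if gm == 0.0:
            a = b = m
            break
        if np.sign(gm) == np.sign(ga):
            a, ga = m, gm
        else:
            b, gb = m, gm
    crossing = 0.5 * (a + b)
    return ThresholdResult(
        param, wtp, float(crossing), multiple, (lo, hi), evaluations, bool(gb < 0)
    )
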