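"""Model parameters, their uncertainty distributions, and tabular inputs.

Every quantity the cost-effectiveness model consumes lives on a single
:class:`ParameterSet`: clinical probabilities, diagnostic-test accuracy,
unit costs (GBP, 2020), health-state utilities and discount rates, plus
the structural settings (cohort start age, horizon, half-cycle flag).
Probabilistic sensitivity analysis draws from per-parameter
:class:`DistSpec` entries (Beta for probabilities and utilities, Gamma
for costs, Dirichlet for outcome simplexes).

Two tabular inputs are defined here and synthesized by
:mod:`sahcea.fixtures`: an age-indexed background-mortality life table
and a years-since-presentation annual re-bleed probability schedule.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DistSpec",
    "ParameterSet",
    "LifeTable",
    "RebleedSchedule",
    "ConfigFormatError",
    "ParameterValidationError",
    "load_parameters",
    "write_parameters",
    "default_parameters",
    "validate",
    "derive_gamma_spec",
    "distribution_mean",
    "audit_distributions",
]

SIMPLEX_TOL = 1e-9


class ConfigFormatError(ValueError):
    """A parameter file could not be parsed as a flat YAML mapping."""


class ParameterValidationError(ValueError):
    """One or more parameter invariants are violated.

    Carries the full list of violations, not just the first.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid parameters:\n  " + "\n  ".join(self.violations)
        )


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------

_FAMILIES = ("beta", "gamma", "dirichlet", "point")


@dataclass(frozen=True)
class DistSpec:
    """A parametric sampling distribution for one model parameter.

    family
        One of ``beta`` (alpha, beta), ``gamma`` (shape alpha, *rate*
        lambda), ``dirichlet`` (concentration vector, length >= 2) or
        ``point`` (a single degenerate value).
    params
        The family-specific positive reals, in the order above.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(x) for x in self.params))
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "point":
            if len(self.params) != 1:
                raise ValueError("point spec takes exactly one value")
            return
        if any(x <= 0 for x in self.params):
            raise ValueError(f"{self.family} parameters must be positive: {self.params}")
        n_expected = {"beta": 2, "gamma": 2}.get(self.family)
        if n_expected is not None and len(self.params) != n_expected:
            raise ValueError(f"{self.family} spec takes {n_expected} parameters")
        if self.family == "dirichlet" and len(self.params) < 2:
            raise ValueError("dirichlet concentration vector needs length >= 2")


def derive_gamma_spec(mean: float, sd_divisor: float = 12.0) -> DistSpec:
    """Gamma spec with the given mean and sd = mean / ``sd_divisor``.

    With shape ``alpha = sd_divisor**2`` and rate ``lambda = alpha/mean``
    the Gamma mean is exactly ``mean`` and its coefficient of variation is
    ``1/sd_divisor``.  The default divisor of 12 (shape 144) matches the
    convention used for every cost parameter's uncertainty distribution.
    """
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if sd_divisor <= 0:
        raise ValueError(f"sd_divisor must be positive, got {sd_divisor}")
    shape = sd_divisor**2
    return DistSpec("gamma", (shape, shape / mean))


def distribution_mean(d: DistSpec):
    """Analytic mean of a :class:`DistSpec` (a vector for dirichlet)."""
    a = d.params
    if d.family == "beta":
        return a[0] / (a[0] + a[1])
    if d.family == "gamma":
        return a[0] / a[1]
    if d.family == "dirichlet":
        v = np.asarray(a, dtype=float)
        return v / v.sum()
    return a[0]  # point


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


def _default_dist_specs() -> dict[str, DistSpec]:
    """The default PSA distribution for every sampled parameter.

    Costs use the shape-144 Gamma convention (:func:`derive_gamma_spec`).
    The 7-day pre-imaging hospital stay is sampled as one block
    (``cost_hospital_stay_block``); the per-day cost is the block divided
    by the length of stay.
    """
    return {
        "prevalence_aneurysm": DistSpec("beta", (5.26, 21.05)),
        "outcome_rebleed": DistSpec("dirichlet", (0.0752, 0.3948, 0.4700)),
        "outcome_elective": DistSpec("dirichlet", (0.51, 0.34, 0.15)),
        "outcome_no_aneurysm_favorable": DistSpec("beta", (1740.84, 258.29)),
        "outcome_no_aneurysm_unfavorable": DistSpec("beta", (9.95, 1246.21)),
        "state_mortality": DistSpec("dirichlet", (0.1067, 0.7778, 0.1155)),
        "cta_sensitivity": DistSpec("beta", (737.51, 15.05)),
        "cta_specificity": DistSpec("beta", (247.50, 3.76)),
        "cost_cta": derive_gamma_spec(331.00),
        "cost_dsa": derive_gamma_spec(1_919.00),
        "cost_hospital_stay_block": derive_gamma_spec(380.75 * 7),
        "cost_elective_coiling": derive_gamma_spec(14_030.80),
        "cost_elective_clipping": derive_gamma_spec(13_212.19),
        "cost_emergency_coiling": derive_gamma_spec(19_983.87),
        "cost_emergency_clipping": derive_gamma_spec(20_275.02),
        "cost_nursing_unfavorable_annual": derive_gamma_spec(84_346.39),
        "utility_favorable": DistSpec("beta", (20.82, 6.05)),
        "utility_unfavorable": DistSpec("beta", (3.82, 5.50)),
    }


@dataclass(frozen=True)
class ParameterSet:
    """Single source of truth for one model run.

    Base-case values are the published point estimates; ``dist`` maps
    parameter names to the distributions used by probabilistic
    sensitivity analysis.  3-simplexes are ``(favorable, unfavorable,
    dead)`` tuples, except ``state_mortality`` whose elements are read as
    the annual death probability from the favorable and unfavorable
    states, with a residual third element kept only so the Dirichlet
    draw is well-formed.
    """

    # clinical
    start_age: float = 55
    prevalence_aneurysm: float = 0.173
    # favorable/unfavorable shares as published; death = remainder (the
    # published concentration triple (0.0752, 0.3948, 0.4700) is kept
    # verbatim for the PSA draw but does not itself sum to 1)
    outcome_rebleed: tuple[float, float, float] = (0.0752, 0.3948, 0.5300)
    outcome_elective: tuple[float, float, float] = (0.51, 0.34, 0.15)
    outcome_no_aneurysm_favorable: float = 0.8708
    outcome_no_aneurysm_unfavorable: float = 0.0792
    state_mortality: tuple[float, float, float] = (0.1067, 0.7778, 0.1155)
    # diagnostic accuracy
    cta_sensitivity: float = 0.98
    cta_specificity: float = 1.00
    dsa_specificity: float = 1.00
    # costs (GBP, 2020)
    cost_cta: float = 331.00
    cost_dsa: float = 1_919.00
    cost_hospital_day: float = 380.75
    los_days: int = 7
    cost_elective_coiling: float = 14_030.80
    cost_elective_clipping: float = 13_212.19
    cost_emergency_coiling: float = 19_983.87
    cost_emergency_clipping: float = 20_275.02
    coiling_fraction: float = 0.5
    cost_nursing_unfavorable_annual: float = 84_346.39
    # utilities
    utility_favorable: float = 0.87
    utility_unfavorable: float = 0.44
    utility_dead: float = 0.0
    utility_no_rebleed: float = 0.60
    # discounting
    discount_qaly: float = 0.035
    discount_cost: float = 0.035
    # structural settings
    stop_age: float = 100
    half_cycle_correction: bool = False
    # when True, re-bleed survivors earn their outcome state's reward in
    # the cycle of the re-bleed itself; when False (default) rewards
    # start the following cycle (the emergency cost always lands in the
    # re-bleed cycle)
    rebleed_reward_same_cycle: bool = False
    # PSA distributions
    dist: Mapping[str, DistSpec] = field(default_factory=_default_dist_specs)

    @property
    def outcome_no_aneurysm(self) -> tuple[float, float, float]:
        """(favorable, unfavorable, dead) split for patients without an aneurysm."""
        f, u = self.outcome_no_aneurysm_favorable, self.outcome_no_aneurysm_unfavorable
        return (f, u, 1.0 - f - u)


# Fields accepted in a YAML config / written by write_parameters.
_CONFIG_FIELDS = tuple(
    f.name for f in dataclasses.fields(ParameterSet) if f.name != "dist"
)
_SIMPLEX_FIELDS = ("outcome_rebleed", "outcome_elective", "state_mortality")


def default_parameters() -> ParameterSet:
    """The packaged base-case parameter set."""
    return ParameterSet()


def validate(p: ParameterSet) -> list[str]:
    """Return every invariant violation (empty list means valid)."""
    v: list[str] = []

    def prob(name, value):
        if not (0.0 <= value <= 1.0):
            v.append(f"{name}: probability {value} outside [0, 1]")

    prob("prevalence_aneurysm", p.prevalence_aneurysm)
    prob("cta_sensitivity", p.cta_sensitivity)
    prob("cta_specificity", p.cta_specificity)
    prob("dsa_specificity", p.dsa_specificity)
    prob("coiling_fraction", p.coiling_fraction)
    prob("outcome_no_aneurysm_favorable", p.outcome_no_aneurysm_favorable)
    prob("outcome_no_aneurysm_unfavorable", p.outcome_no_aneurysm_unfavorable)
    if p.outcome_no_aneurysm_favorable + p.outcome_no_aneurysm_unfavorable > 1 + SIMPLEX_TOL:
        v.append("outcome_no_aneurysm: favorable + unfavorable exceeds 1")

    for name in _SIMPLEX_FIELDS:
        simplex = getattr(p, name)
        if len(simplex) != 3:
            v.append(f"{name}: expected 3 components, got {len(simplex)}")
            continue
        for i, x in enumerate(simplex):
            prob(f"{name}[{i}]", x)
        if abs(sum(simplex) - 1.0) > SIMPLEX_TOL:
            v.append(f"{name}: components sum to {sum(simplex)}, not 1")

    for name in (
        "cost_cta",
        "cost_dsa",
        "cost_hospital_day",
        "cost_elective_coiling",
        "cost_elective_clipping",
        "cost_emergency_coiling",
        "cost_emergency_clipping",
        "cost_nursing_unfavorable_annual",
    ):
        if getattr(p, name) < 0:
            v.append(f"{name}: cost {getattr(p, name)} is negative")

    for name in ("utility_favorable", "utility_unfavorable", "utility_dead", "utility_no_rebleed"):
        u = getattr(p, name)
        if not (0.0 <= u <= 1.0):
            v.append(f"{name}: utility {u} outside [0, 1]")

    for name in ("discount_qaly", "discount_cost"):
        r = getattr(p, name)
        if not (0.0 <= r <= 0.2):
            v.append(f"{name}: discount rate {r} outside [0, 0.2]")

    if p.los_days < 0 or int(p.los_days) != p.los_days:
        v.append(f"los_days: {p.los_days} is not a nonnegative integer")
    if not (0 <= p.start_age < p.stop_age):
        v.append(f"start_age {p.start_age} must lie in [0, stop_age={p.stop_age})")
    return v


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a flat YAML mapping.

    Keys are exactly the ``ParameterSet`` field names; absent keys fall
    back to the packaged base-case defaults; unknown keys are rejected.
    ``path=None`` returns the defaults.
    """
    if path is None:
        return default_parameters()
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise ConfigFormatError(f"cannot read parameter file {path}: {e}") from e
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigFormatError(f"cannot parse {path}{where}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigFormatError(f"{path}: expected a mapping of parameter names to values")

    unknown = sorted(set(raw) - set(_CONFIG_FIELDS))
    if unknown:
        raise ConfigFormatError(f"{path}: unknown parameter keys {unknown}")

    kwargs = {}
    for name, value in raw.items():
        if name in _SIMPLEX_FIELDS:
            value = tuple(float(x) for x in value)
        kwargs[name] = value
    p = replace(default_parameters(), **kwargs)
    violations = validate(p)
    if violations:
        raise ParameterValidationError(violations)
    return p


def write_parameters(p: ParameterSet, path: str | Path, header: str | None = None) -> Path:
    """Write ``p`` as a flat YAML mapping re-loadable by :func:`load_parameters`."""
    path = Path(path)
    data = {}
    for name in _CONFIG_FIELDS:
        value = getattr(p, name)
        if name in _SIMPLEX_FIELDS:
            value = [float(x) for x in value]
        data[name] = value
    buf = io.StringIO()
    if header:
        for line in header.splitlines():
            buf.write(f"# {line}\n")
    yaml.safe_dump(data, buf, sort_keys=False)
    path.write_text(buf.getvalue())
    return path


def audit_distributions(p: ParameterSet) -> pd.DataFrame:
    """Compare each PSA distribution's analytic mean with its base value.

    Returns a table (parameter, base_value, dist_mean, abs_diff,
    mismatch) rather than raising: the published uncertainty
    distributions are reproduced verbatim, and for a few parameters
    (aneurysm prevalence, utility of a favorable outcome, CTA
    specificity) their means are known not to match the base-case column.
    """
    rows = []
    for name, spec in p.dist.items():
        if name == "cost_hospital_stay_block":
            base = p.cost_hospital_day * p.los_days
        else:
            base = getattr(p, name)
        mean = distribution_mean(spec)
        base_arr = np.atleast_1d(np.asarray(base, dtype=float))
        mean_arr = np.atleast_1d(np.asarray(mean, dtype=float))
        diff = float(np.max(np.abs(base_arr - mean_arr)))
        rel = diff / max(float(np.max(np.abs(base_arr))), 1e-12)
        rows.append(
            {
                "parameter": name,
                "base_value": str(base) if isinstance(base, tuple) else f"{base:g}",
                "dist_mean": np.array2string(mean_arr, precision=4)
                if mean_arr.size > 1
                else f"{float(mean_arr[0]):.4g}",
                "abs_diff": diff,
                "rel_diff": rel,
                "mismatch": rel > 0.02,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause background mortality ``qx`` by integer age.

    Ages must be contiguous and the final age has ``qx = 1`` (closure),
    so lookups beyond the table are well defined.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("life table needs matching 1-d age and qx arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life table ages must be contiguous")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life table qx values must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("life table must close with qx = 1 at the final age")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def qx_at(self, age: float) -> float:
        """qx for the year of age containing ``age`` (clamped to the table)."""
        i = int(np.floor(age)) - int(self.ages[0])
        i = min(max(i, 0), self.ages.size - 1)
        return float(self.qx[i])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        if not {"age", "qx"} <= set(df.columns):
            raise ConfigFormatError(f"{path}: life table needs columns age,qx")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_csv(self, path: str | Path, header: str | None = None) -> Path:
        return _write_csv(
            pd.DataFrame({"age": self.ages, "qx": self.qx}), path, header
        )


@dataclass(frozen=True)
class RebleedSchedule:
    """Annual re-bleed probability by year since presentation (1-based).

    ``tail`` controls behaviour past the last tabulated year:
    ``"constant"`` repeats the final probability; ``"zero"`` assumes no
    further re-bleeding risk.
    """

    years: np.ndarray
    probs: np.ndarray
    tail: str = "constant"

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        if years.ndim != 1 or years.shape != probs.shape or years.size == 0:
            raise ValueError("re-bleed schedule needs matching 1-d year and prob arrays")
        if years[0] != 1 or not np.all(np.diff(years) == 1):
            raise ValueError("re-bleed schedule years must run 1, 2, ... contiguously")
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("re-bleed probabilities must lie in [0, 1]")
        if self.tail not in ("constant", "zero"):
            raise ValueError(f"unknown tail rule {self.tail!r}")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "probs", probs)

    def prob_at(self, year: int) -> float:
        if year < 1:
            raise ValueError(f"year since presentation must be >= 1, got {year}")
        if year <= self.years[-1]:
            return float(self.probs[year - 1])
        return float(self.probs[-1]) if self.tail == "constant" else 0.0

    @classmethod
    def from_csv(cls, path: str | Path, tail: str = "constant") -> "RebleedSchedule":
        df = pd.read_csv(path, comment="#")
        if not {"year", "prob"} <= set(df.columns):
            raise ConfigFormatError(f"{path}: re-bleed schedule needs columns year,prob")
        df = df.sort_values("year")
        return cls(df["year"].to_numpy(), df["prob"].to_numpy(), tail=tail)

    def to_csv(self, path: str | Path, header: str | None = None) -> Path:
        return _write_csv(
            pd.DataFrame({"year": self.years, "prob": self.probs}), path, header
        )


def _write_csv(df: pd.DataFrame, path: str | Path, header: str | None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    return path
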