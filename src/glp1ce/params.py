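"""Model parameter space: uncertainty distributions, tables, and joint PSA draws.

Every quantity the cost-effectiveness model consumes — clinical baselines,
adverse-event rates, unit costs, (dis)utilities — is a named :class:`Parameter`
carrying a point value and a :class:`DistributionSpec` describing second-order
(parameter) uncertainty.  Costs use gamma distributions, probabilities /
proportions / utilities use beta, relative effects use normal, and structural
constants are fixed point masses.  The published range of each parameter is
read as a central 95% interval; shape parameters are found numerically so that
the distribution reproduces the stated mean exactly and the interval as
closely as possible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DistributionSpec",
    "Parameter",
    "ParameterSet",
    "ParameterDraw",
    "InfeasibleDistributionError",
    "SchemaError",
    "fit_distribution",
    "sample_draw",
    "load_parameter_table",
    "save_parameter_table",
    "validate_parameters",
    "packaged_parameters",
]

FAMILIES = ("gamma", "beta", "normal", "fixed")
GROUPS = ("clinical", "ae_rate", "cost", "utility", "effect")

#: central interval matched when translating a (low, high) range into
#: distribution shape parameters
_INTERVAL_MASS = 0.95
_ALPHA = (1.0 - _INTERVAL_MASS) / 2.0


class InfeasibleDistributionError(ValueError):
    """Raised when a requested mean/range/family combination has no solution."""


class SchemaError(ValueError):
    """Raised when a parameter table file violates the column schema."""


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted uncertainty distribution for one parameter.

    ``shape1``/``shape2`` hold the family-specific parameters: (shape, scale)
    for gamma, (a, b) for beta, (mean, sd) for normal.  Degenerate specs
    (``low == high``) behave as point masses whatever the declared family.
    """

    family: str
    mean: float
    low: float
    high: float
    shape1: float = math.nan
    shape2: float = math.nan

    @property
    def degenerate(self) -> bool:
        return self.family == "fixed" or self.high <= self.low

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        """Draw from the fitted distribution."""
        if self.degenerate:
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "gamma":
            return rng.gamma(self.shape1, self.shape2, size=size)
        if self.family == "beta":
            return rng.beta(self.shape1, self.shape2, size=size)
        if self.family == "normal":
            return rng.normal(self.shape1, self.shape2, size=size)
        raise InfeasibleDistributionError(f"unknown family {self.family!r}")

    def in_support(self, x: float) -> bool:
        if self.degenerate:
            return math.isclose(x, self.mean, rel_tol=1e-12, abs_tol=1e-12)
        if self.family == "gamma":
            return x > 0
        if self.family == "beta":
            return 0.0 <= x <= 1.0
        return True


def _interval_sse_gamma(log_shape: float, mean: float, low: float, high: float) -> float:
    k = math.exp(log_shape)
    scale = mean / k
    q = stats.gamma.ppf([_ALPHA, 1 - _ALPHA], k, scale=scale)
    return (q[0] - low) ** 2 + (q[1] - high) ** 2


def _interval_sse_beta(log_conc: float, mean: float, low: float, high: float) -> float:
    c = math.exp(log_conc)
    a, b = mean * c, (1.0 - mean) * c
    q = stats.beta.ppf([_ALPHA, 1 - _ALPHA], a, b)
    return (q[0] - low) ** 2 + (q[1] - high) ** 2


def fit_distribution(
    family: str, mean: float, low: float, high: float, name: str = ""
) -> DistributionSpec:
    """Fit a :class:`DistributionSpec` to a stated mean and 95% range.

    The mean is always matched exactly; the shape parameter that remains free
    (gamma shape, beta concentration, normal sd) is chosen so the central 95%
    interval of the fitted distribution matches ``(low, high)`` in the
    least-squares sense.  Ranges that pin the mean to an endpoint (common for
    negotiated drug prices, where the list price is the upper bound) therefore
    still yield a usable distribution.

    Raises
    ------
    InfeasibleDistributionError
        If the family is unknown, the range ordering is violated, or the mean
        lies outside the family's support.
    """
    label = f" for parameter {name!r}" if name else ""
    if family not in FAMILIES:
        raise InfeasibleDistributionError(f"unknown family {family!r}{label}")
    if not (low <= mean <= high):
        raise InfeasibleDistributionError(
            f"range ordering violated{label}: need low <= mean <= high, "
            f"got ({low}, {mean}, {high})"
        )
    if family == "fixed":
        if not (low == mean == high):
            raise InfeasibleDistributionError(
                f"fixed family requires low = mean = high{label}"
            )
        return DistributionSpec("fixed", mean, low, high)
    if high <= low:
        # zero-width range: a point mass whatever the family label says
        return DistributionSpec(family, mean, low, high)

    if family == "gamma":
        if mean <= 0:
            raise InfeasibleDistributionError(f"gamma requires mean > 0{label}")
        res = optimize.minimize_scalar(
            _interval_sse_gamma,
            bounds=(math.log(1e-3), math.log(1e7)),
            args=(mean, low, high),
            method="bounded",
            options={"xatol": 1e-10},
        )
        k = math.exp(res.x)
        return DistributionSpec("gamma", mean, low, high, k, mean / k)

    if family == "beta":
        if not (0.0 <= low and high <= 1.0):
            raise InfeasibleDistributionError(
                f"beta requires the range within [0, 1]{label}"
            )
        if mean <= 0.0 or mean >= 1.0:
            # boundary mean: degenerate by construction
            return DistributionSpec("beta", mean, low, high)
        res = optimize.minimize_scalar(
            _interval_sse_beta,
            bounds=(math.log(1e-2), math.log(1e7)),
            args=(mean, low, high),
            method="bounded",
            options={"xatol": 1e-10},
        )
        c = math.exp(res.x)
        return DistributionSpec("beta", mean, low, high, mean * c, (1 - mean) * c)

    # normal: sd from the 95% range width
    sd = (high - low) / (2.0 * stats.norm.ppf(1 - _ALPHA))
    return DistributionSpec("normal", mean, low, high, mean, sd)


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    units: str
    spec: DistributionSpec
    group: str

    def __post_init__(self):
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for {self.name!r}")


@dataclass
class ParameterSet:
    """Named parameter collection plus the analysis-level constants.

    ``discount_rate`` (per year), ``wtp`` (USD per QALY) and ``exchange_rate``
    (CNY per USD, informational — all stored values are already USD).
    """

    parameters: dict[str, Parameter] = field(default_factory=dict)
    discount_rate: float = 0.05
    wtp: float = 12728.0
    exchange_rate: float = 6.693

    def add(self, p: Parameter) -> None:
        if p.name in self.parameters:
            raise SchemaError(f"duplicate parameter name {p.name!r}")
        self.parameters[p.name] = p

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self.parameters[name]
        except KeyError:
            raise KeyError(f"parameter {name!r} not in set") from None

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self.parameters.values())

    def __len__(self) -> int:
        return len(self.parameters)

    def value(self, name: str) -> float:
        return self[name].value

    def names(self) -> list[str]:
        return list(self.parameters)

    def base_draw(self) -> "ParameterDraw":
        """The degenerate draw at the point values (base-case analysis)."""
        return ParameterDraw(
            values={p.name: p.value for p in self}, draw_index=-1, seed=-1
        )


@dataclass(frozen=True)
class ParameterDraw:
    """One joint realisation of the parameter space (one PSA iteration)."""

    values: Mapping[str, float]
    draw_index: int
    seed: int

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise KeyError(f"parameter {name!r} not in draw") from None

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.values.get(name, default)

    def replace(self, **overrides: float) -> "ParameterDraw":
        vals = dict(self.values)
        vals.update(overrides)
        return ParameterDraw(values=vals, draw_index=self.draw_index, seed=self.seed)


def sample_draw(pset: ParameterSet, seed: int, draw_index: int) -> ParameterDraw:
    """Draw every parameter independently from its fitted distribution.

    Reproducible: identical ``(seed, draw_index)`` give identical draws, and
    distinct draw indices use statistically independent streams.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(draw_index),))
    )
    values = {name: float(pset[name].spec.sample(rng)) for name in sorted(pset.parameters)}
    return ParameterDraw(values=values, draw_index=draw_index, seed=seed)


_COLUMNS = ["name", "mean", "low", "high", "family", "units", "group"]


def _set_from_frame(df: pd.DataFrame, origin: str) -> ParameterSet:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{origin}: missing column(s) {missing}")
    pset = ParameterSet()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mean, low, high = float(row.mean), float(row.low), float(row.high)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{origin}: unparseable number at row {i}") from exc
        name = str(row.name)
        if name in pset:
            raise SchemaError(f"{origin}: duplicate name {name!r} at row {i}")
        try:
            spec = fit_distribution(str(row.family), mean, low, high, name=name)
        except InfeasibleDistributionError as exc:
            raise SchemaError(f"{origin}: row {i}: {exc}") from exc
        pset.add(Parameter(name, mean, str(row.units), spec, str(row.group)))
    return pset


def load_parameter_table(path: str | Path) -> ParameterSet:
    """Read a parameter table from CSV or the equivalent JSON dialect."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["parameters"], columns=_COLUMNS if payload["parameters"] else None)
        if df.empty:
            df = pd.DataFrame(columns=_COLUMNS)
        pset = _set_from_frame(df, str(path))
        for key in ("discount_rate", "wtp", "exchange_rate"):
            if key in payload:
                setattr(pset, key, float(payload[key]))
        return pset
    df = pd.read_csv(path, dtype={"name": str, "units": str, "family": str, "group": str})
    if df.empty and not set(_COLUMNS) <= set(df.columns):
        raise SchemaError(f"{path}: missing header row")
    return _set_from_frame(df, str(path))


def save_parameter_table(pset: ParameterSet, path: str | Path) -> None:
    """Write a parameter table; ``load(save(x))`` round-trips exactly."""
    path = Path(path)
    rows = [
        {
            "name": p.name,
            "mean": p.spec.mean,
            "low": p.spec.low,
            "high": p.spec.high,
            "family": p.spec.family,
            "units": p.units,
            "group": p.group,
        }
        for p in pset
    ]
    if path.suffix.lower() == ".json":
        payload = {
            "discount_rate": pset.discount_rate,
            "wtp": pset.wtp,
            "exchange_rate": pset.exchange_rate,
            "parameters": rows,
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        df = pd.DataFrame(rows, columns=_COLUMNS)
        for col in ("mean", "low", "high"):
            df[col] = df[col].map(repr)  # shortest round-trip representation
        df.to_csv(path, index=False)


def validate_parameters(
    pset: ParameterSet, required: Iterable[str] = ()
) -> list[str]:
    """Return a list of human-readable violations (empty = valid)."""
    report: list[str] = []
    for p in pset:
        s = p.spec
        if not (s.low <= s.mean <= s.high):
            report.append(f"{p.name}: range ordering violated ({s.low}, {s.mean}, {s.high})")
        if s.family == "beta" and not (0.0 <= s.low and s.high <= 1.0):
            report.append(f"{p.name}: beta support must lie within [0, 1]")
        if s.family == "gamma" and s.low < 0:
            report.append(f"{p.name}: gamma support is positive but low = {s.low}")
        if p.group == "cost" and not p.units:
            report.append(f"{p.name}: cost parameter lacks units")
    for name in required:
        if name not in pset:
            report.append(f"missing required parameter {name!r}")
    if not (0.0 <= pset.discount_rate <= 0.08):
        report.append(f"discount_rate {pset.discount_rate} outside [0, 0.08]")
    if pset.wtp <= 0:
        report.append(f"wtp must be positive, got {pset.wtp}")
    return report


def packaged_parameters() -> ParameterSet:
    """The packaged base-case parameter table (clinical, AE, cost, utility)."""
    with resources.as_file(
        resources.files("glp1ce.data").joinpath("parameters.csv")
    ) as p:
        return load_parameter_table(p)
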