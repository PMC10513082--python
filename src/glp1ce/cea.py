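"""Decision-analytic outputs: NMB/INMB/ICER, PSA with CEAC, tornado, scenarios.

All arm comparisons use the paired per-patient results that common random
numbers make possible: the incremental net monetary benefit between two arms
is the mean of per-patient NMB differences, with a percentile-bootstrap
confidence interval over patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .microsim import (
    COMPLICATION_CATEGORIES,
    SimulationResult,
    TreatmentProfile,
    run_arm,
)
from .params import ParameterDraw, ParameterSet
from .riskengine import PatientState, RiskModel, sample_cohort

__all__ = [
    "ModelBundle",
    "PSAResult",
    "nmb",
    "inmb_paired",
    "icer",
    "complication_breakdown",
    "run_base_case",
    "run_psa",
    "compute_ceac",
    "one_way_sa",
    "scenario_horizons",
]

_WTP_DEFAULT = 12728.0
#: below this absolute QALY difference the ICER denominator is unstable
_ICER_MIN_DQALY = 1e-3


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit: wtp * qaly - cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * qaly - cost


def inmb_paired(
    arm: SimulationResult,
    reference: SimulationResult,
    wtp: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Incremental NMB of ``arm`` vs ``reference`` from paired patients."""
    if arm.n != reference.n:
        raise ValueError("paired INMB requires equally sized cohorts")
    diff = arm.per_patient_nmb(wtp) - reference.per_patient_nmb(wtp)
    mean = float(diff.mean())
    if np.allclose(diff, diff[0]):
        return {"inmb": mean, "lo": mean, "hi": mean}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    idx = rng.integers(0, arm.n, size=(n_boot, arm.n))
    boot = diff[idx].mean(axis=1)
    return {
        "inmb": mean,
        "lo": float(np.quantile(boot, 0.025)),
        "hi": float(np.quantile(boot, 0.975)),
    }


def icer(arm: Mapping[str, float], reference: Mapping[str, float]) -> dict:
    """Incremental cost-effectiveness ratio with dominance verdicts.

    Inputs are summaries with ``cost_mean`` and ``qaly_mean`` keys (as from
    :meth:`SimulationResult.summary`).  Near-zero QALY differences are
    flagged unstable rather than reported as a ratio.
    """
    d_cost = arm["cost_mean"] - reference["cost_mean"]
    d_qaly = arm["qaly_mean"] - reference["qaly_mean"]
    out = {"delta_cost": d_cost, "delta_qaly": d_qaly, "icer": math.nan,
           "verdict": ""}
    if d_cost <= 0 and d_qaly > 0:
        out["verdict"] = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        out["verdict"] = "dominated"
    elif abs(d_qaly) < _ICER_MIN_DQALY:
        out["verdict"] = "unstable"
    else:
        out["icer"] = d_cost / d_qaly
        out["verdict"] = "ratio"
    return out


def complication_breakdown(result: SimulationResult) -> pd.DataFrame:
    """Mean per-patient cost and disutility by complication, plus Sum.

    The Sum column equals the row total of the twelve categories exactly
    (it is computed as that total).
    """
    unknown = [c for c in result.categories if c not in COMPLICATION_CATEGORIES]
    if unknown:
        raise ValueError(f"unknown complication categories in ledger: {unknown}")
    cost_means = result.comp_cost.mean(axis=0)
    disu_means = result.comp_disu.mean(axis=0)
    table = pd.DataFrame(
        [cost_means, disu_means],
        index=["cost", "disutility"],
        columns=list(result.categories),
    )
    table["Sum"] = table[list(result.categories)].sum(axis=1)
    table.insert(0, "arm", result.arm)
    return table


# ---------------------------------------------------------------------------
# the analysis bundle


@dataclass
class ModelBundle:
    """Everything one base-case / PSA / scenario run needs."""

    pset: ParameterSet
    risk_model: RiskModel
    profiles: dict[str, TreatmentProfile]
    cohort: Sequence[PatientState]
    sim_seed: int = 0
    horizon: int | None = None
    #: per-arm, per-endpoint (mean, sd) of the change rate, used to draw
    #: treatment effects in the PSA (normal distribution on the effects)
    effect_uncertainty: Mapping[str, Mapping[str, tuple[float, float]]] | None = None

    @property
    def wtp(self) -> float:
        return self.pset.wtp

    def arms(self) -> list[str]:
        return list(self.profiles)


def default_bundle(
    cohort_n: int = 1000,
    seed: int = 0,
    horizon: int | None = None,
    pset: ParameterSet | None = None,
    effect_sd: float | None = 0.005,
) -> ModelBundle:
    """Bundle with the packaged parameters, synthetic risk model and profiles."""
    from .microsim import default_profiles
    from .params import packaged_parameters
    from .synthetic import default_risk_model

    pset = pset or packaged_parameters()
    cohort = sample_cohort(cohort_n, pset, seed)
    profiles = default_profiles()
    unc = None
    if effect_sd is not None:
        unc = {
            arm: {ep: (val, effect_sd) for ep, val in prof.effects.items()}
            for arm, prof in profiles.items()
        }
    return ModelBundle(
        pset=pset,
        risk_model=default_risk_model(),
        profiles=profiles,
        cohort=cohort,
        sim_seed=seed + 1,
        horizon=horizon,
        effect_uncertainty=unc,
    )


def run_base_case(
    bundle: ModelBundle, draw: ParameterDraw | None = None
) -> dict[str, SimulationResult]:
    """Simulate every arm on the shared cohort with common random numbers."""
    if draw is None:
        draw = bundle.pset.base_draw()
    return {
        arm: run_arm(bundle.cohort, prof, bundle.risk_model, draw,
                     bundle.sim_seed, bundle.horizon)
        for arm, prof in bundle.profiles.items()
    }


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAResult:
    arms: tuple[str, ...]
    cost: np.ndarray        # (iterations, arms) mean cost
    qaly: np.ndarray        # (iterations, arms) mean QALY
    draw_index: np.ndarray  # per-iteration parameter draw index
    seed: int
    failed: tuple[int, ...] = ()

    def __post_init__(self):
        if self.cost.shape != self.qaly.shape:
            raise ValueError("cost/qaly matrices must agree in shape")
        if self.cost.shape[1] != len(self.arms):
            raise ValueError("matrix width must match the number of arms")

    @property
    def iterations(self) -> int:
        return self.cost.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.iterations):
            for j, arm in enumerate(self.arms):
                rows.append({"iteration": i, "arm": arm,
                             "cost": self.cost[i, j], "qaly": self.qaly[i, j]})
        return pd.DataFrame(rows)


def run_psa(
    bundle: ModelBundle,
    iterations: int,
    cohort_n: int | None = None,
    seed: int = 0,
) -> PSAResult:
    """Second-order Monte Carlo: one joint parameter draw per iteration.

    Each iteration draws all parameters from their uncertainty
    distributions, draws each arm's treatment effects from their normal
    uncertainty (when ``bundle.effect_uncertainty`` is set), and simulates
    every arm on the same cohort with the same simulation seed, so that
    within an iteration arms differ only parametrically.  Failed iterations
    are recorded and excluded with a warning.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    cohort = bundle.cohort if cohort_n is None else bundle.cohort[:cohort_n]
    arms = bundle.arms()
    cost = np.full((iterations, len(arms)), np.nan)
    qaly = np.full((iterations, len(arms)), np.nan)
    failed: list[int] = []
    for i in range(iterations):
        try:
            draw = _psa_draw(bundle, seed, i)
            profiles = _psa_profiles(bundle, seed, i)
            for j, arm in enumerate(arms):
                res = run_arm(cohort, profiles[arm], bundle.risk_model, draw,
                              bundle.sim_seed, bundle.horizon)
                cost[i, j] = float(res.cost.mean())
                qaly[i, j] = float(res.qaly.mean())
        except Exception as exc:  # pragma: no cover - defensive
            failed.append(i)
            warnings.warn(f"PSA iteration {i} failed and was excluded: {exc}")
    ok = np.array([i for i in range(iterations) if i not in set(failed)], dtype=int)
    return PSAResult(
        arms=tuple(arms),
        cost=cost[ok],
        qaly=qaly[ok],
        draw_index=ok,
        seed=seed,
        failed=tuple(failed),
    )


def _psa_draw(bundle: ModelBundle, seed: int, i: int) -> ParameterDraw:
    from .params import sample_draw

    return sample_draw(bundle.pset, seed, i)


def _psa_profiles(bundle: ModelBundle, seed: int, i: int) -> dict[str, TreatmentProfile]:
    if bundle.effect_uncertainty is None:
        return bundle.profiles
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(i, 7))
    )
    from dataclasses import replace

    out = {}
    for arm, prof in bundle.profiles.items():
        unc = bundle.effect_uncertainty.get(arm, {})
        effects = dict(prof.effects)
        for ep in sorted(unc):
            mean, sd = unc[ep]
            effects[ep] = float(rng.normal(mean, sd))
        out[arm] = replace(prof, effects=effects)
    return out


def compute_ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value: the fraction of PSA iterations in
    which each arm attains the highest NMB, ties split uniformly.  The
    probabilities across arms sum to one at every grid point.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    if psa.iterations == 0:
        raise ValueError("empty PSA")
    rows = []
    for w in grid:
        nmb_matrix = w * psa.qaly - psa.cost  # (iter, arms)
        best = nmb_matrix.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb_matrix, best, rtol=0.0, atol=1e-9)
        share = is_best / is_best.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for j, arm in enumerate(psa.arms):
            rows.append({"wtp": float(w), "arm": arm, "probability": float(probs[j])})
    return pd.DataFrame(rows)


def default_wtp_grid(stop: float = 40000.0, step: float = 400.0) -> np.ndarray:
    return np.arange(0.0, stop + step / 2, step)


# ---------------------------------------------------------------------------
# one-way (deterministic) sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    inmb_low: float
    inmb_high: float

    @property
    def range(self) -> float:
        return abs(self.inmb_high - self.inmb_low)


def one_way_sa(
    bundle: ModelBundle,
    parameters: Sequence[str],
    arm: str,
    reference: str = "exenatide",
    top: int | None = 10,
) -> list[TornadoEntry]:
    """Tornado analysis of the INMB of ``arm`` vs ``reference``.

    Each parameter is set to its low and high bound in turn with everything
    else at base case and common random numbers held fixed.  Parameters
    without bounds are skipped with a warning.  Entries are sorted by
    descending INMB range; ``top`` limits the list.
    """
    base = bundle.pset.base_draw()
    entries = []
    for pname in parameters:
        if pname not in bundle.pset:
            warnings.warn(f"parameter {pname!r} unknown; skipped")
            continue
        spec = bundle.pset[pname].spec
        if spec.high <= spec.low:
            warnings.warn(f"parameter {pname!r} has no range; skipped")
            continue
        vals = []
        for bound in (spec.low, spec.high):
            draw = base.replace(**{pname: float(bound)})
            res_arm = run_arm(bundle.cohort, bundle.profiles[arm],
                              bundle.risk_model, draw, bundle.sim_seed,
                              bundle.horizon)
            res_ref = run_arm(bundle.cohort, bundle.profiles[reference],
                              bundle.risk_model, draw, bundle.sim_seed,
                              bundle.horizon)
            diff = res_arm.per_patient_nmb(bundle.wtp) - res_ref.per_patient_nmb(bundle.wtp)
            vals.append(float(diff.mean()))
        entries.append(TornadoEntry(pname, vals[0], vals[1]))
    entries.sort(key=lambda e: e.range, reverse=True)
    return entries if top is None else entries[:top]


def scenario_horizons(
    bundle: ModelBundle, horizons: Sequence[int] = (10, 20, 30, 40)
) -> pd.DataFrame:
    """Cost / QALY / NMB per arm at truncated time horizons (same seeds)."""
    if any(h <= 0 for h in horizons):
        raise ValueError("horizons must be positive integers")
    draw = bundle.pset.base_draw()
    rows = []
    for h in horizons:
        for arm, prof in bundle.profiles.items():
            res = run_arm(bundle.cohort, prof, bundle.risk_model, draw,
                          bundle.sim_seed, int(h))
            s = res.summary(bundle.wtp)
            rows.append(
                {
                    "horizon": int(h),
                    "arm": arm,
                    "cost": s["cost_mean"],
                    "qaly": s["qaly_mean"],
                    "life_years": s["life_years_mean"],
                    "nmb": s["nmb_mean"],
                }
            )
    return pd.DataFrame(rows)
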