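"""Synthetic stand-ins for external model inputs.

Three of the pipeline's inputs live outside any published table: the
proprietary risk-equation coefficients of the underlying Chinese diabetes
outcomes model, the census life table, and the trial-level 6-month change
rates feeding the network meta-analysis.  This module generates calibrated
substitutes with *known* ground truth so every downstream stage (NMA fitting,
microsimulation, GLM burden analysis) can be exercised and checked end to
end:

* :func:`gen_risk_coefficients` builds logistic risk equations whose
  intercepts are solved exactly so the annual event probability at a stated
  reference patient equals a stated calibration target, with gradient signs
  chosen a priori (risk increasing in age, HbA1c, blood pressure, ...).
* :func:`gen_life_table` is a deterministic Gompertz-Makeham schedule.
* :func:`gen_nma_dataset` draws arm-level observed change rates as
  truth + study-level heterogeneity + sampling noise, recording the truths.
* :func:`gen_glm_dataset` simulates patient-level outcome tables with known
  exposure effects for estimator-recovery tests.

Everything here is synthetic by construction and swappable for real inputs
in the documented file formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .riskengine import (
    EVENT_OUTCOMES,
    OUTCOMES,
    LifeTable,
    PatientState,
    RiskEquation,
    RiskModel,
)

__all__ = [
    "SyntheticNMAConfig",
    "RiskCalibrationTarget",
    "NMADataset",
    "gen_nma_dataset",
    "gen_risk_coefficients",
    "gen_life_table",
    "gen_glm_dataset",
    "default_calibration_targets",
    "default_risk_model",
    "default_nma_config",
    "TREATMENTS",
    "ENDPOINTS",
]

TREATMENTS = (
    "exenatide",
    "liraglutide",
    "loxenatide",
    "dulaglutide",
    "semaglutide",
    "lixisenatide",
)
ENDPOINTS = ("hba1c", "bmi", "sbp", "dbp")


# ---------------------------------------------------------------------------
# NMA trial-aggregate generator


@dataclass
class SyntheticNMAConfig:
    """Configuration of a synthetic trial network with known true effects.

    ``true_effects[treatment][endpoint]`` is the true mean 6-month change
    rate (fraction of baseline; negative = reduction).  ``studies`` is a list
    of ``(design, n_per_arm, obs_sd)`` where ``design`` is the tuple of
    treatments compared and ``obs_sd`` the patient-level SD of the change
    rate within an arm.
    """

    treatments: Sequence[str]
    true_effects: Mapping[str, Mapping[str, float]]
    heterogeneity_sd: Mapping[str, float]
    studies: Sequence[tuple[Sequence[str], int, float]]
    seed: int = 0

    def validate(self) -> None:
        seen = set()
        for design, n, _sd in self.studies:
            if len(design) < 2:
                raise ValueError(f"study design {design} has fewer than 2 arms")
            if n < 2:
                raise ValueError("n per arm must be >= 2")
            seen.update(design)
        missing = set(self.treatments) - seen
        if missing:
            raise ValueError(f"treatments never observed in any study: {sorted(missing)}")
        if not _connected(self.treatments, [d for d, _, _ in self.studies]):
            raise ValueError("treatment network is disconnected")


def _connected(nodes: Sequence[str], designs: Sequence[Sequence[str]]) -> bool:
    nodes = list(nodes)
    if not nodes:
        return True
    adj: dict[str, set[str]] = {t: set() for t in nodes}
    for design in designs:
        for a in design:
            for b in design:
                if a != b and a in adj and b in adj:
                    adj[a].add(b)
    seen, stack = {nodes[0]}, [nodes[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == set(nodes)


@dataclass
class NMADataset:
    """Arm-level aggregate data; one row per (study, endpoint, arm)."""

    arms: pd.DataFrame  # study, design, treatment, endpoint, mean_change_rate, sd, n
    truths: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self):
        counts = self.arms.groupby(["study", "endpoint"])["treatment"].count()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"single-arm studies rejected: {bad}")

    def endpoint(self, endpoint: str) -> pd.DataFrame:
        sub = self.arms[self.arms.endpoint == endpoint]
        if sub.empty:
            raise KeyError(f"no data for endpoint {endpoint!r}")
        return sub.reset_index(drop=True)

    def endpoints(self) -> list[str]:
        return sorted(self.arms.endpoint.unique())

    def treatments(self) -> list[str]:
        return sorted(self.arms.treatment.unique())

    def to_csv(self, path) -> None:
        self.arms.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "NMADataset":
        return cls(pd.read_csv(path))


def gen_nma_dataset(config: SyntheticNMAConfig) -> NMADataset:
    """Simulate arm-level observed change rates for the configured network.

    Observed arm mean = true effect + study-level random effect (shared
    within the study, sd = heterogeneity) + sampling error ``sd/sqrt(n)``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed)))
    endpoints = sorted(next(iter(config.true_effects.values())).keys())
    rows = []
    for s_idx, (design, n, obs_sd) in enumerate(config.studies):
        label = f"study_{s_idx + 1:02d}"
        design_key = "/".join(design)
        for ep in endpoints:
            het = float(config.heterogeneity_sd.get(ep, 0.0))
            # one study-level shift per (study, endpoint): common heterogeneity
            shift = rng.normal(0.0, het) if het > 0 else 0.0
            for t in design:
                truth = float(config.true_effects[t][ep])
                se = obs_sd / math.sqrt(n)
                noise = rng.normal(0.0, se) if obs_sd > 0 else 0.0
                rows.append(
                    {
                        "study": label,
                        "design": design_key,
                        "treatment": t,
                        "endpoint": ep,
                        "mean_change_rate": truth + shift + noise,
                        "sd": obs_sd if obs_sd > 0 else 1e-6,
                        "n": n,
                    }
                )
    truths = {t: dict(config.true_effects[t]) for t in config.true_effects}
    return NMADataset(pd.DataFrame(rows), truths=truths)


#: default true 6-month change rates (fraction of baseline level) used by the
#: packaged synthetic network; ordering of HbA1c control mirrors the relative
#: efficacy narrative of the six regimens (semaglutide strongest, loxenatide
#: ahead of exenatide)
DEFAULT_TRUE_EFFECTS: dict[str, dict[str, float]] = {
    "placebo":      {"hba1c": -0.040, "bmi": -0.003, "sbp": -0.005, "dbp": -0.003},
    "exenatide":    {"hba1c": -0.110, "bmi": -0.030, "sbp": -0.020, "dbp": -0.010},
    "liraglutide":  {"hba1c": -0.130, "bmi": -0.035, "sbp": -0.022, "dbp": -0.011},
    "loxenatide":   {"hba1c": -0.135, "bmi": -0.012, "sbp": -0.015, "dbp": -0.008},
    "dulaglutide":  {"hba1c": -0.125, "bmi": -0.025, "sbp": -0.018, "dbp": -0.009},
    "semaglutide":  {"hba1c": -0.160, "bmi": -0.050, "sbp": -0.025, "dbp": -0.012},
    "lixisenatide": {"hba1c": -0.100, "bmi": -0.020, "sbp": -0.014, "dbp": -0.007},
}

#: the nine-trial roster: designs mirror the published phase-III network
#: (two head-to-head trials, the rest placebo-controlled; the glimepiride arm
#: of the liraglutide trial is outside the treatment set and dropped)
DEFAULT_STUDY_ROSTER: tuple[tuple[tuple[str, ...], int, float], ...] = (
    (("semaglutide", "dulaglutide"), 300, 0.08),   # head-to-head
    (("dulaglutide", "liraglutide"), 300, 0.08),   # head-to-head
    (("placebo", "exenatide"), 112, 0.08),
    (("liraglutide", "placebo"), 100, 0.08),
    (("dulaglutide", "placebo"), 240, 0.08),
    (("lixisenatide", "exenatide"), 317, 0.08),    # largest head-to-head
    (("lixisenatide", "placebo"), 227, 0.08),
    (("lixisenatide", "placebo"), 161, 0.08),
    (("loxenatide", "placebo"), 179, 0.08),
)


def default_nma_config(seed: int = 0, heterogeneity_sd: float = 0.01) -> SyntheticNMAConfig:
    """The packaged six-regimen + placebo synthetic network (nine trials)."""
    return SyntheticNMAConfig(
        treatments=("placebo",) + TREATMENTS,
        true_effects=DEFAULT_TRUE_EFFECTS,
        heterogeneity_sd={ep: heterogeneity_sd for ep in ENDPOINTS},
        studies=DEFAULT_STUDY_ROSTER,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# risk-equation calibration


@dataclass(frozen=True)
class RiskCalibrationTarget:
    """Target annual probability at the reference state, with gradient signs."""

    outcome: str
    target: float
    gradients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.target < 1.0):
            raise ValueError(
                f"calibration target for {self.outcome!r} must lie in (0, 1), "
                f"got {self.target}"
            )


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


#: gradient direction templates: risk rises with age, glycaemia, pressure,
#: smoking and prior disease; renal outcomes fall with eGFR
_BASE_GRADIENTS: dict[str, dict[str, float]] = {
    "mortality": {"age": 0.09, "hba1c": 0.10, "smoker_current": 0.35,
                  "heart_failure": 0.60, "renal_failure": 0.80, "mi": 0.40,
                  "stroke": 0.40, "female": -0.25},
    "mi": {"age": 0.06, "hba1c": 0.12, "sbp": 0.015, "ldl": 0.20,
           "smoker_current": 0.40, "mi": 0.70, "female": -0.30},
    "ihd": {"age": 0.05, "hba1c": 0.10, "sbp": 0.012, "ldl": 0.18,
            "smoker_current": 0.30, "female": -0.20},
    "heart_failure": {"age": 0.07, "hba1c": 0.10, "sbp": 0.012, "bmi": 0.04,
                      "mi": 0.60, "atrial_fibrillation": 0.50},
    "stroke": {"age": 0.07, "hba1c": 0.10, "sbp": 0.020,
               "atrial_fibrillation": 0.60, "smoker_current": 0.35, "stroke": 0.50},
    "pvd": {"age": 0.05, "hba1c": 0.12, "smoker_current": 0.50, "duration": 0.03},
    "neuropathy": {"age": 0.03, "hba1c": 0.15, "duration": 0.04, "bmi": 0.02},
    "amputation": {"hba1c": 0.15, "duration": 0.04, "pvd": 1.00,
                   "neuropathy": 0.80, "ulcer": 1.00},
    "ulcer": {"hba1c": 0.12, "duration": 0.03, "neuropathy": 0.60, "pvd": 0.60},
    "renal_failure": {"age": 0.03, "hba1c": 0.12, "sbp": 0.012, "duration": 0.04,
                      "egfr": -0.03, "ckd_stage": 0.50},
    "cataract": {"age": 0.08, "hba1c": 0.08, "duration": 0.02},
    "retinopathy": {"age": 0.02, "hba1c": 0.18, "duration": 0.05, "sbp": 0.008},
}

#: default annual calibration targets at the reference patient; magnitudes
#: follow the baseline prevalence/incidence scale of the parameter table
DEFAULT_TARGETS: dict[str, float] = {
    "mortality": 0.010,
    "mi": 0.006,
    "ihd": 0.009,
    "heart_failure": 0.005,
    "stroke": 0.010,
    "pvd": 0.003,
    "neuropathy": 0.004,
    "amputation": 0.0008,
    "ulcer": 0.003,
    "renal_failure": 0.004,
    "cataract": 0.012,
    "retinopathy": 0.008,
}

#: deterministic annual drift of the modifiable risk factors (units/year)
DEFAULT_PROGRESSION: dict[str, float] = {
    "hba1c": 0.10,
    "bmi": 0.05,
    "sbp": 0.50,
    "dbp": 0.20,
}


def default_calibration_targets() -> list[RiskCalibrationTarget]:
    return [
        RiskCalibrationTarget(outcome, DEFAULT_TARGETS[outcome],
                              _BASE_GRADIENTS[outcome])
        for outcome in OUTCOMES
    ]


def gen_risk_coefficients(
    targets: Sequence[RiskCalibrationTarget],
    reference: PatientState | None = None,
    progression: Mapping[str, float] | None = None,
    life_table: LifeTable | None = None,
) -> RiskModel:
    """Build a logistic risk model calibrated exactly to the given targets.

    For each outcome the slope vector is taken from the target's gradient
    map and the intercept is solved in closed form so that the annual event
    probability at ``reference`` equals the target: since the link is
    logistic, ``intercept = logit(target) - slopes . x_ref``.
    """
    if reference is None:
        reference = PatientState()
    if not targets:
        raise ValueError("at least one calibration target is required")
    named = {t.outcome for t in targets}
    missing = [o for o in OUTCOMES if o not in named]
    if missing:
        raise ValueError(f"missing calibration targets for outcomes: {missing}")
    ref_arrays = reference.as_arrays()
    equations = {}
    for t in targets:
        eq0 = RiskEquation(t.outcome, {**t.gradients, "intercept": 0.0})
        lp0 = float(eq0.linear_predictor(ref_arrays)[0])
        intercept = _logit(t.target) - lp0
        equations[t.outcome] = RiskEquation(
            t.outcome, {**t.gradients, "intercept": intercept}
        )
    prog = dict(DEFAULT_PROGRESSION if progression is None else progression)
    return RiskModel(equations, prog, life_table)


def default_risk_model(with_life_table: bool = True) -> RiskModel:
    """The packaged calibrated synthetic risk model."""
    table = gen_life_table() if with_life_table else None
    return gen_risk_coefficients(default_calibration_targets(), life_table=table)


# ---------------------------------------------------------------------------
# life table


def gen_life_table(
    makeham: float = 4e-4,
    gompertz_a: float = 2.2e-5,
    gompertz_b: float = 0.092,
    female_factor: float = 0.55,
    ages: tuple[int, int] = (18, 100),
) -> LifeTable:
    """Deterministic Gompertz-Makeham life table by sex.

    Annual hazard ``h(age) = makeham + a * exp(b * age)``; the female hazard
    is scaled by ``female_factor``.  Probabilities are ``1 - exp(-h)`` and
    clipped at 0.999 (with a warning) if the parameters explode before the
    terminal age.
    """
    age_grid = np.arange(ages[0], ages[1] + 1)
    hazard = makeham + gompertz_a * np.exp(gompertz_b * age_grid)
    qx_male = 1.0 - np.exp(-hazard)
    qx_female = 1.0 - np.exp(-hazard * female_factor)
    if np.any(qx_male >= 1.0) or np.any(qx_female >= 1.0):
        import warnings

        warnings.warn("life-table probabilities clipped at 0.999", stacklevel=2)
    qx_male = np.clip(qx_male, 1e-12, 0.999)
    qx_female = np.clip(qx_female, 1e-12, 0.999)
    return LifeTable(age_grid, qx_male, qx_female)


def constant_life_table(q: float, ages: tuple[int, int] = (18, 110)) -> LifeTable:
    """A flat life table (every age, both sexes, death probability ``q``)."""
    grid = np.arange(ages[0], ages[1] + 1)
    qx = np.full(len(grid), float(q))
    return LifeTable(grid, qx, qx.copy())


# ---------------------------------------------------------------------------
# GLM test-bench generator


def gen_glm_dataset(
    n: int,
    effect_hba1c: float,
    effect_bmi: float,
    seed: int,
    noise_family: str = "gaussian",
    noise_scale: float = 1000.0,
    intercept: float = 9000.0,
    covariate_effects: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Patient-level table with known exposure effects on a cost-like outcome.

    Binary exposures are ``poor_hba1c = HbA1c > 7`` and ``high_bmi =
    BMI > 25``.  ``noise_family='gaussian'`` generates ``outcome =
    intercept + effects + covariates + N(0, noise_scale)`` (effects additive
    in outcome units); ``'gamma'`` generates a multiplicative model
    ``outcome = exp(intercept' + effects + ...) * gamma_noise`` where the
    supplied effects are on the log scale.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    if covariate_effects is not None:
        cov_eff = dict(covariate_effects)
    elif noise_family == "gamma":
        # log-scale magnitudes
        cov_eff = {"age": 0.002, "female": -0.013, "sbp": 0.0005}
    else:
        cov_eff = {"age": 15.0, "female": -120.0, "sbp": 4.0}
    df = pd.DataFrame(
        {
            "age": rng.normal(55, 6, n),
            "female": rng.binomial(1, 0.44, n).astype(float),
            "sbp": rng.normal(125.5, 8, n),
            "duration": rng.normal(6, 1.2, n),
            "hba1c": rng.normal(7.5, 1.0, n),
            "bmi": rng.normal(26.5, 3.0, n),
        }
    )
    poor = (df.hba1c > 7.0).astype(float)
    high = (df.bmi > 25.0).astype(float)
    if noise_family == "gaussian":
        mu = intercept + effect_hba1c * poor + effect_bmi * high
        for c, b in cov_eff.items():
            mu = mu + b * (df[c] - df[c].mean())
        y = mu + rng.normal(0.0, noise_scale, n)
    elif noise_family == "gamma":
        eta = math.log(intercept) + effect_hba1c * poor + effect_bmi * high
        for c, b in cov_eff.items():
            eta = eta + b * (df[c] - df[c].mean())
        shape = 20.0
        y = np.exp(eta) * rng.gamma(shape, 1.0 / shape, n)
    else:
        raise ValueError(f"unknown noise family {noise_family!r}")
    df["outcome"] = np.asarray(y, dtype=float)
    return df
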