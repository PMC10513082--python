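"""Annual-cycle risk engine: cohort sampling, event risk equations, mortality.

The engine follows the structure of validated diabetes outcomes models: one
logistic risk equation per complication evaluated once per one-year cycle on
the patient's current risk-factor profile, deterministic annual progression of
the modifiable risk factors (HbA1c, BMI, SBP, DBP), and all-cause mortality
blended with a general-population life table so that a diabetic patient's
death probability is never below the natural-mortality floor for their age
and sex.

The coefficient values themselves are interchangeable: any file following the
JSON schema of :class:`RiskModel` can be loaded, and the packaged defaults are
calibrated synthetic stand-ins (see :mod:`glp1ce.synthetic`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ParameterDraw, ParameterSet

__all__ = [
    "OUTCOMES",
    "EVENT_OUTCOMES",
    "COMORBIDITY_FLAGS",
    "CKD_STAGES",
    "PatientState",
    "RiskEquation",
    "RiskModel",
    "LifeTable",
    "sample_cohort",
    "cohort_to_frame",
    "annual_event_probability",
    "death_probability",
    "progress_risk_factors",
]

#: the thirteen modelled outcomes: all-cause mortality, four macrovascular
#: events, seven microvascular events (risk-factor progression is handled by
#: deterministic rules, not an equation)
OUTCOMES = (
    "mortality",
    "mi",
    "ihd",
    "heart_failure",
    "stroke",
    "pvd",
    "neuropathy",
    "amputation",
    "ulcer",
    "renal_failure",
    "cataract",
    "retinopathy",
)
EVENT_OUTCOMES = OUTCOMES[1:]

COMORBIDITY_FLAGS = (
    "atrial_fibrillation",
    "mi",
    "ihd",
    "heart_failure",
    "stroke",
    "pvd",
    "neuropathy",
    "amputation",
    "ulcer",
    "renal_failure",
    "retinopathy",
    "cataract",
)

CKD_STAGES = ("none", "mild", "mild_moderate", "moderate_severe", "severe")

#: fields a risk equation may reference
_NUMERIC_FIELDS = (
    "age",
    "female",
    "duration",
    "smoker_current",
    "smoker_past",
    "hba1c",
    "bmi",
    "sbp",
    "dbp",
    "hdl",
    "ldl",
    "triglycerides",
    "hemoglobin",
    "white_cell_count",
    "egfr",
    "insulin",
    "noninsulin_agents",
    "antihypertensives",
    "statins",
    "ckd_stage",
) + COMORBIDITY_FLAGS


@dataclass
class PatientState:
    """One simulated individual's risk factors, flags, and treatment status."""

    age: float = 55.0
    female: int = 0
    duration: float = 6.0
    smoker_current: int = 0
    smoker_past: int = 0
    hba1c: float = 8.5
    bmi: float = 26.5
    sbp: float = 125.5
    dbp: float = 78.5
    hdl: float = 1.3
    ldl: float = 3.0
    triglycerides: float = 1.6
    hemoglobin: float = 13.7
    white_cell_count: float = 8.0
    egfr: float = 92.2
    insulin: int = 0
    noninsulin_agents: int = 1
    antihypertensives: int = 0
    statins: int = 0
    ckd_stage: int = 0
    atrial_fibrillation: int = 0
    mi: int = 0
    ihd: int = 0
    heart_failure: int = 0
    stroke: int = 0
    pvd: int = 0
    neuropathy: int = 0
    amputation: int = 0
    ulcer: int = 0
    renal_failure: int = 0
    retinopathy: int = 0
    cataract: int = 0
    alive: bool = True
    treatment: str = ""
    years_on_treatment: float = 0.0

    def __post_init__(self):
        if not (18.0 <= self.age <= 110.0):
            raise ValueError(f"age {self.age} outside [18, 110]")
        if not (4.0 <= self.hba1c <= 20.0):
            raise ValueError(f"HbA1c {self.hba1c} outside [4, 20]")
        if not (10.0 <= self.bmi <= 80.0):
            raise ValueError(f"BMI {self.bmi} outside [10, 80]")

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {f: np.asarray([float(getattr(self, f))]) for f in _NUMERIC_FIELDS}


def cohort_to_frame(cohort: Sequence[PatientState]) -> pd.DataFrame:
    """Cohort as a DataFrame, one row per patient (CSV export)."""
    cols = [f.name for f in fields(PatientState)]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in cohort])


_TRANSFORMS = ("identity", "log", "indicator")


@dataclass(frozen=True)
class RiskEquation:
    """Logistic-link annual event probability on a linear predictor."""

    outcome: str
    coefficients: Mapping[str, float]  # covariate -> beta; "intercept" allowed
    transforms: Mapping[str, str] = field(default_factory=dict)
    link: str = "logistic"

    def linear_predictor(self, arrays: Mapping[str, np.ndarray]) -> np.ndarray:
        n = len(next(iter(arrays.values())))
        lp = np.full(n, float(self.coefficients.get("intercept", 0.0)))
        for cov, beta in self.coefficients.items():
            if cov == "intercept":
                continue
            if cov not in arrays:
                raise KeyError(
                    f"covariate {cov!r} required by outcome {self.outcome!r} "
                    "is missing from the patient state"
                )
            x = np.asarray(arrays[cov], dtype=float)
            tf = self.transforms.get(cov, "identity")
            if tf == "log":
                x = np.log(np.maximum(x, 1e-12))
            elif tf == "indicator":
                x = (x > 0).astype(float)
            elif tf != "identity":
                raise ValueError(f"unknown transform {tf!r} for {cov!r}")
            lp = lp + beta * x
        return lp

    def probability(self, arrays: Mapping[str, np.ndarray]) -> np.ndarray:
        if self.link != "logistic":
            raise ValueError(f"unsupported link {self.link!r}")
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(arrays)))


@dataclass
class LifeTable:
    """Sex-by-age annual death probabilities, ages 18-100."""

    ages: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray
    _warned: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        for q in (self.qx_male, self.qx_female):
            if np.any((q <= 0) | (q >= 1)):
                raise ValueError("life-table probabilities must lie in (0, 1)")

    def lookup(self, age, female) -> np.ndarray:
        """Annual death probability for given ages/sexes (terminal row beyond)."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        female = np.atleast_1d(np.asarray(female, dtype=float))
        if np.any(age > self.ages[-1]) and not self._warned:
            warnings.warn(
                "age beyond life-table range; using terminal row", stacklevel=2
            )
            self._warned = True
        idx = np.clip(np.searchsorted(self.ages, np.floor(age), side="right") - 1,
                      0, len(self.ages) - 1)
        return np.where(female > 0, self.qx_female[idx], self.qx_male[idx])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, qx in (("male", self.qx_male), ("female", self.qx_female)):
            for a, q in zip(self.ages, qx):
                rows.append({"sex": sex, "age": int(a), "qx": float(q)})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        m = df[df.sex == "male"].sort_values("age")
        f = df[df.sex == "female"].sort_values("age")
        return cls(m.age.to_numpy(), m.qx.to_numpy(), f.qx.to_numpy())


@dataclass
class RiskModel:
    """The full set of annual risk equations plus progression rules.

    ``progression`` maps a risk-factor name (hba1c, bmi, sbp, dbp) to its
    deterministic annual drift in the factor's own units.
    """

    equations: dict[str, RiskEquation]
    progression: dict[str, float] = field(default_factory=dict)
    life_table: LifeTable | None = None

    def __post_init__(self):
        missing = [o for o in OUTCOMES if o not in self.equations]
        if missing:
            raise ValueError(f"risk model lacks equations for outcomes: {missing}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "equations": {
                name: {
                    "link": eq.link,
                    "coefficients": dict(eq.coefficients),
                    "transforms": dict(eq.transforms),
                }
                for name, eq in self.equations.items()
            },
            "progression": dict(self.progression),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path, life_table: LifeTable | None = None) -> "RiskModel":
        payload = json.loads(Path(path).read_text())
        eqs = {
            name: RiskEquation(
                outcome=name,
                coefficients=spec["coefficients"],
                transforms=spec.get("transforms", {}),
                link=spec.get("link", "logistic"),
            )
            for name, spec in payload["equations"].items()
        }
        return cls(eqs, payload.get("progression", {}), life_table)


# ---------------------------------------------------------------------------
# cohort sampling

_CONTINUOUS_BASELINES = {
    "age": "Age_years",
    "duration": "Duration_diabetes_years",
    "hba1c": "Baseline_HbA1c",
    "bmi": "Baseline_BMI",
    "sbp": "Baseline_SBP",
    "dbp": "Baseline_DBP",
    "hdl": "Baseline_HDL",
    "ldl": "Baseline_LDL",
    "triglycerides": "Baseline_Triglycerides",
    "hemoglobin": "Baseline_Hemoglobin",
    "white_cell_count": "Baseline_White_cell_count",
    "egfr": "Baseline_eGFR",
}

_FLAG_BASELINES = {
    "female": "Prop_female",
    "insulin": "Insulin_usage_ratio",
    "noninsulin_agents": "Non_insulin_agent_usage_ratio",
    "antihypertensives": "Antihypertensives_usage_ratio",
    "statins": "Statins_usage_ratio",
    "atrial_fibrillation": "Prop_atrial_fibrillation",
    "mi": "Prop_MI",
    "ihd": "Prop_IHD",
    "heart_failure": "Prop_heart_failure",
    "stroke": "Prop_cerebrovascular_disease",
    "pvd": "Prop_PVD",
    "neuropathy": "Prop_neuropathy",
    "amputation": "Prop_amputation",
    "ulcer": "Prop_ulcer_of_skin",
    "renal_failure": "Prop_renal_failure",
    "retinopathy": "Prop_retinopathy",
    "cataract": "Prop_cataract",
}

_BOUNDS = {"age": (18.0, 110.0), "hba1c": (4.0, 20.0), "bmi": (10.0, 80.0)}


def sample_cohort(
    n: int,
    pset: ParameterSet,
    seed: int,
    draw: ParameterDraw | None = None,
) -> list[PatientState]:
    """Sample ``n`` independent baseline patients from the parameter table.

    Continuous baselines are drawn from their fitted uncertainty
    distributions (which double as the between-patient heterogeneity
    distributions), binary flags as Bernoulli at the stated proportions, and
    the CKD stage from the stated stage prevalences.  ``draw`` overrides the
    proportions (used by the PSA); baselines with degenerate specs are
    constant across patients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    values = draw.values if draw is not None else {p.name: p.value for p in pset}

    cols: dict[str, np.ndarray] = {}
    for field_name, pname in _CONTINUOUS_BASELINES.items():
        if pname not in pset:
            raise KeyError(f"missing baseline parameter {pname!r}")
        x = np.asarray(pset[pname].spec.sample(rng, size=n), dtype=float)
        if field_name in _BOUNDS:
            lo, hi = _BOUNDS[field_name]
            x = np.clip(x, lo, hi)
        cols[field_name] = x
    for field_name, pname in _FLAG_BASELINES.items():
        if pname not in pset:
            raise KeyError(f"missing baseline parameter {pname!r}")
        p = float(values.get(pname, pset[pname].value))
        cols[field_name] = (rng.random(n) < p).astype(int)

    # smoking: three-level categorical (current / past / never)
    p_cur = float(values.get("Prop_current_smoker", pset["Prop_current_smoker"].value))
    p_past = float(values.get("Prop_past_smoker", pset["Prop_past_smoker"].value))
    u = rng.random(n)
    cols["smoker_current"] = (u < p_cur).astype(int)
    cols["smoker_past"] = ((u >= p_cur) & (u < p_cur + p_past)).astype(int)

    # CKD stage multinomial from stage prevalences
    stage_p = np.array(
        [
            float(values.get("Prop_mild_CKD", pset["Prop_mild_CKD"].value)),
            float(values.get("Prop_mild_moderate_CKD", pset["Prop_mild_moderate_CKD"].value)),
            float(values.get("Prop_moderate_severe_CKD", pset["Prop_moderate_severe_CKD"].value)),
            float(values.get("Prop_severe_CKD", pset["Prop_severe_CKD"].value)),
        ]
    )
    cum = np.cumsum(stage_p)
    u = rng.random(n)
    stage = np.zeros(n, dtype=int)
    for k in range(len(cum)):
        lower = 0.0 if k == 0 else cum[k - 1]
        stage[(u >= lower) & (u < cum[k])] = k + 1
    cols["ckd_stage"] = stage

    cohort = []
    for i in range(n):
        kwargs = {k: (float(v[i]) if k in _CONTINUOUS_BASELINES else int(v[i]))
                  for k, v in cols.items()}
        cohort.append(PatientState(**kwargs))
    return cohort


# ---------------------------------------------------------------------------
# per-cycle evaluations


def _state_arrays(state: PatientState | Mapping[str, np.ndarray]) -> Mapping[str, np.ndarray]:
    if isinstance(state, PatientState):
        if not state.alive:
            raise ValueError("dead patients are never advanced")
        return state.as_arrays()
    return state


def annual_event_probability(
    equation: RiskEquation, state: PatientState | Mapping[str, np.ndarray]
):
    """Annual probability of ``equation``'s outcome for the given state."""
    p = equation.probability(_state_arrays(state))
    return float(p[0]) if isinstance(state, PatientState) else p


def death_probability(
    state: PatientState | Mapping[str, np.ndarray],
    model: RiskModel,
    life_table: LifeTable | None = None,
    blending: str = "max",
):
    """All-cause annual death probability, floored at natural mortality.

    ``blending="max"`` (default) takes the larger of the model's all-cause
    equation and the life-table probability; ``blending="additive"`` combines
    the two as independent hazards: 1-(1-p_model)(1-q_table).
    """
    arrays = _state_arrays(state)
    table = life_table if life_table is not None else model.life_table
    p_model = model.equations["mortality"].probability(arrays)
    if table is None:
        out = p_model
    else:
        q = table.lookup(arrays["age"], arrays["female"])
        if blending == "max":
            out = np.maximum(p_model, q)
        elif blending == "additive":
            out = 1.0 - (1.0 - p_model) * (1.0 - q)
        else:
            raise ValueError(f"unknown blending {blending!r}")
    return float(out[0]) if isinstance(state, PatientState) else out


_PROGRESSION_FIELDS = ("hba1c", "bmi", "sbp", "dbp")


def progress_risk_factors(
    state: PatientState, model: RiskModel, year: int | None = None
) -> PatientState:
    """One deterministic annual update: drift + age/duration increment."""
    if not state.alive:
        raise ValueError("dead patients are never advanced")
    updates = {"age": min(state.age + 1.0, 110.0), "duration": state.duration + 1.0,
               "years_on_treatment": state.years_on_treatment + 1.0}
    for f in _PROGRESSION_FIELDS:
        drift = float(model.progression.get(f, 0.0))
        updates[f] = getattr(state, f) + drift
    for f, (lo, hi) in _BOUNDS.items():
        if f in updates:
            updates[f] = float(np.clip(updates[f], lo, hi))
    return replace(state, **updates)
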