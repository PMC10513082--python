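"""Per-patient lifetime microsimulation of one treatment arm.

Annual cycles over a lifetime horizon: a 6-month treatment effect applied at
initiation, trial-period adverse events in the first year, a switch from the
GLP-1 receptor agonist to basal insulin glargine at the start of year six,
annual complication events from the risk engine, deterministic risk-factor
progression, and cost/QALY accrual with end-of-cycle discounting.

Common random numbers: every stochastic decision draws from a purpose-keyed
stream derived from the simulation seed, in a fixed order each cycle, for
every patient whether alive or dead.  Two arms run with the same seed
therefore differ only through their treatment parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ParameterDraw
from .riskengine import (
    EVENT_OUTCOMES,
    PatientState,
    RiskModel,
    _NUMERIC_FIELDS,
)

__all__ = [
    "COMPLICATION_CATEGORIES",
    "DoseSegment",
    "TreatmentProfile",
    "Trajectory",
    "CycleRecord",
    "SimulationResult",
    "default_profiles",
    "profiles_from_effects",
    "apply_treatment_effects",
    "simulate_patient",
    "accrue_costs",
    "accrue_utilities",
    "discount_stream",
    "run_arm",
]

#: complication ledger categories (breakdown-table column order)
COMPLICATION_CATEGORIES = (
    "amputation",
    "cataract",
    "mi",
    "pvd",
    "retinopathy",
    "heart_failure",
    "ihd",
    "renal_failure",
    "stroke",
    "neuropathy",
    "ulcer",
    "hypoglycemia",
)

# (event-year cost parameter, following-year cost parameter) per category
_EVENT_COST = {
    "mi": ("Cost_MI_event_year", "Cost_MI_per_following_year"),
    "stroke": ("Cost_Stroke_event_year", "Cost_Stroke_per_following_year"),
    "heart_failure": ("Cost_CHF_first_year", "Cost_CHF_per_following_year"),
    "renal_failure": ("Cost_Renal_failure_per_year", "Cost_Renal_failure_per_year"),
    "ulcer": ("Cost_Skin_ulcer_event_year", "Cost_Care_for_skin_per_following_year"),
    "pvd": ("Cost_PVD_event_year", "Cost_PVD_per_following_year"),
    "amputation": ("Cost_Amputation_event_year", "Cost_Amputation_per_following_year"),
    "neuropathy": ("Cost_Neuropathy_event_year", "Cost_Neuropathy_per_following_year"),
    "ihd": ("Cost_IHD_event_year", "Cost_IHD_per_following_year"),
    "retinopathy": ("Cost_Retinopathy_per_event", None),
    "cataract": ("Cost_Cataract_event_year", "Cost_Cataract_per_following_year"),
}

# (event-year disutility, persistent disutility) per category
_EVENT_DISU = {
    "mi": ("Disu_MI_hospitalization_year", "Disu_MI_after_discharge"),
    "stroke": ("Disu_Stroke_hospitalization", "Disu_Stroke_after_discharge"),
    "heart_failure": ("Disu_CHF", "Disu_CHF"),
    "renal_failure": ("Disu_Renal_failure", "Disu_Renal_failure"),
    "neuropathy": ("Disu_Neuropathy", "Disu_Neuropathy"),
    "amputation": ("Disu_Amputation", "Disu_Post_amputation"),
    "ulcer": ("Disu_Skin_ulcer", "Disu_Skin_ulcer"),
    "retinopathy": ("Disu_Retinopathy", "Disu_Retinopathy"),
    "cataract": ("Disu_Cataract", "Disu_Cataract"),
    "pvd": ("Disu_PVD", "Disu_PVD"),
    "ihd": ("Disu_IHD", "Disu_IHD"),
}

_MAX_AGE = 110.0
_ENDPOINT_FIELDS = ("hba1c", "bmi", "sbp", "dbp")


@dataclass(frozen=True)
class DoseSegment:
    """A titration step: ``dose`` per period for ``count`` periods."""

    dose: float
    period: str  # 'day' or 'week'
    count: int


@dataclass
class TreatmentProfile:
    """One regimen: dosing/titration, pack pricing, AEs, 6-month effects.

    ``pack_content`` is the amount of active substance per pack in the same
    units as ``maintenance_dose``; the unit price is the drawn pack price
    divided by the content.  ``effects`` maps endpoint (hba1c/bmi/sbp/dbp) to
    the arm's absolute 6-month change rate (fraction of baseline, negative =
    reduction).
    """

    name: str
    price_param: str
    pack_content: float
    maintenance_dose: float
    dose_period: str = "day"
    titration: tuple[DoseSegment, ...] = ()
    ae_params: tuple[str, ...] = ()
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.maintenance_dose <= 0 or self.pack_content <= 0:
            raise ValueError(f"{self.name}: doses and pack content must be positive")
        if self.dose_period not in ("day", "week"):
            raise ValueError(f"{self.name}: dose_period must be 'day' or 'week'")

    def annual_drug_cost(self, draw: ParameterDraw, year: int) -> float:
        """Drug cost for simulation year ``year`` (1-based), USD."""
        unit_price = draw[self.price_param] / self.pack_content
        periods = 365 if self.dose_period == "day" else 52
        if year == 1 and self.titration:
            cost, used = 0.0, 0
            for seg in self.titration:
                if seg.period != self.dose_period:
                    raise ValueError(
                        f"{self.name}: titration period {seg.period!r} differs "
                        f"from dosing period {self.dose_period!r}"
                    )
                cost += seg.dose * seg.count * unit_price
                used += seg.count
            cost += self.maintenance_dose * max(periods - used, 0) * unit_price
            return cost
        return self.maintenance_dose * periods * unit_price


def profiles_from_effects(
    effects: Mapping[str, Mapping[str, float]]
) -> dict[str, TreatmentProfile]:
    """Build the six regimen profiles with the given per-arm change rates."""
    ae = {
        "exenatide": ("AE_exenatide_nausea", "AE_exenatide_diarrhea",
                      "AE_exenatide_urti", "AE_exenatide_vomiting",
                      "AE_exenatide_dizziness", "AE_exenatide_sinusitis",
                      "AE_exenatide_hypoglycemia", "AE_exenatide_back_pain"),
        "loxenatide": ("AE_loxenatide_nausea", "AE_loxenatide_diarrhea",
                       "AE_loxenatide_vomiting", "AE_loxenatide_hypoglycemia"),
        "semaglutide": ("AE_semaglutide_nausea", "AE_semaglutide_diarrhea",
                        "AE_semaglutide_urti", "AE_semaglutide_vomiting",
                        "AE_semaglutide_dizziness", "AE_semaglutide_sinusitis",
                        "AE_semaglutide_constipation", "AE_semaglutide_hypoglycemia",
                        "AE_semaglutide_lipase_increased",
                        "AE_semaglutide_decreased_appetite"),
        "dulaglutide": ("AE_dulaglutide_nausea", "AE_dulaglutide_diarrhea",
                        "AE_dulaglutide_vomiting", "AE_dulaglutide_dizziness",
                        "AE_dulaglutide_sinusitis",
                        "AE_dulaglutide_decreased_appetite"),
        "liraglutide": ("AE_liraglutide_nausea", "AE_liraglutide_diarrhea",
                        "AE_liraglutide_vomiting", "AE_liraglutide_dizziness",
                        "AE_liraglutide_sinusitis", "AE_liraglutide_constipation",
                        "AE_liraglutide_decreased_appetite"),
        "lixisenatide": ("AE_lixisenatide_nausea", "AE_lixisenatide_diarrhea",
                         "AE_lixisenatide_vomiting",
                         "AE_lixisenatide_hypoglycemia"),
    }
    profiles = {
        "exenatide": TreatmentProfile(
            "exenatide", "Cost_exenatide_600ug", 600.0, 20.0, "day",
            titration=(DoseSegment(10.0, "day", 28),), ae_params=ae["exenatide"]),
        "liraglutide": TreatmentProfile(
            "liraglutide", "Cost_liraglutide_18mg", 18.0, 1.8, "day",
            titration=(DoseSegment(0.6, "day", 7), DoseSegment(1.2, "day", 7)),
            ae_params=ae["liraglutide"]),
        "loxenatide": TreatmentProfile(
            "loxenatide", "Cost_loxenatide_100ug", 100.0, 100.0, "week",
            ae_params=ae["loxenatide"]),
        "dulaglutide": TreatmentProfile(
            "dulaglutide", "Cost_dulaglutide_1.5mg", 1.5, 1.5, "week",
            ae_params=ae["dulaglutide"]),
        "semaglutide": TreatmentProfile(
            "semaglutide", "Cost_semaglutide_2mg", 2.0, 1.0, "week",
            titration=(DoseSegment(0.25, "week", 4), DoseSegment(0.5, "week", 4)),
            ae_params=ae["semaglutide"]),
        "lixisenatide": TreatmentProfile(
            # pen of 14 x 20 ug doses
            "lixisenatide", "Cost_lixisenatide_20ug", 280.0, 20.0, "day",
            titration=(DoseSegment(10.0, "day", 7), DoseSegment(15.0, "day", 7)),
            ae_params=ae["lixisenatide"]),
    }
    for name, prof in profiles.items():
        if name not in effects:
            raise KeyError(f"no effect set supplied for arm {name!r}")
        prof.effects = dict(effects[name])
    return profiles


def default_profiles() -> dict[str, TreatmentProfile]:
    """Profiles with the packaged synthetic true 6-month change rates."""
    from .synthetic import DEFAULT_TRUE_EFFECTS

    return profiles_from_effects(
        {k: v for k, v in DEFAULT_TRUE_EFFECTS.items() if k != "placebo"}
    )


# ---------------------------------------------------------------------------
# records


@dataclass
class CycleRecord:
    """One simulated year for one (or a vector of) patients."""

    year: int
    alive_start: np.ndarray          # accruing this cycle
    died: np.ndarray                 # death fired this cycle
    events_fired: dict[str, np.ndarray]
    flags_before: dict[str, np.ndarray]  # comorbidity flags at cycle start
    state: dict[str, np.ndarray]     # post-effect risk factors at cycle start
    baseline_bmi: np.ndarray
    hypo_events: np.ndarray          # severe hypoglycaemia fired this cycle
    ae_fired: dict[str, np.ndarray]  # year-1 trial AEs (empty otherwise)
    on_glp1: bool
    drug_cost: float | np.ndarray = 0.0


@dataclass
class Trajectory:
    """Cycle-by-cycle record of a single simulated patient."""

    records: list[dict]
    death_year: int | None
    censored: bool


@dataclass
class SimulationResult:
    """Per-patient discounted totals for one arm."""

    arm: str
    cost: np.ndarray          # total discounted cost, USD
    qaly: np.ndarray          # total discounted QALYs
    life_years: np.ndarray    # undiscounted
    drug_cost: np.ndarray     # discounted drug + therapy component
    comp_cost: np.ndarray     # (n, 12) discounted complication cost ledger
    comp_disu: np.ndarray     # (n, 12) discounted complication disutility ledger
    censored: np.ndarray
    categories: tuple[str, ...] = COMPLICATION_CATEGORIES
    seed: int = 0
    horizon: int | None = None
    discount_rate: float = 0.05
    #: baseline covariates and post-effect (6-month) HbA1c/BMI per patient,
    #: for downstream association analyses
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.cost < -1e-9):
            raise ValueError("negative per-patient cost")

    @property
    def n(self) -> int:
        return len(self.cost)

    def summary(self, wtp: float = 12728.0) -> dict[str, float]:
        """Arm-level means with normal-approximation 95% CIs."""
        out = {"arm": self.arm, "n": self.n}
        for key, x in (("cost", self.cost), ("qaly", self.qaly),
                       ("life_years", self.life_years)):
            se = float(np.std(x, ddof=1) / math.sqrt(self.n)) if self.n > 1 else 0.0
            out[f"{key}_mean"] = float(np.mean(x))
            out[f"{key}_lo"] = float(np.mean(x) - 1.959964 * se)
            out[f"{key}_hi"] = float(np.mean(x) + 1.959964 * se)
        nmb = wtp * self.qaly - self.cost
        se = float(np.std(nmb, ddof=1) / math.sqrt(self.n)) if self.n > 1 else 0.0
        out["nmb_mean"] = float(np.mean(nmb))
        out["nmb_lo"] = float(np.mean(nmb) - 1.959964 * se)
        out["nmb_hi"] = float(np.mean(nmb) + 1.959964 * se)
        return out

    def per_patient_nmb(self, wtp: float) -> np.ndarray:
        return wtp * self.qaly - self.cost

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "arm": self.arm,
                "cost": self.cost,
                "qaly": self.qaly,
                "life_years": self.life_years,
                "drug_cost": self.drug_cost,
                "censored": self.censored,
            }
        )
        for name, col in self.covariates.items():
            df[name] = col
        for j, cat in enumerate(self.categories):
            df[f"cost_{cat}"] = self.comp_cost[:, j]
            df[f"disu_{cat}"] = self.comp_disu[:, j]
        df["comp_cost"] = self.comp_cost.sum(axis=1)
        df["comp_disu"] = self.comp_disu.sum(axis=1)
        return df


# ---------------------------------------------------------------------------
# elementary operations


def apply_treatment_effects(
    state: PatientState | dict[str, np.ndarray],
    profile: TreatmentProfile,
) -> PatientState | dict[str, np.ndarray]:
    """Apply the arm's 6-month change rates: x -> x * (1 + rate)."""
    missing = [e for e in _ENDPOINT_FIELDS if e not in profile.effects]
    if missing:
        raise KeyError(f"arm {profile.name!r} lacks effects for endpoints {missing}")
    if isinstance(state, PatientState):
        from dataclasses import replace

        return replace(
            state,
            **{e: getattr(state, e) * (1.0 + profile.effects[e]) for e in _ENDPOINT_FIELDS},
        )
    out = dict(state)
    for e in _ENDPOINT_FIELDS:
        out[e] = state[e] * (1.0 + profile.effects[e])
    return out


def discount_stream(values: Sequence[float], rate: float) -> float:
    """End-of-cycle discounted total: sum of v_t / (1+rate)^t, t from 1."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    v = np.asarray(values, dtype=float)
    t = np.arange(1, len(v) + 1)
    return float(np.sum(v / (1.0 + rate) ** t))


def accrue_costs(record: CycleRecord, draw: ParameterDraw) -> dict[str, np.ndarray]:
    """Undiscounted cycle costs by category for one cycle record.

    Returns ``{"drug", "therapy", "end_of_life", "<category>"...}`` arrays.
    Complication event years use the event-year cost, subsequent alive years
    the following-year cost; severe hypoglycaemia is costed per event.
    """
    n = len(record.alive_start)
    alive = record.alive_start.astype(float)
    out: dict[str, np.ndarray] = {}
    out["drug"] = np.asarray(record.drug_cost, dtype=float) * alive

    dur = record.state["duration"]
    therapy = np.zeros(n)
    if not record.on_glp1:
        therapy = np.where(
            dur >= 10.0,
            draw["Cost_Antidiabetic_therapy_ge10y"],
            np.where(dur > 5.0, draw["Cost_Antidiabetic_therapy_5_10y"], 0.0),
        )
    out["therapy"] = therapy * alive

    for cat in COMPLICATION_CATEGORIES:
        if cat == "hypoglycemia":
            c = draw["Cost_Hypoglycemia_per_event"] * record.hypo_events.astype(float)
            ae_hypo = np.zeros(n)
            for ae_name, fired in record.ae_fired.items():
                if ae_name.endswith("hypoglycemia"):
                    ae_hypo = ae_hypo + fired.astype(float)
            c = c + draw["Cost_Hypoglycemia_per_event"] * ae_hypo
            out[cat] = c * alive
            continue
        ev_param, follow_param = _EVENT_COST[cat]
        fired = record.events_fired.get(cat, np.zeros(n, dtype=bool))
        pre = record.flags_before.get(cat, np.zeros(n, dtype=bool))
        c = draw[ev_param] * fired.astype(float)
        if follow_param is not None:
            c = c + draw[follow_param] * (pre & ~fired).astype(float)
        out[cat] = c * alive

    out["end_of_life"] = draw["Cost_End-of-life"] * record.died.astype(float)
    for v in out.values():
        if np.any(v < 0):
            raise ValueError("negative cost component")
    return out


def accrue_utilities(
    record: CycleRecord,
    draw: ParameterDraw,
    bmi_decrease_is_gain: bool = True,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Cycle utility (floored at 0) and the per-category decrement ledger.

    utility = 1 - baseline T2DM disutility - active comorbidity decrements
    - first-year AE decrements - BMI deviation term.  The BMI term is
    relative to the patient's baseline BMI: each unit above it subtracts
    ``Disu_BMI_per_increase``; each unit below adds
    ``Utility_BMI_per_decrease`` (a gain, sign controlled by
    ``bmi_decrease_is_gain``).
    """
    n = len(record.alive_start)
    alive = record.alive_start.astype(float)
    decrements: dict[str, np.ndarray] = {}
    total = np.full(n, float(draw["Disu_T2DM_without_complications"]))

    for cat in COMPLICATION_CATEGORIES:
        if cat == "hypoglycemia":
            d = draw["Disu_Hypoglycemia"] * record.hypo_events.astype(float)
            for ae_name, fired in record.ae_fired.items():
                if ae_name.endswith("hypoglycemia"):
                    d = d + draw["Disu_Hypoglycemia"] * fired.astype(float)
            decrements[cat] = d * alive
            total = total + decrements[cat]
            continue
        ev_param, post_param = _EVENT_DISU[cat]
        fired = record.events_fired.get(cat, np.zeros(n, dtype=bool))
        pre = record.flags_before.get(cat, np.zeros(n, dtype=bool))
        d = draw[ev_param] * fired.astype(float) + draw[post_param] * (pre & ~fired).astype(float)
        decrements[cat] = d * alive
        total = total + decrements[cat]

    ae_extra = np.zeros(n)
    for ae_name, fired in record.ae_fired.items():
        if not ae_name.endswith("hypoglycemia"):
            ae_extra = ae_extra + draw["Disu_Grade12_AE"] * fired.astype(float)
    total = total + ae_extra * alive

    delta = record.state["bmi"] - record.baseline_bmi
    bmi_term = draw["Disu_BMI_per_increase"] * np.maximum(delta, 0.0)
    below = np.maximum(-delta, 0.0)
    if bmi_decrease_is_gain:
        bmi_term = bmi_term - draw["Utility_BMI_per_decrease"] * below
    else:
        bmi_term = bmi_term + draw["Utility_BMI_per_decrease"] * below
    total = total + bmi_term * alive

    utility = np.clip(1.0 - total, 0.0, 1.0) * alive
    return utility, decrements


# ---------------------------------------------------------------------------
# the engine

_PURPOSES = ("death",) + EVENT_OUTCOMES + ("hypoglycemia", "ae")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    return {
        p: np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(1000 + i,))
        )
        for i, p in enumerate(_PURPOSES)
    }


def _cohort_arrays(cohort: Sequence[PatientState]) -> dict[str, np.ndarray]:
    return {
        f: np.array([float(getattr(p, f)) for p in cohort], dtype=float)
        for f in _NUMERIC_FIELDS
    }


def _run(
    cohort: Sequence[PatientState],
    profile: TreatmentProfile,
    model: RiskModel,
    draw: ParameterDraw,
    seed: int,
    horizon: int | None,
    record_trajectory: bool = False,
    switch_year: int = 6,
    mortality_blending: str = "max",
    bmi_decrease_is_gain: bool = True,
) -> tuple[SimulationResult, list[dict]]:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)
    arrays = _cohort_arrays(cohort)
    pre_effect = {k: arrays[k].copy()
                  for k in ("age", "female", "duration", "sbp", "dbp",
                            "mi", "ihd", "heart_failure", "stroke")}
    arrays = apply_treatment_effects(arrays, profile)
    baseline_bmi = arrays["bmi"].copy()
    covariates = dict(pre_effect)
    covariates["hba1c"] = arrays["hba1c"].copy()  # post-effect (6-month) level
    covariates["bmi"] = arrays["bmi"].copy()

    rate = float(draw.get("Discount", 0.05))
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    streams = _streams(seed)
    alive = np.ones(n, dtype=bool)
    cats = list(COMPLICATION_CATEGORIES)
    cat_idx = {c: j for j, c in enumerate(cats)}

    disc_cost = np.zeros(n)
    disc_qaly = np.zeros(n)
    disc_drug = np.zeros(n)
    life_years = np.zeros(n)
    comp_cost = np.zeros((n, len(cats)))
    comp_disu = np.zeros((n, len(cats)))
    records: list[dict] = []

    insulin_dose = float(draw.get("Dose_insulin_glargine_IU_per_day", 8.0))
    metformin_dose = float(draw.get("Dose_metformin_mg_per_day", 1365.0))
    met_unit = draw["Cost_Metformin_500mg"] / 500.0
    ins_unit = draw["Cost_Insulin_glargine_300IU"] / 300.0
    hypo_rate = float(draw.get("Annual_incidence_severe_hypoglycemia", 0.01))

    year = 0
    while True:
        year += 1
        if horizon is not None and year > horizon:
            break
        if not alive.any():
            break
        alive_start = alive.copy()
        on_glp1 = year < switch_year

        # --- stochastic draws: fixed order and shape every cycle (CRN)
        u_death = streams["death"].random(n)
        u_events = {ev: streams[ev].random(n) for ev in EVENT_OUTCOMES}
        u_hypo = streams["hypoglycemia"].random(n)
        ae_fired: dict[str, np.ndarray] = {}
        if year == 1:
            for ae_name in profile.ae_params:
                u = streams["ae"].random(n)
                ae_fired[ae_name] = alive_start & (u < float(draw[ae_name]))

        # --- death (blended with natural mortality), evaluated first
        p_model = model.equations["mortality"].probability(arrays)
        if model.life_table is not None:
            q_nat = model.life_table.lookup(arrays["age"], arrays["female"])
            if mortality_blending == "max":
                p_death = np.maximum(p_model, q_nat)
            else:
                p_death = 1.0 - (1.0 - p_model) * (1.0 - q_nat)
        else:
            p_death = p_model
        p_death = np.where(arrays["age"] >= _MAX_AGE, 1.0, p_death)
        died = alive_start & (u_death < p_death)
        survivors = alive_start & ~died

        # --- complication events for survivors (absorbing flags)
        flags_before = {c: arrays[c] > 0 for c in cats if c != "hypoglycemia"}
        events_fired: dict[str, np.ndarray] = {}
        for ev in EVENT_OUTCOMES:
            p = model.equations[ev].probability(arrays)
            fire = survivors & ~(arrays[ev] > 0) & (u_events[ev] < p)
            events_fired[ev] = fire
        hypo_events = survivors & (u_hypo < hypo_rate) if year > 1 else np.zeros(n, dtype=bool)

        rec = CycleRecord(
            year=year,
            alive_start=alive_start,
            died=died,
            events_fired=events_fired,
            flags_before=flags_before,
            state={k: arrays[k] for k in ("duration", "bmi", "age", "hba1c", "sbp", "dbp")},
            baseline_bmi=baseline_bmi,
            hypo_events=hypo_events,
            ae_fired=ae_fired,
            on_glp1=on_glp1,
        )
        drug = profile.annual_drug_cost(draw, year) if on_glp1 else ins_unit * insulin_dose * 365.0
        if on_glp1:
            drug += met_unit * metformin_dose * 365.0
        rec.drug_cost = drug

        costs = accrue_costs(rec, draw)
        utility, decrements = accrue_utilities(rec, draw, bmi_decrease_is_gain)

        df_t = (1.0 + rate) ** (-year)
        total_cost = sum(costs.values())
        disc_cost += total_cost * df_t
        disc_drug += (costs["drug"] + costs["therapy"]) * df_t
        disc_qaly += utility * df_t
        life_years += alive_start.astype(float)
        for c in cats:
            comp_cost[:, cat_idx[c]] += costs[c] * df_t
            comp_disu[:, cat_idx[c]] += decrements[c] * df_t

        if record_trajectory:
            records.append(
                {
                    "year": year,
                    "alive_start": alive_start.copy(),
                    "died": died.copy(),
                    "events": {c: events_fired[c].copy() for c in events_fired},
                    "costs": {k: v.copy() for k, v in costs.items()},
                    "utility": utility.copy(),
                    "state": {k: v.copy() for k, v in rec.state.items()},
                }
            )

        # --- state update for survivors
        for ev, fire in events_fired.items():
            arrays[ev] = np.where(fire, 1.0, arrays[ev])
        for f, drift in model.progression.items():
            arrays[f] = np.where(survivors, arrays[f] + float(drift), arrays[f])
        arrays["hba1c"] = np.clip(arrays["hba1c"], 4.0, 20.0)
        arrays["bmi"] = np.clip(arrays["bmi"], 10.0, 80.0)
        arrays["age"] = np.where(survivors, np.minimum(arrays["age"] + 1.0, _MAX_AGE), arrays["age"])
        arrays["duration"] = np.where(survivors, arrays["duration"] + 1.0, arrays["duration"])
        if year == switch_year - 1:
            arrays["insulin"] = np.ones(n)
        alive = survivors

    result = SimulationResult(
        arm=profile.name,
        cost=disc_cost,
        qaly=disc_qaly,
        life_years=life_years,
        drug_cost=disc_drug,
        comp_cost=comp_cost,
        comp_disu=comp_disu,
        censored=alive.copy(),
        seed=seed,
        horizon=horizon,
        discount_rate=rate,
        covariates=covariates,
    )
    return result, records


def simulate_patient(
    state: PatientState,
    profile: TreatmentProfile,
    model: RiskModel,
    draw: ParameterDraw,
    seed: int,
    horizon: int | None = None,
    **kwargs,
) -> Trajectory:
    """Simulate one patient, returning the full cycle-by-cycle trajectory."""
    if not state.alive:
        raise ValueError("baseline state must be alive")
    result, records = _run([state], profile, model, draw, seed, horizon,
                           record_trajectory=True, **kwargs)
    death_year = None
    for r in records:
        if bool(r["died"][0]):
            death_year = r["year"]
            break
    flat = [
        {
            "year": r["year"],
            "alive_start": bool(r["alive_start"][0]),
            "died": bool(r["died"][0]),
            "events": sorted(c for c, f in r["events"].items() if f[0]),
            "costs": {k: float(v[0]) for k, v in r["costs"].items()},
            "utility": float(r["utility"][0]),
            "state": {k: float(v[0]) for k, v in r["state"].items()},
        }
        for r in records
        if r["alive_start"][0]
    ]
    return Trajectory(records=flat, death_year=death_year,
                      censored=bool(result.censored[0]))


def run_arm(
    cohort: Sequence[PatientState],
    profile: TreatmentProfile,
    model: RiskModel,
    draw: ParameterDraw,
    seed: int,
    horizon: int | None = None,
    **kwargs,
) -> SimulationResult:
    """Simulate the whole cohort under one arm with common random numbers."""
    result, _ = _run(cohort, profile, model, draw, seed, horizon, **kwargs)
    return result
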