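import numpy as np
import pytest

from glp1ce.params import packaged_parameters
from glp1ce.riskengine import PatientState, RiskEquation, RiskModel, sample_cohort
from glp1ce.synthetic import constant_life_table, default_risk_model
from glp1ce.microsim import default_profiles


@pytest.fixture(scope="session")
def pset():
    return packaged_parameters()


@pytest.fixture(scope="session")
def base_draw(pset):
    return pset.base_draw()


@pytest.fixture(scope="session")
def risk_model():
    return default_risk_model()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_cohort(pset):
    return sample_cohort(300, pset, seed=123)


def immortal_risk_model(progression=None, life_table=None):
    """Risk model in which nothing ever happens (event probs ~ 1e-26)."""
    eqs = {
        o: RiskEquation(o, {"intercept": -60.0})
        for o in (
            "mortality", "mi", "ihd", "heart_failure", "stroke", "pvd",
            "neuropathy", "amputation", "ulcer", "renal_failure",
            "cataract", "retinopathy",
        )
    }
    return RiskModel(eqs, progression or {}, life_table)


@pytest.fixture()
def zero_event_model():
    return immortal_risk_model()


@pytest.fixture()
def constant_mortality_model():
    """No complications; death only through a flat q = 0.02 life table."""
    return immortal_risk_model(life_table=constant_life_table(0.02))


def clean_profile(name="testdrug", effects=None):
    """A costless, AE-free profile with the given (default zero) effects."""
    from glp1ce.microsim import TreatmentProfile

    return TreatmentProfile(
        name=name,
        price_param="__zero_price",
        pack_content=1.0,
        maintenance_dose=1.0,
        dose_period="day",
        effects=effects or {"hba1c": 0.0, "bmi": 0.0, "sbp": 0.0, "dbp": 0.0},
    )


@pytest.fixture()
def zero_cost_draw(base_draw):
    return base_draw.replace(
        __zero_price=0.0,
        Cost_Metformin_500mg=0.0,
        Cost_Insulin_glargine_300IU=0.0,
        Cost_Antidiabetic_therapy_5_10y=0.0,
        Cost_Antidiabetic_therapy_ge10y=0.0,
        Annual_incidence_severe_hypoglycemia=0.0,
    )
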