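"""Shared fixtures: small simulated registries/cohorts and a hand-built
ten-person registry with known, hand-derived eligibility outcomes."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import t2dmace as t

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

logging.getLogger("t2dmace").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_registry():
    cfg = t.SimulationConfig(n_persons=400, seed=101)
    return t.generate_registry(cfg), cfg


@pytest.fixture(scope="session")
def fixed_cohort():
    """A fixed synthetic analysis cohort (n=500, seeded)."""
    return t.simulate_cohort(t.SimulationConfig(n_persons=500, seed=2024))


@pytest.fixture(scope="session")
def fitted_models(fixed_cohort):
    prop = t.fit_mediator_propensities(fixed_cohort)
    haz = t.fit_mace_hazard(fixed_cohort)
    return prop, haz


def _date(s):
    return pd.Timestamp(s)


@pytest.fixture(scope="session")
def ten_person_registry():
    """Ten hand-built persons; three violate distinct eligibility rules.

    All first HbA1c measurements fall on 2015-01-01, so the index date is
    2015-06-30 (180 days later).  Hand-derived expectations are returned
    alongside the tables.
    """
    first = _date("2015-01-01")
    index = first + pd.Timedelta(days=180)

    def _person(pid, age, sex, death=None, emig=None):
        return {
            "person_id": pid,
            "birth_date": first - pd.Timedelta(days=round(age * 365.25)),
            "sex": sex,
            "cohabitation": "cohabiting",
            "income_quartile": "Q2",
            "education": "secondary",
            "ethnicity": "native",
            "death_date": death,
            "emigration_date": emig,
        }

    persons = pd.DataFrame(
        [
            _person("H01", 55, "F"),
            _person("H02", 62, "M", death=index + pd.Timedelta(days=round(2.0 * 365.25))),
            _person("H03", 45, "F", death=index + pd.Timedelta(days=round(1.0 * 365.25))),
            _person("H04", 70, "M", emig=index + pd.Timedelta(days=round(1.5 * 365.25))),
            _person("H05", 50, "F"),
            _person("H06", 58, "M"),
            _person("H07", 41, "F"),
            _person("H08", 66, "M"),
            _person("H09", 52, "F"),
            _person("H10", 60, "M", death=first + pd.Timedelta(days=90)),
        ]
    )

    def _lab(pid, day, analyte, value, requester="GP"):
        return {
            "person_id": pid,
            "sample_date": first + pd.Timedelta(days=day),
            "analyte": analyte,
            "value": value,
            "unit": "mmol/mol" if analyte == "HbA1c" else "umol/l",
            "requester": requester,
        }

    labs = pd.DataFrame(
        [
            _lab("H01", 0, "HbA1c", 50), _lab("H01", 100, "HbA1c", 45),
            _lab("H02", 0, "HbA1c", 53), _lab("H02", 150, "HbA1c", 44),
            _lab("H03", 0, "HbA1c", 50), _lab("H03", 120, "HbA1c", 50),
            _lab("H04", 0, "HbA1c", 55), _lab("H04", 120, "HbA1c", 50),
            _lab("H05", 0, "HbA1c", 49), _lab("H05", 110, "HbA1c", 44),
            # creatinine 80 umol/l -> 0.905 mg/dl, eGFR ~69 for F age 50
            _lab("H05", -30, "creatinine", 80.0),
            _lab("H06", 0, "HbA1c", 51), _lab("H06", 130, "HbA1c", 49),
            _lab("H07", 0, "HbA1c", 48), _lab("H07", 90, "HbA1c", 46),
            _lab("H08", 0, "HbA1c", 58), _lab("H08", 95, "HbA1c", 52),
            _lab("H09", 0, "HbA1c", 50), _lab("H09", 100, "HbA1c", 47),
            _lab("H10", 0, "HbA1c", 52),
        ]
    )

    def _rx(pid, day, atc):
        return {"person_id": pid, "dispense_date": first + pd.Timedelta(days=day), "atc_code": atc}

    prescriptions = pd.DataFrame(
        [
            _rx("H02", 30, "A10BA02"),   # GLDT day 30
            _rx("H02", 180, "C10AA05"),  # statin on the index date itself
            _rx("H03", 60, "A10BA02"),
            _rx("H03", 5, "C09AA02"), _rx("H03", 90, "C09AA02"),
            _rx("H05", -200, "C10AA05"),  # outside the 180-day prior lookback
            _rx("H07", 10, "A10BA02"),
            _rx("H09", -100, "A10BA02"),  # prior GLDT -> excluded
        ]
    )

    def _dx(pid, date, icd, primary=True):
        return {"person_id": pid, "discharge_date": date, "icd10_code": icd, "is_primary": primary}

    diagnoses = pd.DataFrame(
        [
            _dx("H05", index - pd.Timedelta(days=round(9 * 365.25)), "I500"),   # HF, inside 10y
            _dx("H06", index - pd.Timedelta(days=round(11 * 365.25)), "C349"),  # cancer, outside
            _dx("H03", index + pd.Timedelta(days=round(1.0 * 365.25)), "I219"),  # MI, same day as death
            _dx("H04", index + pd.Timedelta(days=round(3.0 * 365.25)), "I639"),  # stroke after emigration
        ]
    )

    expected = {
        "n_cohort": 7,
        "excluded": {
            "first HbA1c within 48-57 band": ["H08"],
            "no prior GLDT or diabetes diagnosis": ["H09"],
            "alive, in country and IHD/stroke/PAD-free at index": ["H10"],
        },
        "exposure": {
            "H01": "REMISSION",
            "H02": "WC_GLDT",
            "H03": "PC_GLDT",
            "H04": "PERSISTENT",
            "H05": "REMISSION",
            "H06": "PERSISTENT",
            "H07": "WC_GLDT",
        },
        "m_statin": {"H02": 1, "H01": 0, "H03": 0, "H04": 0, "H05": 0, "H06": 0, "H07": 0},
        "m_rasi": {"H03": 1, "H01": 0, "H02": 0, "H04": 0, "H05": 0, "H06": 0, "H07": 0},
        "followup": {
            "H02": (round(2.0 * 365.25) / 365.25, 1, "death"),
            "H03": (round(1.0 * 365.25) / 365.25, 1, "MI"),
            "H04": (round(1.5 * 365.25) / 365.25, 0, "none"),
        },
        "hf": {"H05": 1, "H06": 0},
        "cancer": {"H06": 0},
        "egfr_band": {"H05": "60-89", "H07": "unknown"},
    }
    bundle = t.RegistryBundle(persons, labs, prescriptions, diagnoses)
    return bundle, expected
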