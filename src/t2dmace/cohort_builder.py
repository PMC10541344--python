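"""Cohort construction from raw registry tables.

Turns the four register-style tables (persons, labs, prescriptions,
diagnoses) into the analysis cohort: locate the first diagnostic HbA1c
(>= 48 mmol/mol), apply the inclusion/exclusion rules in flow-chart order
with a complete attrition log, classify the four exposure groups at the
index date, and derive mediators, covariates and follow-up.

Conventions (the source registers leave these open; they are fixed here and
exercised by tests):

* the exposure/mediator window is half-open on the left and closed on the
  right: (first-HbA1c date, index date];
* a prescription on or before the first-HbA1c date counts as *prior* use;
* for persons on GLDT only HbA1c measurements strictly after the first GLDT
  redemption qualify for classification;
* ties between MACE components on the same day resolve MI > stroke > death,
  so death never masks a same-day cardiovascular code; an event on the same
  day as a censoring counts as an event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._design import AGE_BANDS, COVARIATE_FLAGS

__all__ = [
    "EligibilityConfig",
    "AttritionLog",
    "SchemaError",
    "ClassificationError",
    "DataIntegrityError",
    "compute_egfr_ckdepi",
    "build_cohort",
    "classify_exposure",
    "derive_mediators",
]

DAYS_PER_YEAR = 365.25
FIVE_YEARS_DAYS = 1826.25


class SchemaError(ValueError):
    """A registry table is missing a mandatory column."""


class ClassificationError(ValueError):
    """Exposure classification requested without a qualifying HbA1c."""


class DataIntegrityError(ValueError):
    """Derived follow-up time is negative."""


def _default_code_lists() -> dict:
    # Documented approximations of the register code lists (ICD-10 / ATC
    # prefixes; the lab rules for eGFR and haemoglobin are hard-wired).
    return {
        "prior_diabetes_icd": ("E10", "E11", "E12", "E13", "E14", "O240", "O241", "O242", "O243"),
        "prior_gldt_atc": ("A10",),
        "prior_cvd_icd": ("I20", "I21", "I22", "I23", "I24", "I25", "I63", "I64", "I70", "I71", "I72", "I73", "I74"),
        "hba1c_invalidating_icd": ("D55", "D56", "D57", "D58", "D59", "K70", "K74"),
        "statin_atc": ("C10AA",),
        "rasi_atc": ("C09",),
        "hypertension_icd": ("I10", "I11", "I12", "I13", "I15"),
        "comorbidity_icd": {
            "hf": ("I50",),
            "af": ("I48",),
            "copd_asthma": ("J44", "J45"),
            "cancer": tuple(f"C{i:02d}" for i in range(0, 98)),
        },
        "comorbidity_atc": {"hf": (), "af": (), "copd_asthma": (), "cancer": ()},
        "mace_icd": {"MI": ("I21", "I22"), "stroke": ("I61", "I63", "I64")},
    }


@dataclass
class EligibilityConfig:
    hba1c_diag_threshold: float = 48.0
    hba1c_upper: float = 57.0
    age_min: float = 40.0
    age_max: float = 80.0
    index_offset_days: int = 180
    prior_statin_rasi_lookback_days: int = 180
    comorbidity_lookback_years: float = 10.0
    egfr_exclusion_threshold: float = 30.0
    haemoglobin_exclusion_threshold: float = 6.83
    lab_lookback_days: int = 180
    end_of_study_date: pd.Timestamp = pd.Timestamp("2022-01-31")
    exclude_hypertension: bool = False
    code_lists: dict = field(default_factory=_default_code_lists)

    def validate(self) -> None:
        if self.hba1c_diag_threshold <= 0 or self.hba1c_upper <= 0:
            raise ValueError("HbA1c thresholds must be positive")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.index_offset_days <= 0:
            raise ValueError("index_offset_days must be a positive integer")


@dataclass
class AttritionLog:
    """Ordered flow-chart record of (filter, n excluded, n remaining)."""

    steps: list = field(default_factory=list)

    def add(self, name: str, n_excluded: int, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][2]:
            raise ValueError("attrition log must be non-increasing")
        self.steps.append((name, int(n_excluded), int(n_remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_excluded", "n_remaining"])

    def __str__(self) -> str:  # human-readable flow chart
        lines = []
        for name, excl, rem in self.steps:
            lines.append(f"{name:<42s} excluded {excl:>7d}   remaining {rem:>7d}")
        return "\n".join(lines)


def compute_egfr_ckdepi(creatinine_mgdl, age_years, sex):
    """2009 CKD-EPI estimated glomerular filtration rate.

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^(-1.209) * 0.993^age
    * 1.018 [if female], with k = 0.7 (F) / 0.9 (M) and alpha = -0.329 (F)
    / -0.411 (M).  The race coefficient of the published equation is
    omitted: the registries carry no such field.  Units: creatinine mg/dl
    (divide umol/l values by 88.4), result ml/min per 1.73 m^2.
    """
    scr = np.asarray(creatinine_mgdl, dtype=float)
    age = np.asarray(age_years, dtype=float)
    sex = np.asarray(sex, dtype=object)
    if (scr <= 0).any() or (age <= 0).any():
        raise ValueError("creatinine and age must be positive")
    female = sex == "F"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** (-1.209)
        * 0.993**age
        * np.where(female, 1.018, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def _require_columns(df: pd.DataFrame, table: str, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing column(s): {missing}")


def _prefix_mask(codes: pd.Series, prefixes) -> pd.Series:
    if not prefixes:
        return pd.Series(False, index=codes.index)
    return codes.astype(str).str.startswith(tuple(prefixes))


def derive_mediators(prescriptions: pd.DataFrame, first_date, index_date, code_lists=None):
    """Mediator pair for a single person: 1 iff >= 1 redemption of the
    respective ATC prefix in the exposure window (first_date, index_date]."""
    code_lists = code_lists or _default_code_lists()
    if len(prescriptions) == 0:
        return 0, 0
    d = prescriptions["dispense_date"]
    in_window = (d > first_date) & (d <= index_date)
    atc = prescriptions["atc_code"]
    m_statin = int((in_window & _prefix_mask(atc, code_lists["statin_atc"])).any())
    m_rasi = int((in_window & _prefix_mask(atc, code_lists["rasi_atc"])).any())
    return m_statin, m_rasi


def classify_exposure(on_gldt: bool, latest_hba1c_value, threshold: float = 48.0) -> str:
    """Four-group exposure label from GLDT status and the most recent
    qualifying HbA1c at index.  Raises if no qualifying value exists (such
    persons must have been excluded upstream)."""
    if latest_hba1c_value is None or (
        isinstance(latest_hba1c_value, float) and math.isnan(latest_hba1c_value)
    ):
        raise ClassificationError("no qualifying HbA1c measurement before index")
    controlled = latest_hba1c_value < threshold
    if on_gldt:
        return "WC_GLDT" if controlled else "PC_GLDT"
    return "REMISSION" if controlled else "PERSISTENT"


def build_cohort(registry, config: EligibilityConfig | None = None):
    """Apply the flow-chart eligibility rules and derive the analysis cohort.

    Returns ``(cohort, attrition_log)`` where ``cohort`` has one row per
    eligible person (exposure, mediators, covariates, follow-up) and the log
    lists every filter with its exclusion count.  An empty eligible set
    yields an empty cohort with a complete log, not an error.
    """
    config = config or EligibilityConfig()
    config.validate()
    cl = config.code_lists

    persons, labs = registry.persons, registry.labs
    prescriptions, diagnoses = registry.prescriptions, registry.diagnoses
    _require_columns(
        persons,
        "persons",
        ["person_id", "birth_date", "sex", "cohabitation", "income_quartile", "ethnicity"],
    )
    _require_columns(labs, "labs", ["person_id", "sample_date", "analyte", "value", "requester"])
    _require_columns(prescriptions, "prescriptions", ["person_id", "dispense_date", "atc_code"])
    _require_columns(diagnoses, "diagnoses", ["person_id", "discharge_date", "icd10_code"])

    log = AttritionLog()
    n_source = persons["person_id"].nunique()

    # -- first diagnostic HbA1c ------------------------------------------
    hba1c = labs[labs["analyte"] == "HbA1c"].sort_values(
        ["person_id", "sample_date"], kind="mergesort"
    )
    diag = hba1c[hba1c["value"] >= config.hba1c_diag_threshold]
    first = diag.groupby("person_id", sort=True).first().reset_index()
    first = first.rename(columns={"sample_date": "first_date", "value": "first_value"})
    first = first[["person_id", "first_date", "first_value", "requester"]]
    log.add("first HbA1c >= threshold found", n_source - len(first), len(first))

    base = first.merge(
        persons.set_index("person_id"), left_on="person_id", right_index=True, how="left"
    )
    base["index_date"] = base["first_date"] + pd.to_timedelta(config.index_offset_days, unit="D")
    base["age_at_first"] = (base["first_date"] - base["birth_date"]).dt.days / DAYS_PER_YEAR

    def apply_filter(name: str, keep: pd.Series):
        nonlocal base
        n_before = len(base)
        base = base[keep.to_numpy()]
        log.add(name, n_before - len(base), len(base))

    apply_filter(
        "age 40-80 at first measurement",
        (base["age_at_first"] >= config.age_min) & (base["age_at_first"] <= config.age_max),
    )
    apply_filter("first HbA1c within 48-57 band", base["first_value"] <= config.hba1c_upper)

    # -- prior GLDT or prior diabetes diagnosis ---------------------------
    rx = prescriptions.merge(base[["person_id", "first_date", "index_date"]], on="person_id")
    dx = diagnoses.merge(base[["person_id", "first_date", "index_date"]], on="person_id")
    prior_gldt_ids = set(
        rx.loc[
            _prefix_mask(rx["atc_code"], cl["prior_gldt_atc"])
            & (rx["dispense_date"] <= rx["first_date"]),
            "person_id",
        ]
    )
    prior_dm_ids = set(
        dx.loc[
            _prefix_mask(dx["icd10_code"], cl["prior_diabetes_icd"])
            & (dx["discharge_date"] <= dx["first_date"]),
            "person_id",
        ]
    )
    apply_filter(
        "no prior GLDT or diabetes diagnosis",
        ~base["person_id"].isin(prior_gldt_ids | prior_dm_ids),
    )

    # -- conditions invalidating HbA1c ------------------------------------
    lab_look = pd.to_timedelta(config.lab_lookback_days, unit="D")
    lb = labs.merge(base[["person_id", "first_date", "sex", "age_at_first"]], on="person_id")
    lb_recent = lb[
        (lb["sample_date"] <= lb["first_date"]) & (lb["sample_date"] > lb["first_date"] - lab_look)
    ]
    crea = (
        lb_recent[lb_recent["analyte"] == "creatinine"]
        .sort_values(["person_id", "sample_date"], kind="mergesort")
        .groupby("person_id", sort=True)
        .last()
    )
    crea["egfr"] = compute_egfr_ckdepi(
        crea["value"].to_numpy() / 88.4, crea["age_at_first"].to_numpy(), crea["sex"].to_numpy()
    )
    low_egfr_ids = set(crea.index[crea["egfr"] < config.egfr_exclusion_threshold])
    hgb = (
        lb_recent[lb_recent["analyte"] == "haemoglobin"]
        .sort_values(["person_id", "sample_date"], kind="mergesort")
        .groupby("person_id", sort=True)
        .last()
    )
    anaemia_ids = set(hgb.index[hgb["value"] < config.haemoglobin_exclusion_threshold])
    invalidating_ids = set(
        dx.loc[
            _prefix_mask(dx["icd10_code"], cl["hba1c_invalidating_icd"])
            & (dx["discharge_date"] <= dx["first_date"]),
            "person_id",
        ]
    )
    apply_filter(
        "no condition invalidating HbA1c (eGFR<30, anaemia, other)",
        ~base["person_id"].isin(low_egfr_ids | anaemia_ids | invalidating_ids),
    )

    # -- prior statin / RASi ----------------------------------------------
    sr_look = pd.to_timedelta(config.prior_statin_rasi_lookback_days, unit="D")
    prior_sr = rx[
        _prefix_mask(rx["atc_code"], tuple(cl["statin_atc"]) + tuple(cl["rasi_atc"]))
        & (rx["dispense_date"] <= rx["first_date"])
        & (rx["dispense_date"] > rx["first_date"] - sr_look)
    ]
    apply_filter(
        "no statin/RASi within 180 days prior",
        ~base["person_id"].isin(set(prior_sr["person_id"])),
    )

    if config.exclude_hypertension:
        ht_ids = set(
            dx.loc[
                _prefix_mask(dx["icd10_code"], cl["hypertension_icd"])
                & (dx["discharge_date"] <= dx["first_date"]),
                "person_id",
            ]
        )
        apply_filter("no hypertension prior to first HbA1c", ~base["person_id"].isin(ht_ids))

    # -- at risk at index: alive, present, MACE/CVD-free -------------------
    alive = base["death_date"].isna() | (base["death_date"] > base["index_date"])
    present = base["emigration_date"].isna() | (base["emigration_date"] > base["index_date"])
    mace_prior_ids = set(
        dx.loc[
            _prefix_mask(dx["icd10_code"], cl["prior_cvd_icd"])
            & (dx["discharge_date"] <= dx["index_date"]),
            "person_id",
        ]
    )
    apply_filter(
        "alive, in country and IHD/stroke/PAD-free at index",
        alive & present & ~base["person_id"].isin(mace_prior_ids),
    )

    # -- required follow-up HbA1c -----------------------------------------
    win_rx = rx[
        _prefix_mask(rx["atc_code"], cl["prior_gldt_atc"])
        & (rx["dispense_date"] > rx["first_date"])
        & (rx["dispense_date"] <= rx["index_date"])
    ]
    gldt_date = win_rx.groupby("person_id", sort=True)["dispense_date"].min()
    base = base.merge(gldt_date.rename("gldt_date"), left_on="person_id", right_index=True, how="left")
    base["on_gldt"] = base["gldt_date"].notna()

    hb = hba1c.merge(
        base[["person_id", "first_date", "index_date", "gldt_date"]], on="person_id"
    )
    qual = hb[(hb["sample_date"] > hb["first_date"]) & (hb["sample_date"] <= hb["index_date"])]
    qual = qual[qual["gldt_date"].isna() | (qual["sample_date"] > qual["gldt_date"])]
    # last record in stable input order breaks same-date ties
    latest = (
        qual.sort_values(["person_id", "sample_date"], kind="mergesort")
        .groupby("person_id", sort=True)
        .last()
    )
    base = base.merge(
        latest["value"].rename("latest_hba1c"), left_on="person_id", right_index=True, how="left"
    )
    apply_filter(
        "follow-up HbA1c before index (post-GLDT if on GLDT)",
        base["latest_hba1c"].notna(),
    )

    if len(base) == 0:
        empty = pd.DataFrame(
            columns=["person_id", "index_date", "exposure", "m_statin", "m_rasi"]
        )
        return empty, log

    # -- exposure classification ------------------------------------------
    base["exposure"] = [
        classify_exposure(g, v, config.hba1c_diag_threshold)
        for g, v in zip(base["on_gldt"], base["latest_hba1c"])
    ]

    # -- mediators ---------------------------------------------------------
    ids = base["person_id"]
    win_all = rx[
        (rx["dispense_date"] > rx["first_date"]) & (rx["dispense_date"] <= rx["index_date"])
    ]
    statin_ids = set(win_all.loc[_prefix_mask(win_all["atc_code"], cl["statin_atc"]), "person_id"])
    rasi_ids = set(win_all.loc[_prefix_mask(win_all["atc_code"], cl["rasi_atc"]), "person_id"])
    base["m_statin"] = ids.isin(statin_ids).astype(int)
    base["m_rasi"] = ids.isin(rasi_ids).astype(int)

    # -- covariates ---------------------------------------------------------
    band_idx = np.clip(
        ((base["age_at_first"].to_numpy() - 40.0) // 5).astype(int), 0, len(AGE_BANDS) - 1
    )
    base["age_band"] = np.asarray(AGE_BANDS, dtype=object)[band_idx]
    base["first_hba1c_band"] = np.where(base["first_value"] <= 52, "48-52", "53-57")
    egfr = crea["egfr"].reindex(base["person_id"])
    conditions = [
        egfr.to_numpy() >= 90,
        egfr.to_numpy() >= 60,
        egfr.to_numpy() >= config.egfr_exclusion_threshold,
    ]
    base["egfr_band"] = np.select(conditions, [">=90", "60-89", "30-59"], default="unknown")
    base.loc[base["income_quartile"].isna(), "income_quartile"] = "unknown"

    look = pd.to_timedelta(config.comorbidity_lookback_years * DAYS_PER_YEAR, unit="D")
    dx_kept = dx[dx["person_id"].isin(set(ids))]
    rx_kept = rx[rx["person_id"].isin(set(ids))]
    for flag in COVARIATE_FLAGS:
        icd = cl["comorbidity_icd"].get(flag, ())
        atc = cl["comorbidity_atc"].get(flag, ())
        flag_dx = dx_kept[
            _prefix_mask(dx_kept["icd10_code"], icd)
            & (dx_kept["discharge_date"] <= dx_kept["index_date"])
            & (dx_kept["discharge_date"] > dx_kept["index_date"] - look)
        ]
        flag_ids = set(flag_dx["person_id"])
        if atc:
            flag_rx = rx_kept[
                _prefix_mask(rx_kept["atc_code"], atc)
                & (rx_kept["dispense_date"] <= rx_kept["index_date"])
                & (rx_kept["dispense_date"] > rx_kept["index_date"] - look)
            ]
            flag_ids |= set(flag_rx["person_id"])
        base[flag] = ids.isin(flag_ids).astype(int)

    # -- follow-up -----------------------------------------------------------
    mace_dx = dx[dx["person_id"].isin(set(ids))]
    comp_dates = {}
    for comp, prefixes in cl["mace_icd"].items():
        d = mace_dx[
            _prefix_mask(mace_dx["icd10_code"], prefixes)
            & (mace_dx["discharge_date"] > mace_dx["index_date"])
        ]
        comp_dates[comp] = d.groupby("person_id", sort=True)["discharge_date"].min()
    mi = comp_dates["MI"].reindex(base["person_id"]).to_numpy()
    stroke = comp_dates["stroke"].reindex(base["person_id"]).to_numpy()
    death = base["death_date"].to_numpy()
    emig = base["emigration_date"].to_numpy()
    eos = np.datetime64(config.end_of_study_date, "ns")

    def _nat_to_max(arr):
        a = pd.to_datetime(pd.Series(arr)).to_numpy(dtype="datetime64[ns]")
        return np.where(np.isnat(a), np.datetime64("2200-01-01", "ns"), a)

    mi, stroke, death, emig = map(_nat_to_max, (mi, stroke, death, emig))
    event_date = np.minimum(np.minimum(mi, stroke), death)
    censor_date = np.minimum(emig, eos)
    end_date = np.minimum(event_date, censor_date)
    is_event = event_date <= censor_date  # event wins same-day ties
    event_type = np.where(
        mi == event_date, "MI", np.where(stroke == event_date, "stroke", "death")
    )  # precedence MI > stroke > death
    followup_days = (end_date - base["index_date"].to_numpy(dtype="datetime64[ns]")) / np.timedelta64(1, "D")
    if (followup_days < 0).any():
        bad = base["person_id"].to_numpy()[followup_days < 0]
        raise DataIntegrityError(f"negative follow-up time for person(s) {bad[:5].tolist()}")
    base["followup_years"] = followup_days / DAYS_PER_YEAR
    base["event"] = is_event.astype(int)
    base["event_type"] = np.where(is_event, event_type, "none")

    # -- treatment-uptake clocks (days from first HbA1c to first redemption)
    for med, key in (("statin", "statin_atc"), ("rasi", "rasi_atc")):
        first_rx = (
            rx[_prefix_mask(rx["atc_code"], cl[key]) & (rx["dispense_date"] > rx["first_date"])]
            .groupby("person_id", sort=True)["dispense_date"]
            .min()
            .reindex(base["person_id"])
        )
        days = (first_rx.to_numpy() - base["first_date"].to_numpy()) / np.timedelta64(1, "D")
        base[f"days_to_{med}"] = days

    cohort_cols = [
        "person_id",
        "first_date",
        "index_date",
        "exposure",
        "m_statin",
        "m_rasi",
        "age_at_first",
        "age_band",
        "sex",
        "cohabitation",
        "income_quartile",
        "ethnicity",
        "requester",
        "first_hba1c_band",
        "egfr_band",
        *COVARIATE_FLAGS,
        "followup_years",
        "event",
        "event_type",
        "days_to_statin",
        "days_to_rasi",
        "on_gldt",
        "gldt_date",
        "latest_hba1c",
    ]
    if "education" in base.columns:
        cohort_cols.insert(cohort_cols.index("ethnicity"), "education")
    cohort = base[cohort_cols].reset_index(drop=True)
    return cohort, log
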