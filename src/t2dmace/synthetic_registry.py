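"""Synthetic health-registry simulator with known causal structure.

Emulates the kind of individual-level data found in Nordic administrative
registers — a persons table, laboratory results, redeemed prescriptions and
hospital discharge diagnoses — for a population presenting with a first
HbA1c in the 48–57 mmol/mol band.  The generative model mirrors the target
study design:

* covariates L (age, sex, socioeconomic markers, first-HbA1c band, eGFR
  band, comorbidity flags) drawn from independent marginals;
* GLDT (glucose-lowering drug treatment) initiation within the exposure
  window and HbA1c normalisation are Bernoulli with logistic dependence on
  L, which together define the four exposure groups at the index date;
* statin and RASi initiation within the exposure window are Bernoulli with
  group-specific logistic propensities in L (the mediators);
* time to first MACE (MI / stroke / all-cause death composite) follows a
  proportional-hazards model with a constant or Weibull baseline and a
  log-hazard-ratio vector over exposure, mediators, exposure x mediator
  interactions, and L;
* censoring by emigration (exponential, independent) and by a fixed
  end-of-study date.

Because mediators are binary and covariates discrete, the population
standardized risks and interventional indirect effects implied by a
configuration can be computed exactly by enumeration
(:func:`true_standardized_risks`), which serves as the oracle for the
estimation pipeline.

Dates are laid on a day grid anchored at a fixed synthetic calendar origin;
eligibility-rule violators are injected at configurable fractions and the
clean (fully eligible) subset is recorded in a ground-truth sidecar table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._design import (
    AGE_BANDS,
    COVARIATE_FACTORS,
    COVARIATE_FLAGS,
    EXPOSURE_LEVELS,
    REFERENCE_EXPOSURE,
    build_covariate_design,
    build_cox_design,
    coeff_vector,
    covariate_design_columns,
    cox_design_columns,
)

__all__ = [
    "SimulationConfig",
    "HazardSpec",
    "CensorSpec",
    "RegistryBundle",
    "ConfigurationError",
    "UnsupportedSpecificationError",
    "generate_registry",
    "simulate_cohort",
    "true_standardized_risks",
    "write_registry",
    "read_registry",
]

ORIGIN_DATE = pd.Timestamp("2014-01-01")
DAYS_PER_YEAR = 365.25

VIOLATION_RULES = (
    "prior_gldt",
    "prior_cvd",
    "egfr_low",
    "anaemia",
    "prior_statin_rasi",
    "age_out",
    "missing_followup",
)


class ConfigurationError(ValueError):
    """A simulation config field is invalid; the message names the field."""


class UnsupportedSpecificationError(ValueError):
    """Requested an analytic computation for a non-analytic specification."""


def _default_mediator_coeffs() -> dict:
    # Intercepts chosen so group-wise uptake roughly matches the observed
    # pattern in Danish register data: groups on GLDT initiate statins/RASi
    # far more often (~42-45% / ~26-28%) than groups not on GLDT
    # (~11-14% each).  Mild covariate effects keep positivity healthy.
    common = {"sex=M": 0.15, "first_hba1c_band=53-57": 0.20, "egfr_band=60-89": 0.10}
    return {
        "WC_GLDT": {
            "statin": {"intercept": -0.40, **common},
            "rasi": {"intercept": -1.12, **common},
        },
        "PC_GLDT": {
            "statin": {"intercept": -0.28, **common},
            "rasi": {"intercept": -1.00, **common},
        },
        "REMISSION": {
            "statin": {"intercept": -2.12, **common},
            "rasi": {"intercept": -1.94, **common},
        },
        "PERSISTENT": {
            "statin": {"intercept": -1.86, **common},
            "rasi": {"intercept": -1.86, **common},
        },
    }


def _default_log_hr() -> dict:
    ages = {f"age_band={b}": 0.19 * i for i, b in enumerate(AGE_BANDS) if i > 0}
    return {
        "exposure=PC_GLDT": 0.32,
        "exposure=REMISSION": 0.20,
        "exposure=PERSISTENT": 0.34,
        "m_statin": -0.30,
        "m_rasi": -0.18,
        **ages,
        "sex=M": 0.35,
        "cohabitation=living_alone": 0.15,
        "egfr_band=30-59": 0.30,
        "hf": 0.55,
        "af": 0.35,
        "copd_asthma": 0.25,
        "cancer": 0.45,
    }


@dataclass
class HazardSpec:
    """Baseline hazard family plus log-hazard-ratio vector.

    ``family`` is ``"constant"`` (rate per year) or ``"weibull"`` with
    cumulative baseline hazard (t/scale)^shape, t in years.
    """

    family: str = "constant"
    rate: float = 0.013
    shape: float = 1.0
    scale: float = 1.0
    log_hr: dict = field(default_factory=_default_log_hr)

    def cumulative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.family == "constant":
            return self.rate * t
        if self.family == "weibull":
            return (t / self.scale) ** self.shape
        raise UnsupportedSpecificationError(f"hazard family {self.family!r} is not analytic")

    def inverse_cumulative(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.family == "constant":
            return u / self.rate
        if self.family == "weibull":
            return self.scale * u ** (1.0 / self.shape)
        raise UnsupportedSpecificationError(f"hazard family {self.family!r} is not analytic")


@dataclass
class CensorSpec:
    """Calendar layout and censoring processes.

    Inclusion dates are uniform over ``[0, inclusion_window_days]`` from the
    synthetic origin; the index date sits ``index_offset_days`` later; the
    administrative end of study is a fixed day offset from the origin
    (default mirrors a 2014–2020 inclusion period with follow-up through
    early 2022).  Emigration is exponential and independent of event times.
    """

    inclusion_window_days: int = 2556
    index_offset_days: int = 180
    end_of_study_day: int = 2952
    emigration_rate_per_year: float = 0.005


@dataclass
class SimulationConfig:
    n_persons: int = 14000
    seed: int = 20140101
    age_range: tuple = (40.0, 80.0)
    p_female: float = 0.48
    p_living_alone: float = 0.37
    income_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    p_immigrant: float = 0.165
    p_requester_gp: float = 0.89
    p_first_band_high: float = 0.225
    egfr_band_probs: tuple = (0.51, 0.41, 0.05, 0.03)
    comorbidity_prev: dict = field(
        default_factory=lambda: {"hf": 0.018, "af": 0.026, "copd_asthma": 0.145, "cancer": 0.047}
    )
    p_hypertension: float = 0.19
    education_probs: tuple = (0.33, 0.45, 0.22)
    # GLDT initiation and HbA1c normalisation (logistic in covariates;
    # "gldt" names the extra GLDT-status term of the normalisation model).
    gldt_coeffs: dict = field(
        default_factory=lambda: {
            "intercept": -0.74,
            "first_hba1c_band=53-57": 0.95,
            "age_band=75-80": -0.20,
        }
    )
    normalise_coeffs: dict = field(
        default_factory=lambda: {
            "intercept": 0.62,
            "gldt": 0.0,
            "first_hba1c_band=53-57": -0.90,
        }
    )
    mediator_coeffs: dict = field(default_factory=_default_mediator_coeffs)
    mediator_correlation: float = 0.0
    hazard: HazardSpec = field(default_factory=HazardSpec)
    censor: CensorSpec = field(default_factory=CensorSpec)
    violations: dict = field(default_factory=lambda: {r: 0.0 for r in VIOLATION_RULES})
    event_type_probs: dict = field(
        default_factory=lambda: {"MI": 0.12, "stroke": 0.18, "death": 0.70}
    )
    # yearly post-index initiation rates among pre-index non-initiators,
    # by GLDT status (feeds the treatment-uptake curves only).
    post_init_rates: dict = field(
        default_factory=lambda: {
            "statin": {"gldt": 0.10, "no_gldt": 0.04},
            "rasi": {"gldt": 0.08, "no_gldt": 0.03},
        }
    )

    def validate(self) -> None:
        if not isinstance(self.n_persons, (int, np.integer)) or self.n_persons < 1:
            raise ConfigurationError("n_persons must be a positive integer")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ConfigurationError("age_range must be an increasing positive pair")
        for name in (
            "p_female",
            "p_living_alone",
            "p_immigrant",
            "p_requester_gp",
            "p_first_band_high",
            "p_hypertension",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("income_probs", "egfr_band_probs", "education_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be nonnegative and sum to 1")
        for k, v in self.comorbidity_prev.items():
            if k not in COVARIATE_FLAGS:
                raise ConfigurationError(f"comorbidity_prev: unknown flag {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"comorbidity_prev[{k!r}] must lie in [0, 1]")
        if self.hazard.family not in ("constant", "weibull"):
            raise ConfigurationError("hazard.family must be 'constant' or 'weibull'")
        if self.hazard.family == "constant" and self.hazard.rate <= 0:
            raise ConfigurationError("hazard.rate must be > 0")
        if self.hazard.family == "weibull" and (self.hazard.shape <= 0 or self.hazard.scale <= 0):
            raise ConfigurationError("hazard.shape and hazard.scale must be > 0")
        for rule, frac in self.violations.items():
            if rule not in VIOLATION_RULES:
                raise ConfigurationError(f"violations: unknown rule {rule!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"violations[{rule!r}] must lie in [0, 1]")
        if set(self.mediator_coeffs) != set(EXPOSURE_LEVELS):
            raise ConfigurationError("mediator_coeffs must cover exactly the four exposure groups")
        if not -1.0 < self.mediator_correlation < 1.0:
            raise ConfigurationError("mediator_correlation must lie in (-1, 1)")
        p = np.array([self.event_type_probs.get(k, 0.0) for k in ("MI", "stroke", "death")])
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("event_type_probs must be nonnegative and sum to 1")
        cen = self.censor
        if cen.inclusion_window_days < 0 or cen.index_offset_days < 1:
            raise ConfigurationError("censor: inclusion window and index offset must be positive")
        if cen.end_of_study_day <= cen.inclusion_window_days + cen.index_offset_days:
            raise ConfigurationError(
                "censor.end_of_study_day must exceed inclusion_window_days + index_offset_days"
            )
        if cen.emigration_rate_per_year < 0:
            raise ConfigurationError("censor.emigration_rate_per_year must be >= 0")
        # surface design-column typos in coefficient dicts early
        cov_cols = covariate_design_columns()
        coeff_vector(self.gldt_coeffs, cov_cols, "gldt_coeffs")
        norm = {k: v for k, v in self.normalise_coeffs.items() if k != "gldt"}
        coeff_vector(norm, cov_cols, "normalise_coeffs")
        for g, per_med in self.mediator_coeffs.items():
            for m in ("statin", "rasi"):
                coeff_vector(per_med[m], cov_cols, f"mediator_coeffs[{g}][{m}]")
        coeff_vector(self.hazard.log_hr, cox_design_columns(), "hazard.log_hr")


@dataclass
class RegistryBundle:
    """The four raw register-style tables plus the ground-truth sidecar."""

    persons: pd.DataFrame
    labs: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# person-level causal simulation (ground truth)
# ---------------------------------------------------------------------------


def _draw_factor(rng, levels, probs, n):
    codes = rng.choice(len(levels), size=n, p=np.asarray(probs, dtype=float))
    return np.asarray(levels, dtype=object)[codes]


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the person-level ground truth for ``config``.

    Returns one row per person with covariates, exposure group, mediators,
    day-grid dates, follow-up and event outcome, counterfactual linear
    predictors under each exposure level, and per-rule violation flags.
    The subset with no violation flags is exactly the eligible set the
    cohort builder must recover from the emitted registry tables.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_persons
    cen = config.censor

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    # snap to the day grid so ages recomputed from emitted birth dates agree
    age = np.rint(age * DAYS_PER_YEAR) / DAYS_PER_YEAR
    band_idx = np.clip(((age - 40.0) // 5).astype(int), 0, len(AGE_BANDS) - 1)
    df = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(1, n + 1)],
            "age": age,
            "age_band": np.asarray(AGE_BANDS, dtype=object)[band_idx],
            "sex": np.where(rng.random(n) < config.p_female, "F", "M"),
            "cohabitation": np.where(
                rng.random(n) < config.p_living_alone, "living_alone", "cohabiting"
            ),
            "income_quartile": _draw_factor(
                rng,
                COVARIATE_FACTORS["income_quartile"],
                tuple(config.income_probs) + (0.0,),  # "unknown" never generated
                n,
            ),
            "ethnicity": np.where(rng.random(n) < config.p_immigrant, "immigrant", "native"),
            "requester": np.where(rng.random(n) < config.p_requester_gp, "GP", "other"),
            "first_hba1c_band": np.where(
                rng.random(n) < config.p_first_band_high, "53-57", "48-52"
            ),
            "egfr_band": _draw_factor(
                rng, COVARIATE_FACTORS["egfr_band"], config.egfr_band_probs, n
            ),
        }
    )
    for flag in COVARIATE_FLAGS:
        df[flag] = (rng.random(n) < config.comorbidity_prev.get(flag, 0.0)).astype(int)
    df["hypertension"] = (rng.random(n) < config.p_hypertension).astype(int)
    df["education"] = _draw_factor(
        rng, ("basic", "secondary", "higher"), config.education_probs, n
    )

    cov_cols = covariate_design_columns()
    X = build_covariate_design(df)

    # GLDT initiation and HbA1c normalisation -> exposure group
    lp_gldt = config.gldt_coeffs.get("intercept", 0.0) + X @ coeff_vector(config.gldt_coeffs, cov_cols)
    gldt = rng.random(n) < expit(lp_gldt)
    norm_cov = {k: v for k, v in config.normalise_coeffs.items() if k != "gldt"}
    lp_norm = (
        config.normalise_coeffs.get("intercept", 0.0)
        + config.normalise_coeffs.get("gldt", 0.0) * gldt
        + X @ coeff_vector(norm_cov, cov_cols)
    )
    normalised = rng.random(n) < expit(lp_norm)
    exposure = np.where(
        gldt,
        np.where(normalised, "WC_GLDT", "PC_GLDT"),
        np.where(normalised, "REMISSION", "PERSISTENT"),
    )
    df["gldt"] = gldt.astype(int)
    df["exposure"] = exposure

    # mediators: group-specific logistic propensities, optional Gaussian
    # copula correlation between the two uniforms (default independent)
    p_stat = np.empty(n)
    p_rasi = np.empty(n)
    for g in EXPOSURE_LEVELS:
        mask = exposure == g
        for med, out in (("statin", p_stat), ("rasi", p_rasi)):
            co = config.mediator_coeffs[g][med]
            out[mask] = expit(co.get("intercept", 0.0) + X[mask] @ coeff_vector(co, cov_cols))
    if config.mediator_correlation == 0.0:
        u1, u2 = rng.random(n), rng.random(n)
    else:
        from scipy.stats import norm as _norm

        rho = config.mediator_correlation
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        u1, u2 = _norm.cdf(z1), _norm.cdf(z2)
    df["p_statin_true"] = p_stat
    df["p_rasi_true"] = p_rasi
    df["m_statin"] = (u1 < p_stat).astype(int)
    df["m_rasi"] = (u2 < p_rasi).astype(int)

    # proportional-hazards event time from the index date
    beta = coeff_vector(config.hazard.log_hr, cox_design_columns())
    lp_event = build_cox_design(exposure, df["m_statin"], df["m_rasi"], X) @ beta
    for g in EXPOSURE_LEVELS:
        lp_g = build_cox_design(np.full(n, g, dtype=object), df["m_statin"], df["m_rasi"], X) @ beta
        df[f"lp_{g}"] = lp_g
    df["lp_event"] = lp_event
    t_event = config.hazard.inverse_cumulative(rng.exponential(size=n) / np.exp(lp_event))

    # calendar placement and censoring
    first_day = rng.integers(0, cen.inclusion_window_days + 1, size=n)
    index_day = first_day + cen.index_offset_days
    admin_days = cen.end_of_study_day - index_day
    if cen.emigration_rate_per_year > 0:
        t_emig = rng.exponential(1.0 / cen.emigration_rate_per_year, size=n)
    else:
        t_emig = np.full(n, np.inf)
    event_days = np.maximum(np.rint(t_event * DAYS_PER_YEAR).astype(np.int64), 1)
    emig_days = np.where(
        np.isfinite(t_emig),
        np.maximum(np.rint(np.where(np.isfinite(t_emig), t_emig, 0.0) * DAYS_PER_YEAR), 1),
        1_000_000_000.0,  # finite "never" sentinel (safe to cast)
    ).astype(np.int64)
    censor_days = np.minimum(emig_days, admin_days)
    followup_days = np.minimum(event_days, censor_days)
    event = (event_days <= censor_days).astype(int)  # events precede censoring on ties
    type_p = [config.event_type_probs[k] for k in ("MI", "stroke", "death")]
    drawn_type = _draw_factor(rng, ("MI", "stroke", "death"), type_p, n)
    df["first_day"] = first_day
    df["index_day"] = index_day
    df["followup_days"] = followup_days
    df["followup_years"] = followup_days / DAYS_PER_YEAR
    df["event"] = event
    df["event_type"] = np.where(event == 1, drawn_type, "none")
    df["emigrated"] = ((event == 0) & (emig_days < admin_days)).astype(int)
    df["emigration_day"] = np.where(df["emigrated"] == 1, index_day + followup_days, -1)

    # exposure-window timing on the day grid
    offset = cen.index_offset_days
    gldt_day = rng.integers(1, offset, size=n)  # in [1, offset-1]
    post_gldt_hba1c_day = (
        gldt_day + 1 + (rng.random(n) * (offset - gldt_day)).astype(np.int64)
    )  # in [gldt_day+1, offset]
    second_hba1c_day = rng.integers(30, offset + 1, size=n)
    df["gldt_day"] = np.where(gldt, gldt_day, -1)
    df["followup_hba1c_day"] = np.where(gldt, post_gldt_hba1c_day, second_hba1c_day)
    low_first = df["first_hba1c_band"].to_numpy() == "48-52"
    df["first_hba1c_value"] = np.where(
        low_first, rng.integers(48, 53, size=n), rng.integers(53, 58, size=n)
    )
    df["followup_hba1c_value"] = np.where(
        normalised, rng.integers(40, 48, size=n), rng.integers(48, 58, size=n)
    )
    df["statin_day"] = np.where(df["m_statin"] == 1, rng.integers(1, offset + 1, size=n), -1)
    df["rasi_day"] = np.where(df["m_rasi"] == 1, rng.integers(1, offset + 1, size=n), -1)

    # post-index initiation among pre-index non-initiators (uptake curves)
    for med in ("statin", "rasi"):
        rates = config.post_init_rates[med]
        rate = np.where(gldt, rates["gldt"], rates["no_gldt"]).astype(float)
        with np.errstate(divide="ignore"):
            t_post = rng.exponential(1.0, size=n) / np.where(rate > 0, rate, np.nan)
        post_day = np.rint(t_post * DAYS_PER_YEAR)
        ok = (
            (df[f"m_{med}"].to_numpy() == 0)
            & np.isfinite(post_day)
            & (post_day >= 1)
            & (post_day < followup_days)
        )
        df[f"post_{med}_day"] = np.where(ok, post_day, -1).astype(np.int64)

    # eligibility-rule violations
    for rule in VIOLATION_RULES:
        frac = config.violations.get(rule, 0.0)
        df[f"viol_{rule}"] = (rng.random(n) < frac).astype(int)
    df["eligible"] = (df[[f"viol_{r}" for r in VIOLATION_RULES]].sum(axis=1) == 0).astype(int)
    return df


# ---------------------------------------------------------------------------
# registry-table emission
# ---------------------------------------------------------------------------

_CKDEPI_KAPPA = {"F": 0.7, "M": 0.9}
_CKDEPI_ALPHA = {"F": -0.329, "M": -0.411}
_EGFR_TARGET = {">=90": 100.0, "60-89": 75.0, "30-59": 45.0}


def _creatinine_for_egfr(target: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Invert the 2009 CKD-EPI equation: serum creatinine (mg/dl) giving a
    target eGFR for given age/sex (race term omitted)."""
    kappa = np.where(sex == "F", _CKDEPI_KAPPA["F"], _CKDEPI_KAPPA["M"])
    alpha = np.where(sex == "F", _CKDEPI_ALPHA["F"], _CKDEPI_ALPHA["M"])
    base = 141.0 * 0.993**age * np.where(sex == "F", 1.018, 1.0)
    ratio = target / base
    # ratio < 1 -> high-creatinine branch (Scr/kappa)^(-1.209); else alpha branch
    scr_hi = kappa * ratio ** (-1.0 / 1.209)
    scr_lo = kappa * ratio ** (1.0 / alpha)
    return np.where(ratio < 1.0, scr_hi, scr_lo)


def _dates(day_offsets) -> pd.Series:
    return ORIGIN_DATE + pd.to_timedelta(np.asarray(day_offsets, dtype=np.int64), unit="D")


def generate_registry(config: SimulationConfig) -> RegistryBundle:
    """Generate the four raw registry tables plus the ground-truth sidecar.

    Output is byte-identical for identical (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    truth = simulate_cohort(config, rng)
    n = len(truth)
    first_day = truth["first_day"].to_numpy()
    index_day = truth["index_day"].to_numpy()
    age = truth["age"].to_numpy()
    sex = truth["sex"].to_numpy()

    # --- persons ------------------------------------------------------------
    age_days = np.rint(age * DAYS_PER_YEAR).astype(np.int64)
    viol_age = truth["viol_age_out"].to_numpy() == 1
    age_days = np.where(
        viol_age,
        np.rint(np.where(rng.random(n) < 0.5, 34.5, 85.5) * DAYS_PER_YEAR).astype(np.int64),
        age_days,
    )
    birth_day = first_day - age_days
    died = (truth["event"] == 1) & (truth["event_type"] == "death")
    death_day = np.where(died, index_day + truth["followup_days"].to_numpy(), -1)
    emig_day = truth["emigration_day"].to_numpy()
    persons = pd.DataFrame(
        {
            "person_id": truth["person_id"],
            "birth_date": _dates(birth_day),
            "sex": sex,
            "cohabitation": truth["cohabitation"],
            "income_quartile": truth["income_quartile"],
            "education": truth["education"],
            "ethnicity": truth["ethnicity"],
            "death_date": _dates(np.where(death_day >= 0, death_day, 0)).where(death_day >= 0),
            "emigration_date": _dates(np.where(emig_day >= 0, emig_day, 0)).where(emig_day >= 0),
        }
    )

    # --- labs ---------------------------------------------------------------
    lab_frames = []

    def add_lab(mask, day, analyte, value, unit, requester):
        lab_frames.append(
            pd.DataFrame(
                {
                    "person_id": truth.loc[mask, "person_id"].to_numpy(),
                    "sample_date": _dates(np.asarray(day)[mask]),
                    "analyte": analyte,
                    "value": np.round(np.asarray(value, dtype=float)[mask], 2),
                    "unit": unit,
                    "requester": np.asarray(requester, dtype=object)[mask]
                    if not np.isscalar(requester)
                    else requester,
                }
            )
        )

    # an earlier normal HbA1c for some persons (below threshold, ignored by
    # the first-diagnostic-HbA1c search)
    has_prior_hba1c = rng.random(n) < 0.25
    prior_day = first_day - rng.integers(180, 721, size=n)
    prior_val = rng.integers(38, 46, size=n).astype(float)
    add_lab(has_prior_hba1c, prior_day, "HbA1c", prior_val, "mmol/mol", "GP")

    add_lab(
        np.ones(n, dtype=bool),
        first_day,
        "HbA1c",
        truth["first_hba1c_value"].to_numpy(dtype=float),
        "mmol/mol",
        truth["requester"].to_numpy(),
    )
    has_followup = truth["viol_missing_followup"].to_numpy() == 0
    add_lab(
        has_followup,
        first_day + truth["followup_hba1c_day"].to_numpy(),
        "HbA1c",
        truth["followup_hba1c_value"].to_numpy(dtype=float),
        "mmol/mol",
        "GP",
    )

    egfr_band = truth["egfr_band"].to_numpy()
    viol_egfr = truth["viol_egfr_low"].to_numpy() == 1
    has_crea = (egfr_band != "unknown") | viol_egfr
    target = np.array([_EGFR_TARGET.get(b, 100.0) for b in egfr_band])
    target = np.where(viol_egfr, 20.0, target)
    scr_umol = _creatinine_for_egfr(target, age, sex) * 88.4
    crea_day = first_day - rng.integers(1, 180, size=n)
    add_lab(has_crea, crea_day, "creatinine", scr_umol, "umol/l", "GP")

    viol_anaemia = truth["viol_anaemia"].to_numpy() == 1
    has_hgb = (rng.random(n) < 0.85) | viol_anaemia
    hgb = rng.uniform(8.0, 10.5, size=n)
    hgb = np.where(viol_anaemia, rng.uniform(5.0, 6.5, size=n), hgb)
    hgb_day = first_day - rng.integers(1, 180, size=n)
    add_lab(has_hgb, hgb_day, "haemoglobin", hgb, "mmol/l", "GP")

    has_ldl = rng.random(n) < 0.8
    ldl = np.clip(rng.normal(3.2, 0.8, size=n), 1.0, 6.5)
    ldl_day = first_day - rng.integers(1, 181, size=n)
    add_lab(has_ldl, ldl_day, "LDL", ldl, "mmol/l", "GP")

    labs = pd.concat(lab_frames, ignore_index=True)

    # --- prescriptions ------------------------------------------------------
    rx_frames = []

    def add_rx(mask, day, atc):
        rx_frames.append(
            pd.DataFrame(
                {
                    "person_id": truth.loc[mask, "person_id"].to_numpy(),
                    "dispense_date": _dates(np.asarray(day)[mask]),
                    "atc_code": atc,
                }
            )
        )

    add_rx(truth["gldt"].to_numpy() == 1, first_day + truth["gldt_day"].to_numpy(), "A10BA02")
    add_rx(truth["m_statin"].to_numpy() == 1, first_day + truth["statin_day"].to_numpy(), "C10AA05")
    add_rx(truth["m_rasi"].to_numpy() == 1, first_day + truth["rasi_day"].to_numpy(), "C09AA02")
    add_rx(truth["post_statin_day"].to_numpy() >= 1, index_day + truth["post_statin_day"].to_numpy(), "C10AA05")
    add_rx(truth["post_rasi_day"].to_numpy() >= 1, index_day + truth["post_rasi_day"].to_numpy(), "C09AA02")
    add_rx(
        truth["viol_prior_gldt"].to_numpy() == 1,
        first_day - rng.integers(30, 301, size=n),
        "A10BA02",
    )
    viol_sr = truth["viol_prior_statin_rasi"].to_numpy() == 1
    add_rx(viol_sr, first_day - rng.integers(1, 180, size=n), "C10AA05")
    # unrelated analgesic noise
    noise_rx = rng.random(n) < 0.3
    add_rx(noise_rx, first_day - rng.integers(1, 700, size=n), "N02BE01")
    prescriptions = pd.concat(rx_frames, ignore_index=True)

    # --- diagnoses ----------------------------------------------------------
    dx_frames = []

    def add_dx(mask, day, icd, primary=True):
        dx_frames.append(
            pd.DataFrame(
                {
                    "person_id": truth.loc[mask, "person_id"].to_numpy(),
                    "discharge_date": _dates(np.asarray(day)[mask]),
                    "icd10_code": np.asarray(icd, dtype=object)[mask]
                    if not np.isscalar(icd)
                    else icd,
                    "is_primary": primary,
                }
            )
        )

    comorb_codes = {"hf": "I500", "af": "I489", "copd_asthma": "J449", "cancer": "C349"}
    for flag, code in comorb_codes.items():
        mask = truth[flag].to_numpy() == 1
        day = index_day - rng.integers(30, 3500, size=n)
        add_dx(mask, day, code)
    add_dx(
        truth["hypertension"].to_numpy() == 1,
        first_day - rng.integers(30, 3000, size=n),
        "I10",
    )
    add_dx(
        truth["viol_prior_cvd"].to_numpy() == 1,
        first_day - rng.integers(1, 3000, size=n),
        "I251",
    )
    ev = truth["event"].to_numpy() == 1
    ev_type = truth["event_type"].to_numpy()
    mace_code = np.where(ev_type == "MI", "I219", "I639")
    add_dx(ev & (ev_type != "death"), index_day + truth["followup_days"].to_numpy(), mace_code)
    noise_dx = rng.random(n) < 0.15
    add_dx(noise_dx, first_day - rng.integers(1, 3000, size=n), "M545", primary=False)
    diagnoses = pd.concat(dx_frames, ignore_index=True)

    for frame in (labs, prescriptions, diagnoses):
        frame.sort_values(
            [frame.columns[0], frame.columns[1], frame.columns[2]],
            inplace=True,
            kind="mergesort",
        )
        frame.reset_index(drop=True, inplace=True)

    sidecar = truth[truth["eligible"] == 1].reset_index(drop=True)
    return RegistryBundle(persons, labs, prescriptions, diagnoses, sidecar)


# ---------------------------------------------------------------------------
# exact oracle: true standardized risks and interventional effects
# ---------------------------------------------------------------------------


def _covariate_grid(config: SimulationConfig):
    """Full covariate product grid with marginal-product weights.

    Returns (design matrix over covariate_design_columns, weights).
    """
    lo, hi = config.age_range
    band_lo = 40.0 + 5.0 * np.arange(len(AGE_BANDS))
    overlap = np.maximum(np.minimum(band_lo + 5.0, hi) - np.maximum(band_lo, lo), 0.0)
    factor_probs = {
        "age_band": overlap / overlap.sum(),
        "sex": np.array([config.p_female, 1 - config.p_female]),
        "cohabitation": np.array([1 - config.p_living_alone, config.p_living_alone]),
        "income_quartile": np.asarray(tuple(config.income_probs) + (0.0,), dtype=float),
        "ethnicity": np.array([1 - config.p_immigrant, config.p_immigrant]),
        "requester": np.array([config.p_requester_gp, 1 - config.p_requester_gp]),
        "first_hba1c_band": np.array([1 - config.p_first_band_high, config.p_first_band_high]),
        "egfr_band": np.asarray(config.egfr_band_probs, dtype=float),
    }
    sizes = [len(COVARIATE_FACTORS[f]) for f in COVARIATE_FACTORS] + [2] * len(COVARIATE_FLAGS)
    grids = np.meshgrid(*[np.arange(s) for s in sizes], indexing="ij")
    codes = np.stack([g.ravel() for g in grids], axis=1)
    m = codes.shape[0]
    blocks = []
    weights = np.ones(m)
    for j, fname in enumerate(COVARIATE_FACTORS):
        levels = COVARIATE_FACTORS[fname]
        block = np.zeros((m, len(levels) - 1))
        for k in range(1, len(levels)):
            block[:, k - 1] = codes[:, j] == k
        blocks.append(block)
        weights *= factor_probs[fname][codes[:, j]]
    for j, flag in enumerate(COVARIATE_FLAGS):
        col = codes[:, len(COVARIATE_FACTORS) + j].astype(float)
        blocks.append(col[:, None])
        prev = config.comorbidity_prev.get(flag, 0.0)
        weights *= np.where(col == 1, prev, 1 - prev)
    X = np.hstack(blocks)
    keep = weights > 0
    return X[keep], weights[keep]


def true_standardized_risks(
    config: SimulationConfig,
    horizon: float = 5.0,
    selector: str = "both",
) -> dict:
    """Exact standardized risks and interventional indirect effects.

    For each exposure level ``a`` computes, by enumeration over the four
    (statin, RASi) combinations and the discrete covariate grid,

    * ``psi_within``  — risk at ``horizon`` with mediators drawn from group
      a's own propensities,
    * ``psi_reference`` — with mediators (per ``selector``: both, statin or
      rasi) drawn from the reference group's propensities,
    * ``delta`` = psi_within − psi_reference.

    Requires an analytic baseline hazard (constant or Weibull).
    """
    config.validate()
    if config.hazard.family not in ("constant", "weibull"):
        raise UnsupportedSpecificationError(
            f"hazard family {config.hazard.family!r} has no analytic cumulative hazard"
        )
    if selector not in ("both", "statin", "rasi"):
        raise ValueError(f"invalid mediator selector {selector!r}")
    cov_cols = covariate_design_columns()
    X, w = _covariate_grid(config)
    lam0 = float(config.hazard.cumulative(horizon))
    beta = dict(config.hazard.log_hr)
    lp_cov = X @ coeff_vector({k: v for k, v in beta.items() if k in cov_cols}, cov_cols)

    def propensity(group, med):
        co = config.mediator_coeffs[group][med]
        return expit(co.get("intercept", 0.0) + X @ coeff_vector(co, cov_cols))

    def psi(a, statin_group, rasi_group):
        e_a = beta.get(f"exposure={a}", 0.0) if a != REFERENCE_EXPOSURE else 0.0
        s_a = beta.get("m_statin", 0.0) + (
            beta.get(f"exposure={a}:m_statin", 0.0) if a != REFERENCE_EXPOSURE else 0.0
        )
        r_a = beta.get("m_rasi", 0.0) + (
            beta.get(f"exposure={a}:m_rasi", 0.0) if a != REFERENCE_EXPOSURE else 0.0
        )
        p1 = propensity(statin_group, "statin")
        p2 = propensity(rasi_group, "rasi")
        risk = {
            (m1, m2): 1.0 - np.exp(-lam0 * np.exp(lp_cov + e_a + m1 * s_a + m2 * r_a))
            for m1 in (0, 1)
            for m2 in (0, 1)
        }
        # interaction form: exactly propensity-free under null mediator effects
        total = (
            risk[(0, 0)]
            + p1 * (risk[(1, 0)] - risk[(0, 0)])
            + p2 * (risk[(0, 1)] - risk[(0, 0)])
            + p1 * p2 * (risk[(1, 1)] - risk[(1, 0)] - risk[(0, 1)] + risk[(0, 0)])
        )
        return float(np.sum(w * total) / np.sum(w))

    out = {}
    for a in EXPOSURE_LEVELS:
        psi_within = psi(a, a, a)
        stat_src = REFERENCE_EXPOSURE if selector in ("both", "statin") else a
        rasi_src = REFERENCE_EXPOSURE if selector in ("both", "rasi") else a
        psi_ref = psi(a, stat_src, rasi_src)
        out[a] = {
            "psi_within": psi_within,
            "psi_reference": psi_ref,
            "delta": psi_within - psi_ref,
        }
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "persons": "persons.csv",
    "labs": "labs.csv",
    "prescriptions": "prescriptions.csv",
    "diagnoses": "diagnoses.csv",
}
_TRUTH_FILE = "ground_truth_synthetic.csv"
_CONFIG_FILE = "simulation_config.yaml"


def write_registry(bundle: RegistryBundle, outdir, config: SimulationConfig | None = None) -> None:
    """Write the registry tables (UTF-8 CSV, ISO-8601 dates), the clearly
    named synthetic ground-truth sidecar, and optionally the config."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        getattr(bundle, attr).to_csv(out / fname, index=False, date_format="%Y-%m-%d")
    if bundle.truth is not None:
        bundle.truth.to_csv(out / _TRUTH_FILE, index=False)
    if config is not None:
        import yaml

        cfg = dataclasses.asdict(config)
        with open(out / _CONFIG_FILE, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(cfg), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_registry(indir) -> RegistryBundle:
    import pathlib

    ind = pathlib.Path(indir)
    frames = {}
    date_cols = {
        "persons": ["birth_date", "death_date", "emigration_date"],
        "labs": ["sample_date"],
        "prescriptions": ["dispense_date"],
        "diagnoses": ["discharge_date"],
    }
    for attr, fname in _TABLE_FILES.items():
        frames[attr] = pd.read_csv(ind / fname, parse_dates=date_cols[attr])
    truth_path = ind / _TRUTH_FILE
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return RegistryBundle(truth=truth, **frames)
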