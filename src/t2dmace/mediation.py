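"""Standardized absolute risks and interventional mediation effects.

The estimand machinery: whole-population standardized absolute 5-year MACE
risks per exposure level under (i) the group's own observed mediator regime
and (ii) the reference group's regime, computed by g-computation from the
fitted Cox model; total-effect risk differences versus the reference group;
interventional indirect (mediation) effects

    Delta_a = Psi_a(within-group regime) - Psi_a(reference regime),

with a selector equalizing both mediators, statins only, or RASi only; and
percentile bootstrap confidence intervals that re-run the entire model
pipeline per resample.

Two compute paths give the same estimand:

* ``standardized_risk_exact`` enumerates the four (statin, RASi)
  combinations — exact, deterministic, the default;
* ``standardized_risk_mc`` repeats random mediator assignment R times
  (default 200) and averages, with common random numbers shared across
  regimes and exposure levels to shrink the Monte Carlo noise of
  contrasts.

Every standardized risk averages over ALL included individuals, never only
the group's own members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._design import EXPOSURE_LEVELS, REFERENCE_EXPOSURE, build_covariate_design
from .risk_models import HazardModel, ModelFitError, PropensityModelSet, fit_hazard_ladder

__all__ = [
    "MediatorRegime",
    "MediationEstimate",
    "standardized_risk_exact",
    "standardized_risk_mc",
    "total_effect_differences",
    "interventional_indirect_effect",
    "bootstrap_cis",
    "estimate_mediation",
]

logger = logging.getLogger("t2dmace")

SELECTORS = ("both", "statin", "rasi")


@dataclass(frozen=True)
class MediatorRegime:
    """Which exposure group's propensity models assign each mediator.

    ``"within"`` resolves to the exposure level being standardized;
    ``"reference"`` to the reference group; an explicit group name is used
    as-is.
    """

    statin: str = "within"
    rasi: str = "within"

    @classmethod
    def within(cls) -> "MediatorRegime":
        return cls("within", "within")

    @classmethod
    def reference(cls, selector: str = "both") -> "MediatorRegime":
        """The intervention regime: the selected mediator(s) follow the
        reference group's propensities, the rest stay within-group."""
        if selector not in SELECTORS:
            raise ValueError(f"invalid mediator selector {selector!r}; choose from {SELECTORS}")
        return cls(
            statin="reference" if selector in ("both", "statin") else "within",
            rasi="reference" if selector in ("both", "rasi") else "within",
        )

    def resolve(self, exposure: str, reference: str = REFERENCE_EXPOSURE):
        def _one(spec):
            if spec == "within":
                return exposure
            if spec == "reference":
                return reference
            if spec not in EXPOSURE_LEVELS:
                raise ValueError(f"unknown regime group {spec!r}")
            return spec

        return _one(self.statin), _one(self.rasi)


def _risk_grid(hazard: HazardModel, X_cov, exposure: str, t: float):
    """Predicted risk at t for each (m_statin, m_rasi) combination."""
    n = len(X_cov)
    expo = np.full(n, exposure, dtype=object)
    grid = {}
    for m1 in (0, 1):
        for m2 in (0, 1):
            grid[(m1, m2)] = hazard.predict_absolute_risk(
                X_cov, expo, np.full(n, m1), np.full(n, m2), t
            )
    return grid


def _psi_exact_arrays(risk_grid, p1, p2) -> float:
    # interaction form of the 2x2 mixture: algebraically identical to the
    # product-weight form, and exactly propensity-free when the four risks
    # coincide (null mediator effects cancel to 0 in floating point too)
    r00, r01 = risk_grid[(0, 0)], risk_grid[(0, 1)]
    r10, r11 = risk_grid[(1, 0)], risk_grid[(1, 1)]
    total = r00 + p1 * (r10 - r00) + p2 * (r01 - r00) + p1 * p2 * (r11 - r10 - r01 + r00)
    return float(total.mean())


def standardized_risk_exact(cohort, propensities, hazard, exposure, regime, t=5.0) -> float:
    """Exact-enumeration standardized risk Psi_a at horizon t.

    Psi = mean_i sum_{(m1,m2)} p(m1|L_i) p(m2|L_i) risk_i(a, m1, m2, t),
    averaging over every included individual.
    """
    X_cov = build_covariate_design(cohort)
    g1, g2 = regime.resolve(exposure, hazard.reference)
    p1 = propensities.predict(g1, "statin", X_cov)
    p2 = propensities.predict(g2, "rasi", X_cov)
    return _psi_exact_arrays(_risk_grid(hazard, X_cov, exposure, t), p1, p2)


def mc_draws(n: int, R: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Shared uniform draws for Monte Carlo mediator assignment (common
    random numbers across regimes and exposure levels)."""
    rng = np.random.default_rng(seed)
    return rng.random((n, R)), rng.random((n, R))


def _psi_mc_arrays(risk_grid, p1, p2, draws) -> float:
    u1, u2 = draws
    m1 = u1 < p1[:, None]
    m2 = u2 < p2[:, None]
    risk = (
        np.where(m1, risk_grid[(1, 0)][:, None], risk_grid[(0, 0)][:, None]) * (~m2)
        + np.where(m1, risk_grid[(1, 1)][:, None], risk_grid[(0, 1)][:, None]) * m2
    )
    return float(risk.mean())


def standardized_risk_mc(
    cohort, propensities, hazard, exposure, regime, R: int = 200, t: float = 5.0,
    seed=None, draws=None,
) -> float:
    """Monte Carlo standardized risk: mediators are randomly assigned from
    the regime's propensities R times (default 200) and predicted risks are
    averaged over draws and individuals.

    Pass the same ``draws`` (or ``seed``) to several calls to share random
    numbers between regimes; omit both for independent redraws.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    X_cov = build_covariate_design(cohort)
    g1, g2 = regime.resolve(exposure, hazard.reference)
    p1 = propensities.predict(g1, "statin", X_cov)
    p2 = propensities.predict(g2, "rasi", X_cov)
    if draws is None:
        draws = mc_draws(len(X_cov), R, seed)
    return _psi_mc_arrays(_risk_grid(hazard, X_cov, exposure, t), p1, p2, draws)


def total_effect_differences(psi_obs: dict, reference: str = REFERENCE_EXPOSURE) -> dict:
    """Signed standardized-risk differences Psi_a^obs - Psi_ref^obs."""
    ref = psi_obs[reference]
    return {a: psi_obs[a] - ref for a in psi_obs}


def interventional_indirect_effect(
    cohort, propensities, hazard, group: str, selector: str = "both",
    R: int = 200, t: float = 5.0, seed=None, method: str = "exact",
) -> float:
    """Delta_a: standardized-risk difference between the within-group
    mediator regime and the regime with the selected mediator(s) set to the
    reference group's propensities.  Identically 0 for the reference group.
    With ``method="mc"`` the two regimes share common random numbers."""
    if selector not in SELECTORS:
        raise ValueError(f"invalid mediator selector {selector!r}; choose from {SELECTORS}")
    if group == hazard.reference:
        return 0.0
    within, ref = MediatorRegime.within(), MediatorRegime.reference(selector)
    if method == "exact":
        psi_w = standardized_risk_exact(cohort, propensities, hazard, group, within, t)
        psi_r = standardized_risk_exact(cohort, propensities, hazard, group, ref, t)
    elif method == "mc":
        draws = mc_draws(len(cohort), R, seed)
        psi_w = standardized_risk_mc(cohort, propensities, hazard, group, within, R, t, draws=draws)
        psi_r = standardized_risk_mc(cohort, propensities, hazard, group, ref, R, t, draws=draws)
    else:
        raise ValueError(f"unknown method {method!r}")
    return psi_w - psi_r


# ---------------------------------------------------------------------------
# full-pipeline quantities and bootstrap
# ---------------------------------------------------------------------------


@dataclass
class _Arrays:
    """Cohort columns needed by the pipeline, as plain arrays."""

    X_cov: np.ndarray
    exposure: np.ndarray
    m_statin: np.ndarray
    m_rasi: np.ndarray
    time: np.ndarray
    event: np.ndarray

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "_Arrays":
        return cls(
            build_covariate_design(cohort),
            cohort["exposure"].to_numpy(dtype=object),
            cohort["m_statin"].to_numpy(dtype=float),
            cohort["m_rasi"].to_numpy(dtype=float),
            cohort["followup_years"].to_numpy(dtype=float),
            cohort["event"].to_numpy(dtype=int),
        )

    def take(self, idx) -> "_Arrays":
        return _Arrays(
            self.X_cov[idx], self.exposure[idx], self.m_statin[idx],
            self.m_rasi[idx], self.time[idx], self.event[idx],
        )


def _fast_risk_grid(haz: HazardModel, X_cov, exposure: str, t: float, lp_cov=None):
    """Risk grid via the additive decomposition of the Cox linear
    predictor: numerically equal to :func:`_risk_grid` but without
    rebuilding design matrices per mediator combination."""
    beta = haz.full_beta()
    others = [g for g in EXPOSURE_LEVELS if g != haz.reference]
    if lp_cov is None:
        lp_cov = X_cov @ beta[11:]
    if exposure == haz.reference:
        e_a = s_int = r_int = 0.0
    else:
        j = others.index(exposure)
        e_a, s_int, r_int = beta[j], beta[5 + j], beta[8 + j]
    s_a = beta[3] + s_int
    r_a = beta[4] + r_int
    lam = haz.cumhaz_at(t)
    grid = {}
    for m1 in (0, 1):
        for m2 in (0, 1):
            grid[(m1, m2)] = 1.0 - np.exp(-lam * np.exp(lp_cov + e_a + m1 * s_a + m2 * r_a))
    return grid


def _pipeline_quantities(
    arr: _Arrays, t: float, selectors, reference: str,
    method: str = "exact", R: int = 200, draws_seed=None, warm=None,
    return_models: bool = False,
):
    """Refit both nuisance models and compute every reported quantity.

    Returns the fitted models as well when ``warm`` plumbing is used by the
    bootstrap (warm-starting each resample's Newton iterations from the
    full-sample fit)."""
    warm_prop, warm_haz = warm if warm is not None else (None, None)
    prop = PropensityModelSet.fit_arrays(
        arr.X_cov, arr.exposure, arr.m_statin, arr.m_rasi, warm=warm_prop
    )
    haz = fit_hazard_ladder(
        arr.X_cov, arr.exposure, arr.m_statin, arr.m_rasi, arr.time, arr.event,
        reference=reference, warm=warm_haz,
    )
    p_cache = {
        (g, med): prop.predict(g, med, arr.X_cov)
        for g in EXPOSURE_LEVELS
        for med in ("statin", "rasi")
    }
    if method == "mc":
        draws = mc_draws(len(arr.X_cov), R, draws_seed)

    out: dict = {}
    psi_obs = {}
    lp_cov = arr.X_cov @ haz.full_beta()[11:]
    for a in EXPOSURE_LEVELS:
        grid = _fast_risk_grid(haz, arr.X_cov, a, t, lp_cov=lp_cov)

        def _psi(stat_g, rasi_g):
            if method == "exact":
                return _psi_exact_arrays(grid, p_cache[(stat_g, "statin")], p_cache[(rasi_g, "rasi")])
            return _psi_mc_arrays(grid, p_cache[(stat_g, "statin")], p_cache[(rasi_g, "rasi")], draws)

        psi_obs[a] = _psi(a, a)
        out[f"psi_obs[{a}]"] = psi_obs[a]
        for sel in selectors:
            sg = reference if sel in ("both", "statin") else a
            rg = reference if sel in ("both", "rasi") else a
            psi_ref = _psi(sg, rg)
            out[f"psi_ref_{sel}[{a}]"] = psi_ref
            out[f"delta_{sel}[{a}]"] = psi_obs[a] - psi_ref
    for a, diff in total_effect_differences(psi_obs, reference).items():
        out[f"total_diff[{a}]"] = diff
    if return_models:
        return out, (prop, haz)
    return out


def bootstrap_cis(
    cohort: pd.DataFrame,
    statistic=None,
    B: int = 1000,
    seed=0,
    t: float = 5.0,
    selectors=SELECTORS,
    reference: str = REFERENCE_EXPOSURE,
    method: str = "exact",
    R: int = 200,
    max_failure_fraction: float = 0.10,
    alpha: float = 0.05,
):
    """Percentile bootstrap over individuals, refitting the entire pipeline
    (propensity fits, Cox fit, Breslow baseline, standardization) on each
    of B resamples (default 1000).

    ``statistic``, if given, is a callable ``cohort -> {name: value}``
    replacing the default full pipeline.  Returns ``(intervals, n_failed)``
    with ``intervals[name] = (lower, upper)``.  Resamples whose model fits
    fail are dropped and counted; more than ``max_failure_fraction`` of B
    failing is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    warm = None
    arr = None
    if statistic is None:
        arr = _Arrays.from_cohort(cohort)
        _, warm = _pipeline_quantities(
            arr, t, selectors, reference, method, R, None, return_models=True
        )
    draw_seeds = rng.integers(0, 2**31 - 1, size=B)
    results: dict[str, list] = {}
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            if statistic is None:
                vals = _pipeline_quantities(
                    arr.take(idx), t, selectors, reference, method, R, draw_seeds[b], warm=warm
                )
            else:
                vals = statistic(cohort.iloc[idx].reset_index(drop=True))
        except ModelFitError as exc:
            n_failed += 1
            logger.debug("bootstrap resample %d failed: %s", b, exc)
            continue
        for k, v in vals.items():
            results.setdefault(k, []).append(v)
    if n_failed > max_failure_fraction * B:
        raise ModelFitError(
            f"{n_failed}/{B} bootstrap resamples failed model fitting "
            f"(limit {max_failure_fraction:.0%}); the design is too rich for the data"
        )
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    intervals = {
        k: (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
        for k, v in results.items()
    }
    return intervals, n_failed


@dataclass
class MediationEstimate:
    """All standardized risks, differences and indirect effects with CIs."""

    horizon_years: float
    reference: str
    psi_obs: dict
    psi_ref: dict  # selector -> {group: value}
    total_diff: dict
    delta: dict  # selector -> {group: value}
    ci: dict = field(default_factory=dict)  # quantity name -> (lo, hi)
    mc_draws: int = 200
    bootstrap_samples: int = 0
    bootstrap_failed: int = 0
    method: str = "exact"
    seed: int | None = None
    n: int = 0
    n_events: int = 0

    def to_json_dict(self) -> dict:
        return {
            "horizon_years": self.horizon_years,
            "reference": self.reference,
            "psi_obs": self.psi_obs,
            "psi_ref": self.psi_ref,
            "total_diff": self.total_diff,
            "delta": self.delta,
            "ci": {k: list(v) for k, v in sorted(self.ci.items())},
            "mc_draws": self.mc_draws,
            "bootstrap_samples": self.bootstrap_samples,
            "bootstrap_failed": self.bootstrap_failed,
            "method": self.method,
            "seed": self.seed,
            "n": self.n,
            "n_events": self.n_events,
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat results table (one row per quantity)."""
        rows = []

        def _ci(name):
            lo, hi = self.ci.get(name, (float("nan"), float("nan")))
            return lo, hi

        for a in EXPOSURE_LEVELS:
            name = f"psi_obs[{a}]"
            rows.append(("standardized_risk_observed", a, "", self.psi_obs[a], *_ci(name)))
            name = f"total_diff[{a}]"
            rows.append(("risk_difference_vs_reference", a, "", self.total_diff[a], *_ci(name)))
            for sel in self.delta:
                name = f"delta_{sel}[{a}]"
                rows.append(("indirect_effect", a, sel, self.delta[sel][a], *_ci(name)))
        return pd.DataFrame(
            rows, columns=["quantity", "exposure", "selector", "estimate", "ci_lower", "ci_upper"]
        )


def estimate_mediation(
    cohort: pd.DataFrame,
    t: float = 5.0,
    R: int = 200,
    B: int = 1000,
    seed: int = 0,
    method: str = "exact",
    selectors=SELECTORS,
    reference: str = REFERENCE_EXPOSURE,
    bootstrap: bool = True,
) -> MediationEstimate:
    """One-call driver: fit models, standardize, contrast, bootstrap.

    ``method="exact"`` (default) enumerates the mediator combinations;
    ``method="mc"`` reproduces the repeated-random-assignment procedure
    with R draws and common random numbers.
    """
    rng = np.random.default_rng(seed)
    sub_mc, sub_boot = rng.integers(0, 2**31 - 1, size=2)
    arr = _Arrays.from_cohort(cohort)
    point = _pipeline_quantities(arr, t, selectors, reference, method, R, sub_mc)
    ci: dict = {}
    n_failed = 0
    if bootstrap:
        ci, n_failed = bootstrap_cis(
            cohort, B=B, seed=sub_boot, t=t, selectors=selectors,
            reference=reference, method=method, R=R,
        )
        for name, (lo, hi) in ci.items():
            val = point.get(name)
            if val is not None and not (lo <= val <= hi):
                logger.warning(
                    "bootstrap skew: point estimate %s=%.5f outside percentile interval "
                    "(%.5f, %.5f)", name, val, lo, hi,
                )
    psi_obs = {a: point[f"psi_obs[{a}]"] for a in EXPOSURE_LEVELS}
    psi_ref = {
        sel: {a: point[f"psi_ref_{sel}[{a}]"] for a in EXPOSURE_LEVELS} for sel in selectors
    }
    delta = {sel: {a: point[f"delta_{sel}[{a}]"] for a in EXPOSURE_LEVELS} for sel in selectors}
    total = {a: point[f"total_diff[{a}]"] for a in EXPOSURE_LEVELS}
    return MediationEstimate(
        horizon_years=t,
        reference=reference,
        psi_obs=psi_obs,
        psi_ref=psi_ref,
        total_diff=total,
        delta=delta,
        ci=ci,
        mc_draws=R,
        bootstrap_samples=B if bootstrap else 0,
        bootstrap_failed=n_failed,
        method=method,
        seed=int(seed),
        n=len(cohort),
        n_events=int(cohort["event"].sum()),
    )
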