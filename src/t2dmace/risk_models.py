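"""Nuisance models: mediator propensity logistics and the MACE Cox model.

Eight logistic regressions (one per exposure group x mediator) model the
propensity of statin / RASi initiation before the index date given the
adjustment covariates.  A single Cox proportional-hazards model for the
MACE composite carries exposure contrasts, both mediators, full exposure x
mediator interactions (each group keeps its own mediator effect) and the
covariate expansion; the Breslow estimator of the baseline cumulative
hazard turns it into an absolute-risk machine:

    risk(t | x) = 1 - exp(-Lambda0(t) * exp(x' beta)).

Both solvers are plain Newton–Raphson on dense numpy arrays so that the
bootstrap (which refits everything per resample) stays fast; Efron's
correction handles the heavy day-grid ties of registry follow-up.  Fitted
models serialize to self-describing JSON documents for exact reload.

Degenerate designs are handled explicitly: zero-variance columns are
dropped (coefficient 0); a propensity outcome that is constant within a
group falls back to the empirical proportion; non-convergence walks a
fallback ladder (maximum likelihood -> ridge-stabilized -> empirical) and
only then errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._design import (
    EXPOSURE_LEVELS,
    MEDIATORS,
    REFERENCE_EXPOSURE,
    build_covariate_design,
    build_cox_design,
    covariate_design_columns,
    cox_design_columns,
)

__all__ = [
    "ModelFitError",
    "PredictionError",
    "LogisticModel",
    "PropensityModelSet",
    "HazardModel",
    "fit_mediator_propensities",
    "fit_mace_hazard",
    "predict_absolute_risk",
]

logger = logging.getLogger("t2dmace")

_PROB_EPS = 1e-12


class ModelFitError(RuntimeError):
    pass


class PredictionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# logistic regression (IRLS / Newton)
# ---------------------------------------------------------------------------


def _logistic_loglik(eta, y, beta, ridge):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * ridge * np.sum(beta[1:] ** 2))


def _logistic_newton(X, y, ridge=0.0, max_iter=60, tol=1e-8, beta0=None):
    """Newton MLE for logit(P(y=1)) = X beta; X includes the intercept
    column first.  The ridge penalty (if any) spares the intercept.
    ``beta0`` warm-starts the iteration (e.g. from the full-sample fit when
    refitting bootstrap resamples)."""
    n, p = X.shape
    if beta0 is not None and len(beta0) == p:
        beta = np.array(beta0, dtype=float)
    else:
        beta = np.zeros(p)
        pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[0] = np.log(pbar / (1 - pbar))
    pen = np.zeros(p)
    pen[1:] = ridge
    with np.errstate(over="ignore"):
        ll = _logistic_loglik(X @ beta, y, beta, ridge)
        H = None
        for _ in range(max_iter):
            eta = X @ beta
            mu = expit(eta)
            w = mu * (1 - mu) + 1e-12
            grad = X.T @ (y - mu) - pen * beta
            H = (X * w[:, None]).T @ X
            H[np.diag_indices_from(H)] += pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:
                raise ModelFitError(f"singular information matrix: {exc}") from None
            # step-halving line search
            for _ in range(30):
                cand = beta + step
                ll_new = _logistic_loglik(X @ cand, y, cand, ridge)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                step = step / 2.0
            moved = np.max(np.abs(cand - beta))
            beta, ll = cand, ll_new
            # a coefficient this large on a dummy/flag design is separation
            if np.max(np.abs(beta)) > 20:
                raise ModelFitError("divergent coefficients (separation suspected)")
            if moved < tol:
                break
        else:
            raise ModelFitError("logistic Newton did not converge")
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov)), ll


@dataclass
class LogisticModel:
    """One fitted propensity model over the covariate design expansion."""

    intercept: float
    coef: np.ndarray  # over kept covariate design columns
    columns: list
    kept: np.ndarray  # boolean mask over ``columns``
    se: np.ndarray | None = None
    kind: str = "mle"  # mle | ridge | empirical

    def predict(self, X_cov: np.ndarray) -> np.ndarray:
        if self.kind == "empirical":
            p = np.full(len(X_cov), self.intercept)
        else:
            p = expit(self.intercept + X_cov[:, self.kept] @ self.coef)
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)

    def full_coef(self) -> np.ndarray:
        out = np.zeros(len(self.columns))
        if self.kind != "empirical":
            out[self.kept] = self.coef
        return out

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "intercept": float(self.intercept),
            "coef": [float(v) for v in np.atleast_1d(self.coef)],
            "columns": list(self.columns),
            "kept": [bool(k) for k in np.atleast_1d(self.kept)],
            "se": None if self.se is None else [float(v) for v in np.atleast_1d(self.se)],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            intercept=d["intercept"],
            coef=np.asarray(d["coef"], dtype=float),
            columns=list(d["columns"]),
            kept=np.asarray(d["kept"], dtype=bool),
            se=None if d.get("se") is None else np.asarray(d["se"], dtype=float),
            kind=d["kind"],
        )


def _fit_logistic_ladder(X_cov, y, columns, group, mediator, ridge_fallback=1e-2, warm=None):
    y = np.asarray(y, dtype=float)
    if y.mean() in (0.0, 1.0):
        logger.warning(
            "propensity %s/%s: mediator constant at %d; using empirical proportion",
            group,
            mediator,
            int(y.mean()),
        )
        return LogisticModel(float(y.mean()), np.zeros(0), columns, np.zeros(len(columns), bool), kind="empirical")
    kept = X_cov.std(axis=0) > 0
    Xk = np.column_stack([np.ones(len(y)), X_cov[:, kept]])
    beta0 = None
    if warm is not None and warm.kind != "empirical":
        beta0 = np.concatenate([[warm.intercept], warm.full_coef()[kept]])
    # quasi-complete separation pre-check (all design columns are 0/1): a
    # dummy level with constant outcome has no finite MLE, so start at the
    # ridge rung directly
    Xd = X_cov[:, kept]
    n1 = Xd.sum(axis=0)
    t1 = y @ Xd
    ysum = y.sum()
    quasi_sep = bool(
        np.any((t1 == 0) | (t1 == n1) | (ysum - t1 == 0) | (ysum - t1 == len(y) - n1))
    )
    rungs = ((0.0, "mle"), (ridge_fallback, "ridge"))
    if quasi_sep:
        rungs = ((ridge_fallback, "ridge"),)
    for ridge, kind in rungs:
        try:
            beta, se, _ = _logistic_newton(Xk, y, ridge=ridge, beta0=beta0)
            if kind == "ridge":
                logger.debug("propensity %s/%s: ridge-stabilized fit", group, mediator)
            return LogisticModel(beta[0], beta[1:], columns, kept, se=se[1:], kind=kind)
        except ModelFitError:
            continue
    logger.warning("propensity %s/%s: falling back to empirical proportion", group, mediator)
    return LogisticModel(float(y.mean()), np.zeros(0), columns, np.zeros(len(columns), bool), kind="empirical")


@dataclass
class PropensityModelSet:
    """Per-(exposure group, mediator) logistic propensity models, 8 total."""

    models: dict = field(default_factory=dict)  # (group, mediator) -> LogisticModel
    columns: list = field(default_factory=covariate_design_columns)

    @classmethod
    def fit_arrays(cls, X_cov, exposure, m_statin, m_rasi, warm=None) -> "PropensityModelSet":
        cols = covariate_design_columns()
        out = cls(columns=cols)
        med_y = {"statin": np.asarray(m_statin), "rasi": np.asarray(m_rasi)}
        exposure = np.asarray(exposure, dtype=object)
        for g in EXPOSURE_LEVELS:
            mask = exposure == g
            if not mask.any():
                raise ModelFitError(f"no participants in exposure group {g!r}")
            for med in MEDIATORS:
                out.models[(g, med)] = _fit_logistic_ladder(
                    X_cov[mask], med_y[med][mask], cols, g, med,
                    warm=None if warm is None else warm.models.get((g, med)),
                )
        return out

    def predict(self, group: str, mediator: str, X_cov: np.ndarray) -> np.ndarray:
        try:
            model = self.models[(group, mediator)]
        except KeyError:
            raise PredictionError(f"no fitted propensity model for ({group!r}, {mediator!r})")
        return model.predict(X_cov)

    def to_json_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "models": {f"{g}|{m}": mod.to_json_dict() for (g, m), mod in sorted(self.models.items())},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PropensityModelSet":
        out = cls(columns=list(d["columns"]))
        for key, md in d["models"].items():
            g, m = key.split("|")
            out.models[(g, m)] = LogisticModel.from_json_dict(md)
        return out


def fit_mediator_propensities(cohort) -> PropensityModelSet:
    """Fit all 8 propensity models from an analysis cohort DataFrame."""
    X_cov = build_covariate_design(cohort)
    return PropensityModelSet.fit_arrays(
        X_cov, cohort["exposure"].to_numpy(), cohort["m_statin"].to_numpy(), cohort["m_rasi"].to_numpy()
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards, Efron ties, Breslow baseline
# ---------------------------------------------------------------------------


def _cox_efron_newton(X, time, event, ridge=0.0, max_iter=60, tol=1e-9, beta0=None):
    """Newton maximization of the Efron-corrected partial likelihood.

    Returns (beta, information matrix, loglik).  ``X`` should be centered
    by the caller for numerical stability.  ``beta0`` warm-starts the
    iteration.
    """
    n, p = X.shape
    if p == 0:
        return np.zeros(0), np.zeros((0, 0)), 0.0
    order = np.argsort(time, kind="mergesort")
    Xs = X[order]
    ts = time[order]
    es = np.asarray(event, dtype=bool)[order]
    ev_idx = np.flatnonzero(es)
    if len(ev_idx) == 0:
        raise ModelFitError("no events in sample")
    t_ev = ts[ev_idx]
    X_ev = Xs[ev_idx]
    uniq_t, grp_start = np.unique(t_ev, return_index=True)
    m = len(ev_idx)
    n_grp = len(uniq_t)
    grp_sizes = np.diff(np.append(grp_start, m))
    grp_of_event = np.repeat(np.arange(n_grp), grp_sizes)
    l_within = np.arange(m) - grp_start[grp_of_event]
    frac = l_within / grp_sizes[grp_of_event]
    risk_start = np.searchsorted(ts, uniq_t, side="left")
    sum_x_events = X_ev.sum(axis=0)

    def loglik_only(beta):
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            eta = Xs @ beta
            w = np.exp(eta)
            S0 = np.cumsum(w[::-1])[::-1][risk_start]
            T0 = np.add.reduceat(w[ev_idx], grp_start)
            D = S0[grp_of_event] - frac * T0[grp_of_event]
            return float(eta[ev_idx].sum() - np.log(D).sum() - 0.5 * ridge * beta @ beta)

    beta = np.array(beta0, dtype=float) if beta0 is not None and len(beta0) == p else np.zeros(p)
    ll = loglik_only(beta)
    if not np.isfinite(ll):
        beta = np.zeros(p)
        ll = loglik_only(beta)
    H = None
    for _ in range(max_iter):
        with np.errstate(over="ignore"):
            eta = Xs @ beta
            w = np.exp(eta)
        w_ev = w[ev_idx]
        S0 = np.cumsum(w[::-1])[::-1][risk_start]
        S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1][risk_start]
        T0 = np.add.reduceat(w_ev, grp_start)
        T1 = np.add.reduceat(w_ev[:, None] * X_ev, grp_start, axis=0)
        D = S0[grp_of_event] - frac * T0[grp_of_event]
        a = 1.0 / D
        b = frac / D
        a_cum = np.cumsum(a)
        pos = np.searchsorted(t_ev, ts, side="right") - 1
        A = np.where(pos >= 0, a_cum[np.maximum(pos, 0)], 0.0)
        B = np.add.reduceat(b, grp_start)
        wA = w * A
        wB_ev = w_ev * B[grp_of_event]
        grad = sum_x_events - Xs.T @ wA + X_ev.T @ wB_ev - ridge * beta
        Ge = (S1[grp_of_event] - frac[:, None] * T1[grp_of_event]) * a[:, None]
        H = Xs.T @ (Xs * wA[:, None]) - X_ev.T @ (X_ev * wB_ev[:, None]) - Ge.T @ Ge
        H = H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise ModelFitError(
                "singular information matrix in Cox fit; consider reducing the design"
            ) from None
        for _ in range(30):
            cand = beta + step
            ll_new = loglik_only(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        moved = np.max(np.abs(cand - beta))
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > 25:
            raise ModelFitError(
                "divergent Cox coefficients (monotone likelihood / separation); "
                "consider reducing the design"
            )
        if moved < tol:
            break
    else:
        raise ModelFitError("Cox Newton did not converge")
    return beta, H, ll


def _breslow_baseline(X_raw, time, event, beta):
    """Breslow estimator of the baseline cumulative hazard on the raw
    (uncentered) design: Lambda0 jumps d_i / sum_{R(t_i)} exp(x'beta)."""
    order = np.argsort(time, kind="mergesort")
    ts = time[order]
    es = np.asarray(event, dtype=bool)[order]
    w = np.exp(X_raw[order] @ beta) if len(beta) else np.ones(len(ts))
    ev_idx = np.flatnonzero(es)
    t_ev = ts[ev_idx]
    uniq_t, grp_start = np.unique(t_ev, return_index=True)
    grp_sizes = np.diff(np.append(grp_start, len(ev_idx)))
    risk_start = np.searchsorted(ts, uniq_t, side="left")
    S0 = np.cumsum(w[::-1])[::-1][risk_start]
    jumps = grp_sizes / S0
    return uniq_t, np.cumsum(jumps)


@dataclass
class HazardModel:
    """Fitted MACE Cox model with Breslow baseline cumulative hazard."""

    columns: list
    kept: np.ndarray  # boolean mask over columns (zero-variance dropped)
    beta: np.ndarray  # over kept columns
    se: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    reference: str = REFERENCE_EXPOSURE
    loglik: float = float("nan")
    n: int = 0
    n_events: int = 0

    def full_beta(self) -> np.ndarray:
        out = np.zeros(len(self.columns))
        out[self.kept] = self.beta
        return out

    def cumhaz_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise PredictionError("time must be nonnegative")
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        out = np.where(idx >= 0, self.baseline_cumhaz[np.maximum(idx, 0)], 0.0)
        return out

    def linear_predictor(self, X_cov, exposure, m_statin, m_rasi) -> np.ndarray:
        X = build_cox_design(
            np.asarray(exposure, dtype=object), m_statin, m_rasi, X_cov, self.reference
        )
        return X @ self.full_beta()

    def predict_absolute_risk(self, X_cov, exposure, m_statin, m_rasi, t) -> np.ndarray:
        lp = self.linear_predictor(X_cov, exposure, m_statin, m_rasi)
        lam = self.cumhaz_at(t)
        return 1.0 - np.exp(-lam * np.exp(lp))

    def to_json_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "kept": [bool(k) for k in self.kept],
            "beta": [float(v) for v in self.beta],
            "se": [float(v) for v in self.se],
            "baseline_times": [float(v) for v in self.baseline_times],
            "baseline_cumhaz": [float(v) for v in self.baseline_cumhaz],
            "reference": self.reference,
            "loglik": float(self.loglik),
            "n": int(self.n),
            "n_events": int(self.n_events),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "HazardModel":
        return cls(
            columns=list(d["columns"]),
            kept=np.asarray(d["kept"], dtype=bool),
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], dtype=float),
            reference=d["reference"],
            loglik=d["loglik"],
            n=d["n"],
            n_events=d["n_events"],
        )

    @classmethod
    def fit_arrays(
        cls,
        X_cov,
        exposure,
        m_statin,
        m_rasi,
        time,
        event,
        reference: str = REFERENCE_EXPOSURE,
        ridge: float = 0.0,
        warm=None,
    ) -> "HazardModel":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if (time <= 0).any():
            raise ModelFitError("follow-up times must be positive")
        if event.sum() < 1:
            raise ModelFitError("at least one event is required")
        exposure = np.asarray(exposure, dtype=object)
        X = build_cox_design(exposure, m_statin, m_rasi, X_cov, reference)
        cols = cox_design_columns(reference)
        kept = X.std(axis=0) > 0
        Xk = X[:, kept]
        if ridge == 0.0:
            # a varying 0/1 column with no events among its level makes the
            # partial likelihood monotone (beta -> -inf): no finite MLE
            binary = np.all((Xk == 0) | (Xk == 1), axis=0)
            ev_count = event @ Xk
            if np.any(binary & (ev_count == 0)):
                raise ModelFitError(
                    "monotone partial likelihood: a design level carries no events; "
                    "consider reducing the design"
                )
        xbar = Xk.mean(axis=0)
        beta0 = warm.full_beta()[kept] if warm is not None else None
        beta, H, ll = _cox_efron_newton(Xk - xbar, time, event, ridge=ridge, beta0=beta0)
        if len(beta):
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
        else:
            se = np.zeros(0)
        bt, bh = _breslow_baseline(Xk, time, event, beta)
        return cls(
            columns=cols,
            kept=kept,
            beta=beta,
            se=se,
            baseline_times=bt,
            baseline_cumhaz=bh,
            reference=reference,
            loglik=ll,
            n=len(time),
            n_events=int(event.sum()),
        )


def fit_hazard_ladder(
    X_cov, exposure, m_statin, m_rasi, time, event,
    reference: str = REFERENCE_EXPOSURE,
    ridge_ladder=(0.0, 1e-2, 1e-1),
    warm=None,
) -> HazardModel:
    """Cox fit with a stabilization ladder for resampling loops.

    Tries plain maximum partial likelihood first; on monotone likelihood
    (e.g. a rare exposure x mediator cell with no events in a bootstrap
    resample) retries with increasing small ridge penalties before giving
    up.  Penalized refits are logged at debug level."""
    last: Exception | None = None
    for ridge in ridge_ladder:
        try:
            model = HazardModel.fit_arrays(
                X_cov, exposure, m_statin, m_rasi, time, event,
                reference=reference, ridge=ridge, warm=warm,
            )
            if ridge > 0:
                logger.debug("Cox fit ridge-stabilized (ridge=%g)", ridge)
            return model
        except ModelFitError as exc:
            last = exc
    raise last  # type: ignore[misc]


def fit_mace_hazard(cohort, reference: str = REFERENCE_EXPOSURE, ridge: float = 0.0) -> HazardModel:
    """Fit the MACE Cox model (exposure, mediators, interactions,
    covariates) from an analysis cohort DataFrame."""
    X_cov = build_covariate_design(cohort)
    return HazardModel.fit_arrays(
        X_cov,
        cohort["exposure"].to_numpy(),
        cohort["m_statin"].to_numpy(),
        cohort["m_rasi"].to_numpy(),
        cohort["followup_years"].to_numpy(),
        cohort["event"].to_numpy(),
        reference=reference,
        ridge=ridge,
    )


def predict_absolute_risk(model: HazardModel, cohort, exposure, m_statin, m_rasi, t):
    """Absolute MACE risk at ``t`` years for each cohort row with exposure
    and mediators set by intervention."""
    X_cov = build_covariate_design(cohort)
    n = len(cohort)
    expo = np.full(n, exposure, dtype=object) if isinstance(exposure, str) else np.asarray(exposure, dtype=object)
    ms = np.full(n, m_statin) if np.isscalar(m_statin) else np.asarray(m_statin)
    mr = np.full(n, m_rasi) if np.isscalar(m_rasi) else np.asarray(m_rasi)
    try:
        return model.predict_absolute_risk(X_cov, expo, ms, mr, t)
    except ValueError as exc:
        raise PredictionError(str(exc)) from None
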