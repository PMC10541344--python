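"""Nonparametric risk estimators.

Stratified Kaplan–Meier crude cumulative incidence (appropriate here
because all-cause death is inside the MACE composite, so there is no
competing event for the primary outcome), and the Aalen–Johansen cumulative
incidence function for treatment initiation with MACE as a competing risk.

Tie convention: events at a time t precede censorings at t (censored
subjects at t remain in the risk set for events at t).  Point estimates
only; step functions are right-continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StepFunctionEstimate", "kaplan_meier_cuminc", "aalen_johansen_cif"]


@dataclass
class StepFunctionEstimate:
    """Right-continuous step function with value 0 before the first jump."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return vals if vals.ndim else float(vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "estimate": self.values})


def _validate(times, status, codes):
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    if len(times) != len(status):
        raise ValueError("times and status must have equal length")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    bad = set(np.unique(status)) - set(codes)
    if bad:
        raise ValueError(f"status codes {sorted(bad)} outside declared set {sorted(codes)}")
    return times, status.astype(int)


def _event_table(times, status):
    """Unique sorted times with per-cause event counts and numbers at risk."""
    order = np.argsort(times, kind="mergesort")
    t = times[order]
    s = status[order]
    ut, start = np.unique(t, return_index=True)
    n = len(t)
    n_at_risk = n - start
    counts = {}
    for code in np.unique(s):
        cum = np.concatenate([[0], np.cumsum(s == code)])
        end = np.concatenate([start[1:], [n]])
        counts[int(code)] = cum[end] - cum[start]
    return ut, n_at_risk, counts


def kaplan_meier_cuminc(times, status, strata=None, horizon: float | None = None):
    """Kaplan–Meier cumulative incidence, 1 - prod(1 - d_i/n_i), per stratum.

    ``status`` codes: 0 censored, 1 event.  Returns
    ``{stratum: StepFunctionEstimate}`` and, if ``horizon`` is given, a
    second dict of risks at the horizon.  With ``strata=None`` a single
    stratum ``"all"`` is used.  An empty stratum raises, naming it.
    """
    times, status = _validate(times, status, (0, 1))
    if strata is None:
        strata = np.full(len(times), "all", dtype=object)
    strata = np.asarray(strata, dtype=object)
    curves: dict = {}
    risks: dict = {}
    for s in pd.unique(strata):
        mask = strata == s
        if not mask.any():
            raise ValueError(f"empty stratum {s!r}")
        ut, n_at_risk, counts = _event_table(times[mask], status[mask])
        d = counts.get(1, np.zeros(len(ut), dtype=int))
        surv = np.cumprod(1.0 - d / n_at_risk)
        est = StepFunctionEstimate(ut, 1.0 - surv)
        curves[s] = est
        if horizon is not None:
            risks[s] = est(horizon)
    if horizon is None:
        return curves
    return curves, risks


def aalen_johansen_cif(times, status, cause: int = 1, horizon: float | None = None):
    """Aalen–Johansen cumulative incidence of ``cause``.

    ``status`` codes: 0 censored, 1.. causes; CIF_k(t) =
    sum_{t_i <= t} S(t_i-) d_{k,i} / n_i with S the all-cause Kaplan–Meier
    survivor function.  Returns a StepFunctionEstimate (and the value at
    ``horizon`` if given).
    """
    times_arr = np.asarray(times, dtype=float)
    status_arr = np.asarray(status).astype(int)
    codes = set(np.unique(status_arr))
    if cause not in codes:
        raise ValueError(f"cause {cause} not present in status codes {sorted(codes)}")
    times_arr, status_arr = _validate(times_arr, status_arr, codes | {0})
    ut, n_at_risk, counts = _event_table(times_arr, status_arr)
    d_all = sum(counts.get(c, 0) for c in codes if c != 0)
    d_all = np.asarray(d_all)
    surv = np.cumprod(1.0 - d_all / n_at_risk)
    surv_minus = np.concatenate([[1.0], surv[:-1]])
    d_k = counts.get(cause, np.zeros(len(ut), dtype=int))
    cif = np.cumsum(surv_minus * d_k / n_at_risk)
    est = StepFunctionEstimate(ut, cif)
    if horizon is None:
        return est
    return est, est(horizon)
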