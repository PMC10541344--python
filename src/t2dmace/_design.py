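"""Shared design-matrix construction for the adjustment covariates.

All regression models in this package (mediator propensity logistics, the
MACE Cox model) and the simulator's generative linear predictors share one
canonical design expansion: treatment-contrast (reference level) dummy
coding of a fixed set of categorical covariates plus four binary
comorbidity flags.  Keeping the expansion in one place guarantees that a
coefficient named in a simulation config, a fitted model and a serialized
model document all refer to the same column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Exposure groups at the index date: GLDT yes/no x latest qualifying HbA1c
# band.  WC_GLDT (well-controlled on glucose-lowering drug treatment) is the
# reference group throughout.
EXPOSURE_LEVELS = ("WC_GLDT", "PC_GLDT", "REMISSION", "PERSISTENT")
REFERENCE_EXPOSURE = "WC_GLDT"

MEDIATORS = ("statin", "rasi")

AGE_BANDS = ("40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-80")

# factor name -> ordered levels; the first level is the reference.
COVARIATE_FACTORS: dict[str, tuple[str, ...]] = {
    "age_band": AGE_BANDS,
    "sex": ("F", "M"),
    "cohabitation": ("cohabiting", "living_alone"),
    "income_quartile": ("Q1", "Q2", "Q3", "Q4", "unknown"),
    "ethnicity": ("native", "immigrant"),
    "requester": ("GP", "other"),
    "first_hba1c_band": ("48-52", "53-57"),
    "egfr_band": (">=90", "60-89", "30-59", "unknown"),
}

# 0/1 flags, entered as-is.
COVARIATE_FLAGS = ("hf", "af", "copd_asthma", "cancer")

COVARIATE_COLUMNS_ALL = tuple(COVARIATE_FACTORS) + COVARIATE_FLAGS


def covariate_design_columns() -> list[str]:
    """Column names of the covariate design expansion (no intercept)."""
    cols: list[str] = []
    for name, levels in COVARIATE_FACTORS.items():
        cols.extend(f"{name}={lvl}" for lvl in levels[1:])
    cols.extend(COVARIATE_FLAGS)
    return cols


def build_covariate_design(df: pd.DataFrame) -> np.ndarray:
    """Expand the covariate columns of ``df`` into a dense design matrix.

    Returns an (n, p) float array whose columns follow
    :func:`covariate_design_columns`.  Raises ``ValueError`` naming any
    unseen factor level.
    """
    n = len(df)
    blocks: list[np.ndarray] = []
    for name, levels in COVARIATE_FACTORS.items():
        vals = df[name].to_numpy()
        lut = {lvl: i for i, lvl in enumerate(levels)}
        try:
            codes = np.array([lut[v] for v in vals], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValueError(f"unseen level {exc.args[0]!r} for factor {name!r}") from None
        block = np.zeros((n, len(levels) - 1))
        for j in range(1, len(levels)):
            block[:, j - 1] = codes == j
        blocks.append(block)
    flags = df[list(COVARIATE_FLAGS)].to_numpy(dtype=float)
    blocks.append(flags)
    return np.hstack(blocks)


def exposure_design_columns(reference: str = REFERENCE_EXPOSURE) -> list[str]:
    others = [g for g in EXPOSURE_LEVELS if g != reference]
    cols = [f"exposure={g}" for g in others]
    cols += ["m_statin", "m_rasi"]
    cols += [f"exposure={g}:m_statin" for g in others]
    cols += [f"exposure={g}:m_rasi" for g in others]
    return cols


def cox_design_columns(reference: str = REFERENCE_EXPOSURE) -> list[str]:
    """Full Cox design: exposure contrasts, mediators, their interactions,
    then the covariate expansion."""
    return exposure_design_columns(reference) + covariate_design_columns()


def build_cox_design(
    exposure: np.ndarray,
    m_statin: np.ndarray,
    m_rasi: np.ndarray,
    covariate_design: np.ndarray,
    reference: str = REFERENCE_EXPOSURE,
) -> np.ndarray:
    """Assemble the Cox design matrix for given exposure/mediator columns.

    ``exposure`` is an array of group labels; mediators are 0/1 arrays;
    ``covariate_design`` is the output of :func:`build_covariate_design`.
    """
    others = [g for g in EXPOSURE_LEVELS if g != reference]
    unknown = set(np.unique(exposure)) - set(EXPOSURE_LEVELS)
    if unknown:
        raise ValueError(f"unseen exposure level(s): {sorted(unknown)}")
    n = len(exposure)
    expo = np.zeros((n, len(others)))
    for j, g in enumerate(others):
        expo[:, j] = exposure == g
    ms = np.asarray(m_statin, dtype=float).reshape(n, 1)
    mr = np.asarray(m_rasi, dtype=float).reshape(n, 1)
    inter_s = expo * ms
    inter_r = expo * mr
    return np.hstack([expo, ms, mr, inter_s, inter_r, covariate_design])


def coeff_vector(coeffs: dict[str, float], columns: list[str], context: str = "coefficients") -> np.ndarray:
    """Turn a {column name -> value} mapping into a dense vector.

    Unspecified columns default to 0.  A name not among ``columns`` (and not
    ``"intercept"``) raises a ``ValueError`` so that config typos surface.
    """
    idx = {c: i for i, c in enumerate(columns)}
    beta = np.zeros(len(columns))
    for name, value in coeffs.items():
        if name == "intercept":
            continue
        if name not in idx:
            raise ValueError(f"{context}: unknown design column {name!r}")
        beta[idx[name]] = float(value)
    return beta
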