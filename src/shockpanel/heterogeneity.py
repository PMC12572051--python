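"""Effect-heterogeneity screening and stratified estimation.

The squared semi-partial correlation of covariate ``j`` with the estimated
individual-level effects is the drop in R-squared between a linear fit of the
effects on all covariates and the same fit without ``j`` — the share of
independent variation attributable to ``j``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .aipw import AteEstimate, subgroup_ate

logger = logging.getLogger(__name__)


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of an OLS fit with intercept (minimum-norm under rank deficiency)."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / tss)


def spc2(effects: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """Squared semi-partial correlation of each covariate with the effects.

    Sorted descending, ties broken by covariate name.
    """
    effects = np.asarray(effects, float)
    if len(effects) != len(X):
        raise ValueError("effects and covariates must have equal length")
    if len(effects) <= X.shape[1]:
        raise ValueError("need more observations than covariates for the fits")
    cols = list(X.columns)
    M = X.to_numpy(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(M)), M]))
    if rank < M.shape[1] + 1:
        logger.info("design is rank-deficient (%d < %d); aliased covariates get SPC2 0",
                    rank, M.shape[1] + 1)
    r2_full = _r_squared(effects, M)
    rows = []
    for j, name in enumerate(cols):
        r2_wo = _r_squared(effects, np.delete(M, j, axis=1))
        rows.append({"covariate": name, "spc2": float(np.clip(r2_full - r2_wo, 0.0, 1.0))})
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["spc2", "covariate"], ascending=[False, True]
    ).reset_index(drop=True)


def default_strata(X: pd.DataFrame, education_cut: float | None = None) -> dict[str, np.ndarray]:
    """Gender, single-status, and education strata from pre-treatment columns.

    Education splits at ``education_cut`` years (default: sample median).
    """
    strata: dict[str, np.ndarray] = {}
    if "female" in X.columns:
        f = X["female"].to_numpy(float)
        strata["female"] = f == 1
        strata["male"] = f == 0
    if "single" in X.columns:
        s = X["single"].to_numpy(float)
        strata["single"] = s == 1
        strata["not_single"] = s == 0
    if "educ_years" in X.columns:
        e = X["educ_years"].to_numpy(float)
        cut = float(np.median(e)) if education_cut is None else float(education_cut)
        strata["educ_high"] = e > cut
        strata["educ_low"] = e <= cut
    return strata


def stratified_effects(
    estimate: AteEstimate, X: pd.DataFrame, strata: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Subgroup ATEs per stratum from retained per-row summands."""
    strata = strata if strata is not None else default_strata(X)
    rows = []
    for name, mask in strata.items():
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError(f"empty stratum {name!r}")
        est = subgroup_ate(estimate, mask)
        rows.append(
            {
                "stratum": name, "n": int(mask.sum()), "estimate": est.estimate,
                "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)
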