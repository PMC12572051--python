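"""Balance, descriptive, sensitivity, and attrition diagnostics."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .aipw import ddml_ate, naive_difference
from .samples import TimingSpec, attrition_outcome, build_sample, lag_grid

logger = logging.getLogger(__name__)

ASMD_FLAG_THRESHOLD = 0.1


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[np.isfinite(x)])
    return np.all(np.isin(vals, (0.0, 1.0)))


def asmd(sample) -> pd.DataFrame:
    """Absolute standardized mean difference per covariate.

    |mean1 - mean0| / sqrt((s1^2 + s0^2) / 2), with s^2 = p(1 - p) for binary
    covariates.  Covariates with zero pooled variance get ASMD 0 when the
    means agree and NaN (flagged incomputable) otherwise.
    """
    t = np.asarray(sample.t, bool)
    if t.all() or not t.any():
        raise ValueError("both arms must be non-empty")
    records = []
    for col in sample.X.columns:
        x = sample.X[col].to_numpy(float)
        x1, x0 = x[t], x[~t]
        m1, m0 = x1.mean(), x0.mean()
        if _is_binary(x):
            v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
        else:
            v1 = x1.var(ddof=1) if len(x1) > 1 else 0.0
            v0 = x0.var(ddof=1) if len(x0) > 1 else 0.0
        pooled = np.sqrt((v1 + v0) / 2.0)
        if pooled == 0.0:
            value = 0.0 if np.isclose(m1, m0) else np.nan
        else:
            value = abs(m1 - m0) / pooled
        records.append(
            {
                "covariate": col,
                "asmd": value,
                "imbalanced": bool(np.isnan(value) or value > ASMD_FLAG_THRESHOLD),
            }
        )
    return pd.DataFrame(records).sort_values("asmd", ascending=False).reset_index(drop=True)


def chi2_equal_shares(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table
    [[a, b], [c, d]]; returns (statistic, p-value)."""
    table = np.array([[a, b], [c, d]], float)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def pretreatment_outcome_table(panel, threshold=0.25, outcomes=None, domains=None) -> pd.DataFrame:
    """Pre-window outcome shares overall / by shock status with chi2 p-values."""
    from .shocks import DOMAINS

    outcomes = outcomes or ("smoke", "diet", "sport")
    domains = domains or DOMAINS
    rows = []
    for outcome in outcomes:
        for domain in domains:
            # use each outcome's first feasible reference wave at lag 0
            t_ref = _default_reference(panel, outcome)
            timing = TimingSpec(outcome, domain, t_ref, lag_grid(outcome)[0])
            sample = build_sample(panel, timing, threshold)
            ylag = sample.X["y_lag"].to_numpy(float)
            treated = sample.t.astype(bool)
            n1, n0 = int(treated.sum()), int((~treated).sum())
            a = int(ylag[treated].sum())
            c = int(ylag[~treated].sum())
            stat, p = chi2_equal_shares(a, n1 - a, c, n0 - c)
            rows.append(
                {
                    "outcome": outcome,
                    "domain": domain,
                    "n": sample.n,
                    "share_overall": float(ylag.mean()),
                    "n_shock": n1,
                    "share_shock": a / n1 if n1 else np.nan,
                    "n_noshock": n0,
                    "share_noshock": c / n0 if n0 else np.nan,
                    "chi2": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _default_reference(panel, outcome: str) -> int:
    """First score wave with a computable shock and an earlier outcome wave."""
    waves = sorted(panel.waves.loc[panel.waves["mcs"].notna(), "year"].unique())
    ycol = {"smoke": "y_smoke", "diet": "y_diet", "sport": "y_sport"}[outcome]
    yyears = sorted(panel.waves.loc[panel.waves[ycol].notna(), "year"].unique())
    for t in waves[1:]:
        if any(y <= t - 2 for y in yyears):
            return int(t)
    raise ValueError(f"no feasible reference wave for {outcome}")


def threshold_sensitivity(
    panel,
    timing: TimingSpec,
    spec=None,
    thresholds=None,
    K: int = 5,
    R: int = 3,
    seed: int = 0,
    min_treated: int = 30,
) -> pd.DataFrame:
    """Re-estimate the ATE over a grid of shock-definition thresholds.

    Cells with fewer treated rows than ``min_treated`` are flagged and not
    estimated.  The same seed path is used at every threshold, so the cell at
    the main threshold reproduces the main estimate exactly.
    """
    if thresholds is None:
        thresholds = [round(x, 2) for x in np.arange(0.01, 0.41, 0.01)]
    rows = []
    for thr in thresholds:
        sample = build_sample(panel, timing, thr)
        row = {"threshold": float(thr), "n": sample.n, "n_treated": sample.n_treated}
        if sample.n_treated < min_treated or sample.n - sample.n_treated < min_treated:
            row.update(estimate=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                       flagged=True)
            logger.info("threshold %.2f flagged: %d treated", thr, sample.n_treated)
        else:
            est = ddml_ate(sample, spec, K=K, R=R, seed=seed, keep_summands=False)
            row.update(estimate=est.estimate, se=est.se, ci_low=est.ci_low,
                       ci_high=est.ci_high, flagged=False)
        rows.append(row)
    return pd.DataFrame(rows)


def attrition_rates(panel, outcome: str, domain: str, threshold=0.25) -> pd.DataFrame:
    """Share of the baseline (first-lag) sample missing the outcome at each
    later lag, per treatment x baseline-outcome cell."""
    t_ref = _default_reference(panel, outcome)
    grid = lag_grid(outcome)
    base = build_sample(panel, TimingSpec(outcome, domain, t_ref, grid[0]), threshold)
    ycol = {"smoke": "y_smoke", "diet": "y_diet", "sport": "y_sport"}[outcome]
    ywide = panel.waves.pivot(index="id", columns="year", values=ycol)
    base_ids = pd.Index(base.ids)
    cells = {
        (tr, y0): base_ids[(base.t == tr) & (base.y == y0)]
        for tr in (0, 1)
        for y0 in (0, 1)
    }
    rows = []
    for s in grid[1:]:
        year = t_ref + s
        observed = ywide[year].notna() if year in ywide.columns else pd.Series(False, ywide.index)
        for (tr, y0), ids in cells.items():
            if len(ids) == 0:
                continue
            rate = float((~observed.reindex(ids).fillna(False)).mean())
            rows.append(
                {"lag": s, "treated": tr, "baseline_outcome": y0,
                 "n_cell": len(ids), "attrition_rate": rate}
            )
    return pd.DataFrame(rows)


def attrition_effect(
    panel, outcome: str, domain: str, spec=None, threshold=0.25,
    lags=None, K: int = 5, R: int = 3, seed: int = 0,
) -> pd.DataFrame:
    """DDML 'effect' of the shock on outcome missingness, per lag."""
    t_ref = _default_reference(panel, outcome)
    lags = lags if lags is not None else lag_grid(outcome)[1:]
    rows = []
    for s in lags:
        sample = attrition_outcome(panel, TimingSpec(outcome, domain, t_ref, s), threshold)
        est = ddml_ate(sample, spec, K=K, R=R, seed=seed, keep_summands=False)
        naive = naive_difference(sample)
        rows.append(
            {
                "lag": s, "estimate": est.estimate, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "naive": naive.estimate, "n": sample.n, "n_treated": sample.n_treated,
            }
        )
    return pd.DataFrame(rows)
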