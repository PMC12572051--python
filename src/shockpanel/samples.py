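"""Analysis-dataset construction from a long panel.

One estimation sample per (outcome, shock domain, lag): the binary treatment
is a shock in the two-year window ending at the reference score wave ``t``,
the outcome is observed ``s`` years after ``t``, and all conditioning
variables are measured at or before ``t - 2`` (baseline covariates, both
component scores at ``t - 2``, and the last pre-window outcome value).
Placebo variants shift the shock window forward and look at earlier outcomes;
the attrition variant turns outcome missingness itself into the outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shocks import DOMAINS, flag_panel_shocks

logger = logging.getLogger(__name__)

#: years after the reference wave at which each outcome is observed
_LAG_GRIDS = {
    "smoke": tuple(range(0, 15, 2)),
    "diet": tuple(range(0, 9, 2)),
    "sport": tuple(range(1, 16, 2)),
}
_OUTCOME_COLUMNS = {"smoke": "y_smoke", "diet": "y_diet", "sport": "y_sport"}


def lag_grid(outcome: str) -> tuple[int, ...]:
    """Ordered lags on which an outcome is observed relative to its reference."""
    try:
        return _LAG_GRIDS[outcome]
    except KeyError:
        raise ValueError(f"unknown outcome {outcome!r}") from None


@dataclass(frozen=True)
class TimingSpec:
    outcome: str
    shock_domain: str
    reference_year: int
    lag: int
    covariate_mode: str = "t_minus_2"  # or "full_history"
    placebo: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in _LAG_GRIDS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.shock_domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.shock_domain!r}")
        if self.covariate_mode not in ("t_minus_2", "full_history"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")


@dataclass
class EstimationSample:
    """One outcome-shock-lag analysis set ready for estimation."""

    ids: np.ndarray
    y: np.ndarray          # binary outcome at t + lag
    t: np.ndarray          # binary shock indicator for (t-2, t]
    X: pd.DataFrame        # strictly pre-treatment conditioning variables
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_treated(self) -> int:
        return int(self.t.sum())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "y": self.y, "t": self.t})
        return pd.concat([out, self.X.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        return dict(self.meta, n=self.n, n_treated=self.n_treated)


def _wide(waves: pd.DataFrame, col: str) -> pd.DataFrame:
    return waves.pivot(index="id", columns="year", values=col)


def _treatment(panel, timing: TimingSpec, threshold) -> pd.Series:
    """Shock indicator at the reference wave, indexed by id (defined rows only)."""
    flags = flag_panel_shocks(panel, timing.shock_domain, threshold)
    at_ref = flags[flags["year"] == timing.reference_year]
    if at_ref.empty:
        raise ValueError(
            f"no computable shock indicators at reference year {timing.reference_year}"
        )
    return at_ref.set_index("id")["shock"]


def _lagged_outcome(panel, outcome: str, cutoff_year: int) -> pd.Series | None:
    """Last observed outcome value at or before ``cutoff_year`` per id."""
    col = _OUTCOME_COLUMNS[outcome]
    wide = _wide(panel.waves, col)
    years = [y for y in wide.columns if y <= cutoff_year]
    if not years:
        return None
    sub = wide[years]
    # forward-fill across years, keep the most recent observed value
    return sub.ffill(axis=1).iloc[:, -1]


def _base_covariates(panel, timing: TimingSpec) -> pd.DataFrame:
    """Baseline covariates + component scores at t-2 + pre-window outcome."""
    t = timing.reference_year
    X = panel.individuals.set_index("id").copy()
    mcs = _wide(panel.waves, "mcs")
    pcs = _wide(panel.waves, "pcs")
    if t - 2 not in mcs.columns:
        raise ValueError(f"panel has no score wave at {t - 2}")
    X["mcs_tm2"] = mcs[t - 2]
    X["pcs_tm2"] = pcs[t - 2]
    lagged = _lagged_outcome(panel, timing.outcome, t - 2)
    if lagged is None:
        raise ValueError(f"no pre-window outcome observation for {timing.outcome}")
    X["y_lag"] = lagged
    return X


def build_sample(panel, timing: TimingSpec, threshold=0.25) -> EstimationSample:
    """Assemble (Y_{t+s}, T, X) for one timing cell.

    Rows are kept only when the shock indicator is computable, the outcome is
    observed at ``t + s``, and the conditioning set is complete.  Controls are
    all individuals without a shock in the window, unconditional on later
    health events.
    """
    t, s = timing.reference_year, timing.lag
    outcome_year = t + s
    ycol = _OUTCOME_COLUMNS[timing.outcome]
    ywide = _wide(panel.waves, ycol)
    if outcome_year not in ywide.columns:
        raise ValueError(f"{timing.outcome} not observed at {outcome_year}")

    treat = _treatment(panel, timing, threshold)
    X = _base_covariates(panel, timing)
    if timing.covariate_mode == "full_history":
        X = _history_block(panel, timing, X)

    df = X.copy()
    df["t"] = treat
    df["y"] = ywide[outcome_year]
    df = df.dropna()
    if df.empty:
        raise ValueError(f"empty estimation sample for {timing}")
    return EstimationSample(
        ids=df.index.to_numpy(),
        y=df["y"].to_numpy(float),
        t=df["t"].to_numpy(int),
        X=df.drop(columns=["t", "y"]).reset_index(drop=True),
        meta={
            "outcome": timing.outcome,
            "domain": timing.shock_domain,
            "reference_year": t,
            "lag": s,
            "threshold": float(threshold.fraction if hasattr(threshold, "fraction") else threshold),
            "covariate_mode": timing.covariate_mode,
            "placebo": timing.placebo,
        },
    )


def _history_block(panel, timing: TimingSpec, X: pd.DataFrame) -> pd.DataFrame:
    """Append time-varying covariates from every observed pre-window wave."""
    t = timing.reference_year
    n_before = len(X)
    mcs = _wide(panel.waves, "mcs")
    pcs = _wide(panel.waves, "pcs")
    hist_waves = [y for y in mcs.columns if y < t - 2 and mcs[y].notna().any()]
    if not hist_waves:
        raise ValueError(f"no pre-window score waves before {t - 2}")
    for y in hist_waves:
        X[f"mcs_{y}"] = mcs[y]
        X[f"pcs_{y}"] = pcs[y]
    ycol = _OUTCOME_COLUMNS[timing.outcome]
    ywide = _wide(panel.waves, ycol)
    for y in [c for c in ywide.columns if c <= t - 2 and ywide[c].notna().any()]:
        X[f"{ycol}_{y}"] = ywide[y]
    dropped = int(X.isna().any(axis=1).sum())
    if dropped:
        logger.info(
            "full-history conditioning will drop %d of %d rows lacking complete "
            "pre-window records", dropped, n_before,
        )
    return X


def build_placebo_samples(
    panel, outcome: str, shock_domain: str, shifted_reference: int, threshold=0.25
) -> list[EstimationSample]:
    """Pre-treatment 'effect' samples for a forward-shifted shock window.

    The shock is measured in ``(shifted_reference - 2, shifted_reference]``
    while outcomes come from earlier waves (negative lags).  Conditioning
    variables are re-anchored per lag to years strictly before the outcome.
    """
    t = shifted_reference
    ycol = _OUTCOME_COLUMNS[outcome]
    ywide = _wide(panel.waves, ycol)
    outcome_years = sorted(y for y in ywide.columns if y < t)
    if not outcome_years:
        raise ValueError(f"no pre-window outcomes before {t} for {outcome}")
    treat = _treatment(
        panel, TimingSpec(outcome, shock_domain, t, 0, placebo=True), threshold
    )
    mcs = _wide(panel.waves, "mcs")
    pcs = _wide(panel.waves, "pcs")
    base = panel.individuals.set_index("id")
    samples = []
    for oy in outcome_years:
        s = oy - t
        X = base.copy()
        score_waves = [w for w in mcs.columns if w <= oy - 2]
        if score_waves:
            w = score_waves[-1]
            X[f"mcs_tm2"] = mcs[w]
            X[f"pcs_tm2"] = pcs[w]
        lagged = _lagged_outcome(panel, outcome, oy - 2)
        if lagged is not None:
            X["y_lag"] = lagged
        df = X.copy()
        df["t"] = treat
        df["y"] = ywide[oy]
        df = df.dropna()
        if df.empty:
            continue
        samples.append(
            EstimationSample(
                ids=df.index.to_numpy(),
                y=df["y"].to_numpy(float),
                t=df["t"].to_numpy(int),
                X=df.drop(columns=["t", "y"]).reset_index(drop=True),
                meta={
                    "outcome": outcome,
                    "domain": shock_domain,
                    "reference_year": t,
                    "lag": s,
                    "threshold": float(
                        threshold.fraction if hasattr(threshold, "fraction") else threshold
                    ),
                    "covariate_mode": "t_minus_2",
                    "placebo": True,
                },
            )
        )
    return samples


def attach_history(sample: EstimationSample, panel, timing: TimingSpec) -> EstimationSample:
    """Rebuild a sample with the full pre-window covariate history attached."""
    timing = TimingSpec(
        timing.outcome,
        timing.shock_domain,
        timing.reference_year,
        timing.lag,
        covariate_mode="full_history",
        placebo=timing.placebo,
    )
    return build_sample(panel, timing, sample.meta.get("threshold", 0.25))


def attrition_outcome(panel, timing: TimingSpec, threshold=0.25) -> EstimationSample:
    """Sample whose outcome is 1 iff the behavior is unobserved at t + lag.

    Rows are retained regardless of behavioral-outcome missingness; only the
    treatment indicator and the conditioning set must be complete.
    """
    t, s = timing.reference_year, timing.lag
    ycol = _OUTCOME_COLUMNS[timing.outcome]
    ywide = _wide(panel.waves, ycol)
    outcome_year = t + s
    treat = _treatment(panel, timing, threshold)
    X = _base_covariates(panel, timing)
    df = X.copy()
    df["t"] = treat
    df = df.dropna()
    if df.empty:
        raise ValueError(f"empty attrition sample for {timing}")
    if outcome_year in ywide.columns:
        observed = ywide[outcome_year].notna()
    else:
        observed = pd.Series(False, index=ywide.index)
    missing = (~observed).reindex(df.index).fillna(True)
    return EstimationSample(
        ids=df.index.to_numpy(),
        y=missing.to_numpy(float),
        t=df["t"].to_numpy(int),
        X=df.drop(columns=["t"]).reset_index(drop=True),
        meta={
            "outcome": f"attrition_{timing.outcome}",
            "domain": timing.shock_domain,
            "reference_year": t,
            "lag": s,
            "threshold": float(threshold.fraction if hasattr(threshold, "fraction") else threshold),
            "covariate_mode": timing.covariate_mode,
            "placebo": False,
        },
    )
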