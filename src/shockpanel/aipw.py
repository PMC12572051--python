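"""Doubly robust ATE estimation: AIPW summands, cross-fitting, resampling.

The per-row summand is

    psi_i = [ T_i Y_i / pi_i - (T_i - pi_i)/pi_i * g1_i ]
          - [ (1 - T_i) Y_i / (1 - pi_i) + (T_i - pi_i)/(1 - pi_i) * g0_i ]

whose sample mean is the AIPW ATE.  The full estimator repeats cross-fitting
over R fresh partitions and reports the median of the R point estimates; its
variance combines each resample's influence-function variance with the spread
of the resample estimates around the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nuisance import CrossfitPlan, LearnerSpec, NuisancePredictions, fit_predict_crossfit

_Z90 = float(stats.norm.ppf(0.95))


def aipw_summands(y, t, pi, g1, g0) -> np.ndarray:
    """Per-row AIPW summands; their mean is the ATE estimate."""
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    pi = np.asarray(pi, float)
    g1 = np.asarray(g1, float)
    g0 = np.asarray(g0, float)
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    treated_part = t * y / pi - (t - pi) / pi * g1
    control_part = (1.0 - t) * y / (1.0 - pi) + (t - pi) / (1.0 - pi) * g0
    return treated_part - control_part


def summands_from_predictions(sample, preds: NuisancePredictions) -> np.ndarray:
    return aipw_summands(sample.y, sample.t, preds.pi, preds.g1, preds.g0)


def ipw_ate(y, t, pi) -> float:
    """Pure inverse-probability-weighting ATE (AIPW with g terms dropped)."""
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    pi = np.asarray(pi, float)
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    return float(np.mean(t * y / pi - (1.0 - t) * y / (1.0 - pi)))


@dataclass
class AteEstimate:
    """Median-aggregated ATE with influence-function inference."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    estimates_r: np.ndarray      # per-resample point estimates
    variances_r: np.ndarray      # per-resample influence-function variances
    n: int
    n_treated: int
    K: int = 0
    R: int = 0
    learner: str = ""
    summands: np.ndarray | None = None  # n x R matrix of per-row summands
    meta: dict = field(default_factory=dict)

    @property
    def individual_effects(self) -> np.ndarray:
        """Per-row summands averaged over resamples (heterogeneity screening)."""
        if self.summands is None:
            raise ValueError("summands were not retained for this estimate")
        return self.summands.mean(axis=1)

    def to_record(self) -> dict:
        return dict(
            self.meta,
            estimate=self.estimate,
            se=self.se,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            n=self.n,
            n_treated=self.n_treated,
            K=self.K,
            R=self.R,
            learner=self.learner,
        )


def _median_aggregate(taus: np.ndarray, variances: np.ndarray) -> tuple[float, float]:
    tau = float(np.median(taus))
    var = float(np.median(variances + (taus - tau) ** 2))
    return tau, float(np.sqrt(var))


def _if_variance(psi: np.ndarray) -> float:
    tau = psi.mean()
    return float(np.sum((psi - tau) ** 2) / len(psi) ** 2)


def ddml_ate(
    sample,
    spec: LearnerSpec | None = None,
    K: int = 5,
    R: int = 3,
    seed: int = 0,
    keep_summands: bool = True,
) -> AteEstimate:
    """Cross-fitted AIPW ATE over R independent partitions, median-reported."""
    if R < 1:
        raise ValueError("R must be >= 1")
    spec = spec or LearnerSpec()
    n = sample.n
    taus = np.empty(R)
    variances = np.empty(R)
    psis = np.empty((n, R)) if keep_summands else None
    child_seeds = np.random.SeedSequence(seed).spawn(R)
    for r in range(R):
        plan = CrossfitPlan(
            K=K, resample_index=r + 1, seed=int(child_seeds[r].generate_state(1)[0])
        )
        preds = fit_predict_crossfit(sample, spec, plan)
        psi = summands_from_predictions(sample, preds)
        taus[r] = psi.mean()
        variances[r] = _if_variance(psi)
        if psis is not None:
            psis[:, r] = psi
    tau, se = _median_aggregate(taus, variances)
    return AteEstimate(
        estimate=tau,
        se=se,
        ci_low=tau - _Z90 * se,
        ci_high=tau + _Z90 * se,
        estimates_r=taus,
        variances_r=variances,
        n=n,
        n_treated=sample.n_treated,
        K=K,
        R=R,
        learner=spec.kind,
        summands=psis,
        meta=dict(sample.meta) if hasattr(sample, "meta") else {},
    )


def subgroup_ate(estimate: AteEstimate, mask) -> AteEstimate:
    """ATE restricted to ``mask`` rows: per-resample masked summand means,
    median-aggregated, with inference from the masked rows only."""
    mask = np.asarray(mask, bool)
    if estimate.summands is None:
        raise ValueError("subgroup estimation needs retained summands")
    if mask.shape[0] != estimate.summands.shape[0]:
        raise ValueError("mask length does not match the sample")
    if not mask.any():
        raise ValueError("empty subgroup mask")
    sub = estimate.summands[mask]
    taus = sub.mean(axis=0)
    variances = np.array([_if_variance(sub[:, r]) for r in range(sub.shape[1])])
    tau, se = _median_aggregate(taus, variances)
    return AteEstimate(
        estimate=tau,
        se=se,
        ci_low=tau - _Z90 * se,
        ci_high=tau + _Z90 * se,
        estimates_r=taus,
        variances_r=variances,
        n=int(mask.sum()),
        n_treated=-1,
        K=estimate.K,
        R=estimate.R,
        learner=estimate.learner,
        summands=sub,
        meta=dict(estimate.meta, subgroup=True),
    )


def naive_difference(sample) -> AteEstimate:
    """Unadjusted group-mean differential with a two-sample standard error."""
    y = np.asarray(sample.y, float)
    t = np.asarray(sample.t, int)
    y1, y0 = y[t == 1], y[t == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValueError("both arms must be non-empty")
    diff = float(y1.mean() - y0.mean())
    se = float(np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0)))
    return AteEstimate(
        estimate=diff,
        se=se,
        ci_low=diff - _Z90 * se,
        ci_high=diff + _Z90 * se,
        estimates_r=np.array([diff]),
        variances_r=np.array([se**2]),
        n=len(y),
        n_treated=len(y1),
        learner="naive",
        meta=dict(getattr(sample, "meta", {}), naive=True),
    )
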