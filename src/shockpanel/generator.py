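"""Synthetic survey-panel generator with known causal ground truth.

Produces long-format individual-by-year panels that mimic the structure of a
biannual health survey: two latent health domains (physical, mental) followed
as AR(1) processes, component summary scores normalized to mean 50 / SD 10 in
the baseline wave, three binary lifestyle outcomes with differing availability
grids, ~40 mostly binary covariates, confounded latent-health drop events that
surface as score shocks, panel attrition, and additive treatment effects on
the outcome-probability scale.

Both potential outcomes are recorded per (individual, outcome, domain, lag)
using common random numbers, so a configuration with zero effects has an
oracle average treatment effect of exactly zero, and an injected effect of
``delta`` has an oracle ATE of ``delta`` up to probability clipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from ._util import sigmoid
from .shocks import flag_shock_array

logger = logging.getLogger(__name__)

OUTCOMES = ("smoke", "diet", "sport")
OUTCOME_COLUMN = {o: f"y_{o}" for o in OUTCOMES}
_PROB_EPS = 1e-6


@dataclass(frozen=True)
class CovariateDef:
    """One baseline covariate: continuous (loc/scale) or binary (prevalence)."""

    name: str
    kind: str  # "continuous" | "binary"
    loc: float = 0.0
    scale: float = 1.0
    prevalence: float = 0.5
    # derive_from links a binary covariate to a continuous parent via a
    # logistic threshold, e.g. retirement status to age
    derive_from: str | None = None
    derive_loc: float = 0.0
    derive_scale: float = 1.0


def default_covariates() -> tuple[CovariateDef, ...]:
    """Stylized 38-column baseline covariate set (4 continuous, 34 binary).

    Together with the two lagged component scores attached at estimation time
    this yields the 40-variable conditioning set (6 continuous).
    """
    cont = [
        CovariateDef("age", "continuous", loc=45.0, scale=12.0),
        CovariateDef("bmi", "continuous", loc=26.0, scale=4.0),
        CovariateDef("educ_years", "continuous", loc=12.0, scale=2.5),
        CovariateDef("hh_size", "continuous", loc=2.5, scale=1.2),
    ]
    prevalences = {
        "female": 0.52, "single": 0.30, "german": 0.88, "employed": 0.62,
        "unemployed": 0.05, "self_employed": 0.08, "married": 0.55,
        "has_children": 0.35, "urban": 0.65, "east": 0.20, "homeowner": 0.45,
        "white_collar": 0.40, "blue_collar": 0.25, "civil_servant": 0.07,
        "disabled": 0.06, "chronic_condition": 0.22, "hospital_last_year": 0.12,
        "doctor_visits_high": 0.30, "health_satisfied": 0.60,
        "leisure_satisfied": 0.55, "income_low": 0.20, "income_high": 0.20,
        "insurance_private": 0.11, "religious": 0.35, "migrant_background": 0.15,
        "parttime": 0.18, "shiftwork": 0.14, "smoker_household": 0.25,
        "alcohol_regular": 0.30, "sleep_problems": 0.18, "sport_club": 0.20,
        "care_duties": 0.08,
    }
    binary = [CovariateDef(n, "binary", prevalence=p) for n, p in prevalences.items()]
    binary.append(
        CovariateDef("retired", "binary", prevalence=0.20,
                     derive_from="age", derive_loc=63.0, derive_scale=2.5)
    )
    binary.append(
        CovariateDef("obese", "binary", prevalence=0.16,
                     derive_from="bmi", derive_loc=30.0, derive_scale=1.5)
    )
    return tuple(cont + binary)


def _default_confounding() -> dict[str, float]:
    # drives the latent-health drop hazard; overlaps with the outcome models
    return {
        "age": 0.60, "retired": 0.30, "unemployed": 0.25, "educ_years": -0.25,
        "bmi": 0.20, "chronic_condition": 0.35, "disabled": 0.30, "income_low": 0.15,
    }


def _default_outcome_coefs() -> dict[str, dict[str, float]]:
    return {
        "smoke": {  # not smoking
            "educ_years": 0.45, "age": 0.25, "unemployed": -0.35, "female": 0.20,
            "income_low": -0.20, "alcohol_regular": -0.30, "smoker_household": -0.50,
        },
        "diet": {
            "female": 0.50, "age": 0.35, "educ_years": 0.25,
            "health_satisfied": 0.20, "income_high": 0.15,
        },
        "sport": {
            "age": -0.50, "educ_years": 0.45, "bmi": -0.35, "sport_club": 1.00,
            "income_high": 0.25, "disabled": -0.40,
        },
    }


@dataclass(frozen=True)
class AttritionModel:
    """Annual absorbing-dropout hazard plus transient item non-response."""

    base_hazard: float = 0.02
    shock_coef: float = 0.0          # added to the hazard after a recent shock
    outcome_coef: float = 0.0        # added per lagged not-smoking status
    transient_nonresponse_prob: float = 0.02


@dataclass(frozen=True)
class GeneratorConfig:
    n_individuals: int = 5000
    years: tuple[int, ...] = tuple(range(2001, 2020))
    score_wave_parity: int = 0  # parity of calendar years carrying scores
    latent_persistence: dict = field(
        default_factory=lambda: {"physical": 0.9, "mental": 0.9}
    )
    innovation_sd: dict | None = None  # default: stationary unit variance
    score_noise_sd: float = 1.0
    covariate_spec: tuple[CovariateDef, ...] = field(default_factory=default_covariates)
    confounding_weights: dict = field(default_factory=_default_confounding)
    # annual latent drop-event hazard intercepts (log-odds); calibrated so the
    # flagged-shock share sits in the 5-8% band with mental ~ physical + 2pp
    drop_hazard_intercepts: dict = field(
        default_factory=lambda: {"physical": -4.20, "mental": -3.75}
    )
    drop_size: float = 2.5  # latent SD units subtracted per drop event
    hazard_baseline_outcome: dict = field(default_factory=dict)  # outcome -> coef
    effect_profile: dict = field(default_factory=dict)  # (outcome, domain, lag) -> delta
    baseline_prevalence: dict = field(
        default_factory=lambda: {"smoke": 0.70, "diet": 0.51, "sport": 0.26}
    )
    outcome_coefs: dict = field(default_factory=_default_outcome_coefs)
    # intercepts pre-calibrated at n=50,000 for the default coefficients;
    # calibrate_intercepts() re-solves them for modified configurations
    outcome_intercepts: dict = field(
        default_factory=lambda: {"smoke": 0.9225, "diet": 0.0454, "sport": -1.2193}
    )
    state_dependence: dict = field(
        default_factory=lambda: {"smoke": 3.0, "diet": 1.5, "sport": 2.0}
    )
    attrition_model: AttritionModel = field(default_factory=AttritionModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if self.score_noise_sd <= 0:
            raise ValueError("score_noise_sd must be positive")
        if self.innovation_sd is not None and any(
            v <= 0 for v in self.innovation_sd.values()
        ):
            raise ValueError("innovation sds must be positive")
        for d, rho in self.latent_persistence.items():
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"latent persistence for {d} must be in [0, 1)")
        for o, p in self.baseline_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline prevalence for {o} must be in (0, 1)")
        for key, delta in self.effect_profile.items():
            outcome, domain, lag = key
            if outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome in effect profile: {outcome}")
            if abs(delta) >= 1.0:
                raise ValueError(f"|effect| must be < 1, got {delta} for {key}")
            target = self.baseline_prevalence[outcome]
            if not 0.0 < target + delta < 1.0:
                raise ValueError(
                    f"effect {delta} for {key} pushes the target prevalence "
                    f"{target} outside (0, 1)"
                )
        for o in self.hazard_baseline_outcome:
            if o == "diet":
                raise ValueError(
                    "hazard_baseline_outcome supports smoke/sport only: the diet "
                    "series starts after drop events begin"
                )

    # -- derived structure ---------------------------------------------------

    def score_years(self) -> list[int]:
        return [y for y in self.years if y % 2 == self.score_wave_parity]

    def outcome_years(self, outcome: str) -> list[int]:
        """Availability grid: smoke/diet on even years, sport on odd years."""
        if outcome == "smoke":
            return [y for y in self.years if y % 2 == 0]
        if outcome == "diet":
            return [y for y in self.years if y % 2 == 0 and 2004 <= y <= 2014]
        if outcome == "sport":
            return [y for y in self.years if y % 2 == 1]
        raise ValueError(f"unknown outcome {outcome!r}")

    def reference_year(self, outcome: str) -> int:
        """Earliest score wave with a computable shock and a prior outcome."""
        waves = self.score_years()
        grid = self.outcome_years(outcome)
        for t in waves[1:]:
            if any(y <= t - 2 for y in grid):
                return t
        raise ValueError(f"no feasible reference wave for {outcome}")


@dataclass
class PanelTable:
    """Long panel: one row per (id, year); static covariates kept separately."""

    waves: pd.DataFrame        # id, year, mcs, pcs, y_smoke, y_diet, y_sport, attrited
    individuals: pd.DataFrame  # id + baseline covariates

    def covariate_names(self) -> list[str]:
        return [c for c in self.individuals.columns if c != "id"]

    def merged(self) -> pd.DataFrame:
        return self.waves.merge(self.individuals, on="id", how="left")

    def to_csv(self, path) -> None:
        self.merged().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelTable":
        wide = pd.read_csv(path)
        wave_cols = ["id", "year", "mcs", "pcs", "y_smoke", "y_diet", "y_sport", "attrited"]
        cov_cols = [c for c in wide.columns if c not in wave_cols]
        individuals = wide[["id"] + cov_cols].drop_duplicates("id").reset_index(drop=True)
        return cls(waves=wide[wave_cols].copy(), individuals=individuals)


@dataclass
class TruthTable:
    """Potential outcomes per (id, outcome, domain, lag) under common draws."""

    table: pd.DataFrame  # id, outcome, domain, lag, y1, y0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def oracle_ate(truth: TruthTable, outcome: str, shock_domain: str, lag: int) -> float:
    """Ground-truth ATE: mean(Y1 - Y0) for the requested cell."""
    t = truth.table
    cell = t[(t["outcome"] == outcome) & (t["domain"] == shock_domain) & (t["lag"] == lag)]
    if cell.empty:
        raise ValueError(f"truth table has no cell ({outcome}, {shock_domain}, {lag})")
    return float((cell["y1"] - cell["y0"]).mean())


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _standardized(X: pd.DataFrame, spec: tuple[CovariateDef, ...]) -> pd.DataFrame:
    """Center/scale by the nominal (not sample) moments for determinism."""
    Z = {}
    for c in spec:
        x = X[c.name].to_numpy(float)
        if c.kind == "continuous":
            Z[c.name] = (x - c.loc) / c.scale
        else:
            Z[c.name] = x - c.prevalence
    return pd.DataFrame(Z, index=X.index)


def _linear_index(Z: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    idx = np.zeros(len(Z))
    for name, w in weights.items():
        if name not in Z.columns:
            raise KeyError(f"coefficient on unknown covariate {name!r}")
        idx += w * Z[name].to_numpy()
    return idx


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_individuals
    data = {"id": np.arange(n)}
    for c in config.covariate_spec:
        if c.kind == "continuous":
            x = rng.normal(c.loc, c.scale, size=n)
            if c.name == "age":
                x = np.clip(x, 18, 85)
            elif c.name == "bmi":
                x = np.clip(x, 15, 50)
            elif c.name == "educ_years":
                x = np.clip(x, 7, 18)
            elif c.name == "hh_size":
                x = np.clip(np.round(x), 1, 8)
            data[c.name] = x
        elif c.derive_from is not None:
            parent = data[c.derive_from]
            p = sigmoid((parent - c.derive_loc) / c.derive_scale)
            data[c.name] = (rng.uniform(size=n) < p).astype(float)
        else:
            data[c.name] = (rng.uniform(size=n) < c.prevalence).astype(float)
    return pd.DataFrame(data)


class _PanelDraws:
    """All random inputs and deterministic intermediates of one generation.

    Holding these separately lets `calibrate_intercepts` re-run only the cheap
    outcome recursion while varying an intercept, keeping every other draw
    fixed.
    """

    def __init__(self, config: GeneratorConfig, seed: int):
        config.validate()
        self.config = config
        n = config.n_individuals
        years = list(config.years)
        self.years = years
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xACE5]))

        self.X = _draw_covariates(config, rng)
        self.Z = _standardized(self.X, config.covariate_spec)

        # common random numbers for outcome draws, one per (outcome, year)
        self.u = {
            o: {y: rng.uniform(size=n) for y in config.outcome_years(o)} for o in OUTCOMES
        }

        # baseline outcomes at each outcome's first wave predate any drop
        # event, so they may feed the drop hazard without circularity
        self.baseline_outcome = {}
        for o in OUTCOMES:
            y0 = config.outcome_years(o)[0]
            p = sigmoid(
                config.outcome_intercepts[o]
                + _linear_index(self.Z, config.outcome_coefs[o])
            )
            self.baseline_outcome[o] = (self.u[o][y0] < p).astype(float)

        # latent-health drop events (start the year after the baseline wave,
        # keeping the first score wave an undisturbed norm population)
        first_drop_year = config.score_years()[0] + 1
        conf_idx = _linear_index(self.Z, config.confounding_weights)
        self.drops = {}
        for d in ("physical", "mental"):
            hz = config.drop_hazard_intercepts[d] + conf_idx
            for o, coef in config.hazard_baseline_outcome.items():
                hz = hz + coef * (
                    self.baseline_outcome[o] - config.baseline_prevalence[o]
                )
            p_drop = sigmoid(hz)
            udrop = rng.uniform(size=(n, len(years)))
            active = np.array([y >= first_drop_year for y in years])
            self.drops[d] = (udrop < p_drop[:, None]) & active[None, :]

        # latent AR(1) paths and scores
        self.scores = {}
        for d in ("physical", "mental"):
            rho = config.latent_persistence[d]
            inn_sd = (
                config.innovation_sd[d]
                if config.innovation_sd is not None
                else float(np.sqrt(1.0 - rho**2))
            )
            h = rng.normal(size=n)  # stationary start
            latent = {}
            for j, y in enumerate(years):
                if j > 0:
                    h = rho * h + rng.normal(scale=inn_sd, size=n)
                h = h - config.drop_size * self.drops[d][:, j]
                latent[y] = h.copy()
            score = {}
            for y in config.score_years():
                noise = rng.normal(scale=config.score_noise_sd, size=n)
                score[y] = np.clip(50.0 + 10.0 * latent[y] + noise, 0.0, 100.0)
            self.scores[d] = score

        # emergent shock indicators per (domain, wave)
        self.flags = {}
        waves = config.score_years()
        for d in ("physical", "mental"):
            self.flags[d] = {}
            for prev_y, curr_y in zip(waves, waves[1:]):
                self.flags[d][curr_y] = flag_shock_array(
                    self.scores[d][prev_y], self.scores[d][curr_y], 0.25
                )

        # attrition / transient non-response draws
        self.u_attrit = rng.uniform(size=(n, len(years)))
        self.u_transient = {
            o: {y: rng.uniform(size=n) for y in config.outcome_years(o)} for o in OUTCOMES
        }

    # -- outcome recursion ---------------------------------------------------

    def _shift(self, outcome: str, year: int) -> np.ndarray:
        """Total additive treatment effect hitting this outcome-year."""
        cfg = self.config
        shift = np.zeros(cfg.n_individuals)
        for (o, d, lag), delta in cfg.effect_profile.items():
            if o != outcome:
                continue
            w = year - lag
            if w in self.flags.get(d, {}):
                shift += delta * np.nan_to_num(self.flags[d][w])
        return shift

    def simulate_outcome(self, outcome: str, intercept: float | None = None):
        """Factual path plus per-year base probabilities and shifts.

        Returns (values, pbase, shift) as dicts year -> array.  ``pbase`` is
        the no-effect probability given the factual lagged outcome, so the
        potential-outcome pair at any single reference toggle is a one-step
        deviation sharing the factual history.
        """
        cfg = self.config
        if intercept is None:
            intercept = cfg.outcome_intercepts[outcome]
        beta_idx = _linear_index(self.Z, cfg.outcome_coefs[outcome])
        gamma = cfg.state_dependence[outcome]
        target = cfg.baseline_prevalence[outcome]
        values, pbase, shifts = {}, {}, {}
        prev = None
        for y in cfg.outcome_years(outcome):
            state = 0.0 if prev is None else gamma * (prev - target)
            p0 = sigmoid(intercept + beta_idx + state)
            sh = self._shift(outcome, y)
            p = np.clip(p0 + sh, _PROB_EPS, 1.0 - _PROB_EPS)
            yv = (self.u[outcome][y] < p).astype(float)
            values[y], pbase[y], shifts[y] = yv, p0, sh
            prev = yv
        return values, pbase, shifts


def _attrition_year(draws: _PanelDraws, outcome_values: dict) -> np.ndarray:
    """First calendar year of absorbing dropout per individual (inf = never)."""
    cfg = draws.config
    am = cfg.attrition_model
    n = cfg.n_individuals
    years = draws.years
    waves = cfg.score_years()
    att_year = np.full(n, np.inf)
    recent_flag = np.zeros(n)
    last_smoke = draws.baseline_outcome["smoke"]
    for j, y in enumerate(years[1:], start=1):
        # most recent wave's shock status (either domain) feeds the hazard
        past_waves = [w for w in waves[1:] if w <= y]
        if past_waves:
            w = past_waves[-1]
            recent_flag = np.fmax(
                np.nan_to_num(draws.flags["physical"][w]),
                np.nan_to_num(draws.flags["mental"][w]),
            )
        if y - 1 in outcome_values["smoke"]:
            last_smoke = outcome_values["smoke"][y - 1]
        hazard = np.clip(
            am.base_hazard + am.shock_coef * recent_flag + am.outcome_coef * last_smoke,
            0.0,
            1.0,
        )
        hit = (draws.u_attrit[:, j] < hazard) & ~np.isfinite(att_year)
        att_year[hit] = y
    return att_year


def generate_panel(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[PanelTable, TruthTable]:
    """Generate one panel and its ground-truth potential-outcome table.

    Deterministic given ``seed`` (defaults to ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    draws = _PanelDraws(config, seed)
    cfg = config
    n = cfg.n_individuals

    outcome_values, outcome_pbase, outcome_shift = {}, {}, {}
    for o in OUTCOMES:
        outcome_values[o], outcome_pbase[o], outcome_shift[o] = draws.simulate_outcome(o)

    _check_effect_clipping(cfg, outcome_pbase, outcome_shift)

    truth = _build_truth(cfg, draws, outcome_pbase, outcome_shift)

    att_year = _attrition_year(draws, outcome_values)

    rows = []
    for y in cfg.years:
        row = {"id": draws.X["id"].to_numpy(), "year": np.full(n, y)}
        attrited = att_year <= y
        for d, col in (("mental", "mcs"), ("physical", "pcs")):
            s = draws.scores[d].get(y)
            if s is None:
                row[col] = np.full(n, np.nan)
            else:
                row[col] = np.where(attrited, np.nan, s)
        for o in OUTCOMES:
            col = OUTCOME_COLUMN[o]
            if y in outcome_values[o]:
                v = outcome_values[o][y].copy()
                miss = attrited | (
                    draws.u_transient[o][y] < cfg.attrition_model.transient_nonresponse_prob
                )
                v = np.where(miss, np.nan, v)
                row[col] = v
            else:
                row[col] = np.full(n, np.nan)
        row["attrited"] = attrited
        rows.append(pd.DataFrame(row))
    waves = pd.concat(rows, ignore_index=True).sort_values(["id", "year"]).reset_index(drop=True)
    panel = PanelTable(waves=waves, individuals=draws.X.copy())
    return panel, truth


def _check_effect_clipping(cfg, pbase, shifts) -> None:
    """Reject effect profiles that clip a non-trivial share of probabilities."""
    for o in OUTCOMES:
        for y, sh in shifts[o].items():
            hit = sh != 0
            if not hit.any():
                continue
            p = pbase[o][y][hit] + sh[hit]
            frac = float(np.mean((p <= 0.0) | (p >= 1.0)))
            if frac > 0.05:
                raise ValueError(
                    f"effect profile pushes {frac:.1%} of {o} probabilities at "
                    f"{y} outside (0, 1); shrink the effects or recalibrate"
                )


def _build_truth(cfg, draws, pbase, shifts) -> TruthTable:
    from .samples import lag_grid  # grids shared with the sample builder

    records = []
    for o in OUTCOMES:
        t_ref = cfg.reference_year(o)
        grid = cfg.outcome_years(o)
        for d in ("physical", "mental"):
            flag_ref = np.nan_to_num(draws.flags[d].get(t_ref, np.zeros(cfg.n_individuals)))
            for s in lag_grid(o):
                y = t_ref + s
                if y not in grid:
                    continue
                delta = cfg.effect_profile.get((o, d, s), 0.0)
                # toggle only the reference-wave shock of this domain;
                # everything else (other shocks, factual history) is shared
                p_other = pbase[o][y] + shifts[o][y] - flag_ref * delta
                u = draws.u[o][y]
                y1 = u < np.clip(p_other + delta, _PROB_EPS, 1 - _PROB_EPS)
                y0 = u < np.clip(p_other, _PROB_EPS, 1 - _PROB_EPS)
                records.append(
                    pd.DataFrame(
                        {
                            "id": draws.X["id"].to_numpy(),
                            "outcome": o,
                            "domain": d,
                            "lag": s,
                            "y1": y1.astype(int),
                            "y0": y0.astype(int),
                        }
                    )
                )
    return TruthTable(pd.concat(records, ignore_index=True))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def pre_shock_prevalence(config: GeneratorConfig, draws: _PanelDraws, outcome: str,
                         intercept: float | None = None) -> float:
    """Share with the good habit at the last outcome wave before t_ref - 1."""
    values, _, _ = draws.simulate_outcome(outcome, intercept=intercept)
    t_ref = config.reference_year(outcome)
    pre_years = [y for y in config.outcome_years(outcome) if y <= t_ref - 2]
    return float(values[pre_years[-1]].mean())


def calibrate_intercepts(
    config: GeneratorConfig, n: int = 50_000, seed: int = 0, tol_pp: float = 0.1
) -> GeneratorConfig:
    """Solve each outcome intercept so the simulated pre-shock prevalence hits
    the configured target (Brent root-finding on a fixed set of draws)."""
    work = replace(config, n_individuals=n)
    work.validate()
    draws = _PanelDraws(work, seed)
    new_intercepts = dict(config.outcome_intercepts)
    for o in OUTCOMES:
        target = config.baseline_prevalence[o]

        def gap(c, _o=o, _t=target):
            return pre_shock_prevalence(work, draws, _o, intercept=c) - _t

        lo, hi = -8.0, 8.0
        if gap(lo) > 0 or gap(hi) < 0:
            raise ValueError(
                f"target prevalence {target} for {o} unattainable with the "
                "configured coefficients"
            )
        root = optimize.brentq(gap, lo, hi, xtol=1e-3)
        achieved = target + gap(root)
        if abs(achieved - target) > tol_pp:
            raise ValueError(
                f"calibration for {o} landed at {achieved:.3f} vs target {target}"
            )
        new_intercepts[o] = float(root)
        logger.info("calibrated %s intercept to %.4f (share %.4f)", o, root, achieved)
    return replace(config, outcome_intercepts=new_intercepts)
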