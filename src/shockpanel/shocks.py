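"""Binary health-shock indicators from component-score trajectories.

A shock in a domain (physical or mental) is a relative drop of *more than*
``threshold`` (default 25%) in the corresponding component score between two
consecutive score waves two years apart.  Indicators are undefined — not 0 —
whenever either score is missing or the baseline score is non-positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("physical", "mental")
#: panel column holding the score for each domain
SCORE_COLUMN = {"physical": "pcs", "mental": "mcs"}


@dataclass(frozen=True)
class ShockThreshold:
    """Relative-drop threshold rendering a score decline a shock."""

    fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"threshold fraction must be in (0, 1), got {self.fraction}")


def _as_fraction(threshold: "ShockThreshold | float") -> float:
    if isinstance(threshold, ShockThreshold):
        return threshold.fraction
    return ShockThreshold(float(threshold)).fraction


def flag_shock(prev: float, curr: float, threshold: ShockThreshold | float = 0.25) -> int:
    """1 iff the relative change (curr - prev)/prev is strictly below -threshold.

    ``prev`` must be strictly positive; a drop of exactly ``threshold`` is not
    a shock (strict inequality).
    """
    frac = _as_fraction(threshold)
    if not np.isfinite(prev) or not np.isfinite(curr):
        raise ValueError("scores must be finite; missing scores yield no indicator")
    if prev <= 0:
        raise ValueError(f"baseline score must be positive, got {prev}")
    if curr < 0:
        raise ValueError(f"current score must be non-negative, got {curr}")
    return int((curr - prev) / prev < -frac)


def flag_shock_array(
    prev: np.ndarray, curr: np.ndarray, threshold: ShockThreshold | float = 0.25
) -> np.ndarray:
    """Vectorized indicator; NaN where undefined (missing or prev <= 0)."""
    frac = _as_fraction(threshold)
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    out = np.full(prev.shape, np.nan)
    ok = np.isfinite(prev) & np.isfinite(curr) & (prev > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[ok] = ((curr[ok] - prev[ok]) / prev[ok] < -frac).astype(float)
    n_nonpos = int(np.sum(np.isfinite(prev) & np.isfinite(curr) & (prev <= 0)))
    if n_nonpos:
        logger.info("excluded %d records with non-positive baseline score", n_nonpos)
    return out


def flag_panel_shocks(
    panel, domain: str, threshold: ShockThreshold | float = 0.25
) -> pd.DataFrame:
    """Shock indicators for every consecutive score-wave pair of a panel.

    Returns a frame with columns (id, year, shock) where ``year`` is the later
    wave of each pair.  Rows where either score is missing are absent.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    waves = panel.waves if hasattr(panel, "waves") else panel
    col = SCORE_COLUMN[domain]
    score_years = sorted(waves.loc[waves[col].notna(), "year"].unique())
    pairs = [(a, b) for a, b in zip(score_years, score_years[1:]) if b - a == 2]
    if not pairs:
        warnings.warn("panel has no consecutive score-wave pairs; empty indicator table")
        return pd.DataFrame(columns=["id", "year", "shock"])
    wide = waves.pivot(index="id", columns="year", values=col)
    frames = []
    for prev_y, curr_y in pairs:
        flags = flag_shock_array(wide[prev_y].to_numpy(), wide[curr_y].to_numpy(), threshold)
        keep = np.isfinite(flags)
        frames.append(
            pd.DataFrame(
                {"id": wide.index[keep], "year": curr_y, "shock": flags[keep].astype(int)}
            )
        )
    return pd.concat(frames, ignore_index=True)


def repeated_shock_counts(
    panel, domain: str, threshold: ShockThreshold | float = 0.25
) -> pd.Series:
    """Distribution of per-individual shock counts across all wave pairs.

    Indexed by count 0, 1, 2, ...; values are numbers of individuals with at
    least one computable indicator.
    """
    flags = flag_panel_shocks(panel, domain, threshold)
    if flags.empty:
        return pd.Series(dtype=int, name="n_individuals")
    per_id = flags.groupby("id")["shock"].sum().astype(int)
    counts = per_id.value_counts().sort_index()
    counts = counts.reindex(range(int(counts.index.max()) + 1), fill_value=0)
    counts.name = "n_individuals"
    counts.index.name = "n_shocks"
    return counts


def shock_correlation(panel, threshold: ShockThreshold | float = 0.25) -> float:
    """Pearson correlation of the physical and mental shock indicators.

    Computed on (id, year) cells where both indicators are defined.  NaN with
    a warning when either indicator is constant.
    """
    phys = flag_panel_shocks(panel, "physical", threshold).rename(columns={"shock": "s_phys"})
    ment = flag_panel_shocks(panel, "mental", threshold).rename(columns={"shock": "s_ment"})
    both = phys.merge(ment, on=["id", "year"])
    if both.empty:
        warnings.warn("no common cells with both indicators defined")
        return float("nan")
    a = both["s_phys"].to_numpy(float)
    b = both["s_ment"].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("shock indicator has zero variance; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
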