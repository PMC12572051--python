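import numpy as np
import pandas as pd
import pytest

from shockpanel import GeneratorConfig, LearnerSpec, generate_panel
from shockpanel.generator import PanelTable


@pytest.fixture(scope="session")
def default_panel():
    """Mid-sized default-configuration panel shared across tests."""
    cfg = GeneratorConfig(n_individuals=4000, seed=3)
    panel, truth = generate_panel(cfg, seed=3)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def effect_panel():
    """Panel with a known +0.05 effect of physical shocks on not-smoking."""
    profile = {("smoke", "physical", 0): 0.05, ("smoke", "physical", 2): 0.05}
    cfg = GeneratorConfig(n_individuals=8000, effect_profile=profile, seed=11)
    panel, truth = generate_panel(cfg, seed=11)
    return cfg, panel, truth


@pytest.fixture()
def fast_lasso():
    return LearnerSpec(kind="lasso", lasso_Cs=(1.0,))


@pytest.fixture()
def fast_rf():
    return LearnerSpec(kind="random_forest", n_trees=25, depth_grid=(4,))


def make_toy_panel(score_rows, outcome_rows=None, covariates=None) -> PanelTable:
    """Hand-built panel from (id, year, mcs, pcs) and optional outcome tuples."""
    years = sorted({r[1] for r in score_rows})
    ids = sorted({r[0] for r in score_rows})
    waves = pd.DataFrame(
        [(i, y) for i in ids for y in years], columns=["id", "year"]
    )
    waves["mcs"] = np.nan
    waves["pcs"] = np.nan
    for col in ("y_smoke", "y_diet", "y_sport"):
        waves[col] = np.nan
    waves["attrited"] = False
    waves = waves.set_index(["id", "year"])
    for i, y, mcs, pcs in score_rows:
        waves.loc[(i, y), ["mcs", "pcs"]] = [mcs, pcs]
    if outcome_rows:
        for i, y, col, val in outcome_rows:
            waves.loc[(i, y), col] = val
    waves = waves.reset_index()
    if covariates is None:
        covariates = pd.DataFrame({"id": ids, "age": 40.0, "female": 0.0})
    return PanelTable(waves=waves, individuals=covariates)


@pytest.fixture()
def toy_panel_factory():
    return make_toy_panel
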