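import numpy as np
import pandas as pd
import pytest

from dpgap import ScenarioConfig, default_scenario, run_pipeline
from dpgap.tables import AGE_GROUPS, CountTable


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A compact world: constant parameters, two analysis years."""
    return ScenarioConfig(
        years=(2000, 2001),
        total_population=100_000,
        dp_prevalence=0.05,
        hazard_dp=0.02,
        hazard_nondp=0.002,
    )


@pytest.fixture(scope="session")
def default_det_run():
    """Deterministic full-pipeline run of the baseline scenario."""
    return run_pipeline(default_scenario())


def stock_table(values: dict[int, float], region="East", age_group="30-34",
                subpop="DP") -> CountTable:
    """One-series stock table from {year: count}."""
    rows = [
        {"year": y, "region": region, "age_group": age_group, "subpop": subpop, "count": c}
        for y, c in values.items()
    ]
    return CountTable("stock", pd.DataFrame(rows))


def full_grid_table(role: str, years, value, subpop="DP") -> CountTable:
    """Constant-valued table over the full (year, region, age group) grid."""
    grid = pd.MultiIndex.from_product(
        [list(years), ["East", "West"], list(AGE_GROUPS)],
        names=["year", "region", "age_group"],
    )
    df = pd.DataFrame(index=grid).reset_index()
    df["subpop"] = subpop
    df["count"] = value
    return CountTable(role, df)
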