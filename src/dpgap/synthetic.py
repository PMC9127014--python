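"""Synthetic register samples and population tables with known ground truth.

The original analysis rests on restricted pension-register microdata (a 1%
year-end stock sample, *Bestand*, and a 10% sample of deaths during the
reporting year, *Wegfall*) combined with national population and death counts.
None of those files can be redistributed, so this module generates a
structurally faithful synthetic world: a two-region (East/West) male
population aged 30-59 in 5-year groups, a disability-pension (DP)
subpopulation with its own death hazard, and the two-stage sampling scheme.

Ground truth is retained alongside the samples, so reconstruction, rate
estimation and decomposition can be verified end to end.

Modes
-----
deterministic
    Counts are expectations (real-valued): DP stock = N*pi, deaths =
    exposure * hazard.  Round trips through the pipeline are then exact.
stochastic
    DP stock ~ Binomial(N, pi); deaths ~ Poisson(exposure * hazard);
    sampling thins each cell binomially.  Reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .errors import ConfigurationError, ValidationError
from .tables import AGE_GROUPS, CELL_KEY, REGIONS, CountTable

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["year", "region", "age_group", "pension_type", "record_kind"]

#: Default annual death hazards for men not receiving DP, by 5-year age group
#: (per person-year).  Chosen at the order of magnitude of west-European male
#: working-age mortality around 2000; DP hazards are nine times these.
DEFAULT_NONDP_HAZARD = {
    "30-34": 0.0008,
    "35-39": 0.0010,
    "40-44": 0.0015,
    "45-49": 0.0025,
    "50-54": 0.0040,
    "55-59": 0.0065,
}

#: Default male population per 5-year age group (persons).  Real-world
#: magnitude: roughly 3.3M East vs 16.5M West German men aged 30-59.
DEFAULT_POPULATION = {"East": 550_000, "West": 2_750_000}


def default_scenario(mode: str = "deterministic", seed: int = 0) -> ScenarioConfig:
    """The documented baseline scenario.

    East DP prevalence 5%, West 3% (every age group); within each region the
    DP death hazard is nine times the non-DP hazard and the non-DP hazards are
    shared between regions, so the entire East-West gap is compositional.
    Years 1995-2013, 1% stock / 10% death sampling.
    """
    hazard_nd = dict(DEFAULT_NONDP_HAZARD)
    hazard_dp = {a: 9.0 * m for a, m in hazard_nd.items()}
    return ScenarioConfig(
        years=(1995, 2013),
        total_population={r: float(n) for r, n in DEFAULT_POPULATION.items()},
        dp_prevalence={"East": 0.05, "West": 0.03},
        hazard_dp={"East": hazard_dp, "West": dict(hazard_dp)},
        hazard_nondp={"East": hazard_nd, "West": dict(hazard_nd)},
        mode=mode,
        seed=seed,
    )


@dataclass
class TrueCounts:
    """Ground truth of one synthetic world.

    ``stock`` holds DP and total year-end populations for the lead-in year
    through the last analysis year; ``deaths`` holds DP, nonDP and total death
    counts for the analysis years (additive by construction).  The auxiliary
    ``other_*`` frames count non-DP pensioners (survivor pensions etc.) whose
    records pad the samples and must be filtered out during reconstruction;
    they are a subset of the nonDP subpopulation, not a third one.
    """

    stock: CountTable
    deaths: CountTable
    other_stock: pd.DataFrame = field(default=None, repr=False)
    other_deaths: pd.DataFrame = field(default=None, repr=False)

    def is_empty(self) -> bool:
        return self.stock.data.empty and self.deaths.data.empty


def build_true_counts(config: ScenarioConfig, seed: int | None = None) -> TrueCounts:
    """Generate the ground-truth world for ``config``.

    Deaths are generated against mid-year exposure — the average of the two
    successive year-end stocks — matching the exposure definition used in
    reconstruction, so deterministic round trips are exact.

    Parameters
    ----------
    seed:
        Overrides ``config.seed`` (stochastic mode only).
    """
    grid = config.grid()  # validated; hazards <= 1 guaranteed
    y0, _ = config.years
    rng = np.random.default_rng(config.seed if seed is None else seed)
    stochastic = config.mode == "stochastic"

    n = grid["N"].to_numpy()
    if stochastic:
        dp_stock = rng.binomial(np.rint(n).astype(np.int64), grid["pi"].to_numpy()).astype(float)
        other_stock = rng.binomial(
            np.rint(n).astype(np.int64), config.other_pension_share
        ).astype(float)
    else:
        dp_stock = n * grid["pi"].to_numpy()
        other_stock = n * config.other_pension_share

    stock = grid.copy()
    stock["DP"] = dp_stock
    stock["total"] = n
    stock["other"] = other_stock

    # Mid-year exposure per analysis year: average of year-end stocks (t-1, t).
    wide = stock.reset_index().pivot_table(
        index=["region", "age_group"], columns="year",
        values=["DP", "total", "other", "m_dp", "m_nd"],
    )
    years = sorted(stock.index.get_level_values("year").unique())
    analysis_years = [y for y in years if y >= y0]

    frames = []
    for y in analysis_years:
        exp_dp = (wide[("DP", y - 1)] + wide[("DP", y)]) / 2.0
        exp_tot = (wide[("total", y - 1)] + wide[("total", y)]) / 2.0
        exp_oth = (wide[("other", y - 1)] + wide[("other", y)]) / 2.0
        lam_dp = exp_dp * wide[("m_dp", y)]
        lam_nd = (exp_tot - exp_dp) * wide[("m_nd", y)]
        lam_oth = exp_oth * wide[("m_nd", y)]
        if stochastic:
            d_dp = rng.poisson(lam_dp.to_numpy()).astype(float)
            d_nd = rng.poisson(lam_nd.to_numpy()).astype(float)
            d_oth = rng.poisson(lam_oth.to_numpy()).astype(float)
        else:
            d_dp, d_nd, d_oth = lam_dp.to_numpy(), lam_nd.to_numpy(), lam_oth.to_numpy()
        f = pd.DataFrame(index=wide.index)
        f["year"] = y
        f["DP"], f["nonDP"], f["other"] = d_dp, d_nd, d_oth
        frames.append(f.reset_index())
    deaths = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["region", "age_group", "year", "DP", "nonDP", "other"])
    deaths["total"] = deaths["DP"] + deaths["nonDP"]

    stock_long = (
        stock.reset_index()
        .melt(id_vars=["year", "region", "age_group"], value_vars=["DP", "total"],
              var_name="subpop", value_name="count")
    )
    deaths_long = deaths.melt(
        id_vars=["year", "region", "age_group"], value_vars=["DP", "nonDP", "total"],
        var_name="subpop", value_name="count")

    other_stock_df = stock.reset_index()[["year", "region", "age_group", "other"]].rename(
        columns={"other": "count"})
    other_deaths_df = deaths[["year", "region", "age_group", "other"]].rename(
        columns={"other": "count"})
    return TrueCounts(
        stock=CountTable("stock", stock_long),
        deaths=CountTable("deaths", deaths_long),
        other_stock=other_stock_df,
        other_deaths=other_deaths_df,
    )


def thin_counts(cells: pd.DataFrame, fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    """Binomially thin per-cell counts: each unit retained with prob. ``fraction``.

    Non-integer counts (deterministic-mode worlds) are rounded to the nearest
    integer first, with a log notice.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"sampling fraction must be in (0, 1], got {fraction}")
    out = cells.copy()
    n = out["count"].to_numpy(dtype=float)
    if not np.allclose(n, np.rint(n)):
        logger.info("rounding %d non-integer cell counts before thinning",
                    int((~np.isclose(n, np.rint(n))).sum()))
    n_int = np.rint(n).astype(np.int64)
    if fraction == 1.0:
        out["count"] = n_int.astype(float)
    else:
        out["count"] = rng.binomial(n_int, fraction).astype(float)
    return out


def draw_sample(
    counts: TrueCounts,
    kind: str,
    fraction: float,
    seed: int,
) -> pd.DataFrame:
    """Draw a record-level register sample from the true counts.

    ``kind="stock"`` emulates the Bestand (pension payments at year-end,
    sampled at the 1% fraction); ``kind="death"`` the Wegfall (pension
    terminations through death, 10%).  Both mix disability pensions with
    other pension types, as the real samples do.  Units are retained
    independently with probability ``fraction`` within each cell; a fixed
    seed reproduces the sample exactly.

    Returns a frame with one row per sampled record and columns
    ``year, region, age_group, pension_type, record_kind``.
    """
    if kind not in ("stock", "death"):
        raise ValidationError(f"sample kind must be 'stock' or 'death', got {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "stock":
        dp_cells = counts.stock.subset("DP").data[["year", "region", "age_group", "count"]]
        other_cells = counts.other_stock
    else:
        dp_cells = counts.deaths.subset("DP").data[["year", "region", "age_group", "count"]]
        other_cells = counts.other_deaths

    parts = []
    for cells, ptype in ((dp_cells, "disability"), (other_cells, "other")):
        if cells is None or len(cells) == 0:
            continue
        thinned = thin_counts(cells, fraction, rng)
        reps = thinned["count"].to_numpy(dtype=np.int64)
        base = thinned[["year", "region", "age_group"]]
        expanded = base.loc[base.index.repeat(reps)].reset_index(drop=True)
        expanded["pension_type"] = ptype
        parts.append(expanded)
    if not parts:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    records = pd.concat(parts, ignore_index=True)
    records["record_kind"] = kind
    return records[RECORD_COLUMNS]


def write_records_csv(records: pd.DataFrame, path) -> None:
    """Serialize sample records with the canonical header."""
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    records = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records CSV {path} missing columns {missing}")
    return records[RECORD_COLUMNS]
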