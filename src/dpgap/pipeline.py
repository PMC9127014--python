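"""End-to-end pipeline: simulate -> reconstruct -> rates -> decompose.

Chains every stage in order and collects the quantities of interest: SDR
series for the total, DP-only and DP-excluded populations by region, the DP
prevalence series, and the year-by-year decomposition of the East-West SDR
difference with its component shares.

Reporting convention: decomposition outputs follow the printed-table
convention ``total = SDR_West - SDR_East`` — negative values indicate the
advantage of West over East.  (The core ``decompose_year`` computes East
minus West; the pipeline flips the direction via the exact antisymmetry of
the order-averaged contributions.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .decomposition import (
    DecompositionResult,
    ParamSet,
    aggregate_result,
    component_shares,
    decompose_year,
    results_frame,
)
from .errors import ValidationError
from .rates import (
    RateTable,
    StandardPopulation,
    death_rates,
    default_standard,
    moving_average,
    prevalence,
)
from .reconstruction import derive_nondp, midyear_exposure
from .synthetic import TrueCounts, build_true_counts, thin_counts
from .tables import CountTable, concat_tables

logger = logging.getLogger(__name__)

SMOOTHING_WINDOW = 3


@dataclass
class PipelineRun:
    """All artifacts of one pipeline execution."""

    config: ScenarioConfig
    seed: int
    true_counts: TrueCounts
    dp_exposure: CountTable
    dp_deaths: CountTable
    nondp_exposure: CountTable
    nondp_deaths: CountTable
    total_exposure: CountTable
    total_deaths: CountTable
    rates: RateTable
    sdr: pd.DataFrame
    sdr_smoothed: pd.DataFrame
    prevalence: pd.DataFrame
    results: list[DecompositionResult]
    aggregate: DecompositionResult
    shares: pd.DataFrame
    table: str
    log: list[str] = field(default_factory=list)
    output_paths: dict = field(default_factory=dict)


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.INFO)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(f"{record.levelname}: {record.getMessage()}")


def _reconstruct_dp(
    counts: TrueCounts,
    config: ScenarioConfig,
    rng_stock: np.random.Generator,
    rng_death: np.random.Generator,
) -> tuple[CountTable, CountTable]:
    """Reconstructed DP stock and death tables (cell level).

    Stochastic mode thins each cell binomially at the configured sampling
    fraction and weights the result back up by its reciprocal (100 for the 1%
    stock sample, 10 for the 10% death sample).  Deterministic mode keeps the
    exact expected counts — the fraction-1/weight-1 identity.
    """
    true_stock = counts.stock.subset("DP").data[["year", "region", "age_group", "count"]]
    true_deaths = counts.deaths.subset("DP").data[["year", "region", "age_group", "count"]]
    if config.mode == "deterministic":
        logger.info("deterministic mode: identity sampling (fraction 1, weight 1)")
        stock_hat, deaths_hat = true_stock, true_deaths
    else:
        f_b, f_w = config.bestand_fraction, config.wegfall_fraction
        logger.info("weighting stock sample by %.0f, death sample by %.0f", 1 / f_b, 1 / f_w)
        stock_hat = thin_counts(true_stock, f_b, rng_stock)
        stock_hat["count"] /= f_b
        deaths_hat = thin_counts(true_deaths, f_w, rng_death)
        deaths_hat["count"] /= f_w
    y0, y1 = config.years
    stock_tbl = CountTable("stock", stock_hat.assign(subpop="DP")).reindex_grid(
        range(y0 - 1, y1 + 1), config.regions, config.age_groups)
    deaths_tbl = CountTable("deaths", deaths_hat.assign(subpop="DP")).reindex_grid(
        range(y0, y1 + 1), config.regions, config.age_groups)
    return stock_tbl, deaths_tbl


def run_pipeline(
    config: ScenarioConfig,
    seed: int | None = None,
    standard: StandardPopulation | None = None,
    smooth_decomposition_inputs: bool = False,
    out_dir: str | Path | None = None,
) -> PipelineRun:
    """Execute the full pipeline on one synthetic world.

    Parameters
    ----------
    seed:
        Master seed overriding ``config.seed``; it drives world generation
        and both sampling stages through independent child streams.
    standard:
        Standard population for direct standardization (default:
        :func:`dpgap.rates.default_standard`).
    smooth_decomposition_inputs:
        When true, the age-specific rate and prevalence series feeding the
        decomposition are smoothed with the same centered 3-year window used
        for SDR reporting (losing one year at each end); by default the
        decomposition consumes unsmoothed annual inputs covering all years.
    out_dir:
        If given, all tabular outputs, the rendered table and the run log
        are written there; re-running with identical config and seed
        reproduces the files byte for byte.
    """
    log_sink: list[str] = []
    handler = _ListHandler(log_sink)
    pkg_logger = logging.getLogger("dpgap")
    pkg_logger.addHandler(handler)
    old_level = pkg_logger.level
    if pkg_logger.level > logging.INFO or pkg_logger.level == logging.NOTSET:
        pkg_logger.setLevel(logging.INFO)
    try:
        run = _run(config, seed, standard, smooth_decomposition_inputs, log_sink)
    finally:
        pkg_logger.removeHandler(handler)
        pkg_logger.setLevel(old_level)
    if out_dir is not None:
        _write_outputs(run, Path(out_dir))
    return run


def _run(config, seed, standard, smooth_inputs, log_sink) -> PipelineRun:
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    world_seed, stock_ss, death_ss = ss.spawn(3)
    standard = standard or default_standard()

    counts = build_true_counts(config, seed=world_seed)
    dp_stock, dp_deaths = _reconstruct_dp(
        counts, config, np.random.default_rng(stock_ss), np.random.default_rng(death_ss))

    dp_exposure = midyear_exposure(dp_stock)
    total_exposure = midyear_exposure(counts.stock.subset("total"))
    total_deaths = counts.deaths.subset("total")
    nondp_exposure, nondp_deaths = derive_nondp(
        total_exposure, total_deaths, dp_exposure, dp_deaths)

    all_deaths = concat_tables(dp_deaths, nondp_deaths, total_deaths)
    all_exposure = concat_tables(dp_exposure, nondp_exposure, total_exposure)
    rate_table = death_rates(all_deaths, all_exposure)

    from .rates import standardize  # local import keeps module top uncluttered

    sdr = standardize(rate_table, standard)
    sdr_smoothed = moving_average(sdr, SMOOTHING_WINDOW)
    prev = prevalence(dp_exposure, total_exposure)

    if smooth_inputs:
        logger.info("smoothing decomposition inputs with window %d", SMOOTHING_WINDOW)
        rate_in = RateTable(
            moving_average(rate_table.data, SMOOTHING_WINDOW, value_col="rate"),
            provenance="smoothed")
        prev_in = moving_average(prev, SMOOTHING_WINDOW, value_col="pi")
    else:
        rate_in, prev_in = rate_table, prev

    years = sorted(prev_in["year"].unique())
    results: list[DecompositionResult] = []
    for year in years:
        west = ParamSet.from_tables(prev_in, rate_in, "West", year, config.age_groups)
        east = ParamSet.from_tables(prev_in, rate_in, "East", year, config.age_groups)
        # decompose_year gives East - West; negate for the printed convention
        results.append(decompose_year(west, east, standard).negated())

    share_rows = []
    for r in results:
        if r.total == 0:
            logger.info("zero total difference in %d: shares undefined, omitted", r.year)
            continue
        s_nd, s_dp, s_pi = component_shares(r)
        share_rows.append({"year": r.year, "share_mort_nondp": s_nd,
                           "share_mort_dp": s_dp, "share_prevalence": s_pi})
    shares = pd.DataFrame(
        share_rows, columns=["year", "share_mort_nondp", "share_mort_dp", "share_prevalence"])

    return PipelineRun(
        config=config,
        seed=master,
        true_counts=counts,
        dp_exposure=dp_exposure,
        dp_deaths=dp_deaths,
        nondp_exposure=nondp_exposure,
        nondp_deaths=nondp_deaths,
        total_exposure=total_exposure,
        total_deaths=total_deaths,
        rates=rate_table,
        sdr=sdr,
        sdr_smoothed=sdr_smoothed,
        prevalence=prev,
        results=results,
        aggregate=aggregate_result(results),
        shares=shares,
        table=render_decomposition_table(results),
        log=log_sink,
    )


def render_decomposition_table(results: list[DecompositionResult]) -> str:
    """Format the decomposition as a fixed-width year-by-year table.

    One row per year, one-decimal values, sign convention preserved; every
    row's additivity is re-checked before rendering and duplicate years are
    rejected.
    """
    if not results:
        raise ValidationError("cannot render an empty decomposition")
    years = [r.year for r in results]
    if len(set(years)) != len(years):
        dupes = sorted({y for y in years if years.count(y) > 1})
        raise ValidationError(f"duplicate year(s) in decomposition results: {dupes}")
    for r in results:
        resid = abs(sum(r.components()) - r.total)
        if resid > 1e-9 * max(1.0, abs(r.total)):
            raise ValidationError(
                f"row {r.year} fails the additivity check (residual {resid:.3e})")
    header = (f"{'Year':<6}{'Mortality non-DP':>18}{'Mortality DP':>14}"
              f"{'Prevalence DP':>15}{'Total difference':>18}")
    lines = [header, "-" * len(header)]
    def fmt(x: float, width: int) -> str:
        return f"{round(x, 1) + 0.0:>{width}.1f}"  # +0.0 normalizes -0.0

    for r in sorted(results, key=lambda r: r.year):
        lines.append(
            f"{r.year:<6}{fmt(r.comp_mort_nondp, 18)}{fmt(r.comp_mort_dp, 14)}"
            f"{fmt(r.comp_prevalence, 15)}{fmt(r.total, 18)}")
    return "\n".join(lines)


def _write_outputs(run: PipelineRun, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, writer):
        path = out_dir / name
        writer(path)
        paths[name.split(".")[0]] = path

    save("true_stock.csv", run.true_counts.stock.to_csv)
    save("true_deaths.csv", run.true_counts.deaths.to_csv)
    save("dp_exposure.csv", run.dp_exposure.to_csv)
    save("dp_deaths.csv", run.dp_deaths.to_csv)
    save("nondp_exposure.csv", run.nondp_exposure.to_csv)
    save("nondp_deaths.csv", run.nondp_deaths.to_csv)
    save("rates.csv", lambda p: run.rates.data.to_csv(p, index=False))
    save("sdr.csv", lambda p: run.sdr.rename(columns={"sdr": "value"}).to_csv(p, index=False))
    save("sdr_smoothed.csv",
         lambda p: run.sdr_smoothed.rename(columns={"sdr": "value"}).to_csv(p, index=False))
    save("prevalence.csv", lambda p: run.prevalence.to_csv(p, index=False))
    save("decomposition.csv", lambda p: results_frame(run.results).to_csv(p, index=False))
    save("shares.csv", lambda p: run.shares.to_csv(p, index=False))
    save("table.txt", lambda p: Path(p).write_text(run.table + "\n"))
    save("log.txt", lambda p: Path(p).write_text("\n".join(run.log) + "\n"))
    run.output_paths = paths
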