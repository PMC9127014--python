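"""Reconstruct subpopulation counts from weighted register samples.

The stock sample contains 1% of all pension records, so a weighting factor of
100 estimates the number of DP recipients in the full population; each record
of the 10% death sample is weighted by 10.  The non-DP population and its
deaths follow as the difference between national totals and the reconstructed
DP figures.  Mid-year exposure is the average of two successive year-end
stocks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvariantError, ValidationError
from .tables import AGE_GROUPS, CELL_KEY, CountTable, check_contiguous_years

logger = logging.getLogger(__name__)

_ROLE_OF_KIND = {"stock": "stock", "death": "deaths"}


def expand_sample(
    records: pd.DataFrame,
    weight: float,
    age_groups: tuple[str, ...] = AGE_GROUPS,
) -> CountTable:
    """Weight disability-pension sample records up to population counts.

    Records with other pension types are filtered out (and logged) before
    counting; the cell count is (number of disability records) x ``weight``.
    All records must share one ``record_kind``; stock records yield a table
    with role ``stock``, death records one with role ``deaths``.
    """
    if weight <= 0:
        raise ValidationError(f"weight must be positive, got {weight}")
    if records.empty:
        return CountTable("stock", pd.DataFrame(columns=CELL_KEY + ["count"]))
    kinds = records["record_kind"].unique()
    if len(kinds) != 1:
        raise ValidationError(f"mixed record kinds in sample: {sorted(kinds)}")
    kind = kinds[0]
    if kind not in _ROLE_OF_KIND:
        raise ValidationError(f"unknown record kind {kind!r}")
    unknown = set(records["age_group"]) - set(age_groups)
    if unknown:
        raise ValidationError(f"unknown age-group label(s) in sample: {sorted(unknown)}")

    dp = records[records["pension_type"] == "disability"]
    n_filtered = len(records) - len(dp)
    if n_filtered:
        logger.info("filtered %d non-disability pension records", n_filtered)
    counts = (
        dp.groupby(["year", "region", "age_group"], observed=True)
        .size()
        .mul(float(weight))
        .rename("count")
        .reset_index()
    )
    counts["subpop"] = "DP"
    return CountTable(_ROLE_OF_KIND[kind], counts)


def midyear_exposure(stock: CountTable) -> CountTable:
    """Mid-year population as the average of two successive year-end stocks.

    ``exposure(t) = [stock(t-1) + stock(t)] / 2``; the earliest stock year
    serves only as the lead-in and yields no exposure row (logged).  A gap in
    year coverage is rejected, naming the missing year.
    """
    if stock.role != "stock":
        raise ValidationError(f"midyear_exposure needs a stock table, got role {stock.role!r}")
    if stock.data.empty:
        logger.warning("empty stock table: no exposure computed")
        return CountTable("exposure", pd.DataFrame(columns=CELL_KEY + ["count"]))

    out = []
    for (region, age_group, subpop), grp in stock.data.groupby(
        ["region", "age_group", "subpop"], observed=True
    ):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        check_contiguous_years(years, context=f"stock {region}/{age_group}/{subpop}")
        if len(years) < 2:
            logger.warning(
                "single stock year %d for %s/%s/%s: no exposure defined",
                years[0], region, age_group, subpop)
            continue
        vals = grp["count"].to_numpy(dtype=float)
        out.append(pd.DataFrame({
            "year": years[1:],
            "region": region,
            "age_group": age_group,
            "subpop": subpop,
            "count": (vals[:-1] + vals[1:]) / 2.0,
        }))
    if not out:
        logger.warning("no exposure rows produced (insufficient stock years)")
        return CountTable("exposure", pd.DataFrame(columns=CELL_KEY + ["count"]))
    first = int(stock.data["year"].min())
    logger.info("dropped lead-in stock year %d when forming mid-year exposure", first)
    return CountTable("exposure", pd.concat(out, ignore_index=True))


def _difference(total: CountTable, part: CountTable, what: str) -> CountTable:
    if total.role != part.role:
        raise ValidationError(
            f"{what}: role mismatch between total ({total.role}) and DP ({part.role}) tables")
    t = total.data.set_index(["year", "region", "age_group"])["count"]
    p = part.data.set_index(["year", "region", "age_group"])["count"]
    if not t.index.sort_values().equals(p.index.sort_values()):
        only_t = t.index.difference(p.index).tolist()[:5]
        only_p = p.index.difference(t.index).tolist()[:5]
        raise ValidationError(
            f"{what}: coverage mismatch between total and DP tables "
            f"(total-only cells: {only_t}; DP-only cells: {only_p})")
    diff = (t - p).rename("count")
    neg = diff[diff < 0]
    if len(neg):
        cells = [tuple(ix) for ix in neg.index]
        raise InvariantError(
            f"{what}: DP exceeds total in {len(neg)} cell(s): {cells} — "
            "inputs are inconsistent (e.g. sampling noise exceeding the margin)")
    out = diff.reset_index()
    out["subpop"] = "nonDP"
    return CountTable(total.role, out)


def derive_nondp(
    total_pop: CountTable,
    total_deaths: CountTable,
    dp_pop: CountTable,
    dp_deaths: CountTable,
) -> tuple[CountTable, CountTable]:
    """Non-DP population and deaths as total minus DP, cell-wise.

    Additivity DP + nonDP = total then holds exactly by construction.  Any
    negative difference is an error reporting every offending cell; clamping
    would silently bias the non-DP rates.
    """
    nondp_pop = _difference(total_pop, dp_pop, "population")
    nondp_deaths = _difference(total_deaths, dp_deaths, "deaths")
    return nondp_pop, nondp_deaths
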