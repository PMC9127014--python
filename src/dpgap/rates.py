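"""Age-specific death rates, direct standardization, smoothing, prevalence.

Rates are expressed per 100,000 person-years.  The standardized death rate
(SDR) is the direct standardization ``SDR = sum_a c_a * m_a`` with weights
``c_a`` from a fixed standard population, which removes age-structure
differences between the compared populations.  SDR series are stabilized
with a centered 3-year moving average (small DP death counts at younger
working ages make annual SDRs noisy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import AGE_GROUPS, CountTable, check_contiguous_years

logger = logging.getLogger(__name__)

PER = 100_000.0


@dataclass
class RateTable:
    """Death rates per 100,000 person-years per (year, region, age group, subpop)."""

    data: pd.DataFrame = field(repr=False)
    provenance: str = "raw"

    def __post_init__(self) -> None:
        need = ["year", "region", "age_group", "subpop", "rate"]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise ValidationError(f"rate table missing columns: {missing}")
        df = self.data.loc[:, need].copy()
        if (df["rate"] < 0).any() or not np.isfinite(df["rate"]).all():
            raise ValidationError("rates must be finite and non-negative")
        self.data = df.sort_values(need[:4], kind="mergesort").reset_index(drop=True)

    def subset(self, subpop: str) -> pd.DataFrame:
        return self.data[self.data["subpop"] == subpop]


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group weights for direct standardization.

    Weights are normalized to sum to one on use; any non-negative counts or
    proportions covering exactly the configured age groups are accepted.
    """

    weights: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if not w:
            raise ValidationError("standard population has no age groups")
        if any(v < 0 for v in w.values()):
            raise ValidationError("standard-population weights must be non-negative")
        if sum(w.values()) <= 0:
            raise ValidationError("standard-population weights sum to zero")
        object.__setattr__(self, "weights", w)

    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def normalized(self) -> dict[str, float]:
        total = float(sum(self.weights.values()))
        return {a: v / total for a, v in self.weights.items()}

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age_group": list(self.weights), "weight": list(self.weights.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "StandardPopulation":
        df = pd.read_csv(path)
        if not {"age_group", "weight"}.issubset(df.columns):
            raise ValidationError(f"standard-population CSV {path} needs age_group,weight")
        return cls(dict(zip(df["age_group"], df["weight"])), label=label or str(path))


def default_standard() -> StandardPopulation:
    """Approximate German male population 2005, ages 30-59 (thousands).

    Synthetic stand-in: the counts are rounded approximations of the German
    male age distribution in 2005, not official figures.  Within this
    pipeline only the relative weights matter, and any replacement standard
    can be supplied as a CSV of ``age_group,weight``.
    """
    return StandardPopulation(
        {
            "30-34": 2545.0,
            "35-39": 3113.0,
            "40-44": 3536.0,
            "45-49": 3201.0,
            "50-54": 2832.0,
            "55-59": 2418.0,
        },
        label="Germany 2005, males 30-59 (approximate)",
    )


def death_rates(deaths: CountTable, exposure: CountTable) -> RateTable:
    """Age-specific death rates: deaths / exposure x 100,000, cell-wise.

    Zero exposure with zero deaths yields rate 0 (logged); zero exposure with
    positive deaths is rejected naming the cell.
    """
    if deaths.role != "deaths":
        raise ValidationError(f"death_rates needs a deaths table, got role {deaths.role!r}")
    if exposure.role != "exposure":
        raise ValidationError(f"death_rates needs an exposure table, got role {exposure.role!r}")
    d = deaths.indexed()
    e = exposure.indexed()
    if not d.index.equals(e.index):
        only_d = d.index.difference(e.index).tolist()[:5]
        only_e = e.index.difference(d.index).tolist()[:5]
        raise ValidationError(
            f"coverage mismatch between deaths and exposure "
            f"(deaths-only: {only_d}; exposure-only: {only_e})")
    zero_exp = e == 0
    bad = zero_exp & (d > 0)
    if bad.any():
        cells = [tuple(ix) for ix in d.index[bad]]
        raise ValidationError(f"zero exposure with positive deaths at cell(s): {cells}")
    if zero_exp.any():
        logger.info("defining rate 0 at %d zero-exposure, zero-death cell(s)",
                    int(zero_exp.sum()))
    rate = pd.Series(0.0, index=d.index)
    nz = ~zero_exp
    rate[nz] = d[nz] / e[nz] * PER
    out = rate.rename("rate").reset_index()
    return RateTable(out, provenance="raw")


def standardize(rates: RateTable, standard: StandardPopulation) -> pd.DataFrame:
    """Directly standardized death rate per (year, region, subpop).

    ``SDR = sum_a c_a * m_a`` with the standard's normalized weights; linear
    in each age-specific rate.  Missing age groups are rejected.
    """
    weights = standard.normalized()
    out = []
    for (year, region, subpop), grp in rates.data.groupby(
        ["year", "region", "subpop"], observed=True
    ):
        m = dict(zip(grp["age_group"], grp["rate"]))
        missing = [a for a in weights if a not in m]
        if missing:
            raise ValidationError(
                f"rates for ({year}, {region}, {subpop}) miss age group(s) {missing}")
        sdr = sum(weights[a] * m[a] for a in weights)
        out.append({"year": int(year), "region": region, "subpop": subpop, "sdr": sdr})
    return pd.DataFrame(out, columns=["year", "region", "subpop", "sdr"])


def moving_average(series: pd.DataFrame, window: int = 3, value_col: str | None = None) -> pd.DataFrame:
    """Centered moving average over contiguous years, per series.

    The ``(window-1)/2`` endpoint years on each side are dropped: a 1995-2013
    input with window 3 yields 1996-2012.  Series shorter than the window are
    rejected, as are gaps in year coverage.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be an odd integer >= 1, got {window}")
    if value_col is None:
        candidates = [c for c in series.columns
                      if c not in ("year", "region", "subpop", "age_group")]
        if len(candidates) != 1:
            raise ValidationError(f"cannot infer value column among {candidates}")
        value_col = candidates[0]
    keys = [c for c in ("region", "subpop", "age_group") if c in series.columns]
    half = (window - 1) // 2

    def smooth_one(grp: pd.DataFrame) -> pd.DataFrame:
        grp = grp.sort_values("year")
        check_contiguous_years(grp["year"].to_numpy(), context="series")
        if len(grp) < window:
            raise ValidationError(
                f"series of length {len(grp)} is shorter than window {window}")
        vals = grp[value_col].rolling(window, center=True).mean()
        out = grp.copy()
        out[value_col] = vals
        return out.iloc[half: len(grp) - half] if half else out

    if keys:
        parts = [smooth_one(grp) for _, grp in series.groupby(keys, observed=True)]
        smoothed = pd.concat(parts, ignore_index=True)
    else:
        smoothed = smooth_one(series).reset_index(drop=True)
    if half:
        logger.info("moving average (window %d) dropped %d endpoint year(s) per series",
                    window, 2 * half)
    return smoothed


def prevalence(dp_exposure: CountTable, total_exposure: CountTable) -> pd.DataFrame:
    """DP prevalence pi = DP / total per (year, region, age group).

    Both inputs are mid-year populations; DP exceeding the total is rejected.
    """
    dp = dp_exposure.data.set_index(["year", "region", "age_group"])["count"]
    tot = total_exposure.data.set_index(["year", "region", "age_group"])["count"]
    if not dp.index.sort_values().equals(tot.index.sort_values()):
        raise ValidationError("coverage mismatch between DP and total exposure tables")
    if (tot <= 0).any():
        cells = [tuple(ix) for ix in tot.index[tot <= 0]]
        raise ValidationError(f"non-positive total exposure at cell(s): {cells}")
    pi = dp / tot
    if (pi > 1).any():
        cells = [tuple(ix) for ix in pi.index[pi > 1]]
        raise ValidationError(f"DP exposure exceeds total at cell(s): {cells}")
    return pi.rename("pi").reset_index()
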