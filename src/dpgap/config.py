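"""Scenario configuration for the synthetic two-region pension world.

A :class:`ScenarioConfig` fully parameterizes the synthetic world: calendar
years, the East/West region pair, 5-year age groups spanning ages 30-59, total
male population per cell, disability-pension (DP) prevalence, annual death
hazards for the DP and non-DP subpopulations, the two register sampling
fractions (1% stock / 10% deaths), a mode switch and a seed.

Parameter fields accept, interchangeably:

* a scalar (one value for every cell);
* a mapping ``{region: value}`` where each value is a scalar or a mapping
  ``{age_group: value}``;
* a long-format :class:`pandas.DataFrame` with columns
  ``year, region, age_group, value`` covering the full grid (for
  time-varying scenarios).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .tables import AGE_GROUPS, REGIONS, validate_age_groups

ParamSpec = Union[float, Mapping, pd.DataFrame]

_PARAM_FIELDS = ("total_population", "dp_prevalence", "hazard_dp", "hazard_nondp")
_PARAM_COLS = {"total_population": "N", "dp_prevalence": "pi",
               "hazard_dp": "m_dp", "hazard_nondp": "m_nd"}


def _resolve(spec: ParamSpec, years, regions, age_groups, name: str) -> pd.Series:
    """Broadcast a parameter spec onto the full (year, region, age group) grid."""
    grid = pd.MultiIndex.from_product(
        [years, regions, age_groups], names=["year", "region", "age_group"]
    )
    if isinstance(spec, pd.DataFrame):
        need = {"year", "region", "age_group", "value"}
        if not need.issubset(spec.columns):
            raise ConfigurationError(f"{name}: frame spec needs columns {sorted(need)}")
        ser = spec.set_index(["year", "region", "age_group"])["value"].reindex(grid)
        if ser.isna().any():
            missing = ser[ser.isna()].index[0]
            raise ConfigurationError(f"{name}: frame spec does not cover cell {missing}")
        return ser.astype(float)
    if isinstance(spec, Mapping):
        unknown = set(spec) - set(regions)
        if unknown:
            raise ConfigurationError(f"{name}: unknown region keys {sorted(unknown)}")
        vals = pd.Series(index=grid, dtype=float)
        for region in regions:
            if region not in spec:
                raise ConfigurationError(f"{name}: no value for region {region!r}")
            sub = spec[region]
            if isinstance(sub, Mapping):
                unknown = set(sub) - set(age_groups)
                if unknown:
                    raise ConfigurationError(f"{name}: unknown age groups {sorted(unknown)}")
                for a in age_groups:
                    if a not in sub:
                        raise ConfigurationError(f"{name}: no value for {region}/{a}")
                    vals.loc[(slice(None), region, a)] = float(sub[a])
            else:
                vals.loc[(slice(None), region, slice(None))] = float(sub)
        return vals
    return pd.Series(float(spec), index=grid)


@dataclass
class ScenarioConfig:
    """Full parameterization of the synthetic East/West pension world.

    ``years`` is the inclusive analysis range; the generator additionally
    produces year-end stock for ``years[0] - 1`` so that mid-year exposure is
    defined from the first analysis year onward.
    """

    years: tuple[int, int] = (1995, 2013)
    regions: tuple[str, str] = REGIONS
    age_groups: tuple[str, ...] = AGE_GROUPS
    total_population: ParamSpec = 1_000_000
    dp_prevalence: ParamSpec = 0.04
    hazard_dp: ParamSpec = 0.02
    hazard_nondp: ParamSpec = 0.002
    #: Share of the male population drawing a non-disability pension before 60
    #: (survivor pensions etc.); filler the reconstruction must filter out.
    other_pension_share: float = 0.02
    bestand_fraction: float = 0.01
    wegfall_fraction: float = 0.10
    mode: str = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError(f"empty year range {self.years}")
        if tuple(self.regions) != REGIONS:
            raise ConfigurationError(f"regions must be {REGIONS}, got {tuple(self.regions)}")
        try:
            validate_age_groups(tuple(self.age_groups))
        except Exception as exc:  # surface as a configuration problem
            raise ConfigurationError(str(exc)) from exc
        for frac, fname in ((self.bestand_fraction, "bestand_fraction"),
                            (self.wegfall_fraction, "wegfall_fraction")):
            if not (0 < frac <= 1):
                raise ConfigurationError(f"{fname} must be in (0, 1], got {frac}")
        if not (0 <= self.other_pension_share < 1):
            raise ConfigurationError(
                f"other_pension_share must be in [0, 1), got {self.other_pension_share}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ConfigurationError(f"mode must be deterministic|stochastic, got {self.mode!r}")
        # Resolve once; also validates coverage and ranges.
        self._grid = self._build_grid()

    def _build_grid(self) -> pd.DataFrame:
        y0, y1 = self.years
        stock_years = list(range(y0 - 1, y1 + 1))
        cols = {}
        for fname in _PARAM_FIELDS:
            cols[_PARAM_COLS[fname]] = _resolve(
                getattr(self, fname), stock_years, self.regions, self.age_groups, fname
            )
        grid = pd.DataFrame(cols)
        if (grid["N"] < 0).any():
            raise ConfigurationError("total_population must be non-negative")
        if ((grid["pi"] < 0) | (grid["pi"] > 1)).any():
            raise ConfigurationError("dp_prevalence must lie in [0, 1]")
        if (grid[["m_dp", "m_nd"]] < 0).to_numpy().any():
            raise ConfigurationError("hazards must be non-negative")
        if (grid[["m_dp", "m_nd"]] > 1).to_numpy().any():
            raise ConfigurationError(
                "hazard exceeds 1/person-year: expected deaths would exceed exposure")
        return grid

    def grid(self) -> pd.DataFrame:
        """Per-cell parameters (N, pi, m_dp, m_nd) over stock years (lead-in included)."""
        return self._grid.copy()

    def with_(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with fields replaced (dataclasses.replace wrapper)."""
        return replace(self, **kwargs)

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "years": list(self.years),
            "regions": list(self.regions),
            "age_groups": list(self.age_groups),
            "other_pension_share": self.other_pension_share,
            "bestand_fraction": self.bestand_fraction,
            "wegfall_fraction": self.wegfall_fraction,
            "mode": self.mode,
            "seed": self.seed,
        }
        for fname in _PARAM_FIELDS:
            spec = getattr(self, fname)
            if isinstance(spec, pd.DataFrame):
                raise ConfigurationError(
                    f"{fname}: frame-valued parameters cannot be written to YAML")
            doc[fname] = _plain(spec)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError(f"scenario file {path} is not a mapping")
        kwargs = dict(doc)
        for key in ("years", "regions", "age_groups"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad scenario file {path}: {exc}") from exc


def _plain(spec):
    if isinstance(spec, Mapping):
        return {k: _plain(v) for k, v in spec.items()}
    return float(spec)
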