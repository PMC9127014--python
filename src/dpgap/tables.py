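"""Cell-indexed count tables shared by every pipeline stage.

All stages exchange counts aggregated to cells ``(year, region, age group,
subpopulation)``.  The register stock sample (Bestand) and the death sample
(Wegfall) cannot be linked at the individual level, so nothing downstream of
sampling ever operates on individual records — the :class:`CountTable` is the
only interface between stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

ROLES = ("stock", "exposure", "deaths")
SUBPOPS = ("DP", "nonDP", "total")
REGIONS = ("East", "West")

#: Five-year groups spanning working ages 30-59, half-open [30,35) ... [55,60).
AGE_GROUPS = ("30-34", "35-39", "40-44", "45-49", "50-54", "55-59")

CELL_KEY = ["year", "region", "age_group", "subpop"]

#: Relative tolerance for the DP + nonDP = total additivity check.
ADDITIVITY_RTOL = 1e-6


def parse_age_group(label: str) -> tuple[int, int]:
    """Parse a ``"30-34"`` style label into a half-open interval ``(30, 35)``."""
    try:
        lo_s, hi_s = label.split("-")
        lo, hi = int(lo_s), int(hi_s)
    except (ValueError, AttributeError) as exc:
        raise ValidationError(f"unparseable age-group label: {label!r}") from exc
    if hi < lo:
        raise ValidationError(f"inverted age-group label: {label!r}")
    return lo, hi + 1


def validate_age_groups(groups: tuple[str, ...], span: tuple[int, int] = (30, 60)) -> None:
    """Check that ``groups`` are ordered, disjoint, contiguous and span ``span``."""
    if not groups:
        raise ValidationError("no age groups configured")
    intervals = [parse_age_group(g) for g in groups]
    lo, hi = span
    if intervals[0][0] != lo or intervals[-1][1] != hi:
        raise ValidationError(
            f"age groups must span [{lo},{hi}), got [{intervals[0][0]},{intervals[-1][1]})"
        )
    for (_, prev_hi), (nxt_lo, _) in zip(intervals, intervals[1:]):
        if nxt_lo != prev_hi:
            raise ValidationError(
                f"age groups must be contiguous and disjoint; gap/overlap at age {nxt_lo}"
            )


def check_contiguous_years(years: np.ndarray, context: str = "") -> None:
    """Raise if the sorted year vector has gaps, naming the first missing year."""
    years = np.sort(np.asarray(years))
    gaps = np.flatnonzero(np.diff(years) != 1)
    if gaps.size:
        missing = int(years[gaps[0]]) + 1
        where = f" in {context}" if context else ""
        raise ValidationError(f"year coverage has a gap{where}: missing year {missing}")


@dataclass
class CountTable:
    """Counts per (year, region, age group, subpopulation) with a role tag.

    Parameters
    ----------
    role:
        One of ``stock`` (year-end population), ``exposure`` (mid-year
        person-years) or ``deaths``.
    data:
        Long-format frame with columns ``year, region, age_group, subpop,
        count``.  Counts are non-negative reals; in stochastic scenarios they
        are integers by construction.
    """

    role: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown table role {self.role!r}; expected one of {ROLES}")
        missing = [c for c in CELL_KEY + ["count"] if c not in self.data.columns]
        if missing:
            raise ValidationError(f"count table missing columns: {missing}")
        df = self.data.loc[:, CELL_KEY + ["count"]].copy()
        df["year"] = df["year"].astype(int)
        df["count"] = df["count"].astype(float)
        df = df.sort_values(CELL_KEY, kind="mergesort").reset_index(drop=True)
        if df.duplicated(CELL_KEY).any():
            dupes = df.loc[df.duplicated(CELL_KEY), CELL_KEY].iloc[0].tolist()
            raise ValidationError(f"duplicate cell in count table: {tuple(dupes)}")
        if (df["count"] < 0).any():
            bad = df.loc[df["count"] < 0, CELL_KEY].iloc[0].tolist()
            raise ValidationError(f"negative count at cell {tuple(bad)}")
        unknown = set(df["subpop"]) - set(SUBPOPS)
        if unknown:
            raise ValidationError(f"unknown subpopulation labels: {sorted(unknown)}")
        self.data = df
        self._check_additivity()

    def _check_additivity(self) -> None:
        wide = self.data.pivot_table(
            index=["year", "region", "age_group"], columns="subpop", values="count"
        )
        if not all(s in wide.columns for s in SUBPOPS):
            return
        full = wide.dropna()
        resid = (full["DP"] + full["nonDP"] - full["total"]).abs()
        tol = ADDITIVITY_RTOL * full["total"].clip(lower=1.0)
        if (resid > tol).any():
            cell = resid[resid > tol].index[0]
            raise ValidationError(f"DP + nonDP != total at cell {cell} in {self.role} table")

    # -- access helpers -------------------------------------------------

    def subset(self, subpop: str) -> "CountTable":
        """Rows for one subpopulation, as a new table of the same role."""
        return CountTable(self.role, self.data[self.data["subpop"] == subpop])

    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def wide(self) -> pd.DataFrame:
        """Pivot to (region, age_group, subpop) rows x year columns."""
        return self.data.pivot_table(
            index=["region", "age_group", "subpop"], columns="year", values="count"
        )

    def total(self) -> float:
        return float(self.data["count"].sum())

    def indexed(self) -> pd.Series:
        """Counts as a Series indexed by the full cell key."""
        return self.data.set_index(CELL_KEY)["count"].sort_index()

    def reindex_grid(
        self,
        years: np.ndarray | list[int],
        regions=REGIONS,
        age_groups=AGE_GROUPS,
        subpops=("DP",),
    ) -> "CountTable":
        """Complete the table on a full cell grid, filling absent cells with 0.

        Sampled tables legitimately omit cells in which no record was drawn;
        the zero is the correct (weighted) estimate there.
        """
        grid = pd.MultiIndex.from_product(
            [list(map(int, years)), list(regions), list(age_groups), list(subpops)],
            names=CELL_KEY,
        )
        ser = self.indexed().reindex(grid, fill_value=0.0)
        return CountTable(self.role, ser.reset_index())

    # -- CSV round trip --------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the schema ``year,region,age_group,subpop,role,count``."""
        out = self.data.copy()
        out.insert(4, "role", self.role)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        df = pd.read_csv(path)
        if "role" not in df.columns:
            raise ValidationError(f"count-table CSV {path} lacks a 'role' column")
        roles = df["role"].unique()
        if len(roles) != 1:
            raise ValidationError(f"count-table CSV {path} mixes roles {sorted(roles)}")
        return cls(str(roles[0]), df.drop(columns="role"))

    @classmethod
    def from_cells(cls, role: str, cells: dict, subpop: str = "DP") -> "CountTable":
        """Build a table from ``{(year, region, age_group): count}``."""
        rows = [
            {"year": y, "region": r, "age_group": a, "subpop": subpop, "count": c}
            for (y, r, a), c in cells.items()
        ]
        return cls(role, pd.DataFrame(rows, columns=CELL_KEY + ["count"]))


def concat_tables(*tables: CountTable) -> CountTable:
    """Concatenate same-role tables (e.g. DP, nonDP and total subpops)."""
    roles = {t.role for t in tables}
    if len(roles) != 1:
        raise ValidationError(f"cannot concatenate tables of different roles: {sorted(roles)}")
    return CountTable(roles.pop(), pd.concat([t.data for t in tables], ignore_index=True))
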