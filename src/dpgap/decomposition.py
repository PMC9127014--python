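"""Stepwise-replacement decomposition of a standardized-rate difference.

Within each age group the overall death rate is the mixture

    m_a = pi_a * m_a^DP + (1 - pi_a) * m_a^ND,

so the SDR difference between two regions can be attributed to three kinds of
elements: non-DP mortality (``m^ND``), DP mortality (``m^DP``) and DP
prevalence (``pi``, the compositional element).  The stepwise replacement
algorithm swaps elements one at a time from one region's values to the
other's and credits each element with the change in the aggregate measure at
its replacement step; contributions telescope to the total difference
exactly.  Because a single replacement order is arbitrary, per-age
contributions here are the average over all 3! within-age orders — the
Shapley value of the three elements — which is symmetric, order-free, and
still exactly additive.  The SDR is additively separable over age groups, so
the order in which ages are visited cannot matter (a property the tests
assert with the generic engine).

For the mixture above the order-averaged contributions have a closed form
(midpoint rule; a bar denotes the East/West midpoint):

    delta_pi = c_a * (pi_E - pi_W) * (mbar^DP - mbar^ND)
    delta_DP = c_a * (m_E^DP - m_W^DP) * pibar
    delta_ND = c_a * (m_E^ND - m_W^ND) * (1 - pibar)

``decompose_cell`` implements this closed form; :func:`shapley_oracle`
averages explicit stepwise runs over all permutations and serves as the
independent cross-check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvariantError, ValidationError
from .rates import RateTable, StandardPopulation
from .tables import AGE_GROUPS

logger = logging.getLogger(__name__)

#: Relative tolerance of the exact-additivity contract.
ADDITIVITY_RTOL = 1e-9

COMPONENT_COLUMNS = ["year", "comp_mort_nondp", "comp_mort_dp",
                     "comp_prevalence", "total_difference"]


@dataclass
class ParamSet:
    """Per-region-year parameters: (pi_a, m_a^DP, m_a^ND) for each age group.

    Rates are per 100,000 person-years; ``pi`` is a fraction in [0, 1].
    """

    region: str
    year: int
    params: pd.DataFrame = field(repr=False)  # index age_group; columns pi, m_dp, m_nd

    def __post_init__(self) -> None:
        need = {"pi", "m_dp", "m_nd"}
        if not need.issubset(self.params.columns):
            raise ValidationError(f"ParamSet needs columns {sorted(need)}")
        p = self.params[["pi", "m_dp", "m_nd"]].astype(float)
        if ((p["pi"] < 0) | (p["pi"] > 1)).any():
            raise ValidationError(f"prevalence outside [0, 1] in ParamSet {self.region}/{self.year}")
        if (p[["m_dp", "m_nd"]] < 0).to_numpy().any():
            raise ValidationError(f"negative rate in ParamSet {self.region}/{self.year}")
        self.params = p

    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(self.params.index)

    @classmethod
    def from_tables(
        cls,
        prevalence: pd.DataFrame,
        rates: RateTable,
        region: str,
        year: int,
        age_groups: Sequence[str] = AGE_GROUPS,
    ) -> "ParamSet":
        """Assemble a ParamSet from pipeline prevalence and rate tables."""
        pi = prevalence.query("region == @region and year == @year").set_index("age_group")["pi"]
        sub = rates.data.query("region == @region and year == @year")
        m_dp = sub[sub["subpop"] == "DP"].set_index("age_group")["rate"]
        m_nd = sub[sub["subpop"] == "nonDP"].set_index("age_group")["rate"]
        frame = pd.DataFrame({"pi": pi, "m_dp": m_dp, "m_nd": m_nd}).reindex(list(age_groups))
        if frame.isna().to_numpy().any():
            missing = frame[frame.isna().any(axis=1)].index.tolist()
            raise ValidationError(
                f"incomplete parameters for {region}/{year}: missing {missing}")
        return cls(region=region, year=year, params=frame)


def overall_rate(p: ParamSet, age_group: str) -> float:
    """Mixture death rate pi*m^DP + (1-pi)*m^ND at one age group (per 100,000)."""
    try:
        row = p.params.loc[age_group]
    except KeyError as exc:
        raise ValidationError(f"age group {age_group!r} not in ParamSet") from exc
    return float(row["pi"] * row["m_dp"] + (1.0 - row["pi"]) * row["m_nd"])


def stepwise_replacement(
    functional: Callable[[np.ndarray], float],
    theta_from: Sequence[float],
    theta_to: Sequence[float],
    order: Sequence[int] | None = None,
) -> np.ndarray:
    """Single-order stepwise replacement contributions.

    Elements of ``theta_from`` are replaced by ``theta_to`` one at a time in
    ``order`` (default: positional order); element ``i``'s contribution is the
    change in the functional at its replacement step.  Contributions telescope
    to ``functional(theta_to) - functional(theta_from)`` exactly.
    """
    a = np.asarray(theta_from, dtype=float)
    b = np.asarray(theta_to, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("theta_from and theta_to must be 1-d vectors of equal length")
    n = a.size
    if order is None:
        order = np.arange(n)
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(n)):
        raise ValidationError(f"order {order.tolist()} is not a permutation of 0..{n - 1}")
    contrib = np.zeros(n)
    current = a.copy()
    prev = functional(current)
    for i in order:
        current[i] = b[i]
        nxt = functional(current)
        contrib[i] = nxt - prev
        prev = nxt
    return contrib


def shapley_oracle(
    functional: Callable[[np.ndarray], float],
    theta_from: Sequence[float],
    theta_to: Sequence[float],
) -> np.ndarray:
    """Order-averaged stepwise replacement via exhaustive permutation.

    Brute force over all ``n!`` replacement orders (guarded to n <= 8);
    the mean contribution of each element is its Shapley value, and the
    contributions sum to the total difference exactly.
    """
    a = np.asarray(theta_from, dtype=float)
    n = a.size
    if n > 8:
        raise ValidationError(f"shapley_oracle is exhaustive; refusing n = {n} > 8 elements")
    total = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        total += stepwise_replacement(functional, theta_from, theta_to, order)
        count += 1
    return total / count


def decompose_cell(
    west: ParamSet,
    east: ParamSet,
    age_group: str,
    weight: float,
) -> tuple[float, float, float]:
    """Order-averaged contributions (delta_ND, delta_DP, delta_pi) at one age.

    The three elements (pi, m^DP, m^ND) are replaced from West to East inside
    ``weight * overall_rate``; contributions are the exhaustive order average
    (Shapley value), evaluated in closed form, and sum exactly to
    ``weight * (rate_East - rate_West)``.
    """
    w = west.params.loc[age_group]
    e = east.params.loc[age_group]
    pi_bar = 0.5 * (w["pi"] + e["pi"])
    mdp_bar = 0.5 * (w["m_dp"] + e["m_dp"])
    mnd_bar = 0.5 * (w["m_nd"] + e["m_nd"])
    d_nd = weight * (e["m_nd"] - w["m_nd"]) * (1.0 - pi_bar)
    d_dp = weight * (e["m_dp"] - w["m_dp"]) * pi_bar
    d_pi = weight * (e["pi"] - w["pi"]) * (mdp_bar - mnd_bar)
    return float(d_nd), float(d_dp), float(d_pi)


@dataclass
class DecompositionResult:
    """Components of one year's SDR difference (per 100,000).

    ``total`` is the signed SDR difference being decomposed; under the
    reporting convention used in the pipeline (West minus East) negative
    values indicate the advantage of West over East.  The components satisfy
    ``comp_mort_nondp + comp_mort_dp + comp_prevalence = total`` to 1e-9
    relative tolerance.
    """

    year: int
    comp_mort_nondp: float
    comp_mort_dp: float
    comp_prevalence: float
    total: float
    per_age: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        resid = abs(self.comp_mort_nondp + self.comp_mort_dp + self.comp_prevalence - self.total)
        if resid > ADDITIVITY_RTOL * max(1.0, abs(self.total)):
            raise InvariantError(
                f"components do not sum to the total difference in year {self.year}: "
                f"residual {resid:.3e}")

    def components(self) -> tuple[float, float, float]:
        return (self.comp_mort_nondp, self.comp_mort_dp, self.comp_prevalence)

    def negated(self) -> "DecompositionResult":
        """Flip the direction of comparison (exact antisymmetry)."""
        return replace(
            self,
            comp_mort_nondp=-self.comp_mort_nondp,
            comp_mort_dp=-self.comp_mort_dp,
            comp_prevalence=-self.comp_prevalence,
            total=-self.total,
            per_age=None if self.per_age is None else self.per_age.assign(
                **{c: -self.per_age[c] for c in self.per_age.columns if c != "age_group"}),
        )


def decompose_year(
    west: ParamSet,
    east: ParamSet,
    standard: StandardPopulation,
) -> DecompositionResult:
    """Decompose the East-minus-West SDR difference for one year.

    Components are sums of per-age order-averaged contributions; the total is
    ``SDR_East - SDR_West`` computed independently from the mixture rates, and
    the additivity contract is verified before returning.  Cross-age
    replacement order is irrelevant because the SDR is additively separable
    over age groups.
    """
    weights = standard.normalized()
    for ps, name in ((west, "west"), (east, "east")):
        missing = [a for a in weights if a not in ps.age_groups]
        if missing:
            raise ValidationError(f"{name} ParamSet misses age group(s) {missing}")
    rows = []
    c_nd = c_dp = c_pi = 0.0
    sdr_e = sdr_w = 0.0
    for a, c_a in weights.items():
        d_nd, d_dp, d_pi = decompose_cell(west, east, a, c_a)
        c_nd += d_nd
        c_dp += d_dp
        c_pi += d_pi
        sdr_e += c_a * overall_rate(east, a)
        sdr_w += c_a * overall_rate(west, a)
        rows.append({"age_group": a, "comp_mort_nondp": d_nd,
                     "comp_mort_dp": d_dp, "comp_prevalence": d_pi,
                     "total_difference": d_nd + d_dp + d_pi})
    if west.year != east.year:
        raise ValidationError(f"year mismatch: west {west.year} vs east {east.year}")
    return DecompositionResult(
        year=west.year,
        comp_mort_nondp=c_nd,
        comp_mort_dp=c_dp,
        comp_prevalence=c_pi,
        total=sdr_e - sdr_w,
        per_age=pd.DataFrame(rows),
    )


def component_shares(result: DecompositionResult) -> tuple[float, float, float]:
    """Each component as a percentage of the total difference, one decimal.

    Undefined (rejected) when the total difference is zero.  The three shares
    sum to 100 up to rounding.
    """
    if result.total == 0:
        raise ValidationError(f"component shares undefined: zero total difference "
                              f"in year {result.year}")
    return tuple(round(100.0 * c / result.total, 1) for c in result.components())


def aggregate_result(results: Sequence[DecompositionResult]) -> DecompositionResult:
    """Period total: components and differences summed over years.

    Mirrors 'all years combined' reporting; the summed components inherit
    exact additivity.  The ``year`` of the aggregate is the first year.
    """
    if not results:
        raise ValidationError("cannot aggregate an empty result collection")
    return DecompositionResult(
        year=min(r.year for r in results),
        comp_mort_nondp=sum(r.comp_mort_nondp for r in results),
        comp_mort_dp=sum(r.comp_mort_dp for r in results),
        comp_prevalence=sum(r.comp_prevalence for r in results),
        total=sum(r.total for r in results),
    )


def results_frame(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    """Long table of results in the canonical CSV column order."""
    return pd.DataFrame(
        [
            {
                "year": r.year,
                "comp_mort_nondp": r.comp_mort_nondp,
                "comp_mort_dp": r.comp_mort_dp,
                "comp_prevalence": r.comp_prevalence,
                "total_difference": r.total,
            }
            for r in results
        ],
        columns=COMPONENT_COLUMNS,
    )
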