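"""Stepwise replacement, the Shapley oracle, and the three-way decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpgap import (
    DecompositionResult,
    ParamSet,
    StandardPopulation,
    aggregate_result,
    component_shares,
    decompose_cell,
    decompose_year,
    default_standard,
    overall_rate,
    shapley_oracle,
    stepwise_replacement,
)
from dpgap.errors import InvariantError, ValidationError
from dpgap.tables import AGE_GROUPS


def make_paramset(region, year, pi, m_dp, m_nd, age_groups=AGE_GROUPS):
    pi = np.broadcast_to(pi, (len(age_groups),))
    m_dp = np.broadcast_to(m_dp, (len(age_groups),))
    m_nd = np.broadcast_to(m_nd, (len(age_groups),))
    return ParamSet(region, year, pd.DataFrame(
        {"pi": pi, "m_dp": m_dp, "m_nd": m_nd}, index=list(age_groups)))


def random_paramset(rng, region="East", year=2000):
    return make_paramset(
        region, year,
        pi=rng.uniform(0, 1, len(AGE_GROUPS)),
        m_dp=rng.uniform(0, 5000, len(AGE_GROUPS)),
        m_nd=rng.uniform(0, 1000, len(AGE_GROUPS)),
    )


class TestOverallRate:
    def test_degenerate_mixtures(self):
        p = make_paramset("East", 2000, 0.0, 2000.0, 200.0)
        assert overall_rate(p, "30-34") == pytest.approx(200.0)
        p = make_paramset("East", 2000, 1.0, 2000.0, 200.0)
        assert overall_rate(p, "30-34") == pytest.approx(2000.0)

    def test_hand_mixture(self):
        p = make_paramset("East", 2000, 0.05, 2000.0, 200.0)
        assert overall_rate(p, "30-34") == pytest.approx(290.0)


class TestStepwiseReplacement:
    def quad(self, theta):
        # A functional with pairwise interactions: telescoping must still hold.
        return float(theta @ self.w + theta @ self.q @ theta)

    def setup_method(self, method):
        rng = np.random.default_rng(11)
        self.w = rng.normal(size=5)
        self.q = rng.normal(size=(5, 5))

    def test_identical_vectors_zero(self):
        theta = np.arange(5.0)
        contrib = stepwise_replacement(self.quad, theta, theta)
        assert np.allclose(contrib, 0.0)

    def test_telescoping_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.normal(size=5), rng.normal(size=5)
            order = rng.permutation(5)
            contrib = stepwise_replacement(self.quad, a, b, order)
            assert np.isclose(contrib.sum(), self.quad(b) - self.quad(a), atol=1e-9)

    def test_linear_functional_order_free(self):
        # For sum(w_i * theta_i), element i always contributes w_i * delta_i.
        w = np.array([2.0, -3.0, 0.5, 4.0])
        lin = lambda t: float(t @ w)
        a, b = np.zeros(4), np.array([1.0, 2.0, 3.0, 4.0])
        import itertools
        for order in itertools.permutations(range(4)):
            contrib = stepwise_replacement(lin, a, b, order)
            assert np.allclose(contrib, w * (b - a))

    def test_bad_order_rejected(self):
        with pytest.raises(ValidationError, match="permutation"):
            stepwise_replacement(self.quad, np.zeros(5), np.ones(5), [0, 0, 1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            stepwise_replacement(self.quad, np.zeros(4), np.ones(5))


class TestShapleyOracle:
    def test_equal_vectors_zero(self):
        f = lambda t: float(np.prod(t))
        assert np.allclose(shapley_oracle(f, np.ones(3), np.ones(3)), 0.0)

    def test_length_two_is_average_of_both_orders(self):
        f = lambda t: float(t[0] * t[1])
        a, b = np.array([1.0, 2.0]), np.array([3.0, 5.0])
        o1 = stepwise_replacement(f, a, b, [0, 1])
        o2 = stepwise_replacement(f, a, b, [1, 0])
        assert np.allclose(shapley_oracle(f, a, b), (o1 + o2) / 2)

    def test_exhaustive_guard(self):
        f = lambda t: float(t.sum())
        with pytest.raises(ValidationError, match="refusing"):
            shapley_oracle(f, np.zeros(9), np.ones(9))


def cell_oracle(west, east, age_group, weight):
    """Exhaustive-permutation reference for decompose_cell."""
    w = west.params.loc[age_group]
    e = east.params.loc[age_group]
    f = lambda t: weight * (t[0] * t[1] + (1 - t[0]) * t[2])  # (pi, m_dp, m_nd)
    contrib = shapley_oracle(
        f,
        np.array([w["pi"], w["m_dp"], w["m_nd"]]),
        np.array([e["pi"], e["m_dp"], e["m_nd"]]),
    )
    return contrib[2], contrib[1], contrib[0]  # (d_nd, d_dp, d_pi)


class TestDecomposeCell:
    def test_identical_regions_zero(self):
        p = make_paramset("West", 2000, 0.04, 1800.0, 250.0)
        q = make_paramset("East", 2000, 0.04, 1800.0, 250.0)
        assert decompose_cell(p, q, "30-34", 0.2) == pytest.approx((0.0, 0.0, 0.0))

    def test_prevalence_only_difference(self):
        # Shared rates: delta_pi = c*(pi_E - pi_W)*(m_DP - m_ND), others zero.
        west = make_paramset("West", 2000, 0.03, 2000.0, 200.0)
        east = make_paramset("East", 2000, 0.05, 2000.0, 200.0)
        d_nd, d_dp, d_pi = decompose_cell(west, east, "30-34", 0.5)
        assert d_nd == 0.0 and d_dp == 0.0
        assert d_pi == pytest.approx(0.5 * 0.02 * 1800.0)
        assert np.allclose((d_nd, d_dp, d_pi), cell_oracle(west, east, "30-34", 0.5))

    def test_nondp_mortality_only_difference(self):
        # Shared pi: delta_ND = c*(1 - pi)*(m_E^ND - m_W^ND), others zero.
        west = make_paramset("West", 2000, 0.04, 2000.0, 200.0)
        east = make_paramset("East", 2000, 0.04, 2000.0, 260.0)
        d_nd, d_dp, d_pi = decompose_cell(west, east, "30-34", 1.0)
        assert d_dp == 0.0 and d_pi == 0.0
        assert d_nd == pytest.approx(0.96 * 60.0)
        assert np.allclose((d_nd, d_dp, d_pi), cell_oracle(west, east, "30-34", 1.0))

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            west = random_paramset(rng, "West")
            east = random_paramset(rng, "East")
            a = AGE_GROUPS[rng.integers(len(AGE_GROUPS))]
            c = rng.uniform(0, 1)
            got = decompose_cell(west, east, a, c)
            want = cell_oracle(west, east, a, c)
            assert np.allclose(got, want, atol=1e-10)


class TestDecomposeYear:
    def test_identical_regions_all_zero(self):
        p = make_paramset("West", 2000, 0.04, 1800.0, 250.0)
        q = make_paramset("East", 2000, 0.04, 1800.0, 250.0)
        res = decompose_year(p, q, default_standard())
        assert res.components() == pytest.approx((0.0, 0.0, 0.0))
        assert res.total == pytest.approx(0.0)

    def test_prevalence_only_scenario_attributes_all_to_composition(self):
        west = make_paramset("West", 2000, 0.03, 2000.0, 200.0)
        east = make_paramset("East", 2000, 0.05, 2000.0, 200.0)
        res = decompose_year(west, east, default_standard())
        assert res.comp_mort_nondp == 0.0 and res.comp_mort_dp == 0.0
        assert res.comp_prevalence == pytest.approx(res.total)
        assert res.total == pytest.approx(0.02 * 1800.0)

    def test_components_equal_summed_cell_oracle(self):
        rng = np.random.default_rng(3)
        std = default_standard()
        weights = std.normalized()
        west = random_paramset(rng, "West")
        east = random_paramset(rng, "East")
        res = decompose_year(west, east, std)
        want = np.zeros(3)
        for a, c in weights.items():
            want += np.array(cell_oracle(west, east, a, c))
        assert np.allclose(res.components(), want, atol=1e-9)

    def test_cross_age_order_irrelevant(self):
        # Generic 18-element engine: interleave age blocks in random cross-age
        # orders (within-age sub-order fixed); per-age contribution sums match.
        rng = np.random.default_rng(4)
        std = default_standard()
        weights = std.normalized()
        west = random_paramset(rng, "West")
        east = random_paramset(rng, "East")
        wvec = np.concatenate([west.params.loc[a].to_numpy() for a in AGE_GROUPS])
        evec = np.concatenate([east.params.loc[a].to_numpy() for a in AGE_GROUPS])
        c = np.array([weights[a] for a in AGE_GROUPS])

        def sdr(theta):
            t = theta.reshape(len(AGE_GROUPS), 3)
            return float(np.sum(c * (t[:, 0] * t[:, 1] + (1 - t[:, 0]) * t[:, 2])))

        base = stepwise_replacement(sdr, wvec, evec).reshape(-1, 3).sum(axis=1)
        for _ in range(100):
            # random interleaving of blocks, preserving within-block order
            pool = [list(range(3 * i, 3 * i + 3)) for i in range(len(AGE_GROUPS))]
            order = []
            while pool:
                k = rng.integers(len(pool))
                order.append(pool[k].pop(0))
                if not pool[k]:
                    pool.pop(k)
            per_age = stepwise_replacement(sdr, wvec, evec, order).reshape(-1, 3).sum(axis=1)
            assert np.allclose(per_age, base, atol=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        # Swapping East and West negates every component exactly.
        rng = np.random.default_rng(seed)
        west = random_paramset(rng, "West")
        east = random_paramset(rng, "East")
        fwd = decompose_year(west, east, default_standard())
        rev = decompose_year(east, west, default_standard())
        assert np.allclose(fwd.components(), -np.asarray(rev.components()), atol=1e-9)
        assert fwd.total == pytest.approx(-rev.total)

    def test_year_mismatch_rejected(self):
        west = make_paramset("West", 2000, 0.03, 2000.0, 200.0)
        east = make_paramset("East", 2001, 0.05, 2000.0, 200.0)
        with pytest.raises(ValidationError, match="year"):
            decompose_year(west, east, default_standard())

    def test_missing_age_group_rejected(self):
        west = make_paramset("West", 2000, 0.03, 2000.0, 200.0, age_groups=AGE_GROUPS[:3])
        east = make_paramset("East", 2000, 0.05, 2000.0, 200.0)
        with pytest.raises(ValidationError, match="miss"):
            decompose_year(west, east, default_standard())


class TestComponentShares:
    def test_published_1995_shares(self):
        res = DecompositionResult(1995, -84.3, -21.4, -45.9, -151.6)
        assert component_shares(res) == (55.6, 14.1, 30.3)

    def test_published_2013_shares(self):
        res = DecompositionResult(2013, -28.6, -13.0, -45.5, -87.1)
        assert component_shares(res) == (32.8, 14.9, 52.2)

    def test_single_component_is_100_percent(self):
        res = DecompositionResult(2000, -50.0, 0.0, 0.0, -50.0)
        assert component_shares(res) == (100.0, 0.0, 0.0)

    def test_zero_total_rejected(self):
        res = DecompositionResult(2000, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValidationError, match="zero total"):
            component_shares(res)


class TestDecompositionResult:
    def test_additivity_enforced_on_construction(self):
        with pytest.raises(InvariantError, match="sum"):
            DecompositionResult(2000, -10.0, -10.0, -10.0, -40.0)

    def test_negation_is_exact(self):
        res = DecompositionResult(2000, -10.0, -20.0, -30.0, -60.0)
        neg = res.negated()
        assert neg.components() == (10.0, 20.0, 30.0)
        assert neg.total == 60.0

    def test_aggregate_sums_years(self):
        r1 = DecompositionResult(2000, -10.0, -20.0, -30.0, -60.0)
        r2 = DecompositionResult(2001, -5.0, -10.0, -15.0, -30.0)
        agg = aggregate_result([r1, r2])
        assert agg.components() == pytest.approx((-15.0, -30.0, -45.0))
        assert agg.total == pytest.approx(-90.0)
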