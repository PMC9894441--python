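"""Trend-test statistics against brute-force and permutation oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from jttrend import (
    ADDITIVE_SCORES,
    DegenerateTableError,
    GeneticModelSpec,
    GenotypeTable,
    ScoreVector,
    ca_trend_test,
    cell_probabilities,
    chisq1_upper_tail,
    jt_null_moments,
    jt_trend_test,
    jt_u_statistic,
)
from jttrend.power_sim import SimulationConfig, empirical_power
from jttrend.trend_tests import ca_statistic_many, jt_statistic_many

from conftest import random_integer_tables
from oracles import u_brute_force, u_permutation_moments


def ca_brute_force(table: GenotypeTable, x: tuple[float, float, float]) -> float:
    r, s = np.asarray(table.r, float), np.asarray(table.s, float)
    n = r + s
    x = np.asarray(x, float)
    R, S, N = r.sum(), s.sum(), r.sum() + s.sum()
    return N * (N * (r @ x) - R * (n @ x)) ** 2 / (R * S * (N * (n @ x**2) - (n @ x) ** 2))


# -- Cochran-Armitage ------------------------------------------------------

class TestCATrendTest:
    def test_worked_example(self, rs2398162):
        res = ca_trend_test(rs2398162, ADDITIVE_SCORES)
        assert res.statistic == pytest.approx(19.97, abs=0.005)
        assert res.p_value == pytest.approx(7.9e-6, rel=0.02)
        assert res.df == 1

    def test_proportional_table_gives_zero(self):
        # r_i = c * n_i for constant c: no trend
        res = ca_trend_test(GenotypeTable((10, 20, 5), (20, 40, 10)))
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == 1.0

    def test_affine_score_invariance(self):
        for t in random_integer_tables(20, 40, seed=11):
            t1 = ca_trend_test(t, ScoreVector((0, 0.5, 1))).statistic
            t2 = ca_trend_test(t, ScoreVector((0, 1, 2))).statistic
            t3 = ca_trend_test(t, ScoreVector((3, 4, 5))).statistic
            assert t1 == pytest.approx(t2, rel=1e-10, abs=1e-12)
            assert t1 == pytest.approx(t3, rel=1e-10, abs=1e-12)

    def test_matches_direct_formula(self):
        for t in random_integer_tables(20, 40, seed=13):
            got = ca_trend_test(t).statistic
            assert got == pytest.approx(ca_brute_force(t, (0, 0.5, 1)), rel=1e-12, abs=1e-12)

    def test_degenerate_conditions(self):
        with pytest.raises(DegenerateTableError, match="cases and controls"):
            ca_trend_test(GenotypeTable((1, 2, 3), (0, 0, 0)))
        with pytest.raises(DegenerateTableError, match="score variance"):
            # all mass on the middle score
            ca_trend_test(GenotypeTable((0, 5, 0), (0, 5, 0)))

    def test_accepts_fractional_tables(self):
        t = GenotypeTable((10.5, 20.25, 5.5), (22.5, 38.0, 11.0))
        assert ca_trend_test(t).statistic >= 0


# -- Jonckheere-Terpstra ---------------------------------------------------

class TestJTUStatistic:
    def test_hand_worked_small_table(self):
        # pairs (0,1): 0 + .5*(0+1); (0,2): 1 + .5*(1+0); (1,2): 1 + .5*0
        t = GenotypeTable((1, 0, 1), (1, 1, 0))
        assert jt_u_statistic(t) == pytest.approx(3.0)
        assert u_brute_force(t) == pytest.approx(3.0)

    def test_closed_form_equals_triple_sum(self):
        for t in random_integer_tables(25, 10, seed=17):  # N <= 30 regime
            assert jt_u_statistic(t) == pytest.approx(u_brute_force(t), abs=1e-9)

    def test_proportional_table_u_equals_null_mean(self):
        t = GenotypeTable((10, 20, 5), (10, 20, 5))
        m = jt_null_moments(t)
        assert m.U == pytest.approx(m.EU)


class TestJTNullMoments:
    def test_mean_identity_two_ways(self):
        for t in random_integer_tables(20, 30, seed=19):
            m = jt_null_moments(t)
            n = t.n
            pairwise = sum(n[i] * n[j] for i in range(3) for j in range(i + 1, 3)) / 2.0
            assert m.EU == pytest.approx(pairwise, rel=1e-12)

    def test_exhaustive_permutation_oracle_n8(self):
        t = GenotypeTable((2, 1, 1), (1, 2, 1))
        m = jt_null_moments(t)
        mean, var = u_permutation_moments(t)
        assert m.EU == pytest.approx(mean, abs=1e-9)
        assert m.VarU == pytest.approx(var, abs=1e-9)

    def test_permutation_oracle_random_tables(self):
        for t in random_integer_tables(15, 4, seed=23):
            m = jt_null_moments(t)
            mean, var = u_permutation_moments(t)
            assert m.EU == pytest.approx(mean, abs=1e-9)
            assert m.VarU == pytest.approx(var, abs=1e-9, rel=1e-9)

    def test_degenerate_single_group(self):
        with pytest.raises(DegenerateTableError):
            jt_null_moments(GenotypeTable((5, 0, 0), (5, 0, 0)))

    def test_too_small(self):
        with pytest.raises(DegenerateTableError, match="N >= 3"):
            jt_null_moments(GenotypeTable((1, 0, 0), (0, 1, 0)))


class TestJTTrendTest:
    def test_worked_example(self, rs2398162):
        res = jt_trend_test(rs2398162)
        assert res.statistic == pytest.approx(22.82, abs=0.005)
        assert res.p_value == pytest.approx(1.8e-6, rel=0.02)

    def test_proportional_table(self):
        res = jt_trend_test(GenotypeTable((10, 20, 5), (10, 20, 5)))
        assert res.statistic == pytest.approx(0.0, abs=1e-18)
        assert res.p_value == 1.0

    def test_null_distribution_is_chisq1(self):
        """Simulated null statistics match chi2(1) by a KS goodness-of-fit check."""
        spec = GeneticModelSpec(K=0.1, q=0.2, lam=0.0, theta=math.pi / 4)
        probs = cell_probabilities(spec)
        rng = np.random.default_rng(2024)
        r = rng.multinomial(250, probs.tau, size=200)
        s = rng.multinomial(250, probs.upsilon, size=200)
        stats_jt = jt_statistic_many(r, s)
        assert not np.isnan(stats_jt).any()
        ks = stats.kstest(stats_jt, stats.chi2(df=1).cdf)
        assert ks.pvalue > 0.01


cell_counts = st.lists(st.integers(0, 60), min_size=6, max_size=6).filter(
    lambda c: sum(c) >= 3
    and sum(c[:3]) >= 1
    and sum(c[3:]) >= 1
    and sum(1 for a, b in zip(c[:3], c[3:]) if a + b > 0) >= 2
)


class TestSymmetries:
    @settings(derandomize=True, max_examples=60)
    @given(cells=cell_counts)
    def test_symmetries_hold_for_arbitrary_tables(self, cells):
        """Row swap and column reversal leave both squared statistics fixed,
        and U + U(swapped rows) exhausts the pair count 2 * E(U)."""
        t = GenotypeTable(tuple(cells[:3]), tuple(cells[3:]))
        m = jt_null_moments(t)
        m_swap = jt_null_moments(t.swapped_rows())
        assert m.U + m_swap.U == pytest.approx(2 * m.EU, rel=1e-12)
        assert jt_trend_test(t.swapped_rows()).statistic == pytest.approx(
            jt_trend_test(t).statistic, rel=1e-9, abs=1e-12
        )
        assert ca_trend_test(t.reversed_columns()).statistic == pytest.approx(
            ca_trend_test(t).statistic, rel=1e-9, abs=1e-12
        )

    def test_label_swap_and_column_reversal(self):
        for t in random_integer_tables(15, 30, seed=29):
            ca0 = ca_trend_test(t).statistic
            jt0 = jt_trend_test(t).statistic
            for variant in (t.swapped_rows(), t.reversed_columns()):
                assert ca_trend_test(variant).statistic == pytest.approx(ca0, rel=1e-10, abs=1e-12)
                assert jt_trend_test(variant).statistic == pytest.approx(jt0, rel=1e-10, abs=1e-12)

    def test_continuity_under_cell_perturbation(self):
        t = GenotypeTable((30, 20, 10), (20, 25, 15))
        base_ca = ca_trend_test(t).statistic
        base_jt = jt_trend_test(t).statistic
        eps = 1e-6
        t2 = GenotypeTable((30 + eps, 20, 10), (20, 25, 15))
        assert abs(ca_trend_test(t2).statistic - base_ca) < 1e-3
        assert abs(jt_trend_test(t2).statistic - base_jt) < 1e-3


class TestChisq1UpperTail:
    def test_reference_points(self):
        assert chisq1_upper_tail(0.0) == 1.0
        assert chisq1_upper_tail(3.841459) == pytest.approx(0.05, abs=1e-6)
        assert chisq1_upper_tail(19.97) == pytest.approx(7.9e-6, rel=0.02)

    def test_erfc_identity_and_monotonicity(self):
        xs = np.linspace(0, 30, 50)
        ps = np.array([chisq1_upper_tail(x) for x in xs])
        assert np.allclose(ps, [math.erfc(math.sqrt(x / 2)) for x in xs], rtol=1e-12)
        assert (np.diff(ps) <= 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chisq1_upper_tail(-0.1)


class TestVectorizedPaths:
    def test_match_scalar_implementations(self):
        tables = random_integer_tables(30, 40, seed=31)
        r = np.array([t.r for t in tables])
        s = np.array([t.s for t in tables])
        ca_vec = ca_statistic_many(r, s)
        jt_vec = jt_statistic_many(r, s)
        for k, t in enumerate(tables):
            assert ca_vec[k] == pytest.approx(ca_trend_test(t).statistic, rel=1e-12)
            assert jt_vec[k] == pytest.approx(jt_trend_test(t).statistic, rel=1e-12)

    def test_degenerate_rows_become_nan(self):
        r = np.array([[0, 5, 0], [3, 2, 1]])
        s = np.array([[0, 5, 0], [1, 2, 3]])
        assert np.isnan(ca_statistic_many(r, s)[0])
        assert np.isnan(jt_statistic_many(r, s)[0])
        assert np.isfinite(ca_statistic_many(r, s)[1])
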