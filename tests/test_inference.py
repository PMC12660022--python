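import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efrd import _tilt
from efrd.core import DataError
from efrd.inference import (exact_enumeration_pvalue, randomization_pvalue,
                            stratified_rank_statistic)

from conftest import make_comparison


class TestStatistic:
    def test_treated_rank_sum_single_stratum(self):
        assert stratified_rank_statistic(
            [1, 2, 3, 4], [0, 0, 1, 1], {0: np.arange(4)}) == 7.0

    def test_midranks_for_ties(self):
        assert stratified_rank_statistic(
            [1, 1, 2], [1, 0, 0], {0: np.arange(3)}) == 1.5

    def test_additive_across_strata(self):
        y = [1, 2, 3, 4, 1, 2, 3, 4]
        a = [0, 0, 1, 1] * 2
        strata = {0: np.arange(4), 1: np.arange(4, 8)}
        assert stratified_rank_statistic(y, a, strata) == 14.0

    def test_noninformative_stratum_contributes_zero(self):
        y = [1, 2, 3, 4, 5, 6]
        a = [0, 0, 1, 1, 1, 1]   # second stratum all treated
        strata = {0: np.arange(4), 1: np.arange(4, 6)}
        assert stratified_rank_statistic(y, a, strata) == 7.0

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            stratified_rank_statistic([], [], {})

    @given(st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=-5, max_value=5))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, scale, shift):
        y = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        a = [1, 0, 1, 0, 1, 0]
        strata = {0: np.arange(3), 1: np.arange(3, 6)}
        base = stratified_rank_statistic(y, a, strata)
        assert stratified_rank_statistic(scale * y + shift, a, strata) == base


class TestExactEnumeration:
    def test_top_two_of_four(self):
        comp = make_comparison([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 0, 0])
        res = exact_enumeration_pvalue(comp, np.array([1.0, 2, 3, 4]))
        assert res.p_value == pytest.approx(1 / 6)
        assert res.method == "exact"

    def test_two_strata_of_two(self):
        comp = make_comparison([1, 2, 1, 2], [0, 1, 0, 1], [0, 0, 1, 1])
        res = exact_enumeration_pvalue(comp, np.array([1.0, 2, 1, 2]))
        assert res.p_value == pytest.approx(1 / 4)

    def test_exact_p_is_ratio_of_integers(self):
        comp = make_comparison([5, 1, 4, 2, 3], [1, 0, 1, 0, 0],
                               [0, 0, 0, 0, 0])
        res = exact_enumeration_pvalue(comp, np.array([5.0, 1, 4, 2, 3]))
        total = res.n_perm  # enumeration size
        assert (res.p_value * total) == pytest.approx(
            round(res.p_value * total))

    def test_one_sided_duality(self):
        y = np.array([3.0, 1, 4, 1.5, 5, 9])
        comp = make_comparison(y, [1, 0, 1, 0, 1, 0], [0, 0, 0, 1, 1, 1])
        pg = exact_enumeration_pvalue(comp, y, "greater").p_value
        pl = exact_enumeration_pvalue(comp, y, "less").p_value
        assert pg + pl >= 1.0   # the observed value is counted in both tails

    def test_limit_enforced(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        comp = make_comparison(y, rng.integers(0, 2, 40), np.zeros(40))
        with pytest.raises(DataError, match="Monte Carlo"):
            exact_enumeration_pvalue(comp, y, limit=100)


class TestRandomization:
    def test_monte_carlo_matches_exact(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            y = rng.normal(size=9)
            a = np.array([1, 0, 0, 1, 0, 1, 1, 0, 0])
            lab = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
            comp = make_comparison(y, a, lab)
            exact = exact_enumeration_pvalue(comp, y).p_value
            mc = randomization_pvalue(comp, y, n_perm=2000,
                                      seed=trial).p_value
            se = np.sqrt(exact * (1 - exact) / 2000)
            assert abs(mc - exact) <= 3 * se + 1 / 2001

    def test_degenerate_assignment_gives_one(self):
        comp = make_comparison([1.0, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])
        res = randomization_pvalue(comp, np.array([1.0, 2, 3, 4]))
        assert res.p_value == 1.0 and res.degenerate

    def test_null_distribution_invariant_to_within_stratum_shuffle(self):
        y = np.array([3.0, 1, 4, 1.5, 5, 9])
        lab = np.array([0, 0, 0, 1, 1, 1])
        a = np.array([1, 0, 0, 0, 1, 0])
        y_shuf = y.copy()
        y_shuf[[0, 1, 2]] = y[[2, 0, 1]]   # permute within stratum 0
        d1, _ = _tilt.comparison_strata(a, y, {0: np.arange(3),
                                               1: np.arange(3, 6)})
        d2, _ = _tilt.comparison_strata(a, y_shuf, {0: np.arange(3),
                                                    1: np.arange(3, 6)})
        n1 = _tilt.mc_null_statistics(d1, 500, np.random.default_rng(3))
        n2 = _tilt.mc_null_statistics(d2, 500, np.random.default_rng(3))
        np.testing.assert_array_equal(n1, n2)

    def test_p_value_in_unit_interval(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=12)
        comp = make_comparison(y, rng.integers(0, 2, 12),
                               np.repeat([0, 1, 2], 4))
        res = randomization_pvalue(comp, y, n_perm=200, seed=0)
        assert 0 < res.p_value <= 1

    def test_less_alternative_mirrors(self):
        y = np.array([1.0, 2, 3, 4])
        comp = make_comparison(y, [0, 0, 1, 1], [0, 0, 0, 0])
        pg = exact_enumeration_pvalue(comp, y, "greater").p_value
        pl = exact_enumeration_pvalue(comp, y, "less").p_value
        assert pg == pytest.approx(1 / 6)
        assert pl == pytest.approx(1.0)
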