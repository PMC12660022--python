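import numpy as np
import pytest

from efrd.core import AnalysisConfig, ConfigError
from efrd.inference import randomization_pvalue
from efrd.sensitivity import (sensitivity_curve, sensitivity_profile,
                              worst_case_pvalue)

from conftest import make_comparison


@pytest.fixture
def pair_comparison():
    """One stratum of 2, one treated, treated has the larger outcome."""
    y = np.array([1.0, 2.0])
    return make_comparison(y, [0, 1], [0, 0]), y


@pytest.fixture
def multi_comparison():
    rng = np.random.default_rng(5)
    y = rng.normal(size=12)
    a = np.array([1, 0, 1, 0] * 3)
    lab = np.repeat([0, 1, 2], 4)
    return make_comparison(y, a, lab), y


class TestWorstCase:
    def test_gamma_one_equals_unadjusted_seed_matched(self, multi_comparison):
        comp, y = multi_comparison
        unadj = randomization_pvalue(comp, y, n_perm=800, seed=21).p_value
        bound = worst_case_pvalue(comp, y, 1.0, n_perm=800, seed=21,
                                  exact=False)
        assert bound == unadj

    @pytest.mark.parametrize("gamma", [1.0, 2.0, 5.0])
    def test_pair_bound_is_gamma_odds(self, pair_comparison, gamma):
        comp, y = pair_comparison
        expected = gamma / (1 + gamma)
        exact = worst_case_pvalue(comp, y, gamma, exact=True)
        assert exact == pytest.approx(expected, abs=1e-12)
        mc = worst_case_pvalue(comp, y, gamma, n_perm=4000, seed=2,
                               exact=False)
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(mc - expected) <= 3 * se + 1 / 4001

    def test_large_gamma_saturates_at_one(self, pair_comparison):
        comp, y = pair_comparison
        assert worst_case_pvalue(comp, y, 1000.0, exact=True) > 0.99

    def test_monotone_in_gamma_common_random_numbers(self, multi_comparison):
        comp, y = multi_comparison
        gammas = [1.0, 1.2, 1.5, 2.0, 3.0, 5.0]
        mc = [worst_case_pvalue(comp, y, g, n_perm=2000, seed=9, exact=False)
              for g in gammas]
        assert all(b >= a for a, b in zip(mc, mc[1:]))
        exact = [worst_case_pvalue(comp, y, g, exact=True) for g in gammas]
        assert all(b >= a - 1e-12 for a, b in zip(exact, exact[1:]))

    def test_mc_matches_exact_tilted_law(self, multi_comparison):
        comp, y = multi_comparison
        for gamma in (1.5, 3.0):
            ex = worst_case_pvalue(comp, y, gamma, exact=True)
            mc = worst_case_pvalue(comp, y, gamma, n_perm=3000, seed=13,
                                   exact=False)
            se = np.sqrt(ex * (1 - ex) / 3000)
            assert abs(mc - ex) <= 3 * se + 1 / 3001

    def test_gamma_below_one_rejected(self, pair_comparison):
        comp, y = pair_comparison
        with pytest.raises(ConfigError):
            worst_case_pvalue(comp, y, 0.9)

    def test_degenerate_returns_one(self):
        comp = make_comparison([1.0, 2.0], [1, 1], [0, 0])
        assert worst_case_pvalue(comp, np.array([1.0, 2.0]), 2.0) == 1.0

    def test_curve_reports_unadjusted_at_gamma_one(self, multi_comparison):
        comp, y = multi_comparison
        curve = sensitivity_curve(comp, y, [1.0, 1.5, 2.0], n_perm=500,
                                  seed=4)
        assert curve.gamma[0] == 1.0
        assert np.all(np.diff(curve.p_upper) >= 0)


class TestProfile:
    def _factors(self):
        rng = np.random.default_rng(11)
        out = []
        for level in (1, 2):
            y = rng.normal(size=10)
            a = np.array([1, 0] * 5)
            comp = make_comparison(y, a, np.repeat([0, 1], 5), level=level)
            out.append((comp, y))
        return [c for c, _ in out], [y for _, y in out]

    def test_grid_shape_long_format(self):
        factors, ys = self._factors()
        cfg = AnalysisConfig(q=2, n_perm=400, seed=0,
                             gamma_grid={1: [1.0, 1.5, 2.0],
                                         2: [1.0, 1.5, 2.0]})
        profile = sensitivity_profile(factors, ys, cfg)
        assert len(profile) == 9
        assert {"gamma_1", "gamma_2", "p_1", "p_2",
                "p_combined"} <= set(profile.columns)

    def test_all_gamma_one_reduces_to_primary_analysis(self):
        from efrd.combine import fisher_combined
        factors, ys = self._factors()
        cfg = AnalysisConfig(q=2, n_perm=400, seed=0,
                             gamma_grid={1: [1.0], 2: [1.0]})
        profile = sensitivity_profile(factors, ys, cfg)
        ps = [worst_case_pvalue(c, y, 1.0, n_perm=400,
                                seed=cfg.seed + 1000 * c.level)
              for c, y in zip(factors, ys)]
        assert profile["p_combined"].iloc[0] == pytest.approx(
            fisher_combined(ps, 2).p_combined)

    def test_combined_monotone_in_single_gamma(self):
        factors, ys = self._factors()
        cfg = AnalysisConfig(q=2, n_perm=400, seed=0,
                             gamma_grid={1: [1.0, 2.0, 4.0], 2: [1.0]})
        profile = sensitivity_profile(factors, ys, cfg).sort_values("gamma_1")
        assert profile["p_combined"].is_monotonic_increasing


class TestAllocation:
    def test_pair_allocation_marks_high_outcome_unit(self, pair_comparison):
        from efrd.sensitivity import worst_case_allocation
        comp, y = pair_comparison
        np.testing.assert_array_equal(
            worst_case_allocation(comp, y, 2.0), [0, 1])
        # at gamma = 1 the tilt is inactive and u is all zero
        np.testing.assert_array_equal(
            worst_case_allocation(comp, y, 1.0), [0, 0])

    def test_allocation_entries_binary(self, multi_comparison):
        from efrd.sensitivity import worst_case_allocation
        comp, y = multi_comparison
        u = worst_case_allocation(comp, y, 1.5)
        assert set(np.unique(u)) <= {0, 1}
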