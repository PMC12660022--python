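import numpy as np
import pandas as pd
import pytest

from efrd.core import ConfigError, DataError, DesignSpec
from efrd.design import (assign_eligibility, residualize_outcome,
                         select_window, stratify)

from conftest import make_table


class TestEligibility:
    @pytest.mark.parametrize("running,expected", [
        ([-2, 0, 3], [0, 1, 1]),       # tie at the cutoff is eligible
        ([-35, 35], [0, 1]),
        ([-5, -1, -0.1], [0, 0, 0]),   # all below: degenerate but legal
    ])
    def test_ge_rule(self, running, expected, k2_spec):
        np.testing.assert_array_equal(
            assign_eligibility(np.array(running, float), k2_spec), expected)

    def test_le_rule_mirrors(self):
        spec = DesignSpec(K=2, eligibility_direction="le", cutoff=0.0)
        np.testing.assert_array_equal(
            assign_eligibility(np.array([-2.0, 0.0, 3.0]), spec), [1, 1, 0])

    def test_mismatch_with_observed_z1(self, k2_spec):
        with pytest.raises(DataError, match=r"\[0\]"):
            assign_eligibility(np.array([1.0, -1.0]), k2_spec,
                               z1=np.array([0, 0]))


class TestStratify:
    def test_identical_tuples_share_stratum(self):
        cov = pd.DataFrame({"a": [1, 1, 2], "b": [0, 0, 0]})
        table = make_table([0, 1, 2], [[0, 0], [1, 0], [1, 1]],
                           [1.0, 2.0, 3.0], cov)
        s = stratify(table)
        assert s.labels[0] == s.labels[1] != s.labels[2]

    def test_all_distinct_gives_singletons(self):
        cov = pd.DataFrame({"a": [1, 2, 3, 4]})
        table = make_table([0, 1, 2, 3], [[0, 0]] * 4, [1.0] * 4, cov)
        s = stratify(table)
        assert s.n_strata == 4
        assert all(len(m) == 1 for m in s.strata.values())

    def test_crossed_binary_covariates(self):
        cov = pd.DataFrame({"a": [0, 0, 1, 1] * 2, "b": [0, 1] * 4})
        table = make_table(range(8), [[0, 0]] * 8, [1.0] * 8, cov)
        s = stratify(table)
        assert s.n_strata == 4
        assert sorted(len(m) for m in s.strata.values()) == [2, 2, 2, 2]

    def test_row_order_invariance(self):
        cov = [0, 1, 0, 2, 1]
        table = make_table(range(5), [[0, 0]] * 5, [1.0] * 5, cov)
        perm = [4, 2, 0, 3, 1]
        shuffled = make_table(range(5), [[0, 0]] * 5, [1.0] * 5,
                              [cov[i] for i in perm])
        s1, s2 = stratify(table), stratify(shuffled)
        # same partition of covariate values regardless of row order
        assert s1.keys == s2.keys
        for sid, members in s1.strata.items():
            assert {cov[i] for i in members} == {s1.keys[sid][0]}


class TestResidualize:
    def test_exact_linear_fit_gives_zero(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.5 * x - 1.0
        assert np.max(np.abs(residualize_outcome(y, x))) < 1e-10

    def test_intercept_only_limit(self):
        # x chosen so the fitted slope is exactly 0: residuals are
        # deviations from the mean
        r = residualize_outcome(np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, -2.0, 1.0]))
        np.testing.assert_allclose(r, [-1.0, 0.0, 1.0], atol=1e-10)

    def test_three_point_closed_form(self):
        # normal equations by hand: slope 2, intercept -1/3
        r = residualize_outcome(np.array([0.0, 1.0, 4.0]),
                                np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(r, [1 / 3, -2 / 3, 1 / 3], atol=1e-10)

    def test_residuals_centered_and_orthogonal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 1.5 + 0.3 * x + rng.normal(size=50)
        r = residualize_outcome(y, x)
        assert abs(r.sum()) < 1e-8
        assert abs(r @ x) < 1e-8

    def test_subset_fit(self):
        x = np.array([0.0, 1.0, 2.0, 100.0])
        y = np.array([0.0, 1.0, 2.0, 5.0])
        r = residualize_outcome(y, x, subset=np.array([0, 1, 2]))
        assert len(r) == 3 and np.max(np.abs(r)) < 1e-10

    def test_constant_running_rejected(self):
        with pytest.raises(DataError, match="constant"):
            residualize_outcome(np.array([1.0, 2.0, 3.0]), np.ones(3))


def _window_table(n, seed, cov_equals_eligibility=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    cov = ((x >= 0).astype(int) if cov_equals_eligibility
           else rng.integers(0, 2, size=n))
    z1 = (x >= 0).astype(int)
    z = np.column_stack([z1, np.zeros(n, dtype=int)])
    return make_table(x, z, rng.normal(size=n), cov)


class TestSelectWindow:
    def test_single_passing_candidate_chosen(self, k2_spec):
        table = _window_table(150, seed=2)
        res = select_window(table, k2_spec, [1.0], n_perm=300, seed=0)
        assert res.chosen == (-1.0, 1.0)
        assert len(res.candidates_tested) == 1

    def test_perfect_imbalance_fails(self, k2_spec):
        table = _window_table(150, seed=3, cov_equals_eligibility=True)
        with pytest.raises(ConfigError, match="balance"):
            select_window(table, k2_spec, [0.5, 1.0], n_perm=300, seed=0)

    def test_balanced_covariate_keeps_largest_window(self, k2_spec):
        # covariate independent of eligibility: each candidate passes with
        # probability ~0.85, so the largest is chosen most of the time
        hits = 0
        for seed in range(30):
            table = _window_table(120, seed=100 + seed)
            try:
                res = select_window(table, k2_spec, [0.5, 1.0, 2.0],
                                    n_perm=200, seed=seed)
            except ConfigError:
                continue
            hits += res.chosen == (-2.0, 2.0)
        assert hits >= 18

    def test_threshold_monotonicity(self):
        table = _window_table(200, seed=7)
        chosen = {}
        for thr in (0.05, 0.3):
            spec = DesignSpec(K=2, balance_threshold=thr)
            try:
                chosen[thr] = select_window(table, spec, [0.5, 1.0, 2.0],
                                            n_perm=400, seed=11).chosen
            except ConfigError:
                chosen[thr] = (0.0, 0.0)
        assert chosen[0.3][1] <= chosen[0.05][1]

    def test_audit_trail_records_all_candidates(self, k2_spec):
        table = _window_table(150, seed=5)
        res = select_window(table, k2_spec, [0.5, 1.0], n_perm=200, seed=1)
        assert len(res.candidates_tested) == 2
        assert all("c" in c["p_values"] for c in res.candidates_tested)
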