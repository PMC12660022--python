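"""Stratified rank statistics and randomization p-values.

The test statistic at each level is a stratified two-sample Wilcoxon rank
sum: within every covariate stratum containing both arms, outcomes are
mid-ranked and the treated arm's rank sum accumulated across strata.  Its
null distribution comes from permuting the assignment independently within
each stratum with treated counts fixed — the only source of randomness
under the sharp null, with outcomes held fixed.  An exact-enumeration
routine serves as an oracle on small comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tilt
from .core import DataError
from .factors import EFComparison

__all__ = ["TestResult", "stratified_rank_statistic", "randomization_pvalue",
           "exact_enumeration_pvalue"]

ENUMERATION_LIMIT = 1_000_000


@dataclass(frozen=True)
class TestResult:
    level: int
    statistic: float
    p_value: float
    method: str                 # "monte_carlo" | "exact"
    n_perm: int
    seed: int | None
    n_treat: int
    n_control: int
    n_strata_informative: int
    alternative: str = "greater"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "level", "statistic", "p_value", "method", "n_perm", "seed",
            "n_treat", "n_control", "n_strata_informative", "alternative",
            "degenerate")}


def _comparison_outcome(comp: EFComparison, y: np.ndarray) -> np.ndarray:
    """Outcome vector aligned with comp.subjects.

    ``y`` may be full-table length (sliced by the comparison's subjects) or
    already restricted to the comparison.
    """
    y = np.asarray(y, dtype=float)
    if len(y) == len(comp.assignment):
        return y
    return y[comp.subjects]


def stratified_rank_statistic(y: np.ndarray, assignment: np.ndarray,
                              strata: dict[int, np.ndarray]) -> float:
    """Sum over informative strata of the treated within-stratum rank sum.

    Ranks use mid-ranks for ties; strata with a constant assignment
    contribute zero.
    """
    y = np.asarray(y, dtype=float)
    assignment = np.asarray(assignment)
    if y.size == 0:
        raise DataError("empty input")
    _, t_obs = _tilt.comparison_strata(assignment, y, strata)
    return t_obs


def _degenerate_result(comp: EFComparison, method: str, n_perm: int,
                       seed: int | None, alternative: str) -> TestResult:
    return TestResult(comp.level, 0.0, 1.0, method, n_perm, seed,
                      comp.n_treat, comp.n_control, 0, alternative,
                      degenerate=True)


def _natural_statistic(strata_data, t_obs: float, alternative: str) -> float:
    """Treated rank sum of y itself (sign-flip trick ranks -y for 'less')."""
    if alternative == "greater":
        return t_obs
    return sum(sd.t * (len(sd.scores) + 1) for sd in strata_data) - t_obs


def randomization_pvalue(comp: EFComparison, y: np.ndarray,
                         alternative: str = "greater",
                         n_perm: int = 2000, seed: int = 0) -> TestResult:
    """Monte-Carlo randomization p-value for one evidence factor.

    One-sided add-one estimate ``(1 + #{T* >= T_obs}) / (n_perm + 1)`` for
    ``alternative='greater'`` (mirrored for ``'less'``), permuting the
    assignment within strata with treated counts fixed.  Degenerate
    comparisons conservatively report p = 1.
    """
    y_local = _comparison_outcome(comp, y)
    sign = 1.0 if alternative == "greater" else -1.0
    strata_data, t_obs = _tilt.comparison_strata(
        comp.assignment, sign * y_local, comp.strata.strata)
    if not strata_data:
        return _degenerate_result(comp, "monte_carlo", n_perm, seed,
                                  alternative)
    rng = np.random.default_rng(seed)
    null = _tilt.mc_null_statistics(strata_data, n_perm, rng, gamma=1.0)
    p = float((1 + np.sum(null >= t_obs - 1e-9)) / (n_perm + 1))
    stat = _natural_statistic(strata_data, t_obs, alternative)
    return TestResult(comp.level, stat, p, "monte_carlo", n_perm, seed,
                      comp.n_treat, comp.n_control, len(strata_data),
                      alternative)


def exact_enumeration_pvalue(comp: EFComparison, y: np.ndarray,
                             alternative: str = "greater",
                             limit: int = ENUMERATION_LIMIT) -> TestResult:
    """Exact p-value by full enumeration of within-stratum assignments.

    Intended as an independent oracle for small comparisons; raises when the
    product of per-stratum assignment counts exceeds ``limit``.
    """
    y_local = _comparison_outcome(comp, y)
    sign = 1.0 if alternative == "greater" else -1.0
    strata_data, t_obs = _tilt.comparison_strata(
        comp.assignment, sign * y_local, comp.strata.strata)
    if not strata_data:
        return _degenerate_result(comp, "exact", 0, None, alternative)
    size = _tilt.enumeration_size(strata_data)
    if size > limit:
        raise DataError(
            f"enumeration space has {size} assignments (> {limit}); use "
            "randomization_pvalue (Monte Carlo) instead")
    p = _tilt.exact_tail_probability(strata_data, t_obs, gamma=1.0)
    stat = _natural_statistic(strata_data, t_obs, alternative)
    return TestResult(comp.level, stat, float(p), "exact", size, None,
                      comp.n_treat, comp.n_control, len(strata_data),
                      alternative)
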