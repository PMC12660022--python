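"""Worst-case p-values under biased assignment at each level.

The sensitivity parameter Γ_k >= 1 bounds how much two subjects in the same
stratum may differ in their odds of assignment at level k because of an
unmeasured binary covariate u.  For a one-sided alternative the worst case
over u in [0,1]^n is attained at a binary u equal to 1 on the units with
the largest within-stratum rank scores ('less' mirrors with the smallest);
the bound is the tail probability of the observed statistic under the
exponentially tilted within-stratum assignment law P(A) ∝ Γ^{Σ_{i∈A} u_i}
with treated counts fixed.  Γ = 1 recovers the unadjusted randomization
p-value exactly, draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from . import _tilt
from .combine import fisher_combined, truncated_product_combined
from .core import AnalysisConfig, ConfigError
from .factors import EFComparison

__all__ = ["SensitivityCurve", "worst_case_pvalue", "worst_case_allocation",
           "sensitivity_profile"]

EXACT_LIMIT = 100_000


def worst_case_allocation(comp: EFComparison, y: np.ndarray, gamma: float,
                          alternative: str = "greater") -> np.ndarray:
    """Binary unmeasured-covariate configuration attaining the bound.

    Returns u over the comparison's subjects (local order): within each
    informative stratum, u = 1 on the units with the largest (greater) or
    smallest (less) within-stratum rank scores, with the per-stratum count
    chosen as in :func:`worst_case_pvalue`.  Audit output only.
    """
    if gamma < 1.0:
        raise ConfigError(f"gamma must be >= 1 (got {gamma})")
    from .inference import _comparison_outcome
    y_local = _comparison_outcome(comp, y)
    sign = 1.0 if alternative == "greater" else -1.0
    u = np.zeros(len(comp.assignment), dtype=int)
    for sid in sorted(comp.strata.strata):
        members = comp.strata.strata[sid]
        a = comp.assignment[members]
        t = int(a.sum())
        if t == 0 or t == len(members):
            continue
        scores = _tilt.rankdata(sign * y_local[members])
        b = 0 if gamma == 1.0 else _tilt.choose_worst_b(scores, t, gamma)
        if b:
            top = np.argsort(-scores, kind="stable")[:b]
            u[members[top]] = 1
    return u


@dataclass
class SensitivityCurve:
    level: int
    gamma: np.ndarray       # Γ values, ascending
    p_upper: np.ndarray     # worst-case p-values aligned with gamma
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {"level": self.level, "gamma": list(map(float, self.gamma)),
                "p_upper": list(map(float, self.p_upper)),
                "n_perm": self.n_perm, "seed": self.seed}


def worst_case_pvalue(comp: EFComparison, y: np.ndarray, gamma: float,
                      alternative: str = "greater", n_perm: int = 2000,
                      seed: int = 0, exact: bool | None = None) -> float:
    """Upper bound on the one-sided p-value at sensitivity level ``gamma``.

    Uses exact enumeration of the tilted law when the assignment space is
    small (or ``exact=True``), otherwise an add-one Monte-Carlo tail with
    the same seeded draws for every gamma, so bounds at different gammas
    share random numbers.  Degenerate comparisons return 1.
    """
    if gamma < 1.0:
        raise ConfigError(f"gamma must be >= 1 (got {gamma})")
    from .inference import _comparison_outcome
    y_local = _comparison_outcome(comp, y)
    sign = 1.0 if alternative == "greater" else -1.0
    strata_data, t_obs = _tilt.comparison_strata(
        comp.assignment, sign * y_local, comp.strata.strata)
    if not strata_data:
        return 1.0
    if exact is None:
        exact = _tilt.enumeration_size(strata_data) <= EXACT_LIMIT
    if exact:
        return float(_tilt.exact_tail_probability(strata_data, t_obs, gamma))
    rng = np.random.default_rng(seed)
    null = _tilt.mc_null_statistics(strata_data, n_perm, rng, gamma=gamma)
    return float((1 + np.sum(null >= t_obs - 1e-9)) / (n_perm + 1))


def sensitivity_curve(comp: EFComparison, y: np.ndarray, gammas,
                      alternative: str = "greater", n_perm: int = 2000,
                      seed: int = 0) -> SensitivityCurve:
    gammas = np.asarray(sorted(gammas), dtype=float)
    p = np.array([worst_case_pvalue(comp, y, g, alternative, n_perm, seed)
                  for g in gammas])
    return SensitivityCurve(comp.level, gammas, p, n_perm, seed)


def sensitivity_profile(factors: list[EFComparison], outcomes: list[np.ndarray],
                        config: AnalysisConfig) -> pd.DataFrame:
    """Per-factor bounds and the combined bound over the full Γ grid.

    ``outcomes[k]`` is the outcome vector used by factor k (residualized for
    the level-1 factor when enabled).  The grid is the Cartesian product of
    the per-level Γ lists in ``config.gamma_grid``; each row reports
    (gamma_1..gamma_K, p_1..p_K, p_combined) in long format, with common
    random numbers across grid points.
    """
    K = len(factors)
    if config.gamma_grid is None:
        grid = {k: [1.0, 1.1, 1.2, 1.5, 2.0] for k in range(1, K + 1)}
    else:
        grid = {k: list(config.gamma_grid.get(k, [1.0]))
                for k in range(1, K + 1)}
    # bounds vary per level independently: evaluate each factor once per
    # gamma, then assemble the product grid
    per_level: dict[int, dict[float, float]] = {}
    for comp, y in zip(factors, outcomes):
        level_seed = config.seed + 1000 * comp.level
        per_level[comp.level] = {
            float(g): worst_case_pvalue(comp, y, float(g),
                                        config.alternative, config.n_perm,
                                        level_seed)
            for g in grid[comp.level]}
    rows = []
    for point in product(*(grid[k] for k in range(1, K + 1))):
        ps = [per_level[k][float(point[k - 1])] for k in range(1, K + 1)]
        if config.combiner == "fisher":
            comb = fisher_combined(ps, config.q, config.null_draws,
                                   config.seed)
        else:
            comb = truncated_product_combined(ps, config.q, config.truncation,
                                              config.null_draws, config.seed)
        row = {f"gamma_{k}": float(point[k - 1]) for k in range(1, K + 1)}
        row.update({f"p_{k}": ps[k - 1] for k in range(1, K + 1)})
        row["p_combined"] = comb.p_combined
        rows.append(row)
    return pd.DataFrame(rows)
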