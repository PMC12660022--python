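"""Combining the K factor p-values through their q largest order statistics.

With q the conjectured minimum number of valid factors, the K - q smallest
p-values are discarded — they may belong to biased comparisons — and the
combining statistic is applied to the q largest.  Because the j-th smallest
retained p-value is always at least the j-th smallest p-value of any q
valid factors, referring the statistic to its null law under q independent
uniforms yields a p-value that is valid whenever at least q factors are
unbiased (without knowing which), and conservative when more are.  For
Fisher's statistic that null is chi-square with 2q degrees of freedom; the
truncated product's null is simulated with seed-reproducible draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConfigError

__all__ = ["CombinedResult", "fisher_combined", "truncated_product_combined"]


@dataclass(frozen=True)
class CombinedResult:
    q: int
    combiner: str
    member_p: tuple[float, ...]
    retained_p: tuple[float, ...]
    retained_indices: tuple[int, ...]
    statistic: float
    p_combined: float
    null_method: str            # "closed_form" | "monte_carlo"
    null_draws: int
    seed: int | None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "q", "combiner", "statistic", "p_combined", "null_method",
            "null_draws", "seed")}
        d["member_p"] = list(self.member_p)
        d["retained_p"] = list(self.retained_p)
        d["retained_indices"] = list(self.retained_indices)
        return d


def _retain_largest(pvals: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of the q largest p-values.

    Ties at the retention boundary are broken by sorted position with
    stable original-index order.
    """
    order = np.argsort(-pvals, kind="stable")
    idx = np.sort(order[:q])
    return idx, pvals[idx]


def _check_inputs(pvals: np.ndarray, q: int) -> None:
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ConfigError("all p-values must lie in (0, 1]")
    if not 1 <= q <= len(pvals):
        raise ConfigError(f"q = {q} out of range for {len(pvals)} p-values")


def fisher_combined(pvals, q: int, null_draws: int = 100_000,
                    seed: int = 0) -> CombinedResult:
    """Fisher's statistic on the q largest of K p-values.

    H = -2 Σ log p over the retained p-values, referred to the chi-square
    distribution with 2q degrees of freedom (the null of H on q independent
    uniforms); for q = K this is the classical Fisher combination.
    ``null_draws`` and ``seed`` are accepted for interface symmetry with
    the truncated product but unused — the null is closed form for every q.
    """
    pvals = np.asarray(pvals, dtype=float)
    _check_inputs(pvals, q)
    idx, retained = _retain_largest(pvals, q)
    H = float(-2.0 * np.log(retained).sum())
    p_comb = float(stats.chi2.sf(H, df=2 * q))
    return CombinedResult(q, "fisher", tuple(pvals), tuple(retained),
                          tuple(int(i) for i in idx), H,
                          max(p_comb, np.finfo(float).tiny),
                          "closed_form", 0, None)


def truncated_product_combined(pvals, q: int, truncation: float = 0.2,
                               null_draws: int = 100_000,
                               seed: int = 0) -> CombinedResult:
    """Truncated product statistic on the q largest of K p-values.

    W = Π p^{1(p <= τ)} over the retained p-values: only p-values at or
    below the truncation point τ enter the product, so W = 1 (and the
    combined p is 1) when every retained p exceeds τ.  The combined
    p-value is the add-one Monte-Carlo estimate of P(W_null <= W_obs)
    under q independent uniforms.  At τ = 1 and q = K this agrees with
    Fisher's combination up to Monte-Carlo error.
    """
    pvals = np.asarray(pvals, dtype=float)
    _check_inputs(pvals, q)
    if not 0.0 < truncation <= 1.0:
        raise ConfigError("truncation must lie in (0, 1]")
    idx, retained = _retain_largest(pvals, q)
    logw = float(np.sum(np.where(retained <= truncation,
                                 np.log(retained), 0.0)))
    rng = np.random.default_rng(seed)
    u = rng.random((null_draws, q))
    logw_null = np.sum(np.where(u <= truncation, np.log(u), 0.0), axis=1)
    p_comb = float((1 + np.sum(logw_null <= logw + 1e-12)) / (null_draws + 1))
    return CombinedResult(q, "truncated_product", tuple(pvals),
                          tuple(retained), tuple(int(i) for i in idx),
                          float(np.exp(logw)), p_comb, "monte_carlo",
                          null_draws, seed)
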