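"""Shared randomization machinery for stratified rank statistics.

Both the plain randomization test and the worst-case sensitivity bound draw
treated sets within each stratum from the exponentially tilted law

    P(treated set A) ∝ Γ^{Σ_{i∈A} u_i},   |A| = t fixed,

with a binary unmeasured covariate u.  Because u is binary, the treated set
splits into "how many of the u = 1 units are treated" (a Fisher noncentral
hypergeometric count) and uniform choices within the two u-classes.  The
worst-case u for a one-sided (greater) alternative puts u = 1 on the ``b``
largest within-stratum scores, with ``b`` chosen to maximize the expected
statistic under the tilt.  At Γ = 1 every b yields the same mean, the
tie-break picks b = 0, and the sampler reduces exactly to uniform
within-stratum randomization — so the unadjusted test is the Γ = 1 special
case, draw for draw.

Sampling uses inverse-CDF on uniforms drawn before any per-stratum
permutations, so runs at different Γ with the same seed share random
numbers and the simulated statistics are pathwise nondecreasing in Γ for a
fixed worst-case class size.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats
from scipy.stats import rankdata

__all__ = ["StratumData", "comparison_strata", "mc_null_statistics",
           "exact_tail_probability", "enumeration_size", "choose_worst_b"]


@dataclass(frozen=True)
class StratumData:
    """One informative stratum: within-stratum scores and treated count."""

    scores: np.ndarray   # within-stratum rank scores, member order
    t: int               # number of treated in the stratum


def comparison_strata(assignment: np.ndarray, y: np.ndarray,
                      strata: "dict[int, np.ndarray]"
                      ) -> tuple[list[StratumData], float]:
    """Informative strata (both arms present) with mid-rank scores.

    Returns the per-stratum data and the observed statistic: the sum over
    informative strata of the treated units' within-stratum rank sum.
    Strata with a constant assignment contribute nothing.
    """
    data: list[StratumData] = []
    t_obs = 0.0
    for sid in sorted(strata):
        members = strata[sid]
        a = np.asarray(assignment)[members]
        t = int(a.sum())
        if t == 0 or t == len(members):
            continue
        scores = rankdata(np.asarray(y)[members])  # mid-ranks for ties
        data.append(StratumData(scores, t))
        t_obs += float(scores[a == 1].sum())
    return data, t_obs


def choose_worst_b(scores: np.ndarray, t: int, gamma: float) -> int:
    """Class size b of the worst-case binary u (u = 1 on the b top scores).

    b maximizes the expected treated score sum under the tilted law; ties
    (in particular the Γ = 1 case, where the mean is free of b) resolve to
    the smallest b.
    """
    m = len(scores)
    srt = np.sort(scores)[::-1]
    csum = np.concatenate([[0.0], np.cumsum(srt)])
    total = csum[-1]
    best_b, best_mean = 0, -np.inf
    for b in range(m + 1):
        es = _fnch_mean(m, b, t, gamma)
        mean1 = csum[b] / b if b else 0.0
        mean0 = (total - csum[b]) / (m - b) if m - b else 0.0
        mean = es * mean1 + (t - es) * mean0
        if mean > best_mean + 1e-12:
            best_b, best_mean = b, mean
    return best_b


def _fnch_support_pmf(m: int, b: int, t: int,
                      gamma: float) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = max(0, t - (m - b)), min(t, b)
    support = np.arange(lo, hi + 1)
    if gamma == 1.0:
        pmf = stats.hypergeom.pmf(support, m, b, t)
    else:
        pmf = stats.nchypergeom_fisher.pmf(support, m, b, t, gamma)
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    return support, pmf


def _fnch_mean(m: int, b: int, t: int, gamma: float) -> float:
    if b == 0:
        return 0.0
    support, pmf = _fnch_support_pmf(m, b, t, gamma)
    return float(support @ pmf)


def mc_null_statistics(strata_data: list[StratumData], n_perm: int,
                       rng: np.random.Generator,
                       gamma: float = 1.0) -> np.ndarray:
    """``n_perm`` draws of the statistic under the (tilted) assignment law.

    With ``gamma == 1`` this is the uniform within-stratum randomization
    null.  With ``gamma > 1`` each stratum's treated set is drawn from the
    tilted law at the worst-case u (one-sided greater orientation; callers
    handle 'less' by negating scores).
    """
    n_strata = len(strata_data)
    totals = np.zeros(n_perm)
    # count uniforms first so random-number consumption is Γ-invariant
    u_counts = rng.random((n_perm, n_strata))
    rows = np.arange(n_perm)
    for j, sd in enumerate(strata_data):
        m, t = len(sd.scores), sd.t
        srt = np.sort(sd.scores)[::-1]
        b = 0 if gamma == 1.0 else choose_worst_b(sd.scores, t, gamma)
        # one shared permutation stream per stratum, independent of gamma
        perm = rng.permuted(np.tile(np.arange(m), (n_perm, 1)), axis=1)
        if b == 0:
            cum0 = np.concatenate(
                [np.zeros((n_perm, 1)), np.cumsum(srt[perm], axis=1)], axis=1)
            totals += cum0[:, t]
            continue
        support, pmf = _fnch_support_pmf(m, b, t, gamma)
        cdf = np.cumsum(pmf)
        s = support[np.minimum(np.searchsorted(cdf, u_counts[:, j],
                                               side="left"),
                               len(support) - 1)]
        mask = perm < b
        idx1 = perm[mask].reshape(n_perm, b)
        idx0 = perm[~mask].reshape(n_perm, m - b)
        cum1 = np.concatenate(
            [np.zeros((n_perm, 1)), np.cumsum(srt[idx1], axis=1)], axis=1)
        cum0 = np.concatenate(
            [np.zeros((n_perm, 1)), np.cumsum(srt[idx0], axis=1)], axis=1)
        totals += cum1[rows, s] + cum0[rows, sd.t - s]
    return totals


def enumeration_size(strata_data: list[StratumData]) -> int:
    size = 1
    for sd in strata_data:
        size *= comb(len(sd.scores), sd.t)
    return size


def exact_tail_probability(strata_data: list[StratumData], t_obs: float,
                           gamma: float = 1.0) -> float:
    """Exact P(T >= t_obs) under the (tilted) within-stratum assignment law.

    Enumerates every within-stratum treated set; score sums are held as
    doubled integers (mid-ranks are half-integers) so the tail comparison is
    exact.  At Γ = 1 the result is a ratio of integers.
    """
    from itertools import combinations

    dist: dict[int, float] = {0: 1.0}
    for sd in strata_data:
        m = len(sd.scores)
        srt = np.sort(sd.scores)[::-1]
        doubled = np.rint(2 * srt).astype(int)
        b = 0 if gamma == 1.0 else choose_worst_b(sd.scores, sd.t, gamma)
        local: dict[int, float] = {}
        for sel in combinations(range(m), sd.t):
            val = int(sum(doubled[list(sel)]))
            w = gamma ** sum(1 for i in sel if i < b)
            local[val] = local.get(val, 0.0) + w
        new: dict[int, float] = {}
        for v1, w1 in dist.items():
            for v2, w2 in local.items():
                new[v1 + v2] = new.get(v1 + v2, 0.0) + w1 * w2
        dist = new
    total = sum(dist.values())
    target = int(np.rint(2 * t_obs))
    tail = sum(w for v, w in dist.items() if v >= target)
    return tail / total
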