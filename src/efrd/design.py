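"""Eligibility rule, covariate stratification, window selection, residualization.

The level-1 comparison treats the discontinuity as a locally randomized
experiment: inside a small window around the cutoff, eligibility is assumed
as-if random given the observed covariates.  The window is chosen as the
largest candidate for which every covariate passes a randomization balance
test, and the level-1 outcome is residualized on the running variable to
remove its direct trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConfigError, DataError, DesignSpec, SubjectTable

__all__ = [
    "Stratification",
    "WindowSearchResult",
    "assign_eligibility",
    "stratify",
    "select_window",
    "residualize_outcome",
]


@dataclass
class Stratification:
    """Exact-matching strata on the full covariate tuple.

    ``labels[i]`` is the integer stratum id of subject ``i``; ``strata`` maps
    each id to the member row indices.  Strata without within-stratum
    assignment variation are kept here but contribute nothing downstream.
    """

    labels: np.ndarray                       # int, shape (n,)
    strata: dict[int, np.ndarray]            # id -> member row indices
    keys: dict[int, tuple]                   # id -> covariate tuple

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def restrict(self, subset: np.ndarray) -> "Stratification":
        """Stratification of ``subset`` (row indices), relabelled locally.

        Members are positions *within* the subset, so the result can be used
        directly against sliced outcome/assignment vectors.
        """
        subset = np.asarray(subset)
        sub_labels = self.labels[subset]
        strata: dict[int, np.ndarray] = {}
        keys: dict[int, tuple] = {}
        new_labels = np.empty(len(subset), dtype=int)
        remap: dict[int, int] = {}
        for pos, lab in enumerate(sub_labels):
            if lab not in remap:
                remap[lab] = len(remap)
                keys[remap[lab]] = self.keys[lab]
            new_labels[pos] = remap[lab]
        for new_id in remap.values():
            strata[new_id] = np.flatnonzero(new_labels == new_id)
        return Stratification(new_labels, strata, keys)


def assign_eligibility(running: np.ndarray, spec: DesignSpec,
                       z1: np.ndarray | None = None) -> np.ndarray:
    """Deterministic eligibility from the running variable.

    Subjects on the eligible side of the cutoff (ties included) get 1.  When
    the table's observed ``Z_1`` is supplied it must agree exactly,
    otherwise a :class:`DataError` names the offending rows.
    """
    running = np.asarray(running, dtype=float)
    if not np.all(np.isfinite(running)):
        raise DataError("running variable contains non-finite values")
    if spec.eligibility_direction == "ge":
        elig = (running >= spec.cutoff).astype(int)
    else:
        elig = (running <= spec.cutoff).astype(int)
    if z1 is not None:
        mismatch = np.flatnonzero(np.asarray(z1, dtype=int) != elig)
        if mismatch.size:
            raise DataError(
                "observed Z_1 disagrees with the eligibility rule at rows "
                f"{mismatch.tolist()}", mismatch)
    return elig


def stratify(table: SubjectTable) -> Stratification:
    """Group subjects into exact-matching strata on the covariate tuple.

    Stratum ids are assigned in sorted covariate-tuple order so the result
    is invariant to row order.
    """
    tuples = table.covariate_tuples()
    uniq = sorted(set(tuples))
    key_to_id = {t: i for i, t in enumerate(uniq)}
    labels = np.array([key_to_id[t] for t in tuples], dtype=int)
    strata = {i: np.flatnonzero(labels == i) for i in range(len(uniq))}
    keys = {i: t for t, i in key_to_id.items()}
    return Stratification(labels, strata, keys)


@dataclass
class WindowSearchResult:
    chosen: tuple[float, float]
    candidates_tested: list[dict]     # {"window": (lo,hi), "p_values": {...}}
    threshold: float

    def to_dict(self) -> dict:
        return {
            "chosen": list(self.chosen),
            "threshold": self.threshold,
            "candidates_tested": [
                {"window": list(c["window"]),
                 "p_values": {str(k): v for k, v in c["p_values"].items()}}
                for c in self.candidates_tested
            ],
        }


def _balance_pvalue(x: np.ndarray, elig: np.ndarray, n_perm: int,
                    rng: np.random.Generator) -> float:
    """Two-sided randomization p for a difference in covariate means.

    Eligibility labels are permuted freely within the window (no strata):
    covariates are what the strata would later be built from, so the balance
    test cannot condition on them.
    """
    x = np.asarray(x, dtype=float)
    n1 = int(elig.sum())
    n = len(x)
    if n1 == 0 or n1 == n:
        return 0.0  # one arm empty: maximal imbalance by convention
    obs = abs(x[elig == 1].mean() - x[elig == 0].mean())
    # permute by drawing n1 positions without replacement, vectorized
    u = rng.random((n_perm, n))
    order = np.argpartition(u, n1 - 1, axis=1)[:, :n1]
    tot = x.sum()
    sums1 = x[order].sum(axis=1)
    stat = np.abs(sums1 / n1 - (tot - sums1) / (n - n1))
    return float((1 + np.sum(stat >= obs - 1e-12)) / (n_perm + 1))


def select_window(table: SubjectTable, spec: DesignSpec,
                  candidates: list[float], n_perm: int = 1000,
                  seed: int = 0) -> WindowSearchResult:
    """Choose the largest symmetric window passing covariate balance.

    Each candidate half-width ``w`` defines the window
    ``(cutoff - w, cutoff + w)``.  For every covariate a two-sided
    randomization p-value compares eligible and ineligible means within the
    window; a candidate passes when the minimum p-value across covariates
    exceeds ``spec.balance_threshold``.  The largest passing candidate wins;
    if none passes an error asks for narrower candidates (no silent
    fallback).
    """
    if not candidates:
        raise ConfigError("at least one candidate window width is required")
    candidates = sorted(float(w) for w in candidates)
    elig_all = assign_eligibility(table.running, spec)
    rng = np.random.default_rng(seed)
    tested: list[dict] = []
    chosen: tuple[float, float] | None = None
    for w in candidates:
        lo, hi = spec.cutoff - w, spec.cutoff + w
        inside = (table.running > lo) & (table.running < hi)
        pvals: dict[str, float] = {}
        for col in table.covariates.columns:
            x = table.covariates[col].to_numpy(dtype=float)[inside]
            pvals[str(col)] = _balance_pvalue(x, elig_all[inside],
                                              n_perm, rng)
        tested.append({"window": (lo, hi), "p_values": pvals})
        if pvals and min(pvals.values()) > spec.balance_threshold:
            chosen = (lo, hi)
    if chosen is None:
        raise ConfigError(
            "no candidate window passed the covariate balance test at "
            f"threshold {spec.balance_threshold}; supply narrower candidates "
            "or lower the threshold")
    return WindowSearchResult(chosen, tested, spec.balance_threshold)


def residualize_outcome(y: np.ndarray, running: np.ndarray,
                        subset: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of the outcome on the running variable over ``subset``.

    Removes the running variable's direct linear trend before the level-1
    (intent-to-treat) comparison; only entries in ``subset`` are fitted and
    returned.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(running, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        y, x = y[subset], x[subset]
    if len(y) < 3:
        raise DataError("residualization needs at least 3 subjects")
    if np.ptp(x) == 0:
        raise DataError("running variable is constant over the subset; "
                        "slope is unidentifiable")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta
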