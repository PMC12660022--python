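"""Construction of the K evidence-factor comparisons.

Evidence factor 1 is the intent-to-treat comparison of eligible vs
ineligible subjects inside the local-randomization window.  Evidence factor
``k >= 2`` compares ``Z_k = 1`` vs ``Z_k = 0`` only among subjects whose
earlier statuses are all 1, so bias entering at an earlier level cannot
propagate into the later comparison.  Under two-sided non-compliance this
means EF 2 drops every ineligible subject regardless of later statuses while
keeping eligible subjects outside the window.  Variation of ``Z_k`` among
subjects with any prior status 0 is never used.

The unconditioned benchmarks compare ``Z_k = 1`` vs ``Z_k = 0`` over *all*
subjects (an as-treated analysis at level K); they share the covariate
strata but ignore the sequential structure, which is exactly what lets an
earlier-level bias spill into them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DesignSpec, SubjectTable
from .design import Stratification

__all__ = ["EFComparison", "build_factors", "build_unconditioned",
           "membership_table"]


@dataclass
class EFComparison:
    """One factor: subject subset, binary assignment, strata at level k."""

    level: int
    subjects: np.ndarray          # row indices into the full table
    assignment: np.ndarray        # Z_level restricted to subjects
    strata: Stratification        # restricted to subjects (local positions)
    window_applied: bool
    outcome_used: str             # "raw" | "residualized"

    @property
    def degenerate(self) -> bool:
        """True when no stratum contains both assignment arms."""
        for members in self.strata.strata.values():
            a = self.assignment[members]
            if 0 < a.sum() < len(a):
                return False
        return True

    @property
    def n_treat(self) -> int:
        return int(self.assignment.sum())

    @property
    def n_control(self) -> int:
        return int(len(self.assignment) - self.assignment.sum())


def _window_mask(table: SubjectTable, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (table.running > lo) & (table.running < hi)


def build_factors(table: SubjectTable, spec: DesignSpec,
                  strat: Stratification, window: tuple[float, float],
                  residualize: bool = True) -> list[EFComparison]:
    """The K evidence-factor comparisons.

    EF 1: all subjects inside ``window``, assignment ``Z_1``
    (intent-to-treat); EF k >= 2: subjects with ``Z_1 = ... = Z_{k-1} = 1``
    (no window restriction), assignment ``Z_k``.  A factor whose strata
    never contain both arms is carried along flagged degenerate (its
    p-value is reported as 1) rather than dropped.
    """
    table.check(spec)
    comparisons: list[EFComparison] = []
    for k in range(1, spec.K + 1):
        if k == 1:
            subjects = np.flatnonzero(_window_mask(table, window))
            window_applied = True
            outcome_used = "residualized" if residualize else "raw"
        else:
            subjects = np.flatnonzero((table.z[:, : k - 1] == 1).all(axis=1))
            window_applied = False
            outcome_used = "raw"
        assignment = table.z[subjects, k - 1]
        comparisons.append(EFComparison(
            level=k,
            subjects=subjects,
            assignment=assignment,
            strata=strat.restrict(subjects),
            window_applied=window_applied,
            outcome_used=outcome_used,
        ))
    return comparisons


def build_unconditioned(table: SubjectTable, spec: DesignSpec,
                        strat: Stratification, window: tuple[float, float],
                        residualize: bool = True) -> list[EFComparison]:
    """Benchmark comparisons ignoring earlier statuses.

    Level k compares ``Z_k = 1`` vs ``Z_k = 0`` over all subjects with the
    same covariate strata; level 1 coincides with EF 1 by construction
    (window applied, Z_1 assignment).
    """
    table.check(spec)
    comparisons: list[EFComparison] = []
    for k in range(1, spec.K + 1):
        if k == 1:
            subjects = np.flatnonzero(_window_mask(table, window))
            window_applied = True
            outcome_used = "residualized" if residualize else "raw"
        else:
            subjects = np.arange(table.n)
            window_applied = False
            outcome_used = "raw"
        assignment = table.z[subjects, k - 1]
        comparisons.append(EFComparison(
            level=k,
            subjects=subjects,
            assignment=assignment,
            strata=strat.restrict(subjects),
            window_applied=window_applied,
            outcome_used=outcome_used,
        ))
    return comparisons


def membership_table(table: SubjectTable,
                     comparisons: list[EFComparison]) -> pd.DataFrame:
    """Audit view: subject id x level -> 'T', 'C' or '.' (excluded)."""
    out = pd.DataFrame({"id": table.ids})
    for comp in comparisons:
        col = np.full(table.n, ".", dtype=object)
        col[comp.subjects] = np.where(comp.assignment == 1, "T", "C")
        out[f"EF{comp.level}"] = col
    return out
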