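"""Synthetic data generation and the rejection-rate study.

The generator emulates a fuzzy RD design with sequential assignments.  A
discrete baseline covariate C shifts the running variable X and the later
assignment stages; eligibility is Z_1 = 1{X >= 0}.  Three kinds of
unmeasured binary covariates create level-specific bias: U_1 is a mediator
on the Z_1 -> Y path (violating the exclusion restriction of eligibility
when its outcome coefficient lambda_1 is nonzero), while U_2, U_3 confound
the level-2 and level-3 assignments with the outcome when lambda_2,
lambda_3 are nonzero.  The treatment effect enters the outcome only through
the final status Z_K.

Design 1 is K = 3 with one-sided compliance (Z_k = 0 whenever a prior
status is 0); Design 2 is K = 2 with two-sided non-compliance (ineligible
subjects may still end up treated).  Seven lambda-cases per design-1 study
switch the biased levels on and off; the rejection-rate study compares the
evidence-factor p-values with unconditioned (as-treated style) benchmarks
at a nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _tilt
from .core import ConfigError, DesignSpec, SubjectTable
from .design import residualize_outcome, stratify
from .factors import build_factors, build_unconditioned

__all__ = ["SimCase", "SimTruth", "DGPCoefficients", "StudyResult",
           "generate_design1", "generate_design2", "design1_case",
           "design2_case", "run_study", "plot_rejection"]


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class DGPCoefficients:
    """Structural coefficients of the generator, exposed as parameters.

    Defaults: the covariate C ~ Binomial(2, 1/2) shifts the running
    variable by ``x_cov`` per level and the level-k assignment logits by
    ``assign_cov``; U_2, U_3 are fair coins entering their assignment
    logits with weight ``assign_unmeasured``; the mediator U_1 is Bernoulli
    with success probability ``u1_base + u1_gain * Z_1``; the outcome has
    unit Gaussian noise and an optional linear running-variable trend
    ``y_slope * X``.  The trend defaults to zero: eligibility is a
    deterministic function of X, so any direct X -> Y effect would bias
    the as-treated benchmarks even with no unmeasured bias, whereas the
    study design calls for every comparison to be valid when all lambdas
    vanish.  Residualization of the level-1 outcome stays in the analysis
    workflow either way.
    """

    x_cov: float = 0.5            # C -> X shift per covariate level
    x_sd: float = 1.0             # running-variable noise SD
    assign_intercept: float = 0.2
    assign_cov: float = 0.4       # C -> assignment logit, levels >= 2
    assign_unmeasured: float = 1.0
    u1_base: float = 0.3
    u1_gain: float = 0.4          # Z1 -> U1 (mediator strength)
    y_slope: float = 0.0          # X -> Y direct trend (see above)
    y_sd: float = 1.0
    # design 2 only: logit of Z2 with a Z1 main effect (two-sided)
    d2_intercept: float = -1.2
    d2_z1: float = 2.2


@dataclass(frozen=True)
class SimCase:
    design: str                   # "design1" | "design2"
    n: int
    lambdas: tuple[float, ...]    # outcome coefficient of U_1..U_K
    effect: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.design not in ("design1", "design2"):
            raise ConfigError(f"unknown design {self.design!r}")
        K = 3 if self.design == "design1" else 2
        if len(self.lambdas) != K:
            raise ConfigError(f"{self.design} needs {K} lambda values")
        if self.n < 1:
            raise ConfigError("n must be >= 1")

    @property
    def K(self) -> int:
        return 3 if self.design == "design1" else 2

    @property
    def q_rule(self) -> int:
        """Correctly specified q: K minus the number of biased levels."""
        return self.K - sum(1 for lam in self.lambdas if lam != 0.0)


@dataclass
class SimTruth:
    """Ground truth behind a generated table.

    ``u`` holds the realized unmeasured covariates (U_1 is the value at
    the realized Z_1); ``potential_outcomes`` maps each admissible
    treatment vector to the outcome the subject would show under it, with
    the consistency property that the observed outcome equals the
    potential outcome at the realized vector.
    """

    u: np.ndarray                                   # (n, K)
    u1_potential: np.ndarray                        # (n, 2): U_1(z1=0), U_1(z1=1)
    potential_outcomes: dict[tuple[int, ...], np.ndarray]


def _design1_spec() -> DesignSpec:
    return DesignSpec(K=3, compliance="one_sided", cutoff=0.0,
                      eligibility_direction="ge")


def _design2_spec() -> DesignSpec:
    return DesignSpec(K=2, compliance="two_sided", cutoff=0.0,
                      eligibility_direction="ge")


def generate_design1(case: SimCase,
                     coef: DGPCoefficients = DGPCoefficients()
                     ) -> tuple[SubjectTable, SimTruth]:
    """K = 3, one-sided compliance.

    Z_2 is drawn only among the eligible, Z_3 only among level-2 takers;
    the treatment effect enters through Z_3 alone.
    """
    if case.design != "design1":
        raise ConfigError("generate_design1 requires a design1 case")
    rng = np.random.default_rng(case.seed)
    n = case.n
    c = rng.binomial(2, 0.5, size=n)
    x = coef.x_cov * (c - 1) + rng.normal(0.0, coef.x_sd, size=n)
    z1 = (x >= 0.0).astype(int)
    # mediator U1: monotone coupling of its two potential values
    v = rng.random(n)
    u1_pot = np.column_stack([(v < coef.u1_base).astype(int),
                              (v < coef.u1_base + coef.u1_gain).astype(int)])
    u1 = u1_pot[np.arange(n), z1]
    u2 = rng.integers(0, 2, size=n)
    u3 = rng.integers(0, 2, size=n)

    logit2 = (coef.assign_intercept + coef.assign_cov * (c - 1)
              + coef.assign_unmeasured * (u2 - 0.5))
    z2 = np.where(z1 == 1, rng.binomial(1, _expit(logit2)), 0)
    logit3 = (coef.assign_intercept + coef.assign_cov * (c - 1)
              + coef.assign_unmeasured * (u3 - 0.5))
    z3 = np.where(z2 == 1, rng.binomial(1, _expit(logit3)), 0)

    lam = case.lambdas
    eps = rng.normal(0.0, coef.y_sd, size=n)
    base = coef.y_slope * x + lam[1] * u2 + lam[2] * u3 + eps
    patterns = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]
    potential = {p: base + lam[0] * u1_pot[:, p[0]] + case.effect * p[2]
                 for p in patterns}
    zmat = np.column_stack([z1, z2, z3])
    y = np.select([np.all(zmat == p, axis=1) for p in patterns],
                  [potential[p] for p in patterns])
    table = SubjectTable(ids=np.arange(n), running=x, z=zmat, y=y,
                         covariates=pd.DataFrame({"c": c}))
    truth = SimTruth(np.column_stack([u1, u2, u3]), u1_pot, potential)
    return table, truth


def generate_design2(case: SimCase,
                     coef: DGPCoefficients = DGPCoefficients()
                     ) -> tuple[SubjectTable, SimTruth]:
    """K = 2, two-sided non-compliance.

    Z_2 is drawn for everyone with a strong Z_1 main effect, so all four
    (Z_1, Z_2) patterns occur; the effect enters through Z_2.
    """
    if case.design != "design2":
        raise ConfigError("generate_design2 requires a design2 case")
    rng = np.random.default_rng(case.seed)
    n = case.n
    c = rng.binomial(2, 0.5, size=n)
    x = coef.x_cov * (c - 1) + rng.normal(0.0, coef.x_sd, size=n)
    z1 = (x >= 0.0).astype(int)
    v = rng.random(n)
    u1_pot = np.column_stack([(v < coef.u1_base).astype(int),
                              (v < coef.u1_base + coef.u1_gain).astype(int)])
    u1 = u1_pot[np.arange(n), z1]
    u2 = rng.integers(0, 2, size=n)

    logit2 = (coef.d2_intercept + coef.d2_z1 * z1 + coef.assign_cov * (c - 1)
              + coef.assign_unmeasured * (u2 - 0.5))
    z2 = rng.binomial(1, _expit(logit2))

    lam = case.lambdas
    eps = rng.normal(0.0, coef.y_sd, size=n)
    base = coef.y_slope * x + lam[1] * u2 + eps
    patterns = [(0, 0), (0, 1), (1, 0), (1, 1)]
    potential = {p: base + lam[0] * u1_pot[:, p[0]] + case.effect * p[1]
                 for p in patterns}
    zmat = np.column_stack([z1, z2])
    y = np.select([np.all(zmat == p, axis=1) for p in patterns],
                  [potential[p] for p in patterns])
    table = SubjectTable(ids=np.arange(n), running=x, z=zmat, y=y,
                         covariates=pd.DataFrame({"c": c}))
    truth = SimTruth(np.column_stack([u1, u2]), u1_pot, potential)
    return table, truth


DESIGN1_CASES: dict[int, tuple[float, float, float]] = {
    1: (0.0, 0.0, 0.0),
    2: (1.0, 0.0, 0.0),
    3: (0.0, 1.0, 0.0),
    4: (0.0, 0.0, 1.0),
    5: (1.0, 1.0, 0.0),
    6: (1.0, 0.0, 1.0),
    7: (0.0, 1.0, 1.0),
}


def design1_case(case_id: int, n: int = 500, effect: float = 0.0,
                 seed: int = 0, scale: float = 1.0) -> SimCase:
    """One of the seven Design-1 bias cases; ``scale`` rescales the
    nonzero lambda magnitudes."""
    if case_id not in DESIGN1_CASES:
        raise ConfigError(
            f"unknown design1 case {case_id}; valid cases are 1-7")
    lam = tuple(scale * v for v in DESIGN1_CASES[case_id])
    return SimCase("design1", n, lam, effect, seed, label=f"case{case_id}")


def design2_case(lambdas: tuple[float, float] = (0.0, 0.0), n: int = 500,
                 effect: float = 0.0, seed: int = 0) -> SimCase:
    return SimCase("design2", n, tuple(lambdas), effect, seed,
                   label="design2")


def _combined_pvalue(pvals: np.ndarray, q: int) -> float:
    """Fisher combination of the q largest p-values (chi-square 2q null)."""
    from scipy import stats
    top = np.sort(pvals)[len(pvals) - q:]
    h = float(-2.0 * np.log(top).sum())
    return max(float(stats.chi2.sf(h, df=2 * q)), np.finfo(float).tiny)


def _fast_pvalue(assignment: np.ndarray, y: np.ndarray,
                 strata: dict[int, np.ndarray], n_perm: int,
                 rng: np.random.Generator) -> float:
    """One-sided (greater) within-stratum permutation p, add-one MC."""
    strata_data, t_obs = _tilt.comparison_strata(assignment, y, strata)
    if not strata_data:
        return 1.0
    null = _tilt.mc_null_statistics(strata_data, n_perm, rng, gamma=1.0)
    return float((1 + np.sum(null >= t_obs - 1e-9)) / (n_perm + 1))


def _replicate_pvalues(table: SubjectTable, spec: DesignSpec,
                       window: tuple[float, float], n_perm: int,
                       rng: np.random.Generator) -> dict[str, float]:
    """EF and unconditioned p-values for one generated dataset."""
    strat = stratify(table)
    factors = build_factors(table, spec, strat, window, residualize=True)
    uncond = build_unconditioned(table, spec, strat, window, residualize=True)
    # residual trend removed with a full-sample fit; see design module notes
    y_resid = residualize_outcome(table.y, table.running)
    out: dict[str, float] = {}
    for comp in factors:
        y_local = (y_resid[comp.subjects] if comp.level == 1
                   else table.y[comp.subjects])
        out[f"p_{comp.level}"] = _fast_pvalue(
            comp.assignment, y_local, comp.strata.strata, n_perm, rng)
    out["pt_1"] = out["p_1"]      # level-1 unconditioned equals EF 1
    for comp in uncond[1:]:
        out[f"pt_{comp.level}"] = _fast_pvalue(
            comp.assignment, table.y[comp.subjects], comp.strata.strata,
            n_perm, rng)
    return out


@dataclass
class StudyResult:
    """Per-replicate p-values and the long-format rejection table."""

    pvalues: dict[str, pd.DataFrame]
    table: pd.DataFrame
    alpha: float
    replicates: int
    q_by_case: dict[str, int] = field(default_factory=dict)

    def rate(self, case: str, stat: str) -> float:
        sel = self.table[(self.table["case"] == case)
                         & (self.table["statistic"] == stat)]
        return float(sel["rejection_rate"].iloc[0])


def run_study(cases: Sequence[SimCase], replicates: int = 500,
              n_perm: int = 400, alpha: float = 0.05,
              window: tuple[float, float] = (-1.0, 1.0),
              seed: int = 0,
              coef: DGPCoefficients = DGPCoefficients(),
              q: int | None = None,
              reselect_window: bool = False,
              window_candidates: Sequence[float] = (0.5, 1.0, 1.5),
              ) -> StudyResult:
    """Rejection-rate study across the given cases.

    Per replicate: generate data, build the EF and unconditioned
    comparisons, compute each randomization p-value and the q-largest
    Fisher combinations (q follows the correctly-specified rule
    K - #biased levels unless overridden).  The level-1 window is fixed in
    advance by default; ``reselect_window`` re-runs the balance search per
    replicate.
    """
    from .design import select_window

    rows = []
    pvalue_frames: dict[str, pd.DataFrame] = {}
    q_by_case: dict[str, int] = {}
    for ci, case in enumerate(cases):
        K = case.K
        case_q = q if q is not None else case.q_rule
        q_by_case[case.label or f"case{ci}"] = case_q
        spec = _design1_spec() if case.design == "design1" else _design2_spec()
        gen = generate_design1 if case.design == "design1" else generate_design2
        records = []
        for rep in range(replicates):
            ss = np.random.SeedSequence([seed, ci, rep])
            gen_seed, perm_seed = (int(s) % (2 ** 31)
                                   for s in ss.generate_state(2))
            rep_case = SimCase(case.design, case.n, case.lambdas,
                               case.effect, gen_seed, case.label)
            table, _ = gen(rep_case, coef)
            rng = np.random.default_rng(perm_seed)
            win = window
            if reselect_window:
                win = select_window(table, spec, list(window_candidates),
                                    n_perm=200, seed=perm_seed).chosen
            ps = _replicate_pvalues(table, spec, win, n_perm, rng)
            ef = np.array([ps[f"p_{k}"] for k in range(1, K + 1)])
            un = np.array([ps[f"pt_{k}"] for k in range(1, K + 1)])
            ps["p_comb"] = _combined_pvalue(ef, case_q)
            ps["pt_comb"] = _combined_pvalue(un, case_q)
            records.append(ps)
        frame = pd.DataFrame.from_records(records)
        label = case.label or f"case{ci}"
        pvalue_frames[label] = frame
        for stat in frame.columns:
            rows.append({
                "case": label, "design": case.design,
                "lambdas": ",".join(f"{v:g}" for v in case.lambdas),
                "effect": case.effect, "statistic": stat,
                "rejection_rate": float((frame[stat] <= alpha).mean()),
                "alpha": alpha, "replicates": replicates, "q": case_q,
            })
    return StudyResult(pvalue_frames, pd.DataFrame(rows), alpha, replicates,
                       q_by_case)


def plot_rejection(table: pd.DataFrame, path: str) -> None:
    """Bar chart of rejection rates, EF vs unconditioned, per case."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cases = list(dict.fromkeys(table["case"]))
    fig, axes = plt.subplots(1, len(cases), figsize=(4 * len(cases), 3.2),
                             squeeze=False, sharey=True)
    for ax, case in zip(axes[0], cases):
        sub = table[table["case"] == case]
        stats_order = [s for s in sub["statistic"]]
        rates = sub["rejection_rate"].to_numpy()
        colors = ["tab:blue" if s.startswith("p_") else "tab:gray"
                  for s in stats_order]
        ax.bar(range(len(stats_order)), rates, color=colors)
        ax.set_xticks(range(len(stats_order)))
        ax.set_xticklabels(stats_order, rotation=60, fontsize=7)
        ax.axhline(float(sub["alpha"].iloc[0]), color="k", ls="--", lw=0.8)
        ax.set_title(case, fontsize=9)
    axes[0][0].set_ylabel("rejection rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
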