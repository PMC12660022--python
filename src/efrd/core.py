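"""Domain types, table I/O and structural validation.

The central object is a :class:`SubjectTable`: one row per subject, with a
running variable, a real outcome, ``K`` binary sequential treatment statuses
``Z_1..Z_K`` (eligibility, receipt, use, ...) and discrete covariates used
for exact stratification.  A :class:`DesignSpec` describes the discontinuity
design itself (cutoff, eligibility side, compliance type, window) and an
:class:`AnalysisConfig` the inferential knobs (permutation draws, the
conjectured number of valid factors ``q``, sensitivity grids, seeds).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("efrd")

__all__ = [
    "ConfigError",
    "DataError",
    "SubjectTable",
    "DesignSpec",
    "AnalysisConfig",
    "DesignReport",
    "read_table",
    "write_table",
    "validate_design",
    "admissible_patterns",
    "load_config",
]


class ConfigError(ValueError):
    """A configuration (spec/analysis settings) problem."""


class DataError(ValueError):
    """A subject-table content problem; carries offending row indices."""

    def __init__(self, message: str, rows: Sequence[int] = ()):  # noqa: D107
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class DesignSpec:
    """Structural description of the sequential fuzzy RD design.

    Parameters
    ----------
    K : int
        Number of sequential treatment assignment levels (>= 2; a single
        level is a sharp design, outside this tool's scope).
    compliance : {"one_sided", "two_sided"}
        Whether later statuses are nested in earlier ones (one-sided) or
        may be 1 for subjects with an earlier status 0 (two-sided).
    cutoff : float
        Cutoff ``c`` on the running variable.
    eligibility_direction : {"ge", "le"}
        Side of the cutoff that is eligible (``Z_1 = 1``).  Ties at the
        cutoff count as eligible.
    window : tuple (lo, hi), optional
        Local-randomization window around the cutoff for the level-1
        comparison; may be left unset and chosen later by balance search.
    balance_threshold : float
        Minimum covariate-balance p-value a candidate window must exceed.
    alpha : float
        Nominal test level used in reports and the simulation study.
    """

    K: int
    compliance: str = "one_sided"
    cutoff: float = 0.0
    eligibility_direction: str = "ge"
    window: tuple[float, float] | None = None
    balance_threshold: float = 0.15
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not isinstance(self.K, (int, np.integer)) or self.K < 2:
            raise ConfigError(
                f"K must be an integer >= 2 for a fuzzy design (got {self.K}); "
                "K = 1 is a sharp RD design and is not supported"
            )
        if self.compliance not in ("one_sided", "two_sided"):
            raise ConfigError(f"unknown compliance type {self.compliance!r}")
        if self.eligibility_direction not in ("ge", "le"):
            raise ConfigError(
                f"eligibility_direction must be 'ge' or 'le', got "
                f"{self.eligibility_direction!r}"
            )
        if self.window is not None:
            lo, hi = self.window
            if not (lo < self.cutoff < hi):
                raise ConfigError(
                    f"window ({lo}, {hi}) must strictly contain the cutoff "
                    f"{self.cutoff}"
                )
            object.__setattr__(self, "window", (float(lo), float(hi)))
        if not 0.0 < self.balance_threshold < 1.0:
            raise ConfigError("balance_threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class AnalysisConfig:
    """Inference settings shared across the pipeline.

    ``q`` is the conjectured minimum number of valid factors among the K
    comparisons; combination retains only the ``q`` largest p-values so the
    result stays valid when up to ``K - q`` factors are biased.
    ``gamma_grid`` maps a level (1-based) to the Γ values at which the
    sensitivity analysis bounds that factor's p-value.
    """

    q: int
    combiner: str = "fisher"
    truncation: float = 1.0
    n_perm: int = 2000
    null_draws: int = 100_000
    gamma_grid: Mapping[int, Sequence[float]] | None = None
    seed: int = 0
    alternative: str = "greater"

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ConfigError(f"q must be >= 1 (got {self.q})")
        if self.combiner not in ("fisher", "truncated_product"):
            raise ConfigError(f"unknown combiner {self.combiner!r}")
        if not 0.0 < self.truncation <= 1.0:
            raise ConfigError("truncation must lie in (0, 1]")
        if self.n_perm < 1 or self.null_draws < 1:
            raise ConfigError("n_perm and null_draws must be >= 1")
        if self.alternative not in ("greater", "less"):
            raise ConfigError("alternative must be 'greater' or 'less'")
        if self.gamma_grid is not None:
            for level, grid in self.gamma_grid.items():
                if any(g < 1.0 for g in grid):
                    raise ConfigError(
                        f"gamma grid for level {level} contains values < 1"
                    )

    def validate_against(self, spec: DesignSpec) -> None:
        if self.q > spec.K:
            raise ConfigError(f"q = {self.q} exceeds the design's K = {spec.K}")


@dataclass
class SubjectTable:
    """Rectangular subject data: running variable, covariates, Z_1..Z_K, Y."""

    ids: np.ndarray              # opaque labels, shape (n,)
    running: np.ndarray          # float, shape (n,)
    z: np.ndarray                # int {0,1}, shape (n, K)
    y: np.ndarray                # float, shape (n,)
    covariates: pd.DataFrame     # discrete codes, shape (n, p)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.running = np.asarray(self.running, dtype=float)
        self.z = np.asarray(self.z, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if self.z.ndim != 2:
            raise DataError("z must be a 2-D (n, K) array")
        n = len(self.ids)
        if not (len(self.running) == n == self.z.shape[0] == len(self.y)
                == len(self.covariates)):
            raise DataError("field lengths disagree")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def K(self) -> int:
        return self.z.shape[1]

    def check(self, spec: DesignSpec) -> None:
        """Raise :class:`DataError` on any type-invariant violation."""
        if self.K != spec.K:
            raise DataError(
                f"table has {self.K} treatment columns but design declares "
                f"K = {spec.K}"
            )
        if not np.all(np.isfinite(self.running)):
            rows = np.flatnonzero(~np.isfinite(self.running))
            raise DataError(f"non-finite running values at rows {rows.tolist()}",
                            rows)
        if not np.all(np.isfinite(self.y)):
            rows = np.flatnonzero(~np.isfinite(self.y))
            raise DataError(f"non-finite outcomes at rows {rows.tolist()}", rows)
        if not np.isin(self.z, (0, 1)).all():
            rows = np.flatnonzero(~np.isin(self.z, (0, 1)).all(axis=1))
            raise DataError(f"non-binary treatment statuses at rows "
                            f"{rows.tolist()}", rows)
        if spec.compliance == "one_sided":
            # z must be nonincreasing within each row: z_k = 1 requires
            # z_{k-1} = 1
            bad = np.flatnonzero((np.diff(self.z, axis=1) > 0).any(axis=1))
            if bad.size:
                raise DataError(
                    "one-sided compliance violated (some z_k = 1 with a prior "
                    f"status 0) at rows {bad.tolist()}", bad)

    def covariate_tuples(self) -> list[tuple]:
        return [tuple(row) for row in self.covariates.itertuples(index=False)]

    def to_frame(self, covariate_prefix: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "running": self.running})
        for k in range(self.K):
            df[f"z{k + 1}"] = self.z[:, k]
        df["outcome"] = self.y
        for col in self.covariates.columns:
            name = f"{covariate_prefix}{col}" if covariate_prefix else col
            df[name] = self.covariates[col].to_numpy()
        return df


DEFAULT_COLUMNS = {"id": "id", "running": "running", "outcome": "outcome"}


def read_table(path: str | Path, spec: DesignSpec,
               columns: Mapping[str, object] | None = None,
               sep: str | None = None) -> SubjectTable:
    """Read a delimited subject table and validate it against ``spec``.

    ``columns`` maps roles to column names: keys ``id``, ``running``,
    ``outcome``, ``z`` (a list of K names, default ``z1..zK``) and
    ``covariates`` (default: every remaining column).  Rows with a missing
    outcome or covariate are dropped with a logged count.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    z_cols = cols.get("z") or [f"z{k + 1}" for k in range(spec.K)]
    needed = [cols["id"], cols["running"], cols["outcome"], *z_cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"missing required column(s) {missing} in {path.name}")
    cov_cols = cols.get("covariates")
    if cov_cols is None:
        cov_cols = [c for c in df.columns if c not in needed]
    else:
        missing = [c for c in cov_cols if c not in df.columns]
        if missing:
            raise ConfigError(f"missing covariate column(s) {missing}")

    # drop rows with missing outcome or covariates, never impute
    keep = df[cols["outcome"]].notna()
    for c in cov_cols:
        keep &= df[c].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d row(s) with missing outcome/covariates",
                       dropped)
        df = df[keep].reset_index(drop=True)

    table = SubjectTable(
        ids=df[cols["id"]].to_numpy(),
        running=df[cols["running"]].to_numpy(dtype=float),
        z=df[z_cols].to_numpy(),
        y=df[cols["outcome"]].to_numpy(dtype=float),
        covariates=df[cov_cols].copy(),
    )
    table.check(spec)
    return table


def write_table(table: SubjectTable, path: str | Path,
                sep: str | None = None) -> None:
    """Write a subject table back to delimited text (inverse of read_table)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    table.to_frame().to_csv(path, sep=sep, index=False)


def admissible_patterns(K: int, compliance: str) -> list[tuple[int, ...]]:
    """Treatment-status vectors attainable under the compliance regime.

    One-sided compliance nests the statuses, so only the K + 1 nonincreasing
    patterns (e.g. 000, 100, 110, 111 for K = 3) can occur; two-sided allows
    all 2^K patterns.
    """
    if compliance == "one_sided":
        return [tuple([1] * j + [0] * (K - j)) for j in range(K + 1)]
    from itertools import product
    return [tuple(p) for p in product((0, 1), repeat=K)]


@dataclass
class DesignReport:
    """Structural summary: status-pattern cells and per-factor arm sizes."""

    pattern_counts: dict[tuple[int, ...], int]
    factor_arms: dict[int, tuple[int, int]]   # level -> (n_control, n_treat)
    warnings: list[str] = field(default_factory=list)

    @property
    def nonempty_cells(self) -> int:
        return sum(1 for c in self.pattern_counts.values() if c > 0)

    def to_dict(self) -> dict:
        return {
            "pattern_counts": {"".join(map(str, k)): v
                               for k, v in self.pattern_counts.items()},
            "factor_arms": {str(k): list(v) for k, v in self.factor_arms.items()},
            "warnings": list(self.warnings),
        }


def validate_design(table: SubjectTable, spec: DesignSpec) -> DesignReport:
    """Report group sizes per status pattern and per evidence factor.

    Purely structural: the causal assumptions (sequential assignment with no
    unmeasured common causes among the statuses) are untestable from data
    and are surfaced as a documented warning only.
    """
    table.check(spec)
    patterns = admissible_patterns(spec.K, spec.compliance)
    observed = [tuple(row) for row in table.z]
    counts = {p: 0 for p in patterns}
    for p in observed:
        counts[p] = counts.get(p, 0) + 1

    warnings: list[str] = []
    factor_arms: dict[int, tuple[int, int]] = {}
    for k in range(1, spec.K + 1):
        if k == 1:
            mask = np.ones(table.n, dtype=bool)
        else:
            mask = (table.z[:, : k - 1] == 1).all(axis=1)
        zk = table.z[mask, k - 1]
        n_t, n_c = int((zk == 1).sum()), int((zk == 0).sum())
        factor_arms[k] = (n_c, n_t)
        if n_t == 0:
            warnings.append(f"EF {k} has an empty treatment arm")
        if n_c == 0:
            warnings.append(f"EF {k} has an empty control arm")
    warnings.append(
        "structural check only: sequential assignment with no unmeasured "
        "common causes among treatment statuses cannot be verified from data"
    )
    return DesignReport(counts, factor_arms, warnings)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def design_spec_from_dict(d: Mapping) -> DesignSpec:
    fields = {f.name for f in dataclasses.fields(DesignSpec)}
    kwargs = {k: v for k, v in d.items() if k in fields}
    if "window" in kwargs and kwargs["window"] is not None:
        kwargs["window"] = tuple(kwargs["window"])
    return DesignSpec(**kwargs)


def analysis_config_from_dict(d: Mapping) -> AnalysisConfig:
    fields = {f.name for f in dataclasses.fields(AnalysisConfig)}
    kwargs = {k: v for k, v in d.items() if k in fields}
    if kwargs.get("gamma_grid"):
        kwargs["gamma_grid"] = {int(k): list(map(float, v))
                                for k, v in kwargs["gamma_grid"].items()}
    return AnalysisConfig(**kwargs)
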