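"""Model specification and design-matrix construction.

A relative-risk model is declared, not fitted: the user supplies covariate
definitions (continuous, or categorical with an ordered list of levels),
optional interaction terms, and one log relative risk per design column,
typically taken from published cohort or case-control analyses.

Column conventions (these make externally supplied coefficient files
unambiguous):

* a continuous covariate contributes one column named after itself;
* a K-level categorical contributes K-1 indicator columns against its first
  declared (reference) level, named ``name[level]`` in declared level order;
* an interaction contributes the elementwise products of its factors'
  columns, named by joining the factor column names with ``:`` (first factor
  varying slowest);
* main effects appear in covariate declaration order, then interactions in
  declaration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = ["Covariate", "ModelSpec", "build_design_matrix"]


@dataclass(frozen=True)
class Covariate:
    """A declared risk factor: ``kind`` is ``'continuous'`` or ``'categorical'``.

    For categoricals ``levels`` is the ordered list of admissible values; the
    first level is the reference.
    """

    name: str
    kind: str
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 1:
                raise ValueError(f"categorical covariate {self.name!r} needs levels")
            object.__setattr__(self, "levels", tuple(self.levels))
        elif self.levels is not None:
            raise ValueError(f"continuous covariate {self.name!r} cannot have levels")

    @property
    def columns(self) -> list[str]:
        if self.kind == "continuous":
            return [self.name]
        return [f"{self.name}[{lvl}]" for lvl in self.levels[1:]]


@dataclass
class ModelSpec:
    """Covariate declarations, interactions and log relative risks.

    ``log_relative_risks`` maps every design column to its log hazard ratio
    (log odds ratios are accepted interchangeably under the rare-disease
    approximation). ``family_history`` optionally names a binary 0/1
    covariate whose coefficient may be attenuated when SNPs are added.
    """

    covariates: list[Covariate]
    log_relative_risks: dict[str, float]
    interactions: list[tuple[str, ...]] = field(default_factory=list)
    family_history: str | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        self._by_name = {c.name: c for c in self.covariates}
        self.interactions = [tuple(t) for t in self.interactions]
        for term in self.interactions:
            for nm in term:
                if nm not in self._by_name:
                    raise ValueError(f"interaction references unknown covariate {nm!r}")
        if self.family_history is not None:
            fh = self._by_name.get(self.family_history)
            if fh is None:
                raise ValueError(
                    f"family_history covariate {self.family_history!r} not declared"
                )
        cols = set(self.design_columns())
        got = set(self.log_relative_risks)
        if cols != got:
            missing = sorted(cols - got)
            extra = sorted(got - cols)
            raise ValueError(
                "log_relative_risks must have exactly one entry per design column; "
                f"missing {missing}, unexpected {extra}"
            )

    def covariate(self, name: str) -> Covariate:
        return self._by_name[name]

    def design_columns(self) -> list[str]:
        cols: list[str] = []
        for cov in self.covariates:
            cols.extend(cov.columns)
        for term in self.interactions:
            factor_cols = [self._by_name[nm].columns for nm in term]
            cols.extend(":".join(combo) for combo in product(*factor_cols))
        return cols

    def beta(self) -> np.ndarray:
        """Coefficient vector aligned with :meth:`design_columns`."""
        return np.array(
            [self.log_relative_risks[c] for c in self.design_columns()], dtype=float
        )

    def column_covariates(self) -> dict[str, tuple[str, ...]]:
        """Map design column -> covariate names it references (for missing-data
        partitioning: a column is observable iff all of these are observed)."""
        out: dict[str, tuple[str, ...]] = {}
        for cov in self.covariates:
            for col in cov.columns:
                out[col] = (cov.name,)
        for term in self.interactions:
            factor_cols = [self._by_name[nm].columns for nm in term]
            for combo in product(*factor_cols):
                out[":".join(combo)] = tuple(term)
        return out

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelSpec":
        covs = [
            Covariate(
                name=c["name"],
                kind=c.get("type", c.get("kind")),
                levels=tuple(c["levels"]) if c.get("levels") is not None else None,
            )
            for c in d["covariates"]
        ]
        return cls(
            covariates=covs,
            log_relative_risks={k: float(v) for k, v in d["log_relative_risks"].items()},
            interactions=[tuple(t) for t in d.get("interactions", [])],
            family_history=d.get("family_history_name"),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "covariates": [
                {
                    "name": c.name,
                    "type": c.kind,
                    **({"levels": list(c.levels)} if c.levels else {}),
                }
                for c in self.covariates
            ],
            "interactions": [list(t) for t in self.interactions],
            "log_relative_risks": dict(self.log_relative_risks),
            "family_history_name": self.family_history,
        }


def _covariate_columns(
    cov: Covariate, values: pd.Series, allow_missing: bool
) -> pd.DataFrame:
    miss = values.isna()
    if miss.any() and not allow_missing:
        raise ValueError(
            f"covariate {cov.name!r} has missing values in rows "
            f"{list(values.index[miss])[:10]}; route missing profiles through "
            "the imputation machinery"
        )
    if cov.kind == "continuous":
        out = pd.DataFrame({cov.name: pd.to_numeric(values, errors="raise")})
        return out.astype(float)
    cat = pd.Categorical(values[~miss], categories=list(cov.levels))
    if (cat.codes < 0).any():
        bad = sorted({str(v) for v, c in zip(values[~miss], cat.codes) if c < 0})
        raise ValueError(
            f"covariate {cov.name!r}: values {bad} not among declared levels "
            f"{list(cov.levels)}"
        )
    codes = np.full(len(values), -1, dtype=int)
    codes[~miss.to_numpy()] = cat.codes
    out = pd.DataFrame(index=values.index)
    for k, lvl in enumerate(cov.levels[1:], start=1):
        col = (codes == k).astype(float)
        col[codes < 0] = np.nan
        out[f"{cov.name}[{lvl}]"] = col
    return out


def build_design_matrix(
    spec: ModelSpec, data: pd.DataFrame, missing: str = "error"
) -> pd.DataFrame:
    """Design matrix for ``data`` under ``spec``, columns per the module rules.

    ``missing='error'`` (default) rejects missing covariate values.
    ``missing='nan'`` propagates them: every design column referencing a
    missing covariate is NaN in that row (indicators of an unobserved
    categorical are all NaN, and interactions are NaN whenever any factor is,
    even if an observed factor is zero).
    """
    if missing not in ("error", "nan"):
        raise ValueError("missing must be 'error' or 'nan'")
    for cov in spec.covariates:
        if cov.name not in data.columns:
            raise ValueError(f"data lacks covariate column {cov.name!r}")
    parts = [
        _covariate_columns(cov, data[cov.name], missing == "nan")
        for cov in spec.covariates
    ]
    main = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=data.index)
    out = main.copy()
    missing_cov = pd.DataFrame(
        {cov.name: data[cov.name].isna() for cov in spec.covariates}, index=data.index
    )
    for term in spec.interactions:
        factor_cols = [spec.covariate(nm).columns for nm in term]
        any_missing = missing_cov[list(term)].any(axis=1).to_numpy()
        for combo in product(*factor_cols):
            prod_col = np.ones(len(data))
            for c in combo:
                prod_col = prod_col * main[c].to_numpy()
            prod_col[any_missing] = np.nan
            out[":".join(combo)] = prod_col
    return out[spec.design_columns()]
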