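"""Age-indexed event-rate tables.

Registries publish disease incidence and all-cause mortality as rates per
person-year on age strata (single-year or coarser). Internally every
computation runs on a per-integer-age grid, so tables are expanded by
piecewise-constant interpolation: each integer age inherits the rate of the
stratum that contains it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RateTable", "CoverageError", "expand_rate_table"]


class CoverageError(ValueError):
    """Raised when rate strata do not cover (or overlap on) a requested age range."""


@dataclass(frozen=True)
class RateTable:
    """Event rates on inclusive integer-age strata.

    Parameters
    ----------
    age_start, age_end
        Inclusive integer bounds of each stratum.
    rate
        Probability of the event per person-year in the stratum; must lie in
        ``[0, 1)``.
    """

    age_start: np.ndarray
    age_end: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.age_start, dtype=int)
        end = np.asarray(self.age_end, dtype=int)
        rate = np.asarray(self.rate, dtype=float)
        if not (start.shape == end.shape == rate.shape) or start.ndim != 1:
            raise ValueError("age_start, age_end and rate must be 1-d and equal length")
        if start.size == 0:
            raise ValueError("rate table is empty")
        if np.any(end < start):
            raise ValueError("age_end must be >= age_start in every stratum")
        if np.any(~np.isfinite(rate)) or np.any(rate < 0) or np.any(rate >= 1):
            raise ValueError("rates must be finite, >= 0 and < 1")
        order = np.argsort(start, kind="stable")
        object.__setattr__(self, "age_start", start[order])
        object.__setattr__(self, "age_end", end[order])
        object.__setattr__(self, "rate", rate[order])
        # overlap check on the sorted strata
        covered: dict[int, int] = {}
        for i, (a, b) in enumerate(zip(self.age_start, self.age_end)):
            for age in range(int(a), int(b) + 1):
                if age in covered:
                    raise ValueError(
                        f"overlapping strata: age {age} covered by strata "
                        f"{covered[age]} and {i}"
                    )
                covered[age] = i

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RateTable":
        cols = {"age_start", "age_end", "rate"}
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        return cls(
            df["age_start"].to_numpy(), df["age_end"].to_numpy(), df["rate"].to_numpy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_start": self.age_start, "age_end": self.age_end, "rate": self.rate}
        )

    @property
    def min_age(self) -> int:
        return int(self.age_start.min())

    @property
    def max_age(self) -> int:
        return int(self.age_end.max())

    def expand(self, age_min: int, age_max: int) -> np.ndarray:
        """Per-age rate vector for integer ages ``age_min..age_max`` (inclusive)."""
        return expand_rate_table(self, (age_min, age_max))


def expand_rate_table(table: RateTable, age_range: tuple[int, int]) -> np.ndarray:
    """Expand strata to a vector with one rate per integer age.

    Each integer age in ``age_range`` (inclusive bounds) receives the rate of
    the stratum containing it. A gap in coverage raises :class:`CoverageError`
    naming the uncovered ages.
    """
    lo, hi = int(age_range[0]), int(age_range[1])
    if hi < lo:
        raise ValueError("empty age range")
    ages = np.arange(lo, hi + 1)
    out = np.full(ages.shape, np.nan)
    for a, b, r in zip(table.age_start, table.age_end, table.rate):
        mask = (ages >= a) & (ages <= b)
        out[mask] = r
    uncovered = ages[np.isnan(out)]
    if uncovered.size:
        raise CoverageError(
            f"rate table does not cover ages {uncovered.min()}-{uncovered.max()}: "
            f"missing ages {uncovered.tolist()}"
        )
    return out
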