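"""Synthetic cohorts, nested case-control samples and reference datasets.

The generator reproduces the statistical structure used to exercise the
validation machinery: disease onset ages follow a Cox model with a Weibull
baseline hazard lambda_0(t) = lambda * gamma * t^(gamma-1) (defaults
lambda = 0.9e-6, gamma = 2.15 — a rate profile typical of female breast
cancer), covariates act multiplicatively through declared log relative
risks, study entry is discrete-uniform on 50..72 years and observed
follow-up discrete-uniform on 5..13 years. SNP genotypes are drawn under
HWE, conditional on family history when the model includes it. A nested
case-control subsample is then selected by a logistic model of inclusion on
case status, entry age and follow-up (with interactions), default
coefficients (-6.52, 8.47, 0.05, 0.11, -0.09, 0.04) — nearly all cases and
a small fraction of controls.

Onset ages are drawn by inverse transform from the cumulative hazard
Lambda(t|Z) = lambda * t^gamma * exp(beta'Z):

    T = ( -log(U) / (lambda * exp(beta'Z)) )^(1/gamma).

Onset is continuous; entry/exit are integers. Subjects already diseased at
entry (prevalent cases) are excluded and redrawn, since absolute-risk
prediction conditions on being disease-free at the interval start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design_matrix
from .snps import SnpInfo, simulate_reference_genotypes
from .validation import COLUMNS

__all__ = [
    "SimulationConfig",
    "DEFAULT_SELECTION_COEFFICIENTS",
    "simulate_reference",
    "simulate_onset_ages",
    "simulate_cohort",
    "select_nested_case_control",
    "weibull_yearly_baseline",
]


def weibull_yearly_baseline(
    lam: float, gamma: float, ages: np.ndarray
) -> np.ndarray:
    """Per-integer-age baseline hazard matching the continuous Weibull.

    The value at age t is the increment of the Weibull cumulative baseline
    hazard lambda * t^gamma over [t, t+1), so a piecewise-constant-per-year
    model built on this grid has exactly the continuous model's cumulative
    hazard at integer ages — the discrete counterpart of the generator's
    baseline.
    """
    a = np.asarray(ages, dtype=float)
    return lam * ((a + 1.0) ** gamma - a**gamma)

#: (intercept, outcome, entry age, follow-up, outcome x entry, outcome x follow-up)
DEFAULT_SELECTION_COEFFICIENTS = (-6.52, 8.47, 0.05, 0.11, -0.09, 0.04)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int
    spec: ModelSpec | None = None
    reference: pd.DataFrame | None = None        # resampled for covariates
    snps: SnpInfo | None = None
    weibull_lambda: float = 0.9e-6
    weibull_gamma: float = 2.15
    entry_age_range: tuple[int, int] = (50, 72)
    followup_range: tuple[int, int] = (5, 13)
    selection_coefficients: tuple[float, ...] = DEFAULT_SELECTION_COEFFICIENTS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weibull_lambda <= 0 or self.weibull_gamma <= 0:
            raise ValueError("Weibull parameters must be positive")
        for rng_ in (self.entry_age_range, self.followup_range):
            if rng_[1] < rng_[0]:
                raise ValueError("ranges must be non-empty")
        if (self.spec is None) != (self.reference is None):
            raise ValueError("spec and reference must be supplied together")
        if self.spec is None and self.snps is None:
            raise ValueError("simulation needs covariates, SNPs or both")


def simulate_reference(
    marginals: list[dict],
    n: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Reference dataset with independent covariates from declared marginals.

    Each entry of ``marginals`` is either
    ``{"name", "type": "categorical", "levels": [...], "probs": [...]}`` or
    ``{"name", "type": "continuous", "mean": m, "sd": s}`` (Gaussian).
    Correlated covariates should instead be supplied as an empirical
    reference dataset; independence here is a deliberate simplification.
    """
    rng = np.random.default_rng(rng)
    cols = {}
    for m in marginals:
        name, kind = m["name"], m.get("type", m.get("kind"))
        if kind == "categorical":
            levels = list(m["levels"])
            probs = np.asarray(m["probs"], dtype=float)
            if probs.size != len(levels):
                raise ValueError(f"{name}: probs must match levels")
            if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
                raise ValueError(f"{name}: probabilities must be >= 0 and sum to 1")
            idx = rng.choice(len(levels), size=n, p=probs)
            cols[name] = np.asarray(levels, dtype=object)[idx]
        elif kind == "continuous":
            cols[name] = rng.normal(m.get("mean", 0.0), m.get("sd", 1.0), size=n)
        else:
            raise ValueError(f"{name}: unknown marginal type {kind!r}")
    return pd.DataFrame(cols)


def simulate_onset_ages(
    linear_predictor: np.ndarray,
    weibull_lambda: float,
    weibull_gamma: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Continuous disease-onset ages via inverse transform of the Weibull-Cox
    cumulative hazard."""
    rng = np.random.default_rng(rng)
    lp = np.asarray(linear_predictor, dtype=float)
    u = rng.random(lp.shape)
    return (-np.log(u) / (weibull_lambda * np.exp(lp))) ** (1.0 / weibull_gamma)


def _draw_covariates_and_lp(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    parts = []
    lp = np.zeros(n)
    if config.spec is not None:
        idx = rng.integers(0, len(config.reference), size=n)
        covs = config.reference.iloc[idx].reset_index(drop=True)
        design = build_design_matrix(config.spec, covs, missing="error")
        lp = lp + design.to_numpy() @ config.spec.beta()
        parts.append(covs)
    if config.snps is not None:
        fh = None
        if config.spec is not None and config.spec.family_history is not None:
            fh = pd.to_numeric(covs[config.spec.family_history]).to_numpy().astype(int)
        geno = simulate_reference_genotypes(
            config.snps, n_subjects=n, fh_status=fh, n_imputations=1, rng=rng
        )[0]
        lp = lp + geno.astype(float) @ config.snps.log_odds_ratio
        parts.append(pd.DataFrame(geno, columns=list(config.snps.names)))
    return pd.concat(parts, axis=1), lp


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Simulate a cohort under the Weibull-Cox model of the module docstring.

    Returns one row per subject with ``id``, ``study.entry.age``,
    ``study.exit.age``, ``time.of.onset`` (continuous onset age, possibly
    beyond exit), ``observed.outcome`` (onset within [entry, exit]),
    ``observed.followup`` and the covariate/genotype columns. Prevalent
    cases (onset before entry) are redrawn so the cohort has exactly
    ``n_subjects`` at-risk members.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n_target = config.n_subjects
    chunks: list[pd.DataFrame] = []
    n_have = 0
    while n_have < n_target:
        n_draw = max(int(1.05 * (n_target - n_have)) + 16, 32)
        covs, lp = _draw_covariates_and_lp(config, n_draw, rng)
        entry = rng.integers(
            config.entry_age_range[0], config.entry_age_range[1] + 1, size=n_draw
        )
        fu = rng.integers(
            config.followup_range[0], config.followup_range[1] + 1, size=n_draw
        )
        onset = simulate_onset_ages(
            lp, config.weibull_lambda, config.weibull_gamma, rng
        )
        keep = onset > entry  # exclude prevalent cases
        chunk = covs.loc[keep].reset_index(drop=True)
        chunk[COLUMNS["entry"]] = entry[keep]
        chunk[COLUMNS["exit"]] = entry[keep] + fu[keep]
        chunk[COLUMNS["onset"]] = onset[keep]
        chunk[COLUMNS["followup"]] = fu[keep]
        chunk["linear.predictor.true"] = lp[keep]
        chunks.append(chunk)
        n_have += int(keep.sum())
    cohort = pd.concat(chunks, ignore_index=True).iloc[:n_target].copy()
    cohort[COLUMNS["outcome"]] = (
        cohort[COLUMNS["onset"]] <= cohort[COLUMNS["exit"]]
    ).astype(int)
    cohort.insert(0, COLUMNS["id"], np.arange(1, n_target + 1))
    return cohort


def selection_probabilities(
    cohort: pd.DataFrame, coefficients: tuple[float, ...] = DEFAULT_SELECTION_COEFFICIENTS
) -> np.ndarray:
    """True inclusion probabilities under the logistic selection model."""
    y = cohort[COLUMNS["outcome"]].to_numpy(float)
    a = cohort[COLUMNS["entry"]].to_numpy(float)
    f = (
        cohort[COLUMNS["followup"]].to_numpy(float)
        if COLUMNS["followup"] in cohort.columns
        else cohort[COLUMNS["exit"]].to_numpy(float) - a
    )
    X = np.column_stack([np.ones_like(y), y, a, f, y * a, y * f])
    lin = X @ np.asarray(coefficients, dtype=float)
    return 1.0 / (1.0 + np.exp(-lin))


def select_nested_case_control(
    cohort: pd.DataFrame,
    coefficients: tuple[float, ...] = DEFAULT_SELECTION_COEFFICIENTS,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the nested case-control subsample.

    Inclusion is Bernoulli with the logistic selection probabilities.
    Returns ``(cohort_with_inclusion, subsample)``: the cohort copy gains
    ``inclusion`` and ``true.selection.prob`` columns; the subsample keeps
    both, so the true probabilities can serve as oracle sampling weights.
    """
    rng = np.random.default_rng(rng)
    prob = selection_probabilities(cohort, coefficients)
    inclusion = (rng.random(len(cohort)) < prob).astype(int)
    out = cohort.copy()
    out[COLUMNS["inclusion"]] = inclusion
    out["true.selection.prob"] = prob
    sub = out[out[COLUMNS["inclusion"]] == 1].reset_index(drop=True)
    return out, sub
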