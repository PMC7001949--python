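"""Baseline-hazard calibration to marginal incidence rates.

Under the proportional-hazards model lambda(t|Z) = lambda_0(t) exp(beta'Z),
the registry (marginal) incidence rate satisfies

    lambda_m(t) = lambda_0(t) * E[exp(beta'Z) | T >= t],

where the conditional distribution of Z among survivors tilts the population
risk-factor distribution F(Z) by each profile's disease-free survival. The
calibration inverts this relationship on a per-integer-age grid: iteration 0
applies the rare-disease approximation

    lambda_0(t) = lambda_m(t) / mean_w[exp(beta'Z_j)],

and each subsequent pass re-weights reference rows j by

    w_j * exp(-sum_{u<t} lambda_0(u) exp(beta'z_j)),

i.e. survival from the disease hazard alone, then recomputes
lambda_0(t) = lambda_m(t) / E_w[exp(beta'Z) | T >= t]. Fixed-point iteration
stops when the maximum relative change over ages drops below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BaselineHazard", "estimate_baseline_hazard", "marginal_rates_from_model"]


@dataclass(frozen=True)
class BaselineHazard:
    """Per-integer-age baseline hazard over ``ages`` (inclusive grid)."""

    ages: np.ndarray
    values: np.ndarray
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be 1-d and equal length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers")
        if np.any(values < 0):
            raise ValueError("baseline hazard must be non-negative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def slice(self, age_start: int, age_stop: int) -> np.ndarray:
        """Values for integer ages ``age_start..age_stop`` inclusive."""
        if age_start < self.min_age or age_stop > self.max_age:
            raise ValueError(
                f"ages {age_start}-{age_stop} outside hazard coverage "
                f"{self.min_age}-{self.max_age}"
            )
        i = age_start - self.min_age
        return self.values[i : i + (age_stop - age_start) + 1]


def _normalized_weights(n: int, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights length must match reference rows")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("reference weights must be positive and finite")
    return w / w.sum()


def _survivor_mean_rr(
    rr: np.ndarray, w: np.ndarray, cum_lam0: np.ndarray, block: int = 65_536
) -> np.ndarray:
    """E_w[exp(beta'Z) | T >= t] per age, with survivor weights
    w_j * exp(-rr_j * cumulative lambda_0). Blocked over reference rows to
    bound memory for large references."""
    num = np.zeros(cum_lam0.size)
    den = np.zeros(cum_lam0.size)
    for lo in range(0, rr.size, block):
        sl = slice(lo, lo + block)
        surv = np.exp(-np.outer(rr[sl], cum_lam0)) * w[sl, None]
        den += surv.sum(axis=0)
        num += (surv * rr[sl, None]).sum(axis=0)
    return num / den


def estimate_baseline_hazard(
    beta: np.ndarray,
    ref_design: np.ndarray,
    disease_rates: np.ndarray,
    ages: np.ndarray,
    ref_weights: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> BaselineHazard:
    """Calibrate lambda_0(t) so the model reproduces ``disease_rates``.

    Parameters
    ----------
    beta
        Log relative risks aligned with ``ref_design`` columns.
    ref_design
        Reference-population design matrix (rows are representative profiles,
        complete, no missing values).
    disease_rates
        Marginal incidence rate per integer age on the ``ages`` grid.
    ages
        Consecutive integer ages covered by ``disease_rates``. Survivor
        re-weighting accumulates hazard from ``ages[0]`` onward.
    ref_weights
        Optional positive sampling weights for the reference rows; all
        expectations over the reference are weight-aware.
    tol, max_iter
        Fixed-point stopping rule: maximum relative change below ``tol``, or
        ``max_iter`` passes (``converged`` flag reports which).
    """
    beta = np.asarray(beta, dtype=float)
    design = np.atleast_2d(np.asarray(ref_design, dtype=float))
    rates = np.asarray(disease_rates, dtype=float)
    ages = np.asarray(ages, dtype=int)
    if rates.shape != ages.shape:
        raise ValueError("disease_rates and ages must have equal length")
    if design.shape[1] != beta.size:
        raise ValueError("ref_design columns must align with beta")
    if np.any(np.isnan(design)):
        raise ValueError("reference design contains missing values")
    w = _normalized_weights(design.shape[0], ref_weights)
    with np.errstate(over="ignore"):
        rr = np.exp(design @ beta)
    if np.any(~np.isfinite(rr)):
        raise ValueError("non-finite relative risk exp(beta'Z) in reference")

    lam0 = rates / np.sum(w * rr)  # rare-disease initialization
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        cum = np.concatenate([[0.0], np.cumsum(lam0)[:-1]])
        denom = _survivor_mean_rr(rr, w, cum)
        new = rates / denom
        scale = np.where(lam0 > 0, lam0, 1.0)
        delta = np.max(np.abs(new - lam0) / scale)
        lam0 = new
        if delta < tol:
            converged = True
            break
    if np.any(~np.isfinite(lam0)) or np.any(lam0 < 0):
        raise ValueError("calibrated baseline hazard is negative or undefined")
    return BaselineHazard(ages=ages, values=lam0, n_iter=n_iter, converged=converged)


def marginal_rates_from_model(
    lambda0: BaselineHazard,
    beta: np.ndarray,
    ref_design: np.ndarray,
    ref_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Forward map: marginal incidence rates implied by lambda_0, beta and F(Z).

    The exact inverse of :func:`estimate_baseline_hazard`; useful for
    consistency checks and for generating rate tables that match a simulated
    population.
    """
    beta = np.asarray(beta, dtype=float)
    design = np.atleast_2d(np.asarray(ref_design, dtype=float))
    w = _normalized_weights(design.shape[0], ref_weights)
    rr = np.exp(design @ beta)
    lam0 = np.asarray(lambda0.values, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(lam0)[:-1]])
    return lam0 * _survivor_mean_rr(rr, w, cum)
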