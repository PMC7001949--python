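"""Model-free imputation of missing covariates on the risk-score scale.

Because absolute risk depends on the covariates only through the scalar risk
score R = beta'Z, missingness can be handled without modelling the joint
covariate distribution. The score is partitioned R = R_obs + R_unobs over
design columns: a column is observable iff every covariate it references
(including all interaction factors) is observed. The reference dataset's
scores, recomputed under the same missing pattern (masked to the observed
columns), are cut into equal-probability percentile strata; the profile's
observable score is matched to a stratum, donors are drawn from it with
replacement (reference weights act as sampling probabilities), and each
donor's unobservable score component completes the profile. The final risk
averages the absolute risks of the completed scores — a hot-deck multiple
imputation on the risk-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design_matrix

__all__ = [
    "PartitionedRiskScore",
    "PercentileStrata",
    "partition_design_row",
    "build_percentile_strata",
    "impute_linear_predictors",
    "impute_linear_predictors_with_donors",
    "impute_risk",
]


@dataclass(frozen=True)
class PartitionedRiskScore:
    """Observable component of a risk score and its missing pattern."""

    observable_score: float
    missing_columns: tuple[str, ...]
    design_row: pd.Series  # NaN in the unobservable columns


@dataclass(frozen=True)
class PercentileStrata:
    """Equal-probability bins of reference observable scores.

    ``cutpoints`` are the upper cut-points of bins ``0..n_bins-2`` (weighted
    quantiles at k/n_bins); the last bin is unbounded above. A score belongs
    to the lowest bin whose upper cut-point is >= the score (ties go to the
    lower bin). ``assignments`` holds the bin of each reference row.
    """

    cutpoints: np.ndarray
    assignments: np.ndarray
    n_bins: int

    def assign(self, scores: np.ndarray) -> np.ndarray:
        """Bin index for each score, snapped to the nearest non-empty bin.

        Degenerate references (e.g. all scores tied) leave some bins without
        members; matching snaps to the closest populated bin, preferring the
        lower one, so a matched stratum is never empty.
        """
        raw = np.searchsorted(self.cutpoints, np.asarray(scores, dtype=float),
                              side="left")
        populated = np.unique(self.assignments)
        pos = np.searchsorted(populated, raw)
        pos_lo = np.clip(pos - 1, 0, populated.size - 1)
        pos_hi = np.clip(pos, 0, populated.size - 1)
        lo, hi = populated[pos_lo], populated[pos_hi]
        exact = np.isin(raw, populated)
        take_hi = (hi - raw) < (raw - lo)  # strictly closer above; ties -> lower
        snapped = np.where(take_hi, hi, lo)
        return np.where(exact, raw, snapped)

    def members(self, bin_index: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == bin_index)


def partition_design_row(
    profile: pd.Series | pd.DataFrame,
    spec: ModelSpec,
    beta: np.ndarray,
) -> PartitionedRiskScore:
    """Split a (possibly incomplete) profile's risk score into observable and
    unobservable parts. An all-missing profile has observable score 0 and
    every column in the pattern."""
    frame = profile.to_frame().T if isinstance(profile, pd.Series) else profile
    if len(frame) != 1:
        raise ValueError("partition_design_row expects a single profile row")
    design = build_design_matrix(spec, frame, missing="nan")
    row = design.iloc[0]
    beta = np.asarray(beta, dtype=float)
    observed = ~row.isna().to_numpy()
    score = float(np.nansum(beta[observed] * row.to_numpy()[observed])) if observed.any() else 0.0
    return PartitionedRiskScore(
        observable_score=score,
        missing_columns=tuple(row.index[~observed]),
        design_row=row,
    )


def build_percentile_strata(
    scores: np.ndarray,
    weights: np.ndarray | None = None,
    n_bins: int = 100,
) -> PercentileStrata:
    """Cut reference observable scores into ``n_bins`` weighted-quantile bins.

    Cut-points are the left-continuous inverse of the (weighted) empirical
    distribution at k/n_bins. With fewer distinct scores than bins, bins
    collapse onto the distinct order statistics.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty reference")
    if np.any(~np.isfinite(scores)):
        raise ValueError("reference scores must be finite")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins == 1:
        cut = np.empty(0)
    else:
        probs = np.arange(1, n_bins) / n_bins
        if weights is None:
            cut = np.quantile(scores, probs, method="inverted_cdf")
        else:
            w = np.asarray(weights, dtype=float)
            cut = np.quantile(scores, probs, weights=w, method="inverted_cdf")
    cut = np.asarray(cut, dtype=float)
    assignments = np.searchsorted(cut, scores, side="left")
    return PercentileStrata(cutpoints=cut, assignments=assignments, n_bins=n_bins)


def impute_linear_predictors_with_donors(
    profile_design: pd.DataFrame,
    beta: np.ndarray,
    ref_design: np.ndarray,
    ref_weights: np.ndarray | None = None,
    n_bins: int = 100,
    n_imputations: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hot-deck completion of risk scores for a batch of design rows.

    ``profile_design`` holds NaN in unobservable columns (as produced by
    ``build_design_matrix(..., missing='nan')``); ``ref_design`` is the
    complete reference design matrix with matching column order.

    Returns ``(lp_draws, reported_lp, donors)``: ``lp_draws`` has shape
    ``(n_profiles, n_imputations)`` with the completed linear predictors
    (complete rows repeat their exact score); ``reported_lp`` is the
    profile's linear predictor for reporting — the exact score when complete,
    otherwise the weighted mean full score of all reference members of the
    matched stratum; ``donors`` holds the sampled reference row index behind
    each draw (-1 for complete rows, which need no donor).
    """
    rng = np.random.default_rng(rng)
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(profile_design.to_numpy(), dtype=float)
    R = np.asarray(ref_design, dtype=float)
    if R.shape[1] != X.shape[1] or beta.size != X.shape[1]:
        raise ValueError("profile design, reference design and beta must align")
    if np.any(np.isnan(R)):
        raise ValueError("reference design must be complete")
    w = np.ones(R.shape[0]) if ref_weights is None else np.asarray(ref_weights, float)
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("reference weights must be positive and finite")

    ref_full_lp = R @ beta
    n = X.shape[0]
    lp_draws = np.empty((n, n_imputations))
    reported = np.empty(n)
    donors = np.full((n, n_imputations), -1, dtype=int)

    obs_mask = ~np.isnan(X)
    complete = obs_mask.all(axis=1)
    if complete.any():
        full = X[complete] @ beta
        lp_draws[complete] = full[:, None]
        reported[complete] = full

    # group incomplete profiles by missing pattern: strata are built once per
    # pattern from the reference scores masked to the observed columns
    if (~complete).any():
        patterns: dict[bytes, list[int]] = {}
        for i in np.flatnonzero(~complete):
            patterns.setdefault(obs_mask[i].tobytes(), []).append(i)
        for key, rows in patterns.items():
            observed = np.frombuffer(key, dtype=bool)
            b_obs = np.where(observed, beta, 0.0)
            b_uno = np.where(observed, 0.0, beta)
            ref_obs_scores = R @ b_obs
            ref_uno_scores = R @ b_uno
            strata = build_percentile_strata(
                ref_obs_scores, None if ref_weights is None else w, n_bins=n_bins
            )
            rows = np.asarray(rows)
            obs_scores = np.nansum(np.where(observed, X[rows], 0.0) * beta, axis=1)
            bins = strata.assign(obs_scores)
            for i, score, b in zip(rows, obs_scores, bins):
                members = strata.members(int(b))
                pw = w[members] / w[members].sum()
                drawn = rng.choice(members, size=n_imputations, replace=True, p=pw)
                donors[i] = drawn
                lp_draws[i] = score + ref_uno_scores[drawn]
                reported[i] = float(np.average(ref_full_lp[members], weights=w[members]))
    return lp_draws, reported, donors


def impute_linear_predictors(
    profile_design: pd.DataFrame,
    beta: np.ndarray,
    ref_design: np.ndarray,
    ref_weights: np.ndarray | None = None,
    n_bins: int = 100,
    n_imputations: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`impute_linear_predictors_with_donors`, without the donor
    bookkeeping: returns ``(lp_draws, reported_lp)``."""
    lp_draws, reported, _ = impute_linear_predictors_with_donors(
        profile_design, beta, ref_design, ref_weights=ref_weights,
        n_bins=n_bins, n_imputations=n_imputations, rng=rng,
    )
    return lp_draws, reported


def impute_risk(
    profile: pd.Series | pd.DataFrame,
    spec: ModelSpec,
    beta: np.ndarray,
    ref_design: np.ndarray,
    risk_evaluator: Callable[[np.ndarray], np.ndarray],
    ref_weights: np.ndarray | None = None,
    n_bins: int = 100,
    n_imputations: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Imputation-averaged absolute risk for one profile.

    ``risk_evaluator`` maps an array of linear predictors to absolute risks
    (the age interval and rates are fixed by the caller). Returns
    ``(risk, reported_linear_predictor)``; for a complete profile this is the
    plug-in risk, independent of ``n_imputations`` and ``rng``.
    """
    frame = profile.to_frame().T if isinstance(profile, pd.Series) else profile
    design = build_design_matrix(spec, frame, missing="nan")
    lp_draws, reported = impute_linear_predictors(
        design, beta, ref_design, ref_weights=ref_weights,
        n_bins=n_bins, n_imputations=n_imputations, rng=rng,
    )
    risks = np.asarray(risk_evaluator(lp_draws[0]), dtype=float)
    return float(risks.mean()), float(reported[0])
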