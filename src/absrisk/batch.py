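"""Build an absolute-risk model from its data sources and apply it in batch.

A model is assembled from up to three ingredients: (i) a declared
relative-risk model with a reference covariate dataset representative of the
target population, (ii) a set of independent SNPs given by published odds
ratios and allele frequencies, and (iii) registry incidence (and optional
competing-mortality) rate tables. The covariate-model ingredients — model
spec, reference dataset, covariate profiles — must be supplied together or
not at all; a SNP-only model needs just the SNP table and rates, in which
case the reference genotype distribution is simulated internally under HWE
(10,000 profiles by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design_matrix
from .hazard import BaselineHazard, estimate_baseline_hazard
from .missing import impute_linear_predictors
from .rates import RateTable
from .risk import interval_risk
from .snps import SnpInfo, simulate_reference_genotypes

__all__ = [
    "BuiltRiskModel",
    "BatchRiskResults",
    "ConfigurationError",
    "build_risk_model",
    "predict_risks",
    "compute_absolute_risk_batch",
    "compute_absolute_risk_split_interval",
]

_COVARIATE_SET = ("model spec (with log relative risks)", "reference dataset")


class ConfigurationError(ValueError):
    """Inconsistent combination of model-building arguments."""


@dataclass
class BuiltRiskModel:
    """A calibrated absolute-risk model ready to score profiles."""

    columns: list[str]
    beta: np.ndarray
    ref_design: np.ndarray          # stacked over genotype imputations
    ref_weights: np.ndarray
    lambda0: BaselineHazard
    mortality: np.ndarray | None    # per-age, on the lambda0 grid
    spec: ModelSpec | None
    snps: SnpInfo | None
    n_reference_rows: int           # before stacking
    n_genotype_imputations: int
    method: str = "exact"

    def profile_design(
        self, profiles: pd.DataFrame | None, snp_profiles: pd.DataFrame | None
    ) -> pd.DataFrame:
        """Assemble the (possibly incomplete) design matrix for new profiles."""
        parts = []
        if self.spec is not None:
            if profiles is None:
                raise ConfigurationError(
                    "covariate profiles are required by a model with covariates"
                )
            parts.append(build_design_matrix(self.spec, profiles, missing="nan"))
        elif profiles is not None:
            raise ConfigurationError("covariate profiles given but the model has none")
        if self.snps is not None:
            if snp_profiles is None:
                raise ConfigurationError(
                    "SNP profiles are required by a model with SNPs; pass "
                    "genotypes (missing allowed) or use the reference path"
                )
            missing_snps = [n for n in self.snps.names if n not in snp_profiles.columns]
            if missing_snps:
                raise ConfigurationError(f"SNP profiles lack columns {missing_snps}")
            g = snp_profiles[list(self.snps.names)].to_numpy(dtype=float)
            ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
            if not ok.all():
                raise ValueError("SNP genotypes must be 0, 1, 2 or missing")
            idx = parts[0].index if parts else snp_profiles.index
            parts.append(pd.DataFrame(g, columns=list(self.snps.names), index=idx))
        design = pd.concat(parts, axis=1)
        return design[self.columns]

    def risks_for_lp(
        self,
        lp: np.ndarray,
        age_start: np.ndarray,
        interval_length: np.ndarray,
        return_survival: bool = False,
    ):
        return interval_risk(
            self.lambda0.values,
            self.lambda0.min_age,
            lp,
            age_start,
            interval_length,
            mortality_values=self.mortality,
            method=self.method,
            return_survival=return_survival,
        )


@dataclass
class BatchRiskResults:
    """Per-profile predictions plus optional reference-profile risks."""

    predictions: pd.DataFrame
    mean_risk: float
    reference_risks: np.ndarray | None = None
    reference_linear_predictors: np.ndarray | None = None
    details: pd.DataFrame | None = None

    def details_text(self) -> str:
        lines = ["Absolute risk predictions", "=" * 25]
        if self.details is not None:
            lines.append(self.details.to_string())
        else:
            lines.append(self.predictions.to_string())
        return "\n".join(lines)


def _rate_grid(
    incidence: RateTable, mortality: RateTable | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    lo, hi = incidence.min_age, incidence.max_age
    if mortality is not None:
        lo, hi = max(lo, mortality.min_age), min(hi, mortality.max_age)
        if hi < lo:
            raise ValueError("incidence and mortality tables do not overlap in age")
    ages = np.arange(lo, hi + 1)
    inc = incidence.expand(lo, hi)
    mort = mortality.expand(lo, hi) if mortality is not None else None
    return ages, inc, mort


def build_risk_model(
    incidence: RateTable,
    spec: ModelSpec | None = None,
    reference: pd.DataFrame | None = None,
    ref_weights: np.ndarray | None = None,
    snps: SnpInfo | None = None,
    mortality: RateTable | None = None,
    apply_fh_attenuation: bool = True,
    n_genotype_imputations: int = 5,
    n_internal_reference: int = 10_000,
    hazard_tol: float = 1e-4,
    hazard_max_iter: int = 50,
    method: str = "exact",
    rng: np.random.Generator | int | None = None,
) -> BuiltRiskModel:
    """Assemble design matrices, attenuate family history, simulate reference
    genotypes and calibrate the baseline hazard.

    The covariate-model arguments (``spec``, ``reference``) are all-or-none;
    a SNP-only model (``snps`` + rates) simulates ``n_internal_reference``
    reference genotype profiles internally. When the spec flags a binary
    family-history covariate and SNPs are present, the family-history log
    odds ratio is attenuated (disable with ``apply_fh_attenuation=False`` if
    the supplied coefficient is already SNP-adjusted), and reference
    genotypes are drawn conditionally on each reference subject's family
    history.
    """
    from .snps import attenuate_family_history  # local to keep import graph flat

    rng = np.random.default_rng(rng)
    given = {"model spec (with log relative risks)": spec is not None,
             "reference dataset": reference is not None}
    if any(given.values()) and not all(given.values()):
        missing = [k for k, v in given.items() if not v]
        raise ConfigurationError(
            "the covariate-model arguments must be supplied as a set; missing: "
            + ", ".join(missing)
        )
    if spec is None and snps is None:
        raise ConfigurationError("supply a covariate model, SNPs, or both")

    ages, inc, mort = _rate_grid(incidence, mortality)

    columns: list[str] = []
    beta_parts: list[np.ndarray] = []
    n_imp = 1
    if spec is not None:
        cov_cols = spec.design_columns()
        if snps is not None:
            overlap = set(cov_cols) & set(snps.names)
            if overlap:
                raise ConfigurationError(
                    f"SNPs {sorted(overlap)} appear both as model covariates and in "
                    "the published-OR SNP table; include each SNP by one route only"
                )
        beta = spec.beta()
        if spec.family_history is not None and snps is not None and apply_fh_attenuation:
            fh_cols = spec.covariate(spec.family_history).columns
            if len(fh_cols) != 1:
                raise ConfigurationError(
                    "family-history covariate must contribute exactly one design column"
                )
            j = cov_cols.index(fh_cols[0])
            beta = beta.copy()
            beta[j] = attenuate_family_history(beta[j], snps)
        columns += cov_cols
        beta_parts.append(beta)
        ref_cov = build_design_matrix(spec, reference, missing="error").to_numpy()
        n_ref = ref_cov.shape[0]
        if snps is not None:
            fh_vals = None
            if spec.family_history is not None:
                fh_vals = pd.to_numeric(reference[spec.family_history]).to_numpy()
                if not np.isin(fh_vals, (0, 1)).all():
                    raise ValueError("family-history covariate must be binary 0/1")
            n_imp = n_genotype_imputations
            geno = simulate_reference_genotypes(
                snps, n_subjects=n_ref, fh_status=fh_vals,
                n_imputations=n_imp, rng=rng,
            )
            ref_full = np.concatenate(
                [np.tile(ref_cov, (n_imp, 1)), geno.reshape(n_imp * n_ref, -1)], axis=1
            )
        else:
            ref_full = ref_cov
    else:
        n_ref = n_internal_reference
        geno = simulate_reference_genotypes(
            snps, n_subjects=n_ref, n_imputations=1, rng=rng
        )
        ref_full = geno[0].astype(float)

    if snps is not None:
        columns += list(snps.names)
        beta_parts.append(snps.log_odds_ratio)
    beta = np.concatenate(beta_parts)

    if ref_weights is not None:
        w = np.asarray(ref_weights, dtype=float)
        if w.shape != (n_ref,):
            raise ValueError("ref_weights length must match reference rows")
    else:
        w = np.ones(n_ref)
    w_full = np.tile(w, ref_full.shape[0] // n_ref)

    lambda0 = estimate_baseline_hazard(
        beta, ref_full, inc, ages, ref_weights=w_full,
        tol=hazard_tol, max_iter=hazard_max_iter,
    )
    return BuiltRiskModel(
        columns=columns, beta=beta, ref_design=ref_full, ref_weights=w_full,
        lambda0=lambda0, mortality=mort, spec=spec, snps=snps,
        n_reference_rows=n_ref, n_genotype_imputations=n_imp, method=method,
    )


def _as_per_subject(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim == 0:
        arr = np.full(n, arr)
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a scalar or one value per profile")
    return arr.astype(int)


def predict_risks(
    model: BuiltRiskModel,
    profiles: pd.DataFrame | None = None,
    snp_profiles: pd.DataFrame | None = None,
    age_start: int | np.ndarray = 50,
    interval_length: int | np.ndarray = 30,
    n_imputations: int = 5,
    n_percentile_bins: int = 100,
    return_reference_risks: bool = False,
    rng: np.random.Generator | int | None = None,
) -> BatchRiskResults:
    """Score profiles with a built model, imputing missing covariates/SNPs.

    With no profiles at all (SNP-only model), the internally simulated
    reference genotype profiles are scored and ``mean_risk`` is their average
    — the population-average risk implied by the model.
    """
    rng = np.random.default_rng(rng)
    internal = profiles is None and snp_profiles is None
    if internal:
        if model.spec is not None:
            raise ConfigurationError(
                "covariate profiles must be provided for a model with covariates"
            )
        design = pd.DataFrame(model.ref_design, columns=model.columns)
        ids = pd.RangeIndex(len(design))
    else:
        design = model.profile_design(profiles, snp_profiles)
        ids = design.index
    n = len(design)
    a = _as_per_subject(age_start, n, "age_start")
    tau = _as_per_subject(interval_length, n, "interval_length")

    lp_draws, reported_lp = impute_linear_predictors(
        design, model.beta, model.ref_design, ref_weights=model.ref_weights,
        n_bins=n_percentile_bins, n_imputations=n_imputations, rng=rng,
    )
    risks = model.risks_for_lp(lp_draws, a[:, None], tau[:, None]).mean(axis=1)

    predictions = pd.DataFrame(
        {
            "id": np.asarray(ids),
            "age_start": a,
            "interval_length": tau,
            "risk": risks,
            "linear_predictor": reported_lp,
        }
    )
    ref_risks = ref_lp = None
    if return_reference_risks:
        ref_lp_full = model.ref_design @ model.beta
        # score each reference profile over the first requested interval
        ref_r = model.risks_for_lp(
            ref_lp_full, np.full(ref_lp_full.size, a[0]), np.full(ref_lp_full.size, tau[0])
        )
        ref_risks = ref_r.reshape(model.n_genotype_imputations, model.n_reference_rows).mean(0)
        ref_lp = ref_lp_full.reshape(
            model.n_genotype_imputations, model.n_reference_rows
        ).mean(0)
    details = design.copy()
    details["risk"] = risks
    details["linear_predictor"] = reported_lp
    return BatchRiskResults(
        predictions=predictions,
        mean_risk=float(np.mean(risks)),
        reference_risks=ref_risks,
        reference_linear_predictors=ref_lp,
        details=details,
    )


def compute_absolute_risk_batch(
    incidence: RateTable,
    spec: ModelSpec | None = None,
    reference: pd.DataFrame | None = None,
    ref_weights: np.ndarray | None = None,
    snps: SnpInfo | None = None,
    mortality: RateTable | None = None,
    profiles: pd.DataFrame | None = None,
    snp_profiles: pd.DataFrame | None = None,
    age_start: int | np.ndarray = 50,
    interval_length: int | np.ndarray = 30,
    apply_fh_attenuation: bool = True,
    n_imputations: int = 5,
    n_internal_reference: int = 10_000,
    return_reference_risks: bool = False,
    method: str = "exact",
    seed: np.random.Generator | int | None = None,
) -> BatchRiskResults:
    """One-call model build + prediction (see :func:`build_risk_model` and
    :func:`predict_risks`). The covariate-model arguments {spec, reference,
    profiles} are all-or-none; SNP-only models may omit profiles entirely."""
    rng = np.random.default_rng(seed)
    cov_set = {"model spec (with log relative risks)": spec is not None,
               "reference dataset": reference is not None,
               "covariate profiles": profiles is not None}
    if any(cov_set.values()) and not all(cov_set.values()):
        allowed_internal = spec is None and reference is None and profiles is None
        if not allowed_internal:
            missing = [k for k, v in cov_set.items() if not v]
            raise ConfigurationError(
                "covariate-model arguments must be supplied as a set; missing: "
                + ", ".join(missing)
            )
    model = build_risk_model(
        incidence, spec=spec, reference=reference, ref_weights=ref_weights,
        snps=snps, mortality=mortality, apply_fh_attenuation=apply_fh_attenuation,
        n_genotype_imputations=n_imputations,
        n_internal_reference=n_internal_reference, method=method, rng=rng,
    )
    return predict_risks(
        model, profiles=profiles, snp_profiles=snp_profiles,
        age_start=age_start, interval_length=interval_length,
        n_imputations=n_imputations,
        return_reference_risks=return_reference_risks, rng=rng,
    )


def compute_absolute_risk_split_interval(
    cut_age: int,
    incidence: RateTable,
    spec: ModelSpec | None = None,
    spec2: ModelSpec | None = None,
    reference: pd.DataFrame | None = None,
    ref_weights: np.ndarray | None = None,
    snps: SnpInfo | None = None,
    snps2: SnpInfo | None = None,
    mortality: RateTable | None = None,
    profiles: pd.DataFrame | None = None,
    snp_profiles: pd.DataFrame | None = None,
    age_start: int | np.ndarray = 50,
    interval_length: int | np.ndarray = 30,
    apply_fh_attenuation: bool = True,
    n_imputations: int = 5,
    n_internal_reference: int = 10_000,
    method: str = "exact",
    seed: np.random.Generator | int | None = None,
) -> BatchRiskResults:
    """Absolute risk over [a, a+tau) with different parameters before and
    after ``cut_age`` (e.g. pre/post-menopausal relative risks).

    The cumulative risk composes the sub-intervals:
    ``risk = risk_1(a -> cut) + surv_1(a -> cut) * risk_2(cut -> a+tau)``
    where ``surv_1`` is the probability of remaining disease-free and alive
    to ``cut_age`` under the first parameter set, and each part uses its own
    log relative risks with its own recalibrated baseline hazard. Missing
    covariates are imputed with donors matched on the first parameter set's
    observable score; each donor completes both scores, keeping the two parts
    consistent.
    """
    rng = np.random.default_rng(seed)
    spec2 = spec2 if spec2 is not None else spec
    snps2 = snps2 if snps2 is not None else snps
    m1 = build_risk_model(
        incidence, spec=spec, reference=reference, ref_weights=ref_weights,
        snps=snps, mortality=mortality, apply_fh_attenuation=apply_fh_attenuation,
        n_genotype_imputations=n_imputations,
        n_internal_reference=n_internal_reference, method=method,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    m2 = build_risk_model(
        incidence, spec=spec2, reference=reference, ref_weights=ref_weights,
        snps=snps2, mortality=mortality, apply_fh_attenuation=apply_fh_attenuation,
        n_genotype_imputations=n_imputations,
        n_internal_reference=n_internal_reference, method=method,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    if m1.columns != m2.columns:
        raise ConfigurationError(
            "split-interval parameter sets must share the same design columns"
        )

    internal = profiles is None and snp_profiles is None
    if internal:
        if m1.spec is not None:
            raise ConfigurationError(
                "covariate profiles must be provided for a model with covariates"
            )
        design = pd.DataFrame(m1.ref_design, columns=m1.columns)
    else:
        design = m1.profile_design(profiles, snp_profiles)
    n = len(design)
    a = _as_per_subject(age_start, n, "age_start")
    tau = _as_per_subject(interval_length, n, "interval_length")
    if np.any(cut_age < a) or np.any(cut_age > a + tau):
        raise ValueError("cut_age must lie within [age_start, age_start + interval]")

    lp1_draws, lp2_draws, reported_lp = _shared_donor_lps(
        design, m1, m2, n_imputations, np.random.default_rng(rng.integers(2**31))
    )

    tau1 = cut_age - a
    tau2 = a + tau - cut_age
    r1, s1 = m1.risks_for_lp(
        lp1_draws, a[:, None], tau1[:, None], return_survival=True
    )
    r2 = m2.risks_for_lp(lp2_draws, np.full((n, 1), cut_age), tau2[:, None])
    risks = (r1 + s1 * r2).mean(axis=1)
    predictions = pd.DataFrame(
        {
            "id": np.asarray(design.index),
            "age_start": a,
            "interval_length": tau,
            "risk": risks,
            "linear_predictor": reported_lp,
        }
    )
    return BatchRiskResults(predictions=predictions, mean_risk=float(np.mean(risks)))


def _shared_donor_lps(
    design: pd.DataFrame,
    m1: BuiltRiskModel,
    m2: BuiltRiskModel,
    n_imputations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-predictor draws under both parameter sets with shared donors.

    Donors are matched on the first parameter set's observable score; each
    sampled donor fills the unobservable component of BOTH scores, so the two
    sub-interval risks refer to the same completed profile.
    """
    from .missing import impute_linear_predictors_with_donors

    lp1, reported, donors = impute_linear_predictors_with_donors(
        design, m1.beta, m1.ref_design, ref_weights=m1.ref_weights,
        n_imputations=n_imputations, rng=rng,
    )
    X = design.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    lp2 = np.empty_like(lp1)
    complete = obs.all(axis=1)
    lp2[complete] = (X[complete] @ m2.beta)[:, None]
    for i in np.flatnonzero(~complete):
        uno = ~obs[i]
        obs_score2 = float(np.nansum(X[i, obs[i]] * m2.beta[obs[i]]))
        lp2[i] = obs_score2 + m2.ref_design[donors[i]][:, uno] @ m2.beta[uno]
    return lp1, lp2, reported
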