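"""Independent validation of an absolute-risk model.

Given a prospective cohort — or a case-control sample nested within one —
the model is checked for calibration (do predicted risks match observed case
proportions across risk strata?) and discrimination (does the risk score
separate cases from controls?). Nested designs are handled by inverse
probability weighting (IPW): each sampled subject is weighted by the inverse
of their probability of inclusion pi_i(Y_i, Z_i), which can be estimated
post hoc with a logistic selection model when the study did not record it.

Implemented statistics:

* per-category observed case proportions with influence-function variances
  (binomial term plus a (1-pi)/pi correction for two-phase sampling);
* a Hosmer-Lemeshow-type goodness-of-fit statistic referred to chi-square
  with C degrees of freedom (C = number of risk categories);
* relative-risk calibration with a delta-method variance and a chi-square
  test on C-1 degrees of freedom;
* the IPW concordance (AUC) estimator with an influence-function variance
  built from placement values;
* the overall expected-to-observed case ratio with a log-scale Wald CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .batch import BuiltRiskModel, predict_risks

__all__ = [
    "COLUMNS",
    "SelectionModel",
    "CalibrationResult",
    "RelativeRiskResult",
    "AucResult",
    "ValidationReport",
    "fit_selection_model",
    "categorize_risk",
    "observed_proportion_variance",
    "absolute_risk_calibration",
    "relative_risk_calibration",
    "auc",
    "validate_model",
]

#: Standard validation-study column names.
COLUMNS = {
    "id": "id",
    "outcome": "observed.outcome",
    "entry": "study.entry.age",
    "exit": "study.exit.age",
    "onset": "time.of.onset",
    "weights": "sampling.weights",
    "followup": "observed.followup",
    "inclusion": "inclusion",
}

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# selection (inclusion) model


@dataclass
class SelectionModel:
    """Fitted logistic inclusion model for a nested sub-sample."""

    params: np.ndarray
    fitted: np.ndarray            # per cohort row
    term_names: list[str]

    def weights_for_included(self, inclusion: np.ndarray) -> np.ndarray:
        """Fitted inclusion probabilities of the included subjects, in cohort
        row order — these become the sampling weights pi_i."""
        return self.fitted[np.asarray(inclusion).astype(bool)]


def _selection_design(outcome, entry, followup) -> tuple[np.ndarray, list[str]]:
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(entry, dtype=float)
    f = np.asarray(followup, dtype=float)
    X = np.column_stack([np.ones_like(y), y, a, f, y * a, y * f])
    names = [
        "intercept",
        "observed.outcome",
        "study.entry.age",
        "observed.followup",
        "observed.outcome:study.entry.age",
        "observed.outcome:observed.followup",
    ]
    return X, names


def fit_selection_model(
    cohort: pd.DataFrame,
    inclusion_col: str = COLUMNS["inclusion"],
    outcome_col: str = COLUMNS["outcome"],
    entry_col: str = COLUMNS["entry"],
    followup_col: str | None = None,
) -> SelectionModel:
    """Logistic regression of inclusion on disease status, entry age and
    observed follow-up, with outcome-by-covariate interactions.

    ``followup_col=None`` derives follow-up as exit age minus entry age.
    The fitted probabilities of included subjects are the sampling weights
    for all IPW validation statistics.
    """
    if followup_col is None:
        fu = cohort[COLUMNS["exit"]].to_numpy(float) - cohort[entry_col].to_numpy(float)
    else:
        fu = cohort[followup_col].to_numpy(float)
    X, names = _selection_design(cohort[outcome_col], cohort[entry_col], fu)
    incl = cohort[inclusion_col].to_numpy(float)
    try:
        res = sm.GLM(incl, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as err:  # separation / numerical failure
        raise RuntimeError(
            "selection model did not converge; supply sampling weights "
            "directly instead of post-hoc estimation"
        ) from err
    if not res.converged or np.any(~np.isfinite(res.params)):
        raise RuntimeError(
            "selection model did not converge; supply sampling weights "
            "directly instead of post-hoc estimation"
        )
    return SelectionModel(
        params=np.asarray(res.params), fitted=np.asarray(res.fittedvalues),
        term_names=names,
    )


# ---------------------------------------------------------------------------
# risk-score categories


def categorize_risk(
    scores: np.ndarray,
    n_categories: int = 10,
    sampling_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Equal-IPW-mass risk categories 0..C-1 (0 = lowest risk).

    Cut-points invert the inverse-probability-weighted empirical distribution
    of the score at c/C (left-continuous); an unweighted study uses ordinary
    quantiles. Scores tied with a cut-point fall in the lower category.
    """
    scores = np.asarray(scores, dtype=float)
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if n_categories == 1:
        return np.zeros(scores.size, dtype=int)
    probs = np.arange(1, n_categories) / n_categories
    if sampling_weights is None:
        cut = np.quantile(scores, probs, method="inverted_cdf")
    else:
        pi = np.asarray(sampling_weights, dtype=float)
        cut = np.quantile(scores, probs, weights=1.0 / pi, method="inverted_cdf")
    return np.searchsorted(np.asarray(cut, float), scores, side="left")


# ---------------------------------------------------------------------------
# calibration


def observed_proportion_variance(
    y: np.ndarray, sampling_weights: np.ndarray | None = None
) -> tuple[float, float]:
    """IPW case proportion in one risk category and its variance.

    Influence-function plug-in:
    ``Var = (p(1-p) + E_w[(Y-p)^2 (1-pi)/pi]) / (sum of IPW weights)``
    where the denominator estimates the cohort-scale category count
    N*Pr[category]. With pi = 1 (full cohort) this is the binomial
    ``p(1-p)/n``. Returns ``(p, Var)``.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty risk category")
    pi = np.ones_like(y) if sampling_weights is None else np.asarray(sampling_weights, float)
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("sampling weights must be in (0, 1]")
    w = 1.0 / pi
    mass = w.sum()  # estimates N * Pr[category]
    p = float(np.sum(w * y) / mass)
    correction = float(np.sum(w * (y - p) ** 2 * (1.0 - pi) / pi) / mass)
    var = (p * (1.0 - p) + correction) / mass
    return p, float(var)


@dataclass
class CalibrationResult:
    """Absolute-risk calibration across categories."""

    table: pd.DataFrame           # per category: n, observed, ci, expected, var
    statistic: float
    df: int
    p_value: float
    expected_by_observed: float
    eo_ci: tuple[float, float]

    @property
    def hosmer_lemeshow(self) -> float:
        return self.statistic


def absolute_risk_calibration(
    y: np.ndarray,
    predicted: np.ndarray,
    categories: np.ndarray,
    sampling_weights: np.ndarray | None = None,
) -> CalibrationResult:
    """Hosmer-Lemeshow-type absolute-risk calibration.

    ``HL = sum_c (p_obs_c - p_exp_c)^2 / Var[p_obs_c]`` on C degrees of
    freedom, with IPW means and influence-function variances per category,
    plus the overall expected/observed case ratio with log-scale Wald CI.
    """
    y = np.asarray(y, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    cat = np.asarray(categories)
    pi = np.ones_like(y) if sampling_weights is None else np.asarray(sampling_weights, float)
    w = 1.0 / pi
    levels = np.unique(cat)
    rows = []
    hl = 0.0
    for c in levels:
        m = cat == c
        p_obs, var = observed_proportion_variance(y[m], pi[m] if sampling_weights is not None else None)
        p_exp = float(np.average(pred[m], weights=w[m]))
        if var <= 0:
            if abs(p_obs - p_exp) > 0:
                raise ValueError(
                    f"category {c}: zero variance with nonzero discrepancy — "
                    "degenerate goodness-of-fit test"
                )
            contrib = 0.0
        else:
            contrib = (p_obs - p_exp) ** 2 / var
        hl += contrib
        half = _Z95 * np.sqrt(max(var, 0.0))
        rows.append(
            {
                "category": int(c) + 1,
                "n": int(m.sum()),
                "observed": p_obs,
                "observed_var": var,
                "observed_lo": max(p_obs - half, 0.0),
                "observed_hi": min(p_obs + half, 1.0),
                "expected": p_exp,
            }
        )
    table = pd.DataFrame(rows)
    df = len(levels)
    p_value = float(stats.chi2.sf(hl, df))

    p_obs_all, var_all = observed_proportion_variance(
        y, pi if sampling_weights is not None else None
    )
    p_exp_all = float(np.average(pred, weights=w))
    if p_obs_all <= 0:
        raise ValueError("no observed cases; expected/observed ratio undefined")
    eo = p_exp_all / p_obs_all
    sd_log = np.sqrt(var_all) / p_obs_all
    eo_ci = (float(eo * np.exp(-_Z95 * sd_log)), float(eo * np.exp(_Z95 * sd_log)))
    return CalibrationResult(
        table=table, statistic=float(hl), df=df, p_value=p_value,
        expected_by_observed=float(eo), eo_ci=eo_ci,
    )


@dataclass
class RelativeRiskResult:
    """Relative-risk calibration across categories."""

    table: pd.DataFrame
    statistic: float
    df: int
    p_value: float


def relative_risk_calibration(
    y: np.ndarray,
    predicted: np.ndarray,
    categories: np.ndarray,
    sampling_weights: np.ndarray | None = None,
) -> RelativeRiskResult:
    """Calibration on the relative-risk scale.

    Observed relative risk per category is the category's IPW case
    proportion over the overall IPW case proportion (predicted analogously).
    The covariance of the observed relative risks comes from the delta
    method applied to the diagonal matrix of category absolute-risk
    variances, approximating the overall proportion by the mean over the
    (equal-mass) categories; the test drops the last category and refers
    the quadratic form to chi-square with C-1 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    cat = np.asarray(categories)
    pi = np.ones_like(y) if sampling_weights is None else np.asarray(sampling_weights, float)
    w = 1.0 / pi
    levels = np.unique(cat)
    C = len(levels)
    if C < 2:
        raise ValueError("relative-risk calibration needs at least 2 categories")
    p_obs = np.empty(C)
    var_obs = np.empty(C)
    p_exp = np.empty(C)
    for k, c in enumerate(levels):
        m = cat == c
        p_obs[k], var_obs[k] = observed_proportion_variance(
            y[m], pi[m] if sampling_weights is not None else None
        )
        p_exp[k] = np.average(pred[m], weights=w[m])
    p_obs_all, _ = observed_proportion_variance(
        y, pi if sampling_weights is not None else None
    )
    p_exp_all = float(np.average(pred, weights=w))
    rr_obs = p_obs / p_obs_all
    rr_exp = p_exp / p_exp_all

    # delta method: RR_c = p_c / mu with mu = mean over categories
    mu = p_obs.mean()
    J = np.eye(C) / mu - np.outer(p_obs, np.ones(C)) / (C * mu**2)
    sigma_rr = J @ np.diag(var_obs) @ J.T
    sub = sigma_rr[: C - 1, : C - 1]
    d = (rr_obs - rr_exp)[: C - 1]
    try:
        stat = float(d @ np.linalg.solve(sub, d))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular relative-risk covariance matrix") from err
    df = C - 1
    var_rr = np.diag(sigma_rr)
    half = _Z95 * np.sqrt(var_rr)
    table = pd.DataFrame(
        {
            "category": levels.astype(int) + 1,
            "observed_rr": rr_obs,
            "observed_rr_lo": rr_obs - half,
            "observed_rr_hi": rr_obs + half,
            "expected_rr": rr_exp,
        }
    )
    return RelativeRiskResult(
        table=table, statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df))
    )


# ---------------------------------------------------------------------------
# discrimination


@dataclass
class AucResult:
    """Concordance (AUC) estimate with influence-function variance."""

    auc: float
    variance: float
    ci: tuple[float, float]
    degenerate: bool = False


def _placements(
    scores: np.ndarray, other_scores: np.ndarray, other_w: np.ndarray
) -> np.ndarray:
    """Weighted fraction of ``other_scores`` strictly below each score, ties
    counting one half."""
    order = np.argsort(other_scores, kind="stable")
    s = other_scores[order]
    cw = np.concatenate([[0.0], np.cumsum(other_w[order])])
    lo = np.searchsorted(s, scores, side="left")
    hi = np.searchsorted(s, scores, side="right")
    total = cw[-1]
    return (cw[lo] + 0.5 * (cw[hi] - cw[lo])) / total


def auc(
    case_scores: np.ndarray,
    control_scores: np.ndarray,
    case_weights: np.ndarray | None = None,
    control_weights: np.ndarray | None = None,
) -> AucResult:
    """IPW concordance probability Pr[R_case > R_control], ties count 0.5.

    ``case_weights``/``control_weights`` are sampling probabilities pi; when
    omitted the cohort (unweighted) estimator and variance are used. The
    variance sums, over cases and controls, the IPW variance of the placement
    values plus the two-phase (1-pi)/pi correction, each scaled by the
    estimated cohort counts n_1 and n_0.
    """
    r1 = np.asarray(case_scores, dtype=float)
    r0 = np.asarray(control_scores, dtype=float)
    if r1.size == 0 or r0.size == 0:
        raise ValueError("need at least one case and one control")
    pi1 = np.ones_like(r1) if case_weights is None else np.asarray(case_weights, float)
    pi0 = np.ones_like(r0) if control_weights is None else np.asarray(control_weights, float)
    w1, w0 = 1.0 / pi1, 1.0 / pi0
    n1, n0 = w1.sum(), w0.sum()

    p1 = _placements(r1, r0, w0)          # E_R0[I(R1_i > R0)]
    p0 = 1.0 - _placements(r0, r1, w1)    # E_R1[I(R1 > R0_j)]
    delta = float(np.sum(w1 * p1) / n1)

    if np.all(r1 == r1[0]) and np.all(r0 == r1[0]):
        return AucResult(auc=0.5, variance=0.0, ci=(0.5, 0.5), degenerate=True)

    # Var_w[P] + E_w[(P-d)^2 (1-pi)/pi] collapses to E_w[(P-d)^2 / pi]
    v1 = float(np.sum(w1 * (p1 - delta) ** 2 / pi1) / n1)
    v0 = float(np.sum(w0 * (p0 - delta) ** 2 / pi0) / n0)
    var = v1 / n1 + v0 / n0
    half = _Z95 * np.sqrt(var)
    return AucResult(
        auc=delta, variance=var,
        ci=(float(delta - half), float(delta + half)),
    )


# ---------------------------------------------------------------------------
# full report


@dataclass
class ValidationReport:
    """Everything the validation run produced, printable as a text block."""

    dataset_name: str
    model_name: str
    interval_description: str
    n_subjects: int
    n_cases: int
    followup_mean: float
    followup_range: tuple[float, float]
    entry_age_mean: float
    entry_age_range: tuple[float, float]
    calibration: CalibrationResult
    relative_risk: RelativeRiskResult
    discrimination: AucResult
    risk_scores: np.ndarray = field(repr=False)
    predicted_risks: np.ndarray = field(repr=False)
    outcomes: np.ndarray = field(repr=False)
    categories: np.ndarray = field(repr=False)
    sampling_weights: np.ndarray | None = field(repr=False, default=None)

    def __str__(self) -> str:
        cal, rr, disc = self.calibration, self.relative_risk, self.discrimination
        lines = [
            f"Dataset: {self.dataset_name}",
            "",
            f"Model Name: {self.model_name}",
            "",
            f"Risk Prediction Interval: {self.interval_description}",
            "",
            f"Number of study subjects: {self.n_subjects}",
            "",
            f"Number of cases: {self.n_cases}",
            "",
            f"Follow-up time (years) [mean,range]: "
            f"[{self.followup_mean:.3f}, ({self.followup_range[0]:g},"
            f"{self.followup_range[1]:g})]",
            "",
            f"Baseline age (years) [mean,range]: "
            f"[{self.entry_age_mean:.3f}, ({self.entry_age_range[0]:g},"
            f"{self.entry_age_range[1]:g})]",
            "",
            "Absolute Risk Calibration",
            "",
            "     Hosmer and Lemeshow goodness of fit (GOF) test for Absolute Risk",
            "",
            "data: observed.frequency, expected.frequency",
            f"Chisquare = {cal.statistic:.3f}, df = {cal.df}, "
            f"p-value = {cal.p_value:.4g}",
            "",
            "Relative Risk Calibration",
            "",
            "     Goodness of fit (GOF) test for Relative Risk",
            "",
            "data: observed.frequency, expected.frequency",
            f"Chisquare = {rr.statistic:.3f}, df = {rr.df}, "
            f"p-value = {rr.p_value:.4g}",
            "",
            "Model Discrimination",
            "",
            f"Estimate of AUC: {disc.auc:.3f}",
            "",
            f"95% CI of AUC: ({disc.ci[0]:.3f},{disc.ci[1]:.3f})",
            "",
            "Overall Expected to Observed Ratio",
            "",
            f"Estimate: {cal.expected_by_observed:.3f}",
            "",
            f"95% CI: ({cal.eo_ci[0]:.3g},{cal.eo_ci[1]:.3g})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        cal, rr, disc = self.calibration, self.relative_risk, self.discrimination
        return {
            "dataset_name": self.dataset_name,
            "model_name": self.model_name,
            "interval": self.interval_description,
            "n_subjects": self.n_subjects,
            "n_cases": self.n_cases,
            "followup_mean": self.followup_mean,
            "followup_range": list(self.followup_range),
            "entry_age_mean": self.entry_age_mean,
            "entry_age_range": list(self.entry_age_range),
            "hosmer_lemeshow": {
                "statistic": cal.statistic, "df": cal.df, "p_value": cal.p_value,
            },
            "relative_risk_gof": {
                "statistic": rr.statistic, "df": rr.df, "p_value": rr.p_value,
            },
            "auc": {"estimate": disc.auc, "ci": list(disc.ci)},
            "expected_by_observed": {
                "estimate": cal.expected_by_observed, "ci": list(cal.eo_ci),
            },
            "calibration_table": cal.table.to_dict(orient="records"),
            "relative_risk_table": rr.table.to_dict(orient="records"),
        }


def validate_model(
    study: pd.DataFrame,
    model: BuiltRiskModel | None = None,
    predicted_risks: np.ndarray | None = None,
    risk_scores: np.ndarray | None = None,
    tau: int | None = None,
    n_categories: int = 10,
    design: str | None = None,
    n_imputations: int = 5,
    dataset_name: str = "Validation study",
    model_name: str = "Absolute risk model",
    rng: np.random.Generator | int | None = None,
) -> ValidationReport:
    """Run the full validation analysis on a study dataset.

    ``study`` must carry the standard columns (``observed.outcome``,
    ``study.entry.age``, ``study.exit.age``, ``time.of.onset``, optional
    ``sampling.weights``) plus the model covariates/SNP genotypes. Risks are
    predicted per subject over the minimum of ``tau`` years and observed
    follow-up (``tau=None`` validates over total follow-up), either by the
    supplied built model or taken from ``predicted_risks`` (with
    ``risk_scores`` optionally supplying the discrimination score; predicted
    risks are used when absent).

    ``design`` is ``'cohort'`` or ``'nested'``; by default it is inferred
    from the presence of the sampling-weights column. A nested design
    without weights raises, pointing at :func:`fit_selection_model`.
    """
    for col in (COLUMNS["outcome"], COLUMNS["entry"], COLUMNS["exit"]):
        if col not in study.columns:
            raise ValueError(f"study lacks required column {col!r}")
    entry = study[COLUMNS["entry"]].to_numpy(float)
    exit_age = study[COLUMNS["exit"]].to_numpy(float)
    fu_obs = exit_age - entry
    if np.any(fu_obs < 0):
        raise ValueError("study.exit.age must be >= study.entry.age")

    has_weights = COLUMNS["weights"] in study.columns
    if design is None:
        design = "nested" if has_weights else "cohort"
    if design not in ("cohort", "nested"):
        raise ValueError("design must be 'cohort' or 'nested'")
    if design == "nested" and not has_weights:
        raise ValueError(
            "nested case-control validation requires sampling weights; "
            "estimate them with fit_selection_model"
        )
    pi = study[COLUMNS["weights"]].to_numpy(float) if has_weights else None
    if pi is not None and (np.any(pi <= 0) or np.any(pi > 1)):
        raise ValueError("sampling weights must be in (0, 1]")

    if tau is None:
        interval = fu_obs
        interval_description = "Observed Followup"
    else:
        interval = np.minimum(float(tau), fu_obs)
        interval_description = f"{tau} years"

    outcome = study[COLUMNS["outcome"]].to_numpy(float)
    if COLUMNS["onset"] in study.columns:
        onset = study[COLUMNS["onset"]].to_numpy(float)
        onset = np.where(np.isnan(onset), np.inf, onset)
        y = ((outcome > 0) & (onset <= entry + interval)).astype(float)
    else:
        y = (outcome > 0).astype(float)
    if y.sum() == 0:
        raise ValueError("validation study contains no cases")

    if predicted_risks is not None:
        pred = np.asarray(predicted_risks, dtype=float)
        scores = (
            np.asarray(risk_scores, dtype=float) if risk_scores is not None else pred
        )
    else:
        if model is None:
            raise ValueError("supply either a built model or predicted risks")
        cov_profiles = None
        snp_profiles = None
        if model.spec is not None:
            names = [c.name for c in model.spec.covariates]
            cov_profiles = study[names]
        if model.snps is not None:
            snp_profiles = study[list(model.snps.names)]
        res = predict_risks(
            model, profiles=cov_profiles, snp_profiles=snp_profiles,
            age_start=entry.astype(int), interval_length=np.ceil(interval).astype(int),
            n_imputations=n_imputations, rng=rng,
        )
        pred = res.predictions["risk"].to_numpy()
        scores = res.predictions["linear_predictor"].to_numpy()

    cats = categorize_risk(scores, n_categories=n_categories, sampling_weights=pi)
    cal = absolute_risk_calibration(y, pred, cats, sampling_weights=pi)
    rr = relative_risk_calibration(y, pred, cats, sampling_weights=pi)
    is_case = y > 0
    disc = auc(
        scores[is_case], scores[~is_case],
        case_weights=None if pi is None else pi[is_case],
        control_weights=None if pi is None else pi[~is_case],
    )
    return ValidationReport(
        dataset_name=dataset_name,
        model_name=model_name,
        interval_description=interval_description,
        n_subjects=int(len(study)),
        n_cases=int(y.sum()),
        followup_mean=float(fu_obs.mean()),
        followup_range=(float(fu_obs.min()), float(fu_obs.max())),
        entry_age_mean=float(entry.mean()),
        entry_age_range=(float(entry.min()), float(entry.max())),
        calibration=cal,
        relative_risk=rr,
        discrimination=disc,
        risk_scores=np.asarray(scores),
        predicted_risks=pred,
        outcomes=y,
        categories=cats,
        sampling_weights=pi,
    )


def plot_validation(report: ValidationReport, path: str | None = None):
    """Four-panel validation figure: absolute and relative calibration,
    score distributions by case status, and observed-vs-expected risk."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    t = report.calibration.table
    ax = axes[0, 0]
    ax.errorbar(
        t["category"], t["observed"],
        yerr=[t["observed"] - t["observed_lo"], t["observed_hi"] - t["observed"]],
        fmt="o", label="observed", color="black",
    )
    ax.plot(t["category"], t["expected"], "r^", label="predicted")
    ax.set_xlabel("risk category")
    ax.set_ylabel("absolute risk")
    ax.set_title("Absolute risk calibration")
    ax.legend()

    rt = report.relative_risk.table
    ax = axes[0, 1]
    ax.errorbar(
        rt["category"], rt["observed_rr"],
        yerr=[rt["observed_rr"] - rt["observed_rr_lo"],
              rt["observed_rr_hi"] - rt["observed_rr"]],
        fmt="o", label="observed", color="black",
    )
    ax.plot(rt["category"], rt["expected_rr"], "r^", label="predicted")
    ax.set_xlabel("risk category")
    ax.set_ylabel("relative risk")
    ax.set_title("Relative risk calibration")
    ax.legend()

    ax = axes[1, 0]
    cases = report.outcomes > 0
    ax.hist(report.risk_scores[~cases], bins=30, density=True, alpha=0.5,
            color="black", label="controls")
    ax.hist(report.risk_scores[cases], bins=30, density=True, alpha=0.5,
            color="red", label="cases")
    ax.set_xlabel("risk score")
    ax.set_title("Risk-score distribution")
    ax.legend()

    ax = axes[1, 1]
    ax.scatter(report.predicted_risks, report.outcomes, s=4, alpha=0.2)
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed outcome")
    ax.set_title(f"AUC = {report.discrimination.auc:.3f}")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
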