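import numpy as np
import pandas as pd
import pytest

from absrisk import (
    BaselineHazard,
    ConfigurationError,
    RateTable,
    build_design_matrix,
    build_risk_model,
    compute_absolute_risk,
    compute_absolute_risk_batch,
    compute_absolute_risk_split_interval,
    predict_risks,
)
from absrisk.snps import attenuate_family_history


class TestConfiguration:
    def test_all_or_none_covariate_arguments(self, toy_spec, flat_incidence):
        with pytest.raises(ConfigurationError, match="reference dataset"):
            build_risk_model(flat_incidence, spec=toy_spec)

    def test_batch_requires_profiles_with_covariate_model(
        self, toy_spec, toy_reference, flat_incidence
    ):
        with pytest.raises(ConfigurationError, match="covariate profiles"):
            compute_absolute_risk_batch(
                flat_incidence, spec=toy_spec, reference=toy_reference
            )

    def test_need_some_model(self, flat_incidence):
        with pytest.raises(ConfigurationError, match="covariate model, SNPs"):
            build_risk_model(flat_incidence)

    def test_snp_in_both_routes_rejected(self, toy_reference, flat_incidence, toy_snps):
        from absrisk import Covariate, ModelSpec

        spec = ModelSpec(
            covariates=[Covariate("rs1", "continuous")],
            log_relative_risks={"rs1": 0.2},
        )
        ref = toy_reference.copy()
        ref["rs1"] = 0.0
        with pytest.raises(ConfigurationError, match="rs1"):
            build_risk_model(flat_incidence, spec=spec, reference=ref, snps=toy_snps)


class TestCompleteProfiles:
    def test_batch_matches_single_profile_computation(
        self, toy_spec, toy_reference, flat_incidence, flat_mortality
    ):
        profiles = pd.DataFrame(
            {"famhist": [0.0, 1.0], "bmi": ["low", "high"]}
        )
        model = build_risk_model(
            flat_incidence, spec=toy_spec, reference=toy_reference,
            mortality=flat_mortality, rng=0,
        )
        res = predict_risks(model, profiles, age_start=50, interval_length=25, rng=1)
        design = build_design_matrix(toy_spec, profiles)
        mort = flat_mortality.expand(model.lambda0.min_age, model.lambda0.max_age)
        for i in range(2):
            single = compute_absolute_risk(
                50, 25, model.lambda0, model.beta[: design.shape[1]],
                design.iloc[i].to_numpy(), mortality=mort,
            )
            assert res.predictions["risk"].iloc[i] == pytest.approx(
                single.risk, abs=1e-14
            )

    def test_per_subject_ages_and_intervals(
        self, toy_spec, toy_reference, flat_incidence
    ):
        profiles = pd.DataFrame({"famhist": [1.0, 1.0], "bmi": ["mid", "mid"]})
        model = build_risk_model(
            flat_incidence, spec=toy_spec, reference=toy_reference, rng=0
        )
        res = predict_risks(
            model, profiles, age_start=np.array([50, 60]),
            interval_length=np.array([10, 20]), rng=1,
        )
        assert res.predictions["age_start"].tolist() == [50, 60]
        # longer interval on the same flat hazard gives larger risk
        assert res.predictions["risk"].iloc[1] > res.predictions["risk"].iloc[0]


class TestSnpOnlyModel:
    def test_internal_reference_scored_when_no_profiles(
        self, flat_incidence, toy_snps
    ):
        res = compute_absolute_risk_batch(
            flat_incidence, snps=toy_snps, n_internal_reference=3000, seed=2
        )
        assert len(res.predictions) == 3000
        assert 0 < res.mean_risk < 1

    def test_mean_reference_risk_close_to_marginal_risk(
        self, flat_incidence, toy_snps
    ):
        # population-average risk from the calibrated model must sit near the
        # risk implied by the marginal rates alone
        res = compute_absolute_risk_batch(
            flat_incidence, snps=toy_snps, n_internal_reference=5000, seed=3
        )
        marginal = 1 - np.exp(-0.003 * 30)
        assert res.mean_risk == pytest.approx(marginal, rel=0.05)

    def test_family_history_attenuation_applied(
        self, flat_incidence, toy_snps, toy_reference
    ):
        from absrisk import Covariate, ModelSpec

        spec = ModelSpec(
            covariates=[Covariate("famhist", "continuous")],
            log_relative_risks={"famhist": 0.5},
            family_history="famhist",
        )
        ref = toy_reference[["famhist"]]
        m_on = build_risk_model(
            flat_incidence, spec=spec, reference=ref, snps=toy_snps, rng=0
        )
        m_off = build_risk_model(
            flat_incidence, spec=spec, reference=ref, snps=toy_snps,
            apply_fh_attenuation=False, rng=0,
        )
        assert m_on.beta[0] == pytest.approx(attenuate_family_history(0.5, toy_snps))
        assert m_off.beta[0] == 0.5

    def test_missing_genotypes_imputed(self, flat_incidence, toy_snps):
        snp_prof = pd.DataFrame(
            {"rs1": [0.0, np.nan], "rs2": [1.0, 2.0], "rs3": [np.nan, 0.0]}
        )
        res = compute_absolute_risk_batch(
            flat_incidence, snps=toy_snps, snp_profiles=snp_prof,
            n_internal_reference=2000, seed=4,
        )
        assert np.isfinite(res.predictions["risk"]).all()


class TestSplitInterval:
    def test_identical_parameters_reduce_to_single_interval(
        self, toy_spec, toy_reference, flat_incidence, flat_mortality
    ):
        profiles = pd.DataFrame({"famhist": [1.0], "bmi": ["high"]})
        single = compute_absolute_risk_batch(
            flat_incidence, spec=toy_spec, reference=toy_reference,
            mortality=flat_mortality, profiles=profiles,
            age_start=50, interval_length=30, seed=5,
        )
        split = compute_absolute_risk_split_interval(
            60, flat_incidence, spec=toy_spec, reference=toy_reference,
            mortality=flat_mortality, profiles=profiles,
            age_start=50, interval_length=30, seed=5,
        )
        assert split.predictions["risk"].iloc[0] == pytest.approx(
            single.predictions["risk"].iloc[0], abs=1e-12
        )

    def test_cut_at_interval_start_uses_second_parameter_set(
        self, toy_spec, toy_reference, flat_incidence
    ):
        spec2 = type(toy_spec)(
            covariates=toy_spec.covariates,
            interactions=toy_spec.interactions,
            log_relative_risks={k: 2 * v for k, v in
                                toy_spec.log_relative_risks.items()},
            family_history=toy_spec.family_history,
        )
        profiles = pd.DataFrame({"famhist": [1.0], "bmi": ["high"]})
        split = compute_absolute_risk_split_interval(
            50, flat_incidence, spec=toy_spec, spec2=spec2,
            reference=toy_reference, profiles=profiles,
            age_start=50, interval_length=20, seed=6,
        )
        single2 = compute_absolute_risk_batch(
            flat_incidence, spec=spec2, reference=toy_reference,
            profiles=profiles, age_start=50, interval_length=20, seed=6,
        )
        assert split.predictions["risk"].iloc[0] == pytest.approx(
            single2.predictions["risk"].iloc[0], abs=1e-12
        )

    def test_two_betas_match_piecewise_quadrature(
        self, toy_reference, flat_incidence
    ):
        from absrisk import Covariate, ModelSpec

        spec1 = ModelSpec(
            covariates=[Covariate("famhist", "continuous")],
            log_relative_risks={"famhist": 0.3},
        )
        spec2 = ModelSpec(
            covariates=[Covariate("famhist", "continuous")],
            log_relative_risks={"famhist": 0.9},
        )
        ref = toy_reference[["famhist"]]
        profiles = pd.DataFrame({"famhist": [1.0]})
        split = compute_absolute_risk_split_interval(
            60, flat_incidence, spec=spec1, spec2=spec2, reference=ref,
            profiles=profiles, age_start=50, interval_length=30, seed=7,
        )

        # piecewise fine-grid oracle with each part's calibrated hazard
        m1 = build_risk_model(flat_incidence, spec=spec1, reference=ref, rng=0)
        m2 = build_risk_model(flat_incidence, spec=spec2, reference=ref, rng=0)

        def fine(lam0, lp, lo, hi, dt=1e-3):
            t = np.arange(lo, hi, dt)
            idx = np.floor(t).astype(int) - m1.lambda0.min_age
            h = lam0[idx] * np.exp(lp)
            cum = np.concatenate([[0.0], np.cumsum(h * dt)])[:-1]
            surv_in = np.exp(-(cum + 0.5 * h * dt))
            return np.sum(h * surv_in * dt), np.exp(-np.sum(h * dt))

        r1, s1 = fine(m1.lambda0.values, 0.3, 50, 60)
        r2, _ = fine(m2.lambda0.values, 0.9, 60, 80)
        assert split.predictions["risk"].iloc[0] == pytest.approx(
            r1 + s1 * r2, rel=0.01
        )

    def test_cut_outside_interval_rejected(
        self, toy_spec, toy_reference, flat_incidence
    ):
        profiles = pd.DataFrame({"famhist": [0.0], "bmi": ["low"]})
        with pytest.raises(ValueError, match="cut_age"):
            compute_absolute_risk_split_interval(
                45, flat_incidence, spec=toy_spec, reference=toy_reference,
                profiles=profiles, age_start=50, interval_length=10,
            )


class TestReferenceRisks:
    def test_reference_risks_returned_per_original_row(
        self, toy_spec, toy_reference, flat_incidence, toy_snps
    ):
        profiles = pd.DataFrame({"famhist": [0.0], "bmi": ["low"]})
        snp_prof = pd.DataFrame({"rs1": [0.0], "rs2": [1.0], "rs3": [2.0]})
        res = compute_absolute_risk_batch(
            flat_incidence, spec=toy_spec, reference=toy_reference,
            snps=toy_snps, profiles=profiles, snp_profiles=snp_prof,
            return_reference_risks=True, seed=8,
        )
        assert res.reference_risks.shape == (len(toy_reference),)
        assert np.all((res.reference_risks > 0) & (res.reference_risks < 1))
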