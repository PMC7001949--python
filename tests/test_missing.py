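import numpy as np
import pandas as pd
import pytest

from absrisk import (
    build_design_matrix,
    build_percentile_strata,
    impute_linear_predictors,
    impute_risk,
    partition_design_row,
)


class TestPartition:
    def test_complete_profile_has_empty_pattern(self, toy_spec):
        row = pd.Series({"famhist": 1.0, "bmi": "high"})
        part = partition_design_row(row, toy_spec, toy_spec.beta())
        assert part.missing_columns == ()
        assert part.observable_score == pytest.approx(0.5 + 0.3 + 0.12)

    def test_all_missing_scores_zero(self, toy_spec):
        row = pd.Series({"famhist": np.nan, "bmi": np.nan})
        part = partition_design_row(row, toy_spec, toy_spec.beta())
        assert part.observable_score == 0.0
        assert set(part.missing_columns) == set(toy_spec.design_columns())

    def test_interaction_unobservable_when_one_factor_missing(self, toy_spec):
        row = pd.Series({"famhist": 1.0, "bmi": np.nan})
        part = partition_design_row(row, toy_spec, toy_spec.beta())
        assert "famhist" not in part.missing_columns
        assert {"famhist:bmi[mid]", "famhist:bmi[high]"} <= set(part.missing_columns)
        assert part.observable_score == pytest.approx(0.5)


class TestPercentileStrata:
    def test_single_bin_holds_everything(self, rng):
        s = build_percentile_strata(rng.normal(0, 1, 57), n_bins=1)
        assert (s.assignments == 0).all()

    def test_equal_mass_bins(self, rng):
        scores = rng.normal(0, 1, 1000)
        s = build_percentile_strata(scores, n_bins=100)
        counts = np.bincount(s.assignments, minlength=100)
        assert (counts == 10).all()

    def test_weights_match_row_duplication(self, rng):
        scores = rng.normal(0, 1, 50)
        w = np.ones(50)
        w[0] = 2.0
        dup_scores = np.concatenate([[scores[0]], scores])
        a = build_percentile_strata(scores, weights=w, n_bins=10)
        b = build_percentile_strata(dup_scores, n_bins=10)
        np.testing.assert_allclose(a.cutpoints, b.cutpoints)

    def test_tied_scores_snap_to_populated_bin(self):
        s = build_percentile_strata(np.zeros(5), n_bins=4)
        # all reference rows share one stratum; any query must match it
        assert np.unique(s.assign(np.array([-1.0, 0.0, 1.0]))).tolist() == [0]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_percentile_strata(np.array([]))


def _risk_fn(scale=0.1):
    # monotone map from linear predictor to a probability-like risk
    return lambda lp: 1.0 - np.exp(-scale * np.exp(np.asarray(lp)))


class TestImputation:
    def test_complete_profile_equals_plug_in_for_any_seed(self, toy_spec, toy_reference):
        ref_design = build_design_matrix(toy_spec, toy_reference).to_numpy()
        beta = toy_spec.beta()
        row = pd.Series({"famhist": 1.0, "bmi": "mid"})
        fn = _risk_fn()
        plug_in = float(fn(np.array([0.5 + 0.1 - 0.05]))[0])
        for seed, n_imp in ((1, 1), (2, 7)):
            risk, lp = impute_risk(
                row, toy_spec, beta, ref_design, fn, n_imputations=n_imp, rng=seed
            )
            assert risk == pytest.approx(plug_in, abs=1e-12)
            assert lp == pytest.approx(0.55, abs=1e-12)

    def test_one_missing_binary_matches_enumeration_mixture(self, toy_spec, toy_reference):
        # famhist missing: donors come from the stratum matched on the
        # observable (bmi) score; the exact answer enumerates famhist in it
        ref_design = build_design_matrix(toy_spec, toy_reference).to_numpy()
        beta = toy_spec.beta()
        row = pd.Series({"famhist": np.nan, "bmi": "high"})
        fn = _risk_fn()
        n_imp = 2000
        risk, _ = impute_risk(
            row, toy_spec, beta, ref_design, fn, n_imputations=n_imp, rng=11
        )
        frame = row.to_frame().T
        design_row = build_design_matrix(toy_spec, frame, missing="nan").iloc[0]
        observed = ~design_row.isna().to_numpy()
        obs_score = float(np.nansum(design_row.to_numpy()[observed] * beta[observed]))
        ref_obs = ref_design @ np.where(observed, beta, 0.0)
        ref_uno = ref_design @ np.where(observed, 0.0, beta)
        strata = build_percentile_strata(ref_obs, n_bins=100)
        members = strata.members(int(strata.assign(np.array([obs_score]))[0]))
        exact = float(np.mean(fn(obs_score + ref_uno[members])))
        donor_risks = fn(obs_score + ref_uno[members])
        mc_se = float(np.std(donor_risks) / np.sqrt(n_imp))
        assert abs(risk - exact) < 3 * max(mc_se, 1e-12)

    def test_all_missing_approaches_population_average(self, toy_spec, toy_reference):
        ref_design = build_design_matrix(toy_spec, toy_reference).to_numpy()
        beta = toy_spec.beta()
        fn = _risk_fn()
        row = pd.Series({"famhist": np.nan, "bmi": np.nan})
        n_imp = 4000
        risk, _ = impute_risk(
            row, toy_spec, beta, ref_design, fn, n_imputations=n_imp, rng=3
        )
        pop_risks = fn(ref_design @ beta)
        mc_se = float(np.std(pop_risks) / np.sqrt(n_imp))
        assert abs(risk - float(np.mean(pop_risks))) < 3 * mc_se

    def test_reported_lp_is_stratum_average(self, toy_spec, toy_reference):
        ref_design = build_design_matrix(toy_spec, toy_reference).to_numpy()
        beta = toy_spec.beta()
        row = pd.Series({"famhist": np.nan, "bmi": np.nan})
        _, lp = impute_risk(
            row, toy_spec, beta, ref_design, _risk_fn(), n_imputations=5, rng=0
        )
        # all-missing matches the whole reference: reported linear predictor
        # is the population mean full score
        assert lp == pytest.approx(float(np.mean(ref_design @ beta)), abs=1e-12)

    def test_fixed_seed_determinism(self, toy_spec, toy_reference):
        ref_design = build_design_matrix(toy_spec, toy_reference).to_numpy()
        beta = toy_spec.beta()
        profiles = pd.DataFrame(
            {"famhist": [np.nan, 1.0], "bmi": ["mid", np.nan]}
        )
        design = build_design_matrix(toy_spec, profiles, missing="nan")
        out1 = impute_linear_predictors(design, beta, ref_design, rng=99)
        out2 = impute_linear_predictors(design, beta, ref_design, rng=99)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_weighted_donor_sampling_shifts_mixture(self, toy_spec, toy_reference):
        # weighting high-famhist reference rows up must raise the imputed risk
        ref_design = build_design_matrix(toy_spec, toy_reference).to_numpy()
        beta = toy_spec.beta()
        w_hi = np.where(toy_reference["famhist"].to_numpy() == 1, 10.0, 1.0)
        row = pd.Series({"famhist": np.nan, "bmi": np.nan})
        fn = _risk_fn()
        r_flat, _ = impute_risk(
            row, toy_spec, beta, ref_design, fn, n_imputations=3000, rng=5
        )
        r_hi, _ = impute_risk(
            row, toy_spec, beta, ref_design, fn, ref_weights=w_hi,
            n_imputations=3000, rng=5,
        )
        assert r_hi > r_flat
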