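"""Condition factors, impedance indices, calibration fits and selection."""

import math

import numpy as np
import pandas as pd
import pytest

import turtlebis as tb
from turtlebis.calibration import (IndexSpec, aicc_from_ols, average_replicates,
                                   cohort_design_frame, fit_calibration,
                                   list_equations, load_equation, select_model,
                                   split_validate)
from turtlebis.errors import ArgumentError, FitError

EQ2A = (-0.03, -0.29, 1.07, -0.11)  # final SCL^2/R50 coefficients


class TestElementary:
    @pytest.mark.parametrize("mass,scl,expected", [
        (10.0, 50.0, 0.8),
        (0.0, 50.0, 0.0),
        (100.0, 100.0, 1.0),
    ])
    def test_fulton_k(self, mass, scl, expected):
        assert tb.fulton_k(mass, scl) == pytest.approx(expected)

    def test_fulton_k_rejects_nonpositive_length(self):
        with pytest.raises(ArgumentError):
            tb.fulton_k(10.0, 0.0)

    @pytest.mark.parametrize("length,res,expected", [
        (45.0, 600.0, 3.375),
        (50.0, 500.0, 5.0),
    ])
    def test_impedance_index(self, length, res, expected):
        assert tb.impedance_index(length, res) == pytest.approx(expected)

    def test_impedance_index_rejects_zero_resistance(self):
        with pytest.raises(ArgumentError):
            tb.impedance_index(45.0, 0.0)

    def test_average_replicates(self):
        reps = [tb.measurement_from_cole(
            tb.ColeParameters(re=600 * f, ri_int=1200 * f, fc=30, alpha=0.7),
            n_replicates=1) for f in (0.99, 1.0, 1.01)]
        avg = average_replicates(reps)
        assert avg.n_replicates == 3
        assert avg.r0 == pytest.approx(np.mean([r.r0 for r in reps]))
        assert avg.r50 == pytest.approx(np.mean([r.r50 for r in reps]))


class TestFit:
    def test_exact_recovery_on_noise_free_cohort(self, noise_free_cohort):
        model = fit_calibration(cohort_design_frame(noise_free_cohort),
                                IndexSpec("scl", "r50"))
        for got, want in zip((model.beta0, model.beta_index,
                              model.beta_mass, model.beta_time), EQ2A):
            assert abs(got - want) / abs(want) < 1e-8
        assert model.r2 == pytest.approx(1.0)

    def test_monte_carlo_recovery_unbiased(self):
        # response-side noise (SD 0.19 kg) must leave coefficients unbiased
        true = np.array(EQ2A)
        est = []
        for rep in range(200):
            cohort = tb.generate_cohort(1000, seed=20_000 + rep)
            m = fit_calibration(cohort_design_frame(cohort), IndexSpec("scl", "r50"))
            est.append([m.beta0, m.beta_index, m.beta_mass, m.beta_time])
        est = np.array(est)
        bias = est.mean(axis=0) - true
        mc_se = est.std(axis=0, ddof=1) / math.sqrt(len(est))
        assert (np.abs(bias) <= 2 * mc_se).all()

    def test_aicc_matches_hand_formula_on_small_fixture(self, rng):
        n, k_coef = 10, 4  # intercept + 3 slopes
        x = rng.normal(size=(n, 3))
        y = 1.0 + x @ np.array([0.5, -0.3, 0.2]) + rng.normal(0, 0.1, n)
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(((y - X @ beta) ** 2).sum())
        k = k_coef + 1  # + variance
        loglik = -0.5 * n * (math.log(2 * math.pi * ssr / n) + 1)
        aic = -2 * loglik + 2 * k
        expected = aic + 2 * k * (k + 1) / (n - k - 1)
        assert aicc_from_ols(ssr, n, k) == pytest.approx(expected)
        # and through the fitting front end
        df = pd.DataFrame({"id": [str(i) for i in range(n)],
                           "idx": x[:, 0], "body_mass_kg": x[:, 1],
                           "time_after_capture_h": x[:, 2],
                           "nonat_mass_kg": y})
        m = fit_calibration(df, "idx")
        assert m.aicc == pytest.approx(expected)

    def test_rank_deficient_design_names_columns(self, noise_free_cohort):
        design = cohort_design_frame(noise_free_cohort)
        design["body_mass_kg"] = design["scl2_r50"]  # perfectly collinear
        with pytest.raises(FitError, match="scl2_r50"):
            fit_calibration(design, "scl2_r50")

    def test_missing_values_rejected(self, noise_free_cohort):
        design = cohort_design_frame(noise_free_cohort)
        design.loc[0, "scl2_r50"] = np.nan
        with pytest.raises(ArgumentError):
            fit_calibration(design, "scl2_r50")


class TestSelection:
    def test_single_candidate_is_rank_one(self, noise_free_cohort):
        ranked = select_model(cohort_design_frame(noise_free_cohort),
                              [IndexSpec("scl", "r50")])
        assert len(ranked) == 1
        assert ranked[0].name == "scl2_r50"

    def test_ranking_invariant_to_candidate_order(self, noise_free_cohort):
        design = cohort_design_frame(noise_free_cohort)
        cands = ["scl2_r50", "ccl2_r0", "scl2_rinf"]
        a = [m.name for m in select_model(design, cands)]
        b = [m.name for m in select_model(design, cands[::-1])]
        assert a == b

    def test_true_index_beats_noise_index(self):
        # the generating index wins the AICc ranking essentially always
        wins = 0
        for rep in range(100):
            cohort = tb.generate_cohort(60, seed=30_000 + rep)
            design = cohort_design_frame(cohort)
            noise_rng = np.random.default_rng(60_000 + rep)
            design["noise_index"] = noise_rng.uniform(1.0, 10.0, len(design))
            ranked = select_model(design, ["scl2_r50", "noise_index"])
            wins += ranked[0].name == "scl2_r50"
        assert wins >= 95

    def test_empty_candidates_rejected(self, noise_free_cohort):
        with pytest.raises(ArgumentError):
            select_model(cohort_design_frame(noise_free_cohort), [])


class TestSplitValidation:
    def test_split_sizes_match_two_thirds_rule(self):
        cohort = tb.generate_cohort(49, seed=6)
        result = split_validate(cohort_design_frame(cohort), "scl2_r50", seed=0)
        assert len(result.fit_ids) == 33
        assert len(result.test_ids) == 16

    def test_split_is_a_partition(self):
        cohort = tb.generate_cohort(30, seed=6)
        design = cohort_design_frame(cohort)
        result = split_validate(design, "scl2_r50", seed=3)
        assert set(result.fit_ids).isdisjoint(result.test_ids)
        assert set(result.fit_ids) | set(result.test_ids) == set(design["id"])

    def test_split_seeded_determinism(self):
        cohort = tb.generate_cohort(30, seed=6)
        design = cohort_design_frame(cohort)
        r1 = split_validate(design, "scl2_r50", seed=5)
        r2 = split_validate(design, "scl2_r50", seed=5)
        assert r1.fit_ids == r2.fit_ids and r1.test_ids == r2.test_ids

    def test_too_small_cohort_rejected(self):
        cohort = tb.generate_cohort(8, seed=6)
        with pytest.raises(ArgumentError):
            split_validate(cohort_design_frame(cohort), "scl2_r50", seed=0)


class TestPrediction:
    def test_final_equation_hand_evaluation(self):
        model = load_equation("final_scl_r50")
        pred = tb.predict_adipose_mass(10.0, 3.375, 1.0, model)
        assert pred.value == pytest.approx(0.41875)
        assert not pred.clipped

    def test_prediction_equation_hand_evaluation(self):
        model = load_equation("prediction_scl_r50")
        pred = tb.predict_adipose_mass(10.0, 3.375, 1.0, model)
        assert pred.value == pytest.approx(0.38)

    def test_identity_model_predicts_zero_adipose(self):
        model = tb.CalibrationModel(beta0=0.0, beta_index=0.0, beta_mass=1.0,
                                    beta_time=0.0, index_spec=IndexSpec("scl", "r50"),
                                    n_fit=49)
        pred = tb.predict_adipose_mass(12.5, 4.0, 2.0, model)
        assert pred.value == 0.0

    def test_negative_prediction_clipped_and_flagged(self):
        model = tb.CalibrationModel(beta0=0.0, beta_index=0.0, beta_mass=1.5,
                                    beta_time=0.0, index_spec=IndexSpec("scl", "r50"),
                                    n_fit=49)
        pred = tb.predict_adipose_mass(10.0, 4.0, 0.0, model)
        assert pred.value == 0.0 and pred.clipped

    def test_mass_balance_before_clipping(self, rng):
        model = load_equation("final_scl_r50")
        mass = rng.uniform(5, 30, 50)
        index = rng.uniform(2, 12, 50)
        time = rng.uniform(0, 4, 50)
        nonat = model.predict_nonat(mass, index, time)
        raw_adipose = mass - nonat
        assert np.allclose(raw_adipose + nonat, mass)

    def test_all_printed_equations_load(self):
        names = list_equations()
        assert set(names) == {"prediction_scl_r50", "prediction_ccl_r50",
                              "final_scl_r50", "final_ccl_r50"}
        for name in names:
            m = load_equation(name)
            assert m.beta_mass > 1.0  # nonadipose scales supra-linearly here

    def test_unknown_equation_rejected(self):
        with pytest.raises(ArgumentError):
            load_equation("nope")
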