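"""Logistic IRLS, GEE with sandwich variance, OR reporting, power search."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import expit

from hipshape.association import (
    RankDeficientError,
    SeparationError,
    bonferroni_alpha,
    fit_gee_logistic,
    fit_logistic_irls,
    minimal_detectable_or,
    or_at_k_sd,
    or_per_sd,
    run_association_scan,
)
from hipshape.clinical import add_outcome_flags
from hipshape.synthetic import GeneratorConfig, simulate_cohort


def two_by_two_design(a=30, b=20, c=10, d=40):
    """Exposure/outcome contingency data: exposed a/b, unexposed c/d."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return np.column_stack([np.ones(x.size), x]), y


class TestIRLS:
    def test_two_by_two_closed_form(self):
        # OR = ad/bc = 6.0; SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d)
        design, y = two_by_two_design()
        fit = fit_logistic_irls(design, y)
        assert np.exp(fit.params[1]) == pytest.approx(6.0, rel=1e-9)
        se_expected = np.sqrt(1 / 30 + 1 / 20 + 1 / 10 + 1 / 40)
        assert fit.bse()[1] == pytest.approx(se_expected, rel=1e-9)

    def test_balanced_intercept_only(self):
        y = np.array([0.0, 1.0] * 50)
        fit = fit_logistic_irls(np.ones((100, 1)), y)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)

    def test_null_simulation_within_three_se(self, rng):
        n = 10_000
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_logistic_irls(x, y)
        assert abs(fit.params[1]) < 3 * fit.bse()[1]

    def test_separation_raises(self):
        x = np.column_stack([np.ones(20), np.arange(20.0)])
        y = (np.arange(20) >= 10).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic_irls(x, y)

    def test_rank_deficiency_raises(self, rng):
        z = rng.standard_normal(50)
        x = np.column_stack([np.ones(50), z, 2 * z])
        with pytest.raises(RankDeficientError):
            fit_logistic_irls(x, (z > 0).astype(float))


def clustered_data(rng, n_clusters=200, sigma_u=0.5, beta=0.3):
    ids = np.repeat(np.arange(n_clusters), 2)
    n = ids.size
    z = rng.standard_normal(n)
    u = rng.normal(0, sigma_u, n_clusters)[ids]
    y = (rng.random(n) < expit(beta * z + u)).astype(float)
    return np.column_stack([np.ones(n), z]), y, ids


class TestGEE:
    def test_singleton_clusters_reduce_to_irls_and_hc_sandwich(self, rng):
        n = 300
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(0.4 * x[:, 1])).astype(float)
        gee = fit_gee_logistic(x, y, np.arange(n), working="exchangeable")
        irls = fit_logistic_irls(x, y)
        np.testing.assert_allclose(gee.params, irls.params, atol=1e-8)
        # sandwich equals the heteroskedasticity-robust covariance
        mu = expit(x @ irls.params)
        w = mu * (1 - mu)
        bread = np.linalg.inv(x.T @ (w[:, None] * x))
        meat = x.T @ (((y - mu) ** 2)[:, None] * x)
        np.testing.assert_allclose(gee.cov_robust, bread @ meat @ bread, atol=1e-10)

    def test_independence_working_equals_irls(self, rng):
        x, y, ids = clustered_data(rng)
        gee = fit_gee_logistic(x, y, ids, working="independence")
        irls = fit_logistic_irls(x, y)
        np.testing.assert_allclose(gee.params, irls.params, atol=1e-8)
        assert gee.alpha == 0.0

    def test_exchangeable_matches_independent_reference_implementation(self, rng):
        import statsmodels.api as sm
        from statsmodels.genmod.cov_struct import Exchangeable

        x, y, ids = clustered_data(rng)
        gee = fit_gee_logistic(x, y, ids, working="exchangeable")
        ref = sm.GEE(y, x, groups=ids, family=sm.families.Binomial(),
                     cov_struct=Exchangeable()).fit()
        np.testing.assert_allclose(gee.params, np.asarray(ref.params), atol=1e-7)
        np.testing.assert_allclose(gee.robust_bse(), np.asarray(ref.bse), rtol=1e-6)
        assert gee.alpha == pytest.approx(float(ref.cov_struct.dep_params), abs=1e-6)

    def test_sandwich_exceeds_model_se_for_cluster_constant_covariate(self, rng):
        # with a shared random intercept, ignoring clustering understates
        # the SE of a cluster-constant covariate; the sandwich recovers it
        ratios = []
        for _ in range(200):
            n_clusters = 60
            ids = np.repeat(np.arange(n_clusters), 2)
            xc = rng.standard_normal(n_clusters)[ids]  # cluster-constant
            u = rng.normal(0, 1.0, n_clusters)[ids]
            y = (rng.random(ids.size) < expit(0.3 * xc + u)).astype(float)
            design = np.column_stack([np.ones(ids.size), xc])
            try:
                fit = fit_gee_logistic(design, y, ids, working="independence")
            except SeparationError:
                continue
            ratios.append(fit.robust_bse()[1] / np.sqrt(fit.cov_model[1, 1]))
        assert np.mean(ratios) > 1.0

    def test_mixed_cluster_sizes(self, rng):
        import statsmodels.api as sm
        from statsmodels.genmod.cov_struct import Exchangeable

        sizes = rng.integers(1, 3, size=150)
        ids = np.repeat(np.arange(150), sizes)
        n = ids.size
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(0.3 * x[:, 1])).astype(float)
        gee = fit_gee_logistic(x, y, ids, working="exchangeable")
        ref = sm.GEE(y, x, groups=ids, family=sm.families.Binomial(),
                     cov_struct=Exchangeable()).fit()
        np.testing.assert_allclose(gee.params, np.asarray(ref.params), atol=1e-6)


class TestORReporting:
    def test_null_effect_symmetric_ci(self):
        design, y = two_by_two_design(25, 25, 25, 25)
        fit = fit_logistic_irls(design, y)
        o, lo, hi, p = or_per_sd(fit, 1)
        assert o == pytest.approx(1.0, abs=1e-9)
        assert lo * hi == pytest.approx(1.0, abs=1e-9)

    def test_wald_ci_plug_in_arithmetic(self):
        # beta = log 1.34, robust SE 0.118 -> OR 1.34 (1.06-1.69)
        beta, se = np.log(1.34), 0.118
        o = np.exp(beta)
        lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
        assert (round(o, 2), round(lo, 2), round(hi, 2)) == (1.34, 1.06, 1.69)

    def test_ci_log_symmetry_identity(self, rng):
        x, y, ids = clustered_data(rng)
        fit = fit_gee_logistic(x, y, ids)
        o, lo, hi, _ = or_per_sd(fit, 1)
        assert lo * hi == pytest.approx(np.exp(2 * np.log(o)), rel=1e-9)

    def test_or_at_k_sd_exponentiation(self):
        assert or_at_k_sd(0.75, -3) == 2.37
        assert or_at_k_sd(0.61, -3) == 4.41
        assert or_at_k_sd(0.75, -1) == 1.33
        assert or_at_k_sd(1.7, 0) == 1.0

    def test_or_at_k_sd_reciprocal_rule(self):
        # for protective per-SD ORs and negative k: OR^k == (1/OR)^|k|
        assert or_at_k_sd(0.8, -2) == round((1 / 0.8) ** 2, 2)
        with pytest.raises(ValueError):
            or_at_k_sd(-1.0, 2)

    def test_bonferroni_alpha(self):
        assert bonferroni_alpha(15) == 0.0033
        assert bonferroni_alpha(1) == 0.05
        assert bonferroni_alpha(20) == 0.0025
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


def scan_inputs_from_cohort(cfg):
    _, table, truth = simulate_cohort(cfg)
    flags = add_outcome_flags(table)
    hip_ids = table["participant_id"] + "_" + table["side"]
    scores = truth.true_scores.loc[hip_ids].to_numpy()
    scores = (scores - scores.mean(0)) / scores.std(0, ddof=1)
    outcomes = {"cartilage_defect": flags["cartilage_defect_present"].to_numpy()}
    covars = table[["age", "bmi", "symptomatic_status"]]
    return scores, outcomes, covars, table["participant_id"].to_numpy()


class TestAssociationScan:
    def test_power_on_true_mode_and_size_on_null_modes(self):
        n_seeds = 12
        hits, null_flags, null_total = 0, 0, 0
        for seed in range(n_seeds):
            cfg = GeneratorConfig(
                n_participants=300, seed=100 + seed, n_true_modes=5,
                effect_spec=((2, float(np.log(1.5))),), labral_effect_spec=(),
                random_effect_sd=0.5, baseline_logit=0.0,
            )
            scores, outcomes, covars, ids = scan_inputs_from_cohort(cfg)
            scan = run_association_scan(scores, outcomes, covars, ids, range(5))
            row = scan[scan["mode"] == 2].iloc[0]
            hits += (row["aci_low"] > 1.0) or (row["aci_high"] < 1.0)
            null = scan[scan["mode"] != 2]
            null_flags += int(null["sig_05"].sum())
            null_total += len(null)
        assert hits >= 0.8 * n_seeds
        # null rejections ~ Binomial(48, 0.05); allow 3 SD above the mean
        assert null_flags <= 0.05 * null_total + 3 * np.sqrt(null_total * 0.05 * 0.95)

    def test_constant_outcome_rows_flagged_failed(self, rng):
        n = 40
        scores = rng.standard_normal((n, 3))
        covars = pd.DataFrame({
            "age": np.full(n, 26.0), "bmi": np.full(n, 24.0),
            "symptomatic_status": ["symptomatic", "asymptomatic"] * (n // 2),
        })
        scan = run_association_scan(
            scores, {"cartilage_defect": np.ones(n)}, covars,
            np.repeat(np.arange(n // 2), 2), range(3),
        )
        assert scan["failed"].all()
        assert len(scan) == 3

    def test_row_count_matches_selection(self, rng):
        n = 80
        scores = rng.standard_normal((n, 6))
        y = (rng.random(n) < 0.5).astype(float)
        covars = pd.DataFrame({
            "age": rng.normal(26, 4, n), "bmi": rng.normal(24, 2, n),
            "symptomatic_status": rng.choice(
                ["symptomatic", "other", "asymptomatic"], n
            ),
        })
        scan = run_association_scan(
            scores, {"cartilage_defect": y, "labral_tear": 1 - y}, covars,
            np.repeat(np.arange(n // 2), 2), [0, 2, 5],
        )
        assert len(scan) == 6
        assert sorted(scan["mode"].unique()) == [1, 3, 6]

    def test_or_invariant_to_affine_score_rescaling(self, rng):
        # standardization makes the reported OR independent of the raw scale
        n = 200
        raw = rng.standard_normal(n) * 7.0 + 3.0
        std = (raw - raw.mean()) / raw.std(ddof=1)
        y = (rng.random(n) < expit(0.5 * std)).astype(float)
        ids = np.repeat(np.arange(n // 2), 2)
        design = np.column_stack([np.ones(n), std])
        fit1 = fit_gee_logistic(design, y, ids)
        rescaled = (5.0 * raw - 11.0)
        std2 = (rescaled - rescaled.mean()) / rescaled.std(ddof=1)
        fit2 = fit_gee_logistic(np.column_stack([np.ones(n), std2]), y, ids)
        np.testing.assert_allclose(or_per_sd(fit1, 1), or_per_sd(fit2, 1), rtol=1e-9)


class TestMinimalDetectableOR:
    def test_reciprocal_pair(self):
        o, recip = minimal_detectable_or(
            80, 0.4, power=0.8, n_replicates=120, seed=1
        )
        assert o * recip == pytest.approx(1.0, rel=1e-12)
        assert o > 1.0

    def test_larger_sample_detects_smaller_or(self):
        small, _ = minimal_detectable_or(60, 0.4, power=0.8, n_replicates=150, seed=2)
        large, _ = minimal_detectable_or(240, 0.4, power=0.8, n_replicates=150, seed=2)
        assert large < small

    def test_power_half_matches_analytic_crossing(self):
        # at 50% power the detectable log-OR satisfies beta / SE = z_crit;
        # SE from the Fisher information with a standard-normal exposure
        n, prev = 400, 0.5
        b0 = np.log(prev / (1 - prev))
        zs = np.linspace(-6, 6, 4001)
        wz = np.exp(-zs**2 / 2) / np.sqrt(2 * np.pi)
        wz /= wz.sum()

        def slope_se(beta):
            mu = expit(b0 + beta * zs)
            v = mu * (1 - mu)
            i00 = np.sum(wz * v)
            i01 = np.sum(wz * v * zs)
            i11 = np.sum(wz * v * zs**2)
            info = np.array([[i00, i01], [i01, i11]]) * n
            return np.sqrt(np.linalg.inv(info)[1, 1])

        beta_star = brentq(lambda b: b / slope_se(b) - 1.96, 1e-4, 1.0)
        sim, _ = minimal_detectable_or(
            n, prev, power=0.5, cluster_structure="independent",
            n_replicates=300, seed=3
        )
        assert sim == pytest.approx(np.exp(beta_star), abs=0.05)

    def test_bracket_failure_raises(self):
        with pytest.raises(RuntimeError, match="bracket"):
            minimal_detectable_or(10, 0.5, power=0.99, n_replicates=60,
                                  seed=4, max_or=1.3)
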