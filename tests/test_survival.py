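import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index as lifelines_cindex

import movae
from _oracles import (
    concordance_brute,
    cox_beta_grid,
    logrank_permutation_p,
    logrank_statistic,
)
from movae.survival import (
    DEFAULT_PENALTIES,
    SurvivalTable,
    concordance_index,
    cox_fit,
    cv_cindex,
    km_estimate,
    logrank_multivariate,
)
from movae.vae import LatentSpace


def table(time, event, n_cov=False):
    ids = [f"s{i}" for i in range(len(time))]
    return SurvivalTable(ids, np.asarray(time, float), np.asarray(event, int))


class TestConcordance:
    def test_perfect_concordance(self):
        t = table([1, 2, 3], [1, 1, 1])
        assert concordance_index([3, 2, 1], t) == 1.0

    def test_perfect_anticoncordance(self):
        t = table([1, 2, 3], [1, 1, 1])
        assert concordance_index([1, 2, 3], t) == 0.0

    def test_all_tied_risks_give_half(self):
        t = table([1, 2, 3], [1, 1, 1])
        assert concordance_index([5, 5, 5], t) == 0.5

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(0)
        t = table(rng.exponential(1, 30) + 0.01, rng.integers(0, 2, 30))
        risk = rng.normal(size=30)
        assert concordance_index(risk, t) + concordance_index(-risk, t) == pytest.approx(1.0)

    def test_matches_brute_force_and_lifelines(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(1, 40) + 0.01
        event = rng.integers(0, 2, 40)
        event[0] = 1
        risk = rng.normal(size=40)
        t = table(time, event)
        ours = concordance_index(risk, t)
        assert ours == pytest.approx(concordance_brute(risk, time, event))
        # lifelines counts concordance of predicted survival time (higher = longer)
        assert ours == pytest.approx(lifelines_cindex(time, -risk, event))

    def test_no_comparable_pairs_rejected(self):
        t = table([1, 2], [0, 0])
        with pytest.raises(ValueError):
            concordance_index([1, 2], t)


class TestCoxFit:
    def test_matches_partial_likelihood_grid_oracle(self):
        time, event, x = [1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 1, 0]
        fit = cox_fit({"x": x}, table(time, event))
        oracle = cox_beta_grid(x, time, event)
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-3)

    def test_complete_separation_is_flagged(self):
        # group 1 dies strictly first: the partial-likelihood MLE is unbounded
        with pytest.warns(UserWarning, match="separation|convergence"):
            fit = cox_fit({"x": [1, 1, 0, 0]}, table([1, 2, 3, 4], [1, 1, 1, 1]))
        assert fit.flags

    def test_likelihood_at_estimate_beats_null(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        t = table(rng.exponential(np.exp(-0.5 * x)) + 1e-3, np.ones(60))
        fit = cox_fit({"x": x}, t)
        from _oracles import efron_partial_loglik_1cov

        assert fit.log_likelihood >= efron_partial_loglik_1cov(0.0, x, t.time, t.event)

    def test_strong_ridge_shrinks_towards_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        t = table(rng.exponential(np.exp(-x)) + 1e-3, np.ones(100))
        loose = cox_fit({"x": x}, t, ridge_penalty=0.0)
        tight = cox_fit({"x": x}, t, ridge_penalty=1e6)
        assert abs(tight.coef[0]) < 1e-2 < abs(loose.coef[0])

    def test_null_covariate_ci_covers_zero(self):
        covered = 0
        for rep in range(40):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=150)
            t = table(rng.exponential(1, 150) + 1e-3, np.ones(150))
            fit = cox_fit({"x": x}, t)
            covered += fit.ci_lower[0] <= 0 <= fit.ci_upper[0]
        assert covered >= 34  # ~95% nominal coverage, loose bound

    def test_rejects_no_events_and_constant_covariates(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit({"x": [1.0, 2.0]}, table([1, 2], [0, 0]))
        with pytest.raises(ValueError, match="constant"):
            cox_fit({"x": [1.0, 1.0, 1.0]}, table([1, 2, 3], [1, 1, 1]))

    def test_parameter_recovery_simulation(self, cox_recovery_sims):
        betas = np.array([r["beta"] for r in cox_recovery_sims])
        ses = np.array([r["se"] for r in cox_recovery_sims])
        assert 0.85 <= betas.mean() <= 1.15
        assert np.mean(np.abs(betas - 1.0) <= 3 * ses) >= 0.9


class TestKaplanMeier:
    def test_two_deaths_step_function(self):
        curves = km_estimate(table([1, 2], [1, 1]), ["g", "g"])
        df = curves["g"].set_index("time")["survival"]
        assert df.loc[1] == 0.5 and df.loc[2] == 0.0

    def test_all_censored_stays_at_one(self):
        curves = km_estimate(table([1, 2, 3], [0, 0, 0]), ["g"] * 3)
        assert (curves["g"]["survival"] == 1.0).all()

    def test_curve_is_nonincreasing(self):
        rng = np.random.default_rng(4)
        t = table(rng.exponential(1, 50) + 0.01, rng.integers(0, 2, 50))
        curves = km_estimate(t, ["g"] * 50)
        assert (np.diff(curves["g"]["survival"]) <= 1e-12).all()

    def test_group_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(table([1], [1]), [])


class TestLogrank:
    def test_identical_groups_give_null(self):
        time = [1, 2, 3, 4] * 2
        event = [1, 1, 1, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        chi2, df, p = logrank_multivariate(table(time, event), groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_extreme_separation_is_significant(self):
        time = [1.0] * 20 + [10.0] * 20
        event = [1] * 40
        groups = ["a"] * 20 + ["b"] * 20
        _, df, p = logrank_multivariate(table(time, event), groups)
        assert p < 0.001 and df == 1

    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(5)
        t = table(rng.exponential(1, 30) + 0.01, np.ones(30))
        _, df, _ = logrank_multivariate(t, rng.integers(0, 3, 30))
        assert df == 2

    def test_statistic_matches_first_principles_oracle(self):
        rng = np.random.default_rng(6)
        time = rng.exponential(1, 24) + 0.01
        event = rng.integers(0, 2, 24)
        event[:4] = 1
        groups = rng.integers(0, 2, 24)
        chi2, _, _ = logrank_multivariate(table(time, event), groups)
        assert chi2 == pytest.approx(logrank_statistic(time, event, groups), rel=1e-6)

    def test_chi_square_p_agrees_with_permutation(self):
        rng = np.random.default_rng(7)
        time = np.concatenate([rng.exponential(1.0, 15), rng.exponential(2.2, 15)])
        event = np.ones(30, int)
        groups = np.array([0] * 15 + [1] * 15)
        _, _, p = logrank_multivariate(table(time + 0.01, event), groups)
        p_perm = logrank_permutation_p(time + 0.01, event, groups, 2000, rng)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 2000)
        assert abs(p - p_perm) <= mc_err + 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_multivariate(table([1, 2], [1, 1]), ["a", "a"])


class TestCVCindex:
    def _synthetic(self, informative, seed=0, n=500, k=4):
        stack, truth = movae.generate_multiomics(
            n_samples=n, n_expr=10, n_mut=5, n_cnv=5, k_star=k, seed=seed
        )
        beta = [1.0] if informative else [0.0]
        tab = movae.generate_survival(truth, beta, censor_fraction=0.3, seed=seed + 1)
        Z = LatentSpace(truth.Z, truth.sample_ids)
        return Z, tab

    def test_informative_factor_predicts_survival(self):
        Z, tab = self._synthetic(informative=True)
        res = cv_cindex(Z, tab, folds=5, seed=0)
        assert res["best_mean_cindex"] >= 0.65

    def test_noise_factors_hover_at_chance(self):
        rng = np.random.default_rng(8)
        Z, tab = self._synthetic(informative=False)
        noise = LatentSpace(np.maximum(rng.normal(size=(500, 6)), 0), Z.sample_ids)
        res = cv_cindex(noise, tab, folds=5, seed=0)
        assert 0.40 <= res["best_mean_cindex"] <= 0.60

    def test_default_penalty_grid(self):
        assert DEFAULT_PENALTIES == (1.0, 10.0, 100.0, 1000.0, 10000.0)
        Z, tab = self._synthetic(informative=True, n=120)
        res = cv_cindex(Z, tab, folds=3, seed=0)
        assert set(res["mean_cindex"]) == set(DEFAULT_PENALTIES)
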