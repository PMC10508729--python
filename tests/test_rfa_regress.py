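import numpy as np
import pytest
from sklearn.linear_model import Lasso

from rfa.genotype_space import GenotypeSpace, TermKey, encode_design, enumerate_genotypes
from rfa.nonspecific_link import LinkParams
from rfa.rfa_exact import EffectSet, PhenotypeTable, exact_effects
from rfa.rfa_regress import (
    FitConfig,
    cross_validate,
    fit,
    fit_binary_fourier,
    out_of_sample_r2,
)
from rfa.simulate import (
    SimulationSpec,
    sample_table,
    simulate_architecture,
    simulate_phenotypes,
)

from conftest import random_table


class TestFit:
    @pytest.mark.parametrize("basis", ["onehot", "zero_sum"])
    def test_lambda_zero_complete_equals_exact(self, basis):
        sp = GenotypeSpace.uniform(3, 4)
        t = random_table(sp, seed=0)
        res = fit(t, FitConfig(max_order=2, use_link=False), lam=0.0, basis=basis)
        ex = exact_effects(t, 2)
        diffs = [abs(res.effects.get(k) - ex.get(k)) for k, _ in ex.term_items()]
        assert max(diffs) < 1e-8
        assert res.effects.intercept == pytest.approx(ex.intercept, abs=1e-8)

    def test_constant_phenotype_gives_intercept_only(self):
        sp = GenotypeSpace.uniform(2, 3)
        g = enumerate_genotypes(sp)
        t = PhenotypeTable(sp, g, np.full((len(g), 1), 2.5))
        res = fit(t, FitConfig(max_order=2, use_link=False, grad_tol=1e-12),
                  lam=0.1)
        assert res.effects.intercept == pytest.approx(2.5, abs=1e-4)
        assert all(abs(v) < 1e-4 for _, v in res.effects.term_items())

    def test_matches_sklearn_lasso_at_positive_lambda(self):
        # independent coordinate-descent oracle for the L1 objective
        # (sklearn normalizes by 2n; our objective is plain SSE + lam*|b|)
        sp = GenotypeSpace.uniform(3, 4)
        t = random_table(sp, seed=2)
        y = t.mean_phenotypes
        X, _ = encode_design(sp, t.genotypes, 2, basis="zero_sum")
        for lam in (1.0, 10.0):
            res = fit(
                t, FitConfig(max_order=2, use_link=False, grad_tol=1e-12),
                lam=lam, basis="zero_sum",
            )
            oracle = Lasso(alpha=lam / (2 * len(y)), fit_intercept=True,
                           max_iter=200_000, tol=1e-14)
            oracle.fit(X[:, 1:], y)
            assert np.max(np.abs(res.raw_coefficients[1:] - oracle.coef_)) < 1e-6

    def test_joint_link_and_effect_recovery(self):
        # sigmoid-generated additive landscape, half sampled, no penalty
        sp = GenotypeSpace.uniform(3, 5)
        truth = simulate_architecture(
            SimulationSpec(sp, orders=(1,), link=LinkParams(0.0, 4.0), seed=3)
        )
        table = sample_table(simulate_phenotypes(truth, seed=4), 0.5, seed=5)
        res = fit(table, FitConfig(max_order=1, use_link=True, grad_tol=1e-9),
                  lam=0.0, n_restarts=1)
        assert res.effects.link.L == pytest.approx(0.0, abs=0.01)
        assert res.effects.link.U == pytest.approx(4.0, abs=0.01)
        errs = [
            abs(res.effects.get(k) - v) for k, v in truth.term_items()
        ]
        assert max(errs) < 0.05

    def test_too_few_rows(self):
        sp = GenotypeSpace.uniform(2, 2)
        t = PhenotypeTable(sp, np.array([[0, 0]]), np.array([[1.0]]))
        with pytest.raises(ValueError, match="2 rows"):
            fit(t, FitConfig(use_link=False))


class TestOutOfSampleR2:
    def test_perfect_predictions(self):
        sp = GenotypeSpace.uniform(2, 3)
        t = random_table(sp, seed=6)
        eff = exact_effects(t, 3)
        assert out_of_sample_r2(eff, t) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        sp = GenotypeSpace.uniform(2, 3)
        t = random_table(sp, seed=7)
        eff = EffectSet(sp, float(np.mean(t.mean_phenotypes)))
        assert out_of_sample_r2(eff, t) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_test_set(self):
        sp = GenotypeSpace.uniform(2, 2)
        t = PhenotypeTable(sp, enumerate_genotypes(sp), np.full((4, 1), 1.0))
        with pytest.raises(ValueError, match="variance"):
            out_of_sample_r2(EffectSet(sp, 1.0), t)


class TestCrossValidate:
    def test_noiseless_plateau_selects_strong_lambda(self):
        # realizable additive truth without noise: the R2 plateau spans
        # weak penalties, and the rule picks the strongest one on it
        sp = GenotypeSpace.uniform(3, 4)
        truth = simulate_architecture(SimulationSpec(sp, orders=(1,), seed=8))
        table = simulate_phenotypes(truth, seed=9)
        res = cross_validate(
            table,
            FitConfig(max_order=1, use_link=False, cv_folds=5, cv_repeats=1,
                      n_lambda=10, seed=1),
        )
        cv = res.cv_table
        best = cv["mean_r2"].max()
        chosen_row = cv.loc[cv["lambda"] == res.chosen_lambda].iloc[0]
        assert res.chosen_lambda > 0  # some regularization retained
        assert chosen_row["mean_r2"] >= best - 0.01  # on the plateau
        # everything stronger than the chosen strength sits off the plateau
        stronger = cv[cv["lambda"] > res.chosen_lambda]
        assert (stronger["mean_r2"] <= chosen_row["mean_r2"] + 1e-9).all()

    def test_pure_noise_drives_model_to_intercept(self):
        sp = GenotypeSpace.uniform(3, 4)
        table = random_table(sp, seed=10)
        res = cross_validate(
            table,
            FitConfig(max_order=2, use_link=False, cv_folds=5, cv_repeats=2,
                      n_lambda=10, seed=2),
        )
        row = res.cv_table.loc[res.cv_table["lambda"] == res.chosen_lambda].iloc[0]
        assert abs(row["pooled_r2"]) < 0.1
        assert res.effects.n_nonzero_terms <= 5
        assert all(abs(v) < 0.3 for _, v in res.effects.term_items())

    def test_sparse_support_recovered_with_noise(self):
        # planted sparse architecture: the selected model's support
        # contains the large true terms
        sp = GenotypeSpace.uniform(3, 4)
        truth = EffectSet.from_terms(
            sp, 0.0,
            {
                TermKey((0,), (0,)): 1.5, TermKey((0,), (1,)): -0.5,
                TermKey((0,), (2,)): -1.0,
                TermKey((2,), (0,)): -2.0, TermKey((2,), (1,)): 1.0,
                TermKey((2,), (2,)): 1.0,
            },
            max_order=2,
        )
        table = simulate_phenotypes(truth, omega=0.05, seed=11)
        table = sample_table(table, 0.6, seed=12)
        res = cross_validate(
            table,
            FitConfig(max_order=2, use_link=False, cv_folds=5, cv_repeats=1,
                      n_lambda=10, seed=3),
        )
        for key, v in truth.term_items():
            if abs(v) >= 1.0:
                est = res.effects.get(key)
                assert np.sign(est) == np.sign(v)
                assert abs(est - v) < 0.5

    def test_small_replicated_table_uses_leave_one_replicate_out(self):
        sp = GenotypeSpace.uniform(3, 3)  # 27 genotypes < 50
        truth = simulate_architecture(SimulationSpec(sp, orders=(1,), seed=13))
        rng_tab = simulate_phenotypes(truth, omega=0.01, n_replicates=3, seed=14)
        assert rng_tab.n_replicates == 3
        res = cross_validate(
            rng_tab,
            FitConfig(max_order=1, use_link=False, n_lambda=8, seed=4),
        )
        # one CV replicate per measurement replicate
        assert res.cv_table["n_folds"].iloc[0] == 3
        assert res.r2_in_sample > 0.95

    def test_kfold_needs_enough_rows(self):
        sp = GenotypeSpace.uniform(2, 2)
        t = random_table(sp, seed=15)
        with pytest.raises(ValueError, match="rows"):
            cross_validate(t, FitConfig(use_link=False, cv_folds=10,
                                        cv_scheme="kfold"))


class TestUnbiasednessAndConsistency:
    def test_first_order_estimates_unbiased_under_random_sampling(self):
        # noiseless landscape with higher-order terms; order-1 regression
        # on random 30% samples is unbiased for the true additive effects
        sp = GenotypeSpace.uniform(3, 4)
        truth = simulate_architecture(SimulationSpec(sp, orders=(1, 2, 3), seed=16))
        table = simulate_phenotypes(truth, seed=17)
        keys = [k for k, _ in truth.term_items() if k.order == 1]
        config = FitConfig(max_order=1, use_link=False)
        estimates = []
        for rep in range(200):
            sub = sample_table(table, 0.3, seed=1000 + rep)
            res = fit(sub, config, lam=0.0)
            estimates.append([res.effects.get(k) for k in keys])
        est = np.array(estimates)
        true_vals = np.array([truth.get(k) for k in keys])
        se = est.std(axis=0, ddof=1) / np.sqrt(est.shape[0])
        z = np.abs(est.mean(axis=0) - true_vals) / np.maximum(se, 1e-12)
        # no term should be biased; allow a generous multiple-testing margin
        assert np.max(z) < 4.5

    def test_error_shrinks_with_sampling_fraction(self):
        sp = GenotypeSpace.uniform(3, 4)
        truth = simulate_architecture(SimulationSpec(sp, orders=(1, 2), seed=18))
        table = simulate_phenotypes(truth, seed=19)
        keys = [k for k, _ in truth.term_items()]
        config = FitConfig(max_order=2, use_link=False)
        med_errs = []
        for frac in (0.4, 0.7, 1.0):
            errs = []
            for rep in range(5):
                sub = sample_table(table, frac, seed=500 + rep)
                res = fit(sub, config, lam=0.0)
                errs.extend(abs(res.effects.get(k) - truth.get(k)) for k in keys)
            med_errs.append(float(np.median(errs)))
        assert med_errs[0] > med_errs[1] > med_errs[2]
        assert med_errs[2] < 1e-8


class TestBinaryFourier:
    def test_complete_lambda0_equals_exact(self):
        sp = GenotypeSpace.uniform(2, 4)
        t = random_table(sp, seed=20)
        res = fit_binary_fourier(t, FitConfig(max_order=4, use_link=False), lam=0.0)
        ex = exact_effects(t, 4)
        diffs = [abs(res.effects.get(k) - ex.get(k)) for k, _ in ex.term_items()]
        assert max(diffs) < 1e-8

    def test_additive_landscape_has_zero_interactions(self):
        sp = GenotypeSpace.uniform(2, 3)
        g = enumerate_genotypes(sp)
        y = 1.0 + 0.5 * g[:, 0] - 0.3 * g[:, 1] + 0.8 * g[:, 2]
        t = PhenotypeTable(sp, g, y[:, None].astype(float))
        res = fit_binary_fourier(t, FitConfig(max_order=3, use_link=False), lam=0.0)
        for key, b in zip(res.columns, res.raw_coefficients):
            if key.order > 1:
                assert abs(b) < 1e-9

    def test_single_site_closed_form(self):
        # f = (y(A) - y(B)) / 2 in the +/-1 convention (state A -> +1);
        # canonical effects are e(A) = +f, e(B) = -f
        sp = GenotypeSpace.uniform(2, 1)
        yA, yB = 1.0, 3.0
        t = PhenotypeTable(sp, np.array([[0], [1]]),
                           np.array([[yA], [yB]]))
        res = fit_binary_fourier(t, FitConfig(max_order=1, use_link=False), lam=0.0)
        f = (yA - yB) / 2
        assert res.effects.get(TermKey((0,), (0,))) == pytest.approx(f)
        assert res.effects.get(TermKey((0,), (1,))) == pytest.approx(-f)

    def test_rejects_non_binary(self):
        t = random_table(GenotypeSpace.uniform(3, 2), seed=21)
        with pytest.raises(ValueError, match="binary"):
            fit_binary_fourier(t, FitConfig(use_link=False), lam=0.0)
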