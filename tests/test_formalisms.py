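import itertools

import numpy as np
import pytest
from scipy.linalg import hadamard

from rfa.formalisms import (
    MissingGenotypesError,
    ba_effects,
    convert,
    fourier_effects,
    rba_effects,
    rba_fit_with_link,
)
from rfa.genotype_space import GenotypeSpace, TermKey, enumerate_genotypes
from rfa.nonspecific_link import LinkParams, link_transform
from rfa.rfa_exact import EffectSet, PhenotypeTable, exact_effects
from rfa.rfa_regress import FitConfig, fit
from rfa.simulate import SimulationSpec, sample_table, simulate_architecture

from conftest import random_table


def ba_oracle(space, y_flat, sites, states, ref=None):
    """Independent oracle: background-averaged term as the literal average
    over backgrounds of the finite difference between mutant and
    reference states at the focal sites."""
    ref = ref if ref is not None else [0] * space.n_sites
    other = [i for i in range(space.n_sites) if i not in sites]
    y = np.asarray(y_flat).reshape(space.shape)
    total, count = 0.0, 0
    for bg in itertools.product(*[range(space.shape[i]) for i in other]):
        acc = 0.0
        for r in range(len(sites) + 1):
            for sub in itertools.combinations(range(len(sites)), r):
                g = [0] * space.n_sites
                for i, b in zip(other, bg):
                    g[i] = b
                for j, i in enumerate(sites):
                    g[i] = states[j] if j in sub else ref[i]
                acc += (-1) ** (len(sites) - r) * y[tuple(g)]
        total += acc
        count += 1
    return total / count


class TestRBA:
    def test_first_order_is_mutant_minus_reference(self):
        sp = GenotypeSpace.uniform(3, 2)
        t = random_table(sp, seed=0)
        ref = np.array([0, 0])
        model = rba_effects(t, ref, 1)
        y = dict(zip(map(tuple, t.genotypes), t.mean_phenotypes))
        assert model.intercept == pytest.approx(y[(0, 0)])
        assert model.terms[TermKey((0,), (2,))] == pytest.approx(
            y[(2, 0)] - y[(0, 0)]
        )

    def test_order_k_exact_on_low_order_mutants(self, small_space):
        t = random_table(small_space, seed=1)
        ref = enumerate_genotypes(small_space)[-1]
        k = min(2, small_space.n_sites)
        model = rba_effects(t, ref, k)
        order = np.sum(t.genotypes != ref[None, :], axis=1)
        low = order <= k
        pred = model.predict(t.genotypes[low])
        assert np.max(np.abs(pred - t.mean_phenotypes[low])) < 1e-9

    def test_full_order_exact_everywhere(self, small_space):
        t = random_table(small_space, seed=2)
        model = rba_effects(t, t.genotypes[0], small_space.n_sites)
        assert np.max(np.abs(model.predict(t.genotypes) - t.mean_phenotypes)) < 1e-9

    def test_constant_landscape_all_zero(self):
        sp = GenotypeSpace.uniform(2, 3)
        g = enumerate_genotypes(sp)
        t = PhenotypeTable(sp, g, np.full((len(g), 1), 4.0))
        model = rba_effects(t, g[0], 3)
        assert all(abs(v) < 1e-12 for v in model.terms.values())

    def test_missing_mutant_listed(self):
        sp = GenotypeSpace.uniform(2, 2)
        g = enumerate_genotypes(sp)
        keep = sp.ravel(g) != sp.ravel(np.array([[0, 1]]))[0]
        t = PhenotypeTable(sp, g[keep], np.zeros((keep.sum(), 1)))
        with pytest.raises(MissingGenotypesError, match="AC"):
            rba_effects(t, np.array([0, 0]), 1)


class TestFourier:
    def test_binary_matches_walsh_hadamard(self):
        # 2^3 landscape: coefficients equal the Hadamard transform up to
        # the sqrt(2)-per-site normalization of the orthonormal basis
        sp = GenotypeSpace.uniform(2, 3)
        t = random_table(sp, seed=3)
        y = t.mean_phenotypes
        H = hadamard(8)  # Kronecker order matches site-0-slowest raveling
        f = H @ y / 8
        model = fourier_effects(t, 3)
        assert model.intercept == pytest.approx(f[0], abs=1e-10)
        for key, coef in model.coeffs.items():
            # Hadamard row index: bit i set when site i is involved
            j = sum(1 << (2 - i) for i in key.sites)
            expect = f[j] * np.sqrt(2) ** len(key.sites)
            assert coef == pytest.approx(expect, abs=1e-9)

    def test_full_order_exact(self, small_space):
        t = random_table(small_space, seed=4)
        model = fourier_effects(t, small_space.n_sites)
        assert np.max(np.abs(model.predict(t.genotypes) - t.mean_phenotypes)) < 1e-9

    def test_constant_landscape(self):
        sp = GenotypeSpace.uniform(3, 2)
        g = enumerate_genotypes(sp)
        t = PhenotypeTable(sp, g, np.full((len(g), 1), 2.0))
        model = fourier_effects(t, 2)
        assert model.intercept == pytest.approx(2.0)
        assert all(abs(v) < 1e-10 for v in model.coeffs.values())


class TestBackgroundAveraged:
    def test_binary_matches_averaged_finite_difference(self):
        sp = GenotypeSpace.uniform(2, 3)
        t = random_table(sp, seed=5)
        model = ba_effects(t, 3)
        for key, v in model.terms.items():
            assert v == pytest.approx(
                ba_oracle(sp, t.mean_phenotypes, key.sites, key.states), abs=1e-9
            )

    def test_multistate_matches_averaged_finite_difference(self):
        sp = GenotypeSpace.uniform(3, 3)
        t = random_table(sp, seed=6)
        model = ba_effects(t, 3)
        for key, v in model.terms.items():
            assert v == pytest.approx(
                ba_oracle(sp, t.mean_phenotypes, key.sites, key.states), abs=1e-9
            )

    def test_full_order_exact(self, small_space):
        t = random_table(small_space, seed=7)
        model = ba_effects(t, small_space.n_sites)
        assert np.max(np.abs(model.predict(t.genotypes) - t.mean_phenotypes)) < 1e-9

    def test_nondefault_reference_states(self):
        sp = GenotypeSpace.uniform(3, 2)
        t = random_table(sp, seed=8)
        ref = np.array([2, 1])
        model = ba_effects(t, 2, reference_states=ref)
        for key, v in model.terms.items():
            assert v == pytest.approx(
                ba_oracle(sp, t.mean_phenotypes, key.sites, key.states, ref=ref),
                abs=1e-9,
            )


class TestConvert:
    @pytest.mark.parametrize("target", ["fourier", "ba", "rba"])
    def test_round_trip_and_prediction_identity(self, target):
        sp = GenotypeSpace.uniform(3, 3)
        t = random_table(sp, seed=9)
        g = enumerate_genotypes(sp)
        for order in (1, 2, 3):
            eff = exact_effects(t, order)
            m = convert(eff, target)
            assert np.max(np.abs(m.predict(g) - eff.predict(g))) < 1e-9
            back = convert(m, "rfa")
            assert np.max(np.abs(back.predict(g) - eff.predict(g))) < 1e-9
            for key, v in eff.term_items():
                assert back.get(key) == pytest.approx(v, abs=1e-9)

    def test_additive_rfa_to_rba_closed_form(self):
        # RBA term for mutation a->b at site i equals e_i(b) - e_i(a)
        sp = GenotypeSpace.uniform(3, 2)
        eff = EffectSet.from_terms(
            sp, 1.0,
            {
                TermKey((0,), (0,)): 0.6, TermKey((0,), (1,)): -0.1,
                TermKey((0,), (2,)): -0.5,
                TermKey((1,), (0,)): 0.2, TermKey((1,), (1,)): -0.2,
                TermKey((1,), (2,)): 0.0,
            },
            max_order=1,
        )
        rba = convert(eff, "rba", reference=np.array([0, 0]))
        assert rba.terms[TermKey((0,), (2,))] == pytest.approx(-0.5 - 0.6)
        assert rba.terms[TermKey((1,), (1,))] == pytest.approx(-0.2 - 0.2)

    def test_zero_model_stays_zero(self):
        sp = GenotypeSpace.uniform(2, 3)
        eff = EffectSet(sp, 0.0, max_order=2)
        for target in ("fourier", "ba", "rba"):
            m = convert(eff, target)
            assert np.max(np.abs(m.predict(enumerate_genotypes(sp)))) < 1e-12

    def test_link_carried_through(self):
        sp = GenotypeSpace.uniform(2, 2)
        t = random_table(sp, seed=10)
        eff = exact_effects(t, 2)
        eff.link = LinkParams(0.0, 1.0)
        m = convert(eff, "fourier")
        assert m.link == eff.link

    def test_unsupported_target(self):
        sp = GenotypeSpace.uniform(2, 2)
        with pytest.raises(ValueError, match="formalism"):
            convert(EffectSet(sp, 0.0), "nope")


class TestRBAWithLink:
    def _sigmoid_additive_table(self, seed=11):
        sp = GenotypeSpace.uniform(3, 4)
        truth = simulate_architecture(
            SimulationSpec(sp, orders=(1,), link=LinkParams(0.0, 2.0), seed=seed)
        )
        g = enumerate_genotypes(sp)
        y = np.asarray(truth.predict(g))
        return truth, PhenotypeTable(sp, g, y[:, None])

    def test_recovers_high_r2_when_grid_holds_truth(self):
        truth, table = self._sigmoid_additive_table()
        res = rba_fit_with_link(table, np.zeros(4, dtype=int), 1)
        assert res.r2_higher_order > 0.98

    def test_degenerate_grid_equals_direct_computation(self):
        truth, table = self._sigmoid_additive_table()
        true_link = LinkParams(0.0, 2.0)
        res = rba_fit_with_link(table, np.zeros(4, dtype=int), 1,
                                link_grid=[true_link])
        assert res.link == true_link
        assert res.r2_higher_order > 0.999

    def test_third_order_only_truth_fits_poorly(self):
        sp = GenotypeSpace.uniform(3, 4)
        truth = simulate_architecture(
            SimulationSpec(sp, orders=(3,), link=LinkParams(0.0, 2.0), seed=12)
        )
        g = enumerate_genotypes(sp)
        y = np.asarray(truth.predict(g))
        table = PhenotypeTable(sp, g, y[:, None])
        res = rba_fit_with_link(table, np.zeros(4, dtype=int), 1)
        assert res.r2_higher_order < 0.5


class TestRegressionMisestimatesRBA:
    def test_regression_rba_differs_from_definition_under_sampling(self):
        # truncated reference-based terms estimated by least squares are
        # not the inclusion-exclusion terms when data are incomplete
        sp = GenotypeSpace.uniform(3, 4)
        truth = simulate_architecture(SimulationSpec(sp, orders=(1, 2, 3), seed=13))
        g = enumerate_genotypes(sp)
        y = np.asarray(truth.predict(g))
        table = PhenotypeTable(sp, g, y[:, None])
        ref = np.zeros(4, dtype=int)

        exact_rba = rba_effects(table, ref, 1)
        sub = sample_table(table, 0.5, seed=14)
        res = fit(sub, FitConfig(max_order=1, use_link=False), lam=0.0,
                  basis="dummy", reference=ref)
        reg_terms = dict(zip(res.columns, res.raw_coefficients))
        diffs = [
            abs(reg_terms[key] - exact_rba.terms[key])
            for key in exact_rba.terms
        ]
        assert max(diffs) > 0.05

        # while the exact-constrained version still matches its definition
        again = rba_effects(table, ref, 1)
        assert all(
            again.terms[k] == pytest.approx(exact_rba.terms[k]) for k in again.terms
        )
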