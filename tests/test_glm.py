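import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from facstress.design import DesignSpec, build_model_matrix, make_design
from facstress.glm import (
    LN2,
    adjust_bh,
    default_grid,
    estimate_dispersion,
    fit_nb_glm,
    shrink_lfc,
    wald_test,
)


def bh_bruteforce(p):
    """Literal step-up rule: adj of the i-th smallest p is
    min_{j >= i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * n / j for j in range(rank, n + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestAdjustBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.4]), [0.4])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_matches_bruteforce(self, seed, n):
        p = np.random.default_rng(seed).random(n)
        np.testing.assert_allclose(adjust_bh(p), bh_bruteforce(p), atol=1e-12)


class TestWald:
    def test_zero_beta_p_one(self):
        z, p = wald_test(np.array([0.0]), np.array([1.0]))
        assert p[0] == 1.0

    @pytest.mark.parametrize("zval,pval", [(1.959964, 0.05), (3.0, 0.0027)])
    def test_normal_tail(self, zval, pval):
        _, p = wald_test(np.array([zval]), np.array([1.0]))
        assert p[0] == pytest.approx(pval, rel=1e-2)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(np.array([1.0]), np.array([0.0]))


@pytest.fixture(scope="module")
def design16():
    return make_design(DesignSpec(factors=("Salinity",), replicates_per_cell=8))


class TestDispersion:
    def test_poisson_genes_near_floor(self, design64):
        rng = np.random.default_rng(101)
        Y = rng.poisson(100.0, (200, 64)).astype(float)
        mm = build_model_matrix(design64)
        alpha = estimate_dispersion(Y, mm, np.ones(64))
        assert (alpha <= 0.05).mean() >= 0.95

    def test_nb_genes_recover_alpha(self, design64):
        rng = np.random.default_rng(102)
        mu, a = 100.0, 0.5
        lam = rng.gamma(1 / a, mu * a, (200, 64))
        Y = rng.poisson(lam).astype(float)
        mm = build_model_matrix(design64)
        alpha = estimate_dispersion(Y, mm, np.ones(64))
        assert 0.3 <= np.median(alpha) <= 0.7

    def test_floor_applied(self, design16):
        # near-constant counts give a negative moment estimate
        Y = np.full((1, 16), 50.0)
        mm = build_model_matrix(design16, factors=("Salinity",))
        alpha = estimate_dispersion(Y, mm, np.ones(16))
        assert alpha[0] == 1e-8

    def test_zero_df_rejected(self):
        d = make_design(DesignSpec(factors=("Salinity",), replicates_per_cell=1))
        mm = build_model_matrix(d, factors=("Salinity",))
        with pytest.raises(ValueError, match="degrees of freedom"):
            estimate_dispersion(np.array([5.0, 7.0]), mm, np.ones(2))


class TestNBFit:
    def test_constant_counts(self, design64):
        Y = np.full(64, 40.0)
        mm = build_model_matrix(design64)
        coef, se, converged, _, _ = fit_nb_glm(Y, mm, np.ones(64), 0.1)
        assert converged
        assert coef[0] == pytest.approx(np.log2(40.0), abs=1e-6)
        np.testing.assert_allclose(coef[1:], 0.0, atol=1e-6)

    def test_two_group_closed_form(self, design16):
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.poisson(50, 8), rng.poisson(200, 8)]).astype(float)
        mm = build_model_matrix(design16, factors=("Salinity",))
        coef, *_ = fit_nb_glm(y, mm, np.ones(16), 0.2)
        # NB-GLM MLE equals group means in a group-mean parameterisation
        assert coef[0] == pytest.approx(np.log2(y[:8].mean()), abs=1e-6)
        assert coef[1] == pytest.approx(np.log2(y[8:].mean() / y[:8].mean()), abs=1e-6)

    def test_matches_statsmodels(self, design16):
        rng = np.random.default_rng(8)
        y = rng.negative_binomial(5, 0.05, 16).astype(float)
        sf = np.exp(rng.normal(0, 0.1, 16))
        alpha = 0.2
        mm = build_model_matrix(design16, factors=("Salinity",))
        coef, se, *_ = fit_nb_glm(y, mm, sf, alpha)
        ref = sm.GLM(
            y, mm.to_numpy(),
            family=sm.families.NegativeBinomial(alpha=alpha),
            offset=np.log(sf),
        ).fit()
        np.testing.assert_allclose(coef * LN2, ref.params, atol=1e-6)

    def test_separation_clamped_and_flagged(self, design16):
        y = np.concatenate([np.zeros(8), np.full(8, 100.0)])
        mm = build_model_matrix(design16, factors=("Salinity",))
        coef, se, converged, _, clamped = fit_nb_glm(y, mm, np.ones(16), 0.1)
        assert clamped
        assert abs(coef[1]) == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("alpha,atol", [(1e-8, 2e-2), (0.1, 2e-2)])
    def test_sample_scale_equivariance(self, design64, rng, alpha, atol):
        # normalised counts are unchanged, so fits move only within noise;
        # exact equality is unattainable because the rescaled sample carries
        # c times the Fisher information under any count likelihood
        mm = build_model_matrix(design64)
        y = rng.poisson(80, 64).astype(float)
        sf = np.ones(64)
        c1, s1, *_ = fit_nb_glm(y, mm, sf, alpha)
        y2, sf2 = y.copy(), sf.copy()
        y2[5] *= 3.0
        sf2[5] *= 3.0
        c2, s2, *_ = fit_nb_glm(y2, mm, sf2, alpha)
        np.testing.assert_allclose(c1, c2, atol=atol)

    def test_nonpositive_alpha_rejected(self, design16):
        mm = build_model_matrix(design16, factors=("Salinity",))
        with pytest.raises(ValueError):
            fit_nb_glm(np.ones(16), mm, np.ones(16), 0.0)


class TestShrinkage:
    def test_conjugate_closed_form(self, rng):
        betas = rng.normal(0, 2, 200)
        ses = rng.uniform(0.2, 1.0, 200)
        tau = 1.5
        res = shrink_lfc(betas, ses, grid=np.array([0.0, tau]),
                         fixed_weights=np.array([0.0, 1.0]))
        expected = betas * tau**2 / (tau**2 + ses**2)
        np.testing.assert_allclose(res.posterior_mean, expected, atol=1e-8)

    def test_point_mass_prior_zeroes_everything(self, rng):
        betas = rng.normal(0, 2, 50)
        ses = np.full(50, 0.5)
        res = shrink_lfc(betas, ses, grid=np.array([0.0, 1.0]),
                         fixed_weights=np.array([1.0, 0.0]))
        np.testing.assert_allclose(res.posterior_mean, 0.0, atol=1e-12)

    def test_tiny_se_dominates(self):
        betas = np.array([2.0] * 5 + [0.0] * 50)
        ses = np.array([1e-5] * 5 + [1.0] * 50)
        res = shrink_lfc(betas, ses)
        np.testing.assert_allclose(res.posterior_mean[:5], 2.0, atol=1e-3)

    def test_never_increases_magnitude(self, rng):
        betas = rng.normal(0, 1.5, 300)
        ses = rng.uniform(0.1, 2.0, 300)
        res = shrink_lfc(betas, ses)
        assert (np.abs(res.posterior_mean) <= np.abs(betas) + 1e-12).all()
        assert res.weights.sum() == pytest.approx(1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            shrink_lfc(np.array([1.0]), np.array([0.5]), grid=np.array([]))

    def test_grid_requires_point_mass(self):
        with pytest.raises(ValueError, match="point mass"):
            shrink_lfc(np.array([1.0]), np.array([0.5]), grid=np.array([1.0]))

    def test_default_grid_shape(self):
        g = default_grid(np.array([1.0, -3.0]), np.array([0.5, 0.8]))
        assert g[0] == 0.0
        assert g[1] == pytest.approx(0.05)
        assert g[-1] >= 6.0
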