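"""Mixture densities, posteriors, and EM estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from conftest import draw_l2n_weights
from edgemix.model import (
    L2NParams,
    PosteriorTable,
    auto_init,
    component_densities,
    fit_em,
    log_likelihood,
    posterior,
    subsample_fit,
)
from edgemix.simulate import L2NSimConfig, gen_l2n_graph
from edgemix.weights import compute_weights


def mixture_density(w, p):
    f0, f1, f2 = component_densities(w, p)
    return p.p0 * f0 + p.p1 * f1 + p.p2 * f2


class TestDensities:
    def test_lognormals_vanish_at_zero(self, generic_params):
        f0, f1, f2 = component_densities(0.0, generic_params)
        assert f1 == 0.0 and f2 == 0.0
        assert f0 == pytest.approx(
            1.0 / np.sqrt(2 * np.pi * generic_params.sigma2)
        )

    def test_mirror_symmetry_with_equal_components(self):
        p = L2NParams(p0=0.8, p1=0.1, p2=0.1, sigma2=0.02,
                      theta1=-0.3, kappa1sq=0.2, theta2=-0.3, kappa2sq=0.2,
                      n_samples=100)
        for w in (0.1, 0.5, 1.3, 2.7):
            _, f1, _ = component_densities(w, p)
            _, _, f2 = component_densities(-w, p)
            assert f1 == pytest.approx(f2, rel=1e-12)

    def test_lognormal_closed_form(self, generic_params):
        # LogNormal(0, 0.25) at w=1: exp(0) / (1 * 0.5 * sqrt(2*pi))
        p = L2NParams(p0=0.9, p1=0.1, p2=0.0, sigma2=0.01,
                      theta1=0.0, kappa1sq=0.25, theta2=0.0, kappa2sq=0.25,
                      n_samples=103)
        _, f1, _ = component_densities(1.0, p)
        assert f1 == pytest.approx(0.7978845608, abs=1e-9)

    @pytest.mark.parametrize("theta1,theta2", [(-0.25, -0.5), (0.5, 0.25)])
    def test_mixture_integrates_to_one(self, theta1, theta2):
        p = L2NParams(p0=0.85, p1=0.10, p2=0.05, sigma2=0.05,
                      theta1=theta1, kappa1sq=0.25,
                      theta2=theta2, kappa2sq=0.16, n_samples=100)
        total, _ = quad(lambda w: mixture_density(w, p), -20, 0,
                        limit=200)
        pos, _ = quad(lambda w: mixture_density(w, p), 0, 20, limit=200)
        assert total + pos == pytest.approx(1.0, abs=1e-4)


class TestPosterior:
    def test_no_nonnull_mass_means_q0_one(self):
        p = L2NParams(p0=1.0, p1=0.0, p2=0.0, sigma2=0.02,
                      theta1=0.0, kappa1sq=0.25, theta2=0.0, kappa2sq=0.25,
                      n_samples=100)
        for w in (-2.0, 0.0, 0.4, 5.0):
            q0, q1, q2 = posterior(w, p)
            assert q0 == 1.0 and q1 == 0.0 and q2 == 0.0

    def test_zero_weight_is_surely_null(self, generic_params):
        q0, q1, q2 = posterior(0.0, generic_params)
        assert q0 == 1.0 and q1 == 0.0 and q2 == 0.0

    def test_matches_hand_computed_bayes_rule(self, generic_params):
        # independent term-by-term evaluation of the posterior formula
        p = generic_params
        w = 0.37
        f0 = np.exp(-w**2 / (2 * p.sigma2)) / np.sqrt(2 * np.pi * p.sigma2)
        f1 = np.exp(-(np.log(w) - p.theta1) ** 2 / (2 * p.kappa1sq)) / (
            w * np.sqrt(2 * np.pi * p.kappa1sq))
        num = np.array([p.p0 * f0, p.p1 * f1, 0.0])
        expected = num / num.sum()
        got = posterior(w, p)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    @given(w=st.floats(-6.0, 6.0, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_normalization(self, w):
        p = L2NParams(p0=0.9, p1=0.06, p2=0.04, sigma2=1 / 97,
                      theta1=-0.25, kappa1sq=0.25, theta2=-0.5, kappa2sq=0.16,
                      n_samples=100)
        q = posterior(w, p)
        assert sum(q) == pytest.approx(1.0, abs=1e-8)
        assert all(qi >= 0 for qi in q)

    def test_table_labels_prefer_lower_component_on_ties(self, generic_params):
        tab = PosteriorTable.from_weights(np.array([0.0, 3.0, -3.0]),
                                          generic_params)
        np.testing.assert_allclose(tab.q.sum(axis=1), 1.0, atol=1e-8)
        assert tab.labels[0] == 0   # q0 = 1 exactly at w = 0
        assert tab.labels[1] == 1
        assert tab.labels[2] == 2


class TestParams:
    def test_json_roundtrip(self, tmp_path, generic_params):
        p = tmp_path / "params.json"
        generic_params.to_json(p)
        back = L2NParams.from_json(p)
        assert back.to_dict() == generic_params.to_dict()

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            L2NParams(p0=0.5, p1=0.2, p2=0.2, sigma2=0.02,
                      theta1=0, kappa1sq=0.1, theta2=0, kappa2sq=0.1,
                      n_samples=100)

    def test_sigma2_floor_enforced(self):
        with pytest.raises(ValueError, match="floor"):
            L2NParams(p0=1.0, p1=0.0, p2=0.0, sigma2=0.001,
                      theta1=0, kappa1sq=0.1, theta2=0, kappa2sq=0.1,
                      n_samples=100)  # 1/(N-3) ~ 0.0103 > 0.001


class TestEM:
    def test_null_only_data(self):
        # all weights from N(0, 0.01) with N=103 (so the floor equals the
        # true variance): the fitted non-null mass is small (the mixture
        # MLE keeps a sliver of null-shoulder mass in the lognormals on
        # some samples) and, decisively, no edges are ever called at a
        # strict FDR level
        from edgemix.calling import thresholds_from_fdr

        masses = []
        for seed in (5, 6, 7):
            rng = np.random.default_rng(seed)
            w = rng.normal(0, 0.1, 10_000)
            p = fit_em(w, n_samples=103).params
            masses.append(p.p1 + p.p2)
            assert p.sigma2 == pytest.approx(0.01, rel=0.2)
            try:
                thr = thresholds_from_fdr(p, 0.01)
            except ValueError:
                continue  # correctly reports FDR 0.01 unattainable
            assert ((w > thr.c1) | (w < thr.c2)).sum() == 0
        assert np.median(masses) < 0.01
        assert max(masses) < 0.03

    def test_loglik_trace_monotone(self):
        w, _ = draw_l2n_weights(20_000, 0.9, 0.06, 0.04, 1 / 97,
                                -0.25, 0.25, -0.5, 0.16, seed=3)
        fit = fit_em(w, n_samples=100)
        diffs = np.diff(fit.loglik_trace)
        assert diffs.min() >= -1e-8
        assert fit.converged
        # the generic-path log-likelihood agrees with the fast EM core
        assert log_likelihood(w, fit.params) == pytest.approx(
            fit.loglik_trace[-1], abs=1e-6)

    def test_parameter_recovery_from_model_draws(self):
        # K = G(G-1)/2 for G=500; true values recovered within a few
        # Monte-Carlo standard errors (SE(p1) ~ 5.5e-4, SE(theta1) ~ 7e-3)
        w, _ = draw_l2n_weights(124_750, 0.96, 0.04, 0.0, 1 / 97,
                                0.25, 0.25, 0.0, 0.25, seed=1)
        p = fit_em(w, n_samples=100).params
        assert p.p1 == pytest.approx(0.04, abs=0.002)
        assert p.theta1 == pytest.approx(0.25, abs=0.025)
        assert p.kappa1sq == pytest.approx(0.25, abs=0.03)
        assert p.sigma2 == pytest.approx(1 / 97, rel=0.05)
        assert p.p2 < 0.002

    def test_p1_estimate_tracks_truth_across_theta(self):
        # estimation accuracy improves as the non-null component moves
        # away from the null
        errs = []
        for theta in (-1.0, 0.0):
            w, _ = draw_l2n_weights(50_000, 0.96, 0.04, 0.0, 1 / 97,
                                    theta, 0.25, 0.0, 0.25, seed=9)
            p = fit_em(w, n_samples=100).params
            errs.append(abs(p.p1 - 0.04))
        assert errs[1] <= errs[0]
        assert errs[1] < 0.005

    def test_sign_flip_equivariance(self):
        w, _ = draw_l2n_weights(40_000, 0.9, 0.06, 0.04, 1 / 97,
                                -0.25, 0.25, -0.5, 0.16, seed=13)
        a = fit_em(w, n_samples=100).params
        b = fit_em(-w, n_samples=100).params
        assert a.p0 == pytest.approx(b.p0, abs=1e-9)
        assert a.sigma2 == pytest.approx(b.sigma2, rel=1e-9)
        assert a.p1 == pytest.approx(b.p2, abs=1e-9)
        assert a.theta1 == pytest.approx(b.theta2, abs=1e-9)
        assert a.kappa1sq == pytest.approx(b.kappa2sq, rel=1e-9)

    def test_one_sided_data_pins_opposite_component(self):
        rng = np.random.default_rng(2)
        w = -np.abs(rng.normal(0, 0.1, 5000))  # no positive weights at all
        fit = fit_em(w, n_samples=100)
        assert fit.params.p1 == 0.0
        assert fit.params.p2 >= 0.0  # fit proceeds without error

    def test_bare_array_requires_n_samples(self):
        with pytest.raises(ValueError, match="n_samples"):
            fit_em(np.zeros(10))


@pytest.fixture(scope="module")
def sim_data():
    cfg = L2NSimConfig(structure="complete", G=300, S=60, N=100,
                       theta1=0.25, seed=77)
    return gen_l2n_graph(cfg)


class TestSubsampleFit:

    def test_full_subsample_equals_plain_fit(self, sim_data):
        _, X = sim_data
        fit_a, wv_a = subsample_fit(X, g_prime=X.n_genes, seed=0)
        fit_b = fit_em(compute_weights(X))
        assert fit_a.params.to_dict() == fit_b.params.to_dict()
        assert len(wv_a) == X.n_genes * (X.n_genes - 1) // 2
        assert fit_a.subsample_gene_ids == X.gene_ids

    def test_subsample_parameters_close_to_full_fit(self, sim_data):
        _, X = sim_data
        fit_full, _ = subsample_fit(X, g_prime=X.n_genes, seed=0)
        fit_sub, wv = subsample_fit(X, g_prime=150, seed=4)
        assert len(fit_sub.subsample_gene_ids) == 150
        # the weight vector still covers ALL K pairs
        assert len(wv) == X.n_genes * (X.n_genes - 1) // 2
        a, b = fit_sub.params, fit_full.params
        assert a.p0 == pytest.approx(b.p0, rel=0.10)
        assert a.p1 == pytest.approx(b.p1, rel=0.35)
        assert a.theta1 == pytest.approx(b.theta1, abs=0.15)
        assert a.sigma2 == pytest.approx(b.sigma2, rel=0.10)

    def test_invalid_sizes_rejected(self, sim_data):
        _, X = sim_data
        with pytest.raises(ValueError):
            subsample_fit(X, g_prime=1)
        with pytest.raises(ValueError):
            subsample_fit(X, g_prime=X.n_genes + 1)


def test_auto_init_is_deterministic_and_valid(rng):
    w = rng.normal(0, 0.12, 5000)
    a = auto_init(w, 100)
    b = auto_init(w, 100)
    assert a.to_dict() == b.to_dict()
    a.validate()
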