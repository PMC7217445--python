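"""G-MNL simulated probabilities and maximum simulated likelihood:
degenerate-case oracles, quadrature cross-check, reporting statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import ovichoice as oc
from ovichoice.data import ChoiceDataset
from ovichoice.design import Attribute
from ovichoice.exceptions import InvalidInputError
from ovichoice.gmnl import (
    GeneralizedMultinomialLogit,
    gmnl_probability,
    mcfadden_rho2,
    odds_ratios,
)
from ovichoice.simulate import DrawSet, make_draws


def one_situation_dataset(codes1, codes2, chosen_first=True):
    """A single respondent facing one situation with two alternatives."""
    df = pd.DataFrame(
        {
            "respondent_id": [1, 1],
            "situation_id": [1, 1],
            "alternative_id": [1, 2],
            "chosen": [int(chosen_first), int(not chosen_first)],
            "is_opt_out": [0, 0],
            "z": [codes1, codes2],
        }
    )
    return ChoiceDataset([Attribute("z")], df)


class TestGMNLProbability:
    def test_degenerate_mixture_equals_mnl(self):
        ds = one_situation_dataset(1, -1)
        params = {"asc": [0, 0.3], "beta": {"z": 0.7}, "eta_sd": {}, "tau": 0.0}
        draws = make_draws(64, 0, scheme="pseudo", seed=0)
        p = gmnl_probability(params, draws, ds, random_attrs=[])
        u = np.array([0.7, 0.3 - 0.7])
        expected = np.exp(u[0]) / np.exp(u).sum()
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_single_central_draw_scales_beta(self):
        """With one draw at eta = 0, eps0 = 0 the simulated probability is the
        MNL probability with coefficients shrunk by exp(-tau^2/2)."""
        tau = 0.9
        ds = one_situation_dataset(1, -1)
        draws = DrawSet(eta=np.zeros((1, 0)), eps0=np.zeros(1), scheme="pseudo")
        params = {"asc": [0, 0.0], "beta": {"z": 0.7}, "eta_sd": {}, "tau": tau}
        p = gmnl_probability(params, draws, ds, random_attrs=[])
        shrunk = 0.7 * np.exp(-0.5 * tau**2)
        expected = 1 / (1 + np.exp(-2 * shrunk))
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_quadrature_for_mixed_logit(self):
        """One random attribute, two alternatives: the simulated probability
        converges to the exact normal-mixture integral."""
        sd, beta = 0.8, 0.5
        ds = one_situation_dataset(1, -1)
        params = {"asc": [0, 0.0], "beta": {"z": beta}, "eta_sd": {"z": sd}, "tau": 0.0}

        def integrand(e):
            return stats.norm.pdf(e) / (1 + np.exp(-2 * (beta + sd * e)))

        exact, _ = integrate.quad(integrand, -10, 10)
        draws = make_draws(100_000, 1, scheme="halton", seed=0)
        p = gmnl_probability(params, draws, ds, random_attrs=["z"])
        assert p[0] == pytest.approx(exact, abs=1e-3)

    def test_simulation_error_shrinks_with_draws(self):
        sd, beta = 0.8, 0.5
        ds = one_situation_dataset(1, -1)
        params = {"asc": [0, 0.0], "beta": {"z": beta}, "eta_sd": {"z": sd}, "tau": 0.0}

        def integrand(e):
            return stats.norm.pdf(e) / (1 + np.exp(-2 * (beta + sd * e)))

        exact, _ = integrate.quad(integrand, -10, 10)
        errs = []
        for D in (20, 200, 2000):
            draws = make_draws(D, 1, scheme="halton", seed=0)
            p = gmnl_probability(params, draws, ds, random_attrs=["z"])
            errs.append(abs(p[0] - exact))
        assert errs[2] < errs[0]

    def test_draw_dimension_mismatch(self):
        ds = one_situation_dataset(1, -1)
        params = {"asc": [0, 0.0], "beta": {"z": 0.5}, "eta_sd": {"z": 0.1}, "tau": 0.0}
        with pytest.raises(InvalidInputError):
            gmnl_probability(params, make_draws(10, 2), ds, random_attrs=["z"])


class TestFitGMNL:
    def test_kernel_path_equals_numpy_reference(self, ram_filtered):
        """The fused numba kernels and the vectorized numpy implementation
        compute the same simulated log-likelihood and score."""
        model = GeneralizedMultinomialLogit(
            ram_filtered, random_attrs=["body_size", "tail_type"], n_draws=30, seed=2
        )
        if not model._core.use_kernels:
            pytest.skip("numba not available; only one implementation to compare")
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.3, len(model.param_names))
        ll_k, g_k = model._core.loglik_and_grad(x)
        model._core.use_kernels = False
        ll_n, g_n = model._core.loglik_and_grad(x)
        assert ll_k == pytest.approx(ll_n, abs=1e-9)
        np.testing.assert_allclose(g_k, g_n, atol=1e-9)

    def test_draw_permutation_invariance(self, ram_filtered):
        model = GeneralizedMultinomialLogit(
            ram_filtered, random_attrs=["tail_type"], n_draws=40, draw_scheme="pseudo", seed=3
        )
        model._core.use_kernels = False  # mutate the arrays the numpy path reads
        x = np.r_[np.zeros(9), 0.3, 0.2]
        ll = model.loglike(x)
        rng = np.random.default_rng(0)
        perm = rng.permutation(model._core.D)
        model._core.eta = model._core.eta[:, perm, :]
        model._core.eps0 = model._core.eps0[:, perm]
        assert model.loglike(x) == pytest.approx(ll, abs=1e-10)

    def test_same_seed_refits_identical(self, toy_plan, toy_truth):
        ds = oc.simulate_choices(toy_plan, toy_truth, 150, seed=13)
        kwargs = dict(random_attrs=["x1"], n_draws=30, seed=4)
        a = GeneralizedMultinomialLogit(ds, **kwargs).fit()
        b = GeneralizedMultinomialLogit(ds, **kwargs).fit()
        np.testing.assert_allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-8)

    def test_gradient_matches_finite_differences(self, ram_filtered):
        model = GeneralizedMultinomialLogit(
            ram_filtered, random_attrs=["body_size", "tail_type"], n_draws=25, seed=5
        )
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.3, size=len(model.param_names))
        _, g = model._core.loglik_and_grad(x)
        h = 1e-6
        for j in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (model.loglike(xp) - model.loglike(xm)) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_collapse_reproduces_mnl(self, ram_filtered):
        """No random attributes and tau fixed at zero: the simulated model is
        the plain conditional logit, to optimizer precision."""
        mnl = oc.fit_mnl(ram_filtered)
        g = GeneralizedMultinomialLogit(
            ram_filtered, random_attrs=[], n_draws=5, fix_tau=0.0, seed=1
        ).fit()
        diff = np.abs(g.params.reindex(mnl.params.index) - mnl.params).max()
        assert diff < 1e-6
        assert abs(g.llf - mnl.llf) < 1e-8


class TestReportingStats:
    @pytest.mark.parametrize(
        "ll,ll0,expected",
        [(-1493.1, -1864.1, 0.199), (-1376.3, -1894.4, 0.273)],
    )
    def test_rho2_study_values(self, ll, ll0, expected):
        assert mcfadden_rho2(ll, ll0) == pytest.approx(expected, abs=5e-4)

    def test_rho2_edges(self):
        assert mcfadden_rho2(-10.0, -10.0) == 0.0
        with pytest.raises(InvalidInputError):
            mcfadden_rho2(1.0, -10.0)
        with pytest.raises(InvalidInputError):
            mcfadden_rho2(-11.0, -10.0)

    def test_odds_ratio_study_examples(self):
        tab = odds_ratios(pd.Series({"tail_type": 0.8986}), pd.Series({"tail_type": 0.051}))
        assert tab.loc["tail_type", "odds_ratio"] == pytest.approx(2.46, abs=0.005)
        assert tab.loc["tail_type", "lower"] == pytest.approx(2.22, abs=0.01)
        assert tab.loc["tail_type", "upper"] == pytest.approx(2.71, abs=0.01)

        tab2 = odds_ratios(
            pd.Series({"mothering_ability": 1.3056}), pd.Series({"mothering_ability": 0.357})
        )
        assert tab2.loc["mothering_ability", "odds_ratio"] == pytest.approx(3.69, abs=0.005)
        assert tab2.loc["mothering_ability", "lower"] == pytest.approx(1.83, abs=0.01)
        assert tab2.loc["mothering_ability", "upper"] == pytest.approx(7.42, abs=0.015)

    def test_odds_ratio_zero_coefficient_symmetric(self):
        tab = odds_ratios(pd.Series({"a": 0.0}), pd.Series({"a": 0.2}))
        assert tab.loc["a", "odds_ratio"] == 1.0
        assert tab.loc["a", "lower"] * tab.loc["a", "upper"] == pytest.approx(1.0)

    def test_odds_ratio_without_se(self):
        tab = odds_ratios(pd.Series({"a": 0.5}))
        assert np.isnan(tab.loc["a", "lower"]) and np.isnan(tab.loc["a", "upper"])
        assert tab.loc["a", "odds_ratio"] == pytest.approx(np.exp(0.5))
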