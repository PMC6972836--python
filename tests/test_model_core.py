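import numpy as np
import pytest
from scipy.stats import norm

from latentord import (
    CommunityMatrix,
    LatentState,
    ModelSpec,
    PriorSpec,
    dic,
    linear_predictor,
    log_likelihood,
    mean_response,
    nb_variance,
)
from latentord.model_core import loglik_matrix


def make_state(alpha, beta, Z, Theta, **kw):
    return LatentState(alpha=alpha, beta=beta, Z=Z, Theta=Theta, **kw)


class TestLinearPredictor:
    def test_all_zero(self):
        st = make_state([0.0], [0.0], [[0.0, 0.0]], [[0.0, 0.0]])
        assert linear_predictor(st, 0, 0) == 0.0

    def test_hand_evaluation(self):
        st = make_state([1.0], [-1.0], [[1.0, 2.0]], [[0.5, 0.25]])
        assert linear_predictor(st, 0, 0) == pytest.approx(1.0)

    def test_site_plus_species_effects_only(self):
        # spider presence-scale means with no latent contribution
        st = make_state([0.04, 0.0], [0.10, 0.0], np.zeros((2, 2)), np.ones((2, 2)))
        assert linear_predictor(st, 0, 0) == pytest.approx(0.14)

    def test_index_errors(self):
        st = make_state([0.0], [0.0], [[0.0]], [[0.0]])
        with pytest.raises(IndexError):
            linear_predictor(st, 1, 0)
        with pytest.raises(IndexError):
            linear_predictor(st, 0, -5)


class TestMeanResponse:
    def test_probit_at_zero(self):
        assert mean_response(0.0, ModelSpec("binary")) == pytest.approx(0.5)

    def test_log_link_at_zero(self):
        assert mean_response(0.0, ModelSpec("poisson")) == pytest.approx(1.0)

    def test_ordinal_class_probabilities(self):
        p = mean_response(0.0, ModelSpec("ordinal", n_levels=3), cutoffs=np.array([-1.0, 1.0]))
        expected = [norm.cdf(-1), norm.cdf(1) - norm.cdf(-1), 1 - norm.cdf(1)]
        np.testing.assert_allclose(p, expected, atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("eta", [-3.0, -0.5, 0.0, 1.7, 4.0])
    def test_ordinal_probs_sum_to_one(self, eta):
        rng = np.random.default_rng(int(abs(eta) * 10))
        cuts = np.sort(rng.normal(size=5))
        while np.any(np.diff(cuts) <= 0):
            cuts = np.sort(rng.normal(size=5))
        p = mean_response(eta, ModelSpec("ordinal", n_levels=6), cutoffs=cuts)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            mean_response(0.0, ModelSpec("ordinal", n_levels=3), cutoffs=np.array([1.0, -1.0]))


class TestNBVariance:
    @pytest.mark.parametrize(
        "mu,omega,expected", [(2.0, 0.0, 2.0), (2.0, 0.5, 4.0), (0.0, 3.0, 0.0)]
    )
    def test_values(self, mu, omega, expected):
        assert nb_variance(mu, omega) == pytest.approx(expected)

    def test_exceeds_mean_iff_overdispersed(self):
        mu = np.linspace(0.1, 10, 25)
        assert np.all(nb_variance(mu, 0.3) > mu)
        np.testing.assert_allclose(nb_variance(mu, 0.0), mu)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            nb_variance(-1.0, 0.1)
        with pytest.raises(ValueError):
            nb_variance(1.0, -0.1)


def _single_cell_state(eta, n=2, p=2, **kw):
    # embed a target eta at cell (0,0); other cells share it but we slice
    return make_state(
        np.full(n, eta), np.zeros(p), np.zeros((n, 2)), np.zeros((p, 2)), **kw
    )


class TestLogLikelihood:
    def test_binary_single_cell(self):
        Y = CommunityMatrix(np.ones((2, 2), dtype=int), family="binary")
        st = _single_cell_state(0.0)
        cell = loglik_matrix(Y, st, ModelSpec("binary"))[0, 0]
        assert cell == pytest.approx(np.log(0.5))

    def test_poisson_zero_count(self):
        Y = CommunityMatrix(np.zeros((2, 2), dtype=int), family="count")
        st = _single_cell_state(0.0)
        cell = loglik_matrix(Y, st, ModelSpec("poisson"))[0, 0]
        assert cell == pytest.approx(-1.0)

    def test_negbin_approaches_poisson(self):
        # NB with omega -> 0 must converge to the Poisson likelihood
        rng = np.random.default_rng(5)
        Y = CommunityMatrix(rng.poisson(2.0, size=(5, 5)), family="count")
        st = make_state(
            rng.normal(size=5), rng.normal(size=5),
            rng.normal(size=(5, 2)), rng.normal(size=(5, 2)),
        )
        pois = log_likelihood(Y, st, ModelSpec("poisson"))
        st_nb = make_state(st.alpha, st.beta, st.Z, st.Theta, omega=1e-8)
        nb = log_likelihood(Y, st_nb, ModelSpec("negbin"))
        assert abs(nb - pois) < 1e-4

    def test_family_mismatch_raises(self):
        Y = CommunityMatrix(np.ones((2, 2), dtype=int), family="binary")
        with pytest.raises(ValueError):
            log_likelihood(Y, _single_cell_state(0.0), ModelSpec("poisson"))

    def test_ordinal_k2_matches_binary_probit(self):
        # two ordinal classes with the cutoff at zero reproduce the probit
        # binary likelihood exactly on a grid of linear predictors
        etas = np.linspace(-4, 4, 33)
        for eta in etas:
            stb = _single_cell_state(eta)
            sto = _single_cell_state(eta, cutoffs=np.array([0.0]))
            Yb = CommunityMatrix(np.array([[1, 0], [0, 1]]), family="binary")
            Yo = CommunityMatrix(np.array([[2, 1], [1, 2]]), family="ordinal", n_levels=2)
            lb = loglik_matrix(Yb, stb, ModelSpec("binary"))
            lo = loglik_matrix(Yo, sto, ModelSpec("ordinal", n_levels=2))
            np.testing.assert_allclose(lb, lo, rtol=1e-12)


class TestDIC:
    def test_degenerate_chain_has_zero_pd(self, toy_binary_matrix):
        from latentord import PosteriorChains

        st = make_state([0.1, -0.2], [0.3, 0.0], np.zeros((2, 2)), np.eye(2))
        draws = {
            "alpha": np.tile(st.alpha, (5, 1)),
            "beta": np.tile(st.beta, (5, 1)),
            "Z": np.tile(st.Z, (5, 1, 1)),
            "Theta": np.tile(st.Theta, (5, 1, 1)),
        }
        ch = PosteriorChains(draws=draws, family="binary", dims={"n": 2, "p": 2, "q": 2, "K": 0})
        spec = ModelSpec("binary")
        expected = -2 * log_likelihood(toy_binary_matrix, st, spec)
        assert dic(ch, toy_binary_matrix, spec) == pytest.approx(expected)

    def test_prefers_negbin_for_overdispersed_counts(self):
        from latentord import MCMCSettings, SimulationDesign, fit, generate_community

        design = SimulationDesign(family="negbin", n=25, p=15, omega=1.0, seed=3)
        Y, _ = generate_community(design, 0)
        settings = MCMCSettings(n_iter=3000, burn_in=1500, thin=3, seed=11)
        ch_p = fit(Y, ModelSpec("poisson"), settings)
        ch_nb = fit(Y, ModelSpec("negbin"), settings)
        dic_p = dic(ch_p, Y, ModelSpec("poisson"))
        dic_nb = dic(ch_nb, Y, ModelSpec("negbin"))
        assert dic_nb < dic_p

    def test_no_large_penalty_for_poisson_on_equidispersed_counts(self):
        from latentord import MCMCSettings, SimulationDesign, fit, generate_community

        design = SimulationDesign(family="poisson", n=25, p=15, seed=4)
        Y, _ = generate_community(design, 0)
        settings = MCMCSettings(n_iter=3000, burn_in=1500, thin=3, seed=12)
        dic_p = dic(fit(Y, ModelSpec("poisson"), settings), Y, ModelSpec("poisson"))
        dic_nb = dic(fit(Y, ModelSpec("negbin"), settings), Y, ModelSpec("negbin"))
        assert dic_p <= dic_nb + 15.0  # small slack for Monte Carlo error


class TestCommunityMatrixValidation:
    def test_binary_rejects_twos(self):
        with pytest.raises(ValueError, match="row 0, column 1"):
            CommunityMatrix(np.array([[0, 2], [1, 0]]), family="binary")

    def test_count_rejects_negative(self):
        with pytest.raises(ValueError):
            CommunityMatrix(np.array([[0, 3], [-1, 0]]), family="count")

    def test_ordinal_needs_levels(self):
        with pytest.raises(ValueError):
            CommunityMatrix(np.array([[1, 2], [2, 1]]), family="ordinal")

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            CommunityMatrix(np.array([[1, 0]]), family="binary")


class TestPriorSpec:
    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            PriorSpec(v_alpha=0.0)

    def test_rejects_non_pd_theta_prior(self):
        with pytest.raises(ValueError):
            PriorSpec(v_theta=np.array([[1.0, 2.0], [2.0, 1.0]]))
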