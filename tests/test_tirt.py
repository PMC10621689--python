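import warnings

import numpy as np
import pytest

import tirtsim as ts
from tirtsim.tirt import (
    McmcConfig,
    TirtPosterior,
    build_model,
    eap_scores,
    fit,
    quadrature_eap,
)


class TestBuildModel:
    def test_outcome_bookkeeping(self, small_design, rng):
        phi = ts.make_correlation("zero", 5)
        persons = ts.draw_traits(phi, 5, rng)
        resp = ts.simulate_responses(small_design, persons, rng)
        model = build_model(small_design, resp)
        # 15 triplet blocks -> 45 binary outcomes per person
        assert model.n_outcomes_per_person == 3 * small_design.n_blocks == 45

    def test_full_30_trait_design(self, rng):
        design = ts.make_design(30, "equal", "high_uniform", rng)
        phi = ts.make_correlation("zero", 30)
        persons = ts.draw_traits(phi, 3, rng)
        resp = ts.simulate_responses(design, persons, rng)
        model = build_model(design, resp)
        assert model.n_outcomes_per_person == 3 * 90

    def test_rejects_out_of_range_items(self, small_design):
        bad = ts.ResponseData(
            rankings=np.full((1, small_design.n_blocks, 3), 999, dtype=int)
        )
        with pytest.raises(ValueError):
            build_model(small_design, bad)


class TestMicroModelAgainstQuadrature:
    """1-person model with known item parameters: the MCMC EAP must agree
    with deterministic dense-grid integration of the exact likelihood."""

    def test_eap_matches_quadrature(self, pair_micro_model):
        design, phi, responses = pair_micro_model
        oracle = quadrature_eap(design, responses, phi)
        model = build_model(
            design,
            responses,
            fixed_loadings=design.loadings,
            fixed_means=design.item_means,
            fixed_phi=phi,
        )
        post = fit(model, McmcConfig(chains=2, warmup=500, samples=12000, seed=4))
        assert np.max(np.abs(post.eap_eta() - oracle)) < 0.05

    def test_two_seeds_agree(self, pair_micro_model):
        design, phi, responses = pair_micro_model
        model = build_model(
            design,
            responses,
            fixed_loadings=design.loadings,
            fixed_means=design.item_means,
            fixed_phi=phi,
        )
        e1 = fit(model, McmcConfig(chains=2, warmup=500, samples=12000, seed=1)).eap_eta()
        e2 = fit(model, McmcConfig(chains=2, warmup=500, samples=12000, seed=2)).eap_eta()
        assert np.max(np.abs(e1 - e2)) < 0.05

    def test_fit_deterministic_given_seed(self, pair_micro_model):
        design, phi, responses = pair_micro_model
        model = build_model(
            design,
            responses,
            fixed_loadings=design.loadings,
            fixed_means=design.item_means,
            fixed_phi=phi,
        )
        cfg = McmcConfig(chains=1, warmup=50, samples=50, seed=9)
        p1, p2 = fit(model, cfg), fit(model, cfg)
        np.testing.assert_array_equal(p1.eta_draws, p2.eta_draws)


class TestPosteriorContainer:
    def _posterior(self, eta_draws):
        c, d, p, t = eta_draws.shape
        return TirtPosterior(
            eta_draws=eta_draws,
            lam_draws=np.full((c, d, 1), 0.5),
            mu_draws=np.zeros((c, d, 1)),
            phi_draws=np.broadcast_to(np.eye(t), (c, d, t, t)).copy(),
            rhat={"eta": 1.0},
            converged=True,
        )

    def test_symmetric_draws_give_zero_eap(self, rng):
        draws = rng.normal(size=(2, 100, 3, 2))
        draws = np.concatenate([draws, -draws], axis=1)
        post = self._posterior(draws)
        np.testing.assert_allclose(post.eap_eta(), 0.0, atol=1e-12)

    def test_eap_invariant_to_draw_order(self, rng):
        draws = rng.normal(size=(1, 50, 4, 2))
        post1 = self._posterior(draws)
        post2 = self._posterior(draws[:, ::-1])
        np.testing.assert_allclose(post1.eap_eta(), post2.eap_eta())

    def test_nonconverged_scores_warn(self, rng):
        post = self._posterior(rng.normal(size=(2, 10, 3, 2)))
        post.converged = False
        with pytest.warns(RuntimeWarning):
            eap_scores(post)


def test_gamma_centered_when_generated_at_zero(rng):
    # symmetric design with all item means zero: estimated pair intercepts
    # should concentrate near zero
    design = ts.make_design(3, "equal", "high_uniform", rng)
    design = type(design)(
        n_traits=design.n_traits,
        trait_of_item=design.trait_of_item,
        loadings=design.loadings,
        item_means=np.zeros(design.n_items),
        blocks=design.blocks,
        keying="equal",
    )
    phi = ts.make_correlation("zero", 3)
    persons = ts.draw_traits(phi, 200, rng)
    resp = ts.simulate_responses(design, persons, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(
            build_model(design, resp),
            McmcConfig(chains=2, warmup=400, samples=400, seed=3),
        )
    gammas_hat = []
    mu_hat = post.eap_means()
    for pairs in design.pair_index():
        for i, k in pairs:
            gammas_hat.append(mu_hat[k] - mu_hat[i])
    assert abs(np.mean(gammas_hat)) < 0.1


def test_item_parameter_recovery_mixed_keying(rng):
    # loading magnitudes and trait correlations are recovered on a mixed
    # keyed questionnaire (the well-identified regime)
    design = ts.make_design(5, "mixed", "high_uniform", rng)
    phi = ts.make_correlation("zero", 5)
    persons = ts.draw_traits(phi, 500, rng)
    resp = ts.simulate_responses(design, persons, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(
            build_model(design, resp),
            McmcConfig(chains=2, warmup=800, samples=800, seed=21),
        )
    lam_corr = np.corrcoef(np.abs(post.eap_loadings()), np.abs(design.loadings))[0, 1]
    assert lam_corr > 0.8
    _, bias = ts.intercorrelation_bias(post.eap_phi(), phi.phi)
    assert abs(bias) < 0.1
    # estimated loading signs honour the keying constraint
    np.testing.assert_array_equal(
        np.sign(post.eap_loadings()), np.sign(design.loadings)
    )


def test_eap_tracks_classical_scores_with_unit_like_loadings(rng):
    # with all loading magnitudes pinned high and correlations ignored, the
    # model's EAP ordering closely resembles classical point totals
    design = ts.make_design(3, "equal", "high_uniform", rng)
    fixed = np.full(design.n_items, 0.9)
    phi = ts.make_correlation("zero", 3)
    persons = ts.draw_traits(phi, 120, rng)
    resp = ts.simulate_responses(design, persons, rng)
    classical = ts.standardize(ts.score_person(design, resp))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(
            build_model(design, resp, fixed_loadings=fixed, fixed_phi=phi.phi),
            McmcConfig(chains=2, warmup=400, samples=400, seed=17),
        )
    eap = eap_scores(post)
    for t in range(3):
        r = np.corrcoef(eap.theta[:, t], classical.theta[:, t])[0, 1]
        assert r > 0.8


def test_posterior_predictive_matches_observed_frequencies(rng):
    from tirtsim.tirt import posterior_predictive_pair_freq

    design = ts.make_design(3, "mixed", "high_uniform", rng)
    phi = ts.make_correlation("zero", 3)
    persons = ts.draw_traits(phi, 150, rng)
    resp = ts.simulate_responses(design, persons, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(
            build_model(design, resp),
            McmcConfig(chains=2, warmup=400, samples=400, seed=13),
        )
        observed = ts.rank_to_pairwise(resp, design).mean(axis=0)
        predicted = posterior_predictive_pair_freq(
            post, build_model(design, resp), np.random.default_rng(5), n_draws=60
        )
    assert np.mean(np.abs(predicted - observed)) < 0.05


def test_invalid_mcmc_config(pair_micro_model):
    design, phi, responses = pair_micro_model
    model = build_model(design, responses)
    with pytest.raises(ValueError):
        fit(model, McmcConfig(chains=0, warmup=10, samples=10, seed=1))
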