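"""EM estimator correctness: oracle equivalence, monotonicity, closed forms,
missing-data handling, and label symmetry."""

import numpy as np
import pytest

from conftest import brute_force, random_panel, random_params
from ictrans.lta import (
    ConvergenceError,
    IndicatorPanel,
    LTAParams,
    ZeroLikelihoodError,
    assign_modal,
    e_step,
    fit,
    loglikelihood,
    m_step,
)


@pytest.mark.parametrize("n,S,J,missing,w2miss", [
    (3, 2, 2, 0.0, 0.0),
    (10, 3, 4, 0.2, 0.2),
    (8, 3, 6, 0.35, 0.3),
    (10, 2, 6, 0.0, 0.5),
])
def test_loglik_and_posterior_match_bruteforce(rng, n, S, J, missing, w2miss):
    """Vectorised likelihood and E-step equal exhaustive enumeration over all
    S^2 latent pairs to 1e-10, under item missingness and fully missing
    second waves."""
    for rep in range(3):
        panel = random_panel(rng, n, J, missing=missing, wave2_all_missing=w2miss)
        params = random_params(rng, S, J)
        ll_oracle, post_oracle = brute_force(panel, params)
        assert loglikelihood(panel, params) == pytest.approx(ll_oracle, abs=1e-10)
        post = e_step(panel, params)
        np.testing.assert_allclose(post.w, post_oracle, atol=1e-10)
        np.testing.assert_allclose(post.w.sum(axis=(1, 2)), 1.0, atol=1e-12)
        np.testing.assert_allclose(post.w1.sum(axis=1), 1.0, atol=1e-12)


def test_single_status_loglik_closed_form(rng):
    """S=1 with rho=0.5 everywhere: every observed cell contributes log 1/2."""
    panel = random_panel(rng, n=7, J=6, missing=0.0)
    params = LTAParams(beta=np.empty((0, 3)), rho=np.full((1, 6), 0.5), tau=np.ones((1, 1)),
                       x_mean=np.zeros(2), x_scale=np.ones(2))
    assert loglikelihood(panel, params) == pytest.approx(7 * 12 * np.log(0.5), rel=1e-12)


def test_wave2_missing_posterior_factorises(rng):
    """For a subject with wave 2 entirely missing, w[a, b] = w1[a] * tau[a, b]."""
    panel = random_panel(rng, n=6, J=4, missing=0.0, wave2_all_missing=1.0)
    params = random_params(rng, 2, 4)
    post = e_step(panel, params)
    np.testing.assert_allclose(post.w, post.w1[:, :, None] * params.tau[None], atol=1e-12)


def test_deterministic_emissions_pin_posterior():
    y = np.zeros((2, 3, 2))
    y[1] = 1.0
    panel = IndicatorPanel(y=y, x=np.empty((2, 0)), ids=np.arange(2))
    params = LTAParams(beta=np.zeros((1, 1)), rho=np.array([[0.0, 0, 0], [1.0, 1, 1]]),
                       tau=np.array([[0.5, 0.5], [0.5, 0.5]]))
    post = e_step(panel, params)
    assert post.w1[0, 0] == pytest.approx(1.0)
    assert post.w1[1, 1] == pytest.approx(1.0)


def test_contradicting_degenerate_emissions():
    y = np.ones((1, 3, 2))
    panel = IndicatorPanel(y=y, x=np.empty((1, 0)), ids=np.array([42]))
    params = LTAParams(beta=np.empty((0, 1)), rho=np.zeros((1, 3)), tau=np.ones((1, 1)))
    assert loglikelihood(panel, params) == -np.inf
    with pytest.raises(ZeroLikelihoodError, match="42"):
        e_step(panel, params)


def test_panel_rejects_all_missing_wave1():
    y = np.full((2, 3, 2), np.nan)
    y[0, :, :] = 1.0
    with pytest.raises(ValueError, match="wave-1"):
        IndicatorPanel(y=y, x=np.empty((2, 0)), ids=np.array([0, 7]))


def test_mstep_intercept_only_closed_form(rng):
    """Without covariates the Newton membership update must land exactly on
    the closed form delta_a = mean_i w1[i, a]."""
    panel = random_panel(rng, n=40, J=4, p_covariates=0)
    params = random_params(rng, 3, 4, p_covariates=0)
    post = e_step(panel, params)
    new = m_step(panel, post, params)
    delta = new.initial_probabilities(panel.x)
    np.testing.assert_allclose(delta[0], post.w1.mean(axis=0), atol=1e-8)
    np.testing.assert_allclose(delta, np.tile(delta[0], (40, 1)), atol=1e-12)


def test_em_iteration_monotone(rng):
    panel = random_panel(rng, n=60, J=5, missing=0.1)
    params = random_params(rng, 3, 5)
    ll = loglikelihood(panel, params)
    for _ in range(10):
        post = e_step(panel, params)
        params = m_step(panel, post, params)
        ll_new = loglikelihood(panel, params)
        assert ll_new >= ll - 1e-8 * (1 + abs(ll))
        ll = ll_new


def test_fit_trace_monotone_and_rho_bounded(rng):
    panel = random_panel(rng, n=200, J=6, missing=0.1, wave2_all_missing=0.1)
    fr = fit(panel, 2, n_starts=4, seed=1, tol=1e-8, max_iter=300)
    trace = np.asarray(fr.loglik_trace)
    assert (np.diff(trace) >= -1e-6).all()
    assert fr.converged
    assert (fr.params.rho >= 1e-4).all() and (fr.params.rho <= 1 - 1e-4).all()


def test_loglik_invariant_under_relabelling(rng):
    """Relabelling statuses (with consistent permutation of delta, rho, tau)
    leaves the likelihood unchanged."""
    panel = random_panel(rng, n=30, J=5)
    params = random_params(rng, 3, 5)
    ll = loglikelihood(panel, params)
    for perm in ([1, 2, 0], [2, 0, 1], [1, 0, 2]):
        assert loglikelihood(panel, params.permute(perm)) == pytest.approx(ll, abs=1e-9)


def test_fit_is_start_order_invariant(rng):
    """The multistart result depends only on the best likelihood reached, not
    on the ordering of the random initialisations."""
    panel = random_panel(rng, n=150, J=6, missing=0.05)
    fr1 = fit(panel, 2, n_starts=5, seed=11, tol=1e-8, max_iter=300, n_final=5)
    fr2 = fit(panel, 2, n_starts=5, seed=11, tol=1e-8, max_iter=300, n_final=5)
    assert fr1.loglik == pytest.approx(fr2.loglik, abs=1e-10)
    np.testing.assert_allclose(fr1.params.rho, fr2.params.rho, atol=1e-10)


def test_subject_order_invariance(rng):
    panel = random_panel(rng, n=80, J=4, missing=0.1)
    perm = rng.permutation(80)
    shuffled = IndicatorPanel(y=panel.y[perm], x=panel.x[perm], ids=panel.ids[perm])
    fr1 = fit(panel, 2, n_starts=3, seed=5, tol=1e-9, max_iter=500)
    fr2 = fit(shuffled, 2, n_starts=3, seed=5, tol=1e-9, max_iter=500)
    assert fr1.loglik == pytest.approx(fr2.loglik, abs=1e-6)
    np.testing.assert_allclose(np.sort(fr1.params.rho.sum(axis=1)),
                               np.sort(fr2.params.rho.sum(axis=1)), atol=1e-4)


def test_fit_single_status_closed_form(rng):
    panel = random_panel(rng, n=50, J=6, missing=0.2)
    fr = fit(panel, 1, seed=0)
    obs = ~np.isnan(panel.y)
    means = np.nansum(panel.y, axis=(0, 2)) / obs.sum(axis=(0, 2))
    np.testing.assert_allclose(fr.params.rho[0], means, atol=1e-12)
    assert fr.converged and fr.n_iter == 1


def test_assign_modal_tie_breaks_healthier():
    from ictrans.lta import PosteriorTable

    w = np.full((1, 2, 2), 0.25)
    post = PosteriorTable(ids=np.array([0]), w=w, w1=w.sum(axis=2), w2=w.sum(axis=1), loglik=0.0)
    s1, s2 = assign_modal(post)
    assert s1[0] == 0 and s2[0] == 0
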