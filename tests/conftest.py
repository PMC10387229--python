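"""Shared fixtures and independent oracles.

The oracles deliberately use plain-python loops and exhaustive enumeration so
they share no code path with the vectorised implementations they check.
"""

import math

import numpy as np
import pytest

from ictrans.lta import IndicatorPanel, LTAParams


# ---------------------------------------------------------------------------
# brute-force latent-pair enumeration oracle
# ---------------------------------------------------------------------------

def brute_force(panel: IndicatorPanel, params: LTAParams):
    """(loglik, joint posterior) by explicit summation over all (a, b) pairs."""
    delta = params.initial_probabilities(panel.x)
    S = params.n_statuses
    J = panel.y.shape[1]
    rho, tau = params.rho, params.tau
    total = 0.0
    post = np.zeros((panel.n, S, S))
    for i in range(panel.n):
        for a in range(S):
            for b in range(S):
                term = delta[i, a] * tau[a, b]
                for j in range(J):
                    for t, s in ((0, a), (1, b)):
                        v = panel.y[i, j, t]
                        if not math.isnan(v):
                            term *= rho[s, j] if v == 1 else 1.0 - rho[s, j]
                post[i, a, b] = term
        L = post[i].sum()
        total += math.log(L)
        post[i] /= L
    return total, post


def random_panel(rng, n, J, p_covariates=2, missing=0.15, wave2_all_missing=0.0):
    """A small random panel, optionally with item missingness and some
    subjects entirely unobserved at wave 2; wave 1 always has data."""
    y = rng.integers(0, 2, size=(n, J, 2)).astype(float)
    mask = rng.random((n, J, 2)) < missing
    y[mask] = np.nan
    for i in range(n):
        if np.isnan(y[i, :, 0]).all():
            y[i, rng.integers(J), 0] = float(rng.integers(0, 2))
        if rng.random() < wave2_all_missing:
            y[i, :, 1] = np.nan
        elif np.isnan(y[i, :, 1]).all():
            y[i, rng.integers(J), 1] = float(rng.integers(0, 2))
    x = rng.normal(size=(n, p_covariates))
    return IndicatorPanel(y=y, x=x, ids=np.arange(n))


def random_params(rng, S, J, p_covariates=2):
    rho = rng.uniform(0.05, 0.95, size=(S, J))
    tau = rng.dirichlet(np.ones(S) * 2, size=S)
    beta = rng.normal(scale=0.5, size=(S - 1, p_covariates + 1)) if S > 1 else np.empty((0, p_covariates + 1))
    return LTAParams(beta=beta, rho=rho, tau=tau,
                     x_mean=np.zeros(p_covariates), x_scale=np.ones(p_covariates))


# ---------------------------------------------------------------------------
# exhaustive concordance oracle
# ---------------------------------------------------------------------------

def concordance_oracle(time, event, risk):
    """Harrell's C by explicit enumeration: a pair is usable when the member
    with the shorter time had the event; higher risk with shorter time is
    concordant; equal risks count half."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                # tied times: usable only when exactly one member had the
                # event (the censored one is known to have lived longer)
                if event[i] + event[j] != 1:
                    continue
                short, long_ = (i, j) if event[i] == 1 else (j, i)
            else:
                short, long_ = (i, j) if time[i] < time[j] else (j, i)
                if event[short] != 1:
                    continue
            den += 1
            if risk[short] > risk[long_]:
                num += 1
            elif risk[short] == risk[long_]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


@pytest.fixture
def rng():
    return np.random.default_rng(20230729)
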