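"""Generator correctness: validation, determinism, and convergence of
empirical frequencies to the configured probabilities."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import binom

from ictrans.coding import DOMAINS
from ictrans.cohort import (
    ConfigValidationError,
    GeneratorConfig,
    expected_transition_fractions,
    generate,
    outcome_cohort,
    paper_replication_config,
)


def small_config(**kw):
    cfg = paper_replication_config()
    return dataclasses.replace(cfg, **kw)


def test_invalid_delta_and_tau_reported():
    cfg = small_config(delta=(0.5, 0.2, 0.2, 0.2))
    with pytest.raises(ConfigValidationError, match="delta"):
        cfg.validate()
    bad_tau = [list(r) for r in paper_replication_config().tau]
    bad_tau[1][1] += 0.3
    cfg = small_config(tau=tuple(tuple(r) for r in bad_tau))
    with pytest.raises(ConfigValidationError, match=r"tau rows \[1\]"):
        cfg.validate()


def test_same_seed_is_bit_identical():
    cfg = small_config(n_subjects=500)
    a = generate(cfg, seed=9)
    b = generate(cfg, seed=9)
    for fa, fb in zip((a.indicators, a.covariates, a.outcomes, a.truth),
                      (b.indicators, b.covariates, b.outcomes, b.truth)):
        pd.testing.assert_frame_equal(fa, fb)
    c = generate(cfg, seed=10)
    assert not a.truth["true_status_w1"].equals(c.truth["true_status_w1"])


def test_deterministic_emissions_identity_tau():
    """0/1 emissions plus an identity transition matrix reproduce the exact
    same indicator pattern at both waves."""
    rho = tuple(tuple(float(v) for v in row) for row in np.eye(4)[:, [0, 1, 2, 3, 0, 1]])
    cfg = small_config(n_subjects=300, rho=rho, tau=tuple(tuple(r) for r in np.eye(4)),
                       survival=None, srh=None, outcomes={}, dropout=0.0)
    co = generate(cfg, seed=3)
    for d in DOMAINS:
        assert co.indicators[f"{d}_w1"].equals(co.indicators[f"{d}_w2"].astype("boolean"))


def test_degenerate_delta_gives_tau_row_frequencies():
    """Starting everyone in status 0, the wave-2 status distribution is a
    multinomial draw from tau row 0 (checked against exact binomial CIs)."""
    cfg = small_config(n_subjects=4000, membership_intercepts=(-30.0, -30.0, -30.0),
                       membership_slopes=((0.0,) * 3,) * 3, dropout=0.0, survival=None)
    co = generate(cfg, seed=21)
    assert (co.truth["true_status_w1"] == 0).all()
    counts = co.truth["true_status_w2"].value_counts()
    row = np.asarray(cfg.tau)[0]
    for b, p in enumerate(row):
        lo, hi = binom.interval(0.9999, 4000, p) if p > 0 else (0, 0)
        assert lo <= counts.get(b, 0) <= hi


def test_replication_config_published_values():
    cfg = paper_replication_config()
    assert cfg.delta == (0.43, 0.17, 0.22, 0.18)
    tau = np.asarray(cfg.tau)
    np.testing.assert_allclose(tau.sum(axis=1), 1.0, atol=1e-12)
    assert tau[0, 1] == 0.60 and tau[0, 2] == 0.06
    assert tau[1, 3] == 0.27
    assert tau[2, 1] == 0.12
    np.testing.assert_array_equal(tau[3], [0, 0, 0, 1])  # no escape from the worst status
    assert (tau[1:, 0] == 0).all()  # no reversion into high IC
    fr = expected_transition_fractions(cfg)
    assert fr["stable"] == pytest.approx(0.61, abs=1e-3)
    assert fr["improved"] == pytest.approx(0.027, abs=2e-3)


def test_membership_calibration_hits_marginal_prevalences():
    cfg = small_config(n_subjects=20000)
    co = generate(cfg, seed=5)
    emp = co.truth["true_status_w1"].value_counts(normalize=True).sort_index().to_numpy()
    np.testing.assert_allclose(emp, cfg.delta, atol=0.01)


def test_emission_frequencies_converge_to_rho(rng):
    cfg = small_config(n_subjects=50000)
    co = generate(cfg, seed=8)
    rho = np.asarray(cfg.rho)
    s1 = co.truth["true_status_w1"].to_numpy()
    for a in range(4):
        m = s1 == a
        n_a = m.sum()
        for j, d in enumerate(DOMAINS):
            freq = co.indicators.loc[m, f"{d}_w1"].astype(float).mean()
            sd = np.sqrt(rho[a, j] * (1 - rho[a, j]) / n_a)
            assert abs(freq - rho[a, j]) < 3 * max(sd, 1e-3) + 1e-9


def test_death_before_wave2_blanks_indicators():
    cfg = small_config(n_subjects=3000)
    co = generate(cfg, seed=12)
    died = co.outcomes["died"] == 1
    assert died.any()
    for d in DOMAINS:
        assert co.indicators.loc[died, f"{d}_w2"].isna().all()
        assert co.indicators.loc[:, f"{d}_w1"].notna().all()
    # truth sidecar still records the latent wave-2 status for oracle use
    assert co.truth.loc[died.to_numpy(), "true_status_w2"].notna().all()


def test_outcome_intercept_calibration():
    """Covariate-standardised event probability at high IC equals the target
    the intercept was calibrated for (fresh covariate sample, MC tolerance)."""
    cfg = paper_replication_config()
    rng = np.random.default_rng(77)
    X = cfg.covariates.design(cfg.covariates.draw(rng, 100000))
    m = cfg.outcomes["disability"]
    p = expit(m.intercept + X @ np.asarray(m.covariate_logor)).mean()
    assert p == pytest.approx(0.177, abs=0.004)
    srh = cfg.srh
    exceed = expit(np.asarray(srh.alpha)[0] + (X @ np.asarray(srh.gamma))[:, None])
    p_very_good = 1 - exceed[:, 0].mean()
    assert p_very_good == pytest.approx(0.16, abs=0.004)


def test_outcome_cohort_columns_and_unknown_outcome():
    cfg = paper_replication_config()
    df = outcome_cohort(cfg, "frailty", 500, seed=4)
    assert len(df) == 500 and set(df["frailty"].unique()) <= {0, 1}
    df = outcome_cohort(cfg, "mortality", 200, seed=4)
    assert (df["time_years"] <= cfg.survival.horizon).all()
    with pytest.raises(ConfigValidationError, match="unknown outcome"):
        outcome_cohort(cfg, "nonexistent", 10, seed=1)


def test_config_yaml_roundtrip(tmp_path):
    cfg = paper_replication_config()
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back.delta == cfg.delta
    np.testing.assert_allclose(np.asarray(back.tau), np.asarray(cfg.tau))
    assert back.outcomes["frailty"].status_logor == cfg.outcomes["frailty"].status_logor
    assert back.survival.hazard_ratios == cfg.survival.hazard_ratios
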