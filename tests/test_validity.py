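"""Outcome models: closed forms, oracles, and invariances."""

import numpy as np
import pandas as pd
import pytest

from conftest import concordance_oracle
from ictrans import validity
from ictrans.validity import (
    EffectEstimate,
    SeparationError,
    adjusted_probability,
    fit_cox,
    fit_gologit,
    fit_logistic,
    harrells_c,
    km_curve,
    loglog_curves,
    ph_diagnostics,
)


def two_by_two(a, b, c, d):
    """exposed-event, exposed-noevent, unexposed-event, unexposed-noevent."""
    status = [1] * (a + b) + [0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"status": status, "y": y})


@pytest.mark.parametrize("cells", [(20, 30, 10, 40), (7, 13, 11, 29), (50, 5, 12, 33)])
def test_logistic_or_equals_cross_product_ratio(cells):
    a, b, c, d = cells
    lf = fit_logistic(two_by_two(a, b, c, d), "y")
    assert lf.effects[0].point == pytest.approx((a * d) / (b * c), rel=1e-8)


def test_logistic_separation_detected():
    df = two_by_two(30, 0, 0, 30)  # outcome == exposure exactly
    with pytest.raises(SeparationError):
        fit_logistic(df, "y")


def test_effect_estimate_ci_sanity():
    with pytest.raises(ValueError):
        EffectEstimate(contrast="x", scale="OR", point=2.0, ci_low=2.5, ci_high=3.0)


def test_adjusted_probability_no_covariates_equals_raw_incidence(rng):
    df = two_by_two(20, 30, 10, 40)
    lf = fit_logistic(df, "y")
    p1 = adjusted_probability(lf, 1, ci="delta")
    p0 = adjusted_probability(lf, 0, ci="delta")
    assert p1.point == pytest.approx(20 / 50, abs=1e-10)
    assert p0.point == pytest.approx(10 / 50, abs=1e-10)
    # weighted by status frequencies, standardised probabilities return the
    # overall prevalence (law of total probability; exact without covariates)
    overall = 0.5 * p1.point + 0.5 * p0.point
    assert overall == pytest.approx(df["y"].mean(), abs=1e-8)


def test_adjusted_probability_intercept_only(rng):
    df = pd.DataFrame({"status": np.zeros(200, int), "y": rng.random(200) < 0.3})
    df["y"] = df["y"].astype(int)
    lf = fit_logistic(df, "y")
    est = adjusted_probability(lf, 0, ci="delta")
    assert est.point == pytest.approx(df["y"].mean(), abs=1e-10)


def test_adjusted_probability_bootstrap_close_to_delta(rng):
    n = 600
    df = pd.DataFrame({
        "status": rng.integers(0, 2, n),
        "age": rng.normal(70, 5, n),
    })
    eta = -1.0 + 0.8 * df["status"] + 0.03 * (df["age"] - 70)
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    lf = fit_logistic(df, "y", covariates=["age"])
    d = adjusted_probability(lf, 1, ci="delta")
    b = adjusted_probability(lf, 1, ci="bootstrap", n_boot=200, seed=3)
    assert b.point == pytest.approx(d.point, abs=1e-12)  # same point estimate
    assert b.ci_low == pytest.approx(d.ci_low, abs=0.03)
    assert b.ci_high == pytest.approx(d.ci_high, abs=0.03)


def test_gologit_probabilities_sum_to_one_and_null_effect(rng):
    n = 4000
    status = rng.integers(0, 3, n)
    srh = rng.choice(5, size=n, p=[0.15, 0.35, 0.3, 0.15, 0.05])  # independent of status
    df = pd.DataFrame({"status": status, "srh": srh})
    gf = fit_gologit(df, "srh")
    marg = gf.marginal_probabilities()
    np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-8)
    for s in (1, 2):
        np.testing.assert_allclose(marg.loc[s], marg.loc[0], atol=0.04)


def test_gologit_merges_empty_category(rng):
    srh = rng.choice([0, 1, 3], size=500)  # category 2 never observed
    df = pd.DataFrame({"status": rng.integers(0, 2, 500), "srh": srh})
    with pytest.warns(UserWarning, match="merged"):
        gf = fit_gologit(df, "srh")
    assert gf.marginal_probabilities().shape[1] == 3


def exp_two_group(rng, n, hr, censor=np.inf):
    status = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.2 * hr**status))
    df = pd.DataFrame({"status": status, "time_years": np.minimum(t, censor),
                       "died": (t < censor).astype(int)})
    return df


def test_cox_recovers_two_group_hazard_ratio(rng):
    df = exp_two_group(rng, 5000, hr=2.0)
    cf = fit_cox(df, covariates=())
    assert cf.effects[0].point == pytest.approx(2.0, rel=0.10)
    assert cf.effects[0].ci_low < 2.0 < cf.effects[0].ci_high


def test_cox_time_scale_invariance(rng):
    df = exp_two_group(rng, 800, hr=1.8)
    cf1 = fit_cox(df, covariates=())
    df2 = df.assign(time_years=df["time_years"] * 3.7)
    cf2 = fit_cox(df2, covariates=())
    assert cf1.effects[0].point == pytest.approx(cf2.effects[0].point, rel=1e-6)


def test_cox_error_paths(rng):
    df = exp_two_group(rng, 50, hr=1.0)
    with pytest.raises(ValueError, match="no events"):
        fit_cox(df.assign(died=0), covariates=())
    df["zero"] = 0.0
    with pytest.raises(ValueError, match="all-zero"):
        fit_cox(df, covariates=["zero"])


def test_harrells_c_extremes(rng):
    t = rng.exponential(1, 400)
    e = np.ones(400, int)
    assert harrells_c(t, e, -t) == pytest.approx(1.0)  # perfectly rank-predictive
    assert abs(harrells_c(t, e, rng.normal(size=400)) - 0.5) < 0.05


def test_harrells_c_hand_worked_censored_example():
    # times 1<2<3<4, subject 2 censored; usable pairs: (1,2),(1,3),(1,4),
    # (3,4) -> risk (4,1,3,2): concordant (1,2),(1,4),(3,4); (1,3): 4>3 conc too
    time = [1.0, 2.0, 3.0, 4.0]
    event = [1, 0, 1, 1]
    risk = [4.0, 1.0, 3.0, 2.0]
    expected = concordance_oracle(time, event, risk)
    assert harrells_c(time, event, risk) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(4 / 4)


def test_harrells_c_equals_oracle_on_random_instances(rng):
    """Exhaustive-pair enumeration oracle, n <= 50, with censoring and tied
    risk scores."""
    for _ in range(15):
        n = int(rng.integers(4, 51))
        time = np.round(rng.exponential(1, n), 3) + 0.001
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        risk = np.round(rng.normal(size=n), 1)  # rounding forces score ties
        assert harrells_c(time, event, risk) == pytest.approx(
            concordance_oracle(time, event, risk), abs=1e-12)


def test_km_no_events_flat(rng):
    curves = km_curve(rng.exponential(1, 30) + 0.01, np.zeros(30, int))
    assert (curves["all"]["survival"] == 1.0).all()


def test_km_product_limit_hand_calc():
    curves = km_curve([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    sf = curves["all"].set_index("time")["survival"]
    np.testing.assert_allclose(sf.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])


def test_km_matches_exponential_survivor(rng):
    t = rng.exponential(1 / 0.3, 3000)
    obs = np.minimum(t, 3.0)
    e = (t < 3.0).astype(int)
    sf = km_curve(obs, e)["all"]
    idx = np.searchsorted(sf["time"].to_numpy(), 1.0)
    assert sf["survival"].iloc[idx] == pytest.approx(np.exp(-0.3), abs=0.03)


def test_ph_diagnostics_flags_crossing_hazards(rng):
    n = 3000
    status = rng.integers(0, 2, n)
    # group 0: increasing hazard (Weibull k=3), group 1: decreasing (k=0.5);
    # hazards cross, proportionality is badly violated
    t = np.where(status == 0, rng.weibull(3.0, n), rng.weibull(0.5, n)) + 1e-6
    df = pd.DataFrame({"status": status, "time_years": t, "died": 1})
    cf = fit_cox(df, covariates=())
    rep = ph_diagnostics(cf)
    assert rep.any_violation


def test_ph_diagnostics_clean_under_proportional_hazards(rng):
    df = exp_two_group(rng, 1500, hr=2.0, censor=5.0)
    cf = fit_cox(df, covariates=())
    rep = ph_diagnostics(cf)
    assert set(rep.table.index) == {"status[1]"}
    assert rep.loglog is not None and len(rep.loglog) == 2
    for curve in rep.loglog.values():  # truncated to where the curve is defined
        assert np.isfinite(curve.to_numpy(float)).all()
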