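"""Concurrent and predictive validity of baseline latent statuses.

Incident binary outcomes (frailty, dementia, disability) are modelled with
covariate-adjusted logistic regressions against the healthiest status;
results are reported both as Wald odds ratios and as covariate-standardised
(marginal) probabilities — the average model-predicted probability over the
observed covariate distribution with status fixed.  Ordinal self-rated
health uses a generalized ordered (partial proportional odds) logit: one
binary logit per cumulative threshold with all coefficients free per
threshold.  Mortality uses Cox proportional hazards (Breslow ties, via
lifelines) with Harrell's C for discrimination, a score test against
log-time-varying effects for the PH assumption, and Kaplan-Meier /
log(-log) curves for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LifelinesConvergenceError
from lifelines.statistics import proportional_hazard_test
from lifelines.utils import concordance_index

__all__ = [
    "EffectEstimate",
    "SeparationError",
    "LogisticFit",
    "GologitFit",
    "CoxFit",
    "PHReport",
    "fit_logistic",
    "adjusted_probability",
    "fit_gologit",
    "fit_cox",
    "harrells_c",
    "ph_diagnostics",
    "km_curve",
    "loglog_curves",
]

Z95 = 1.959963984540054


class SeparationError(RuntimeError):
    """(Quasi-)complete separation: a coefficient diverges."""


@dataclass
class EffectEstimate:
    contrast: str
    scale: str  # "OR" | "HR" | "probability"
    point: float
    ci_low: float
    ci_high: float
    adjusted_for: tuple = ()

    def __post_init__(self):
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(f"inconsistent CI for {self.contrast}: "
                             f"{self.ci_low}, {self.point}, {self.ci_high}")


def _status_design(df: pd.DataFrame, status_col: str, covariates, ref):
    """Design matrix: intercept, status dummies (vs ``ref``), covariates."""
    status = df[status_col]
    levels = [lv for lv in pd.unique(status)]
    levels = sorted(levels)
    if ref is None:
        ref = levels[0]
    if ref not in levels:
        raise ValueError(f"reference status {ref!r} absent from data")
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for lv in levels:
        if lv != ref:
            X[f"status[{lv}]"] = (status == lv).astype(float)
    for c in covariates:
        X[c] = df[c].astype(float)
    if covariates:
        zero = [c for c in covariates if np.allclose(X[c], 0)]
        if zero:
            raise ValueError(f"all-zero covariate columns: {zero}")
    return X, [lv for lv in levels if lv != ref], ref


@dataclass
class LogisticFit:
    result: object  # statsmodels results
    X: pd.DataFrame
    y: pd.Series
    status_col: str
    status_levels: list
    ref: object
    covariates: tuple
    effects: list = field(default_factory=list)

    def predict_at_status(self, status) -> np.ndarray:
        """Predicted probabilities with everyone's status set to ``status``."""
        Xs = self.X.copy()
        for lv in self.status_levels:
            Xs[f"status[{lv}]"] = 1.0 if lv == status else 0.0
        return np.asarray(self.result.predict(Xs))


def fit_logistic(df: pd.DataFrame, outcome: str, status_col: str = "status",
                 covariates=(), ref=None) -> LogisticFit:
    """Covariate-adjusted logistic regression of a binary outcome on status.

    Returns a :class:`LogisticFit` whose ``effects`` hold the Wald odds
    ratios for each status against the reference (default: lowest code, the
    healthiest under canonical ordering).  Raises :class:`SeparationError`
    when a coefficient diverges.
    """
    data = df.dropna(subset=[outcome])
    y = data[outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary")
    X, levels, ref = _status_design(data, status_col, covariates, ref)
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=200, tol=1e-10, disp=False)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as err:
        raise SeparationError(f"logistic fit for {outcome!r} failed: {err}") from err
    big = res.params[np.abs(res.params) > 15]
    if len(big):
        raise SeparationError(
            f"separation in {outcome!r}: diverging coefficients {dict(big)}")
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(f"logistic fit for {outcome!r} did not converge")
    effects = []
    ci = res.conf_int(alpha=0.05)
    for lv in levels:
        name = f"status[{lv}]"
        effects.append(EffectEstimate(
            contrast=f"{lv} vs {ref}", scale="OR",
            point=float(np.exp(res.params[name])),
            ci_low=float(np.exp(ci.loc[name, 0])),
            ci_high=float(np.exp(ci.loc[name, 1])),
            adjusted_for=tuple(covariates),
        ))
    return LogisticFit(result=res, X=X, y=y, status_col=status_col,
                       status_levels=levels, ref=ref, covariates=tuple(covariates),
                       effects=effects)


def adjusted_probability(fit: LogisticFit, status, ci: str = "bootstrap",
                         n_boot: int = 500, seed: int | None = None) -> EffectEstimate:
    """Marginal standardisation: average predicted probability over the
    observed covariate distribution with status fixed to ``status``.

    CIs by nonparametric bootstrap (default, ``n_boot`` refits, seeded) or
    the delta method (``ci="delta"``), which agrees closely and is cheap.
    """
    if status != fit.ref and status not in fit.status_levels:
        raise ValueError(f"status {status!r} not in model")
    n_cell = int((fit.X[f"status[{status}]"] == 1).sum()) if status != fit.ref else int(
        (fit.X[[f"status[{lv}]" for lv in fit.status_levels]].sum(axis=1) == 0).sum())
    if n_cell == 0:
        raise ValueError(f"no subjects observed in status {status!r}")
    p = fit.predict_at_status(status)
    point = float(p.mean())
    if ci == "delta":
        Xs = fit.X.copy()
        for lv in fit.status_levels:
            Xs[f"status[{lv}]"] = 1.0 if lv == status else 0.0
        g = (p * (1 - p))[:, None] * Xs.to_numpy(float)
        grad = g.mean(axis=0)
        var = float(grad @ fit.result.cov_params().to_numpy() @ grad)
        half = Z95 * np.sqrt(var)
        lo, hi = point - half, point + half
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(fit.X)
        stats = []
        data = pd.concat([fit.y.rename("_y"), fit.X], axis=1).reset_index(drop=True)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            sample = data.iloc[idx]
            try:
                res = sm.Logit(sample["_y"], sample.drop(columns="_y")).fit(
                    method="newton", maxiter=100, disp=False)
            except Exception:
                continue
            Xs = sample.drop(columns="_y").copy()
            for lv in fit.status_levels:
                Xs[f"status[{lv}]"] = 1.0 if lv == status else 0.0
            stats.append(float(np.asarray(res.predict(Xs)).mean()))
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    lo = min(lo, point)
    hi = max(hi, point)
    return EffectEstimate(contrast=f"P({status})", scale="probability",
                          point=point, ci_low=float(max(lo, 0.0)),
                          ci_high=float(min(hi, 1.0)), adjusted_for=fit.covariates)


# ---------------------------------------------------------------------------
# generalized ordered logit
# ---------------------------------------------------------------------------

@dataclass
class GologitFit:
    threshold_fits: dict  # k -> statsmodels results for P(Y > k)
    X: pd.DataFrame
    status_col: str
    status_levels: list
    ref: object
    categories: list  # category labels after any merging
    covariates: tuple

    def marginal_probabilities(self) -> pd.DataFrame:
        """Per-status standardised category probabilities (rows sum to 1).

        Because thresholds are unconstrained, averaged cumulative curves can
        cross slightly; tiny negative cell probabilities are clipped to 0 and
        the row renormalised.
        """
        rows = {}
        all_status = [self.ref] + self.status_levels
        for s in all_status:
            Xs = self.X.copy()
            for lv in self.status_levels:
                Xs[f"status[{lv}]"] = 1.0 if lv == s else 0.0
            cum = [1.0]
            for k in sorted(self.threshold_fits):
                cum.append(float(np.asarray(self.threshold_fits[k].predict(Xs)).mean()))
            cum.append(0.0)
            probs = -np.diff(cum)
            probs = np.clip(probs, 0.0, None)
            rows[s] = probs / probs.sum()
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.categories)


def fit_gologit(df: pd.DataFrame, outcome: str = "srh", status_col: str = "status",
                covariates=(), ref=None) -> GologitFit:
    """Generalized ordered logit: K-1 cumulative binary logits P(Y > k) with
    status and covariate coefficients free per threshold (full relaxation).

    Categories unobserved in the data are merged into the adjacent lower
    category with a warning.
    """
    data = df.dropna(subset=[outcome]).copy()
    y = data[outcome].astype(int)
    cats = sorted(y.unique())
    expected = list(range(int(min(cats)), int(max(cats)) + 1))
    missing_cats = [c for c in expected if c not in cats]
    if missing_cats:
        warnings.warn(f"empty ordinal categories {missing_cats} merged with adjacent")
    cats = sorted(set(cats))
    recode = {c: i for i, c in enumerate(cats)}
    y = y.map(recode)
    X, levels, ref = _status_design(data, status_col, covariates, ref)
    fits = {}
    for k in range(len(cats) - 1):
        yk = (y > k).astype(float)
        res = sm.Logit(yk, X).fit(method="newton", maxiter=200, tol=1e-10, disp=False)
        if np.abs(res.params).max() > 15:
            raise SeparationError(f"separation at threshold {k} of {outcome!r}")
        fits[k] = res
    return GologitFit(threshold_fits=fits, X=X, status_col=status_col,
                      status_levels=levels, ref=ref, categories=cats,
                      covariates=tuple(covariates))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    model: CoxPHFitter
    data: pd.DataFrame  # design actually fitted (duration, event, dummies)
    duration_col: str
    event_col: str
    status_levels: list
    ref: object
    covariates: tuple
    effects: list = field(default_factory=list)

    def risk_score(self) -> np.ndarray:
        """Linear predictor (log partial hazard) per subject."""
        covs = self.data.drop(columns=[self.duration_col, self.event_col])
        return np.asarray(self.model.predict_log_partial_hazard(covs)).ravel()


def fit_cox(df: pd.DataFrame, duration_col: str = "time_years", event_col: str = "died",
            status_col: str = "status", covariates=(), ref=None) -> CoxFit:
    """Cox proportional-hazards regression of mortality on baseline status.

    Partial likelihood with Breslow tie handling (lifelines).  ``covariates``
    empty gives the unadjusted (status-only) model.  Raises on data without
    events; flags monotone-likelihood style divergence.
    """
    data = df.dropna(subset=[duration_col, event_col])
    if (data[duration_col] <= 0).any():
        raise ValueError("durations must be positive")
    if data[event_col].sum() == 0:
        raise ValueError("no events observed; Cox model undefined")
    X, levels, ref = _status_design(data, status_col, covariates, ref)
    design = X.drop(columns="const")
    design[duration_col] = data[duration_col].to_numpy(float)
    design[event_col] = data[event_col].to_numpy(float)
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col=duration_col, event_col=event_col)
    except LifelinesConvergenceError as err:
        raise SeparationError(f"Cox fit diverged (monotone likelihood?): {err}") from err
    effects = []
    summ = cph.summary
    for lv in levels:
        name = f"status[{lv}]"
        effects.append(EffectEstimate(
            contrast=f"{lv} vs {ref}", scale="HR",
            point=float(summ.loc[name, "exp(coef)"]),
            ci_low=float(summ.loc[name, "exp(coef) lower 95%"]),
            ci_high=float(summ.loc[name, "exp(coef) upper 95%"]),
            adjusted_for=tuple(covariates),
        ))
    return CoxFit(model=cph, data=design, duration_col=duration_col, event_col=event_col,
                  status_levels=levels, ref=ref, covariates=tuple(covariates),
                  effects=effects)


def harrells_c(time, event, risk_score) -> float:
    """Harrell's concordance: fraction of usable pairs (shorter time is an
    event) where the higher risk score has the shorter time; score ties 0.5.

    Computed via lifelines' concordance machinery; note lifelines orients
    scores as survival predictions, hence the sign flip.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk_score, float)
    if not np.isfinite(risk).all():
        raise ValueError("risk scores must be finite")
    if event.sum() == 0 or len(time) < 2:
        raise ValueError("no usable pairs")
    return float(concordance_index(time, -risk, event))


@dataclass
class PHReport:
    table: pd.DataFrame  # per covariate: test statistic, p, violation flag
    violations: list
    alpha: float
    loglog: dict | None = None  # group -> DataFrame(log_time, cloglog)

    @property
    def any_violation(self) -> bool:
        return len(self.violations) > 0


def ph_diagnostics(fit: CoxFit, alpha: float = 0.05, groups=None) -> PHReport:
    """Proportional-hazards diagnostics for a fitted Cox model.

    (a) score test of a log(time)-varying coefficient per covariate (the
    score-test form of adding ``x * log(t)`` interactions); (b) log(-log)
    survival curves per status for visual inspection.
    """
    res = proportional_hazard_test(fit.model, fit.data, time_transform="log")
    table = res.summary.copy()
    table["violation"] = table["p"] < alpha
    violations = list(table.index[table["violation"]])
    ll = None
    if groups is None and fit.status_levels:
        cols = [f"status[{lv}]" for lv in fit.status_levels]
        groups = pd.Series(fit.ref, index=fit.data.index, dtype=object)
        for lv in fit.status_levels:
            groups[fit.data[f"status[{lv}]"] == 1] = lv
    if groups is not None:
        ll = loglog_curves(fit.data[fit.duration_col], fit.data[fit.event_col], groups)
    return PHReport(table=table, violations=violations, alpha=alpha, loglog=ll)


def km_curve(time, event, group=None) -> dict:
    """Kaplan-Meier product-limit curves, one per group (or ``"all"``)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if group is None:
        group = np.zeros(len(time), int)
        labels = {0: "all"}
    else:
        group = np.asarray(group)
        labels = {g: g for g in pd.unique(group)}
    out = {}
    for g, label in labels.items():
        m = group == g
        km = KaplanMeierFitter()
        km.fit(time[m], event[m])
        sf = km.survival_function_
        out[label] = pd.DataFrame({"time": sf.index.to_numpy(float),
                                   "survival": sf.iloc[:, 0].to_numpy(float)})
    return out


def loglog_curves(time, event, group) -> dict:
    """log(-log S(t)) vs log t per group; undefined points (S = 1 or 0, or
    t beyond the last event) are dropped, i.e. curves are truncated."""
    curves = km_curve(time, event, group)
    out = {}
    for g, df in curves.items():
        s = df["survival"].to_numpy()
        t = df["time"].to_numpy()
        ok = (s > 0) & (s < 1) & (t > 0)
        out[g] = pd.DataFrame({"log_time": np.log(t[ok]),
                               "cloglog": np.log(-np.log(s[ok]))})
    return out
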