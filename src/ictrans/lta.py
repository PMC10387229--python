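"""Latent transition analysis (LTA) for two-wave multi-indicator binary data.

The model.  Each subject i carries an unobserved baseline status a and
follow-up status b out of S statuses.  Baseline membership follows a
multinomial logit on covariates x_i (delta_a(x_i)); statuses move between
waves with a row-stochastic transition matrix tau; given the status at a
wave, the six binary impairment indicators are independent Bernoulli draws
with status-conditional probabilities rho (identical at both waves —
measurement invariance, which is what makes statuses comparable over time).
The observed-data likelihood for subject i is

    L_i = sum_a sum_b delta_a(x_i) tau_ab
          prod_j rho_aj^y_ij1 (1-rho_aj)^(1-y_ij1)
          prod_j rho_bj^y_ij2 (1-rho_bj)^(1-y_ij2)

with missing indicators marginalised by dropping their factors; a fully
missing wave 2 marginalises b out entirely (the subject still informs
delta and rho through wave 1).

Estimation is by EM.  The E-step computes the joint posterior
w_iab = P(a, b | y_i, x_i); the M-step has closed forms for rho and tau and
a Newton-maximised weighted multinomial logit for the membership
coefficients.  Subjects with wave 2 entirely missing are excluded from the
tau update so that mortality/dropout does not leak into the transition
estimates (their marginalised contribution is available behind
``tau_include_missing=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coding import DOMAINS

__all__ = [
    "IndicatorPanel",
    "LTAParams",
    "PosteriorTable",
    "FitResult",
    "ZeroLikelihoodError",
    "DegenerateStatusError",
    "ConvergenceError",
    "loglikelihood",
    "e_step",
    "m_step",
    "fit",
    "assign_modal",
]

RHO_FLOOR = 1e-4  # keeps emission probabilities off the absorbing 0/1 boundary


class ZeroLikelihoodError(ValueError):
    """A subject has zero likelihood under the supplied parameters."""


class DegenerateStatusError(RuntimeError):
    """A status collected (numerically) no posterior mass; fit fewer statuses."""


class ConvergenceError(RuntimeError):
    """No EM start reached the convergence tolerance."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class IndicatorPanel:
    """Binary impairment indicators (n, 6 domains, 2 waves) plus covariates.

    ``y`` is float with NaN for missing; ``x`` holds raw (unstandardised)
    covariate columns without an intercept.
    """

    y: np.ndarray
    x: np.ndarray
    ids: np.ndarray
    covariate_names: tuple = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y.ndim != 3 or self.y.shape[2] != 2:
            # J is 6 for the IC application but the estimator is generic in J
            raise ValueError(f"y must be (n, n_items, 2); got {self.y.shape}")
        self.validate()

    def validate(self) -> None:
        empty = np.isnan(self.y[:, :, 0]).all(axis=1)
        if empty.any():
            bad = list(np.asarray(self.ids)[empty][:10])
            raise ValueError(f"subjects with all wave-1 indicators missing: {bad}")
        if np.isnan(self.x).any():
            raise ValueError("covariates must be complete (impute upstream)")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def wave2_observed(self) -> np.ndarray:
        """Subjects with at least one non-missing wave-2 indicator."""
        return ~np.isnan(self.y[:, :, 1]).all(axis=1)

    @classmethod
    def from_dataframes(
        cls,
        indicators: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        covariate_cols: tuple = ("age", "female", "education"),
        id_col: str = "id",
    ) -> "IndicatorPanel":
        """Build a panel from the indicator CSV dialect (``<domain>_w1/_w2``)."""
        n = len(indicators)
        y = np.full((n, len(DOMAINS), 2), np.nan)
        for t in (1, 2):
            for j, d in enumerate(DOMAINS):
                col = indicators[f"{d}_w{t}"]
                y[:, j, t - 1] = col.astype("Float64").to_numpy(dtype=float, na_value=np.nan)
        ids = indicators[id_col].to_numpy() if id_col in indicators else np.arange(n)
        if covariates is not None:
            cov = covariates.set_index(id_col).loc[ids] if id_col in covariates else covariates
            x = cov[list(covariate_cols)].to_numpy(float)
            names = tuple(covariate_cols)
        else:
            x = np.empty((n, 0))
            names = ()
        return cls(y=y, x=x, ids=ids, covariate_names=names)


@dataclass
class LTAParams:
    """Model parameters.

    ``beta`` is (S-1, p+1) multinomial-logit coefficients (intercept first)
    for initial membership with the *last* status as reference; covariates
    are standardised with the stored ``x_mean``/``x_scale`` before use.
    """

    beta: np.ndarray
    rho: np.ndarray
    tau: np.ndarray
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    covariate_names: tuple = ()
    status_names: tuple | None = None

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.rho = np.asarray(self.rho, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        S = self.rho.shape[0]
        if self.beta.size == 0:
            self.beta = np.empty((0, 1 + (0 if self.x_mean is None else len(self.x_mean))))
        p = self.beta.shape[1] - 1
        if self.x_mean is None:
            self.x_mean = np.zeros(p)
        if self.x_scale is None:
            self.x_scale = np.ones(p)
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.x_scale = np.asarray(self.x_scale, dtype=float)
        if self.tau.shape != (S, S):
            raise ValueError(f"tau must be ({S},{S}); got {self.tau.shape}")
        if self.beta.shape[0] not in (0, S - 1):
            raise ValueError(f"beta must have {S - 1} rows; got {self.beta.shape[0]}")

    @property
    def n_statuses(self) -> int:
        return self.rho.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[1] - 1 if self.beta.size else len(self.x_mean)

    def n_params(self) -> int:
        S, J = self.rho.shape
        p = self.n_covariates
        return (S - 1) * (p + 1) + J * S + S * (S - 1)

    def validate(self) -> None:
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValueError("rho outside [0,1]")
        if np.abs(self.tau.sum(axis=1) - 1).max() > 1e-8 or (self.tau < 0).any():
            raise ValueError("tau rows must be probability vectors")

    def _design(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, float) - self.x_mean) / self.x_scale
        return np.column_stack([np.ones(len(xs)), xs])

    def initial_probabilities(self, x: np.ndarray) -> np.ndarray:
        """delta_a(x): (n, S) covariate-conditional baseline membership."""
        S = self.n_statuses
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        if S == 1:
            return np.ones((x2.shape[0], 1))
        X1 = self._design(x2)
        logits = np.zeros((X1.shape[0], S))
        logits[:, :-1] = X1 @ self.beta.T  # reference = last status
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def permute(self, perm) -> "LTAParams":
        """Relabel statuses by ``perm`` (new index -> old index), consistently
        across rho, tau and the membership logits (re-referenced to the new
        last status)."""
        perm = np.asarray(perm)
        S = self.n_statuses
        full = np.zeros((S, self.beta.shape[1] if self.beta.size else 1 + self.n_covariates))
        if self.beta.size:
            full[:-1] = self.beta
        full = full[perm]
        full -= full[-1]  # re-reference
        return LTAParams(
            beta=full[:-1] if S > 1 else np.empty((0, full.shape[1])),
            rho=self.rho[perm],
            tau=self.tau[np.ix_(perm, perm)],
            x_mean=self.x_mean.copy(),
            x_scale=self.x_scale.copy(),
            covariate_names=self.covariate_names,
            status_names=tuple(np.asarray(self.status_names)[perm]) if self.status_names else None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "beta": self.beta.tolist(),
                    "rho": self.rho.tolist(),
                    "tau": self.tau.tolist(),
                    "x_mean": self.x_mean.tolist(),
                    "x_scale": self.x_scale.tolist(),
                    "covariate_names": list(self.covariate_names),
                    "status_names": list(self.status_names) if self.status_names else None,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def load(cls, path) -> "LTAParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            beta=np.asarray(d["beta"], float),
            rho=np.asarray(d["rho"], float),
            tau=np.asarray(d["tau"], float),
            x_mean=np.asarray(d["x_mean"], float),
            x_scale=np.asarray(d["x_scale"], float),
            covariate_names=tuple(d.get("covariate_names") or ()),
            status_names=tuple(d["status_names"]) if d.get("status_names") else None,
        )


@dataclass
class PosteriorTable:
    """Joint and marginal posterior status probabilities per subject."""

    ids: np.ndarray
    w: np.ndarray  # (n, S, S): P(status_w1=a, status_w2=b | data)
    w1: np.ndarray  # (n, S) baseline marginal
    w2: np.ndarray  # (n, S) follow-up marginal
    loglik: float


@dataclass
class FitResult:
    params: LTAParams
    loglik: float
    n_params: int
    n_iter: int
    converged: bool
    seed_of_best_start: int
    loglik_trace: list = field(default_factory=list)
    n_subjects: int = 0


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _log_emissions(y_wave: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """(n, S) log P(observed indicators at one wave | status), missing items
    contributing nothing."""
    obs = ~np.isnan(y_wave)
    y0 = np.where(obs, y_wave, 0.0)
    n0 = obs.astype(float) - y0  # observed zeros
    with np.errstate(divide="ignore"):
        lr = np.log(rho)
        l1 = np.log1p(-rho)
    # exact 0/1 emission probabilities: a matching observation contributes 0
    # (0 * log 0 := 0), a contradicting one drives the row to -inf
    lr_inf, l1_inf = ~np.isfinite(lr), ~np.isfinite(l1)
    out = y0 @ np.where(lr_inf, 0.0, lr).T + n0 @ np.where(l1_inf, 0.0, l1).T
    contradictions = y0 @ lr_inf.astype(float).T + n0 @ l1_inf.astype(float).T
    out[contradictions > 0] = -np.inf
    return out


def _joint_logterms(panel: IndicatorPanel, params: LTAParams) -> np.ndarray:
    """(n, S, S) array of log[delta_a(x) tau_ab E1_a E2_b]."""
    e1 = _log_emissions(panel.y[:, :, 0], params.rho)
    e2 = _log_emissions(panel.y[:, :, 1], params.rho)
    with np.errstate(divide="ignore"):
        log_delta = np.log(params.initial_probabilities(panel.x))
        log_tau = np.log(params.tau)
    return (log_delta + e1)[:, :, None] + log_tau[None, :, :] + e2[:, None, :]


def loglikelihood(panel: IndicatorPanel, params: LTAParams) -> float:
    """Observed-data log likelihood (missing items marginalised).

    Returns ``-inf`` when degenerate emission probabilities (exact 0/1)
    contradict an observed indicator.
    """
    ll = _joint_logterms(panel, params)
    m = ll.max(axis=(1, 2))
    finite = np.isfinite(m)
    per_subject = np.full(panel.n, -np.inf)
    if finite.any():
        shifted = np.exp(ll[finite] - m[finite, None, None])
        per_subject[finite] = np.log(shifted.sum(axis=(1, 2))) + m[finite]
    return float(per_subject.sum())


def e_step(panel: IndicatorPanel, params: LTAParams) -> PosteriorTable:
    """Posterior P(status_w1, status_w2 | data) per subject, plus the loglik."""
    ll = _joint_logterms(panel, params)
    m = ll.max(axis=(1, 2))
    if not np.isfinite(m).all():
        bad = list(np.asarray(panel.ids)[~np.isfinite(m)][:10])
        raise ZeroLikelihoodError(f"zero likelihood for subjects {bad}")
    w = np.exp(ll - m[:, None, None])
    tot = w.sum(axis=(1, 2))
    w /= tot[:, None, None]
    loglik = float((np.log(tot) + m).sum())
    return PosteriorTable(ids=panel.ids, w=w, w1=w.sum(axis=2), w2=w.sum(axis=1), loglik=loglik)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _weighted_multinomial_logit(
    X1: np.ndarray, w1: np.ndarray, beta0: np.ndarray, max_iter: int = 50, gtol: float = 1e-9
) -> np.ndarray:
    """Maximise sum_i sum_a w1_ia log p_a(x_i; beta) by damped Newton.

    Soft-label weighted multinomial logit; reference class is the last.
    Step-halving guarantees the objective never decreases, which keeps the
    enclosing EM monotone even if Newton stops early.
    """
    n, q = X1.shape
    S = w1.shape[1]
    beta = beta0.copy()

    def probs(b):
        logits = np.zeros((n, S))
        logits[:, :-1] = X1 @ b.T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def objective(b):
        return float(np.sum(w1 * np.log(np.clip(probs(b), 1e-300, None))))

    obj = objective(beta)
    for _ in range(max_iter):
        p = probs(beta)
        resid = w1[:, :-1] - p[:, :-1]
        grad = (resid.T @ X1).ravel()  # ((S-1) * q,)
        if np.abs(grad).max() < gtol * max(1.0, n):
            break
        H = np.zeros((S - 1, q, S - 1, q))
        for a in range(S - 1):
            for b in range(S - 1):
                wab = p[:, a] * ((1.0 if a == b else 0.0) - p[:, b])
                H[a, :, b, :] = -(X1 * wab[:, None]).T @ X1
        Hm = H.reshape((S - 1) * q, (S - 1) * q)
        Hm -= 1e-10 * np.eye(len(Hm))
        try:
            step = np.linalg.solve(Hm, -grad).reshape(S - 1, q)
        except np.linalg.LinAlgError:
            step = grad.reshape(S - 1, q) / max(1.0, n)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                beta, obj = cand, cand_obj
                break
            scale *= 0.5
        else:
            break  # no improving step; keep current beta
    return beta


def m_step(
    panel: IndicatorPanel,
    posterior: PosteriorTable,
    params: LTAParams | None = None,
    tau_include_missing: bool = False,
) -> LTAParams:
    """Closed-form rho/tau updates plus the Newton membership update.

    rho pools both waves (measurement invariance) over non-missing items;
    tau uses only subjects with some wave-2 data unless
    ``tau_include_missing`` (for the marginalised alternative).
    """
    w1, w2, w = posterior.w1, posterior.w2, posterior.w
    n, S = w1.shape
    mass = w1.sum(axis=0)
    if mass.min() < 1e-8:
        empty = [int(a) for a in np.where(mass < 1e-8)[0]]
        raise DegenerateStatusError(
            f"statuses {empty} carry no posterior mass; consider fewer statuses"
        )

    # rho: weighted impairment frequencies pooled across waves
    obs1 = ~np.isnan(panel.y[:, :, 0])
    obs2 = ~np.isnan(panel.y[:, :, 1])
    y1 = np.where(obs1, panel.y[:, :, 0], 0.0)
    y2 = np.where(obs2, panel.y[:, :, 1], 0.0)
    num = w1.T @ y1 + w2.T @ y2
    den = w1.T @ obs1 + w2.T @ obs2
    rho = np.clip(num / np.maximum(den, 1e-300), RHO_FLOOR, 1 - RHO_FLOOR)

    # tau: transition flows among subjects observed at wave 2
    keep = np.ones(n, bool) if tau_include_missing else panel.wave2_observed
    flow = w[keep].sum(axis=0)
    row = flow.sum(axis=1, keepdims=True)
    if params is not None:
        tau = np.where(row > 1e-12, flow / np.maximum(row, 1e-300), params.tau)
    else:
        tau = flow / np.maximum(row, 1e-300)
    tau = tau / tau.sum(axis=1, keepdims=True)

    # membership coefficients
    x_mean = params.x_mean if params is not None else np.zeros(panel.x.shape[1])
    x_scale = params.x_scale if params is not None else np.ones(panel.x.shape[1])
    if S == 1:
        beta = np.empty((0, panel.x.shape[1] + 1))
    else:
        xs = (panel.x - x_mean) / x_scale
        X1 = np.column_stack([np.ones(n), xs])
        beta0 = params.beta if params is not None and params.beta.size else np.zeros((S - 1, X1.shape[1]))
        beta = _weighted_multinomial_logit(X1, w1, beta0)

    return LTAParams(
        beta=beta,
        rho=rho,
        tau=tau,
        x_mean=x_mean,
        x_scale=x_scale,
        covariate_names=panel.covariate_names,
        status_names=params.status_names if params is not None else None,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _random_params(rng: np.random.Generator, S: int, panel: IndicatorPanel,
                   x_mean: np.ndarray, x_scale: np.ndarray) -> LTAParams:
    J = panel.y.shape[1]
    rho = rng.uniform(0.15, 0.85, size=(S, J))
    tau = rng.uniform(0.2, 1.0, size=(S, S)) + 2.0 * np.eye(S)
    tau /= tau.sum(axis=1, keepdims=True)
    beta = np.zeros((S - 1, panel.x.shape[1] + 1)) if S > 1 else np.empty((0, panel.x.shape[1] + 1))
    if S > 1:
        beta[:, 0] = rng.normal(0, 0.1, size=S - 1)
    return LTAParams(beta=beta, rho=rho, tau=tau, x_mean=x_mean, x_scale=x_scale,
                     covariate_names=panel.covariate_names)


def _em_run(panel, params, tol, max_iter, trace=None, tau_include_missing=False):
    trace = [] if trace is None else trace
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = e_step(panel, params)
        trace.append(post.loglik)
        if post.loglik - ll_old < tol * (1.0 + abs(post.loglik)) and it > 1:
            converged = True
            break
        ll_old = post.loglik
        params = m_step(panel, post, params, tau_include_missing=tau_include_missing)
    return params, trace, converged, it


def fit(
    panel: IndicatorPanel,
    S: int,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    burn_iters: int = 40,
    n_final: int | None = None,
    order: bool = True,
    tau_include_missing: bool = False,
) -> FitResult:
    """Maximum-likelihood EM fit with a burn-in multistart.

    All ``n_starts`` random initialisations run ``burn_iters`` EM iterations;
    the most promising ``n_final`` (default: best quarter, at least one) run
    to convergence (relative log-likelihood gain below ``tol``).  With
    ``order=True`` the best solution is relabelled to the canonical severity
    order.  Raises :class:`ConvergenceError` if no full run converges.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    p = panel.x.shape[1]
    x_mean = panel.x.mean(axis=0) if p else np.zeros(0)
    x_sd = panel.x.std(axis=0) if p else np.zeros(0)
    x_scale = np.where(x_sd > 1e-12, x_sd, 1.0) if p else np.ones(0)

    if S == 1:
        # closed form: single status, rho = pooled item means
        obs = ~np.isnan(panel.y)
        num = np.nansum(panel.y, axis=(0, 2))
        den = obs.sum(axis=(0, 2))
        rho = np.clip(num / den, RHO_FLOOR, 1 - RHO_FLOOR)[None, :]
        params = LTAParams(beta=np.empty((0, p + 1)), rho=rho, tau=np.ones((1, 1)),
                           x_mean=x_mean, x_scale=x_scale, covariate_names=panel.covariate_names)
        ll = loglikelihood(panel, params)
        return FitResult(params=params, loglik=ll, n_params=params.n_params(), n_iter=1,
                         converged=True, seed_of_best_start=-1, loglik_trace=[ll],
                         n_subjects=panel.n)

    ss = np.random.SeedSequence(seed)
    start_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_starts)]
    if n_final is None:
        n_final = max(1, min(5, n_starts // 4 if n_starts >= 4 else n_starts))

    burned = []
    for s in start_seeds:
        rng = np.random.default_rng(s)
        params0 = _random_params(rng, S, panel, x_mean, x_scale)
        try:
            params1, trace, _, _ = _em_run(
                panel, params0, tol, min(burn_iters, max_iter), tau_include_missing=tau_include_missing
            )
        except DegenerateStatusError:
            continue
        burned.append((trace[-1], s, params1, trace))
    if not burned:
        raise DegenerateStatusError(f"every start collapsed a status; S={S} looks too large")
    burned.sort(key=lambda t: -t[0])

    results = []
    failures = []
    for ll_burn, s, params1, trace in burned[:n_final]:
        try:
            params2, trace, converged, extra = _em_run(
                panel, params1, tol, max_iter, trace=trace, tau_include_missing=tau_include_missing
            )
        except DegenerateStatusError as err:
            failures.append((s, str(err)))
            continue
        results.append((trace[-1], s, params2, trace, converged, len(trace)))
    if not results or not any(r[4] for r in results):
        detail = [(s, tr[-1] if tr else None) for _, s, _, tr, _, _ in results] + failures
        raise ConvergenceError(f"no start converged within {max_iter} iterations: {detail}")

    ll, s, params, trace, converged, n_iter = max(results, key=lambda r: r[0])
    if order:
        from .selection import order_statuses

        params = order_statuses(params)
    return FitResult(params=params, loglik=ll, n_params=params.n_params(), n_iter=n_iter,
                     converged=converged, seed_of_best_start=s, loglik_trace=trace,
                     n_subjects=panel.n)


def assign_modal(posterior: PosteriorTable) -> tuple[np.ndarray, np.ndarray]:
    """Modal status per wave from the marginal posteriors.

    Exact ties go to the lowest status index, i.e. the healthier status once
    parameters are in canonical severity order.
    """
    return posterior.w1.argmax(axis=1), posterior.w2.argmax(axis=1)
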