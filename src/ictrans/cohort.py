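"""Synthetic two-wave cohorts with a latent-Markov impairment structure.

The generator emulates the data structure the latent transition analysis
assumes: each subject has an unobserved baseline status drawn from a
covariate-dependent multinomial-logit membership model, a follow-up status
drawn from a status-to-status transition matrix, and six binary domain
impairments emitted independently at each wave with status-conditional
probabilities (the same emission probabilities at both waves = measurement
invariance).  Mortality follows status-specific exponential hazards with a
common administrative censoring horizon; death before follow-up (or random
dropout) makes the wave-2 indicators missing.  Incident outcomes (frailty,
dementia, disability) follow status + covariate logistic models and are
missing for subjects flagged as prevalent at baseline or lost to follow-up;
ordinal self-rated health follows status-specific cumulative logits sharing
common covariate effects.

:func:`paper_replication_config` freezes a configuration transcribing the
published estimates of the 10/66 intrinsic-capacity transition study:
baseline status prevalences 43/17/22/18%, the printed transition entries,
per-status impairment probabilities from the baseline cross-tabulation,
published effect sizes, and the published adjusted disability probability and
self-rated-health margins.  Intercept-type constants are calibrated once,
deterministically, so that covariate-averaged quantities hit the published
marginal values; every non-printed constant is documented inline.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .coding import DOMAINS

__all__ = [
    "STATUS_NAMES",
    "CovariateModel",
    "OutcomeModel",
    "SurvivalModel",
    "SRHModel",
    "GeneratorConfig",
    "ConfigValidationError",
    "SyntheticCohort",
    "generate",
    "outcome_cohort",
    "paper_replication_config",
    "expected_transition_fractions",
]

#: canonical severity order, healthiest first
STATUS_NAMES = ("high_ic", "low_det_locomotion", "high_det_no_cog", "high_det_cog")

#: covariates entering the membership/outcome models, in design order
COVARIATE_DESIGN = ("age_std", "female", "education")


class ConfigValidationError(ValueError):
    """Invalid generator configuration; message lists offending entries."""


@dataclass
class CovariateModel:
    """Marginal covariate distributions (drawn independently).

    ``age_mean``/``age_sd`` double as the fixed standardisation constants for
    the ``age_std`` design column, so models are parameterised on the same
    scale regardless of the realised sample.
    """

    age_mean: float = 74.5
    age_sd: float = 7.1
    age_min: float = 65.0
    age_max: float = 100.0
    p_female: float = 0.632
    # none / some / complete primary / complete secondary / high school+
    education_probs: tuple = (0.146, 0.259, 0.293, 0.192, 0.110)
    comorbidity_probs: tuple = (0.705, 0.219, 0.076)  # 0 / 1 / 2+

    def __post_init__(self):
        self.education_probs = tuple(self.education_probs)
        self.comorbidity_probs = tuple(self.comorbidity_probs)

    def draw(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        a = (self.age_min - self.age_mean) / self.age_sd
        b = (self.age_max - self.age_mean) / self.age_sd
        age = truncnorm.rvs(a, b, loc=self.age_mean, scale=self.age_sd, size=n, random_state=rng)
        female = rng.random(n) < self.p_female
        education = rng.choice(5, size=n, p=np.asarray(self.education_probs))
        comorbidities = rng.choice(3, size=n, p=np.asarray(self.comorbidity_probs))
        return pd.DataFrame(
            {
                "age": age,
                "female": female.astype(int),
                "education": education,
                "comorbidities": comorbidities,
            }
        )

    def design(self, covariates: pd.DataFrame) -> np.ndarray:
        """(n, 3) design matrix: standardised age, female, education level."""
        return np.column_stack(
            [
                (covariates["age"].to_numpy(float) - self.age_mean) / self.age_sd,
                covariates["female"].to_numpy(float),
                covariates["education"].to_numpy(float),
            ]
        )


@dataclass
class OutcomeModel:
    """Logistic model for one incident outcome given baseline status.

    ``status_logor`` holds conditional log odds ratios vs the healthiest
    status (first entry 0); ``intercept`` sets the covariate-standardised
    probability for the healthiest status.
    """

    status_logor: tuple
    covariate_logor: tuple
    intercept: float = 0.0
    prevalence_by_status: tuple = (0.0, 0.0, 0.0, 0.0)
    n_published: int = 0

    def __post_init__(self):
        self.status_logor = tuple(self.status_logor)
        self.covariate_logor = tuple(self.covariate_logor)
        self.prevalence_by_status = tuple(self.prevalence_by_status)

    def event_probability(self, status: np.ndarray, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(self.status_logor)[status] + X @ np.asarray(self.covariate_logor)
        return expit(eta)


@dataclass
class SurvivalModel:
    """Status-only exponential hazards with administrative censoring."""

    baseline_rate: float  # hazard of the healthiest status, per year
    hazard_ratios: tuple  # per status, healthiest first (first entry 1)
    horizon: float = 4.2  # years of administrative follow-up
    n_published: int = 0

    def __post_init__(self):
        self.hazard_ratios = tuple(self.hazard_ratios)

    def rates(self) -> np.ndarray:
        return self.baseline_rate * np.asarray(self.hazard_ratios)

    def death_probabilities(self) -> np.ndarray:
        """P(death before the censoring horizon), per status."""
        return 1.0 - np.exp(-self.rates() * self.horizon)


@dataclass
class SRHModel:
    """Ordinal self-rated health, 0 'very good' .. 4 'very bad'.

    Per-status cumulative logits share common covariate effects, so the
    generating process is a partial proportional-odds model with status
    effects free per threshold (the model the analysis fits, relaxed).
    ``alpha[s, k]`` is the threshold constant for P(Y > k | status s).
    """

    alpha: tuple  # (S, 4)
    gamma: tuple  # covariate effects on every threshold
    category_targets: tuple = ()  # documented marginal category probabilities
    n_published: int = 0

    def __post_init__(self):
        self.alpha = tuple(tuple(r) for r in self.alpha)
        self.gamma = tuple(self.gamma)
        self.category_targets = tuple(tuple(r) for r in self.category_targets)

    def exceedance(self, status: np.ndarray, X: np.ndarray) -> np.ndarray:
        """(n, 4) matrix of P(Y > k | status, x), k = 0..3."""
        eta = np.asarray(self.alpha)[status] + (X @ np.asarray(self.gamma))[:, None]
        return expit(eta)


@dataclass
class GeneratorConfig:
    n_subjects: int
    seed: int
    delta: tuple  # marginal baseline status prevalences, healthiest first
    rho: tuple  # (S, 6) status-conditional impairment probabilities
    tau: tuple  # (S, S) transition matrix
    membership_intercepts: tuple  # (S-1,), statuses 2..S vs healthiest
    membership_slopes: tuple  # (S-1, 3) on (age_std, female, education)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    outcomes: dict = field(default_factory=dict)  # name -> OutcomeModel
    survival: SurvivalModel | None = None
    srh: SRHModel | None = None
    dropout: float = 0.05  # wave-2 loss unrelated to death
    status_names: tuple = STATUS_NAMES

    @property
    def n_statuses(self) -> int:
        return len(self.delta)

    def validate(self) -> None:
        problems = []
        delta = np.asarray(self.delta)
        if abs(delta.sum() - 1) > 1e-8:
            problems.append(f"delta sums to {delta.sum():.6f}, expected 1")
        if ((delta < 0) | (delta > 1)).any():
            problems.append(f"delta entries outside [0,1]: {delta}")
        rho = np.asarray(self.rho)
        if ((rho < 0) | (rho > 1)).any():
            problems.append(f"rho entries outside [0,1] at {np.argwhere((rho < 0) | (rho > 1)).tolist()}")
        tau = np.asarray(self.tau)
        bad_rows = np.where(np.abs(tau.sum(axis=1) - 1) > 1e-8)[0]
        if bad_rows.size:
            problems.append(f"tau rows {bad_rows.tolist()} do not sum to 1: {tau.sum(axis=1)[bad_rows]}")
        if ((tau < 0) | (tau > 1)).any():
            problems.append(f"tau entries outside [0,1] at {np.argwhere((tau < 0) | (tau > 1)).tolist()}")
        if not 0 <= self.dropout <= 1:
            problems.append(f"dropout {self.dropout} outside [0,1]")
        if self.survival is not None and (self.survival.rates() <= 0).any():
            problems.append(f"non-positive hazard rates: {self.survival.rates()}")
        if problems:
            raise ConfigValidationError("; ".join(problems))

    def membership_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(n, S) covariate-conditional baseline status probabilities."""
        logits = np.zeros((X.shape[0], self.n_statuses))
        logits[:, 1:] = np.asarray(self.membership_intercepts) + X @ np.asarray(self.membership_slopes).T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["covariates"] = CovariateModel(**d["covariates"])
        d["outcomes"] = {k: OutcomeModel(**v) for k, v in (d.get("outcomes") or {}).items()}
        if d.get("survival"):
            d["survival"] = SurvivalModel(**d["survival"])
        if d.get("srh"):
            d["srh"] = SRHModel(**d["srh"])
        for key in ("delta", "membership_intercepts", "status_names"):
            d[key] = tuple(d[key])
        for key in ("rho", "tau", "membership_slopes"):
            d[key] = tuple(tuple(r) for r in d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generated cohort: observable tables plus an oracle truth sidecar."""

    covariates: pd.DataFrame  # id, age, female, education, comorbidities
    indicators: pd.DataFrame  # id, <domain>_w1, <domain>_w2 (nullable boolean)
    outcomes: pd.DataFrame  # id, incident flags, time_years, died, srh
    truth: pd.DataFrame  # id, true_status_w1/w2, wave2_observed

    def write_csv(self, directory, header_lines=None) -> dict:
        from pathlib import Path

        from .coding import write_indicator_csv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("covariates", self.covariates),
            ("indicators", self.indicators),
            ("outcomes", self.outcomes),
            ("truth", self.truth),
        ]:
            p = directory / f"{name}.csv"
            write_indicator_csv(df, p, header_lines=header_lines)
            paths[name] = p
        return paths


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig, seed: int | None = None, n: int | None = None) -> SyntheticCohort:
    """Draw a complete two-wave cohort.  Bit-reproducible given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects if n is None else n
    S = config.n_statuses

    cov = config.covariates.draw(rng, n)
    X = config.covariates.design(cov)

    # latent statuses
    p1 = config.membership_probabilities(X)
    u = rng.random(n)
    status1 = (u[:, None] >= p1.cumsum(axis=1)).sum(axis=1)
    tau = np.asarray(config.tau)
    u = rng.random(n)
    status2 = (u[:, None] >= tau[status1].cumsum(axis=1)).sum(axis=1)

    # emissions, measurement-invariant across waves
    rho = np.asarray(config.rho)
    y1 = rng.random((n, len(DOMAINS))) < rho[status1]
    y2 = rng.random((n, len(DOMAINS))) < rho[status2]

    # mortality & attrition
    if config.survival is not None:
        rates = config.survival.rates()[status1]
        t_death = rng.exponential(1.0 / rates)
        horizon = config.survival.horizon
        died = t_death < horizon
        time_years = np.minimum(t_death, horizon)
    else:
        died = np.zeros(n, bool)
        time_years = np.full(n, np.nan)
    dropout = rng.random(n) < config.dropout
    wave2_observed = ~died & ~dropout

    ind = pd.DataFrame({"id": np.arange(n)})
    for j, d in enumerate(DOMAINS):
        ind[f"{d}_w1"] = pd.array(y1[:, j], dtype="boolean")
    for j, d in enumerate(DOMAINS):
        col = pd.array(y2[:, j], dtype="boolean")
        col[~wave2_observed] = pd.NA
        ind[f"{d}_w2"] = col

    out = pd.DataFrame({"id": np.arange(n)})
    for name, model in config.outcomes.items():
        prevalent = rng.random(n) < np.asarray(model.prevalence_by_status)[status1]
        event = rng.random(n) < model.event_probability(status1, X)
        col = pd.array(event, dtype="boolean")
        col[prevalent | ~wave2_observed] = pd.NA  # incident outcomes need follow-up
        out[f"incident_{name}"] = col
        out[f"prevalent_{name}"] = pd.array(prevalent, dtype="boolean")
    if config.survival is not None:
        out["time_years"] = time_years
        out["died"] = died.astype(int)
    if config.srh is not None:
        exceed = config.srh.exceedance(status1, X)
        u = rng.random(n)
        out["srh"] = (u[:, None] < exceed).sum(axis=1)

    cov.insert(0, "id", np.arange(n))
    truth = pd.DataFrame(
        {
            "id": np.arange(n),
            "true_status_w1": status1,
            "true_status_w2": status2,
            "wave2_observed": wave2_observed.astype(int),
        }
    )
    return SyntheticCohort(covariates=cov, indicators=ind, outcomes=out, truth=truth)


def outcome_cohort(config: GeneratorConfig, outcome: str, n: int, seed: int) -> pd.DataFrame:
    """Simulate a validation sample for a single outcome model.

    Statuses are drawn from the covariate-dependent membership model, then the
    requested outcome alone is generated for everybody (no attrition and no
    baseline-prevalence exclusions), giving a sample of exactly ``n`` subjects
    at risk — the situation the per-outcome analysis sees after exclusions.

    ``outcome`` is one of the configured logistic outcomes, ``"mortality"``,
    or ``"srh"``.  Returns covariates + ``status`` + the outcome column(s).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cov = config.covariates.draw(rng, n)
    X = config.covariates.design(cov)
    p1 = config.membership_probabilities(X)
    u = rng.random(n)
    status = (u[:, None] >= p1.cumsum(axis=1)).sum(axis=1)

    df = cov.copy()
    df["status"] = status
    df["status_name"] = pd.Categorical.from_codes(status, list(config.status_names))
    if outcome == "mortality":
        if config.survival is None:
            raise ConfigValidationError("config has no survival model")
        rates = config.survival.rates()[status]
        t = rng.exponential(1.0 / rates)
        horizon = config.survival.horizon
        df["time_years"] = np.minimum(t, horizon)
        df["died"] = (t < horizon).astype(int)
    elif outcome == "srh":
        if config.srh is None:
            raise ConfigValidationError("config has no self-rated-health model")
        exceed = config.srh.exceedance(status, X)
        u = rng.random(n)
        df["srh"] = (u[:, None] < exceed).sum(axis=1)
    else:
        if outcome not in config.outcomes:
            raise ConfigValidationError(f"unknown outcome {outcome!r}; have {sorted(config.outcomes)}")
        model = config.outcomes[outcome]
        df[outcome] = (rng.random(n) < model.event_probability(status, X)).astype(int)
    return df


def expected_transition_fractions(config: GeneratorConfig) -> dict:
    """Truth-implied worsened/stable/improved fractions among wave-2-observed
    subjects (death depends on the baseline status only, so transition rows are
    unchanged among survivors; only the status weights shift)."""
    delta = np.asarray(config.delta)
    tau = np.asarray(config.tau)
    p_obs = np.ones_like(delta)
    if config.survival is not None:
        p_obs = 1.0 - config.survival.death_probabilities()
    w = delta * p_obs  # common dropout factor cancels in the normalisation
    w = w / w.sum()
    ranks = np.arange(len(delta))
    stable = float(np.sum(w * np.diag(tau)))
    worsened = float(sum(w[a] * tau[a, b] for a in ranks for b in ranks if b > a))
    improved = float(sum(w[a] * tau[a, b] for a in ranks for b in ranks if b < a))
    return {"worsened": worsened, "stable": stable, "improved": improved}


# ---------------------------------------------------------------------------
# the frozen replication configuration
# ---------------------------------------------------------------------------

_CALIBRATION_SEED = 19_660_201  # internal, fixed: calibration must not depend on user seeds
_CALIBRATION_N = 150_000


def _calibration_design(covariates: CovariateModel) -> np.ndarray:
    rng = np.random.default_rng(_CALIBRATION_SEED)
    return covariates.design(covariates.draw(rng, _CALIBRATION_N))


def _calibrate_membership_intercepts(slopes: np.ndarray, target: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fixed-point search for intercepts giving covariate-averaged prevalences
    equal to ``target`` (healthiest status is the reference with logit 0)."""
    alpha = np.zeros(len(target) - 1)
    eta_slopes = X @ slopes.T
    for _ in range(200):
        logits = np.zeros((X.shape[0], len(target)))
        logits[:, 1:] = alpha + eta_slopes
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        mean_p = p.mean(axis=0)
        step = np.log(target[1:] / mean_p[1:]) - np.log(target[0] / mean_p[0])
        alpha += step
        if np.abs(step).max() < 1e-12:
            break
    return alpha


def _calibrate_logit_intercept(target: float, eta_covariates: np.ndarray) -> float:
    return brentq(lambda c: expit(c + eta_covariates).mean() - target, -25.0, 25.0, xtol=1e-12)


def paper_replication_config() -> GeneratorConfig:
    """Frozen configuration transcribing the published 10/66 estimates.

    Returns a fresh copy on every call (the calibrated instance is cached
    internally); see :func:`_build_replication_config` for the constants.
    """
    import copy

    return copy.deepcopy(_build_replication_config())


@functools.lru_cache(maxsize=1)
def _build_replication_config() -> GeneratorConfig:
    """Frozen configuration transcribing the published 10/66 estimates.

    Printed values (see docs/methods.md for the full provenance table):

    * baseline prevalences 43/17/22/18% (healthiest first);
    * transition entries: high IC -> low det 0.60, high IC -> high det
      without cognitive impairment 0.06, low det -> high det with cognitive
      impairment 0.27, high det without cog -> low det 0.12, and an identity
      row for high det with cognitive impairment (no escape); no reversion
      into high IC from anywhere;
    * per-status impairment probabilities from the baseline cross-tabulation
      (the single 0.0% cell floored to 0.01 to keep emissions nondegenerate);
    * published conditional effect sizes for incident frailty, dementia and
      disability (adjusted ORs) and mortality (unadjusted HRs);
    * adjusted incident-disability probability 17.7% for high IC;
    * self-rated-health margins: P(very good)=0.16 / P(very bad)~0.00 for
      high IC, 0.07 / 0.05 for high det with cognitive impairment.

    Completions of unprinted constants: the high-det-no-cog transition row
    keeps 0.859 in place and sends 0.021 to the worst status — the single
    free split is set so the truth-implied stable fraction among observed
    subjects equals the published 61%.  Covariate slopes are chosen once to
    mimic the published per-status covariate gradients (older, more female,
    less educated in worse statuses) and are documented in docs/methods.md.
    """
    delta = np.array([0.43, 0.17, 0.22, 0.18])
    rho = (
        # locomotion, nutrition, vision, hearing, cognition, psychological
        (0.140, 0.060, 0.161, 0.050, 0.036, 0.076),  # high IC
        (0.628, 0.018, 0.126, 0.096, 0.142, 0.010),  # low det, locomotion
        (0.413, 0.278, 0.627, 0.333, 0.056, 0.647),  # high det, no cognitive imp.
        (0.516, 0.230, 0.463, 0.300, 0.926, 0.411),  # high det, cognitive imp.
    )
    tau = (
        (0.34, 0.60, 0.06, 0.000),
        (0.00, 0.73, 0.00, 0.270),
        (0.00, 0.12, 0.859, 0.021),
        (0.00, 0.00, 0.00, 1.000),
    )

    covariates = CovariateModel()
    # membership gradients vs high IC on (age_std, female, education level)
    slopes = np.array(
        [
            [0.45, 0.45, -0.55],  # low det: older, somewhat more female, much less educated
            [0.10, 0.90, -0.20],  # high det no cog: similar age, strongly more female
            [1.10, 0.65, -0.45],  # high det cog: much older, more female, less educated
        ]
    )
    X = _calibration_design(covariates)
    intercepts = _calibrate_membership_intercepts(slopes, delta, X)

    # survival: unadjusted hazard-ratio column; baseline rate set so the
    # healthiest status reaches the observed 10.6% mortality by 4.2 years
    horizon = 4.2
    baseline_rate = -np.log(1.0 - 0.106) / horizon
    survival = SurvivalModel(
        baseline_rate=float(baseline_rate),
        hazard_ratios=(1.0, 2.10, 1.61, 4.60),
        horizon=horizon,
        n_published=12_258,
    )

    def _outcome(status_or, cov_logor, p_high_ic, prevalence, n_published):
        m = OutcomeModel(
            status_logor=tuple(float(np.log(r)) for r in status_or),
            covariate_logor=cov_logor,
            prevalence_by_status=prevalence,
            n_published=n_published,
        )
        m.intercept = float(_calibrate_logit_intercept(p_high_ic, X @ np.asarray(cov_logor)))
        return m

    outcomes = {
        # status ORs: (high IC ref, low det, high det no cog, high det cog)
        "frailty": _outcome(
            (1.0, 2.02, 3.37, 3.49),
            (0.35, 0.15, -0.10),
            0.10,  # chosen incidence at high IC; no incidence is published
            (0.048, 0.122, 0.332, 0.343),  # baseline prevalence cross-tab
            8_842,
        ),
        "dementia": _outcome(
            (1.0, 6.10, 2.82, 16.94),
            (0.55, 0.05, -0.15),
            0.04,  # chosen incidence at high IC
            (0.010, 0.040, 0.020, 0.300),  # chosen; concentrated in the cognitive status
            9_215,
        ),
        "disability": _outcome(
            (1.0, 2.07, 2.87, 4.61),
            (0.40, 0.20, -0.12),
            0.177,  # printed adjusted probability for high IC
            (0.135, 0.231, 0.427, 0.592),  # baseline prevalence cross-tab
            7_425,
        ),
    }

    # self-rated health: published margins anchor the extreme categories of
    # the extreme statuses; middle categories interpolated
    category_targets = (
        (0.160, 0.450, 0.320, 0.066, 0.004),  # high IC
        (0.120, 0.380, 0.370, 0.112, 0.018),
        (0.100, 0.330, 0.400, 0.140, 0.030),
        (0.070, 0.270, 0.400, 0.210, 0.050),  # high det with cognitive imp.
    )
    gamma = (0.25, 0.10, -0.08)
    eta_cov = X @ np.asarray(gamma)
    alpha = []
    for probs in category_targets:
        cum = 1.0 - np.cumsum(probs)[:-1]  # P(Y > k), k = 0..3
        alpha.append(tuple(float(_calibrate_logit_intercept(c, eta_cov)) for c in cum))
    srh = SRHModel(
        alpha=tuple(alpha), gamma=gamma, category_targets=category_targets, n_published=14_923
    )

    cfg = GeneratorConfig(
        n_subjects=20_000,
        seed=1066,
        delta=tuple(float(d) for d in delta),
        rho=rho,
        tau=tau,
        membership_intercepts=tuple(float(a) for a in intercepts),
        membership_slopes=tuple(tuple(float(s) for s in row) for row in slopes),
        covariates=covariates,
        outcomes=outcomes,
        survival=survival,
        srh=srh,
        dropout=0.05,
    )
    cfg.validate()
    return cfg
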