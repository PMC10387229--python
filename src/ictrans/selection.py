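"""Status-count selection, canonical severity ordering, transition summaries.

A ladder of status counts is fitted and compared on AIC, BIC and relative
entropy (classification certainty).  BIC is the default selector; the status
count finally used in an analysis may be overridden on clinical grounds,
which is why the report carries the whole ladder.

Statuses are given a canonical order by expected impairment burden
(sum_j rho_aj, ascending), with one domain-specific refinement: among the
two most-burdened ("high deterioration") statuses, the one with the higher
cognition emission probability ranks last/worst — cognitive impairment marks
the status with no escape in the fitted transition structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import DOMAINS
from .lta import FitResult, IndicatorPanel, LTAParams, e_step, fit

__all__ = [
    "SelectionReport",
    "TransitionSummary",
    "select",
    "relative_entropy",
    "order_statuses",
    "severity_ranks",
    "summarise_transitions",
]

COGNITION_IDX = DOMAINS.index("cognition")


@dataclass
class SelectionReport:
    table: pd.DataFrame  # per S: loglik, n_params, AIC, BIC, entropy, converged
    chosen_S: int
    fits: dict = field(default_factory=dict)  # S -> FitResult (successful only)

    def best_fit(self) -> FitResult:
        return self.fits[self.chosen_S]


@dataclass
class TransitionSummary:
    counts: dict  # worsened / stable / improved counts
    fractions: dict  # same, as fractions of both-wave-assigned subjects
    cell_fractions: pd.DataFrame  # modal cross-tab, rows = baseline status
    n: int


def relative_entropy(w1: np.ndarray) -> float:
    """1 - (posterior Shannon entropy) / (n log S); 1 = perfectly crisp
    classification, 0 = uninformative posteriors."""
    n, S = w1.shape
    if S == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(w1 > 0, w1 * np.log(w1), 0.0).sum()
    return float(1.0 - h / (n * np.log(S)))


def select(panel: IndicatorPanel, S_max: int, chosen_S: int | None = None, **fit_opts) -> SelectionReport:
    """Fit S = 1..S_max and tabulate fit indices.

    AIC = -2 l + 2k, BIC = -2 l + k log n.  Failures (degenerate statuses,
    non-convergence) are flagged in the table rather than raised, so the
    ladder always completes.  ``chosen_S`` defaults to the BIC minimiser.
    """
    if S_max < 2:
        raise ValueError("S_max must be >= 2")
    rows = []
    fits = {}
    n = panel.n
    for S in range(1, S_max + 1):
        try:
            fr = fit(panel, S, **fit_opts)
        except Exception as err:  # per-S failure must not sink the ladder
            rows.append({"S": S, "loglik": np.nan, "n_params": np.nan, "AIC": np.nan,
                         "BIC": np.nan, "entropy": np.nan, "converged": False,
                         "failure": f"{type(err).__name__}: {err}"})
            continue
        post = e_step(panel, fr.params)
        k = fr.n_params
        rows.append({
            "S": S,
            "loglik": fr.loglik,
            "n_params": k,
            "AIC": -2 * fr.loglik + 2 * k,
            "BIC": -2 * fr.loglik + k * np.log(n),
            "entropy": relative_entropy(post.w1),
            "converged": fr.converged,
            "failure": "",
        })
        fits[S] = fr
    table = pd.DataFrame(rows)
    if chosen_S is None:
        ok = table.dropna(subset=["BIC"])
        if ok.empty:
            raise RuntimeError("every status count failed to fit:\n" + table.to_string())
        chosen_S = int(ok.loc[ok["BIC"].idxmin(), "S"])
    return SelectionReport(table=table, chosen_S=chosen_S, fits=fits)


def severity_ranks(rho: np.ndarray) -> np.ndarray:
    """Permutation (new order -> old index) sorting statuses from healthiest
    to worst by expected impairment count, with the cognition rule breaking
    the top of the scale."""
    rho = np.asarray(rho)
    burden = rho.sum(axis=1)
    order = np.argsort(burden, kind="stable")
    # cognition rule only applies to panels that carry the cognition domain
    if len(order) >= 2 and rho.shape[1] > COGNITION_IDX:
        a, b = order[-2], order[-1]
        if rho[a, COGNITION_IDX] > rho[b, COGNITION_IDX]:
            order[-2], order[-1] = b, a
    return order


def order_statuses(params: LTAParams) -> LTAParams:
    """Return params relabelled to canonical severity order (idempotent)."""
    return params.permute(severity_ranks(params.rho))


def summarise_transitions(status_w1: np.ndarray, status_w2: np.ndarray,
                          both_observed: np.ndarray | None = None,
                          n_statuses: int | None = None) -> TransitionSummary:
    """Worsened / stable / improved fractions from modal assignments.

    Status codes are severity ranks (0 = healthiest); ``worsened`` means the
    follow-up rank exceeds the baseline rank.  Only subjects with both waves
    assigned (``both_observed``) enter the denominators.
    """
    s1 = np.asarray(status_w1)
    s2 = np.asarray(status_w2)
    if both_observed is not None:
        keep = np.asarray(both_observed, bool)
        s1, s2 = s1[keep], s2[keep]
    n = len(s1)
    if n == 0:
        raise ValueError("no subjects with both waves assigned")
    counts = {
        "worsened": int((s2 > s1).sum()),
        "stable": int((s2 == s1).sum()),
        "improved": int((s2 < s1).sum()),
    }
    fractions = {k: v / n for k, v in counts.items()}
    S = n_statuses if n_statuses is not None else int(max(s1.max(), s2.max())) + 1
    tab = pd.crosstab(pd.Series(s1, name="baseline"), pd.Series(s2, name="follow_up"))
    tab = tab.reindex(index=range(S), columns=range(S), fill_value=0)
    cell = tab.div(tab.sum(axis=1).replace(0, np.nan), axis=0)
    return TransitionSummary(counts=counts, fractions=fractions, cell_fractions=cell, n=n)
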