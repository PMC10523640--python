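"""Descriptive choice models: history logistic regression and leaky integrator.

These models summarize *what* a choice sequence depends on without
committing to a circuit: a logistic regression of the current choice on
signed reward and choice histories (how many past trials matter, and with
what weight), shuffle controls for those coefficients, and a per-option
leaky-integrator value model whose best-fitting timescale tau measures how
far back rewards are integrated.

History coding (signed, per lag j): reward code +1 if odor 0 was chosen and
rewarded j trials back, -1 if odor 1 was chosen and rewarded, 0 if the
choice went unrewarded; choice code +1/-1 for odor 0/1.  The response is 1
when odor 0 is chosen.  Swapping odor labels flips the response and negates
every regressor, so fitted coefficients are invariant to the labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import fit_logistic
from .metrics import choices_only

__all__ = [
    "HistoryFit",
    "LeakyIntegratorFit",
    "build_history_design",
    "fit_choice_regression",
    "shuffle_control",
    "fit_leaky_integrator",
]


@dataclass(frozen=True)
class HistoryFit:
    reward_coefs: np.ndarray  # lag 1..n_back
    choice_coefs: np.ndarray
    bias: float
    deviance: float
    null_deviance: float
    pct_deviance_explained: float
    n_back: int
    n_obs: int
    separation_flag: bool


@dataclass(frozen=True)
class LeakyIntegratorFit:
    tau: float
    beta: float
    bias: float
    profile: pd.DataFrame  # tau -> log-likelihood
    degenerate: bool  # single-odor (or otherwise uninformative) log


def _codes(log: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ch = choices_only(log)
    sign = np.where(ch["odor_id"].values == 0, 1.0, -1.0)
    reward_code = sign * ch["rewarded"].values
    choice_code = sign
    y = (ch["odor_id"].values == 0).astype(float)
    return reward_code, choice_code, y


def build_history_design(log: pd.DataFrame, n_back: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix of lagged reward/choice codes and the response vector.

    Rows with incomplete history (the first ``n_back`` choices) are dropped.
    ``n_back = 0`` yields an empty design (bias-only null model).
    """
    reward_code, choice_code, y = _codes(log)
    n = len(y)
    if n_back < 0:
        raise ValueError("n_back must be >= 0")
    if n_back >= n:
        raise ValueError(f"n_back={n_back} >= number of choices ({n})")
    cols = {}
    for j in range(1, n_back + 1):
        cols[f"reward_{j}"] = reward_code[n_back - j : n - j]
        cols[f"choice_{j}"] = choice_code[n_back - j : n - j]
    X = pd.DataFrame(cols, index=np.arange(n_back, n))
    return X, y[n_back:]


def fit_choice_regression(X: pd.DataFrame, y: np.ndarray, l2: float = 1e-4) -> HistoryFit:
    """Ridge-stabilized logistic MLE of choice on history, vs bias-only null."""
    res = fit_logistic(X.values if len(X.columns) else np.zeros((len(y), 0)), y, l2=l2)
    cols = list(X.columns)
    by_name = dict(zip(cols, res["coef"]))
    rc = np.array([by_name[c] for c in cols if c.startswith("reward_")])
    cc = np.array([by_name[c] for c in cols if c.startswith("choice_")])
    n_back = max(len(rc), len(cc))
    return HistoryFit(
        reward_coefs=rc,
        choice_coefs=cc,
        bias=res["bias"],
        deviance=res["deviance"],
        null_deviance=res["null_deviance"],
        pct_deviance_explained=res["pct_deviance_explained"],
        n_back=n_back,
        n_obs=len(y),
        separation_flag=res["separation_flag"],
    )


def fit_history_model(log: pd.DataFrame, n_back: int, l2: float = 1e-4) -> HistoryFit:
    """Convenience: design + fit in one call."""
    X, y = build_history_design(log, n_back)
    return fit_choice_regression(X, y, l2=l2)


def shuffle_control(
    log: pd.DataFrame,
    n_back: int,
    n_shuffles: int = 200,
    seed: int = 0,
    l2: float = 1e-4,
) -> dict:
    """Null coefficient distribution from within-fly trial permutations.

    Choice rows are permuted jointly (odor and reward travel together), the
    design is rebuilt and refit per shuffle.  This destroys temporal
    dependence while preserving marginal choice bias and reward rate.
    Empirical two-sided p-values use the add-one correction.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    real = fit_history_model(log, n_back, l2=l2)
    real_coefs = np.concatenate([real.reward_coefs, real.choice_coefs])
    ch = choices_only(log)
    null = np.empty((n_shuffles, 2 * n_back))
    for s in range(n_shuffles):
        perm = ch.sample(frac=1.0, random_state=rng.integers(2**31 - 1)).reset_index(drop=True)
        perm["trial_index"] = np.arange(1, len(perm) + 1)
        fit = fit_history_model(perm, n_back, l2=l2)
        null[s] = np.concatenate([fit.reward_coefs, fit.choice_coefs])
    lo = (np.sum(null <= real_coefs, axis=0) + 1) / (n_shuffles + 1)
    hi = (np.sum(null >= real_coefs, axis=0) + 1) / (n_shuffles + 1)
    pvals = np.minimum(1.0, 2 * np.minimum(lo, hi))
    names = [f"reward_{j}" for j in range(1, n_back + 1)] + [
        f"choice_{j}" for j in range(1, n_back + 1)
    ]
    return {
        "real": dict(zip(names, real_coefs)),
        "null": pd.DataFrame(null, columns=names),
        "pvalues": dict(zip(names, pvals)),
        "fit": real,
    }


def _leaky_values(odors: np.ndarray, rewards: np.ndarray, tau: float) -> np.ndarray:
    """Per-option values V(t) *before* choice t; both options decay each trial."""
    n = len(odors)
    v = np.zeros((n, 2))
    cur = np.zeros(2)
    for t in range(n):
        v[t] = cur
        gain = np.zeros(2)
        gain[odors[t]] = rewards[t]
        cur = (1 - 1 / tau) * cur + gain / tau
    return v


def fit_leaky_integrator(
    log: pd.DataFrame, tau_grid=None, l2: float = 1e-4
) -> LeakyIntegratorFit:
    """Profile-likelihood fit of the leaky-integrator timescale.

    For each tau on the grid the per-option values are computed from the
    log's own choice/reward sequence, and the choice rule
    P(odor 0) = logistic(beta * (V_0 - V_1) + bias) is fit by (penalized)
    maximum likelihood; the best tau maximizes the profile log-likelihood.
    """
    if tau_grid is None:
        tau_grid = np.arange(1, 31)
    tau_grid = np.asarray(list(tau_grid), dtype=float)
    if len(tau_grid) == 0:
        raise ValueError("tau grid must be non-empty")
    ch = choices_only(log)
    odors = ch["odor_id"].values
    rewards = ch["rewarded"].values.astype(float)
    y = (odors == 0).astype(float)
    degenerate = len(np.unique(odors)) < 2
    if degenerate:
        profile = pd.DataFrame({"tau": tau_grid, "loglik": np.nan})
        return LeakyIntegratorFit(np.nan, np.nan, np.nan, profile, True)
    rows = []
    best = None
    for tau in tau_grid:
        v = _leaky_values(odors, rewards, tau)
        dv = (v[:, 0] - v[:, 1])[:, None]
        res = fit_logistic(dv, y, l2=l2)
        ll = -res["deviance"] / 2.0
        rows.append({"tau": tau, "loglik": ll})
        if best is None or ll > best[1]:
            best = (tau, ll, res)
    profile = pd.DataFrame(rows)
    tau, _, res = best
    return LeakyIntegratorFit(
        tau=float(tau),
        beta=float(res["coef"][0]),
        bias=float(res["bias"]),
        profile=profile,
        degenerate=False,
    )
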