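"""Inferring the mushroom-body plasticity rule from accept/reject sequences.

Because the candidate plasticity rules are *linear* in their components and
weight changes accumulate additively, the MBON drive at any encounter is a
linear function of history statistics that can be computed from the behavior
log alone.  Writing the per-choice weight update as a combination of four
candidate components -- a constant, a KC (sensory) term, a DAN (reward)
term, and the KC x DAN product (the covariance term once either factor is
mean-subtracted) -- the log-odds of accepting the encountered odor becomes

    logit P(accept at t) = b + sum_k beta_k * X_k(t),

where each regressor accumulates that component over all prior choices.
The constant and DAN components are synapse-unspecific (a drift applies to
every synapse; dopamine is a broadcast signal), so they accumulate over
every prior choice; the KC and product components are carried by the
specific synapses whose KCs were active, so they project onto the currently
encountered odor through the overlap of KC patterns:

    X_const(t) = sum_{c<t} 1
    X_kc(t)    = sum_{c<t} K(c) . P_t / n_active
    X_dan(t)   = sum_{c<t} D(c)
    X_prod(t)  = sum_{c<t} D(c) * (K(c) . P_t) / n_active

with D(c) = R or R - E[R] and K(c) the chosen odor's binary pattern P_c or
its expectation-subtracted version P_c - E[S], depending on the variant;
expectations are recomputed from the observed log itself (timescale tau,
initialized at zero), so the inference is self-contained given behavior.
KC activity enters through the noiseless binary patterns (an analyst does
not observe the fly's KC noise).  With zero overlap an odor's KC and
product regressors change only after choices of that same odor.

Fitting the accept/reject response on these four regressors plus a bias by
logistic regression recovers the generating rule: the variant whose
regressors match the generator explains the most deviance, and under an
expectation-based generator the product (covariance) term carries the
largest coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic
from .agent import KCEnsemble, RULE_VARIANTS
from .metrics import undermatching_mse

__all__ = [
    "RULE_TERMS",
    "RuleFit",
    "VariantComparison",
    "build_rule_regressors",
    "fit_rule_model",
    "compare_variants",
    "coefficient_correlations",
    "matching_vs_fit_regression",
]

RULE_TERMS = ("const", "kc", "dan", "prod")


@dataclass(frozen=True)
class RuleFit:
    """Fitted four-term rule regression for one fly/agent log."""

    variant: str
    coefs: dict  # term -> coefficient
    bias: float
    deviance: float
    null_deviance: float
    pct_deviance_explained: float
    n_obs: int
    separation_flag: bool

    @property
    def largest_term(self) -> str:
        return max(self.coefs, key=lambda k: abs(self.coefs[k]))


@dataclass(frozen=True)
class VariantComparison:
    """All four variants fit to one log, with deviance gaps vs noncov."""

    fits: dict  # variant -> RuleFit
    table: pd.DataFrame  # variant, pct_deviance_explained, delta_vs_noncov

    @property
    def best_variant(self) -> str:
        return self.table.sort_values("pct_deviance_explained").iloc[-1]["variant"]

    def delta(self, variant: str) -> float:
        row = self.table[self.table["variant"] == variant]
        return float(row["delta_vs_noncov"].iloc[0])


def build_rule_regressors(
    log: pd.DataFrame,
    variant: str,
    tau: float = 3.5,
    ensemble: KCEnsemble | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-encounter history regressors for one rule variant.

    Returns ``(X, y)``: X has one row per odor encounter with columns
    :data:`RULE_TERMS`, y is the accept (1) / reject (0) response.  Row t
    depends only on events strictly before t.
    """
    if variant not in RULE_VARIANTS:
        raise ValueError(f"unknown rule variant {variant!r}; use one of {RULE_VARIANTS}")
    if ensemble is None:
        ensemble = KCEnsemble()
    if len(log) == 0:
        raise ValueError("empty trial log")
    n_odors = ensemble.n_odors
    n_active = ensemble.n_active
    patterns = ensemble.patterns

    acc = np.zeros((n_odors, len(RULE_TERMS)))
    e_r = 0.0
    e_s = np.zeros(ensemble.n_kc)
    xs, ys = [], []
    lg = log.sort_values(["trial_index", "encounter_index"])
    for odor, accepted, is_choice, rewarded in zip(
        lg["odor_id"].values.astype(int),
        lg["accepted"].values,
        lg["is_choice"].values,
        lg["rewarded"].values,
    ):
        xs.append(acc[odor].copy())
        ys.append(float(accepted))
        if is_choice:
            r = float(rewarded)
            pat = patterns[odor]
            if variant in ("sensory_exp", "both"):
                k_vec = pat - e_s
            else:
                k_vec = pat
            d_val = r - e_r if variant in ("reward_exp", "both") else r
            # projection of this choice's KC factor onto every odor's pattern
            k_proj = (patterns @ k_vec) / n_active
            acc[:, 0] += 1.0
            acc[:, 1] += k_proj
            acc[:, 2] += d_val
            acc[:, 3] += d_val * k_proj
            e_r = (1 - 1 / tau) * e_r + r / tau
            e_s = (1 - 1 / tau) * e_s + pat / tau
    X = pd.DataFrame(np.array(xs), columns=list(RULE_TERMS))
    return X, np.array(ys)


def fit_rule_model(
    X: pd.DataFrame, y: np.ndarray, variant: str = "", l2: float = 1e-4
) -> RuleFit:
    """Logistic regression of accept/reject on the four rule regressors + bias."""
    if len(y) < 20:
        raise ValueError(f"need >= 20 encounter rows, got {len(y)}")
    if len(np.unique(y)) < 2:
        kind = "accepts" if y[0] else "rejects"
        raise ValueError(
            f"log contains only {kind}; accept/reject regression undefined"
        )
    res = fit_logistic(X.values, y, l2=l2)
    coefs = dict(zip(X.columns, res["coef"]))
    return RuleFit(
        variant=variant,
        coefs=coefs,
        bias=res["bias"],
        deviance=res["deviance"],
        null_deviance=res["null_deviance"],
        pct_deviance_explained=res["pct_deviance_explained"],
        n_obs=len(y),
        separation_flag=res["separation_flag"],
    )


def fit_variant(
    log: pd.DataFrame,
    variant: str,
    tau: float = 3.5,
    ensemble: KCEnsemble | None = None,
    l2: float = 1e-4,
) -> RuleFit:
    """Build regressors for one variant and fit them."""
    X, y = build_rule_regressors(log, variant, tau=tau, ensemble=ensemble)
    return fit_rule_model(X, y, variant=variant, l2=l2)


def compare_variants(
    log: pd.DataFrame,
    tau: float = 3.5,
    ensemble: KCEnsemble | None = None,
    l2: float = 1e-4,
) -> VariantComparison:
    """Fit all four variants to one log; report deviance explained vs noncov."""
    fits = {v: fit_variant(log, v, tau=tau, ensemble=ensemble, l2=l2) for v in RULE_VARIANTS}
    base = fits["noncov"].pct_deviance_explained
    table = pd.DataFrame(
        {
            "variant": list(RULE_VARIANTS),
            "pct_deviance_explained": [fits[v].pct_deviance_explained for v in RULE_VARIANTS],
            "delta_vs_noncov": [fits[v].pct_deviance_explained - base for v in RULE_VARIANTS],
        }
    )
    return VariantComparison(fits=fits, table=table)


def coefficient_correlations(fits: list[RuleFit]) -> pd.DataFrame:
    """Pairwise Pearson correlations of term coefficients across fits."""
    if len(fits) < 3:
        raise ValueError("need >= 3 fits")
    mat = np.array([[f.coefs[t] for t in RULE_TERMS] for f in fits])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(corr, index=list(RULE_TERMS), columns=list(RULE_TERMS))


@dataclass(frozen=True)
class MatchingFitRegression:
    delta_slope: float
    delta_intercept: float
    prod_slope: float
    prod_intercept: float
    n: int
    degenerate: bool  # constant undermatching: slopes undefined


def matching_vs_fit_regression(
    logs,
    comparisons: list[VariantComparison],
    variant: str = "reward_exp",
    window: int = 10,
) -> MatchingFitRegression:
    """OLS of fit-quality gap (and product coefficient) on undermatching.

    Undermatching is the per-log mean squared error between instantaneous
    choice and reward fractions.  On mixed populations (covariance and
    noncov generators pooled) the deviance-gap slope is negative: the worse
    a log matches, the less an expectation-based rule helps.
    """
    if isinstance(logs, pd.DataFrame):
        logs = [logs]
    if len(logs) != len(comparisons):
        raise ValueError("one comparison per log required")
    if len(logs) < 3:
        raise ValueError("need >= 3 points")
    mse = np.array([undermatching_mse(lg, window=window) for lg in logs])
    delta = np.array([c.delta(variant) for c in comparisons])
    prod = np.array([c.fits[variant].coefs["prod"] for c in comparisons])
    if np.ptp(mse) == 0:
        return MatchingFitRegression(np.nan, np.nan, np.nan, np.nan, len(mse), True)
    f1 = stats.linregress(mse, delta)
    f2 = stats.linregress(mse, prod)
    return MatchingFitRegression(
        delta_slope=float(f1.slope),
        delta_intercept=float(f1.intercept),
        prod_slope=float(f2.slope),
        prod_intercept=float(f2.intercept),
        n=len(mse),
        degenerate=False,
    )
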