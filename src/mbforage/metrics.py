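"""Matching-law analytics over trial logs (simulated or experimental).

Herrnstein's matching law says choices are divided between options in
proportion to the rewards obtained from them.  In fraction space (choices to
option 0 over all choices, rewards from option 0 over all rewards) the law
is the identity line, so matching strength is read off the slope of choice
fraction regressed on reward fraction -- slope 1 is matching, slope < 1 is
undermatching, slope 0 a reward-blind chooser.

All metrics operate on the per-encounter trial log produced by
:mod:`mbforage.task`; they use only its choice rows unless noted and orient
fractions toward odor 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchingSummary",
    "choices_only",
    "relabel_odors",
    "instantaneous_fractions",
    "block_matching",
    "undermatching_mse",
    "transition_dynamics",
    "wsls_comparison",
    "history_conditional_probs",
]


def choices_only(log: pd.DataFrame) -> pd.DataFrame:
    """The choice rows of a log, in trial order."""
    if len(log) == 0:
        raise ValueError("empty trial log")
    return log[log["is_choice"]].sort_values("trial_index").reset_index(drop=True)


def relabel_odors(log: pd.DataFrame) -> pd.DataFrame:
    """Swap odor labels 0 <-> 1 (two-odor logs)."""
    out = log.copy()
    out["odor_id"] = 1 - out["odor_id"]
    out.attrs = dict(log.attrs)
    if "block_probs" in out.attrs:
        out.attrs["block_probs"] = [tuple(reversed(p)) for p in out.attrs["block_probs"]]
    return out


def instantaneous_fractions(log: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Trailing-window choice and reward fractions toward odor 0.

    Returns a DataFrame indexed by trial_index with columns ``choice_frac``
    and ``reward_frac``.  The first ``window - 1`` trials are NaN (incomplete
    window), as is the reward fraction wherever the window contains no
    rewards at all.
    """
    ch = choices_only(log)
    if len(ch) < window:
        raise ValueError(f"log has {len(ch)} choices, fewer than window={window}")
    to_a = (ch["odor_id"] == 0).astype(float)
    rew_a = (ch["rewarded"] & (ch["odor_id"] == 0)).astype(float)
    rew = ch["rewarded"].astype(float)
    choice_frac = to_a.rolling(window).mean()
    rew_sum = rew.rolling(window).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        reward_frac = rew_a.rolling(window).sum() / rew_sum
    reward_frac[rew_sum == 0] = np.nan
    return pd.DataFrame(
        {"choice_frac": choice_frac.values, "reward_frac": reward_frac.values},
        index=pd.Index(ch["trial_index"].values, name="trial_index"),
    )


@dataclass(frozen=True)
class MatchingSummary:
    """Pooled per-block fractions and the fitted matching line."""

    blocks: pd.DataFrame  # fly_id, block_index, choice_fraction, reward_fraction
    slope: float
    intercept: float
    rvalue: float
    n_excluded: int  # blocks dropped for having zero rewards


def _per_block_fractions(log: pd.DataFrame) -> pd.DataFrame:
    ch = choices_only(log)
    rows = []
    for (fly, block), g in ch.groupby(["fly_id", "block_index"]):
        n = len(g)
        n_a = int((g["odor_id"] == 0).sum())
        r_tot = int(g["rewarded"].sum())
        r_a = int((g["rewarded"] & (g["odor_id"] == 0)).sum())
        rows.append(
            {
                "fly_id": fly,
                "block_index": block,
                "choice_fraction": n_a / n,
                "reward_fraction": r_a / r_tot if r_tot > 0 else np.nan,
                "n_choices": n,
                "n_rewards": r_tot,
            }
        )
    return pd.DataFrame(rows)


def block_matching(logs) -> MatchingSummary:
    """Block-averaged choice fraction vs reward fraction, OLS across blocks.

    ``logs`` is one log or a list of logs; blocks with zero rewards are
    excluded from the fit (and counted in ``n_excluded``).
    """
    if isinstance(logs, pd.DataFrame):
        logs = [logs]
    blocks = pd.concat([_per_block_fractions(lg) for lg in logs], ignore_index=True)
    ok = blocks.dropna(subset=["reward_fraction"])
    if len(ok) == 0:
        raise ValueError("all blocks are rewardless; matching undefined")
    if len(ok) < 2 or ok["reward_fraction"].nunique() < 2:
        raise ValueError("need >= 2 blocks with distinct reward fractions")
    fit = stats.linregress(ok["reward_fraction"], ok["choice_fraction"])
    return MatchingSummary(
        blocks=blocks,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rvalue=float(fit.rvalue),
        n_excluded=int(len(blocks) - len(ok)),
    )


def undermatching_mse(log: pd.DataFrame, window: int = 10) -> float:
    """Mean squared gap between instantaneous choice and reward fractions."""
    frac = instantaneous_fractions(log, window=window)
    d = (frac["choice_frac"] - frac["reward_frac"]).dropna()
    if len(d) == 0:
        raise ValueError("no overlapping unmasked samples")
    return float(np.mean(d.values**2))


def transition_dynamics(
    logs,
    block_probs=None,
    min_prob_change: float = 0.4,
    window: int = 10,
    pre: int = 20,
    post: int = 40,
) -> pd.DataFrame:
    """Mean choice-fraction trajectory around large block transitions.

    A transition qualifies when the baiting probability of odor 0 changes by
    at least ``min_prob_change``.  Each qualifying transition contributes its
    instantaneous choice fraction on lags ``-pre .. post`` around the first
    trial of the new block, oriented so that the newly richer odor is
    positive; curves are averaged across transitions.

    ``block_probs`` may be one shared schedule (list of per-block probability
    tuples) or omitted, in which case each log's ``attrs['block_probs']`` is
    used.  Returns a DataFrame with columns lag, mean, sem, n (empty, with a
    warning, if nothing qualifies).
    """
    if isinstance(logs, pd.DataFrame):
        logs = [logs]
    curves = []
    for lg in logs:
        probs = block_probs if block_probs is not None else lg.attrs.get("block_probs")
        if probs is None:
            raise ValueError("block probabilities unavailable (pass block_probs)")
        frac = instantaneous_fractions(lg, window=window)["choice_frac"]
        ch = choices_only(lg)
        block_starts = ch.groupby("block_index")["trial_index"].min()
        for k in range(1, len(probs)):
            dp = probs[k][0] - probs[k - 1][0]
            if abs(dp) < min_prob_change:
                continue
            # newly richer odor: relative richness increased for odor 0 iff
            # (p0 - p1) went up.
            rel = (probs[k][0] - probs[k][1]) - (probs[k - 1][0] - probs[k - 1][1])
            t0 = int(block_starts.get(k + 1, -1))
            if t0 < 0:
                continue
            lags = np.arange(-pre, post + 1)
            vals = frac.reindex(t0 + lags).values
            curves.append(vals if rel >= 0 else 1.0 - vals)
    if not curves:
        warnings.warn("no qualifying block transitions found")
        return pd.DataFrame(columns=["lag", "mean", "sem", "n"])
    arr = np.vstack(curves)
    lags = np.arange(-pre, post + 1)
    n = np.sum(~np.isnan(arr), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return pd.DataFrame({"lag": lags, "mean": mean, "sem": sem, "n": n})


def wsls_comparison(log: pd.DataFrame) -> dict:
    """Win-stay/lose-switch prediction vs realized stay/switch behavior.

    Returns the 2x2 joint probability table (rows: WSLS predicts stay/switch;
    columns: animal stayed/switched) and the overall agreement rate.
    """
    ch = choices_only(log)
    if len(ch) < 2:
        raise ValueError("need at least 2 choices")
    prev_rew = ch["rewarded"].values[:-1]
    stayed = ch["odor_id"].values[1:] == ch["odor_id"].values[:-1]
    pred_stay = prev_rew.astype(bool)
    table = np.zeros((2, 2))
    for ps, st in zip(pred_stay, stayed):
        table[0 if ps else 1, 0 if st else 1] += 1
    table /= table.sum()
    agreement = float(table[0, 0] + table[1, 1])
    return {
        "table": pd.DataFrame(
            table,
            index=["pred_stay", "pred_switch"],
            columns=["stayed", "switched"],
        ),
        "agreement": agreement,
        "n": int(len(stayed)),
    }


def history_conditional_probs(logs, pattern) -> dict:
    """P(next choice = each odor | exact trailing (odor, rewarded) pattern).

    ``pattern`` is a sequence of (odor_id, rewarded) pairs, oldest first.
    Probabilities are NaN when the pattern never occurs.
    """
    pattern = [(int(o), bool(r)) for o, r in pattern]
    if len(pattern) < 1:
        raise ValueError("pattern must have length >= 1")
    k = len(pattern)
    counts = {0: 0, 1: 0}
    total = 0
    if isinstance(logs, pd.DataFrame):
        logs = [logs]
    for lg in logs:
        ch = choices_only(lg)
        odors = ch["odor_id"].values
        rews = ch["rewarded"].values.astype(bool)
        for t in range(k, len(ch)):
            window = list(zip(odors[t - k : t], rews[t - k : t]))
            if [(int(o), bool(r)) for o, r in window] == pattern:
                total += 1
                counts[int(odors[t])] = counts.get(int(odors[t]), 0) + 1
    probs = {o: (c / total if total > 0 else np.nan) for o, c in counts.items()}
    return {"probs": probs, "count": total}
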