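"""Mushroom-body-inspired foraging agents and candidate plasticity rules.

The core generative model mirrors the fly mushroom body: each odor drives a
sparse binary pattern of Kenyon cells (KCs); a mushroom body output neuron
(MBON) reads out the KC activity through a plastic weight vector W; MBON
activity m = W . S encodes the tendency to *reject* the encountered odor and
is passed through a sigmoid to give the rejection probability.  Reward is
signalled by dopaminergic-neuron (DAN) activity, which depresses KC->MBON
synapses (learning rate eta < 0), so rewarded odors become harder to reject.

Four candidate reward-dependent plasticity rules are implemented, differing
in whether the sensory and/or reward terms are mean-subtracted by running
expectations:

    noncov       dW_i = eta *  S_i            *  R
    reward_exp   dW_i = eta *  S_i            * (R - E[R])
    sensory_exp  dW_i = eta * (S_i - E[S_i])  *  R
    both         dW_i = eta * (S_i - E[S_i])  * (R - E[R])

Expectations are recency-weighted running averages with timescale tau
(trials): E <- (1 - 1/tau) E + (1/tau) x, updated once per choice.  A rule
with at least one mean-subtracted factor is covariance-based and drives the
choice-conditioned covariance between its factors to zero at steady state,
which is exactly the operant-matching equilibrium; the noncov rule is
unidirectional (weights only depress) and saturates instead.

Plasticity occurs only at choice (acceptance) events; weights are fixed
during rejections and between trials.  Updates apply to all KCs: for the
sensory-expectation rules the (S_i - E[S_i]) factor is negative for cells
silent at the choice, so rewards earned on one odor potentiate the other
odor's synapses -- this bidirectional coupling is what lets those rules
equalize returns across options.

A separate :class:`WTAAgent` implements the original winner-take-all circuit
the mushroom-body model descends from: both option pathways are active every
trial and the choice is the pathway with the larger (noisy) appetitive
output.  In that convention reward potentiates the chosen pathway (internal
rate -eta > 0) and weights are unbounded above; saturation only arises in
the one-odor-at-a-time fly task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import TaskConfig, run_session

__all__ = [
    "KCEnsemble",
    "PlasticityRule",
    "RULE_VARIANTS",
    "MBAgent",
    "WTAAgent",
    "LeakyValueAgent",
    "mbon_activity",
    "p_reject",
    "apply_plasticity",
    "update_expectations",
    "simulate_population",
    "simulate_winner_take_all",
]

RULE_VARIANTS = ("noncov", "reward_exp", "sensory_exp", "both")


@dataclass(frozen=True)
class KCEnsemble:
    """Sparse binary KC odor representations with controlled overlap.

    ``patterns[o]`` is the binary activity vector of odor ``o``; each pattern
    has ``n_active`` active cells and consecutive odors share exactly
    ``round(overlap * n_active)`` of them.  Per-encounter responses add
    Gaussian jitter of sd ``noise_sd`` (clipped at zero, activity is a rate).
    """

    n_kc: int = 100
    active_fraction: float = 0.1
    overlap: float = 0.0
    noise_sd: float = 0.0
    n_odors: int = 2
    patterns: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        n_active = self.n_active
        if self.patterns is None:
            shared = int(round(self.overlap * n_active))
            pats = np.zeros((self.n_odors, self.n_kc), dtype=float)
            # odor o occupies a contiguous span, shifted so consecutive odors
            # share exactly `shared` cells; layout is deterministic.
            for o in range(self.n_odors):
                start = o * (n_active - shared)
                if start + n_active > self.n_kc:
                    raise ValueError("n_kc too small for requested patterns")
                pats[o, start : start + n_active] = 1.0
            object.__setattr__(self, "patterns", pats)
        else:
            object.__setattr__(self, "patterns", np.asarray(self.patterns, dtype=float))

    @property
    def n_active(self) -> int:
        n = int(round(self.n_kc * self.active_fraction))
        if n < 1:
            raise ValueError("active fraction yields no active cells")
        return n

    def response(self, odor_id: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Realized KC activity for one encounter of ``odor_id``."""
        if not (0 <= odor_id < self.n_odors):
            raise ValueError(f"unknown odor id {odor_id!r}")
        s = self.patterns[odor_id].copy()
        if self.noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            s = np.clip(s + rng.normal(0.0, self.noise_sd, size=s.shape), 0.0, None)
        return s

    def overlap_matrix(self) -> np.ndarray:
        """Normalized pattern overlaps: ov[p, q] = P_p . P_q / n_active."""
        return (self.patterns @ self.patterns.T) / self.n_active


@dataclass(frozen=True)
class PlasticityRule:
    """Which rule variant to use, its (negative) learning rate and timescales."""

    variant: str = "both"
    eta: float = -0.3
    tau_r: float = 3.5
    tau_s: float = 3.5

    def __post_init__(self) -> None:
        if self.variant not in RULE_VARIANTS:
            raise ValueError(f"unknown rule variant {self.variant!r}; use one of {RULE_VARIANTS}")
        if self.eta >= 0:
            raise ValueError("eta must be strictly negative (depression-based learning)")
        if self.tau_r < 1 or self.tau_s < 1:
            raise ValueError("expectation timescales must be >= 1 trial")


def mbon_activity(w: np.ndarray, kc: np.ndarray) -> float:
    """MBON output: weighted sum of KC activity."""
    w = np.asarray(w, dtype=float)
    kc = np.asarray(kc, dtype=float)
    if w.shape != kc.shape:
        raise ValueError(f"dimension mismatch: weights {w.shape} vs activity {kc.shape}")
    return float(w @ kc)


def p_reject(m: float, m0: float, s: float) -> float:
    """Sigmoidal rejection probability, midpoint m0 and slope scale s."""
    from scipy.special import expit

    return float(expit((m - m0) / s))


def apply_plasticity(
    w: np.ndarray,
    kc: np.ndarray,
    reward: int,
    rule: PlasticityRule,
    e_r: float,
    e_s: np.ndarray,
    w_max: float,
) -> np.ndarray:
    """One plasticity event at a choice; returns the updated, clipped weights.

    ``e_r``/``e_s`` must be the expectations *before* this event.
    """
    kc = np.asarray(kc, dtype=float)
    if rule.variant in ("sensory_exp", "both"):
        k_term = kc - e_s
    else:
        k_term = kc
    if rule.variant in ("reward_exp", "both"):
        d_term = reward - e_r
    else:
        d_term = float(reward)
    return np.clip(w + rule.eta * k_term * d_term, 0.0, w_max)


def update_expectations(
    e_r: float, e_s: np.ndarray, kc: np.ndarray, reward: int, rule: PlasticityRule
) -> tuple[float, np.ndarray]:
    """Leaky update of the reward and sensory running averages (once per choice)."""
    e_r = (1.0 - 1.0 / rule.tau_r) * e_r + reward / rule.tau_r
    e_s = (1.0 - 1.0 / rule.tau_s) * e_s + np.asarray(kc, dtype=float) / rule.tau_s
    return float(e_r), e_s


class MBAgent:
    """The mushroom-body agent: KC patterns -> plastic weights -> sigmoid reject.

    The sigmoid is calibrated so that (i) a naive agent rejects at exactly
    0.5 (midpoint m0 equals the initial MBON drive w0 * n_active), and (ii)
    the extremes are near-deterministic: p_reject at fully depressed weights
    (m = 0) is at most 0.02 and at the weight ceiling at least 0.98.  The
    slope scale s = m0/30 satisfies both with margin; together with the
    learning rate it is chosen so that preferences re-equilibrate within
    roughly 15-20 trials of a block switch -- the adaptation speed flies
    show -- which is what lets matching be expressed within 80-trial blocks.
    With the alternating encounter loop this calibration also pins the
    noncov rule's asymptote near 75% in a 100:0 schedule: the rewarded
    odor's weights floor (acceptance ~1) while the never-rewarded odor's
    stay at their naive 50%.
    """

    def __init__(
        self,
        rule: PlasticityRule | None = None,
        ensemble: KCEnsemble | None = None,
        w0: float = 1.0,
    ) -> None:
        self.rule = rule if rule is not None else PlasticityRule()
        self.ensemble = ensemble if ensemble is not None else KCEnsemble()
        self.w0 = float(w0)
        self.w = np.full(self.ensemble.n_kc, self.w0, dtype=float)
        self.w_max = 2.0 * self.w0
        self.m0 = self.w0 * self.ensemble.n_active
        self.s = self.m0 / 30.0
        self.e_r = 0.0
        self.e_s = np.zeros(self.ensemble.n_kc, dtype=float)
        self._last_kc: np.ndarray | None = None

    @property
    def rule_name(self) -> str:
        return self.rule.variant

    def p_reject_odor(self, odor_id: int, rng: np.random.Generator | None = None) -> float:
        kc = self.ensemble.response(odor_id, rng)
        return p_reject(mbon_activity(self.w, kc), self.m0, self.s)

    def encounter(self, odor_id: int, rng: np.random.Generator) -> bool:
        """Accept/reject hook; stores the realized KC vector for plasticity."""
        kc = self.ensemble.response(odor_id, rng)
        self._last_kc = kc
        reject = p_reject(mbon_activity(self.w, kc), self.m0, self.s)
        return bool(rng.random() >= reject)

    def observe_choice(self, odor_id: int, reward: int) -> None:
        """Plasticity then expectation update, at the choice event only."""
        kc = self._last_kc
        if kc is None:  # direct-mode or forced path without a stored encounter
            kc = self.ensemble.response(odor_id)
        self.w = apply_plasticity(
            self.w, kc, reward, self.rule, self.e_r, self.e_s, self.w_max
        )
        self.e_r, self.e_s = update_expectations(self.e_r, self.e_s, kc, reward, self.rule)
        self._last_kc = None


class WTAAgent:
    """Original two-pathway winner-take-all circuit (both options always present).

    Each option has a scalar appetitive pathway weight (initial ``w0``,
    bounded in [0, 2 w0] like the mushroom-body synapses).  Both sensory
    inputs are active every trial; the choice is the pathway with the larger
    noisy output w_o + noise.  Because rewards arrive while both inputs are
    on, plasticity is gated by the pathway (postsynaptic) activity -- 1 for
    the winner, 0 for the loser -- which stands in for the sensory factor of
    the configured rule; in this original circuit reward *potentiates* (rate
    -eta > 0).  Under the noncovariance rule both weights are driven to the
    ceiling, the richer option's first, so a session shows a partial,
    transient preference: a choice-vs-reward slope between flat and unity
    rather than the flat line the one-odor-at-a-time readout produces.
    """

    def __init__(
        self,
        rule: PlasticityRule | None = None,
        n_odors: int = 2,
        w0: float = 1.0,
        noise_sd: float = 0.4,
    ) -> None:
        self.rule = rule if rule is not None else PlasticityRule()
        self.n_odors = n_odors
        self.w0 = float(w0)
        self.w = np.full(n_odors, float(w0))
        self.w_max = 2.0 * float(w0)
        self.noise_sd = float(noise_sd)
        self.e_r = 0.0
        self.e_n = np.zeros(n_odors)  # running average of pathway activity

    @property
    def rule_name(self) -> str:
        return f"wta_{self.rule.variant}"

    def choose(self, rng: np.random.Generator) -> int:
        return int(np.argmax(self.w + rng.normal(0.0, self.noise_sd, self.n_odors)))

    def observe_choice(self, odor_id: int, reward: int) -> None:
        n_vec = np.zeros(self.n_odors)
        n_vec[odor_id] = 1.0
        if self.rule.variant in ("sensory_exp", "both"):
            k_term = n_vec - self.e_n
        else:
            k_term = n_vec
        if self.rule.variant in ("reward_exp", "both"):
            d_term = reward - self.e_r
        else:
            d_term = float(reward)
        self.w = np.clip(self.w + (-self.rule.eta) * k_term * d_term, 0.0, self.w_max)
        self.e_r = (1 - 1 / self.rule.tau_r) * self.e_r + reward / self.rule.tau_r
        self.e_n = (1 - 1 / self.rule.tau_s) * self.e_n + n_vec / self.rule.tau_s


class LeakyValueAgent:
    """Value-based chooser with exponentially filtered per-option reward history.

    V_o decays every trial with timescale ``tau`` and integrates the reward
    when option o is chosen; choices are softmax-like:
    P(choose 0) = logistic(beta * (V_0 - V_1) + bias).
    """

    def __init__(self, tau: float = 7.0, beta: float = 5.0, bias: float = 0.0) -> None:
        if tau < 1:
            raise ValueError("tau must be >= 1")
        self.tau = float(tau)
        self.beta = float(beta)
        self.bias = float(bias)
        self.v = np.zeros(2)

    rule_name = "leaky_value"

    def choose(self, rng: np.random.Generator) -> int:
        from scipy.special import expit

        p0 = expit(self.beta * (self.v[0] - self.v[1]) + self.bias)
        return 0 if rng.random() < p0 else 1

    def observe_choice(self, odor_id: int, reward: int) -> None:
        r_vec = np.zeros(2)
        r_vec[odor_id] = float(reward)
        self.v = (1 - 1 / self.tau) * self.v + r_vec / self.tau


def simulate_population(
    config: TaskConfig,
    rule: PlasticityRule,
    ensemble: KCEnsemble | None = None,
    n_flies: int = 1,
    seed: int = 0,
    mode: str = "encounter",
) -> list[pd.DataFrame]:
    """Independent seeded mushroom-body agents run through the same schedule.

    Fly ``i`` (1-based id ``i+1``) uses seed ``seed + i`` for its session,
    so populations are reproducible bit-for-bit.
    """
    logs = []
    for i in range(n_flies):
        agent = MBAgent(rule=rule, ensemble=ensemble)
        logs.append(
            run_session(config, agent, fly_id=i + 1, seed=seed + i, mode=mode)
        )
    return logs


def simulate_winner_take_all(
    config: TaskConfig,
    rule: PlasticityRule,
    n_agents: int = 1,
    seed: int = 0,
    noise_sd: float = 0.4,
) -> list[pd.DataFrame]:
    """Population of winner-take-all agents (direct choice, no encounter loop)."""
    logs = []
    for i in range(n_agents):
        agent = WTAAgent(rule=rule, noise_sd=noise_sd)
        logs.append(
            run_session(config, agent, fly_id=i + 1, seed=seed + i, mode="direct")
        )
    return logs
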