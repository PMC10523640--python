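"""Two-option dynamic-foraging task with baited probabilistic rewards.

The task is a discrete-trial analogue of a fly foraging between two odorized
arms of a Y-maze.  On every trial each odor independently becomes *baited*
with a fixed per-trial probability; a bait, once set, persists until the
animal chooses that odor (resource replenishment and depletion).  The animal
samples odors one at a time in an accept/reject loop: it encounters one odor
(first one drawn uniformly), and either accepts it -- which registers a
choice and harvests any bait -- or rejects it, in which case it encounters
the other odor next.  Baiting probabilities are piecewise constant within
blocks and change across blocks.

The session loop is agent-agnostic: any object exposing an
``encounter(odor_id, rng) -> bool`` hook (accept/reject) and an
``observe_choice(odor_id, reward)`` hook can be run.  Agents that select an
option directly each trial (no accept/reject loop, e.g. winner-take-all
readouts or value-based choosers) instead expose ``choose(rng) -> odor_id``
and are run with ``mode="direct"``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "TaskConfig",
    "BaitState",
    "update_baits",
    "harvest",
    "run_session",
    "random_block_schedule",
    "MATCHING_PROBABILITY_MENU",
    "LOG_COLUMNS",
]

#: Column order of the per-encounter trial log (the package's lingua franca).
LOG_COLUMNS = [
    "fly_id",
    "trial_index",
    "block_index",
    "encounter_index",
    "odor_id",
    "accepted",
    "is_choice",
    "rewarded",
    "forced",
]

#: Baiting-probability pairs used in randomized three-block matching schedules.
MATCHING_PROBABILITY_MENU = ((0.8, 0.2), (0.4, 0.1), (0.2, 0.8), (0.1, 0.4))


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p!r}")


@dataclass(frozen=True)
class Block:
    """One block of trials with fixed per-odor baiting probabilities."""

    n_trials: int
    p: tuple[float, ...]  # one baiting probability per odor

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        for i, pi in enumerate(self.p):
            _check_prob(pi, f"p[{i}]")


@dataclass(frozen=True)
class TaskConfig:
    """Block schedule and global task settings.

    Parameters
    ----------
    blocks
        Ordered, non-empty sequence of :class:`Block`.
    baiting
        If True (default) rewards persist until collected; if False each
        choice is an independent Bernoulli draw with the chosen odor's
        probability.
    n_odors
        Number of odor options (the analytics assume 2).
    seed
        Default seed for sessions run from this config.
    """

    blocks: tuple[Block, ...]
    baiting: bool = True
    n_odors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.blocks) == 0:
            raise ValueError("block list must be non-empty")
        for b in self.blocks:
            if len(b.p) != self.n_odors:
                raise ValueError(
                    f"block has {len(b.p)} probabilities for {self.n_odors} odors"
                )

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def block_probs(self) -> list[tuple[float, ...]]:
        return [b.p for b in self.blocks]

    def to_dict(self) -> dict:
        return {
            "blocks": [[b.n_trials, list(b.p)] for b in self.blocks],
            "baiting": self.baiting,
            "n_odors": self.n_odors,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        blocks = tuple(Block(int(n), tuple(float(x) for x in p)) for n, p in d["blocks"])
        return cls(
            blocks=blocks,
            baiting=bool(d.get("baiting", True)),
            n_odors=int(d.get("n_odors", 2)),
            seed=int(d.get("seed", 0)),
        )


def random_block_schedule(
    rng: np.random.Generator,
    n_blocks: int = 3,
    n_trials: int = 80,
    menu: tuple[tuple[float, float], ...] = MATCHING_PROBABILITY_MENU,
) -> TaskConfig:
    """Draw a randomized matching schedule (consecutive blocks always differ)."""
    probs: list[tuple[float, float]] = []
    while len(probs) < n_blocks:
        pair = menu[rng.integers(len(menu))]
        if probs and pair == probs[-1]:
            continue
        probs.append(pair)
    return TaskConfig(blocks=tuple(Block(n_trials, p) for p in probs))


@dataclass(frozen=True)
class BaitState:
    """Persistent per-odor reward availability."""

    baited: tuple[bool, ...]

    @classmethod
    def empty(cls, n_odors: int = 2) -> "BaitState":
        return cls(baited=(False,) * n_odors)


def update_baits(state: BaitState, probs, rng: np.random.Generator) -> BaitState:
    """Set each currently unbaited odor's bait with its probability.

    Already-baited odors remain baited (baits persist until collected).
    """
    probs = tuple(float(p) for p in probs)
    if len(probs) != len(state.baited):
        raise ValueError("one probability per odor required")
    for i, p in enumerate(probs):
        _check_prob(p, f"p[{i}]")
    new = tuple(
        True if b else bool(rng.random() < p) for b, p in zip(state.baited, probs)
    )
    return BaitState(baited=new)


def harvest(state: BaitState, chosen_odor: int) -> tuple[int, BaitState]:
    """Collect the chosen odor's bait: reward 1 iff baited, then clear it."""
    if not (0 <= chosen_odor < len(state.baited)):
        raise ValueError(f"unknown odor id {chosen_odor!r}")
    reward = int(state.baited[chosen_odor])
    new = tuple(
        False if i == chosen_odor else b for i, b in enumerate(state.baited)
    )
    return reward, BaitState(baited=new)


def run_session(
    config: TaskConfig,
    agent,
    *,
    fly_id: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "encounter",
    max_encounters: int = 100,
) -> pd.DataFrame:
    """Couple an agent to the task and return its per-encounter trial log.

    Each trial: both odors' baits update once at the start of the trial; then
    the encounter loop runs to a choice (``mode="encounter"``: first odor
    uniform, rejection leads deterministically to the other odor, with a
    safety cap of ``max_encounters`` after which acceptance is forced and the
    row flagged ``forced``), or the agent picks an odor outright
    (``mode="direct"``).  The chosen odor's bait is harvested and the agent's
    post-choice hook is called with the realized reward.

    Returns a DataFrame with columns :data:`LOG_COLUMNS`; session metadata
    (seed, config hash, block probabilities, rule name if the agent exposes
    one) is stored in ``df.attrs``.
    """
    if mode not in ("encounter", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)

    state = BaitState.empty(config.n_odors)
    rows: list[tuple] = []
    trial = 0
    for block_index, block in enumerate(config.blocks, start=1):
        for _ in range(block.n_trials):
            trial += 1
            state = update_baits(state, block.p, rng)
            if mode == "direct":
                odor = int(agent.choose(rng))
                if not (0 <= odor < config.n_odors):
                    raise ValueError(f"agent chose unknown odor {odor!r}")
                if config.baiting:
                    reward, state = harvest(state, odor)
                else:
                    reward = int(rng.random() < block.p[odor])
                    _, state = harvest(state, odor)  # keep bait state consistent
                rows.append((fly_id, trial, block_index, 1, odor, True, True, bool(reward), False))
                agent.observe_choice(odor, reward)
                continue

            odor = int(rng.integers(config.n_odors))
            for enc in range(1, max_encounters + 1):
                forced = enc == max_encounters
                accepted = True if forced else bool(agent.encounter(odor, rng))
                if accepted:
                    if config.baiting:
                        reward, state = harvest(state, odor)
                    else:
                        reward = int(rng.random() < block.p[odor])
                        _, state = harvest(state, odor)
                    rows.append(
                        (fly_id, trial, block_index, enc, odor, True, True, bool(reward), forced)
                    )
                    agent.observe_choice(odor, reward)
                    break
                rows.append(
                    (fly_id, trial, block_index, enc, odor, False, False, False, False)
                )
                odor = (odor + 1) % config.n_odors

    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    log = log.astype(
        {
            "fly_id": "int64",
            "trial_index": "int64",
            "block_index": "int64",
            "encounter_index": "int64",
            "odor_id": "int64",
            "accepted": "bool",
            "is_choice": "bool",
            "rewarded": "bool",
            "forced": "bool",
        }
    )
    log.attrs["config_hash"] = config.config_hash()
    log.attrs["seed"] = seed if seed is not None else config.seed
    log.attrs["block_probs"] = config.block_probs
    log.attrs["block_lengths"] = [b.n_trials for b in config.blocks]
    log.attrs["rule"] = getattr(agent, "rule_name", type(agent).__name__)
    return log
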