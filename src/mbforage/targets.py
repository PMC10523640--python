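"""End-to-end reproduction targets: simulate, measure, report.

Each target runs a full pipeline -- seeded agent populations through the
task, then the matching analytics -- and returns the headline number:

t1  matching slope of the full covariance rule ([S-E(S)][R-E(R)]) on
    randomized three-block schedules (expected ~1, the matching law);
t2  noncovariance-rule asymptotic preference in the 100:0 protocol,
    percent choices toward the rewarded odor over the last 20 training
    trials (expected ~75%: the rewarded odor's synapses saturate while the
    never-rewarded odor keeps its naive 50% acceptance);
t3  same for the 80:20 protocol (expected ~50%: both odors' synapses
    saturate);
t4  matching slope of the noncovariance rule on the three-block task
    (expected near-flat, well below 1).
"""

from __future__ import annotations

import numpy as np

from .agent import MBAgent, PlasticityRule
from .metrics import block_matching, choices_only
from .task import Block, TaskConfig, random_block_schedule, run_session

__all__ = ["TARGETS", "compute_target", "compute_all"]


def _matching_slope(variant: str, seed: int, n_agents: int) -> tuple[float, int]:
    logs = []
    for i in range(n_agents):
        rng = np.random.default_rng(seed + i)
        config = random_block_schedule(rng)
        agent = MBAgent(rule=PlasticityRule(variant=variant))
        logs.append(run_session(config, agent, fly_id=i + 1, rng=rng))
    summary = block_matching(logs)
    return summary.slope, len(summary.blocks) - summary.n_excluded


def _noncov_plateau(p_pair: tuple[float, float], seed: int, n_agents: int) -> tuple[float, int]:
    config = TaskConfig(blocks=(Block(60, (0.0, 0.0)), Block(60, p_pair)))
    fracs = []
    for i in range(n_agents):
        agent = MBAgent(rule=PlasticityRule(variant="noncov"))
        log = run_session(config, agent, fly_id=i + 1, seed=seed + i)
        ch = choices_only(log)
        late = ch[(ch["trial_index"] >= 101) & (ch["trial_index"] <= 120)]
        fracs.append(float((late["odor_id"] == 0).mean()))
    return 100.0 * float(np.mean(fracs)), n_agents


def target_t1(seed: int = 1, n_agents: int = 50) -> dict:
    value, n = _matching_slope("both", seed, n_agents)
    return {"value": value, "n": n}


def target_t2(seed: int = 1, n_agents: int = 50) -> dict:
    value, n = _noncov_plateau((1.0, 0.0), seed, n_agents)
    return {"value": value, "n": n}


def target_t3(seed: int = 1, n_agents: int = 50) -> dict:
    value, n = _noncov_plateau((0.8, 0.2), seed, n_agents)
    return {"value": value, "n": n}


def target_t4(seed: int = 1, n_agents: int = 50) -> dict:
    value, n = _matching_slope("noncov", seed, n_agents)
    return {"value": value, "n": n}


#: id -> (function, human-readable claim, expected value, tolerance note)
TARGETS = {
    "t1": (target_t1, "covariance-rule matching slope", 1.0, "+/- 0.1"),
    "t2": (target_t2, "noncov 100:0 plateau (%)", 75.0, "+/- 5"),
    "t3": (target_t3, "noncov 80:20 plateau (%)", 50.0, "+/- 5"),
    "t4": (target_t4, "noncov matching slope", 0.3, "below"),
}


def compute_target(target_id: str, seed: int = 1, n_agents: int = 50) -> dict:
    if target_id not in TARGETS:
        raise ValueError(f"unknown target id {target_id!r}; known: {sorted(TARGETS)}")
    fn = TARGETS[target_id][0]
    return fn(seed=seed, n_agents=n_agents)


def compute_all(seed: int = 1, n_agents: int = 50) -> dict:
    return {tid: compute_target(tid, seed=seed, n_agents=n_agents) for tid in TARGETS}
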