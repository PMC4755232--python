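"""Discrete conformational / protonation-state switching.

A flexible solute carries an ordered list of rigid conformations (e.g.
structures along a normal mode, or protonation states at different pH).  At
scheduled times a trial move to another conformation is proposed and
accepted by one of three criteria: always, downhill (accept iff the
interaction energy does not increase), or Metropolis (uphill moves accepted
with probability exp(-(dG1-dG0)/kT)).  A swap changes only which
conformation is active — position and orientation are untouched, so
conformers must be pre-aligned in a common body frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import kt
from .model import SwitchSchedule

__all__ = [
    "SwitchProposal",
    "next_switch_time",
    "propose_conformation",
    "accept_switch",
    "simulate_state_occupancy",
]


@dataclass
class SwitchProposal:
    solute_id: int
    current_index: int
    proposed_index: int
    dg0: float  # interaction energy in the current conformation, kcal/mol
    dg1: float  # interaction energy in the proposed conformation, kcal/mol

    def __post_init__(self):
        if self.proposed_index == self.current_index:
            raise ValueError("proposed conformation equals the current one")


def next_switch_time(schedule: SwitchSchedule, now: float, rng: np.random.Generator, dt: float = 0.0) -> float:
    """Time of the next trial move.

    Fixed mode adds the mean interval; normal mode draws the interval from
    Normal(mean, sd), floored at one BD step so it can never be in the past.
    """
    if schedule.mode == "fixed":
        return now + schedule.mean_interval
    draw = rng.normal(schedule.mean_interval, schedule.sd_interval)
    return now + max(dt, draw)


def propose_conformation(nearest: bool, current: int, n_conf: int, rng: np.random.Generator) -> int:
    """Propose a trial conformation index.

    ``nearest`` restricts moves to list neighbours (endpoints have a single
    neighbour, which biases their sampling — a documented property of
    adjacency proposals); otherwise the proposal is uniform over all other
    conformations.
    """
    if n_conf < 2:
        raise ValueError("need at least two conformations to switch")
    if not (0 <= current < n_conf):
        raise ValueError("current index out of range")
    if nearest:
        options = [i for i in (current - 1, current + 1) if 0 <= i < n_conf]
        return int(options[rng.integers(len(options))])
    j = int(rng.integers(n_conf - 1))
    return j if j < current else j + 1


def accept_switch(
    criterion: str,
    proposal: SwitchProposal,
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Apply one of the three acceptance criteria to a trial switch."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if criterion == "always":
        return True
    if criterion == "downhill":
        return proposal.dg1 <= proposal.dg0
    if criterion == "metropolis":
        if proposal.dg1 <= proposal.dg0:
            return True
        return bool(rng.random() < np.exp((proposal.dg0 - proposal.dg1) / kt(temperature)))
    raise ValueError(f"unknown acceptance criterion {criterion!r}")


def simulate_state_occupancy(
    state_energies: Sequence[float],
    criterion: str,
    temperature: float,
    n_attempts: int,
    rng: np.random.Generator,
    nearest: bool = False,
    start_index: int = 0,
) -> np.ndarray:
    """Markov chain of conformational switches in a fixed external field.

    The solute's interaction energy depends only on its state (the
    surroundings are static), so this isolates the acceptance statistics:
    with random proposals and the Metropolis criterion the visit counts
    converge to Boltzmann weights; with the downhill criterion the chain
    absorbs into the lowest-energy state.  Returns per-state visit counts
    over ``n_attempts`` trial moves.
    """
    energies = np.asarray(state_energies, dtype=float)
    n_conf = len(energies)
    counts = np.zeros(n_conf, dtype=np.int64)
    current = start_index
    for _ in range(n_attempts):
        proposed = propose_conformation(nearest, current, n_conf, rng)
        prop = SwitchProposal(0, current, proposed, float(energies[current]), float(energies[proposed]))
        if accept_switch(criterion, prop, temperature, rng):
            current = proposed
        counts[current] += 1
    return counts
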