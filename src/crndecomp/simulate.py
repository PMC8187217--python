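"""Exact stochastic simulation (Gillespie SSA) and empirical stationary
distributions.

One named pseudo-random generator is seeded from the trajectory config;
reaction selection is cumulative-sum inversion in reaction-file order, so a
fixed seed gives a bit-identical event list.  The stationary estimate is the
time-weighted occupancy (π is the CTMC's stationary law, so holding times
matter, not event counts).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ClosureError, ValidationError
from .kinetics import KineticsSpec
from .network import ReactionNetwork
from .statespace import IrreducibleComponent, StochasticSystem
from .stationary import StationaryDistribution

__all__ = ["TrajectoryConfig", "Trajectory", "ssa_trajectory", "empirical_stationary"]


@dataclass(frozen=True)
class TrajectoryConfig:
    initial_state: tuple
    t_end: Optional[float] = None
    max_events: Optional[int] = None
    burn_in: float = 0.2
    seed: int = 0
    sampling: str = "time_average"  # or "fixed_interval"
    sample_interval: float = 1.0

    def __post_init__(self):
        if self.t_end is None and self.max_events is None:
            raise ValidationError("need t_end or max_events")
        if not (0.0 <= self.burn_in < 1.0):
            raise ValidationError("burn-in fraction must be in [0, 1)")
        if self.sampling not in ("time_average", "fixed_interval"):
            raise ValidationError(f"unknown sampling mode {self.sampling!r}")


@dataclass
class Trajectory:
    times: list[float]        # jump times; times[0] == 0.0 is the start
    states: list[tuple]       # states[i] holds on [times[i], times[i+1])
    t_final: float            # end of the observation window
    absorbed: bool            # no active reactions at the last state

    def __len__(self) -> int:
        return len(self.states)


def ssa_trajectory(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    config: TrajectoryConfig,
) -> Trajectory:
    """Exact SSA: exponential waiting times with the total intensity,
    reaction drawn proportionally to its intensity.

    Terminates at ``t_end``, ``max_events``, or absorption (a state with no
    active reactions — a normal termination, reported on the trajectory).
    """
    system = StochasticSystem(network, kinetics)
    rng = np.random.default_rng(config.seed)
    jumps = system.jumps
    state = tuple(int(v) for v in config.initial_state)
    if len(state) != network.n_species or any(v < 0 for v in state):
        raise ValidationError(f"invalid initial state {state}")
    t = 0.0
    times = [0.0]
    states = [state]
    events = 0
    absorbed = False
    while True:
        if config.max_events is not None and events >= config.max_events:
            break
        props = system.propensities(state)
        total = math.fsum(props)
        if total <= 0.0:
            absorbed = True
            break
        wait = rng.exponential(1.0 / total)
        if config.t_end is not None and t + wait > config.t_end:
            t = config.t_end
            break
        t += wait
        pick = rng.random() * total
        acc = 0.0
        chosen = len(props) - 1
        for i, p in enumerate(props):
            acc += p
            if pick < acc:
                chosen = i
                break
        state = tuple(v + j for v, j in zip(state, jumps[chosen]))
        times.append(t)
        states.append(state)
        events += 1
    t_final = t if config.t_end is None else (config.t_end if not absorbed else t)
    if config.t_end is None:
        t_final = times[-1]
    return Trajectory(times=times, states=states, t_final=t_final, absorbed=absorbed)


def empirical_stationary(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    config: TrajectoryConfig,
    component: IrreducibleComponent,
) -> tuple[StationaryDistribution, dict]:
    """Time-weighted occupancy estimate of π on a finite closed component.

    The first ``burn_in`` fraction of the observation window is discarded.
    Per-state standard errors are binomial-style, p(1−p)/ESS with the number
    of post-burn-in jumps as a (crude) effective sample size.  Leaving the
    component signals a closure bug and raises.
    """
    if not component.closed or component.truncated:
        raise ClosureError("empirical estimate needs a finite closed component")
    if tuple(config.initial_state) not in component:
        raise ValidationError("trajectory must start inside the component")
    trajectory = ssa_trajectory(network, kinetics, config)
    index = component.index()
    weights = np.zeros(len(component.states))
    t_burn = config.burn_in * trajectory.t_final
    n_events = 0
    times, states = trajectory.times, trajectory.states
    for i, state in enumerate(states):
        start = times[i]
        end = times[i + 1] if i + 1 < len(times) else trajectory.t_final
        if state not in index:
            raise ClosureError(f"trajectory left the component at {state}")
        lo = max(start, t_burn)
        if end > lo:
            weights[index[state]] += end - lo
            if start >= t_burn and i > 0:
                n_events += 1
    total = weights.sum()
    if total <= 0.0:
        # single absorbed state and zero observation window
        weights[index[states[-1]]] = 1.0
        total = 1.0
    probs = weights / total
    ess = max(n_events, 1)
    errors = np.sqrt(probs * (1.0 - probs) / ess)
    dist = StationaryDistribution(component=component, probs=probs)
    info = {
        "n_events": len(states) - 1,
        "effective_events": n_events,
        "t_final": trajectory.t_final,
        "absorbed": trajectory.absorbed,
        "standard_errors": errors,
    }
    return dist, info
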