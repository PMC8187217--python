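"""CTMC semantics: intensities, reachability, irreducible components,
essentiality and projections.

States are immutable integer tuples in the network's species order.
Accessibility on a potentially unbounded lattice is semidecidable, so every
exploration runs under a per-species cap; for conservative networks the cap
is derived from the conservation value (which makes the exploration exact),
otherwise a margin above the seed is used and truncation is reported rather
than guessed away.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .config import DEFAULT, Settings
from .errors import ValidationError
from .kinetics import KineticsSpec
from .network import ReactionNetwork, Reaction, conservation_vector

__all__ = [
    "State",
    "StochasticSystem",
    "IrreducibleComponent",
    "intensity",
    "successors",
    "reachable_set",
    "irreducible_component",
    "is_essential",
    "accessible",
    "default_bound",
    "project_states",
]

State = tuple  # tuple[int, ...] in species order


class StochasticSystem:
    """Cached propensity/successor evaluator for one (network, kinetics) pair."""

    def __init__(self, network: ReactionNetwork, kinetics: KineticsSpec | None = None):
        self.network = network
        self.kinetics = kinetics or KineticsSpec()
        species = network.species
        self._thetas = [self.kinetics.theta(s) for s in species]
        self._reactants: list[list[tuple[int, int]]] = []  # (species idx, count)
        self._jumps: list[tuple[int, ...]] = []
        for r in network.reactions:
            self._reactants.append(
                [(i, r.reactant.get(s)) for i, s in enumerate(species) if r.reactant.get(s)]
            )
            self._jumps.append(r.jump(species))
        self._mass_action = all(t.is_mass_action for t in self._thetas)

    @property
    def jumps(self) -> list[tuple[int, ...]]:
        return list(self._jumps)

    def propensity(self, r_index: int, x: Sequence[int]) -> float:
        """λ_{ν→ν'}(x) = κ ∏_i ∏_{j<ν_i} θ_i(x_i − j)."""
        lam = self.network.reactions[r_index].rate
        if self._mass_action:
            for i, count in self._reactants[r_index]:
                xi = x[i]
                if xi < count:
                    return 0.0
                for j in range(count):
                    lam *= xi - j
            return lam
        for i, count in self._reactants[r_index]:
            theta = self._thetas[i]
            xi = x[i]
            for j in range(count):
                value = theta(xi - j)
                if value == 0.0:
                    return 0.0
                lam *= value
        return lam

    def propensities(self, x: Sequence[int]) -> list[float]:
        return [self.propensity(i, x) for i in range(len(self._jumps))]

    def successors(self, x: Sequence[int]) -> dict[tuple, float]:
        """Aggregate positive rates by jump vector ξ = ν' − ν."""
        agg: dict[tuple, float] = {}
        for i, jump in enumerate(self._jumps):
            lam = self.propensity(i, x)
            if lam > 0.0:
                target = tuple(a + b for a, b in zip(x, jump))
                agg[target] = agg.get(target, 0.0) + lam
        return agg


def intensity(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    reaction: Reaction | int,
    x: Sequence[int],
) -> float:
    """Transition intensity of one reaction at state *x*."""
    system = StochasticSystem(network, kinetics)
    if isinstance(reaction, Reaction):
        reaction = network.reactions.index(reaction)
    return system.propensity(reaction, tuple(x))


def successors(
    network: ReactionNetwork, kinetics: KineticsSpec | None, x: Sequence[int]
) -> dict[tuple, float]:
    """Positive-rate one-step transitions from *x*, aggregated by jump vector."""
    return StochasticSystem(network, kinetics).successors(tuple(x))


def _normalize_bound(
    network: ReactionNetwork, bound: int | Sequence[int] | None, x0: Sequence[int],
    margin: int,
) -> tuple[int, ...]:
    if bound is None:
        return default_bound(network, x0, margin=margin)
    if isinstance(bound, (int, np.integer)):
        bound = [int(bound)] * network.n_species
    bound = tuple(int(b) for b in bound)
    if len(bound) != network.n_species:
        raise ValidationError("bound length must match species count")
    if any(b < int(v) for b, v in zip(bound, x0)):
        raise ValidationError("bound must dominate the seed state componentwise")
    return bound


def default_bound(
    network: ReactionNetwork, x0: Sequence[int], margin: int | None = None
) -> tuple[int, ...]:
    """Per-species exploration cap.

    Conservative network: the reachable set from x0 satisfies ⟨c, x⟩ =
    ⟨c, x0⟩, hence x_i ≤ ⟨c, x0⟩ / c_i exactly.  Otherwise: the seed's
    largest coordinate plus a margin (default from settings), an honest
    heuristic that triggers ``truncated`` reporting rather than wrong answers.
    """
    margin = DEFAULT.bound_margin if margin is None else margin
    c = conservation_vector(network)
    if c is not None and network.n_species:
        total = sum(ci * int(v) for ci, v in zip(c, x0))
        return tuple(int(total / ci) for ci in c)
    top = max([int(v) for v in x0], default=0) + margin
    return tuple(top for _ in range(network.n_species))


def reachable_set(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    x0: Sequence[int],
    bound: int | Sequence[int] | None = None,
    *,
    settings: Settings = DEFAULT,
) -> tuple[frozenset, bool]:
    """Breadth-first closure of x0 under positive-rate jumps, capped per species.

    Returns ``(states, truncated)``; ``truncated`` is True iff at least one
    positive-rate jump out of the cap was suppressed.
    """
    x0 = tuple(int(v) for v in x0)
    cap = _normalize_bound(network, bound, x0, settings.bound_margin)
    system = StochasticSystem(network, kinetics)
    seen = {x0}
    frontier = [x0]
    truncated = False
    while frontier:
        state = frontier.pop()
        for target in system.successors(state):
            if any(v > b for v, b in zip(target, cap)):
                truncated = True
                continue
            if target not in seen:
                if len(seen) >= settings.max_states:
                    truncated = True
                    continue
                seen.add(target)
                frontier.append(target)
    return frozenset(seen), truncated


@dataclass(frozen=True)
class IrreducibleComponent:
    """A finite (or truncated) forward-closed set of states.

    ``closed`` means every one-step successor stays inside and all states are
    mutually accessible; when ``truncated`` the closure verdict only holds
    within the exploration bound.
    """

    species: tuple[str, ...]
    states: tuple[tuple, ...]
    closed: bool
    truncated: bool
    seed_state: tuple

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(sorted(self.states)))

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, state) -> bool:
        return tuple(state) in self.index()

    def index(self) -> dict:
        cached = self.__dict__.get("_index")
        if cached is None:
            cached = {state: i for i, state in enumerate(self.states)}
            self.__dict__["_index"] = cached
        return cached

    def species_range(self, name: str) -> tuple[int, int]:
        i = self.species.index(name)
        values = [state[i] for state in self.states]
        return min(values), max(values)

    def to_json(self) -> dict:
        return {
            "species": list(self.species),
            "states": [list(state) for state in self.states],
            "closed": self.closed,
            "truncated": self.truncated,
            "seed_state": list(self.seed_state),
        }


def irreducible_component(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    x0: Sequence[int],
    bound: int | Sequence[int] | None = None,
    *,
    settings: Settings = DEFAULT,
) -> IrreducibleComponent:
    """Forward-reachable set from x0 with an exact mutual-accessibility check.

    The component is ``closed`` iff the reachable graph is one strongly
    connected class (then every state reaches every other and nothing
    escapes); with ``truncated`` the verdict is relative to the bound.
    """
    states, truncated = reachable_set(
        network, kinetics, x0, bound, settings=settings
    )
    system = StochasticSystem(network, kinetics)
    graph = nx.DiGraph()
    graph.add_nodes_from(states)
    for state in states:
        for target in system.successors(state):
            if target in states:
                graph.add_edge(state, target)
    closed = nx.number_strongly_connected_components(graph) == 1
    return IrreducibleComponent(
        species=network.species,
        states=tuple(states),
        closed=closed,
        truncated=truncated,
        seed_state=tuple(int(v) for v in x0),
    )


def _species_groups(network: ReactionNetwork) -> list[list[int]]:
    """Reaction indices grouped by connectivity of the species they touch.

    Reactions in different groups share no species, so the dynamics is a
    product of independent chains and accessibility factorizes.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(network.reactions)))
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(network.reactions):
        for s in r.reactant.species() | r.product.species():
            by_species.setdefault(s, []).append(i)
    for members in by_species.values():
        for j in members[1:]:
            graph.add_edge(members[0], j)
    return [sorted(part) for part in nx.connected_components(graph)]


def accessible(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    source: Sequence[int],
    target: Sequence[int],
    bound: int | Sequence[int] | None = None,
    *,
    settings: Settings = DEFAULT,
) -> str:
    """Is *target* accessible from *source*?  ``"yes"``/``"no"``/``"inconclusive"``.

    ``"no"`` is only returned when the exploration exhausted without
    truncation; a truncated search that misses the target is inconclusive.
    Species-disjoint reaction groups evolve independently, so the query is
    split across them first (and species no reaction touches must agree).
    """
    source = tuple(int(v) for v in source)
    target = tuple(int(v) for v in target)
    if source == target:
        return "yes"
    groups = _species_groups(network)
    if len(groups) > 1 and bound is None:
        touched: set[str] = set()
        for r in network.reactions:
            touched |= r.reactant.species() | r.product.species()
        for i, s in enumerate(network.species):
            if s not in touched and source[i] != target[i]:
                return "no"
        verdict = "yes"
        for group in groups:
            sub = network.subnetwork(group)
            idx = [network.species.index(s) for s in sub.species]
            part = accessible(
                sub,
                kinetics,
                tuple(source[i] for i in idx),
                tuple(target[i] for i in idx),
                settings=settings,
            )
            if part == "no":
                return "no"
            if part == "inconclusive":
                verdict = "inconclusive"
        return verdict
    cap = _normalize_bound(network, bound, source, settings.bound_margin)
    if any(v > b for v, b in zip(target, cap)):
        # target outside the cap: can never be *found*, only inconclusive
        pass
    system = StochasticSystem(network, kinetics)
    seen = {source}
    frontier = [source]
    truncated = False
    while frontier:
        state = frontier.pop()
        for nxt in system.successors(state):
            if nxt == target:
                return "yes"
            if any(v > b for v, b in zip(nxt, cap)):
                truncated = True
                continue
            if nxt not in seen:
                if len(seen) >= settings.max_states:
                    truncated = True
                    continue
                seen.add(nxt)
                frontier.append(nxt)
    return "inconclusive" if truncated else "no"


def is_essential(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None = None,
    bound: int | Sequence[int] | None = None,
    *,
    settings: Settings = DEFAULT,
) -> str:
    """``"essential"``, ``"not_essential"`` or ``"inconclusive"``.

    Uses the accessibility characterization: the network is essential iff for
    every reaction ν → ν' the reactant ν (as a state) is accessible from the
    product ν'.  Reversible and weakly reversible networks short-circuit to
    essential.  A truncated, unresolved accessibility test yields
    ``"inconclusive"`` unless some other reaction already failed definitely.
    """
    from .network import reversibility_class

    if not network.reactions:
        return "essential"
    if reversibility_class(network) in ("reversible", "weakly_reversible"):
        return "essential"
    saw_inconclusive = False
    for r in network.reactions:
        source = tuple(r.product.get(s) for s in network.species)
        target = tuple(r.reactant.get(s) for s in network.species)
        verdict = accessible(network, kinetics, source, target, bound, settings=settings)
        if verdict == "no":
            return "not_essential"
        if verdict == "inconclusive":
            saw_inconclusive = True
    return "inconclusive" if saw_inconclusive else "essential"


def project_states(
    states: Iterable[Sequence[int]],
    species: Sequence[str],
    subset: Sequence[str],
) -> frozenset:
    """Coordinate projection of a state set onto an ordered species subset."""
    unknown = [s for s in subset if s not in species]
    if unknown:
        raise ValidationError(f"unknown species in projection: {unknown}")
    idx = [species.index(s) for s in subset]
    return frozenset(tuple(state[i] for i in idx) for state in states)
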