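"""Decomposition of reaction networks and assembly of product-form
stationary distributions from the parts.

The pipeline: enumerate reaction-disjoint bipartitions, keep those whose
parts are essential (then projections of irreducible components of the join
are unions of irreducible components of the parts), solve each part with a
registered closed-form solver (complex-balanced Poisson, the two-species
birth–death motif family, or a direct solve plus factorization for small
conservative parts), match the shared-species product-form functions up to
the free exponential tilts that conservation laws allow, and assemble
π(x) ∝ ∏_i f_i(x_i) over the joint component.  A successful assembly is
verified against generalized balance with the per-part partition; a failed
proportionality match is a refusal, not an approximation.

Only reaction-disjoint decompositions are searched: the space of
decompositions that glue over shared reactions is uncountable (the union
constructor supports them, the search does not).
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import DEFAULT, Settings
from .errors import RefusalError, UndecomposableError, ValidationError
from .kinetics import KineticsSpec
from .network import (
    ReactionNetwork,
    conservation_vector,
    reversibility_class,
)
from .statespace import (
    IrreducibleComponent,
    StochasticSystem,
    is_essential,
)
from .stationary import (
    BalancePartition,
    ProductFormFunction,
    StationaryDistribution,
    check_generalized_balance,
    explicit_from_product,
    factorize_components,
    ratio_test_summability,
    solve_master_direct,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Decomposition",
    "PartSolution",
    "enumerate_reaction_bipartitions",
    "essential_decompositions",
    "assemble_stationary",
    "solve_by_decomposition",
    "solve_complex_balanced",
    "solve_motif",
    "complex_balance_point",
]


# ---------------------------------------------------------------------------
# decompositions as data
# ---------------------------------------------------------------------------

@dataclass
class Decomposition:
    """A reaction-disjoint split of a parent network into parts."""

    parent: ReactionNetwork
    part_indices: tuple[frozenset, ...]
    solver_tags: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        everything: set[int] = set()
        for part in self.part_indices:
            if part & everything:
                raise ValidationError("decomposition parts share reactions")
            everything |= part
        if everything != set(range(len(self.parent.reactions))):
            raise ValidationError("decomposition does not cover the reactions")

    @property
    def parts(self) -> list[ReactionNetwork]:
        return [self.parent.subnetwork(idx) for idx in self.part_indices]

    def shared_species(self) -> dict[tuple[int, int], frozenset]:
        parts = self.parts
        shared = {}
        for a, b in itertools.combinations(range(len(parts)), 2):
            common = frozenset(parts[a].species) & frozenset(parts[b].species)
            if common:
                shared[(a, b)] = common
        return shared

    def to_json(self) -> dict:
        return {
            "parts": [sorted(idx) for idx in self.part_indices],
            "part_species": [list(p.species) for p in self.parts],
            "solver_tags": list(self.solver_tags) if self.solver_tags else None,
        }


def enumerate_reaction_bipartitions(
    network: ReactionNetwork, unordered: bool = False
) -> Iterator[tuple[frozenset, frozenset]]:
    """All bipartitions R = R1 ∪ R2 with R1 nonempty, as index sets.

    Ordered enumeration yields 2^|R| − 1 pairs (every nonempty R1 against its
    complement, which may be empty) — the count the bipartition argument is
    based on; ``unordered=True`` halves it by requiring reaction 0 ∈ R1.
    Order: increasing |R1|, lexicographic within, hence deterministic.
    """
    m = len(network.reactions)
    if m < 1:
        raise ValidationError("bipartitions need at least one reaction")
    everything = frozenset(range(m))
    for size in range(1, m + 1):
        for combo in itertools.combinations(range(m), size):
            left = frozenset(combo)
            if unordered and 0 not in left:
                continue
            yield left, everything - left


def essential_decompositions(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None = None,
    bound: int | Sequence[int] | None = None,
    max_parts: int = 4,
    *,
    settings: Settings = DEFAULT,
) -> list[Decomposition]:
    """All reaction-disjoint decompositions into ≤ max_parts essential parts.

    Built by recursively bisecting parts; ranked with more parts first
    (finer decompositions give the solvers smaller problems).  The trivial
    one-part decomposition is included when the network itself is essential.
    """
    m = len(network.reactions)
    if m > settings.max_reactions_exhaustive:
        raise UndecomposableError(
            f"exhaustive decomposition search refused for {m} reactions "
            f"(limit {settings.max_reactions_exhaustive}; raise it in settings)"
        )
    essential_memo: dict[frozenset, bool] = {}

    def part_essential(indices: frozenset) -> bool:
        if indices not in essential_memo:
            sub = network.subnetwork(indices)
            essential_memo[indices] = (
                is_essential(sub, kinetics, bound, settings=settings) == "essential"
            )
        return essential_memo[indices]

    split_memo: dict[frozenset, list[tuple[frozenset, frozenset]]] = {}

    def essential_splits(indices: frozenset) -> list[tuple[frozenset, frozenset]]:
        if indices not in split_memo:
            ordered = sorted(indices)
            found = []
            for size in range(1, len(ordered)):
                for combo in itertools.combinations(ordered[1:], size - 1):
                    left = frozenset((ordered[0],) + combo)
                    right = indices - left
                    if part_essential(left) and part_essential(right):
                        found.append((left, right))
            split_memo[indices] = found
        return split_memo[indices]

    everything = frozenset(range(m))
    results: set[frozenset] = set()
    if part_essential(everything):
        results.add(frozenset([everything]))
    frontier: list[tuple[frozenset, ...]] = [(everything,)]
    while frontier:
        parts = frontier.pop()
        if len(parts) >= max_parts:
            continue
        for i, part in enumerate(parts):
            if len(part) < 2:
                continue
            for left, right in essential_splits(part):
                refined = parts[:i] + (left, right) + parts[i + 1:]
                key = frozenset(refined)
                if key not in results:
                    if all(part_essential(p) for p in refined):
                        results.add(key)
                        frontier.append(refined)
    decomps = [
        Decomposition(network, tuple(sorted(parts, key=sorted)))
        for parts in results
    ]
    decomps.sort(key=lambda d: (-len(d.part_indices), [sorted(p) for p in d.part_indices]))
    return decomps


# ---------------------------------------------------------------------------
# leaf solvers
# ---------------------------------------------------------------------------

@dataclass
class PartSolution:
    """Per-species product-form factors for one (leaf) part.

    ``tilt_weights`` is the part's conservation vector when it has one: the
    family f_i(x) ↦ d^(w_i x) f_i(x) leaves the part's stationary
    distributions unchanged on its components and is the freedom the
    matching step exploits.
    """

    reaction_indices: frozenset
    species: tuple[str, ...]
    functions: dict[str, ProductFormFunction]
    tilt_weights: Optional[dict[str, float]]
    tag: str
    meta: dict = field(default_factory=dict)


def complex_balance_point(
    network: ReactionNetwork, *, settings: Settings = DEFAULT
) -> Optional[dict[str, float]]:
    """A positive point c of complex balance, or None.

    Solves, in log space, the per-complex balance out(η) = in(η) where
    out(η) = Σ_{ν→ν', ν=η} κ c^ν and in(η) = Σ_{ν→ν', ν'=η} κ c^ν.
    Weakly reversible deficiency-zero networks admit a solution for every
    choice of rates; otherwise the solve may legitimately fail.
    """
    if not network.reactions:
        return None
    species = network.species
    complexes = sorted(network.complexes, key=lambda c: c.format())
    reactant_vecs = [r.reactant.vector(species) for r in network.reactions]
    rates = [r.rate for r in network.reactions]
    cplx_index = {c: i for i, c in enumerate(complexes)}

    def residuals(log_c: np.ndarray) -> np.ndarray:
        flows = [
            rate * math.exp(min(max(float(vec @ log_c), -200.0), 200.0))
            for rate, vec in zip(rates, reactant_vecs)
        ]
        net = np.zeros(len(complexes))
        gross = np.zeros(len(complexes))
        for i, r in enumerate(network.reactions):
            net[cplx_index[r.reactant]] += flows[i]
            net[cplx_index[r.product]] -= flows[i]
            gross[cplx_index[r.reactant]] += flows[i]
            gross[cplx_index[r.product]] += flows[i]
        # relative imbalance: scale-invariant, so a collapse of c toward 0 or
        # infinity cannot fake a balance point
        return net / gross

    result = least_squares(residuals, np.zeros(len(species)), method="lm")
    if np.max(np.abs(result.x)) > 30.0:
        return None
    if np.max(np.abs(residuals(result.x))) > 1e-10:
        return None
    return {s: math.exp(float(v)) for s, v in zip(species, result.x)}


def solve_complex_balanced(
    part: ReactionNetwork,
    kinetics: KineticsSpec | None,
    context: "SolveContext",
) -> Optional[PartSolution]:
    """Poisson-type product form f_i(x) = c_i^x / ∏_{l≤x} θ_i(l) at a point of
    complex balance; applies to weakly reversible parts admitting one."""
    if reversibility_class(part) == "neither":
        return None
    point = complex_balance_point(part, settings=context.settings)
    if point is None:
        return None
    kinetics = kinetics or KineticsSpec()
    functions = {
        s: ProductFormFunction.poisson(point[s], kinetics.theta(s))
        for s in part.species
    }
    return PartSolution(
        reaction_indices=frozenset(),
        species=part.species,
        functions=functions,
        tilt_weights=_tilt_weights(part),
        tag="complex_balanced",
        meta={"c": point},
    )


def solve_motif(
    part: ReactionNetwork,
    kinetics: KineticsSpec | None,
    context: "SolveContext",
) -> Optional[PartSolution]:
    """The two-species birth–death motif family.

    Covers S1 ⇌ S2 together with 2S1 ⇌ S1+S2 and the autocatalytic
    generalizations S2+(m−1)S1 → mS1: any two-species part whose jumps are
    all ±(e_A − e_B) and whose aggregate rates factor as
    down(x) = θ_A(x_A) D(x_A−1) and up(x) = θ_B(x_B) U(x_A).  The factors are

        f_A(x) = d^x / ∏_{l≤x} θ_A(l) · ∏_{l≤x} U(l−1)/D(l−1),
        f_B(x) = d^x / ∏_{l≤x} θ_B(l),

    the one-dimensional birth–death balance along each conservation line
    x_A + x_B = N.  The factorization is checked on a grid and refused when
    it fails (e.g. a reactant containing two copies of the partner species).
    """
    if part.n_species != 2:
        return None
    kinetics = kinetics or KineticsSpec()
    system = StochasticSystem(part, kinetics)
    jumps = [r.jump(part.species) for r in part.reactions]
    if not all(j in ((1, -1), (-1, 1)) for j in jumps):
        return None
    xmax = max(
        (context.species_max.get(s, 0) for s in part.species), default=0
    )
    grid = max(10, min(xmax, 40))

    for a, b in ((0, 1), (1, 0)):
        theta_a = kinetics.theta(part.species[a])
        theta_b = kinetics.theta(part.species[b])
        down_idx = [i for i, j in enumerate(jumps) if j[a] == -1]
        up_idx = [i for i, j in enumerate(jumps) if j[a] == +1]
        if not down_idx or not up_idx:
            continue

        def state(xa: int, xb: int) -> tuple:
            s = [0, 0]
            s[a], s[b] = xa, xb
            return tuple(s)

        def down(xa: int, xb: int) -> float:
            return sum(system.propensity(i, state(xa, xb)) for i in down_idx)

        def up(xa: int, xb: int) -> float:
            return sum(system.propensity(i, state(xa, xb)) for i in up_idx)

        ok = True
        for xa in range(grid + 1):
            base_down = down(xa, 0)
            theta_val = theta_a(xa)
            for xb in range(grid + 1):
                expected = base_down
                if abs(down(xa, xb) - expected) > 1e-9 * (1.0 + abs(expected)):
                    ok = False
                    break
                up_val = up(xa, xb)
                tb = theta_b(xb)
                if tb == 0.0:
                    if up_val != 0.0:
                        ok = False
                        break
                else:
                    anchor = up(xa, 1) / theta_b(1)
                    if abs(up_val - tb * anchor) > 1e-9 * (1.0 + abs(up_val)):
                        ok = False
                        break
            if not ok:
                break
            if xa >= 1 and theta_val == 0.0:
                ok = False
                break
        if not ok:
            continue

        def big_u(x: int) -> float:
            return up(x, 1) / theta_b(1)

        def big_d(y: int) -> float:
            return down(y + 1, 0) / theta_a(y + 1)

        # ratios must exist on the component's range
        horizon = max(xmax, 1)
        if any(big_u(x) <= 0.0 or big_d(x) <= 0.0 for x in range(horizon)):
            continue

        name_a, name_b = part.species[a], part.species[b]
        f_a = ProductFormFunction(
            lambda x: big_u(x - 1) / (theta_a(x) * big_d(x - 1)),
            tag="motif",
            meta={"species": name_a},
        )
        f_b = ProductFormFunction(
            lambda x: 1.0 / theta_b(x), tag="poisson", meta={"c": 1.0, "theta": theta_b}
        )
        return PartSolution(
            reaction_indices=frozenset(),
            species=part.species,
            functions={name_a: f_a, name_b: f_b},
            tilt_weights={name_a: 1.0, name_b: 1.0},
            tag="motif",
            meta={"autocatalytic_species": name_a},
        )
    return None


def solve_direct_factorize(
    part: ReactionNetwork,
    kinetics: KineticsSpec | None,
    context: "SolveContext",
) -> Optional[PartSolution]:
    """Direct solve + joint factorization for small conservative parts.

    Projects the joint component onto the part's species, splits the
    projection into the part's irreducible components, solves each exactly,
    and fits one set of per-species log-factors shared across all of them
    (with one free constant per component).  A small joint residual verifies
    numerically that the part has a common product form on every projected
    component — exactly the hypothesis the assembly theorem needs.
    """
    settings = context.settings
    if conservation_vector(part) is None:
        return None
    projected = context.project(part.species)
    if len(projected) > settings.dense_solver_limit:
        return None
    system = StochasticSystem(part, kinetics)
    # split the projection into the part's communicating classes
    remaining = set(projected)
    components: list[list[tuple]] = []
    while remaining:
        seed = min(remaining)
        stack, seen = [seed], {seed}
        while stack:
            current = stack.pop()
            for target in system.successors(current):
                if target not in projected:
                    return None  # projection is not a union of components
                if target not in seen:
                    seen.add(target)
                    stack.append(target)
        if not seen <= remaining:
            return None  # overlapping classes: not closed
        components.append(sorted(seen))
        remaining -= seen
    state_sets, log_sets = [], []
    for states in components:
        comp = IrreducibleComponent(
            species=part.species,
            states=tuple(states),
            closed=True,
            truncated=False,
            seed_state=states[0],
        )
        try:
            solved = solve_master_direct(part, kinetics, comp, settings=settings)
        except Exception:
            return None
        support = [
            (s, math.log(p)) for s, p in zip(comp.states, solved.probs) if p > 0
        ]
        if len(support) < len(comp.states):
            return None
        state_sets.append([s for s, _ in support])
        log_sets.append([v for _, v in support])
    fit = factorize_components(
        state_sets, log_sets, part.species, settings=settings
    )
    if not fit.ok:
        return None
    try:
        functions = {s: fit.function_for(s) for s in part.species}
    except ValidationError:
        return None
    return PartSolution(
        reaction_indices=frozenset(),
        species=part.species,
        functions=functions,
        tilt_weights=_tilt_weights(part),
        tag="direct_factorize",
        meta={"n_components": len(components), "fit_residual": fit.max_residual},
    )


def _tilt_weights(part: ReactionNetwork) -> Optional[dict[str, float]]:
    c = conservation_vector(part)
    if c is None:
        return None
    return {s: float(v) for s, v in zip(part.species, c)}


#: closed-form leaf solvers, tried before any further splitting
DEFAULT_SOLVERS: tuple[Callable, ...] = (
    solve_complex_balanced,
    solve_motif,
)

#: expensive leaf solvers, tried only after splitting a part has failed
FALLBACK_SOLVERS: tuple[Callable, ...] = (solve_direct_factorize,)


# ---------------------------------------------------------------------------
# matching and assembly
# ---------------------------------------------------------------------------

@dataclass
class SolveContext:
    network: ReactionNetwork
    kinetics: KineticsSpec | None
    component: IrreducibleComponent
    settings: Settings
    species_values: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        for i, s in enumerate(self.network.species):
            values = sorted({state[i] for state in self.component.states})
            self.species_values[s] = values

    @property
    def species_max(self) -> dict[str, int]:
        return {s: v[-1] for s, v in self.species_values.items()}

    def project(self, subset: Sequence[str]) -> frozenset:
        idx = [self.network.species.index(s) for s in subset]
        return frozenset(
            tuple(state[i] for i in idx) for state in self.component.states
        )


@dataclass
class MatchResult:
    log_tilts: dict[int, float]  # leaf position -> log d
    alphas: dict[str, float]     # shared species -> pre-tilt proportionality constant
    residual: float
    ok: bool


def _match_leaves(
    leaves: Sequence[PartSolution],
    context: SolveContext,
) -> MatchResult:
    """Solve the shared-species proportionality constraints over the tilts.

    For a shared species i between leaves r (reference) and o the condition
    α_i f_i^o = f_i^r, after tilting, is linear in the log tilts:
    w_{r,i} t_r x − w_{o,i} t_o x − log α_i = log f_i^o(x) − log f_i^r(x)
    for every x the species takes on the joint component.  The system is
    solved by least squares; a residual above tolerance means no choice of
    the free constants makes the functions proportional.
    """
    tiltable = [k for k, leaf in enumerate(leaves) if leaf.tilt_weights is not None]
    tilt_col = {k: i for i, k in enumerate(tiltable)}
    owners: dict[str, list[int]] = {}
    for k, leaf in enumerate(leaves):
        for s in leaf.species:
            owners.setdefault(s, []).append(k)
    rows, rhs = [], []
    const_cols: dict[tuple[int, int, str], int] = {}
    n_tilt = len(tiltable)

    def const_col(key) -> int:
        if key not in const_cols:
            const_cols[key] = n_tilt + len(const_cols)
        return const_cols[key]

    for s, ks in sorted(owners.items()):
        if len(ks) < 2:
            continue
        ref = ks[0]
        for other in ks[1:]:
            col = const_col((ref, other, s))
            for x in context.species_values[s]:
                row = {}
                if ref in tilt_col:
                    row[tilt_col[ref]] = leaves[ref].tilt_weights[s] * x
                if other in tilt_col:
                    row[tilt_col[other]] = (
                        row.get(tilt_col[other], 0.0)
                        - leaves[other].tilt_weights[s] * x
                    )
                row[col] = -1.0
                rows.append(row)
                rhs.append(
                    leaves[other].functions[s].log_f(x)
                    - leaves[ref].functions[s].log_f(x)
                )
    n_unknown = n_tilt + len(const_cols)
    if not rows:
        return MatchResult({k: 0.0 for k in range(len(leaves))}, {}, 0.0, True)
    matrix = np.zeros((len(rows), max(n_unknown, 1)))
    for i, row in enumerate(rows):
        for j, value in row.items():
            matrix[i, j] = value
    target = np.array(rhs)
    solution, *_ = np.linalg.lstsq(matrix, target, rcond=None)
    residual = float(np.max(np.abs(matrix @ solution - target)))
    log_tilts = {k: 0.0 for k in range(len(leaves))}
    for k, col in tilt_col.items():
        log_tilts[k] = float(solution[col])
    alphas = {
        key[2]: math.exp(float(solution[col])) for key, col in const_cols.items()
    }
    ok = residual <= context.settings.matching_residual
    return MatchResult(log_tilts, alphas, residual, ok)


def _assembled_functions(
    leaves: Sequence[PartSolution], match: MatchResult
) -> dict[str, ProductFormFunction]:
    functions: dict[str, ProductFormFunction] = {}
    for k, leaf in enumerate(leaves):
        for s in leaf.species:
            if s in functions:
                continue
            fn = leaf.functions[s]
            if leaf.tilt_weights is not None and match.log_tilts[k] != 0.0:
                fn = fn.tilted(
                    math.exp(match.log_tilts[k]), weight=leaf.tilt_weights[s]
                )
            functions[s] = fn
    return functions


def assemble_stationary(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    component: IrreducibleComponent,
    decomposition: Decomposition,
    part_solutions: Sequence[PartSolution],
    *,
    settings: Settings = DEFAULT,
    force: bool = False,
) -> StationaryDistribution:
    """Assemble π(x) = (1/Z) ∏_i f_i(x_i) from per-part product forms.

    Shared-species functions must be proportional after exploiting the free
    tilt constants; otherwise the assembly is refused (``RefusalError``)
    unless ``force=True``, which builds the best-effort product anyway (a
    diagnostic: a forced product from mismatched parts is *not* stationary).
    The assembled distribution on a finite component is verified to satisfy
    generalized balance with the per-part partition {(R_j, R_j)}_j; on a
    truncated component the ratio-test summability verdict is recorded.
    """
    leaves = [
        PartSolution(
            reaction_indices=idx,
            species=sol.species,
            functions=sol.functions,
            tilt_weights=sol.tilt_weights,
            tag=sol.tag,
            meta=sol.meta,
        )
        for idx, sol in zip(decomposition.part_indices, part_solutions)
    ]
    context = SolveContext(network, kinetics, component, settings)
    match = _match_leaves(leaves, context)
    if not match.ok and not force:
        raise RefusalError(
            "shared-species product-form functions are not proportional "
            f"(match residual {match.residual:.3e})"
        )
    functions = _assembled_functions(leaves, match)
    dist = explicit_from_product(component, functions)
    summability = ratio_test_summability(functions.values(), component)
    if summability == "divergent":
        raise RefusalError("assembled product form is not summable")
    partition = BalancePartition.per_part(
        network, [sorted(idx) for idx in decomposition.part_indices]
    )
    ok, residual = check_generalized_balance(
        network, kinetics, dist, partition, settings=settings
    )
    dist.residual = residual
    dist.meta.update(
        {
            "match_residual": match.residual,
            "alphas": match.alphas,
            "tilts": {k: math.exp(v) for k, v in match.log_tilts.items()},
            "balance_ok": ok,
            "summability": summability,
            "decomposition": decomposition.to_json(),
        }
    )
    return dist


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

@dataclass
class SolutionNode:
    indices: frozenset
    tag: str
    solution: Optional[PartSolution] = None
    children: tuple["SolutionNode", ...] = ()

    def leaves(self) -> list["SolutionNode"]:
        if self.solution is not None:
            return [self]
        out: list[SolutionNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_json(self) -> dict:
        data = {"reactions": sorted(self.indices), "solver": self.tag}
        if self.children:
            data["children"] = [child.to_json() for child in self.children]
        return data


def solve_by_decomposition(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    component: IrreducibleComponent,
    *,
    solvers: Sequence[Callable] = DEFAULT_SOLVERS,
    fallback_solvers: Sequence[Callable] = FALLBACK_SOLVERS,
    settings: Settings = DEFAULT,
    allow_fallback: bool = True,
) -> tuple[StationaryDistribution, dict]:
    """Find an essential decomposition with solvable, matchable parts and
    assemble the stationary distribution on *component*.

    The search recursively bisects reaction subsets (smallest part first,
    deterministic order), keeps only essential parts, tries the registered
    leaf solvers before splitting further, gates every merge on the
    shared-species proportionality match, and short-circuits at the first
    success.  When nothing matches, a finite component falls back to the
    direct solve (reported as such); an infinite one raises
    ``UndecomposableError``.

    Returns the distribution and a provenance report (decomposition tree,
    per-part solver tags, tilt and proportionality constants, verification
    residuals, summability verdict).
    """
    m = len(network.reactions)
    if m > settings.max_reactions_exhaustive:
        raise UndecomposableError(
            f"decomposition search refused for {m} reactions "
            f"(limit {settings.max_reactions_exhaustive})"
        )
    context = SolveContext(network, kinetics, component, settings)
    essential_memo: dict[frozenset, bool] = {}
    attempt_memo: dict[frozenset, Optional[SolutionNode]] = {}
    refusals = {"count": 0}

    def part_essential(indices: frozenset) -> bool:
        if indices not in essential_memo:
            sub = network.subnetwork(indices)
            essential_memo[indices] = (
                is_essential(sub, kinetics, settings=settings) == "essential"
            )
        return essential_memo[indices]

    def attempt(indices: frozenset) -> Optional[SolutionNode]:
        if indices in attempt_memo:
            return attempt_memo[indices]
        part = network.subnetwork(indices)
        node: Optional[SolutionNode] = None
        for solver in solvers:
            solution = solver(part, kinetics, context)
            if solution is not None:
                solution.reaction_indices = indices
                node = SolutionNode(indices, solution.tag, solution=solution)
                break
        if node is None and len(indices) >= 2:
            ordered = sorted(indices)
            # left always contains the smallest index, so every unordered
            # bipartition is visited exactly once; order is by |left|
            for size in range(1, len(ordered)):
                for combo in itertools.combinations(ordered[1:], size - 1):
                    left = frozenset((ordered[0],) + combo)
                    right = indices - left
                    if not (part_essential(left) and part_essential(right)):
                        continue
                    left_node = attempt(left)
                    if left_node is None:
                        continue
                    right_node = attempt(right)
                    if right_node is None:
                        continue
                    candidate = SolutionNode(
                        indices, "union", children=(left_node, right_node)
                    )
                    match = _match_leaves(
                        [leaf.solution for leaf in candidate.leaves()], context
                    )
                    if not match.ok:
                        refusals["count"] += 1
                        continue
                    node = candidate
                    break
                if node is not None:
                    break
        if node is None:
            for solver in fallback_solvers:
                solution = solver(part, kinetics, context)
                if solution is not None:
                    solution.reaction_indices = indices
                    node = SolutionNode(indices, solution.tag, solution=solution)
                    break
        attempt_memo[indices] = node
        return node

    everything = frozenset(range(m))
    root = attempt(everything) if m else None
    report: dict = {"refusals": refusals["count"]}
    if root is not None:
        leaves = root.leaves()
        decomposition = Decomposition(
            network,
            tuple(leaf.indices for leaf in leaves),
            solver_tags=tuple(leaf.tag for leaf in leaves),
        )
        dist = assemble_stationary(
            network,
            kinetics,
            component,
            decomposition,
            [leaf.solution for leaf in leaves],
            settings=settings,
        )
        report.update(
            {
                "method": "decomposition",
                "tree": root.to_json(),
                "decomposition": decomposition.to_json(),
                "match_residual": dist.meta["match_residual"],
                "alphas": dist.meta["alphas"],
                "tilts": dist.meta["tilts"],
                "balance_residual": dist.residual,
                "summability": dist.meta["summability"],
            }
        )
        return dist, report
    if allow_fallback and component.closed and not component.truncated:
        logger.info("no solvable decomposition; falling back to direct solve")
        dist = solve_master_direct(network, kinetics, component, settings=settings)
        report.update({"method": "direct_fallback"})
        return dist, report
    raise UndecomposableError(
        "no decomposition with solvable, matchable parts was found"
    )
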