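"""Reaction-network data model, text format, unions and structural analysis.

A reaction network is the triple (species, complexes, reactions).  Complexes
are non-negative integer combinations of species; every reaction points from
one complex to a different one and carries a positive rate constant.  The
structural quantities computed here — linkage classes, reversibility class,
stoichiometric dimension, deficiency, conservativity — are the standard ones
of chemical reaction network theory.

Rank and nullspace computations run over the rationals (sympy) so that the
deficiency is never corrupted by floating-point rank decisions, and
conservation vectors are returned as exact rationals re-verified against the
integer stoichiometry.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import sympy
from scipy.optimize import linprog

from .errors import CRNParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Complex",
    "Reaction",
    "ReactionNetwork",
    "StructuralReport",
    "parse_network",
    "write_network",
    "network_union",
    "reaction_graph",
    "linkage_classes",
    "reversibility_class",
    "stoichiometric_matrix",
    "stoichiometric_dimension",
    "deficiency",
    "structural_report",
    "conservation_vector",
]


class Complex(Mapping):
    """An immutable complex: map from species name to a positive coefficient.

    Zero coefficients are dropped; the empty complex is the zero complex ∅.
    """

    __slots__ = ("_items",)

    def __init__(self, coeffs: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(coeffs)
        cleaned = {}
        for name, coeff in items.items():
            if not isinstance(coeff, (int, np.integer)):
                raise ValidationError(f"coefficient of {name} must be an integer, got {coeff!r}")
            if coeff < 0:
                raise ValidationError(f"coefficient of {name} must be >= 0, got {coeff}")
            if coeff:
                cleaned[str(name)] = int(coeff)
        object.__setattr__(self, "_items", tuple(sorted(cleaned.items())))

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, key: str) -> int:
        for name, coeff in self._items:
            if name == key:
                return coeff
        raise KeyError(key)

    def get(self, key: str, default: int = 0) -> int:  # type: ignore[override]
        try:
            return self[key]
        except KeyError:
            return default

    def __iter__(self) -> Iterator[str]:
        return (name for name, _ in self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __hash__(self) -> int:
        return hash(self._items)

    def __eq__(self, other) -> bool:
        if isinstance(other, Complex):
            return self._items == other._items
        return NotImplemented

    # -- domain ------------------------------------------------------------
    @property
    def molecularity(self) -> int:
        return sum(coeff for _, coeff in self._items)

    @property
    def is_zero(self) -> bool:
        return not self._items

    def species(self) -> frozenset:
        return frozenset(name for name, _ in self._items)

    def vector(self, species_order: Sequence[str]) -> np.ndarray:
        return np.array([self.get(s) for s in species_order], dtype=np.int64)

    def format(self, species_order: Sequence[str] | None = None) -> str:
        if self.is_zero:
            return "0"
        order = [s for s in (species_order or ()) if self.get(s)] or [n for n, _ in self._items]
        parts = []
        for name in order:
            coeff = self.get(name)
            parts.append(name if coeff == 1 else f"{coeff} {name}")
        return " + ".join(parts)

    def __repr__(self) -> str:
        return f"Complex({self.format()!r})"


@dataclass(frozen=True)
class Reaction:
    """A reaction ``reactant -> product`` with a positive rate constant."""

    reactant: Complex
    product: Complex
    rate: float

    def __post_init__(self):
        if self.reactant == self.product:
            raise ValidationError(f"reactant equals product: {self.reactant.format()}")
        if not (self.rate > 0):
            raise ValidationError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def key(self) -> tuple[Complex, Complex]:
        """Identity of the reaction irrespective of its rate."""
        return (self.reactant, self.product)

    def reversed_key(self) -> tuple[Complex, Complex]:
        return (self.product, self.reactant)

    def jump(self, species_order: Sequence[str]) -> tuple[int, ...]:
        """The net stoichiometric change ν' − ν as an integer tuple."""
        return tuple(
            self.product.get(s) - self.reactant.get(s) for s in species_order
        )

    def format(self, species_order: Sequence[str] | None = None) -> str:
        return (
            f"{self.reactant.format(species_order)} -> "
            f"{self.product.format(species_order)} ; rate={self.rate!r}"
        )


@dataclass
class ReactionNetwork:
    """The triple (species, complexes, reactions).

    ``species`` fixes the coordinate order of every state vector derived from
    this network; by convention it is the order of first appearance in the
    input.  The complex set is derived from the reactions.  Species that
    appear in no complex are permitted only when listed explicitly.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    provenance: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        seen_keys = set()
        used = set()
        for r in self.reactions:
            if r.key in seen_keys:
                raise ValidationError(
                    f"duplicate reaction {r.reactant.format()} -> {r.product.format()}"
                )
            seen_keys.add(r.key)
            used |= r.reactant.species() | r.product.species()
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species name")
        missing = used - set(self.species)
        if missing:
            raise ValidationError(f"species used but not declared: {sorted(missing)}")

    # -- construction ------------------------------------------------------
    @classmethod
    def build(
        cls,
        reactions: Iterable[Reaction],
        species: Sequence[str] | None = None,
    ) -> "ReactionNetwork":
        """Build a network, merging duplicate reactions by summing rates.

        Species order defaults to the order of first appearance across the
        reaction list (reactant side before product side).
        """
        merged: dict[tuple[Complex, Complex], float] = {}
        order: list[tuple[Complex, Complex]] = []
        appearance: list[str] = []
        for r in reactions:
            if r.key in merged:
                logger.warning(
                    "duplicate reaction %s -> %s merged; rates summed",
                    r.reactant.format(),
                    r.product.format(),
                )
                merged[r.key] += r.rate
            else:
                merged[r.key] = r.rate
                order.append(r.key)
            for cplx in (r.reactant, r.product):
                for name in cplx:
                    if name not in appearance:
                        appearance.append(name)
        if species is None:
            species = appearance
        return cls(
            species=tuple(species),
            reactions=tuple(
                Reaction(reactant, product, merged[(reactant, product)])
                for reactant, product in order
            ),
        )

    @classmethod
    def empty(cls) -> "ReactionNetwork":
        return cls(species=(), reactions=())

    # -- derived structure -------------------------------------------------
    @property
    def complexes(self) -> frozenset:
        return frozenset(c for r in self.reactions for c in (r.reactant, r.product))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def reaction_keys(self) -> frozenset:
        return frozenset(r.key for r in self.reactions)

    def has_reverse(self, reaction: Reaction) -> bool:
        return reaction.reversed_key() in self.reaction_keys

    def subnetwork(self, reaction_indices: Iterable[int]) -> "ReactionNetwork":
        """Restrict to a reaction subset; species keep the parent's order."""
        subset = tuple(self.reactions[i] for i in sorted(set(reaction_indices)))
        used = set()
        for r in subset:
            used |= r.reactant.species() | r.product.species()
        return ReactionNetwork(
            species=tuple(s for s in self.species if s in used),
            reactions=subset,
        )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        return {
            "species": list(self.species),
            "reactions": [
                {
                    "reactant": dict(r.reactant),
                    "product": dict(r.product),
                    "rate": r.rate,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_json(cls, data: Mapping) -> "ReactionNetwork":
        return cls(
            species=tuple(data["species"]),
            reactions=tuple(
                Reaction(Complex(r["reactant"]), Complex(r["product"]), r["rate"])
                for r in data["reactions"]
            ),
        )

    def __str__(self) -> str:
        return write_network(self)


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(\d*)\s*\*?\s*([A-Za-z_]\w*)$")
_ZERO_TOKENS = {"0", "∅", "Ø"}


def _parse_complex(text: str, lineno: int) -> Complex:
    text = text.strip()
    if text in _ZERO_TOKENS:
        return Complex()
    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        match = _TERM_RE.match(term)
        if not match:
            raise CRNParseError(f"cannot parse complex term {term!r}", lineno)
        coeff = int(match.group(1)) if match.group(1) else 1
        name = match.group(2)
        coeffs[name] = coeffs.get(name, 0) + coeff
    return Complex(coeffs)


def _first_appearance(complexes: Iterable[Complex], order_hint: Iterable[str]) -> list[str]:
    seen: list[str] = list(order_hint)
    for cplx in complexes:
        for name in cplx:
            if name not in seen:
                seen.append(name)
    return seen


def parse_network(text: str) -> ReactionNetwork:
    """Parse the reaction-list text format.

    One reaction per line: ``2 S1 + S2 -> S3 ; rate=1.0`` or a reversible
    pair ``S1 <-> S2 ; rates=0.3,0.4`` (forward rate first).  ``0`` or ``∅``
    denotes the zero complex, ``#`` starts a comment, an optional
    ``species:`` header declares species order (and permits orphan species),
    and ``kinetics:`` lines are ignored here (see :mod:`crndecomp.io`).
    """
    reactions: list[Reaction] = []
    declared: list[str] | None = None
    appearance: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("species:"):
            declared = line[len("species:"):].replace(",", " ").split()
            continue
        if line.startswith("kinetics:"):
            continue
        if ";" not in line:
            raise CRNParseError("missing ';' rate annotation", lineno)
        body, annot = (part.strip() for part in line.rsplit(";", 1))
        reversible = "<->" in body
        arrow = "<->" if reversible else "->"
        if body.count(arrow) != 1:
            raise CRNParseError(f"expected exactly one {arrow!r}", lineno)
        left, right = (part for part in body.split(arrow))
        reactant = _parse_complex(left, lineno)
        product = _parse_complex(right, lineno)
        try:
            if reversible:
                match = re.match(r"^rates\s*=\s*([^,]+),(.+)$", annot)
                if not match:
                    raise CRNParseError(
                        "reversible reaction needs 'rates=<fwd>,<rev>'", lineno
                    )
                fwd, rev = (float(part) for part in match.groups())
                pair = [
                    Reaction(reactant, product, fwd),
                    Reaction(product, reactant, rev),
                ]
            else:
                match = re.match(r"^rate\s*=\s*(\S+)$", annot)
                if not match:
                    raise CRNParseError("reaction needs 'rate=<r>'", lineno)
                pair = [Reaction(reactant, product, float(match.group(1)))]
        except ValidationError as exc:
            raise CRNParseError(str(exc), lineno) from exc
        except ValueError as exc:
            raise CRNParseError(f"bad rate value in {annot!r}", lineno) from exc
        for r in pair:
            reactions.append(r)
            for cplx in (r.reactant, r.product):
                for name in cplx:
                    if name not in appearance:
                        appearance.append(name)
    species = declared if declared is not None else appearance
    try:
        return ReactionNetwork.build(reactions, species=species)
    except ValidationError as exc:
        raise CRNParseError(str(exc)) from exc


def write_network(network: ReactionNetwork) -> str:
    """Inverse of :func:`parse_network` (stable round trip)."""
    lines = ["species: " + " ".join(network.species)] if network.species else []
    for r in network.reactions:
        lines.append(r.format(network.species))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# unions
# ---------------------------------------------------------------------------

def network_union(g1: ReactionNetwork, g2: ReactionNetwork) -> ReactionNetwork:
    """The union (join) of two networks.

    Species, complexes and reactions are set-unions.  A reaction present in
    both inputs (gluing over reactions) appears once with the summed rate.
    Whether the inputs were reaction-disjoint is recorded in
    ``result.provenance["reaction_disjoint"]``.
    """
    species = list(g1.species) + [s for s in g2.species if s not in g1.species]
    merged: dict[tuple[Complex, Complex], float] = {r.key: r.rate for r in g1.reactions}
    order = [r.key for r in g1.reactions]
    disjoint = True
    for r in g2.reactions:
        if r.key in merged:
            disjoint = False
            merged[r.key] += r.rate
        else:
            merged[r.key] = r.rate
            order.append(r.key)
    result = ReactionNetwork(
        species=tuple(species),
        reactions=tuple(Reaction(a, b, merged[(a, b)]) for a, b in order),
    )
    result.provenance["reaction_disjoint"] = disjoint
    return result


# ---------------------------------------------------------------------------
# structural analysis
# ---------------------------------------------------------------------------

def reaction_graph(network: ReactionNetwork) -> nx.MultiDiGraph:
    """The directed graph on complexes with one arrow per reaction."""
    graph = nx.MultiDiGraph()
    graph.add_nodes_from(network.complexes)
    for r in network.reactions:
        graph.add_edge(r.reactant, r.product, rate=r.rate)
    return graph


def linkage_classes(network: ReactionNetwork) -> list[frozenset]:
    """Partition of the complex set into connected components."""
    graph = reaction_graph(network)
    return [frozenset(part) for part in nx.weakly_connected_components(graph)]


def reversibility_class(network: ReactionNetwork) -> str:
    """``"reversible"``, ``"weakly_reversible"`` or ``"neither"``.

    Reversible: every reaction's reverse is present.  Weakly reversible:
    every connected component of the reaction graph is strongly connected.
    """
    if all(network.has_reverse(r) for r in network.reactions):
        return "reversible"
    graph = reaction_graph(network)
    weak = list(nx.weakly_connected_components(graph))
    strong = list(nx.strongly_connected_components(graph))
    if len(weak) == len(strong):
        return "weakly_reversible"
    return "neither"


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer matrix with one row ν' − ν per reaction."""
    return np.array(
        [r.jump(network.species) for r in network.reactions], dtype=np.int64
    ).reshape(len(network.reactions), len(network.species))


def stoichiometric_dimension(network: ReactionNetwork) -> int:
    """dim(T): exact rational rank of the stoichiometric matrix."""
    if not network.reactions:
        return 0
    return sympy.Matrix(stoichiometric_matrix(network).tolist()).rank()


def conservation_vector(network: ReactionNetwork) -> Optional[tuple[Fraction, ...]]:
    """A strictly positive rational vector orthogonal to every reaction vector.

    Returns an exact vector ``c`` with ``min(c) == 1`` and
    ``(ν' − ν) · c == 0`` for every reaction, or ``None`` when the network is
    not conservative.  The search solves a linear program over a rational
    nullspace basis (positivity is imposed as ``c >= 1``, equivalent to
    ``c > 0`` up to scaling) and the candidate is re-verified exactly.
    """
    n = network.n_species
    if n == 0:
        return ()
    if not network.reactions:
        return tuple(Fraction(1) for _ in range(n))
    matrix = sympy.Matrix(stoichiometric_matrix(network).tolist())
    basis = matrix.nullspace()
    if not basis:
        return None
    exact_basis = [
        [Fraction(int(value.p), int(value.q)) for value in vec] for vec in basis
    ]
    basis_arr = np.array(
        [[float(value) for value in column] for column in exact_basis], dtype=float
    ).T  # n x k
    k = basis_arr.shape[1]
    # minimize total weight subject to B y >= 1 (bounded below, gives a vertex)
    result = linprog(
        c=basis_arr.sum(axis=0),
        A_ub=-basis_arr,
        b_ub=-np.ones(n),
        bounds=[(None, None)] * k,
        method="highs",
    )
    if not result.success:
        return None
    for denominator in (10**6, 10**9, 10**12):
        weights = [Fraction(v).limit_denominator(denominator) for v in result.x]
        candidate = [
            sum(weights[j] * exact_basis[j][i] for j in range(k)) for i in range(n)
        ]
        if all(value > 0 for value in candidate):
            smallest = min(candidate)
            return tuple(value / smallest for value in candidate)
    return None


@dataclass(frozen=True)
class StructuralReport:
    """Summary of the structural analysis of a network."""

    n_species: int
    n_complexes: int
    n_linkage_classes: int
    stoich_dim: int
    deficiency: int
    reversible: bool
    weakly_reversible: bool
    conservative: bool
    conservation_vector: Optional[tuple[Fraction, ...]]

    def to_json(self) -> dict:
        data = {
            "n_species": self.n_species,
            "n_complexes": self.n_complexes,
            "n_linkage_classes": self.n_linkage_classes,
            "stoich_dim": self.stoich_dim,
            "deficiency": self.deficiency,
            "reversible": self.reversible,
            "weakly_reversible": self.weakly_reversible,
            "conservative": self.conservative,
            "conservation_vector": (
                None
                if self.conservation_vector is None
                else [str(value) for value in self.conservation_vector]
            ),
        }
        return data


def structural_report(network: ReactionNetwork) -> StructuralReport:
    """Full structural analysis: δ = |C| − ℓ − dim(T), reversibility, conservativity."""
    n_complexes = len(network.complexes)
    n_linkage = len(linkage_classes(network))
    dim = stoichiometric_dimension(network)
    rev_class = reversibility_class(network)
    conservation = conservation_vector(network)
    report = StructuralReport(
        n_species=network.n_species,
        n_complexes=n_complexes,
        n_linkage_classes=n_linkage,
        stoich_dim=dim,
        deficiency=n_complexes - n_linkage - dim,
        reversible=rev_class == "reversible",
        weakly_reversible=rev_class in ("reversible", "weakly_reversible"),
        conservative=conservation is not None,
        conservation_vector=conservation,
    )
    if report.deficiency < 0:  # pragma: no cover - structural impossibility
        raise ValidationError(f"negative deficiency computed: {report}")
    return report


def deficiency(network: ReactionNetwork) -> int:
    """δ = |C| − ℓ − dim(T) (always ≥ 0)."""
    return structural_report(network).deficiency
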