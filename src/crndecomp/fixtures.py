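"""Fixture generator: reference networks with known structure and, where a
closed form exists, known stationary distributions.

The named fixtures are the small benchmark networks of the decomposition
literature (the three-species double-motif chain, the detailed-balance
counterexample, the gene-expression model, the autocatalytic families, the
triple-exchange complex-balanced pair, ...).  The random families glue
two-species motifs and complex-balanced parts with rates drawn log-uniformly
from [0.1, 10] — the regime the assembly machinery is exercised in.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .kinetics import KineticsSpec, RateLaw
from .network import Complex, Reaction, ReactionNetwork
from .stationary import ProductFormFunction, motif_product_form

__all__ = ["FixtureBundle", "generate_fixture", "FIXTURE_KINDS", "random_rates"]


@dataclass
class FixtureBundle:
    name: str
    network: ReactionNetwork
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    truth: dict = field(default_factory=dict)


def random_rates(rng: np.random.Generator, n: int, low: float = 0.1, high: float = 10.0):
    """Log-uniform rate draws on [low, high]."""
    return tuple(
        float(v) for v in np.exp(rng.uniform(math.log(low), math.log(high), size=n))
    )


def _rev(reactant: str, product: str, fwd: float, rev: float) -> list[Reaction]:
    return [
        Reaction(_cplx(reactant), _cplx(product), fwd),
        Reaction(_cplx(product), _cplx(reactant), rev),
    ]


def _cplx(text: str) -> Complex:
    if text in ("0", "∅"):
        return Complex()
    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if term[0].isdigit():
            count, name = term.split(" ", 1)
            coeffs[name] = coeffs.get(name, 0) + int(count)
        else:
            coeffs[term] = coeffs.get(term, 0) + 1
    return Complex(coeffs)


def _motif_reactions(a: str, b: str, rates: Sequence[float]) -> list[Reaction]:
    """The motif A ⇌ B, 2A ⇌ A+B with rates (κ1, κ2, κ3, κ4)."""
    k1, k2, k3, k4 = rates
    return (
        _rev(a, b, k1, k2)
        + _rev(f"2 {a}", f"{a} + {b}", k3, k4)
    )


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def _double_motif_hub(rates: Optional[Sequence[float]], rng: np.random.Generator) -> FixtureBundle:
    """Three species, eight reactions: S1 ⇌ S2 ⇌ S3 with the two autocatalytic
    exchange motifs 2S1 ⇌ S1+S2 and 2S3 ⇌ S2+S3.  Reversible, deficiency 2,
    conservative; the union of the (S1,S2) motif and the (S2,S3) motif."""
    k = tuple(rates) if rates is not None else random_rates(rng, 8)
    if len(k) != 8:
        raise ValidationError("double_motif_hub needs 8 rates")
    reactions = (
        _rev("S1", "S2", k[0], k[1])
        + _rev("2 S1", "S1 + S2", k[2], k[3])
        + _rev("S2", "S3", k[4], k[5])
        + _rev("2 S3", "S2 + S3", k[6], k[7])
    )
    network = ReactionNetwork.build(reactions, species=("S1", "S2", "S3"))
    f1, f2 = motif_product_form(k[0], k[1], k[2], k[3])
    # second motif read with S3 as the autocatalytic species: the S3-producing
    # rates (k5: S2->S3, k8: S2+S3->2S3) sit in the numerator of the ratios
    f3, _ = motif_product_form(k[5], k[4], k[6], k[7])
    return FixtureBundle(
        name="double_motif_hub",
        network=network,
        truth={
            "deficiency": 2,
            "n_linkage_classes": 3,
            "reversible": True,
            "essential": True,
            "conservative": True,
            "part_reactions": (frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})),
            "functions": {"S1": f1, "S2": f2, "S3": f3},
            "rates": k,
        },
    )


def _detailed_balance_union(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """2A ⇌ A+B, A+2B ⇌ 3B: reversible union of two detailed-balanced parts
    with deficiency one."""
    k = tuple(rates) if rates is not None else random_rates(rng, 4)
    reactions = _rev("2 A", "A + B", k[0], k[1]) + _rev("A + 2 B", "3 B", k[2], k[3])
    return FixtureBundle(
        name="detailed_balance_union",
        network=ReactionNetwork.build(reactions, species=("A", "B")),
        truth={
            "deficiency": 1,
            "n_linkage_classes": 2,
            "reversible": True,
            "essential": True,
            "conservative": True,
        },
    )


def _transient_union(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """X → Y, 3Y → 3X joined with ∅ ⇌ W: union of an almost-essential and an
    essential network that is not almost essential."""
    k = tuple(rates) if rates is not None else random_rates(rng, 4)
    reactions = [
        Reaction(_cplx("X"), _cplx("Y"), k[0]),
        Reaction(_cplx("3 Y"), _cplx("3 X"), k[1]),
        Reaction(_cplx("0"), _cplx("W"), k[2]),
        Reaction(_cplx("W"), _cplx("0"), k[3]),
    ]
    return FixtureBundle(
        name="transient_union",
        network=ReactionNetwork.build(reactions, species=("X", "Y", "W")),
        truth={"essential": False, "conservative": False},
    )


def _gene_expression(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """Gene expression: ∅ ⇌ S1, S2 → ∅, S1 → S1+S2.  Essential, but with no
    reaction-disjoint split into two essential parts."""
    k = tuple(rates) if rates is not None else random_rates(rng, 4)
    reactions = [
        Reaction(_cplx("0"), _cplx("S1"), k[0]),
        Reaction(_cplx("S1"), _cplx("0"), k[1]),
        Reaction(_cplx("S2"), _cplx("0"), k[2]),
        Reaction(_cplx("S1"), _cplx("S1 + S2"), k[3]),
    ]
    return FixtureBundle(
        name="gene_expression",
        network=ReactionNetwork.build(reactions, species=("S1", "S2")),
        truth={"essential": True, "conservative": False, "two_part_essential_splits": 0},
    )


def _source_chain(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """S0 → S1 ⇌ S2 ⇌ S3: not essential (S0 is never replenished)."""
    k = tuple(rates) if rates is not None else random_rates(rng, 5)
    reactions = [Reaction(_cplx("S0"), _cplx("S1"), k[0])] + _rev(
        "S1", "S2", k[1], k[2]
    ) + _rev("S2", "S3", k[3], k[4])
    return FixtureBundle(
        name="source_chain",
        network=ReactionNetwork.build(reactions, species=("S0", "S1", "S2", "S3")),
        truth={
            "essential": False,
            "conservative": True,
            "reversibility": "neither",
        },
    )


def _motif_birth_death(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """The motif S1 ⇌ S2, 2S1 ⇌ S1+S2 joined with the birth–death pair
    ∅ ⇌ S2; infinite components, summable product form for all rates."""
    k = tuple(rates) if rates is not None else random_rates(rng, 6)
    reactions = _motif_reactions("S1", "S2", k[:4]) + [
        Reaction(_cplx("0"), _cplx("S2"), k[4]),
        Reaction(_cplx("S2"), _cplx("0"), k[5]),
    ]
    c2 = k[4] / k[5]
    f1, _ = motif_product_form(k[0], k[1], k[2], k[3], d=c2)
    return FixtureBundle(
        name="motif_birth_death",
        network=ReactionNetwork.build(reactions, species=("S1", "S2")),
        truth={
            "essential": True,
            "conservative": False,
            "c2": c2,
            "functions": {"S1": f1, "S2": ProductFormFunction.poisson(c2)},
            "rates": k,
        },
    )


def _birth_death(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """∅ ⇌ S2: complex balanced with Poisson stationary distribution of mean
    κ+/κ−."""
    k = tuple(rates) if rates is not None else random_rates(rng, 2)
    reactions = [
        Reaction(_cplx("0"), _cplx("S2"), k[0]),
        Reaction(_cplx("S2"), _cplx("0"), k[1]),
    ]
    return FixtureBundle(
        name="birth_death",
        network=ReactionNetwork.build(reactions, species=("S2",)),
        truth={"complex_balance_point": {"S2": k[0] / k[1]}, "deficiency": 0},
    )


def _triple_exchange(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """3S3 ⇌ 3S5: weakly reversible, deficiency zero, conservative; the
    components step by three and carry a restricted Poisson product form."""
    k = tuple(rates) if rates is not None else random_rates(rng, 2)
    reactions = _rev("3 S3", "3 S5", k[0], k[1])
    ratio = (k[0] / k[1]) ** (1.0 / 3.0)
    return FixtureBundle(
        name="triple_exchange",
        network=ReactionNetwork.build(reactions, species=("S3", "S5")),
        truth={
            "deficiency": 0,
            "conservative": True,
            "complex_balance_ratio": ratio,  # c5/c3
        },
    )


def _autocatalytic_motif(
    rates: Optional[Sequence[float]], rng, ms: Sequence[int] = (1, 2)
) -> FixtureBundle:
    """S1 ⇌ S2 with autocatalytic conversions S2+(m−1)S1 → mS1 for m in *ms*
    (the two-species family whose assembly yields the autocatalytic product
    forms).  m = 1 must be present so that S1 can be produced from x1 = 0."""
    if 1 not in ms:
        raise ValidationError("autocatalytic motif needs the m=1 reaction")
    k = tuple(rates) if rates is not None else random_rates(rng, 1 + len(ms))
    reactions = [Reaction(_cplx("S1"), _cplx("S2"), k[0])]
    for m, rate in zip(ms, k[1:]):
        if m == 1:
            reactions.append(Reaction(_cplx("S2"), _cplx("S1"), rate))
        else:
            reactions.append(
                Reaction(_cplx(f"S2 + {m - 1} S1"), _cplx(f"{m} S1"), rate)
            )
    return FixtureBundle(
        name="autocatalytic_motif",
        network=ReactionNetwork.build(reactions, species=("S1", "S2")),
        truth={"essential": True, "conservative": True, "ms": tuple(ms), "rates": k},
    )


def _autocatalytic_join(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """Five species: the four-species autocatalytic-type part
    S1 ⇌ S2 ⇌ S3 ⇌ S4, S1+S2 → 2S2, S2+S3 → 2S2, 2S4 ⇌ S3+S4 joined with
    3S3 ⇌ 3S5.  The default rates satisfy the affine-proportionality
    condition that makes the S2-functions of the two inner autocatalytic
    motifs match (κ_{S1→S2}/κ_{S1+S2→2S2} = κ_{S3→S2}/κ_{S2+S3→2S2})."""
    if rates is None:
        base = random_rates(rng, 9)
        # reactions: S1->S2, S2->S1, S1+S2->2S2 | S2->S3, S3->S2, S2+S3->2S2
        #            | S3<->S4, 2S4<->S3+S4     | 3S3<->3S5
        a12, a21, c1 = base[0], base[1], base[2]
        b23 = base[3]
        c2 = base[4]
        b32 = a12 / c1 * c2  # enforce a12/c1 == b32/c2
        rest = random_rates(rng, 6)
        rates = (a12, a21, c1, b23, b32, c2) + rest
    k = tuple(rates)
    if len(k) != 12:
        raise ValidationError("autocatalytic_join needs 12 rates")
    reactions = (
        _rev("S1", "S2", k[0], k[1])[:1]
        + [Reaction(_cplx("S2"), _cplx("S1"), k[1])]
        + [Reaction(_cplx("S1 + S2"), _cplx("2 S2"), k[2])]
        + _rev("S2", "S3", k[3], k[4])
        + [Reaction(_cplx("S2 + S3"), _cplx("2 S2"), k[5])]
        + _rev("S3", "S4", k[6], k[7])
        + _rev("2 S4", "S3 + S4", k[8], k[9])
        + _rev("3 S3", "3 S5", k[10], k[11])
    )
    network = ReactionNetwork.build(
        reactions, species=("S1", "S2", "S3", "S4", "S5")
    )
    return FixtureBundle(
        name="autocatalytic_join",
        network=network,
        truth={
            "essential": True,
            "conservative": True,
            "matched": math.isclose(k[0] / k[2], k[4] / k[5]),
            "rates": k,
        },
    )


def _open_motif_branches(rates: Optional[Sequence[float]], rng) -> FixtureBundle:
    """Two motif-plus-birth-death branches glued on S1:
    S1 ⇌ S2 ⇌ ∅, 2S1 ⇌ S1+S2 and S1 ⇌ S3 ⇌ ∅, 2S1 ⇌ S1+S3.  Assembly
    requires the S1-functions of the two branches to be proportional, which
    holds only for matched parameters (no conservation law, so no free tilt)."""
    if rates is None:
        first = random_rates(rng, 6)
        scale = float(np.exp(rng.uniform(math.log(0.5), math.log(2.0))))
        # matched by default: proportional motif rates and equal birth-death ratio
        second = tuple(scale * v for v in first[:4]) + first[4:6]
        rates = first + second
    k = tuple(rates)
    if len(k) != 12:
        raise ValidationError("open_motif_branches needs 12 rates")
    reactions = (
        _motif_reactions("S1", "S2", k[:4])
        + [
            Reaction(_cplx("S2"), _cplx("0"), k[4]),
            Reaction(_cplx("0"), _cplx("S2"), k[5]),
        ]
        + _motif_reactions("S1", "S3", k[6:10])
        + [
            Reaction(_cplx("S3"), _cplx("0"), k[10]),
            Reaction(_cplx("0"), _cplx("S3"), k[11]),
        ]
    )
    return FixtureBundle(
        name="open_motif_branches",
        network=ReactionNetwork.build(reactions, species=("S1", "S2", "S3")),
        truth={"essential": True, "conservative": False, "rates": k},
    )


# ---------------------------------------------------------------------------
# random families
# ---------------------------------------------------------------------------

def _motif_chain(
    rates, rng, length: int = 3, kinetics: KineticsSpec | None = None
) -> FixtureBundle:
    """*length* motifs A_t ⇌ Hub, 2A_t ⇌ A_t+Hub glued at the shared hub
    species (the rate-independent assembly family): conservative, essential,
    with product form f_hub = 1/x! and the motif factor for each A_t."""
    if length < 1:
        raise ValidationError("motif_chain needs length >= 1")
    k = tuple(rates) if rates is not None else random_rates(rng, 4 * length)
    if len(k) != 4 * length:
        raise ValidationError(f"motif_chain needs {4 * length} rates")
    reactions: list[Reaction] = []
    functions = {"Hub": ProductFormFunction.poisson(1.0)}
    parts = []
    for t in range(length):
        name = f"A{t + 1}"
        block = k[4 * t: 4 * t + 4]
        reactions.extend(_motif_reactions(name, "Hub", block))
        f_a, _ = motif_product_form(*block)
        functions[name] = f_a
        parts.append(frozenset(range(4 * t, 4 * t + 4)))
    species = tuple(f"A{t + 1}" for t in range(length)) + ("Hub",)
    return FixtureBundle(
        name="motif_chain",
        network=ReactionNetwork.build(reactions, species=species),
        kinetics=kinetics or KineticsSpec(),
        truth={
            "essential": True,
            "conservative": True,
            "part_reactions": tuple(parts),
            "functions": functions,
            "rates": k,
        },
    )


def _double_motif_shared_slow(rates, rng) -> FixtureBundle:
    """Two motifs glued through the rate-dependent species:
    S1 ⇌ S2, 2S1 ⇌ S1+S2 and S1 ⇌ S3, 2S1 ⇌ S1+S3 with the second block's
    rates proportional to the first's.  Matched by construction; perturbing
    a single rate of the second block breaks the proportionality hypothesis
    and assembly must refuse."""
    if rates is None:
        first = random_rates(rng, 4)
        scale = float(np.exp(rng.uniform(math.log(0.2), math.log(5.0))))
        rates = first + tuple(scale * v for v in first)
    k = tuple(rates)
    if len(k) != 8:
        raise ValidationError("double_motif needs 8 rates")
    reactions = _motif_reactions("S1", "S2", k[:4]) + _motif_reactions(
        "S1", "S3", k[4:]
    )
    return FixtureBundle(
        name="double_motif_shared_slow",
        network=ReactionNetwork.build(reactions, species=("S1", "S2", "S3")),
        truth={
            "essential": True,
            "conservative": True,
            "part_reactions": (frozenset(range(4)), frozenset(range(4, 8))),
            "rates": k,
        },
    )


def _disjoint_union(rates, rng) -> FixtureBundle:
    """Two motifs on disjoint species sets: the stationary distribution of
    the union is the outer product of the parts'."""
    k = tuple(rates) if rates is not None else random_rates(rng, 8)
    reactions = _motif_reactions("A", "B", k[:4]) + _motif_reactions("C", "D", k[4:])
    return FixtureBundle(
        name="disjoint_union",
        network=ReactionNetwork.build(reactions, species=("A", "B", "C", "D")),
        truth={
            "essential": True,
            "conservative": True,
            "part_reactions": (frozenset(range(4)), frozenset(range(4, 8))),
            "rates": k,
        },
    )


def _glued_mixed(rates, rng) -> FixtureBundle:
    """A motif star joined with a complex-balanced exchange on the hub:
    motifs (A1,Hub), (A2,Hub) plus Hub ⇌ C."""
    k = tuple(rates) if rates is not None else random_rates(rng, 10)
    reactions = (
        _motif_reactions("A1", "Hub", k[:4])
        + _motif_reactions("A2", "Hub", k[4:8])
        + _rev("Hub", "C", k[8], k[9])
    )
    return FixtureBundle(
        name="glued_mixed",
        network=ReactionNetwork.build(
            reactions, species=("A1", "A2", "Hub", "C")
        ),
        truth={"essential": True, "conservative": True, "rates": k},
    )


_FACTORIES = {
    "double_motif_hub": _double_motif_hub,
    "autocatalytic_join": _autocatalytic_join,
    "open_motif_branches": _open_motif_branches,
    "detailed_balance_union": _detailed_balance_union,
    "transient_union": _transient_union,
    "gene_expression": _gene_expression,
    "source_chain": _source_chain,
    "motif_birth_death": _motif_birth_death,
    "birth_death": _birth_death,
    "triple_exchange": _triple_exchange,
    "autocatalytic_motif": _autocatalytic_motif,
    "motif_chain": _motif_chain,
    "double_motif_shared_slow": _double_motif_shared_slow,
    "disjoint_union": _disjoint_union,
    "glued_mixed": _glued_mixed,
}

FIXTURE_KINDS = tuple(sorted(_FACTORIES))


def generate_fixture(
    kind: str,
    seed: int | None = None,
    rates: Optional[Sequence[float]] = None,
    **params,
) -> FixtureBundle:
    """Build a named fixture; random choices are driven by *seed*.

    ``rates`` overrides the random rate draw (fixed-length per kind); other
    keyword parameters are kind-specific (``length`` for motif_chain, ``ms``
    for autocatalytic_motif, ``kinetics`` where rate laws apply).
    """
    if kind not in _FACTORIES:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; known: {', '.join(FIXTURE_KINDS)}"
        )
    rng = np.random.default_rng(0 if seed is None else seed)
    return _FACTORIES[kind](rates, rng, **params)
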