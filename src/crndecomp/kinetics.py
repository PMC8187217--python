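"""Per-species rate laws for general (non-mass-action) kinetics.

A rate law θ maps an integer copy number to a non-negative activity, with
θ(x) = 0 if and only if x ≤ 0.  Mass action is θ(x) = x.  The Hill laws use
the standard forms x^m/(k^m + x^m) and k1^m/(k2^m + x^m) for x ≥ 1 and are
clamped to 0 at x ≤ 0 so that the vanishing condition holds for all laws.
The transition intensity of a reaction with reactant ν is
κ · ∏_i ∏_{j=0..ν_i−1} θ_i(x_i − j), which reduces to the mass-action
falling factorial κ · x!/(x−ν)! when every θ_i is mass action.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

__all__ = [
    "RateLaw",
    "mass_action",
    "hill_type_I",
    "hill_type_II",
    "tabulated",
    "custom",
    "KineticsSpec",
    "parse_rate_law",
]


@dataclass(frozen=True)
class RateLaw:
    kind: str
    params: tuple = ()
    _fn: Callable[[int], float] | None = field(default=None, compare=False, repr=False)

    def __call__(self, x: int) -> float:
        if x <= 0:
            return 0.0
        if self.kind == "mass_action":
            return float(x)
        if self.kind == "hill_type_I":
            m, k = self.params
            return x**m / (k**m + x**m)
        if self.kind == "hill_type_II":
            m, k1, k2 = self.params
            return k1**m / (k2**m + x**m)
        if self.kind == "tabulated":
            values = self.params[0]
            return values[x - 1] if x <= len(values) else values[-1]
        return self._fn(x)  # type: ignore[misc]

    @property
    def is_mass_action(self) -> bool:
        return self.kind == "mass_action"

    def format(self) -> str:
        if self.kind == "mass_action":
            return "mass_action"
        if self.kind == "hill_type_I":
            return "hill1(m=%r, k=%r)" % self.params
        if self.kind == "hill_type_II":
            return "hill2(m=%r, k1=%r, k2=%r)" % self.params
        if self.kind == "tabulated":
            return "table(%s)" % ",".join(repr(v) for v in self.params[0])
        return "custom"


def mass_action() -> RateLaw:
    return RateLaw("mass_action")


def hill_type_I(m: int, k: float) -> RateLaw:
    if m < 1 or k <= 0:
        raise ValueError("hill_type_I needs m >= 1 and k > 0")
    return RateLaw("hill_type_I", (int(m), float(k)))


def hill_type_II(m: int, k1: float, k2: float) -> RateLaw:
    if m < 1 or k1 <= 0 or k2 <= 0:
        raise ValueError("hill_type_II needs m >= 1 and k1, k2 > 0")
    return RateLaw("hill_type_II", (int(m), float(k1), float(k2)))


def tabulated(values: Sequence[float]) -> RateLaw:
    """θ given by a table for x = 1..len(values); constant beyond the table."""
    vals = tuple(float(v) for v in values)
    if not vals or any(v <= 0 for v in vals):
        raise ValueError("tabulated values must be positive")
    return RateLaw("tabulated", (vals,))


def custom(fn: Callable[[int], float]) -> RateLaw:
    """Wrap an arbitrary θ; the x ≤ 0 clamp is applied on top of *fn*."""
    return RateLaw("custom", (id(fn),), _fn=fn)


_MASS_ACTION = mass_action()


@dataclass(frozen=True)
class KineticsSpec:
    """Assignment of a rate law to each species (mass action by default)."""

    laws: Mapping[str, RateLaw] = field(default_factory=dict)

    def theta(self, species: str) -> RateLaw:
        return self.laws.get(species, _MASS_ACTION)

    @property
    def is_mass_action(self) -> bool:
        return all(law.is_mass_action for law in self.laws.values())

    def format_lines(self) -> list[str]:
        return [
            f"kinetics: {name} = {law.format()}"
            for name, law in sorted(self.laws.items())
            if not law.is_mass_action
        ]


_LAW_RE = {
    "hill1": (hill_type_I, ("m", "k")),
    "hill2": (hill_type_II, ("m", "k1", "k2")),
}


def parse_rate_law(text: str) -> RateLaw:
    """Parse ``mass_action``, ``hill1(m=1, k=2)``, ``hill2(...)`` or ``table(...)``."""
    text = text.strip()
    if text == "mass_action":
        return mass_action()
    import re

    match = re.match(r"^(\w+)\((.*)\)$", text)
    if not match:
        raise ValueError(f"cannot parse rate law {text!r}")
    name, args = match.group(1), match.group(2)
    if name == "table":
        return tabulated([float(v) for v in args.split(",")])
    if name not in _LAW_RE:
        raise ValueError(f"unknown rate law {name!r}")
    factory, keys = _LAW_RE[name]
    kwargs = {}
    for item in args.split(","):
        key, value = (part.strip() for part in item.split("="))
        kwargs[key] = float(value)
    if set(kwargs) != set(keys):
        raise ValueError(f"rate law {name!r} needs parameters {keys}")
    if "m" in kwargs:
        kwargs["m"] = int(kwargs["m"])
    return factory(**kwargs)
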