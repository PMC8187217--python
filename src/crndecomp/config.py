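"""Numerical tolerances and exploration caps.

All decision thresholds used by the solvers live here so that they can be
overridden from a config file or from CLI flags.  The config file format is
plain ``key = value`` lines (``#`` comments allowed); keys are the field
names of :class:`Settings`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class Settings:
    #: acceptable max-norm residual of pi*Q on a direct master-equation solve
    master_residual: float = 1e-10
    #: residual tolerance for generalized-balance verification
    balance_residual: float = 1e-9
    #: relative tolerance for proportionality of shared-species product factors
    proportionality_rtol: float = 1e-10
    #: max log-residual below which a least-squares factorization counts as
    #: product form
    factorization_residual: float = 1e-8
    #: consistency tolerance of the tilt-matching linear system
    matching_residual: float = 1e-8
    #: margin added to the seed's largest coordinate when a network is not
    #: conservative and no explicit exploration bound is given
    bound_margin: int = 10
    #: hard cap on the number of states any breadth-first exploration may visit
    max_states: int = 200_000
    #: component size above which the direct solver switches from a dense to a
    #: sparse factorization
    dense_solver_limit: int = 2000
    #: exhaustive bipartition enumeration is refused above this reaction count
    max_reactions_exhaustive: int = 16

    def replace(self, **kw) -> "Settings":
        return dataclasses.replace(self, **kw)


DEFAULT = Settings()

_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(Settings)}


def load_settings(path: str | Path, base: Settings | None = None) -> Settings:
    """Read ``key = value`` overrides from *path* on top of *base*."""
    overrides = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config key: {key!r}")
        kind = _FIELD_TYPES[key]
        overrides[key] = int(value) if kind in ("int", int) else float(value)
    return (base or DEFAULT).replace(**overrides)
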