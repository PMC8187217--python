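"""Network-file loading/saving with kinetics blocks, plus JSON helpers.

The reaction-list text format is parsed by :func:`crndecomp.network.parse_network`;
this module adds the optional ``kinetics: SPECIES = law(...)`` lines and the
round-trip writer.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

from .errors import CRNParseError
from .kinetics import KineticsSpec, parse_rate_law
from .network import ReactionNetwork, parse_network, write_network

__all__ = ["load_network_text", "load_network_file", "save_network_file", "network_to_json_str"]

_KINETICS_RE = re.compile(r"^kinetics:\s*([A-Za-z_]\w*)\s*=\s*(.+)$")


def load_network_text(text: str) -> tuple[ReactionNetwork, KineticsSpec]:
    """Parse a network file, returning (network, kinetics)."""
    network = parse_network(text)
    laws = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line.startswith("kinetics:"):
            continue
        match = _KINETICS_RE.match(line)
        if not match:
            raise CRNParseError("cannot parse kinetics line", lineno)
        name, law_text = match.groups()
        if name not in network.species:
            raise CRNParseError(f"kinetics for unknown species {name!r}", lineno)
        try:
            laws[name] = parse_rate_law(law_text)
        except ValueError as exc:
            raise CRNParseError(str(exc), lineno) from exc
    return network, KineticsSpec(laws)


def load_network_file(path: str | Path) -> tuple[ReactionNetwork, KineticsSpec]:
    return load_network_text(Path(path).read_text())


def save_network_file(
    path: str | Path, network: ReactionNetwork, kinetics: KineticsSpec | None = None
) -> None:
    text = write_network(network)
    if kinetics is not None:
        lines = kinetics.format_lines()
        if lines:
            text += "\n".join(lines) + "\n"
    Path(path).write_text(text)


def network_to_json_str(network: ReactionNetwork) -> str:
    return json.dumps(network.to_json(), indent=2)
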