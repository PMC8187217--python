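import numpy as np
import pytest

from crndecomp import (
    KineticsSpec,
    ReactionNetwork,
    generate_fixture,
    irreducible_component,
    parse_network,
)


@pytest.fixture
def double_motif_hub():
    """The three-species double-motif network with fixed distinct rates."""
    return generate_fixture("double_motif_hub", rates=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0))


@pytest.fixture
def simple_exchange():
    """S1 ⇌ S2 with equal unit rates."""
    return parse_network("S1 <-> S2 ; rates=1,1")


def binomial_probs(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom(n, p).pmf(np.arange(n + 1))
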