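import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ccanet.io_formats import (
    MUTATED,
    NOT_SEQUENCED,
    WILDTYPE,
    MutationMatrix,
    SignalingLink,
    SignalingNetwork,
)
from ccanet.network import CCANetwork


@pytest.fixture
def tiny_matrix() -> MutationMatrix:
    """4 samples x 2 genes, all co-sequenced; A mutated in s1,s2; B in s1,s3."""
    data = np.array(
        [
            [MUTATED, MUTATED],
            [MUTATED, WILDTYPE],
            [WILDTYPE, MUTATED],
            [WILDTYPE, WILDTYPE],
        ],
        dtype=np.int8,
    )
    return MutationMatrix(["s1", "s2", "s3", "s4"], ["A", "B"], data)


@pytest.fixture
def masked_matrix() -> MutationMatrix:
    """Same as tiny_matrix but s4 not sequenced for B."""
    data = np.array(
        [
            [MUTATED, MUTATED],
            [MUTATED, WILDTYPE],
            [WILDTYPE, MUTATED],
            [WILDTYPE, NOT_SEQUENCED],
        ],
        dtype=np.int8,
    )
    return MutationMatrix(["s1", "s2", "s3", "s4"], ["A", "B"], data)


@pytest.fixture
def triangle_network() -> CCANetwork:
    net = CCANetwork()
    net.add_edge("a", "b", relation="co")
    net.add_edge("b", "c", relation="co")
    net.add_edge("a", "c", relation="anti")
    return net


@pytest.fixture
def paper_composition_signaling() -> SignalingNetwork:
    """Signaling fixture with the reference per-type link counts
    (2,403 activation / 741 repression / 1,915 physical / 30 unknown)."""
    links = []
    counts = {"activation": 2403, "repression": 741, "physical": 1915, "unknown": 30}
    i = 0
    for link_type, n in counts.items():
        for _ in range(n):
            links.append(SignalingLink(f"g{i}", f"g{i + 1}", link_type))
            i += 2
    return SignalingNetwork(links=links)
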