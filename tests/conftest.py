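import numpy as np
import pytest

from axoaxonic.connectome import (
    ConnectionRecord,
    ConnectomeTable,
    NeuronClass,
    NeuronRecord,
    Transmitter,
)
from axoaxonic.synth import GeneratorConfig, generate


def make_table(neurons, connections):
    """neurons: (id, class, type, transmitter, side) tuples; connections: (pre, post, w)."""
    return ConnectomeTable(
        neurons=[
            NeuronRecord(i, NeuronClass(c), t, Transmitter(tr), s)
            for i, c, t, tr, s in neurons
        ],
        connections=[ConnectionRecord(*c) for c in connections],
    )


@pytest.fixture
def toy_table():
    """Five neurons, five connections: one weak edge, one edge onto an
    unknown-transmitter neuron, three clean strong edges."""
    return make_table(
        [
            (1, "DN", "DNa01", "acetylcholine", "L"),
            (2, "DN", "DNa01", "acetylcholine", "R"),
            (3, "DN", "DNb02", "gaba", "L"),
            (4, "AN", "AN01", "glutamate", "R"),
            (5, "IN", "IN01", "unknown", "L"),
        ],
        [
            (1, 2, 5),    # below strength
            (1, 5, 10),   # unknown transmitter on post
            (1, 3, 10),
            (3, 2, 8),
            (4, 1, 6),
        ],
    )


@pytest.fixture(scope="session")
def synth_default():
    """Default synthetic connectome, seed 1, with its ground truth."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def synth_table(synth_default):
    return synth_default[0]


@pytest.fixture(scope="session")
def synth_truth(synth_default):
    return synth_default[1]


@pytest.fixture(scope="session")
def synth_model(synth_default):
    from axoaxonic.lif import build_network

    table, truth = synth_default
    return build_network(table, gf_ids=truth.hub_ids)
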