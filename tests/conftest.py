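import pytest

from synrisk import (
    ConditionalTable,
    DiscreteNetwork,
    NetworkStructure,
    Variable,
)


def make_network(variables, edges, cpts):
    """Build a network from (name, levels), edge pairs, and {var: rows} CPTs."""
    vs = tuple(Variable(n, tuple(ls)) for n, ls in variables)
    structure = NetworkStructure(vs, tuple(edges))
    tables = {
        name: ConditionalTable(name, structure.parents(name), rows)
        for name, rows in cpts.items()
    }
    return DiscreteNetwork(structure, tables)


@pytest.fixture
def chain_ab():
    """A -> B with P(A=1)=0.5, P(B=1|A=1)=0.8, P(B=1|A=0)=0.2."""
    return make_network(
        [("A", ("0", "1")), ("B", ("0", "1"))],
        [("A", "B")],
        {
            "A": {(): {"0": 0.5, "1": 0.5}},
            "B": {
                ("0",): {"0": 0.8, "1": 0.2},
                ("1",): {"0": 0.2, "1": 0.8},
            },
        },
    )


@pytest.fixture
def diamond():
    """A -> B, A -> C, B -> D, C -> D with asymmetric CPTs."""
    return make_network(
        [(n, ("0", "1")) for n in "ABCD"],
        [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")],
        {
            "A": {(): {"0": 0.7, "1": 0.3}},
            "B": {("0",): {"0": 0.9, "1": 0.1}, ("1",): {"0": 0.4, "1": 0.6}},
            "C": {("0",): {"0": 0.6, "1": 0.4}, ("1",): {"0": 0.25, "1": 0.75}},
            "D": {
                ("0", "0"): {"0": 0.95, "1": 0.05},
                ("0", "1"): {"0": 0.7, "1": 0.3},
                ("1", "0"): {"0": 0.5, "1": 0.5},
                ("1", "1"): {"0": 0.1, "1": 0.9},
            },
        },
    )
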