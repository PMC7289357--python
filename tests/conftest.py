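import random

import pytest

from goslice.obo import parse_obo

# Seven-term ontology exercising all three scoping relations.  After scope
# inversion of "A has_part D", every edge points child -> parent:
#   B,C,D are children of A; E under B; F under C; G under D.
SEVEN_TERM_OBO = """\
format-version: 1.2
data-version: test/seven-terms

[Term]
id: GO:000A
name: alpha compartment
namespace: cellular_component
def: "The broadest test compartment." []
relationship: has_part GO:000D

[Term]
id: GO:000B
name: beta compartment
namespace: cellular_component
def: "A kind of alpha." []
is_a: GO:000A ! alpha compartment

[Term]
id: GO:000C
name: gamma compartment
namespace: cellular_component
def: "A part of alpha." []
relationship: part_of GO:000A

[Term]
id: GO:000D
name: delta compartment
namespace: cellular_component
def: "Part of some alpha." []

[Term]
id: GO:000E
name: epsilon compartment
namespace: cellular_component
def: "A kind of beta." []
is_a: GO:000B

[Term]
id: GO:000F
name: zeta compartment
namespace: cellular_component
def: "A kind of gamma." []
is_a: GO:000C

[Term]
id: GO:000G
name: eta compartment
namespace: cellular_component
def: "A kind of delta." []
is_a: GO:000D
"""

A, B, C, D, E, F, G = (f"GO:000{x}" for x in "ABCDEFG")


@pytest.fixture
def seven_graph():
    return parse_obo(SEVEN_TERM_OBO)


def random_dag_obo(n_nodes: int, edge_prob: float, seed: int,
                   has_part_prob: float = 0.0) -> str:
    """OBO text for a random DAG: edges only from higher to lower index,
    so acyclicity holds by construction.  ``has_part_prob`` of the edges
    are stated scope-inverted in the parent stanza."""
    rng = random.Random(seed)
    ids = [f"T:{i:04d}" for i in range(n_nodes)]
    extra_lines: dict = {i: [] for i in range(n_nodes)}
    for child in range(1, n_nodes):
        for parent in range(child):
            if rng.random() >= edge_prob:
                continue
            r = rng.random()
            if r < has_part_prob:
                extra_lines[parent].append(
                    f"relationship: has_part {ids[child]}"
                )
            elif r < 0.5 + has_part_prob / 2:
                extra_lines[child].append(f"is_a: {ids[parent]}")
            else:
                extra_lines[child].append(
                    f"relationship: part_of {ids[parent]}"
                )
    chunks = ["format-version: 1.2", ""]
    for i, tid in enumerate(ids):
        chunks.append("[Term]")
        chunks.append(f"id: {tid}")
        chunks.append(f"name: node {i}")
        chunks.extend(extra_lines[i])
        chunks.append("")
    return "\n".join(chunks)
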