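import numpy as np
import pytest

from ontothresh import (
    ContributionWeights,
    OntologyGraph,
    build_corpus,
    compute_ic,
)

# TOY ontology: R is the root, A and B are children of R, C is a child of A;
# all edges is_a.  Used throughout for hand-derivable expectations.
TOY_EDGES = [("A", "R", "is_a"), ("B", "R", "is_a"), ("C", "A", "is_a")]

TOY_OBO = """\
format-version: 1.2

[Term]
id: R
name: root

[Term]
id: A
name: alpha
is_a: R

[Term]
id: B
name: beta
is_a: R

[Term]
id: C
name: gamma
is_a: A
"""


@pytest.fixture(scope="session")
def toy_graph() -> OntologyGraph:
    return OntologyGraph.from_edges(TOY_EDGES)


@pytest.fixture(scope="session")
def weights() -> ContributionWeights:
    return ContributionWeights()


@pytest.fixture(scope="session")
def toy_corpus(toy_graph):
    # four genes: g1->C, g2->A, g3->B, g4->B; propagated counts R=4 A=2 B=2 C=1
    return build_corpus(
        {"g1": {"C"}, "g2": {"A"}, "g3": {"B"}, "g4": {"B"}}, toy_graph
    )


@pytest.fixture(scope="session")
def toy_ic(toy_corpus):
    return compute_ic(toy_corpus)


def random_dag(
    rng: np.random.Generator,
    n_terms: int,
    max_parents: int = 3,
    relations=("is_a", "part_of", "regulates"),
) -> OntologyGraph:
    """Small random rooted DAG for oracle comparisons."""
    edges = []
    for i in range(1, n_terms):
        n_par = int(rng.integers(1, max_parents + 1))
        for p in rng.choice(i, size=min(n_par, i), replace=False):
            edges.append((f"T{i}", f"T{int(p)}", relations[int(rng.integers(0, len(relations)))]))
    return OntologyGraph.from_edges(edges, terms=["T0"])


def random_annotations(
    rng: np.random.Generator, graph: OntologyGraph, n_genes: int, k: int = 3
) -> dict[str, set[str]]:
    terms = sorted(graph.terms)
    return {
        f"g{i}": {terms[int(j)] for j in rng.integers(0, len(terms), size=k)}
        for i in range(n_genes)
    }
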