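"""Term-level and set-level semantic similarity measures.

Four measures are provided:

* **Wang** — corpus-free hybrid measure.  The semantic contribution of an
  ancestor t to a target term A decays along each edge by the edge's
  contribution factor; S_A(t) takes the best (max-product) path.  The
  semantic value SV(A) sums the contributions of A's ancestor closure, and
  two terms are compared by the overlap of their contribution maps.  Gene
  level: the sum of best matches in both directions divided by m + n.
* **Lin** — IC-based node measure: 2·IC(t0) / (IC(t1) + IC(t2)) with t0 the
  most informative common ancestor.  Gene level: best-match average.
* **simUI** — Jaccard index of the ancestor closures of two term sets.
* **simGIC** — IC-weighted Jaccard of the ancestor closures.

Term-set inputs are a gene's *direct* annotations; closures are taken inside
each measure where its own construction requires them.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable

import networkx as nx

from .corpus import ICTable
from .errors import (
    EmptyAnnotationError,
    NamespaceMismatchError,
    UndefinedInformativenessError,
)
from .ontology import ContributionWeights, OntologyGraph, closure

TermSet = frozenset[str]
PairwiseSim = Callable[[str, str], float]


def semantic_contributions(
    graph: OntologyGraph, weights: ContributionWeights, a: str
) -> dict[str, float]:
    """Wang semantic contribution S_A(t) for every t in the ancestor closure of A.

    S_A(A) = 1 and, walking root-ward in topological order,
    S_A(t) = max over children t' of t inside the closure of w_e · S_A(t'),
    where w_e is the factor of the child -> parent edge e.
    """
    a = graph.resolve(a)
    anc = closure(graph, {a}, "ancestors")
    g = graph.nx_graph
    contrib: dict[str, float] = {a: 1.0}
    # child -> parent edges: topological order of the induced subgraph visits
    # every child before its parents.
    for t in nx.topological_sort(g.subgraph(anc)):
        if t == a:
            continue
        best = 0.0
        for child, _, rel in g.in_edges(t, keys=True):
            if child in contrib:
                w = weights[rel]
                cand = w * contrib[child]
                if cand > best:
                    best = cand
        contrib[t] = best
    return contrib


def semantic_value(contribs: dict[str, float]) -> float:
    """SV(A): sum of the semantic contributions of A and all its ancestors."""
    return sum(contribs.values())


class WangSimilarity:
    """Wang's measure with per-term contribution caching.

    Instances are callable on pairs of terms, and expose ``gene_sim`` for the
    m+n-weighted set-level formula.
    """

    def __init__(
        self, graph: OntologyGraph, weights: ContributionWeights | None = None
    ) -> None:
        self.graph = graph
        self.weights = weights or ContributionWeights()
        self._contrib: dict[str, dict[str, float]] = {}
        self._sv: dict[str, float] = {}
        self._pair: dict[tuple[str, str], float] = {}

    def contributions(self, a: str) -> dict[str, float]:
        a = self.graph.resolve(a)
        if a not in self._contrib:
            self._contrib[a] = semantic_contributions(self.graph, self.weights, a)
        return self._contrib[a]

    def sv(self, a: str) -> float:
        a = self.graph.resolve(a)
        if a not in self._sv:
            self._sv[a] = semantic_value(self.contributions(a))
        return self._sv[a]

    def term_sim(self, a: str, b: str) -> float:
        a, b = self.graph.resolve(a), self.graph.resolve(b)
        if not self.graph.same_namespace(a, b):
            raise NamespaceMismatchError(
                f"terms {a!r} and {b!r} belong to different namespaces"
            )
        key = (a, b) if a <= b else (b, a)
        if key not in self._pair:
            ca, cb = self.contributions(a), self.contributions(b)
            shared = ca.keys() & cb.keys()
            num = sum(ca[t] + cb[t] for t in shared)
            self._pair[key] = num / (self.sv(a) + self.sv(b))
        return self._pair[key]

    __call__ = term_sim

    def gene_sim(self, sg1: Iterable[str], sg2: Iterable[str]) -> float:
        """Sum of directional best matches over (m + n) terms."""
        s1, s2 = list(sg1), list(sg2)
        if not s1 or not s2:
            raise EmptyAnnotationError("gene similarity requires two non-empty term sets")
        total = sum(max(self.term_sim(a, b) for b in s2) for a in s1)
        total += sum(max(self.term_sim(b, a) for a in s1) for b in s2)
        return total / (len(s1) + len(s2))


def wang_term_sim(
    graph: OntologyGraph, weights: ContributionWeights, a: str, b: str
) -> float:
    return WangSimilarity(graph, weights).term_sim(a, b)


def wang_gene_sim(
    graph: OntologyGraph,
    weights: ContributionWeights,
    sg1: Iterable[str],
    sg2: Iterable[str],
) -> float:
    return WangSimilarity(graph, weights).gene_sim(sg1, sg2)


def mica(
    graph: OntologyGraph,
    informativeness: Callable[[str], float],
    t: str,
    s: Iterable[str],
) -> str | None:
    """Most informative common ancestor of term ``t`` and term set ``s``.

    Ancestors are taken inclusively on both sides.  Ties break toward the
    lexicographically smallest identifier; ``None`` if nothing is shared.
    """
    common = closure(graph, {t}, "ancestors") & closure(graph, s, "ancestors")
    if not common:
        return None
    return max(sorted(common), key=informativeness)


def lin_term_sim(ic: ICTable, graph: OntologyGraph, t1: str, t2: str) -> float:
    """Lin similarity 2·IC(t0) / (IC(t1) + IC(t2)); t0 the IC-maximal common ancestor."""
    t1, t2 = graph.resolve(t1), graph.resolve(t2)
    if not graph.same_namespace(t1, t2):
        raise NamespaceMismatchError(
            f"terms {t1!r} and {t2!r} belong to different namespaces"
        )
    denom = ic[t1] + ic[t2]
    if denom == 0.0:
        # both terms are the root: identical, maximally similar by convention
        return 1.0
    t0 = mica(graph, lambda t: ic.get(t, 0.0) or 0.0, t1, {t2})
    if t0 is None or t0 not in ic:
        return 0.0
    return 2.0 * ic[t0] / denom


class LinSimilarity:
    """Lin's term measure lifted to genes by best-match average."""

    def __init__(self, graph: OntologyGraph, ic: ICTable, pooled: bool = False) -> None:
        self.graph = graph
        self.ic = ic
        self.pooled = pooled
        self._pair: dict[tuple[str, str], float] = {}

    def term_sim(self, a: str, b: str) -> float:
        a, b = self.graph.resolve(a), self.graph.resolve(b)
        key = (a, b) if a <= b else (b, a)
        if key not in self._pair:
            self._pair[key] = lin_term_sim(self.ic, self.graph, a, b)
        return self._pair[key]

    __call__ = term_sim

    def gene_sim(self, sg1: Iterable[str], sg2: Iterable[str]) -> float:
        return bma_gene_sim(self.term_sim, sg1, sg2, pooled=self.pooled)


def bma_gene_sim(
    term_sim: PairwiseSim,
    sg1: Iterable[str],
    sg2: Iterable[str],
    pooled: bool = False,
) -> float:
    """Best-match average of a pairwise term similarity over two term sets.

    Default: mean of the two directional best-match means.  With
    ``pooled=True``, all best matches from both directions are pooled into a
    single mean (the m+n-weighted variant); the two agree when m = n.
    """
    s1, s2 = list(sg1), list(sg2)
    if not s1 or not s2:
        raise EmptyAnnotationError("best-match average requires two non-empty term sets")
    best12 = [max(term_sim(a, b) for b in s2) for a in s1]
    best21 = [max(term_sim(b, a) for a in s1) for b in s2]
    if pooled:
        return (sum(best12) + sum(best21)) / (len(s1) + len(s2))
    return 0.5 * (sum(best12) / len(s1) + sum(best21) / len(s2))


def simui(graph: OntologyGraph, sg1: Iterable[str], sg2: Iterable[str]) -> float:
    """Jaccard index of the ancestor closures of the two term sets."""
    s1, s2 = set(sg1), set(sg2)
    if not s1 or not s2:
        raise EmptyAnnotationError("simUI requires two non-empty term sets")
    c1 = closure(graph, s1, "ancestors")
    c2 = closure(graph, s2, "ancestors")
    return len(c1 & c2) / len(c1 | c2)


def simgic(
    graph: OntologyGraph, ic: ICTable, sg1: Iterable[str], sg2: Iterable[str]
) -> float:
    """IC-weighted Jaccard of the ancestor closures of the two term sets."""
    s1, s2 = set(sg1), set(sg2)
    if not s1 or not s2:
        raise EmptyAnnotationError("simGIC requires two non-empty term sets")
    c1 = closure(graph, s1, "ancestors")
    c2 = closure(graph, s2, "ancestors")
    union_ic = sum(ic[t] for t in c1 | c2)
    if union_ic == 0.0:
        # closures carry no information at all; identical sets by convention
        return 1.0 if c1 == c2 else 0.0
    return sum(ic[t] for t in c1 & c2) / union_ic


def gene_similarity_function(
    measure: str,
    graph: OntologyGraph,
    *,
    weights: ContributionWeights | None = None,
    ic: ICTable | None = None,
    pooled_bma: bool = False,
) -> Callable[[Iterable[str], Iterable[str]], float]:
    """Set-level similarity for one of ``wang | lin | simui | simgic``.

    Returns a callable on two direct-annotation term sets.  ``ic`` is
    required for the IC-based measures.
    """
    measure = measure.lower()
    if measure == "wang":
        return WangSimilarity(graph, weights).gene_sim
    if measure in ("lin", "simgic") and ic is None:
        raise UndefinedInformativenessError(
            f"measure {measure!r} needs an IC table; provide an annotation corpus"
        )
    if measure == "lin":
        return LinSimilarity(graph, ic, pooled=pooled_bma).gene_sim
    if measure == "simui":
        return lambda s1, s2: simui(graph, s1, s2)
    if measure == "simgic":
        return lambda s1, s2: simgic(graph, ic, s1, s2)
    raise ValueError(f"unknown measure {measure!r}")
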