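"""Ontology DAG loading and traversal.

An :class:`OntologyGraph` wraps a :class:`networkx.MultiDiGraph` whose edges
run child -> parent and carry a relation kind (``is_a``, ``part_of``,
``regulates``, ...).  Each relation kind used in a semantic-value computation
must have a contribution factor in :class:`ContributionWeights`; relation
kinds without a factor are dropped at load time with a warning so that
arbitrary OBO files (GO, ChEBI, synthetic) load uniformly.

Multi-namespace ontologies such as GO are split on load: every computation
operates within a single namespace, and cross-namespace comparisons are
rejected downstream.
"""

from __future__ import annotations

import io
import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .errors import FormatError, IntegrityError, UnknownTermError

logger = logging.getLogger(__name__)

#: Default semantic contribution factors per relation kind.  0.8 for "is a",
#: 0.6 for "part of", and 0.7 for the whole "regulates" family.
DEFAULT_WEIGHTS: Mapping[str, float] = {
    "is_a": 0.8,
    "part_of": 0.6,
    "regulates": 0.7,
    "positively_regulates": 0.7,
    "negatively_regulates": 0.7,
}

#: Namespace label used when the ontology declares none (e.g. ChEBI).
DEFAULT_NAMESPACE = "default"


@dataclass(frozen=True)
class ContributionWeights:
    """Per-relation semantic contribution factors, each strictly in (0, 1)."""

    factors: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        for rel, w in self.factors.items():
            if not (0.0 < w < 1.0):
                raise ValueError(
                    f"contribution factor for {rel!r} must lie in (0, 1), got {w}"
                )

    def __getitem__(self, relation: str) -> float:
        return self.factors[relation]

    def __contains__(self, relation: str) -> bool:
        return relation in self.factors

    @classmethod
    def from_config(cls, overrides: Mapping[str, float]) -> "ContributionWeights":
        """Default factors with user overrides (config key ``contribution_weights``)."""
        merged = dict(DEFAULT_WEIGHTS)
        merged.update(overrides)
        return cls(merged)


class OntologyGraph:
    """A rooted, acyclic, relation-typed term DAG restricted to one namespace.

    Parameters
    ----------
    graph
        MultiDiGraph with child -> parent edges keyed by relation kind.
    aliases
        Mapping of alternate term identifiers to canonical ones.
    """

    def __init__(
        self,
        graph: nx.MultiDiGraph,
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise IntegrityError(
                f"ontology contains a cycle through term {cycle[0][0]!r}"
            )
        self._g = graph
        self.aliases: dict[str, str] = dict(aliases or {})

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],
        terms: Iterable[str] | None = None,
        namespace: str = DEFAULT_NAMESPACE,
        aliases: Mapping[str, str] | None = None,
    ) -> "OntologyGraph":
        """Build a graph from ``(child, parent, relation)`` triples.

        ``terms`` may add isolated terms not mentioned by any edge.
        """
        g = nx.MultiDiGraph()
        for t in terms or ():
            g.add_node(t, namespace=namespace)
        for child, parent, rel in edges:
            g.add_node(child, namespace=namespace)
            g.add_node(parent, namespace=namespace)
            g.add_edge(child, parent, key=rel)
        return cls(g, aliases=aliases)

    # -- queries -----------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self._g

    @property
    def nx_graph(self) -> nx.MultiDiGraph:
        return self._g

    def resolve(self, term: str) -> str:
        """Canonical identifier for ``term``, following alt_id aliases."""
        if term in self._g:
            return term
        if term in self.aliases:
            return self.aliases[term]
        raise UnknownTermError(f"unknown term {term!r}")

    def namespace(self, term: str) -> str:
        return self._g.nodes[self.resolve(term)].get("namespace", DEFAULT_NAMESPACE)

    def name(self, term: str) -> str | None:
        return self._g.nodes[self.resolve(term)].get("name")

    def parents(self, term: str) -> list[tuple[str, str]]:
        """Direct ``(parent, relation)`` pairs of ``term``."""
        t = self.resolve(term)
        return [(p, rel) for _, p, rel in self._g.out_edges(t, keys=True)]

    def children(self, term: str) -> list[tuple[str, str]]:
        """Direct ``(child, relation)`` pairs of ``term``."""
        t = self.resolve(term)
        return [(c, rel) for c, _, rel in self._g.in_edges(t, keys=True)]

    @property
    def roots(self) -> set[str]:
        return {t for t in self._g.nodes if self._g.out_degree(t) == 0}

    def edges(self) -> list[tuple[str, str, str]]:
        """All ``(child, parent, relation)`` triples."""
        return list(self._g.edges(keys=True))

    def same_namespace(self, *terms: str) -> bool:
        spaces = {self.namespace(t) for t in terms}
        return len(spaces) <= 1


def closure(graph: OntologyGraph, seed: Iterable[str], direction: str) -> set[str]:
    """Reflexive transitive closure of ``seed`` across every relation kind.

    ``direction`` is ``"ancestors"`` (root-ward) or ``"descendants"``
    (leaf-ward).  The result always includes the (resolved) seed terms.
    """
    if direction not in ("ancestors", "descendants"):
        raise ValueError(f"direction must be 'ancestors' or 'descendants', got {direction!r}")
    g = graph.nx_graph
    out: set[str] = set()
    for term in seed:
        t = graph.resolve(term)
        out.add(t)
        # edges run child -> parent, so nx.descendants follows them root-ward
        if direction == "ancestors":
            out |= nx.descendants(g, t)
        else:
            out |= nx.ancestors(g, t)
    return out


_OBSOLETE_RE = re.compile(r"^is_obsolete:\s*true", re.MULTILINE)


def load_obo(
    path: str,
    namespace_filter: str | None = None,
    weights: ContributionWeights | None = None,
) -> OntologyGraph:
    """Load an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are dropped (with a logged count); ``alt_id`` entries are
    recorded as aliases; edges whose relation kind has no contribution factor
    are dropped with a warning; if ``namespace_filter`` is given, the graph is
    restricted to terms of that namespace.
    """
    weights = weights or ContributionWeights()
    try:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        raw = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    except OSError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse OBO file {path!r}: {exc}") from exc

    n_obsolete = len(_OBSOLETE_RE.findall(text))
    if n_obsolete:
        logger.warning("dropped %d obsolete term(s) from %s", n_obsolete, path)

    g = nx.MultiDiGraph()
    aliases: dict[str, str] = {}
    for node, data in raw.nodes(data=True):
        ns = data.get("namespace", DEFAULT_NAMESPACE)
        if namespace_filter is not None and ns != namespace_filter:
            continue
        g.add_node(node, namespace=ns, name=data.get("name"))
        for alt in data.get("alt_id", []):
            aliases[alt] = node

    dropped_rel: dict[str, int] = {}
    for child, parent, rel in raw.edges(keys=True):
        if child not in g or parent not in g:
            continue  # cross-namespace link under a namespace filter
        if rel not in weights:
            dropped_rel[rel] = dropped_rel.get(rel, 0) + 1
            continue
        g.add_edge(child, parent, key=rel)
    for rel, n in dropped_rel.items():
        logger.warning(
            "dropped %d edge(s) of unweighted relation kind %r from %s", n, rel, path
        )

    if g.number_of_nodes() == 0:
        raise FormatError(
            f"OBO file {path!r} yielded no terms"
            + (f" in namespace {namespace_filter!r}" if namespace_filter else "")
        )
    aliases = {a: c for a, c in aliases.items() if c in g and a not in g}
    return OntologyGraph(g, aliases=aliases)
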