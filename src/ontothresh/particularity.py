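"""Semantic particularity of one annotation set with respect to another.

Par(Sg1, Sg2) quantifies the information Sg1 carries beyond Sg2, using a
pluggable term informativeness I (Wang semantic values or corpus IC):

* MPT(Sg1, Sg2) — most particular terms: members of Sg1 with no proper
  descendant in Sg1 and absent from the ancestor closure Sg2*.
* PI(Sg1, Sg2) = sum over tp in MPT of I(tp) - I(MICA(tp, Sg2)), the
  informativeness each particular term holds beyond its most informative
  ancestor shared with Sg2 (0 when nothing is shared).
* MCT(Sg1, Sg2) — most informative common terms, normalising PI.
* Par = PI / (PI + sum over MCT of I), an asymmetric score in [0, 1].

Two readings of MCT are available.  The default, ``"intersection"``, takes
the leaves of the shared sub-graph Sg1* ∩ Sg2*: it keeps MCT non-empty
whenever anything is shared, making Par continuous in shared content.  The
``"literal"`` variant additionally excludes any shared term with a
descendant in either full closure, which can empty MCT (and drive Par to 1)
for sets sharing only upper-level terms.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable
from dataclasses import dataclass

from .corpus import ICTable
from .errors import UndefinedInformativenessError
from .measures import WangSimilarity, mica
from .ontology import ContributionWeights, OntologyGraph, closure


@dataclass(frozen=True)
class ParticularityBreakdown:
    """Intermediate quantities of one Par(Sg1, Sg2) evaluation."""

    mpt: frozenset[str]
    mct: frozenset[str]
    pi: float
    par: float


def sv_informativeness(
    graph: OntologyGraph, weights: ContributionWeights | None = None
) -> Callable[[str], float]:
    """Wang semantic value as a cached term informativeness (I(root) = 1)."""
    return WangSimilarity(graph, weights).sv


def ic_informativeness(ic: ICTable) -> Callable[[str], float]:
    """Corpus IC as term informativeness (I(root) = 0); undefined terms raise."""
    return ic.__getitem__


def most_particular_terms(
    graph: OntologyGraph, sg1: Iterable[str], sg2: Iterable[str]
) -> frozenset[str]:
    """Terms of Sg1 with no proper descendant in Sg1 and not members of Sg2*."""
    s1 = {graph.resolve(t) for t in sg1}
    sg2_star = closure(graph, sg2, "ancestors")
    out = set()
    for t in s1:
        descendants_in_sg1 = (closure(graph, {t}, "descendants") - {t}) & s1
        if not descendants_in_sg1 and t not in sg2_star:
            out.add(t)
    return frozenset(out)


def most_informative_common_terms(
    graph: OntologyGraph,
    sg1: Iterable[str],
    sg2: Iterable[str],
    mode: str = "intersection",
) -> frozenset[str]:
    """Most informative terms shared by Sg1* and Sg2*.

    ``mode="intersection"`` (default): leaves of the shared sub-graph
    Sg1* ∩ Sg2*.  ``mode="literal"``: shared terms with no descendant in
    either full closure.
    """
    c1 = closure(graph, sg1, "ancestors")
    c2 = closure(graph, sg2, "ancestors")
    shared = c1 & c2
    if mode == "intersection":
        exclusion = shared
    elif mode == "literal":
        exclusion = c1 | c2
    else:
        raise ValueError(f"mode must be 'intersection' or 'literal', got {mode!r}")
    out = set()
    for t in shared:
        if not (closure(graph, {t}, "descendants") - {t}) & exclusion:
            out.add(t)
    return frozenset(out)


def particularity(
    graph: OntologyGraph,
    informativeness: Callable[[str], float],
    sg1: Iterable[str],
    sg2: Iterable[str],
    mct_mode: str = "intersection",
) -> ParticularityBreakdown:
    """Full Par(Sg1, Sg2) breakdown.  Asymmetric in its arguments."""
    s1 = {graph.resolve(t) for t in sg1}
    s2 = {graph.resolve(t) for t in sg2}
    mpt = most_particular_terms(graph, s1, s2)
    mct = most_informative_common_terms(graph, s1, s2, mode=mct_mode)

    def info(term: str) -> float:
        try:
            return informativeness(term)
        except KeyError as exc:
            raise UndefinedInformativenessError(
                f"informativeness undefined for term {term!r}"
            ) from exc

    pi = 0.0
    for tp in mpt:
        anchor = mica(graph, info, tp, s2)
        shared_info = info(anchor) if anchor is not None else 0.0
        # SV is not monotone on multi-parent DAGs: a shared ancestor can be
        # more informative than tp itself, in which case tp adds nothing
        pi += max(0.0, info(tp) - shared_info)
    common_info = sum(info(tc) for tc in mct)
    denom = pi + common_info
    par = pi / denom if denom > 0.0 else 0.0
    return ParticularityBreakdown(mpt=mpt, mct=mct, pi=pi, par=par)


class ParticularityMeasure:
    """Par with a fixed graph and informativeness, callable on set pairs."""

    def __init__(
        self,
        graph: OntologyGraph,
        informativeness: Callable[[str], float],
        mct_mode: str = "intersection",
    ) -> None:
        self.graph = graph
        self.informativeness = informativeness
        self.mct_mode = mct_mode

    def breakdown(self, sg1: Iterable[str], sg2: Iterable[str]) -> ParticularityBreakdown:
        return particularity(
            self.graph, self.informativeness, sg1, sg2, mct_mode=self.mct_mode
        )

    def __call__(self, sg1: Iterable[str], sg2: Iterable[str]) -> float:
        return self.breakdown(sg1, sg2).par
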