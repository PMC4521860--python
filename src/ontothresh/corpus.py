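"""Annotation corpora and information content.

A gene annotated to a term is implicitly annotated to every ancestor of that
term (the true-path rule), so term frequencies are propagated root-ward
before computing probabilities.  The information content of a term is the
negative natural log of its annotation probability,

    IC(t) = -ln( term_count[t] / total ),

where ``total`` is the number of genes annotated in the namespace (equal to
the count at the namespace root).  Terms that annotate no gene have *no* IC:
they are absent from the table, and any measure that touches one raises
:class:`~ontothresh.errors.UndefinedInformativenessError` rather than
silently smoothing.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .errors import EmptyCorpusError, FormatError, UndefinedInformativenessError, UnknownTermError
from .ontology import OntologyGraph, closure

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCorpus:
    """Direct gene annotations plus root-ward propagated term frequencies."""

    gene_terms: dict[str, set[str]]
    term_count: dict[str, int]
    total: int
    skipped_rows: int = 0

    def terms_of(self, gene: str) -> set[str]:
        try:
            return self.gene_terms[gene]
        except KeyError:
            raise UnknownTermError(f"gene {gene!r} has no annotations in the corpus")


class ICTable:
    """Term -> information content (nats).  Missing terms raise a described error."""

    def __init__(self, values: Mapping[str, float]) -> None:
        self._values = dict(values)

    def __getitem__(self, term: str) -> float:
        try:
            return self._values[term]
        except KeyError:
            raise UndefinedInformativenessError(
                f"term {term!r} annotates no gene in the corpus; its IC is undefined"
            )

    def __contains__(self, term: str) -> bool:
        return term in self._values

    def __len__(self) -> int:
        return len(self._values)

    def get(self, term: str, default: float | None = None) -> float | None:
        return self._values.get(term, default)

    def items(self):
        return self._values.items()


def build_corpus(
    gene_terms: Mapping[str, Iterable[str]], graph: OntologyGraph
) -> AnnotationCorpus:
    """Propagate direct annotations root-ward and count genes per term.

    A gene annotated to t counts once for t and once for each ancestor of t,
    regardless of how many of its direct terms share that ancestor.
    """
    counts: dict[str, int] = {}
    cleaned: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        direct = {graph.resolve(t) for t in terms}
        if not direct:
            continue
        cleaned[gene] = direct
        for t in closure(graph, direct, "ancestors"):
            counts[t] = counts.get(t, 0) + 1
    if not cleaned:
        raise EmptyCorpusError("no gene has any resolvable annotation")
    return AnnotationCorpus(gene_terms=cleaned, term_count=counts, total=len(cleaned))


def _parse_gaf_line(fields: list[str]) -> tuple[str, str, str, str] | None:
    # GAF 2.x columns (1-based): 2 object id, 4 qualifier, 5 term, 7 evidence
    if len(fields) < 7:
        return None
    return fields[1], fields[3], fields[4], fields[6]


def load_annotations(
    path: str,
    graph: OntologyGraph,
    evidence_filter: set[str] | None = None,
) -> AnnotationCorpus:
    """Read a GAF 2.x file or a two-column ``gene<TAB>term`` TSV.

    NOT-qualified rows are dropped; rows failing the evidence allow-list are
    dropped; rows whose term does not resolve in the graph are skipped with a
    warning (the skip count is reported on the corpus).
    """
    gene_terms: dict[str, set[str]] = {}
    skipped = 0
    is_gaf: bool | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                if line.startswith("!gaf-version"):
                    is_gaf = True
                continue
            fields = line.split("\t")
            if is_gaf is None:
                is_gaf = len(fields) >= 7
            if is_gaf:
                parsed = _parse_gaf_line(fields)
                if parsed is None:
                    raise FormatError(f"malformed GAF row in {path!r}: {line[:80]!r}")
                gene, qualifier, term, evidence = parsed
                if "NOT" in qualifier.split("|"):
                    continue
                if evidence_filter is not None and evidence not in evidence_filter:
                    continue
            else:
                if len(fields) != 2:
                    raise FormatError(f"expected 2-column TSV in {path!r}: {line[:80]!r}")
                gene, term = fields
            try:
                term = graph.resolve(term)
            except UnknownTermError:
                skipped += 1
                continue
            gene_terms.setdefault(gene, set()).add(term)
    if skipped:
        logger.warning("skipped %d row(s) of %s with unknown terms", skipped, path)
    if not gene_terms:
        raise EmptyCorpusError(f"no annotation rows survived parsing of {path!r}")
    corpus = build_corpus(gene_terms, graph)
    corpus.skipped_rows = skipped
    return corpus


def compute_ic(corpus: AnnotationCorpus) -> ICTable:
    """IC(t) = -ln(term_count[t] / total) for every term with a positive count."""
    if corpus.total <= 0:
        raise EmptyCorpusError("corpus has no annotated genes")
    total = float(corpus.total)
    return ICTable(
        {t: -math.log(c / total) for t, c in corpus.term_count.items() if c > 0}
    )
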