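"""Download-free synthetic fixtures: ontologies, corpora and gene groups.

The generator emulates the calibration setting: a rooted, relation-typed
term DAG stands in for an ontology namespace, and groups of genes stand in
for families of functionally similar genes.  Each group is anchored to its
own "home" sub-DAG (a term and its descendants, pairwise disjoint across
groups), and each gene draws its annotation terms from the home sub-DAG
with probability ``coherence`` and uniformly from the whole ontology
otherwise.  High coherence therefore plants a real separation between
intra-group and inter-group similarity, while low coherence collapses it —
exercising the Welch gate's rejection path.

Everything is deterministic under a single integer seed driving one
pseudo-random stream.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .corpus import AnnotationCorpus, build_corpus
from .errors import ConfigurationError
from .ontology import DEFAULT_NAMESPACE, OntologyGraph, closure

#: Relation-kind proportions loosely patterned on GO's edge composition.
DEFAULT_RELATION_MIX: Mapping[str, float] = {
    "is_a": 0.80,
    "part_of": 0.12,
    "regulates": 0.04,
    "positively_regulates": 0.02,
    "negatively_regulates": 0.02,
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic ontology / corpus / group generator.

    Defaults describe the standard calibration scenario used throughout the
    test surface: a 300-term DAG, six groups of ten genes, coherence 0.9.
    """

    n_terms: int = 300
    max_parents: int = 3
    relation_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATION_MIX)
    )
    n_groups: int = 6
    genes_per_group: int = 10
    coherence: float = 0.9
    terms_per_gene: tuple[int, int] = (3, 8)
    min_home_size: int = 6
    extra_parent_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ConfigurationError("n_terms must be at least 1")
        if self.n_terms < self.n_groups:
            raise ConfigurationError("need at least one term per group")
        if not (0.0 <= self.coherence <= 1.0):
            raise ConfigurationError("coherence must lie in [0, 1]")
        if self.max_parents < 1:
            raise ConfigurationError("max_parents must be at least 1")
        lo, hi = self.terms_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("terms_per_gene must be a range of positive ints")
        if any(p < 0 for p in self.relation_mix.values()) or not self.relation_mix:
            raise ConfigurationError("relation_mix must be non-negative and non-empty")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def generate_ontology(
    spec: SynthSpec, rng: np.random.Generator | None = None
) -> OntologyGraph:
    """Random single-rooted DAG: term i>0 links to 1..max_parents earlier terms."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rels = sorted(spec.relation_mix)
    probs = np.array([spec.relation_mix[r] for r in rels], dtype=float)
    probs /= probs.sum()
    edges: list[tuple[str, str, str]] = []
    for i in range(1, spec.n_terms):
        parents = {int(rng.integers(0, i))}
        for _ in range(spec.max_parents - 1):
            if rng.random() < spec.extra_parent_prob:
                parents.add(int(rng.integers(0, i)))
        for p in sorted(parents):
            rel = rels[int(rng.choice(len(rels), p=probs))]
            edges.append((_term_id(i), _term_id(p), rel))
    return OntologyGraph.from_edges(
        edges, terms=[_term_id(0)], namespace=DEFAULT_NAMESPACE
    )


def _pick_homes(
    graph: OntologyGraph, spec: SynthSpec, rng: np.random.Generator
) -> list[set[str]]:
    """Greedily pick pairwise-disjoint descendant sub-DAGs, one per group."""
    root = _term_id(0)
    sized = []
    for t in sorted(graph.terms):
        if t == root:
            continue
        sub = closure(graph, {t}, "descendants")
        # prefer compact sub-DAGs: small disjoint homes are easier to pack
        if spec.min_home_size <= len(sub) <= 4 * spec.min_home_size:
            sized.append((len(sub), t, sub))
    order = rng.permutation(len(sized))
    sized = [sized[i] for i in sorted(order.tolist(), key=lambda i: sized[i][0])]
    homes: list[set[str]] = []
    used: set[str] = set()
    for _, _, sub in sized:
        if sub & used:
            continue
        homes.append(sub)
        used |= sub
        if len(homes) == spec.n_groups:
            return homes
    raise ConfigurationError(
        f"could not find {spec.n_groups} disjoint home sub-DAGs of >= "
        f"{spec.min_home_size} terms; increase n_terms or lower min_home_size"
    )


def generate_groups(
    graph: OntologyGraph, spec: SynthSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[str]], AnnotationCorpus]:
    """Gene groups anchored to disjoint home sub-DAGs, plus their corpus."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    homes = _pick_homes(graph, spec, rng)
    root = _term_id(0)
    pool = [t for t in sorted(graph.terms) if t != root]
    lo, hi = spec.terms_per_gene
    groups: dict[str, list[str]] = {}
    gene_terms: dict[str, set[str]] = {}
    for g, home in enumerate(homes):
        gid = f"GRP{g:02d}"
        home_list = sorted(home)
        members: list[str] = []
        for k in range(spec.genes_per_group):
            gene = f"{gid}_gene{k:02d}"
            n_draw = int(rng.integers(lo, hi + 1))
            terms: set[str] = set()
            for _ in range(n_draw):
                if rng.random() < spec.coherence:
                    terms.add(home_list[int(rng.integers(0, len(home_list)))])
                else:
                    terms.add(pool[int(rng.integers(0, len(pool)))])
            gene_terms[gene] = terms
            members.append(gene)
        groups[gid] = members
    return groups, build_corpus(gene_terms, graph)


def generate(
    spec: SynthSpec,
) -> tuple[OntologyGraph, dict[str, list[str]], AnnotationCorpus]:
    """Ontology, groups and corpus from one seed-driven random stream."""
    rng = np.random.default_rng(spec.seed)
    graph = generate_ontology(spec, rng)
    groups, corpus = generate_groups(graph, spec, rng)
    return graph, groups, corpus


def planted_separation(
    theta: float,
    gap: float = 0.01,
    contamination: float = 0.05,
    n_per_side: int = 500,
    spread: float = 0.3,
    contaminated_spread: float = 0.1,
    seed: int | np.random.Generator = 0,
):
    """S/N value distributions with a known decision boundary ``theta``.

    Clean S values lie uniformly in (theta+gap, theta+gap+spread) and clean N
    values mirror them below; a fixed fraction ``contamination`` of each side
    is planted on the wrong side of theta, within ``contaminated_spread`` of
    the gap.  The minimal achievable FN+FP is therefore 2*contamination, and
    every threshold inside (theta-gap, theta+gap] attains it.
    """
    from .thresholds import LabeledDistributions

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cont = int(round(contamination * n_per_side))
    n_clean = n_per_side - n_cont
    s_clean = rng.uniform(theta + gap, theta + gap + spread, size=n_clean)
    s_cont = rng.uniform(theta - gap - contaminated_spread, theta - gap, size=n_cont)
    n_clean_v = rng.uniform(theta - gap - spread, theta - gap, size=n_clean)
    n_cont_v = rng.uniform(theta + gap, theta + gap + contaminated_spread, size=n_cont)
    s = np.clip(np.concatenate([s_clean, s_cont]), 0.0, 1.0)
    n = np.clip(np.concatenate([n_clean_v, n_cont_v]), 0.0, 1.0)
    return LabeledDistributions(s_values=s.tolist(), n_values=n.tolist())


# ---------------------------------------------------------------------------
# writers, so synthetic data flows through the same readers as real data


def write_obo(graph: OntologyGraph, path: str) -> None:
    """Serialise the graph as a minimal OBO 1.2 document."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {graph.name(term) or 'synthetic term ' + term}\n")
            fh.write(f"namespace: {graph.namespace(term)}\n")
            for parent, rel in sorted(graph.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def write_gaf(gene_terms: Mapping[str, set[str]], path: str, aspect: str = "P") -> None:
    """Serialise direct annotations as GAF 2.1 (constant IEA evidence)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(gene_terms):
            for term in sorted(gene_terms[gene]):
                row = [
                    "SYNTH", gene, gene, "", term, "SYNTH:ref", "IEA", "",
                    aspect, "", "", "gene", "taxon:0000", "20130801", "SYNTH",
                    "", "",
                ]
                fh.write("\t".join(row) + "\n")


def write_groups(groups: Mapping[str, list[str]], path: str) -> None:
    """Serialise groups as ``group_id<TAB>gene_id`` with a comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# group_id\tgene_id\n")
        for gid in sorted(groups):
            for gene in groups[gid]:
                fh.write(f"{gid}\t{gene}\n")


def read_groups(path: str) -> dict[str, list[str]]:
    """Read a ``group_id<TAB>gene_id`` TSV ('#' comments allowed)."""
    groups: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, gene = line.split("\t")
            groups.setdefault(gid, []).append(gene)
    return groups
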