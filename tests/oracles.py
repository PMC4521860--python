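"""Independent brute-force oracles used to cross-check the implementation.

Everything here works straight from the definitions — path enumeration,
subset membership checking, per-term recounting — and never calls the code
paths it verifies.
"""

from __future__ import annotations

import itertools


def naive_obo_edges(text: str) -> list[tuple[str, str, str]]:
    """Line-based OBO edge extraction (is_a + relationship), ignoring obsoletes."""
    edges, term, stanza_edges, obsolete = [], None, [], False
    in_term = False

    def flush():
        if term is not None and in_term and not obsolete:
            edges.extend(stanza_edges)

    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            flush()
            term, stanza_edges, obsolete = None, [], False
            in_term = line == "[Term]"
        elif line.startswith("id:"):
            term = line[3:].strip()
        elif line.startswith("is_a:"):
            stanza_edges.append((term, line[5:].split("!")[0].strip(), "is_a"))
        elif line.startswith("relationship:"):
            rel, target = line[len("relationship:"):].split("!")[0].split()[:2]
            stanza_edges.append((term, target, rel))
        elif line.startswith("is_obsolete:") and "true" in line:
            obsolete = True
    flush()
    return edges


def all_rootward_paths(edges, start):
    """Every directed path from ``start`` toward the root(s), as edge lists."""
    by_child: dict[str, list[tuple[str, str]]] = {}
    for c, p, r in edges:
        by_child.setdefault(c, []).append((p, r))
    paths = [[]]
    frontier = [(start, [])]
    while frontier:
        node, path = frontier.pop()
        for parent, rel in by_child.get(node, []):
            newpath = path + [(node, parent, rel)]
            paths.append(newpath)
            frontier.append((parent, newpath))
    return paths


def wang_contributions_by_paths(edges, weights, a):
    """S_A(t) as the max product of edge factors over all paths A -> t."""
    contrib = {a: 1.0}
    for path in all_rootward_paths(edges, a):
        if not path:
            continue
        prod = 1.0
        for _, _, rel in path:
            prod *= weights[rel]
        end = path[-1][1]
        contrib[end] = max(contrib.get(end, 0.0), prod)
    return contrib


def naive_closure(edges, seed, direction):
    step = {}
    for c, p, _ in edges:
        if direction == "ancestors":
            step.setdefault(c, set()).add(p)
        else:
            step.setdefault(p, set()).add(c)
    out = set(seed)
    frontier = list(seed)
    while frontier:
        node = frontier.pop()
        for nxt in step.get(node, ()):
            if nxt not in out:
                out.add(nxt)
                frontier.append(nxt)
    return out


def naive_mpt(edges, sg1, sg2):
    """Definition check: t in Sg1, no proper descendant in Sg1, t not in Sg2*."""
    sg2_star = naive_closure(edges, sg2, "ancestors")
    out = set()
    for t in sg1:
        desc = naive_closure(edges, {t}, "descendants") - {t}
        if not (desc & set(sg1)) and t not in sg2_star:
            out.add(t)
    return out


def naive_mct(edges, sg1, sg2, mode="intersection"):
    c1 = naive_closure(edges, sg1, "ancestors")
    c2 = naive_closure(edges, sg2, "ancestors")
    shared = c1 & c2
    excl = shared if mode == "intersection" else (c1 | c2)
    return {
        t
        for t in shared
        if not (naive_closure(edges, {t}, "descendants") - {t}) & excl
    }


def recount_terms(edges, gene_terms):
    """Per-term recount: genes whose direct-annotation closure contains the term."""
    counts: dict[str, int] = {}
    all_terms = {t for e in edges for t in e[:2]} | {
        t for ts in gene_terms.values() for t in ts
    }
    for term in all_terms:
        n = sum(
            1
            for terms in gene_terms.values()
            if term in naive_closure(edges, terms, "ancestors")
        )
        if n:
            counts[term] = n
    return counts


def exhaustive_scan(s_values, n_values, grid):
    """Recount FN/FP at every grid point and return the smallest minimizer."""
    best_tau, best_obj = None, None
    curve = []
    for tau in grid:
        fn = sum(1 for v in s_values if v < tau) / len(s_values)
        fp = sum(1 for v in n_values if v >= tau) / len(n_values)
        curve.append((tau, fn, fp))
        if best_obj is None or fn + fp < best_obj - 1e-12:
            best_tau, best_obj = tau, fn + fp
    return best_tau, best_obj, curve


def pattern_label(sim, pab, pba, tau_sim, tau_par):
    return "".join(
        "+" if v >= t else "-"
        for v, t in ((sim, tau_sim), (pab, tau_par), (pba, tau_par))
    )


def exhaustive_par_scan(triples, tau_sim, grid):
    best_tau, best_obj, curve = None, None, []
    for tau in grid:
        labels = [pattern_label(s, a, b, tau_sim, tau) for s, a, b in triples]
        obj = (labels.count("+++") + labels.count("---")) / len(triples)
        curve.append((tau, obj))
        if best_obj is None or obj < best_obj - 1e-12:
            best_tau, best_obj = tau, obj
    return best_tau, best_obj, curve


def all_pairs(groups):
    intra = [
        (g, pair)
        for g, members in groups.items()
        for pair in itertools.combinations(members, 2)
    ]
    inter = [
        ((g1, g2), (a, b))
        for (g1, m1), (g2, m2) in itertools.combinations(groups.items(), 2)
        for a in m1
        for b in m2
    ]
    return intra, inter
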