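"""Eight-way similarity/particularity patterns and transition tabulation.

A comparison of two entities yields a triple (sim(A,B), par(A,B), par(B,A)).
Each component is signed '+' when it is greater than or equal to its
threshold and '-' otherwise, giving one of eight patterns, e.g. "+--" for a
similar pair where neither side is particular.  "+++" and "---" are legal
but uninformative: a pair cannot meaningfully be both similar and mutually
particular, nor neither — their pooled proportion is the objective the
particularity-threshold scan minimises.

Because the order of the two particularity values is arbitrary (the pair is
unordered), "++-"/"+-+" and "-+-"/"--+" are usually merged when tabulating.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateInputError

#: The eight sign patterns, in display order.
PATTERNS: tuple[str, ...] = (
    "+++", "++-", "+-+", "+--", "-++", "-+-", "--+", "---",
)

#: The two uninformative patterns.
UNINFORMATIVE: tuple[str, str] = ("+++", "---")

#: Symmetric merges applied when the particularity order is meaningless.
MERGE_GROUPS: dict[str, str] = {
    "++-": "++-/+-+",
    "+-+": "++-/+-+",
    "-+-": "-+-/--+",
    "--+": "-+-/--+",
}

MERGED_PATTERNS: tuple[str, ...] = (
    "+++", "++-/+-+", "+--", "-++", "-+-/--+", "---",
)


@dataclass(frozen=True)
class ComparisonTriple:
    """One entity-pair comparison: similarity and both particularities."""

    sim: float
    par_ab: float
    par_ba: float
    entity_a: str | None = None
    entity_b: str | None = None

    def values(self) -> tuple[float, float, float]:
        return (self.sim, self.par_ab, self.par_ba)


def classify_pattern(
    sim: float, par_ab: float, par_ba: float, tau_sim: float, tau_par: float
) -> str:
    """Sign pattern of a triple: '+' where the component >= its threshold."""
    signs = (
        "+" if sim >= tau_sim else "-",
        "+" if par_ab >= tau_par else "-",
        "+" if par_ba >= tau_par else "-",
    )
    return "".join(signs)


def _labels(merge_symmetric: bool) -> tuple[str, ...]:
    return MERGED_PATTERNS if merge_symmetric else PATTERNS


def _label(pattern: str, merge_symmetric: bool) -> str:
    return MERGE_GROUPS.get(pattern, pattern) if merge_symmetric else pattern


@dataclass
class TransitionResult:
    """Pattern transition counts between two threshold settings."""

    matrix: pd.DataFrame  # rows: pattern under old thresholds; cols: new
    old_thresholds: tuple[float, float]
    new_thresholds: tuple[float, float]

    @property
    def grand_total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out["Total"] = out.sum(axis=1)
        out.loc["Total"] = out.sum(axis=0)
        return out


def transition_matrix(
    triples: Sequence[tuple[float, float, float] | ComparisonTriple],
    old_thresholds: tuple[float, float],
    new_thresholds: tuple[float, float],
    merge_symmetric: bool = True,
) -> TransitionResult:
    """Cross-tabulate pattern membership under old vs new thresholds."""
    if not triples:
        raise DegenerateInputError("no triples to tabulate")
    labels = _labels(merge_symmetric)
    matrix = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for triple in triples:
        vals = triple.values() if isinstance(triple, ComparisonTriple) else tuple(triple)
        old = _label(classify_pattern(*vals, *old_thresholds), merge_symmetric)
        new = _label(classify_pattern(*vals, *new_thresholds), merge_symmetric)
        matrix.loc[old, new] += 1
    return TransitionResult(
        matrix=matrix, old_thresholds=old_thresholds, new_thresholds=new_thresholds
    )
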