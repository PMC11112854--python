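"""Cross-species interactome comparison via orthologue mapping.

Proteins are mapped into a common orthologue namespace using a curated
one-to-one table first, then a reciprocal-best-hit (RBH) fallback over a
pairwise similarity score table.  A source is excluded, with a recorded
reason, when it has no orthologue or when its best reciprocal hit is
already represented in the mapped set.  Set accounting between two mapped
interactomes (shared / specific / union) then follows by exact set algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import LikError


@dataclass
class OrthologyMap:
    mapped: dict[str, tuple[str, str]] = field(default_factory=dict)  # src -> (tgt, method)
    excluded: list[tuple[str, str]] = field(default_factory=list)     # (src, reason)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.mapped.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [[s, t, m] for s, (t, m) in sorted(self.mapped.items())]
        return pd.DataFrame(rows, columns=["source_id", "target_id", "method"])


@dataclass(frozen=True)
class InteractomeComparison:
    shared: frozenset[str]
    a_specific: frozenset[str]
    b_specific: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.shared | self.a_specific | self.b_specific)


def _reciprocal_best_hits(scores: pd.DataFrame) -> dict[str, str]:
    """Mutual-argmax pairs from a source x target similarity table.

    Ties for the best score disqualify the pair (conservative): a source or
    target with more than one top-scoring partner forms no RBH.
    """
    rbh: dict[str, str] = {}
    col_best: dict[str, str | None] = {}
    for tgt in scores.columns:
        col = scores[tgt].dropna()
        if col.empty:
            continue
        top = col[col == col.max()]
        col_best[tgt] = top.index[0] if len(top) == 1 else None
    for src in scores.index:
        row = scores.loc[src].dropna()
        if row.empty:
            continue
        top = row[row == row.max()]
        if len(top) != 1:
            continue
        tgt = top.index[0]
        if col_best.get(tgt) == src:
            rbh[src] = tgt
    return rbh


def map_orthologues(
    sources: Iterable[str],
    one_to_one_table: Mapping[str, str],
    similarity_scores: pd.DataFrame,
    already_represented: Iterable[str] = (),
) -> OrthologyMap:
    """Map source proteins to target-namespace orthologues.

    Curated 1:1 entries are used first; remaining sources fall back to RBH
    over ``similarity_scores`` (rows = sources, columns = targets, higher is
    better, NaN = no hit).  Sources are processed in lexicographic order so
    the "target already represented" exclusion is deterministic; the
    running mapped-target set starts from ``already_represented``.
    """
    targets = list(one_to_one_table.values())
    if len(targets) != len(set(targets)):
        raise LikError("one-to-one table maps multiple sources to one target")

    out = OrthologyMap()
    taken: set[str] = set(already_represented)
    rbh = _reciprocal_best_hits(similarity_scores)
    for src in sorted(set(sources)):
        if src in one_to_one_table:
            tgt = one_to_one_table[src]
            if tgt in taken:
                out.excluded.append((src, "target_already_represented"))
                continue
            out.mapped[src] = (tgt, "one_to_one")
            taken.add(tgt)
        elif src in rbh:
            tgt = rbh[src]
            if tgt in taken:
                out.excluded.append((src, "target_already_represented"))
                continue
            out.mapped[src] = (tgt, "rbh")
            taken.add(tgt)
        else:
            out.excluded.append((src, "no_orthologue"))
    return out


def compare_interactomes(a: Iterable[str], b: Iterable[str]) -> InteractomeComparison:
    """Shared / specific / union accounting between two protein sets in the
    same (post-orthology) namespace."""
    sa, sb = frozenset(a), frozenset(b)
    return InteractomeComparison(
        shared=sa & sb, a_specific=sa - sb, b_specific=sb - sa)


def term_overlap_fraction(enriched_a: Iterable[str], enriched_b: Iterable[str]) -> float:
    """Fraction of A's enriched terms that are also enriched in B."""
    sa, sb = frozenset(enriched_a), frozenset(enriched_b)
    if not sa:
        raise LikError("overlap fraction undefined for an empty term set")
    return len(sa & sb) / len(sa)
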