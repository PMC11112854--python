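"""Over-representation analysis (ORA) of protein sets against gene sets.

For each term, the overlap between the query set and the term's members
(both restricted to a declared background) is tested with the one-sided
hypergeometric tail P[X >= observed overlap].  Terms whose
background-restricted size reaches a cap (default 1600, excluding very
broad ontology terms) are not tested.  Benjamini-Hochberg FDR adjustment
is applied across the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .calling import bh_adjust
from .errors import LikError
from .io import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    term_size: int      # after background restriction
    overlap: int
    p: float
    adj_p: float


def ora(
    query: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    max_term_size: int = 1600,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` within ``background``.

    Returns one result per tested term, sorted by adjusted then raw p.
    Raises when the query is not contained in the background.
    """
    q = frozenset(query)
    bg = frozenset(background)
    stray = q - bg
    if stray:
        raise LikError(
            "query ids missing from background: " + ", ".join(sorted(stray)[:10]))
    n_bg, n_q = len(bg), len(q)

    tested: list[tuple[str, str, int, int]] = []
    for term in sets:
        members = sets.members(term) & bg
        k = len(members)
        if k == 0 or k >= max_term_size:
            continue
        tested.append((term, sets.name(term), k, len(members & q)))
    if not tested:
        return []

    pvals = [
        float(stats.hypergeom.sf(overlap - 1, n_bg, k, n_q))
        for _, _, k, overlap in tested
    ]
    adj = bh_adjust(pvals)
    results = [
        EnrichmentResult(term, name, k, overlap, p, float(a))
        for (term, name, k, overlap), p, a in zip(tested, pvals, adj)
    ]
    results.sort(key=lambda r: (r.adj_p, r.p, r.term_id))
    return results


def significant_terms(
    results: Iterable[EnrichmentResult],
    alpha: float = 1e-3,
    on: str = "raw",
) -> frozenset[str]:
    """Terms with the chosen p-value strictly below ``alpha``.

    ``on`` selects the raw hypergeometric p or the BH-adjusted p; the
    strict inequality means a term at exactly ``alpha`` is not called.
    """
    if on not in ("raw", "adjusted"):
        raise ValueError("on must be 'raw' or 'adjusted'")
    return frozenset(
        r.term_id for r in results
        if (r.p if on == "raw" else r.adj_p) < alpha
    )


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.term_id, r.term_name, r.term_size, r.overlap, r.p, r.adj_p]
         for r in results],
        columns=["term_id", "term_name", "term_size", "overlap", "p", "adj_p"],
    )
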