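"""Intrinsically-disordered-region (IDR) scoring and group comparison.

A protein's IDR score is the median of its per-residue disorder scores
(scores above 0.5 mark disordered residues).  Interactome groups are
compared against ontology-constrained random background sets — proteins
sampled from the union of ontology terms enriched in the major network
clusters — with a Kruskal-Wallis test followed by Dunn's pairwise z-tests
under Holm adjustment.  Dunn's statistics reuse the pooled mid-ranks (and
tie correction) of the omnibus test, so the post hoc is consistent with it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LikError, ParameterError
from .io import DisorderTrack, GeneSetCollection


def median_idr(track: DisorderTrack) -> tuple[float, float]:
    """(median score, fraction of residues strictly above 0.5)."""
    if len(track) < 1:
        raise LikError("empty disorder track")
    med = float(np.median(track.scores))
    frac = float(np.count_nonzero(track.scores > 0.5) / len(track))
    return med, frac


def idr_score_table(tracks: dict[str, DisorderTrack]) -> pd.DataFrame:
    rows = []
    for pid, t in tracks.items():
        med, frac = median_idr(t)
        rows.append([pid, med, len(t), frac])
    return pd.DataFrame(
        rows, columns=["protein_id", "median_idr", "n_residues", "frac_disordered"]
    ).set_index("protein_id")


def build_background_subset(
    proteome_ids: set[str] | frozenset[str],
    sets: GeneSetCollection,
    enriched_terms: set[str] | frozenset[str],
) -> frozenset[str]:
    """Union of the members of the enriched ontology terms, restricted to
    the proteome."""
    if not enriched_terms:
        raise LikError("no enriched terms: background subset undefined")
    missing = [t for t in enriched_terms if t not in sets]
    if missing:
        raise LikError(f"enriched term(s) not in collection: {sorted(missing)[:5]}")
    out: set[str] = set()
    for term in enriched_terms:
        out |= sets.members(term)
    return frozenset(out & set(proteome_ids))


@dataclass(frozen=True)
class BackgroundSample:
    sets: tuple[tuple[str, ...], ...]
    seed: int

    def pooled(self) -> list[str]:
        return [p for s in self.sets for p in s]


def sample_background(
    subset: frozenset[str] | set[str],
    n_sets: int = 20,
    set_size: int = 200,
    seed: int = 0,
) -> BackgroundSample:
    """``n_sets`` independent draws of ``set_size`` proteins, each without
    replacement, from the background subset."""
    pool = np.array(sorted(subset))
    if pool.size < set_size:
        raise ParameterError(
            f"background subset has {pool.size} proteins, need >= {set_size}")
    rng = np.random.default_rng(seed)
    draws = tuple(
        tuple(rng.choice(pool, size=set_size, replace=False).tolist())
        for _ in range(n_sets)
    )
    return BackgroundSample(sets=draws, seed=seed)


# --------------------------------------------------------------------------
# Kruskal-Wallis + Dunn/Holm

@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    dunn_z: float
    p_raw: float
    p_holm: float


@dataclass(frozen=True)
class GroupComparison:
    kw_statistic: float
    kw_p: float
    pairwise: tuple[PairwiseResult, ...]


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down familywise adjustment."""
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def compare_groups(groups: dict[str, list[float] | np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise z-tests (Holm).

    All groups are pooled and mid-ranked once; the Kruskal-Wallis H uses
    the standard tie correction, and each Dunn z compares two groups' mean
    ranks with the tie-corrected variance
    (N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j), T = sum(t^3 - t).
    """
    names = list(groups)
    if len(names) < 2:
        raise ParameterError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ParameterError(f"group {k!r} has fewer than 2 observations")

    pooled = np.concatenate([arrays[k] for k in names])
    ranks = stats.rankdata(pooled)
    sizes = np.array([arrays[k].size for k in names])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {
        k: ranks[bounds[i]:bounds[i + 1]].mean() for i, k in enumerate(names)
    }
    n_total = pooled.size

    if np.ptp(pooled) == 0:
        kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = stats.kruskal(*[arrays[k] for k in names])

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    zs, praw, pairs = [], [], []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(z)
        praw.append(2.0 * stats.norm.sf(abs(z)))
        pairs.append((a, b))
    holm = _holm(np.asarray(praw))
    pairwise = tuple(
        PairwiseResult(a, b, float(z), float(p), float(ph))
        for (a, b), z, p, ph in zip(pairs, zs, praw, holm)
    )
    return GroupComparison(float(kw_h), float(kw_p), pairwise)


def comparison_frame(cmp: GroupComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.group_a, r.group_b, r.dunn_z, r.p_raw, r.p_holm] for r in cmp.pairwise],
        columns=["group_a", "group_b", "dunn_z", "p_raw", "p_holm"],
    )
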