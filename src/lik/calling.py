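"""Candidate-interactor calling from ChIRP pulldown protein-group tables.

Two alternate criteria identify candidates, applied after QC (contaminant /
decoy removal and a minimum unique-peptide count):

* presence/absence — detection (intensity > 0) in two or more native
  pulldowns, or in a single pulldown for either crosslinked arm;
* intensity-based enrichment — log2(pulldown/control) above a threefold
  threshold (log2 3 = 1.584963).  Crosslinked arms are called on the ratio
  alone; the native arm additionally requires detection in more than 4 of
  the 6 probe combinations and a Welch t-test on log2 intensities with
  Benjamini-Hochberg correction, adjusted p below alpha.

The called set is finally merged with independently validated proteins
(e.g. RIP-qPCR hits) into a named interactome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign, Sample
from .errors import DesignError, InsufficientReplicationError
from .io import ProteinGroupTable

THREEFOLD_LOG2 = math.log2(3.0)  # 1.584963 to the precision quoted in reports


@dataclass
class CallConfig:
    log2fc_threshold: float = THREEFOLD_LOG2
    min_native_pulldowns: int = 2
    min_crosslinked_pulldowns: int = 1
    probe_vote_min: int = 5          # "more than 4 of 6" combinations
    alpha: float = 0.05
    min_unique_peptides: int = 2
    pseudocount_policy: str = "half_min"  # or "none"

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class Evidence:
    criterion: str                    # presence_absence | fold_change | rip_validated
    modes: tuple[str, ...] = ()
    log2_ratio: float | None = None
    adj_p: float | None = None


@dataclass
class CandidateSet:
    """Called proteins with the evidence each one carries."""

    records: dict[str, list[Evidence]] = field(default_factory=dict)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.records)

    def add(self, protein: str, ev: Evidence) -> None:
        self.records.setdefault(protein, []).append(ev)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein: str) -> bool:
        return protein in self.records


@dataclass
class Interactome:
    """A named protein set with per-protein evidence labels."""

    name: str
    evidence: dict[str, list[Evidence]] = field(default_factory=dict)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.evidence)

    def __len__(self) -> int:
        return len(self.evidence)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.evidence):
            evs = self.evidence[pid]
            ratios = [e.log2_ratio for e in evs if e.log2_ratio is not None]
            ps = [e.adj_p for e in evs if e.adj_p is not None]
            modes = sorted({m for e in evs for m in e.modes})
            rows.append([
                pid,
                ";".join(sorted({e.criterion for e in evs})),
                ";".join(modes),
                max(ratios) if ratios else np.nan,
                min(ps) if ps else np.nan,
            ])
        return pd.DataFrame(
            rows, columns=["protein_id", "evidence", "modes", "max_log2fc", "adj_p"])


# --------------------------------------------------------------------------

def qc_filter(table: ProteinGroupTable, cfg: CallConfig) -> ProteinGroupTable:
    """Drop contaminants, decoys and groups identified from too few unique
    peptides; row order is preserved."""
    keep = (
        ~table.meta["is_contaminant"]
        & ~table.meta["is_decoy"]
        & (table.meta["unique_peptides"] >= cfg.min_unique_peptides)
    )
    return table.subset(table.meta.index[keep])


def call_presence_absence(
    table: ProteinGroupTable, design: ExperimentDesign, cfg: CallConfig
) -> CandidateSet:
    """Detection-count rule: >=2 native pulldowns, or >=1 crosslinked
    pulldown.  Controls never support a call."""
    if not design.pulldowns():
        raise DesignError("design has no pulldown samples")
    det = table.detected()
    out = CandidateSet()
    thresholds = {
        "native": cfg.min_native_pulldowns,
        "uv": cfg.min_crosslinked_pulldowns,
        "formaldehyde": cfg.min_crosslinked_pulldowns,
    }
    for pid in table.protein_ids:
        modes = []
        for mode, need in thresholds.items():
            cols = [s.sample_id for s in design.pulldowns(mode)]
            if cols and int(det.loc[pid, cols].sum()) >= need:
                modes.append(mode)
        if modes:
            out.add(pid, Evidence("presence_absence", tuple(modes)))
    return out


def _contrast_samples(design: ExperimentDesign, mode: str) -> tuple[list[str], list[str]]:
    """Pulldown / control sample ids for one crosslink-mode contrast.

    For the native arm the replicated pooled-probe capture (when present)
    defines the contrast; the single-probe captures feed only the probe
    vote and presence/absence calling.
    """
    pulls = design.pulldowns(mode)
    if mode == "native":
        pooled = [s for s in pulls if s.probe_combo == "pooled"]
        if pooled:
            pulls = pooled
    if not pulls:
        return [], []
    ctrl_ids: list[str] = []
    for s in pulls:
        if not s.paired_control_id:
            raise DesignError(f"pulldown {s.sample_id} has no paired control")
        if s.paired_control_id not in ctrl_ids:
            ctrl_ids.append(s.paired_control_id)
    return [s.sample_id for s in pulls], ctrl_ids


def _pseudocount(table: ProteinGroupTable, policy: str) -> float:
    if policy == "none":
        return np.nan
    vals = table.intensities.to_numpy()
    pos = vals[vals > 0]
    if pos.size == 0:
        return np.nan
    return float(pos.min()) / 2.0


def compute_log2_ratios(
    table: ProteinGroupTable,
    design: ExperimentDesign,
    pseudocount_policy: str = "half_min",
) -> pd.DataFrame:
    """Per-protein log2(pulldown/control) for each crosslink-mode contrast.

    The ratio is the difference of mean log2 intensities (geometric-mean
    ratio): pulldown means are over detected samples only, control zeros
    are replaced by half the smallest positive intensity in the table.  A
    protein undetected in every contrast pulldown gets NaN (no ratio).
    """
    pc = _pseudocount(table, pseudocount_policy)
    out = {}
    for mode in ("native", "uv", "formaldehyde"):
        pull_ids, ctrl_ids = _contrast_samples(design, mode)
        if not pull_ids:
            continue
        pull = table.intensities[pull_ids].to_numpy(dtype=float)
        ctrl = table.intensities[ctrl_ids].to_numpy(dtype=float)
        det = pull > 0
        n_det = det.sum(axis=1)
        lp = np.where(det, np.log2(np.where(det, pull, 1.0)), 0.0)
        pull_mean = np.where(n_det > 0, lp.sum(axis=1) / np.maximum(n_det, 1), np.nan)
        ctrl_filled = np.where(ctrl > 0, ctrl, pc)
        ctrl_mean = np.log2(ctrl_filled).mean(axis=1)
        out[mode] = pull_mean - ctrl_mean
    return pd.DataFrame(out, index=table.protein_ids)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _probe_vote(table: ProteinGroupTable, design: ExperimentDesign) -> pd.Series:
    """Number of native probe combinations detecting each protein (a combo
    detects a protein iff intensity > 0 in >=1 of its pulldown samples)."""
    det = table.detected()
    combos = design.probe_combos("native")
    counts = pd.Series(0, index=table.protein_ids, dtype=int)
    for combo in combos:
        cols = [s.sample_id for s in design.pulldowns("native")
                if s.probe_combo == combo]
        counts += det[cols].any(axis=1).astype(int)
    return counts


def call_fold_change(
    ratios: pd.DataFrame,
    table: ProteinGroupTable,
    design: ExperimentDesign,
    cfg: CallConfig,
) -> CandidateSet:
    """Enrichment-based calling per crosslink-mode contrast.

    UV / formaldehyde proteins are selected on the log2 ratio alone
    (strictly above ``cfg.log2fc_threshold``).  Native candidates must also
    clear the probe-combination vote and a Welch t-test on log2 intensities
    (pulldown vs control replicates), BH-adjusted across all proteins with
    a computable native ratio.
    """
    out = CandidateSet()
    thr = cfg.log2fc_threshold

    for mode in ("uv", "formaldehyde"):
        if mode not in ratios.columns:
            continue
        r = ratios[mode]
        for pid in r.index[(r > thr).fillna(False)]:
            out.add(pid, Evidence("fold_change", (mode,), log2_ratio=float(r[pid])))

    if "native" in ratios.columns:
        pull_ids, ctrl_ids = _contrast_samples(design, "native")
        if len(pull_ids) < 2 or len(ctrl_ids) < 2:
            raise InsufficientReplicationError(
                "native fold-change calling needs >=2 pulldown and >=2 control "
                f"replicates, got {len(pull_ids)} and {len(ctrl_ids)}")
        pc = _pseudocount(table, cfg.pseudocount_policy)
        lp = np.log2(np.where(table.intensities[pull_ids] > 0,
                              table.intensities[pull_ids], pc))
        lc = np.log2(np.where(table.intensities[ctrl_ids] > 0,
                              table.intensities[ctrl_ids], pc))
        tested = ratios.index[ratios["native"].notna()]
        mask = table.protein_ids.isin(tested)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = stats.ttest_ind(lp[mask], lc[mask], axis=1, equal_var=False)
        # zero-variance, equal-means rows yield NaN: no evidence, p := 1
        pvals = np.where(np.isnan(tstat.pvalue), 1.0, tstat.pvalue)
        adj = bh_adjust(pvals)
        adj_p = pd.Series(adj, index=table.protein_ids[mask])

        votes = _probe_vote(table, design)
        r = ratios["native"]
        for pid in tested:
            if (
                r[pid] > thr
                and votes[pid] >= cfg.probe_vote_min
                and adj_p[pid] < cfg.alpha
            ):
                out.add(pid, Evidence("fold_change", ("native",),
                                      log2_ratio=float(r[pid]),
                                      adj_p=float(adj_p[pid])))
    return out


def combine_candidates(
    sets: Iterable[CandidateSet],
    validated_extras: Iterable[str] = (),
    name: str = "interactome",
) -> Interactome:
    """Union of all candidate sets plus independently validated proteins
    (labelled ``rip_validated``), evidence merged per protein."""
    out = Interactome(name)
    for cs in sets:
        for pid, evs in cs.records.items():
            out.evidence.setdefault(pid, []).extend(evs)
    for pid in validated_extras:
        out.evidence.setdefault(pid, []).append(Evidence("rip_validated"))
    return out
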