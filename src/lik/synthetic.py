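"""Truth-labelled synthetic fixtures for every pipeline stage.

Each generator emulates the statistical structure one downstream stage
assumes: log-normal LFQ pulldown tables with planted enriched interactors,
planted-partition association graphs, gene-set collections with planted
over-represented terms, two-state per-residue disorder tracks, and
qPCR / FISH validation fixtures.  All randomness flows from one integer
seed through :class:`numpy.random.SeedSequence` substreams, so regenerating
with the same seed is byte-identical.

Non-detection is encoded as an exact 0 intensity, matching the LFQ-table
convention the caller modules rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ExperimentDesign, default_design
from .errors import ParameterError
from .io import DisorderTrack, GeneSetCollection, ProteinGroupTable


@dataclass
class TruthLabels:
    """What the generators planted, for scoring recovery."""

    planted_interactors: frozenset[str] = frozenset()
    planted_communities: dict[str, int] = field(default_factory=dict)
    planted_enriched_terms: frozenset[str] = frozenset()


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# ChIRP pulldown tables

@dataclass
class ChirpSimParams:
    """Generative settings for a synthetic ChIRP-MS protein-group table.

    Intensities are drawn on the log2 scale: each protein gets a baseline
    abundance, planted interactors gain ``effect_log2fc`` in every pulldown,
    Gaussian noise of sd ``noise_sd`` is added per sample, and each truly
    present value is zeroed (dropped out) independently with probability
    ``dropout_p``.
    """

    n_proteins: int = 500
    n_true: int = 50
    effect_log2fc: float = 3.0
    noise_sd: float = 0.4
    dropout_p: float = 0.0
    design: ExperimentDesign = field(default_factory=default_design)
    seed: int = 0
    n_contaminants: int = 5
    n_single_peptide: int = 5

    def __post_init__(self) -> None:
        if self.n_true > self.n_proteins:
            raise ParameterError("n_true exceeds n_proteins")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.dropout_p < 1:
            raise ParameterError("dropout_p must be in [0, 1)")
        if self.n_contaminants + self.n_single_peptide > self.n_proteins:
            raise ParameterError("QC decoration exceeds n_proteins")


def gen_chirp_experiment(params: ChirpSimParams) -> tuple[ProteinGroupTable, TruthLabels]:
    """Simulate one full pulldown experiment under ``params.design``.

    Planted interactors have expected log2(pulldown/control) equal to
    ``effect_log2fc`` in every contrast; all other proteins have expected
    log2 ratio 0.  A handful of contaminant-flagged and single-peptide rows
    (never planted) exercise the QC filter.
    """
    d = params.design
    rng_base, rng_noise, rng_drop, rng_meta = _streams(params.seed, 4)

    ids = np.array([f"PG{i:05d}" for i in range(1, params.n_proteins + 1)])
    planted = np.zeros(params.n_proteins, dtype=bool)
    # QC-decorated rows sit at the end and are excluded from planting
    n_clean = params.n_proteins - params.n_contaminants - params.n_single_peptide
    planted_idx = rng_base.choice(n_clean, size=params.n_true, replace=False)
    planted[planted_idx] = True

    baseline = rng_base.uniform(20.0, 30.0, size=params.n_proteins)
    inten = {}
    for s in d.samples:
        log2 = baseline + rng_noise.normal(0.0, params.noise_sd, params.n_proteins)
        if s.role == "pulldown":
            log2 = log2 + params.effect_log2fc * planted
        vals = np.exp2(log2)
        if params.dropout_p > 0:
            vals[rng_drop.random(params.n_proteins) < params.dropout_p] = 0.0
        inten[s.sample_id] = vals

    meta = pd.DataFrame(index=pd.Index(ids, name="protein_group_id"))
    meta["gene_id"] = np.char.add("GENE", np.char.zfill(
        np.arange(1, params.n_proteins + 1).astype(str), 5))
    meta["unique_peptides"] = rng_meta.integers(2, 20, params.n_proteins)
    meta["is_contaminant"] = False
    meta["is_decoy"] = False
    if params.n_contaminants:
        meta.iloc[n_clean:n_clean + params.n_contaminants,
                  meta.columns.get_loc("is_contaminant")] = True
    if params.n_single_peptide:
        meta.iloc[params.n_proteins - params.n_single_peptide:,
                  meta.columns.get_loc("unique_peptides")] = 1

    table = ProteinGroupTable(meta, pd.DataFrame(inten, index=meta.index))
    truth = TruthLabels(planted_interactors=frozenset(ids[planted]))
    return table, truth


# --------------------------------------------------------------------------
# Planted-partition association networks

@dataclass
class NetworkSimParams:
    n_nodes: int = 150
    n_communities: int = 3
    p_in: float = 0.3
    p_out: float = 0.01
    confidence_range: tuple[float, float] = (0.4, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ParameterError("need 0 <= p_out < p_in <= 1")
        lo, hi = self.confidence_range
        if not (0 <= lo <= hi <= 1):
            raise ParameterError("confidence_range must be within [0, 1]")


def gen_network(params: NetworkSimParams) -> tuple[pd.DataFrame, TruthLabels]:
    """Planted-partition graph as a (a, b, confidence) edge frame.

    Nodes are assigned round-robin to communities; each within-community
    pair is an edge with probability ``p_in``, each between-community pair
    with probability ``p_out``; confidences are uniform on
    ``confidence_range``.
    """
    rng_edge, rng_conf = _streams(params.seed, 2)
    nodes = np.array([f"N{i:04d}" for i in range(params.n_nodes)])
    comm = np.arange(params.n_nodes) % params.n_communities

    iu, ju = np.triu_indices(params.n_nodes, k=1)
    p = np.where(comm[iu] == comm[ju], params.p_in, params.p_out)
    keep = rng_edge.random(p.size) < p
    lo, hi = params.confidence_range
    conf = rng_conf.uniform(lo, hi, size=int(keep.sum()))
    edges = pd.DataFrame({
        "a": nodes[iu[keep]], "b": nodes[ju[keep]], "confidence": conf,
    })
    truth = TruthLabels(planted_communities=dict(zip(nodes, (comm + 1).tolist())))
    return edges, truth


# --------------------------------------------------------------------------
# Gene-set collections with planted over-representation

def gen_gene_sets(
    universe: list[str],
    n_terms: int,
    size_range: tuple[int, int],
    planted_terms: int,
    query: list[str],
    planted_odds: float = 20.0,
    seed: int = 0,
) -> tuple[GeneSetCollection, TruthLabels]:
    """GMT-style collection where the first ``planted_terms`` terms
    over-represent the query at odds ``planted_odds``.

    Members of a planted term are drawn without replacement with sampling
    weight ``planted_odds`` for query genes and 1 otherwise (Gumbel top-k);
    ``planted_odds=1`` makes every term a uniform draw.
    """
    if not universe:
        raise ParameterError("empty universe")
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ParameterError("size_range must fit inside the universe")
    if planted_terms > n_terms:
        raise ParameterError("planted_terms exceeds n_terms")

    rng, = _streams(seed, 1)
    uni = np.asarray(universe, dtype=object)
    in_query = np.isin(uni, np.asarray(list(query), dtype=object))
    logw = np.where(in_query, np.log(planted_odds), 0.0)

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted: set[str] = set()
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        term = f"T{t:04d}"
        if t <= planted_terms:
            keys = logw + rng.gumbel(size=uni.size)
            members = uni[np.argsort(-keys)[:size]]
            planted.add(term)
        else:
            members = rng.choice(uni, size=size, replace=False)
        sets[term] = (f"synthetic term {t}", frozenset(members.tolist()))
    return GeneSetCollection(sets), TruthLabels(planted_enriched_terms=frozenset(planted))


# --------------------------------------------------------------------------
# Two-state disorder tracks

@dataclass
class IdrBlockParams:
    """Shape of the two-state tracks: an ordered baseline punctuated by
    disordered blocks of at least 30 consecutive residues (the long-IDR
    design target of per-residue disorder predictors)."""

    n_blocks: tuple[int, int] = (0, 2)       # inclusive range per protein
    block_length: tuple[int, int] = (30, 120)
    ordered_level: float = 0.2
    disordered_level: float = 0.85
    jitter_sd: float = 0.05


def gen_disorder_tracks(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 600),
    idr_block_params: IdrBlockParams | None = None,
    seed: int = 0,
    id_prefix: str = "PROT",
) -> dict[str, DisorderTrack]:
    """Seeded set of two-state per-residue disorder tracks in [0, 1]."""
    bp = idr_block_params or IdrBlockParams()
    lo, hi = length_range
    if lo < 1:
        raise ParameterError("protein lengths must be >= 1")
    rng, = _streams(seed, 1)
    tracks: dict[str, DisorderTrack] = {}
    for i in range(1, n_proteins + 1):
        length = int(rng.integers(lo, hi + 1))
        scores = np.clip(
            bp.ordered_level + rng.normal(0.0, bp.jitter_sd, length), 0.0, 1.0)
        n_blocks = int(rng.integers(bp.n_blocks[0], bp.n_blocks[1] + 1))
        for _ in range(n_blocks):
            blen = min(int(rng.integers(*bp.block_length)), length)
            start = int(rng.integers(0, max(length - blen, 0) + 1))
            block = np.clip(
                bp.disordered_level + rng.normal(0.0, bp.jitter_sd, blen), 0.0, 1.0)
            scores[start:start + blen] = block
        pid = f"{id_prefix}{i:05d}"
        tracks[pid] = DisorderTrack(pid, scores)
    return tracks


# --------------------------------------------------------------------------
# qPCR / FISH validation fixtures

def gen_validation_fixtures(
    seed: int = 0,
    true_relative_expression: float = 0.5,
    ct_sd: float = 0.1,
    n_technical: int = 3,
    biallelic_p: tuple[float, float] = (0.18, 0.39),
    fish_n: tuple[int, int] = (286, 159),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One knockdown qPCR fixture and one FISH count fixture.

    The Ct table holds technical-replicate Cts for a target and a reference
    gene under ``control`` (empty vector) and ``treatment`` (knockdown)
    conditions; the planted treatment effect shifts the target Ct by
    -log2(``true_relative_expression``) cycles.  FISH counts are binomial
    draws of biallelic-expressing nuclei at the given per-arm proportions.
    """
    if not 0 < true_relative_expression:
        raise ParameterError("true_relative_expression must be positive")
    rng_ct, rng_fish = _streams(seed, 2)

    base = {"target": 24.0, "reference": 20.0}
    rows = []
    for condition in ("control", "treatment"):
        sample = f"{condition}_s1"
        for gene, role in (("TGT", "target"), ("REF", "reference")):
            mu = base[role]
            if condition == "treatment" and role == "target":
                mu = mu - np.log2(true_relative_expression)  # knockdown raises Ct
            for rep in range(1, n_technical + 1):
                rows.append([sample, condition, gene, role, rep,
                             mu + rng_ct.normal(0.0, ct_sd)])
    ct = pd.DataFrame(rows, columns=[
        "sample_id", "condition", "target_gene", "role", "replicate", "ct"])

    fish_rows = []
    for condition, p, n in zip(("control", "treatment"), biallelic_p, fish_n):
        k = int(rng_fish.binomial(n, p))
        fish_rows.append([condition, k, n - k])
    fish = pd.DataFrame(fish_rows, columns=["condition", "biallelic", "not_biallelic"])
    return ct, fish
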