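"""End-to-end pipeline: simulate -> call -> compare -> network -> enrich ->
idr -> validate, from one config, with a JSON manifest of every threshold,
seed and output hash.

The default scenario is fully synthetic: the generators plant a known
interactome, community structure and enriched terms, the calling and
downstream stages recover them, and the manifest records the recovery
metrics.  Individual stages can equally be run on real input files through
the CLI subcommands.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, compare, enrichment, idr, network, synthetic, validation
from .design import default_design
from .errors import LikError
from .io import write_disorder_tracks, write_edges

STAGES = ("simulate", "call-chirp", "compare", "network", "enrich", "idr", "validate")


@dataclass
class PipelineConfig:
    out_dir: str = "lik_run"
    seed: int = 0
    # simulate
    n_proteins: int = 500
    n_true: int = 50
    effect_log2fc: float = 3.0
    noise_sd: float = 0.4
    dropout_p: float = 0.0
    n_native_replicates: int = 4
    # call
    log2fc_threshold: float = calling.THREEFOLD_LOG2
    alpha: float = 0.05
    min_unique_peptides: int = 2
    # network
    min_confidence: float = 0.4
    n_permutations: int = 1000
    net_nodes: int = 150
    net_communities: int = 3
    p_in: float = 0.3
    p_out: float = 0.01
    # enrichment
    ora_alpha: float = 1e-3
    max_term_size: int = 1600
    n_terms: int = 60
    n_planted_terms: int = 5
    # idr
    n_background_sets: int = 20
    background_set_size: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise LikError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured synthetic scenario; returns the
    manifest (also written to <out_dir>/manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, info: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = info
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)

    # --- simulate -----------------------------------------------------
    design = default_design(n_native_replicates=config.n_native_replicates)
    params = synthetic.ChirpSimParams(
        n_proteins=config.n_proteins, n_true=config.n_true,
        effect_log2fc=config.effect_log2fc, noise_sd=config.noise_sd,
        dropout_p=config.dropout_p, design=design,
        seed=_sub_seed(config.seed, 1))
    table, truth = synthetic.gen_chirp_experiment(params)
    pg_path, design_path = out / "protein_groups.tsv", out / "design.tsv"
    truth_path = out / "truth_interactors.tsv"
    table.write(pg_path)
    design.write(design_path)
    pd.DataFrame({"protein_id": sorted(truth.planted_interactors)}).to_csv(
        truth_path, sep="\t", index=False)
    record("simulate", {"n_proteins": config.n_proteins, "n_true": config.n_true},
           [pg_path, design_path, truth_path])

    # --- call-chirp ---------------------------------------------------
    cfg = calling.CallConfig(
        log2fc_threshold=config.log2fc_threshold, alpha=config.alpha,
        min_unique_peptides=config.min_unique_peptides)
    filtered = calling.qc_filter(table, cfg)
    pa = calling.call_presence_absence(filtered, design, cfg)
    ratios = calling.compute_log2_ratios(filtered, design, cfg.pseudocount_policy)
    fc = calling.call_fold_change(ratios, filtered, design, cfg)
    interactome = calling.combine_candidates([fc], name="simulated")
    called = interactome.proteins
    tp = len(called & truth.planted_interactors)
    sens = tp / max(len(truth.planted_interactors), 1)
    fdr = (len(called) - tp) / max(len(called), 1)
    int_path = out / "interactome.tsv"
    interactome.to_frame().to_csv(int_path, sep="\t", index=False)
    record("call-chirp", {
        "n_after_qc": len(filtered), "n_presence_absence": len(pa),
        "n_fold_change": len(fc), "n_called": len(called),
        "sensitivity": sens, "fdr": fdr,
    }, [int_path])

    # --- compare ------------------------------------------------------
    rng = np.random.default_rng(_sub_seed(config.seed, 2))
    universe = list(table.protein_ids)
    pool = [p for p in universe if p not in called]
    shared_ids = sorted(rng.choice(sorted(called), size=min(20, len(called)),
                                   replace=False)) if called else []
    other = sorted(shared_ids) + sorted(
        rng.choice(pool, size=min(60, len(pool)), replace=False))
    cmp_result = compare.compare_interactomes(called, other)
    cmp_path = out / "comparison.tsv"
    pd.DataFrame({
        "metric": ["shared", "a_specific", "b_specific", "union"],
        "value": [len(cmp_result.shared), len(cmp_result.a_specific),
                  len(cmp_result.b_specific), cmp_result.union_size],
    }).to_csv(cmp_path, sep="\t", index=False)
    record("compare", {"shared": len(cmp_result.shared),
                       "union": cmp_result.union_size}, [cmp_path])

    # --- network ------------------------------------------------------
    net_params = synthetic.NetworkSimParams(
        n_nodes=config.net_nodes, n_communities=config.net_communities,
        p_in=config.p_in, p_out=config.p_out, seed=_sub_seed(config.seed, 3))
    edges, net_truth = synthetic.gen_network(net_params)
    edges_path = out / "edges.tsv"
    write_edges(edges, edges_path)
    nodes = sorted(net_truth.planted_communities)
    net = network.build_network(edges, nodes, min_confidence=config.min_confidence)
    stats_d = network.network_stats(net, len(nodes))
    subset = nodes[: max(2, len(nodes) // 5)]
    null = network.permutation_edge_null(
        net, subset=subset, n_perm=config.n_permutations,
        seed=_sub_seed(config.seed, 4))
    partition = network.detect_communities(net, seed=_sub_seed(config.seed, 5))
    part_path = out / "clusters.tsv"
    partition.to_frame().to_csv(part_path, sep="\t", index=False)
    record("network", {
        **stats_d, "n_clusters": partition.n_clusters,
        "modularity": partition.modularity,
        "null_expected_edges": null.expected_edges, "null_p": null.p_value,
    }, [edges_path, part_path])

    # --- enrich -------------------------------------------------------
    gene_universe = sorted(table.meta["gene_id"])
    query = sorted(table.meta.loc[list(called & set(table.protein_ids)), "gene_id"]) \
        if called else gene_universe[:50]
    sets, set_truth = synthetic.gen_gene_sets(
        gene_universe, n_terms=config.n_terms,
        size_range=(10, min(80, len(gene_universe))),
        planted_terms=config.n_planted_terms, query=query,
        seed=_sub_seed(config.seed, 6))
    results = enrichment.ora(query, gene_universe, sets,
                             max_term_size=config.max_term_size)
    sig = enrichment.significant_terms(results, alpha=config.ora_alpha)
    enr_path = out / "enrichment.tsv"
    enrichment.results_frame(results).to_csv(enr_path, sep="\t", index=False)
    record("enrich", {
        "n_tested": len(results), "n_significant": len(sig),
        "planted_recovered": len(sig & set_truth.planted_enriched_terms),
    }, [enr_path])

    # --- idr ----------------------------------------------------------
    hi = synthetic.gen_disorder_tracks(
        60, idr_block_params=synthetic.IdrBlockParams(n_blocks=(2, 4)),
        seed=_sub_seed(config.seed, 7), id_prefix="HI")
    lo = synthetic.gen_disorder_tracks(
        60, idr_block_params=synthetic.IdrBlockParams(n_blocks=(0, 1)),
        seed=_sub_seed(config.seed, 8), id_prefix="LO")
    tracks = {**hi, **lo}
    tracks_path = out / "disorder_tracks.tsv"
    write_disorder_tracks(tracks, tracks_path)
    score = idr.idr_score_table(tracks)
    cmp_groups = idr.compare_groups({
        "interactome": score.loc[list(hi), "median_idr"].tolist(),
        "background": score.loc[list(lo), "median_idr"].tolist(),
    })
    idr_path = out / "idr_comparison.tsv"
    idr.comparison_frame(cmp_groups).to_csv(idr_path, sep="\t", index=False)
    record("idr", {"kw_statistic": cmp_groups.kw_statistic,
                   "kw_p": cmp_groups.kw_p}, [tracks_path, idr_path])

    # --- validate -----------------------------------------------------
    ct, fish = synthetic.gen_validation_fixtures(seed=_sub_seed(config.seed, 9))
    kd = validation.ddct_relative_expression(ct, reference_gene="REF")
    gof = validation.fish_goodness_of_fit(
        validation.fish_counts_from_frame(fish, "control"),
        validation.fish_counts_from_frame(fish, "treatment"))
    val_path = out / "validation.tsv"
    pd.DataFrame(
        [[k.target_gene, k.ddct, k.relative_expression, k.knockdown_percent]
         for k in kd],
        columns=["target_gene", "ddct", "relative_expression", "knockdown_percent"],
    ).to_csv(val_path, sep="\t", index=False)
    record("validate", {
        "knockdown_percent": kd[0].knockdown_percent if kd else None,
        "fish_chi2": gof.chi2, "fish_p": gof.p_value,
    }, [val_path])

    manifest["n_stages_completed"] = len(manifest["stages"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
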