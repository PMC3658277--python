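"""Stage orchestration over a working directory of interchange files.

Each stage reads its inputs from, and writes its outputs to, a single
working directory, so any stage can be rerun from cached upstream outputs.
Stage order: simulate -> pwms -> tree -> scan -> filter -> enrich ->
conserve -> rewire -> kcore -> gosim -> compete.  A machine-readable YAML
report accumulates counts, statistics and p-values per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .competition import build_cluster_table, competitive_pairs, spearman_association
from .conservation import classify_rewiring, conservation_test, project_by_orthology, universe_size
from .gosim import network_benchmark
from .kcore import cross_validate, predict_novel
from .network import filter_candidates, phage_overlap_enrichment
from .pwm import build_pwm, rank_in_proteome
from .simulate import WorldConfig, gen_world
from .tree import SimilarityMatrix, build_specificity_tree

__all__ = ["PipelineConfig", "PipelineError", "STAGES", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "pwms", "tree", "scan", "filter", "enrich",
          "conserve", "rewire", "kcore", "gosim", "compete")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    workdir: Path
    seed: int = 0
    T: float = 1000.0
    alpha: float = 0.05
    kappa: float = 1.0
    trim_threshold: float = 0.76
    sim_threshold: float = 0.5
    id_threshold: float = 0.5
    tf_degree_max: int = 5
    k: int = 3
    folds: int = 10
    n_random: int = 10_000
    n_random_networks: int = 50
    per_bait: int = 100
    world: WorldConfig = field(default_factory=WorldConfig)

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        world = WorldConfig(**raw.pop("world", {}))
        return cls(world=world, **raw)


def _require(cfg: PipelineConfig, stage: str, *names: str) -> list[Path]:
    paths = [cfg.workdir / n for n in names]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        raise PipelineError(
            f"stage {stage!r}: missing upstream output {missing}; "
            f"run the producing stage first"
        )
    return paths


def _stage_simulate(cfg: PipelineConfig, report: dict) -> None:
    world = gen_world(cfg.world, seed=cfg.seed)
    world.write(cfg.workdir)
    report["simulate"] = {
        "n_domains": len(world.domain_ids),
        "n_domains_with_pwm": len(world.generator_pwms),
        "n_proteins": len(world.proteome),
        "n_true_edges": len(world.true_edges),
        "n_candidates": len(world.candidates),
        "scenario_counts": world.scenario_counts(),
    }


def _stage_pwms(cfg: PipelineConfig, report: dict) -> None:
    (peps_path,) = _require(cfg, "pwms", "peptides.tsv")
    pep_sets = io.read_peptides(peps_path)
    pwms = [build_pwm(s, alpha=cfg.alpha, kappa=cfg.kappa,
                      trim_threshold=cfg.trim_threshold) for s in pep_sets]
    io.write_pwm_dir(pwms, cfg.workdir / "pwms")
    report["pwms"] = {
        "n_pwms": len(pwms),
        "widths": {p.key: p.m for p in pwms},
    }


def _stage_tree(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "tree", "pwms")
    pwms = io.read_pwm_dir(cfg.workdir / "pwms")
    matrix = SimilarityMatrix.from_pwms(list(pwms.values()))
    io.write_similarity_matrix(matrix, cfg.workdir / "similarity.tsv")
    newick = build_specificity_tree(matrix)
    (cfg.workdir / "specificity_tree.nwk").write_text(newick + "\n")
    report["tree"] = {"n_leaves": len(matrix.ids)}


def _stage_scan(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "scan", "pwms", "proteome_a.fasta")
    pwms = io.read_pwm_dir(cfg.workdir / "pwms")
    proteome = io.read_fasta(cfg.workdir / "proteome_a.fasta")
    rank_dir = cfg.workdir / "ranks"
    rank_dir.mkdir(exist_ok=True)
    for key, pwm in pwms.items():
        table = rank_in_proteome(pwm, proteome)
        table.to_csv(rank_dir / f"{key}.ranks.tsv", sep="\t", index=False)
    report["scan"] = {"n_domains_scanned": len(pwms),
                      "proteome_size": len(proteome)}


def _read_ranks(cfg: PipelineConfig) -> dict[str, dict[str, int]]:
    ranks = {}
    for path in sorted((cfg.workdir / "ranks").glob("*.ranks.tsv")):
        key = path.name[: -len(".ranks.tsv")]
        df = pd.read_csv(path, sep="\t")
        ranks[key] = dict(zip(df["protein_id"], df["rank"].astype(int)))
    return ranks


def _stage_filter(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "filter", "candidates.tsv", "evidence.tsv")
    cands = io.read_candidates(cfg.workdir / "candidates.tsv")
    ev = io.read_evidence(cfg.workdir / "evidence.tsv")
    result = filter_candidates(cands, ev, T=cfg.T,
                               tf_degree_max=cfg.tf_degree_max)
    io.write_network(result.network, cfg.workdir / "network.tsv")
    io.write_mitab(result.network, cfg.workdir / "network.mitab.tsv")
    report["filter"] = {
        "n_candidates": result.n_candidates,
        "n_edges": len(result.network),
        "counts_before_tf_removal": result.counts_before_tf_removal,
        "counts_after_tf_removal": result.counts_after_tf_removal,
        "n_dropped_unsupported": result.n_dropped_unsupported,
        "tf_preys_removed": list(result.tf_preys_removed),
    }


def _stage_enrich(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "enrich", "network.tsv", "ranks")
    net = io.read_network(cfg.workdir / "network.tsv")
    ranks = _read_ranks(cfg)
    proteome_size = max(len(t) for t in ranks.values())
    curve, auc, p = phage_overlap_enrichment(
        net, ranks, proteome_size, n_random=cfg.n_random, seed=cfg.seed)
    np.savetxt(cfg.workdir / "enrichment_curve.tsv",
               np.column_stack([np.arange(1, curve.size + 1), curve]),
               fmt=("%d", "%.6f"), delimiter="\t", header="rank\tcum_fraction")
    report["enrich"] = {"auc": float(auc), "p_value": float(p)}


def _stage_conserve(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "conserve", "network.tsv", "orthologs.tsv",
             "reference_b_edges.tsv", "domains.tsv")
    net = io.read_network(cfg.workdir / "network.tsv")
    omap = io.read_ortholog_map(cfg.workdir / "orthologs.tsv")
    reference = io.read_reference_ppis(cfg.workdir / "reference_b_edges.tsv")
    domains = pd.read_csv(cfg.workdir / "domains.tsv", sep="\t")
    d2p = dict(zip(domains["domain_id"], domains["protein_id"]))

    class _Proj:
        def __init__(self, edges):
            self.edges = edges

        def __iter__(self):
            return iter(self.edges)

    proj_edges = []
    for e in net:
        if e.bait_type != "sh3_domain":
            continue
        proj_edges.append(type("E", (), {
            "bait_id": e.bait_id, "prey_id": e.prey_id,
            "bait_type": e.bait_type,
            "bait_protein": d2p.get(e.bait_id, e.bait_id)})())
    projected, baits, preys, n_bp = project_by_orthology(_Proj(proj_edges), omap)
    universe = universe_size(len(baits), len(preys), n_bp)
    conserved_proteins = baits | preys
    ref_in_universe = {e for e in reference if e <= conserved_proteins}
    result = conservation_test(projected, ref_in_universe, universe,
                               counts=(len(baits), len(preys), n_bp))
    report["conserve"] = {
        "n_baits_conserved": result.n_baits_conserved,
        "n_preys_conserved": result.n_preys_conserved,
        "n_bp": result.n_bp,
        "universe": result.universe,
        "n_A_interactions": result.n_A_interactions,
        "n_B_interactions": result.n_B_interactions,
        "n_overlap": result.n_overlap,
        "p_value": result.p_value,
    }


def _stage_rewire(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "rewire", "rewire_context.tsv", "pwms",
             "proteome_a.fasta", "proteome_b.fasta", "orthologs.tsv")
    ctx = pd.read_csv(cfg.workdir / "rewire_context.tsv", sep="\t",
                      keep_default_na=False)
    pwms = io.read_pwm_dir(cfg.workdir / "pwms")
    proteome_a = io.read_fasta(cfg.workdir / "proteome_a.fasta")
    proteome_b = io.read_fasta(cfg.workdir / "proteome_b.fasta")
    omap = io.read_ortholog_map(cfg.workdir / "orthologs.tsv")
    calls = []
    for r in ctx.itertuples():
        o_pwm = None
        if r.ortholog_pwm_file:
            o_pwm = io.read_pwm(cfg.workdir / "ortholog_pwms" / r.ortholog_pwm_file)
        o_targets = [proteome_b[b] for b in sorted(omap.orthologs_of(r.target_id))
                     if b in proteome_b]
        calls.append(classify_rewiring(
            r.domain_id, r.target_id,
            domain_pwm=pwms.get(r.domain_id),
            ortholog_domain_pwm=o_pwm,
            ortholog_domain_seq=r.ortholog_domain_seq or None,
            ortholog_has_sh3=bool(r.ortholog_has_sh3),
            target_seq=proteome_a.get(r.target_id),
            ortholog_target_seqs=o_targets,
            sim_threshold=cfg.sim_threshold, id_threshold=cfg.id_threshold,
            T=cfg.T,
        ))
    io.write_rewiring_calls(calls, cfg.workdir / "rewiring_calls.tsv")
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.scenario] = counts.get(c.scenario, 0) + 1
    report["rewire"] = {"n_classified": len(calls), "scenario_counts": counts}


def _stage_kcore(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "kcore", "function_graph.tsv", "seeds.txt", "negatives.txt")
    import networkx as nx

    g = nx.read_edgelist(cfg.workdir / "function_graph.tsv", delimiter="\t")
    seeds = set(io.read_id_list(cfg.workdir / "seeds.txt"))
    negatives = set(io.read_id_list(cfg.workdir / "negatives.txt"))
    mean_auc, folds = cross_validate(g, seeds, negatives, folds=cfg.folds,
                                     seed=cfg.seed)
    predictions = predict_novel(g, seeds, k=cfg.k)
    pd.DataFrame(predictions,
                 columns=["protein_id", "score", "degree_to_seeds"]).to_csv(
        cfg.workdir / "predictions.tsv", sep="\t", index=False)
    report["kcore"] = {"mean_auc": mean_auc, "k": cfg.k,
                       "n_predictions": len(predictions),
                       "per_fold": folds}


def _stage_gosim(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "gosim", "ontology.obo", "annotations.tsv", "network.tsv",
             "proteome_a.fasta", "domains.tsv")
    corpus = io.read_corpus(cfg.workdir / "ontology.obo",
                            cfg.workdir / "annotations.tsv")
    net = io.read_network(cfg.workdir / "network.tsv")
    domains = pd.read_csv(cfg.workdir / "domains.tsv", sep="\t")
    d2p = dict(zip(domains["domain_id"], domains["protein_id"]))
    edges = [(d2p.get(e.bait_id, e.bait_id), e.prey_id) for e in net]
    universe = sorted(io.read_fasta(cfg.workdir / "proteome_a.fasta"))
    metrics = network_benchmark(edges, corpus, universe,
                                n_networks=cfg.n_random_networks,
                                per_bait=min(cfg.per_bait, len(universe)),
                                seed=cfg.seed)
    report["gosim"] = {
        m.name: {"real": m.real, "null_mean": m.null_mean,
                 "null_sd": m.null_sd, "p_value": m.p_value}
        for m in metrics
    }


def _stage_compete(cfg: PipelineConfig, report: dict) -> None:
    _require(cfg, "compete", "network.tsv", "pwms", "proteome_a.fasta",
             "domains.tsv")
    net = io.read_network(cfg.workdir / "network.tsv")
    pwms = io.read_pwm_dir(cfg.workdir / "pwms")
    proteome = io.read_fasta(cfg.workdir / "proteome_a.fasta")
    domains = pd.read_csv(cfg.workdir / "domains.tsv", sep="\t")
    d2p = dict(zip(domains["domain_id"], domains["protein_id"]))
    table = build_cluster_table(net, pwms, proteome, domain_to_protein=d2p,
                                T=cfg.T)
    table.targets.to_csv(cfg.workdir / "cluster_table_targets.tsv",
                         sep="\t", index=False)
    table.baits.to_csv(cfg.workdir / "cluster_table_baits.tsv",
                       sep="\t", index=False)
    pairs = competitive_pairs(net, pwms, proteome, T=cfg.T)
    pairs.to_csv(cfg.workdir / "competitive_pairs.tsv", sep="\t", index=False)
    out = {"n_targets_mapped": len(table.targets)}
    if len(table.targets) >= 3 and table.targets["n_motifs"].nunique() > 1 \
            and table.targets["n_sh3_partners"].nunique() > 1:
        rho, rho2, p = spearman_association(table.targets["n_motifs"],
                                            table.targets["n_sh3_partners"])
        out["motifs_vs_partners"] = {"rho": rho, "rho_squared": rho2, "p": p}
    if len(table.baits) >= 3 and table.baits["n_sh3_domains"].nunique() > 1 \
            and table.baits["degree"].nunique() > 1:
        rho, rho2, p = spearman_association(table.baits["n_sh3_domains"],
                                            table.baits["degree"])
        out["domains_vs_degree"] = {"rho": rho, "rho_squared": rho2, "p": p}
    report["compete"] = out


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "pwms": _stage_pwms, "tree": _stage_tree,
    "scan": _stage_scan, "filter": _stage_filter, "enrich": _stage_enrich,
    "conserve": _stage_conserve, "rewire": _stage_rewire,
    "kcore": _stage_kcore, "gosim": _stage_gosim, "compete": _stage_compete,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; returns the run report.

    The report is also written to ``<workdir>/report.yaml``; rerunning with
    identical configuration and seed reproduces it exactly.
    """
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    config.workdir.mkdir(parents=True, exist_ok=True)

    report_path = config.workdir / "report.yaml"
    report: dict = {}
    if report_path.exists():
        report = yaml.safe_load(report_path.read_text()) or {}
    report["parameters"] = {
        "seed": config.seed, "T": config.T, "alpha": config.alpha,
        "kappa": config.kappa, "trim_threshold": config.trim_threshold,
        "sim_threshold": config.sim_threshold,
        "id_threshold": config.id_threshold, "k": config.k,
        "folds": config.folds, "n_random": config.n_random,
    }
    for stage in STAGES:
        if stage not in requested:
            continue
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, report)
    report_path.write_text(yaml.safe_dump(report, sort_keys=True))
    return report
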