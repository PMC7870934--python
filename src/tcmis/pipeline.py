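"""End-to-end orchestration of the screen.

Stages run in order: literature screen -> network assembly -> gene-set
restriction -> degree analysis -> per-gene-set scoring models ->
consensus -> clustering -> optional single-herb case study. Stages
communicate via files inside the run directory so any stage can be
re-inspected in isolation; a manifest JSON records row counts at every
stage, and every TSV carries a header comment with the config hash and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import chemclust, genesets, hct_network, litmine, permscore
from .stats_core import DomainError

__all__ = ["RunConfig", "StageError", "run_all", "case_study"]

log = logging.getLogger("tcmis")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    literature: Optional[str] = None
    herb_compound: str = ""
    compound_target: str = ""
    genesets_gmt: str = ""
    smiles: Optional[str] = None
    blocklist: Optional[str] = None

    total_papers: int = 29_000_000
    disease_papers: int = 3_874_763

    q_herb: float = 0.01
    r_threshold: float = 0.05
    affinity_um: float = 10.0
    q_compound: float = 0.01
    min_degree: int = 10
    proportion_threshold: float = 0.10

    permutations: int = 100_000
    universe: int = 20462
    seed: int = 0
    roster: list[str] = field(default_factory=lambda: ["IO", "IM", "IN", "IG-1", "IG-2"])
    restriction_geneset: str = "IG-2"
    method: str = "permutation"
    normalization: str = "zstandardize"
    clusters: int = 5

    case_study_herb: Optional[str] = None
    case_study_compounds: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        inputs = raw.get("inputs", {})
        for key in ("literature", "herb_compound", "compound_target", "genesets_gmt", "smiles", "blocklist"):
            if key in inputs:
                setattr(cfg, key, inputs[key])
        corpus = raw.get("corpus", {})
        cfg.total_papers = int(corpus.get("total_papers", cfg.total_papers))
        cfg.disease_papers = int(corpus.get("disease_papers", cfg.disease_papers))
        thr = raw.get("thresholds", {})
        cfg.q_herb = float(thr.get("q_herb", cfg.q_herb))
        cfg.r_threshold = float(thr.get("r", cfg.r_threshold))
        cfg.affinity_um = float(thr.get("affinity_um", cfg.affinity_um))
        cfg.q_compound = float(thr.get("q_compound", cfg.q_compound))
        cfg.min_degree = int(thr.get("min_degree", cfg.min_degree))
        cfg.proportion_threshold = float(thr.get("proportion", cfg.proportion_threshold))
        cfg.permutations = int(raw.get("permutations", cfg.permutations))
        cfg.universe = int(raw.get("universe", cfg.universe))
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.roster = list(raw.get("roster", cfg.roster))
        cfg.restriction_geneset = raw.get("restriction_geneset", cfg.restriction_geneset)
        cfg.method = raw.get("method", cfg.method)
        cfg.normalization = raw.get("normalization", cfg.normalization)
        cfg.clusters = int(raw.get("clusters", cfg.clusters))
        case = raw.get("case_study", {}) or {}
        cfg.case_study_herb = case.get("herb")
        cfg.case_study_compounds = list(case.get("compounds", []))
        return cfg

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_geneset_roster(cfg: RunConfig) -> tuple[genesets.GeneSetCollection, dict]:
    base_sets = genesets.read_gmt(cfg.genesets_gmt)
    base = genesets.GeneSetCollection(sets=base_sets, universe_size=cfg.universe)
    all_sets = list(base_sets)
    if len(base_sets) >= 2:
        all_sets.append(genesets.integrate_min_membership(base, min_sets=2, name="IG-1"))
    all_sets.append(genesets.union_sets(base, name="IG-2"))
    by_name = {s.name: s for s in all_sets}
    missing = [name for name in cfg.roster if name not in by_name]
    if missing:
        raise StageError("genesets", f"roster sets not available: {missing}")
    collection = genesets.GeneSetCollection(
        sets=[by_name[n] for n in dict.fromkeys(cfg.roster + [cfg.restriction_geneset]) if n in by_name],
        universe_size=cfg.universe,
    )
    sizes = {s.name: len(s) for s in all_sets}
    return collection, sizes


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns (and writes) the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config={config.hash()} seed={config.seed}"
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}

    # stage A: literature screen -----------------------------------------
    herb_filter: Optional[set[str]] = None
    if config.literature:
        try:
            records = litmine.read_literature_table(config.literature)
            corpus = litmine.CorpusStats(config.total_papers, config.disease_papers)
            screened = litmine.screen_herbs(
                records, corpus, q_threshold=config.q_herb, r_threshold=config.r_threshold
            )
        except DomainError as exc:
            raise StageError("screen", str(exc)) from exc
        litmine.write_screen_table(screened, out / "screened_herbs.tsv", stamp)
        herb_filter = {r.herb_id for r in screened if r.significant}
        manifest["stages"]["screen"] = {
            "herbs_in": len(screened),
            "herbs_significant": len(herb_filter),
        }
        log.info("screen: %d herbs in, %d significant", len(screened), len(herb_filter))

    # stage B: network assembly ------------------------------------------
    try:
        hc_pairs = hct_network.read_herb_compound_table(config.herb_compound)
        ct_edges = hct_network.read_compound_target_table(
            config.compound_target, threshold_um=config.affinity_um
        )
        network, rejects = hct_network.assemble(hc_pairs, ct_edges, herb_filter)
    except (DomainError, hct_network.AffinityParseError, OSError) as exc:
        raise StageError("network", str(exc)) from exc
    if rejects:
        (out / "assembly_rejects.txt").write_text("\n".join(rejects) + "\n")
    try:
        collection, set_sizes = _load_geneset_roster(config)
    except DomainError as exc:
        raise StageError("genesets", str(exc)) from exc
    restriction = collection[config.restriction_geneset]
    cir_network = hct_network.restrict_to_geneset(network, restriction)
    hct_network.write_edge_lists(cir_network, out / "cir_network", stamp)
    hct_network.to_graphml(cir_network, out / "cir_network" / "network.graphml")
    manifest["stages"]["network"] = {
        "hc_pairs_in": len(hc_pairs),
        "ct_rows_in": len(ct_edges),
        "ct_deduped": len(network.ct_edges),
        "rejected_rows": len(rejects),
        "full": {
            "herbs": len(network.herbs),
            "compounds": len(network.compounds),
            "targets": len(network.targets),
            "ct_edges": len(network.ct_edges),
        },
        "restricted": {
            "geneset": restriction.name,
            "herbs": len(cir_network.herbs),
            "compounds": len(cir_network.compounds),
            "targets": len(cir_network.targets),
            "hc_edges": len(cir_network.hc_edges),
            "ct_edges": len(cir_network.ct_edges),
            "edges_total": cir_network.n_edges,
            "nodes_total": cir_network.n_nodes,
            "direct": cir_network.direct_count(),
            "indirect": len(cir_network.ct_edges) - cir_network.direct_count(),
        },
        "geneset_sizes": set_sizes,
    }
    log.info(
        "network: %d nodes / %d edges after restriction to %s",
        cir_network.n_nodes, cir_network.n_edges, restriction.name,
    )

    # stage C: degree analysis -------------------------------------------
    try:
        report = hct_network.degree_report(cir_network)
    except DomainError as exc:
        raise StageError("degrees", str(exc)) from exc
    high = hct_network.select_high_degree_genes(report, config.min_degree)
    mean_k, mean_d = report.display_means()
    with open(out / "degree_report.tsv", "w") as fh:
        fh.write(f"# {stamp}\n")
        fh.write("node_id\tkind\tdegree\n")
        for c, d in sorted(report.compound_degree.items()):
            fh.write(f"{c}\tcompound\t{d}\n")
        for t, d in sorted(report.target_degree.items()):
            fh.write(f"{t}\ttarget\t{d}\n")
    max_target = max(report.target_degree.items(), key=lambda kv: (kv[1], kv[0]))
    manifest["stages"]["degrees"] = {
        "mean_compound_degree": mean_k,
        "mean_target_degree": mean_d,
        "max_target_degree": max_target[1],
        "max_target_gene": max_target[0],
        "high_degree_genes": len(high),
    }

    # stage D: scoring models --------------------------------------------
    blocked: frozenset[str] = frozenset()
    if config.blocklist and Path(config.blocklist).exists():
        blocked = frozenset(
            line.strip()
            for line in Path(config.blocklist).read_text().splitlines()
            if line.strip()
        )
    profiles = permscore.profiles_from_ct_edges(network.ct_edges)
    models = []
    per_model_counts = {}
    for name in config.roster:
        settings = permscore.ScoreSettings(
            universe_size=config.universe,
            n_permutations=config.permutations,
            seed=config.seed,
            q_threshold=config.q_compound,
            method=config.method,
            blocklist=blocked,
        )
        try:
            model = permscore.score_model(profiles, collection[name], settings)
        except DomainError as exc:
            raise StageError("score", f"model {name}: {exc}") from exc
        models.append(model)
        table = permscore.model_table(model)
        with open(out / f"model_{name}.tsv", "w") as fh:
            fh.write(f"# {stamp} method={config.method}\n")
            table.to_csv(fh, sep="\t", index=False)
        per_model_counts[name] = {
            "scored": len(model.results),
            "positives": len(model.positives),
        }
        log.info("score[%s]: %d scored, %d positive", name, len(model.results), len(model.positives))
    consensus = permscore.combine_models(models, config.normalization)
    with open(out / "consensus.tsv", "w") as fh:
        fh.write(f"# {stamp} normalization={config.normalization}\n")
        fh.write("compound_id\tcombined_z\tn_models_positive\tunion_positive\tall_model_positive\n")
        pos_counts = {
            cid: sum(cid in m.positives for m in models) for cid in consensus.combined_z
        }
        for cid, z in consensus.ranked():
            fh.write(
                f"{cid}\t{z:.6f}\t{pos_counts[cid]}\t"
                f"{cid in consensus.union_positives}\t{cid in consensus.all_model_positives}\n"
            )
    manifest["stages"]["models"] = {
        "per_model": per_model_counts,
        "union_positives": len(consensus.union_positives),
        "all_model_positives": len(consensus.all_model_positives),
        "normalization": config.normalization,
        "method": config.method,
    }

    # positive-ingredient proportions per herb
    proportions = hct_network.positive_proportion_by_herb(
        cir_network, consensus.union_positives, config.proportion_threshold
    )
    with open(out / "herb_positive_proportions.tsv", "w") as fh:
        fh.write(f"# {stamp}\n")
        proportions.to_csv(fh, sep="\t", index=False)
    manifest["stages"]["proportions"] = {
        "herbs_flagged": int(proportions["flagged"].sum()),
    }

    # stage E: clustering -------------------------------------------------
    if config.smiles and consensus.union_positives:
        smiles_rows = {
            cid: smi for cid, smi in chemclust.read_smiles_file(config.smiles)
        }
        fps = []
        unparsed = []
        for cid in sorted(consensus.union_positives):
            if cid not in smiles_rows:
                unparsed.append(cid)
                continue
            try:
                fps.append(
                    chemclust.fingerprint_from_smiles(smiles_rows[cid], compound_id=cid)
                )
            except chemclust.SmilesParseError:
                unparsed.append(cid)
        k = min(config.clusters, len(fps))
        if k >= 1 and fps:
            result = chemclust.cluster(fps, k=k, seed=config.seed)
            chemclust.write_clusters(fps, result, out / "clusters", stamp)
            manifest["stages"]["clusters"] = {
                "compounds": len(fps),
                "k": k,
                "objective_rms": result.objective,
                "unresolved_smiles": len(unparsed),
            }

    # optional case study -------------------------------------------------
    if config.case_study_herb:
        manifest["stages"]["case_study"] = case_study(
            cir_network,
            config.case_study_herb,
            config.case_study_compounds or None,
            out / "case_study",
            stamp,
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def case_study(
    cir_network: hct_network.HCTNetwork,
    herb_id: str,
    focus_compounds: Optional[list[str]],
    out_dir: str | Path,
    stamp: str = "",
) -> dict:
    """Single-herb subnetwork exports plus a shared-target report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        sub = hct_network.herb_subnetwork(cir_network, herb_id)
    except DomainError as exc:
        raise StageError("case_study", str(exc)) from exc
    hct_network.write_edge_lists(sub, out / "herb_subnetwork", stamp)
    info = {
        "herb": herb_id,
        "compounds": len(sub.compounds),
        "targets": len(sub.targets),
        "ct_edges": len(sub.ct_edges),
    }
    if focus_compounds:
        focus = hct_network.herb_subnetwork(cir_network, herb_id, set(focus_compounds))
        hct_network.write_edge_lists(focus, out / "focus_subnetwork", stamp)
        info["focus_compounds"] = len(focus.compounds)
        info["focus_ct_edges"] = len(focus.ct_edges)
        if len(focus.compounds) >= 2:
            shared = hct_network.shared_targets(focus, focus.compounds)
            (out / "shared_targets.txt").write_text(
                "\n".join(sorted(shared.genes)) + ("\n" if shared.genes else "")
            )
            info["focus_shared_targets"] = len(shared)
    return info
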