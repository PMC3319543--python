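"""End-to-end orchestration: expression -> mRMR -> IFS -> seed genes ->
shortest paths -> betweenness permutation -> gene-set statistics.

A single declarative config (YAML or dict) names the input files and
parameters; ``run_pipeline`` executes the stages in order, writes every
result table as TSV plus a run-metadata JSON, and is byte-deterministic
under a fixed rng_seed. A stage failure aborts with the stage name and
leaves a FAILED marker next to the partial outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ifs_scan, optimal_feature_set
from .containers import ExpressionMatrix, GeneSetCollection, IdMap
from .io import (map_probes_to_genes, read_edge_table,
                 read_expression_table, read_gmt, read_id_map, write_tables)
from .network import (build_graph, path_gene_betweenness, permutation_test,
                      seed_pair_shortest_paths)
from .selection import discretize, max_relevance_ranking, mrmr_select, \
    ttest_ranking
from .stats import (functional_profile, overlap_test, profile_similarity,
                    term_enrichment)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input files and parameters for one pipeline run."""

    expression: str
    network: str
    out_dir: str
    label_source: str = "label"
    orientation: str = "samples-as-rows"
    id_map: str | None = None
    annotations: str | None = None   # GMT of pathway/term annotations
    gene_lists: str | None = None    # GMT of curated disease gene lists
    alpha: float = 1.0
    mrmr_rounds: int = 50
    max_i: int | None = None
    transform: str = "complement"
    n_perm: int = 5000
    rng_seed: int = 0
    background: str = "chip"         # "chip" or a path to a gene list file
    n_seed_probes: int | None = None  # None: IFS-optimal set seeds the
    # network stage; an integer uses the top-n mRMR probes instead

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for name in ("expression", "network", "id_map", "annotations",
                     "gene_lists"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name} = {value!r} "
                                        f"does not exist")
        if self.background != "chip" and not Path(self.background).exists():
            raise FileNotFoundError(
                f"background gene list {self.background!r} does not exist")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _seed_nodes(probes: list[str], id_map: IdMap | None,
                graph_nodes: set[str]) -> tuple[list[str], list[str]]:
    """Map optimal probes to network node ids (gene symbol preferred,
    protein id as fallback). Returns (genes, node ids)."""
    if id_map is None:
        genes = [p for p in probes]
    else:
        genes = [g for g in map_probes_to_genes(probes, id_map)
                 if g is not None]
    nodes = []
    for gene in genes:
        if gene in graph_nodes:
            nodes.append(gene)
            continue
        protein = id_map.protein_for_gene(gene) if id_map else None
        if protein and protein in graph_nodes:
            nodes.append(protein)
        else:
            raise KeyError(f"seed gene {gene} (protein {protein}) absent "
                           f"from the network")
    return genes, nodes


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage and write the report bundle to config.out_dir."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    results: dict[str, object] = {}
    meta: dict[str, object] = {
        "pathmarker_version": __version__,
        "parameters": asdict(config),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                write_tables(results, out_dir)
                failed_marker.write_text(f"stage {name}: {exc}\n")
                raise StageError(name, exc) from exc
            meta["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s: done", name)
        return deco

    state: dict[str, object] = {}

    @stage("load")
    def _load():
        state["em"] = read_expression_table(
            config.expression, orientation=config.orientation,
            label_source=config.label_source)
        state["edges"] = read_edge_table(config.network)
        state["id_map"] = (read_id_map(config.id_map)
                           if config.id_map else None)
        state["annotations"] = (read_gmt(config.annotations)
                                if config.annotations else None)
        state["gene_lists"] = (read_gmt(config.gene_lists)
                               if config.gene_lists else None)

    @stage("mrmr")
    def _mrmr():
        em: ExpressionMatrix = state["em"]
        dm = discretize(em, alpha=config.alpha)
        results["maxrel_table"] = max_relevance_ranking(dm, em.labels)
        rounds = min(config.mrmr_rounds, em.n_probes)
        results["mrmr_table"] = mrmr_select(dm, em.labels, rounds)
        results["ttest_table"] = ttest_ranking(em)

    @stage("ifs")
    def _ifs():
        em: ExpressionMatrix = state["em"]
        ranking = results["mrmr_table"]
        max_i = config.max_i or min(1000, len(ranking))
        curve = ifs_scan(ranking, em, max_i=min(max_i, len(ranking)))
        results["ifs_curve"] = curve
        state["optimal_probes"] = optimal_feature_set(curve, ranking)

    @stage("seeds")
    def _seeds():
        if config.n_seed_probes is not None:
            state["optimal_probes"] = results["mrmr_table"].top(
                config.n_seed_probes)
        graph_nodes = set(state["edges"].nodes())
        genes, nodes = _seed_nodes(state["optimal_probes"], state["id_map"],
                                   graph_nodes)
        state["seed_genes"] = genes
        state["seed_nodes"] = nodes
        id_map: IdMap | None = state["id_map"]
        per_probe = [
            (id_map.gene_for_probe(p) or "") if id_map else p
            for p in state["optimal_probes"]]
        results["optimal_set"] = pd.DataFrame({
            "order": range(1, len(state["optimal_probes"]) + 1),
            "probe_id": state["optimal_probes"],
            "gene_symbol": per_probe,
        })

    @stage("paths")
    def _paths():
        graph = build_graph(state["edges"], transform=config.transform)
        state["graph"] = graph
        records = seed_pair_shortest_paths(graph, state["seed_nodes"])
        state["path_records"] = records
        results["paths"] = pd.DataFrame(
            [(r.source, r.target, " -> ".join(r.nodes), r.cost)
             for r in records if r.reachable],
            columns=["source", "target", "path", "cost"])
        state["betweenness"] = path_gene_betweenness(records,
                                                     state["seed_nodes"])

    @stage("permutation")
    def _permutation():
        results["betweenness"] = permutation_test(
            state["graph"], k=len(state["seed_nodes"]),
            observed=state["betweenness"], n_perm=config.n_perm,
            rng_seed=config.rng_seed)
        bt = results["betweenness"]
        state["path_genes"] = bt.table["gene"].tolist()
        state["candidate_genes"] = sorted(set(state["seed_genes"])
                                          | set(state["path_genes"]))

    @stage("geneset_stats")
    def _stats():
        annotations: GeneSetCollection | None = state["annotations"]
        gene_lists: GeneSetCollection | None = state["gene_lists"]
        background = _background_genes(config, state)
        candidates = set(state["candidate_genes"])
        if annotations is not None:
            results["enrichment_candidates"] = term_enrichment(
                candidates, annotations, background)
        if gene_lists is not None:
            rows = []
            for name in gene_lists.names():
                overlap, p = overlap_test(candidates, gene_lists[name],
                                          background)
                rows.append((name, len(overlap),
                             ";".join(sorted(overlap)), p))
            results["overlap"] = pd.DataFrame(
                rows, columns=["gene_list", "overlap", "genes", "p_value"])
            if annotations is not None:
                prof_c = functional_profile(candidates, annotations,
                                            background)
                sims = []
                for name in gene_lists.names():
                    listed = gene_lists[name] & background
                    if not listed:
                        continue
                    prof_l = functional_profile(listed, annotations,
                                                background)
                    try:
                        r = profile_similarity(prof_c, prof_l)
                    except ValueError:
                        r = float("nan")
                    sims.append((name, r))
                results["funcsim"] = pd.DataFrame(
                    sims, columns=["gene_list", "pearson_r"])

    @stage("write")
    def _write():
        written = write_tables(results, out_dir)
        meta["outputs"] = [p.name for p in written]
        meta["rng_seed"] = config.rng_seed
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return results


def _background_genes(config: PipelineConfig,
                      state: dict[str, object]) -> set[str]:
    """Background = all genes on the chip by default, or a supplied list."""
    if config.background != "chip":
        with open(config.background) as fh:
            return {line.strip() for line in fh if line.strip()}
    em: ExpressionMatrix = state["em"]
    id_map: IdMap | None = state["id_map"]
    if id_map is None:
        return set(em.probe_ids)
    genes = map_probes_to_genes(list(em.probe_ids), id_map)
    return {g for g in genes if g is not None}
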