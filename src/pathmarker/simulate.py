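"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the study's inputs at desk scale:

* ``simulate_expression`` — a two-class log-scale expression matrix with a
  small set of planted discriminative probes (mean shift in the positive
  class), optional correlated redundant copies of each, and Gaussian
  background probes. Defaults mirror the study's design: 26 vs 26 paired
  samples, 6 informative probes, effect five noise-SDs.
* ``simulate_network`` — a confidence-weighted undirected network in which
  each designated seed-gene pair is connected by a designed backbone path
  that is the strict cost minimum, with one hub gene placed on several
  backbones. Background edges get confidences low enough that any route
  using one costs more than any full backbone.
* ``simulate_annotations`` — a GMT-style term collection in which one
  designated term over-represents a target gene set by a chosen factor.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import EdgeTable, ExpressionMatrix, GeneSetCollection


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators."""

    informative_probe_ids: list[str] = field(default_factory=list)
    redundant_block_map: dict[str, list[str]] = field(default_factory=dict)
    seed_gene_ids: list[str] = field(default_factory=list)
    planted_path_genes: list[str] = field(default_factory=list)
    planted_hub_id: str | None = None
    hub_betweenness: int = 0
    backbone_paths: dict[tuple[str, str], list[str]] = field(
        default_factory=dict)
    enriched_term_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        redundant = {c for copies in self.redundant_block_map.values()
                     for c in copies}
        if redundant & set(self.informative_probe_ids):
            raise ValueError("informative and redundant sets must be disjoint")
        if set(self.planted_path_genes) & set(self.seed_gene_ids):
            raise ValueError("planted path genes must not be seed genes")


def simulate_expression(n_pos: int = 26, n_neg: int = 26,
                        n_probes: int = 2000, k_informative: int = 6,
                        effect_size: float = 5.0, noise_sd: float = 1.0,
                        n_redundant_per_informative: int = 0,
                        redundancy_noise_sd: float = 0.25,
                        baseline: float = 8.0,
                        seed: int = 0) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Two-class log-scale expression matrix with planted signal.

    Background probes are class-independent Gaussian(baseline, noise_sd).
    Informative probes are shifted by ``effect_size`` in the positive
    class, with the shift direction alternating across probes (up, down,
    up, ...) the way real tumor signatures mix over- and under-expressed
    genes; an all-up signature would move samples along the all-ones
    diagonal, which a direction-based (cosine) classifier cannot see.
    Each redundant copy equals its informative parent plus
    Gaussian(0, redundancy_noise_sd) noise, planting the correlated blocks
    that a redundancy-penalizing selector must demote.
    """
    if n_pos < 1 or n_neg < 1 or n_probes < 1 or k_informative < 0:
        raise ValueError("sample and probe counts must be positive")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if n_redundant_per_informative < 0 or redundancy_noise_sd < 0:
        raise ValueError("redundancy parameters must be non-negative")
    if k_informative * (1 + n_redundant_per_informative) > n_probes:
        raise ValueError("informative probes plus redundant copies exceed "
                         "the probe count")

    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    values = rng.normal(baseline, noise_sd, size=(n, n_probes))
    labels = np.concatenate([np.ones(n_pos, dtype=int),
                             np.zeros(n_neg, dtype=int)])

    # informative probes scattered over the matrix, reproducibly
    special = rng.choice(n_probes,
                         size=k_informative * (1 + n_redundant_per_informative),
                         replace=False)
    informative = special[:k_informative]
    copies = special[k_informative:]
    signs = np.where(np.arange(k_informative) % 2 == 0, 1.0, -1.0)
    values[np.ix_(labels == 1, informative)] += effect_size * signs

    probe_ids = [f"P{j:05d}" for j in range(n_probes)]
    block_map: dict[str, list[str]] = {}
    for r, parent in enumerate(informative):
        mine = copies[r * n_redundant_per_informative:
                      (r + 1) * n_redundant_per_informative]
        for c in mine:
            values[:, c] = values[:, parent] + rng.normal(
                0.0, redundancy_noise_sd, size=n)
        block_map[probe_ids[parent]] = [probe_ids[c] for c in mine]

    sample_ids = ([f"T{j:02d}" for j in range(n_pos)]
                  + [f"N{j:02d}" for j in range(n_neg)])
    em = ExpressionMatrix(values, sample_ids, probe_ids, labels)
    truth = PlantedTruth(
        informative_probe_ids=[probe_ids[j] for j in informative],
        redundant_block_map=block_map,
    )
    return em, truth


def simulate_network(n_nodes: int = 60, seed_gene_count: int = 6,
                     backbone_confidence: float = 700.0,
                     background_edge_prob: float = 0.2,
                     background_confidence_range: tuple[float, float] = (100.0,
                                                                         300.0),
                     hub_degree: int = 7,
                     seed: int = 0) -> tuple[EdgeTable, PlantedTruth]:
    """Weighted network with planted backbone paths joining the seed genes.

    Construction (thousand confidence scale, path cost = sum of
    1000 - confidence):

    * One hub gene is wired directly to the ``m`` seeds with the smallest
      ``m`` such that C(m,2) >= hub_degree, at confidence
      ``backbone_confidence``; among those seeds, C(m,2) - hub_degree pairs
      are "demoted" by a private interior gene at confidence
      ``backbone_confidence + 10`` (cheaper than the hub route), leaving
      exactly ``hub_degree`` pairs whose cheapest route is via the hub.
    * Every remaining seed pair gets a private interior gene at confidence
      ``backbone_confidence - 10`` (still far cheaper than background).
    * Background/filler nodes attach by random edges with confidences drawn
      from ``background_confidence_range``; the range top must sit far
      enough below the backbone band that a single background edge costs
      more than any complete backbone, which makes every designed backbone
      the strict cost minimum.

    For ``n_nodes`` <= 25 strict optimality of every backbone is verified
    at generation time by exhaustive simple-path enumeration.
    """
    k = seed_gene_count
    if k < 2:
        raise ValueError("seed_gene_count must be at least 2")
    n_pairs = k * (k - 1) // 2
    if not 0 <= hub_degree <= n_pairs:
        raise ValueError(f"hub_degree must be in [0, C({k},2)={n_pairs}]")
    bg_lo, bg_hi = background_confidence_range
    if not 0 < bg_lo <= bg_hi < backbone_confidence:
        raise ValueError("backbone_confidence must lie strictly above the "
                         "background confidence range")
    delta = 10.0
    if backbone_confidence + delta > 999:
        raise ValueError("backbone_confidence too high to leave headroom "
                         "for the demoted-pair band")
    # any single background edge must cost more than the costliest backbone
    # (two edges at backbone_confidence - delta)
    if 1000 - bg_hi <= 2 * (1000 - (backbone_confidence - delta)):
        raise ValueError("background confidences too high: a background "
                         "detour could undercut a designed backbone")

    # hub serves exactly hub_degree pairs drawn from a C(m,2) clique
    m = 0
    while m * (m - 1) // 2 < hub_degree:
        m += 1
    if m > k:
        raise ValueError("hub_degree infeasible for this seed count")

    seeds = [f"SEED{j}" for j in range(k)]
    hub = "HUB0"
    hub_seeds = seeds[:m]
    clique_pairs = list(itertools.combinations(hub_seeds, 2))
    hub_pairs = clique_pairs[:hub_degree]
    demoted_pairs = clique_pairs[hub_degree:]
    other_pairs = [p for p in itertools.combinations(seeds, 2)
                   if p not in clique_pairs]

    edges: list[tuple[str, str, float]] = []
    backbones: dict[tuple[str, str], list[str]] = {}
    interior: list[str] = []
    if hub_degree > 0:
        for s in hub_seeds:
            edges.append((s, hub, backbone_confidence))
        interior.append(hub)
    for idx, (s, t) in enumerate(demoted_pairs):
        node = f"VIA_D{idx}"
        edges += [(s, node, backbone_confidence + delta),
                  (node, t, backbone_confidence + delta)]
        backbones[(s, t)] = [s, node, t]
        interior.append(node)
    for idx, (s, t) in enumerate(other_pairs):
        node = f"VIA{idx}"
        edges += [(s, node, backbone_confidence - delta),
                  (node, t, backbone_confidence - delta)]
        backbones[(s, t)] = [s, node, t]
        interior.append(node)
    for s, t in hub_pairs:
        backbones[(s, t)] = [s, hub, t]

    core = seeds + interior
    n_core = len(core)
    if n_nodes < n_core:
        raise ValueError(f"n_nodes must be at least {n_core} to hold "
                         f"{k} seeds and {len(interior)} interior genes")

    rng = np.random.default_rng(seed)
    fillers = [f"BG{j}" for j in range(n_nodes - n_core)]
    all_nodes = core + fillers

    def bg_conf() -> float:
        return float(np.round(rng.uniform(bg_lo, bg_hi), 1))

    # connectivity: every filler hangs off a random earlier node
    for j, node in enumerate(fillers):
        anchor = all_nodes[int(rng.integers(0, n_core + j))]
        edges.append((anchor, node, bg_conf()))
    # extra background edges between non-adjacent node pairs
    designed = {frozenset((a, b)) for a, b, _ in edges}
    for a, b in itertools.combinations(all_nodes, 2):
        if frozenset((a, b)) in designed:
            continue
        if rng.random() < background_edge_prob:
            edges.append((a, b, bg_conf()))

    et = EdgeTable(pd.DataFrame(edges, columns=["node_a", "node_b", "score"]),
                   scale="thousand")
    truth = PlantedTruth(
        seed_gene_ids=seeds,
        planted_path_genes=sorted(interior),
        planted_hub_id=hub if hub_degree > 0 else None,
        hub_betweenness=hub_degree,
        backbone_paths=backbones,
    )

    if n_nodes <= 25:
        _verify_backbones_exhaustively(et, truth)
    return et, truth


def _verify_backbones_exhaustively(et: EdgeTable, truth: PlantedTruth) -> None:
    """Check by simple-path enumeration that each designed backbone is the
    unique cheapest seed-pair route (generation-time internal audit)."""
    g = nx.Graph()
    for row in et.edges.itertuples():
        g.add_edge(row.node_a, row.node_b, weight=1000.0 - row.score)
    # a path of k edges costs >= k * w_min, so any route longer than
    # max_cost / w_min cannot tie or beat a backbone; enumeration can stop
    # at that depth without losing exhaustiveness
    w_min = min(d["weight"] for _, _, d in g.edges(data=True))
    max_cost = max(
        sum(g[u][v]["weight"] for u, v in zip(p, p[1:]))
        for p in truth.backbone_paths.values())
    cutoff = int(max_cost / w_min) + 1
    for (s, t), designed in truth.backbone_paths.items():
        best_cost = math.inf
        best_paths: list[list[str]] = []
        for path in nx.all_simple_paths(g, s, t, cutoff=cutoff):
            cost = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
            if cost < best_cost - 1e-9:
                best_cost, best_paths = cost, [path]
            elif abs(cost - best_cost) <= 1e-9:
                best_paths.append(path)
        if len(best_paths) != 1 or best_paths[0] != designed:
            raise AssertionError(
                f"designed backbone for ({s}, {t}) is not the strict "
                f"cost minimum: found {best_paths} at cost {best_cost}")


def simulate_annotations(n_terms: int, genes: list[str],
                         target_set: list[str] | set[str],
                         enrichment_factor: float = 4.0,
                         base_prob: float = 0.1,
                         seed: int = 0) -> tuple[GeneSetCollection,
                                                 PlantedTruth]:
    """Term annotations with one designated over-represented term.

    Every term annotates each gene independently with probability
    ``base_prob``; the designated term ``TERM_ENRICHED`` annotates genes of
    ``target_set`` with probability ``min(1, enrichment_factor*base_prob)``
    instead. ``enrichment_factor = 1`` is the exchangeable null.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be at least 1")
    if not 0 < base_prob <= 1 or enrichment_factor < 0:
        raise ValueError("invalid annotation probabilities")
    target = set(target_set)
    if not target <= set(genes):
        raise ValueError("target_set must be a subset of genes")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    in_target = np.array([g in target for g in genes])
    p_hit = min(1.0, enrichment_factor * base_prob)

    sets: dict[str, set[str]] = {}
    draws = rng.random((n_terms, len(genes)))
    probs = np.where(in_target, p_hit, base_prob)
    members = draws[0] < probs
    sets["TERM_ENRICHED"] = {g for g, hit in zip(genes, members) if hit}
    for t in range(1, n_terms):
        members = draws[t] < base_prob
        sets[f"TERM{t:04d}"] = {g for g, hit in zip(genes, members) if hit}
    gsc = GeneSetCollection(sets, {name: "simulated" for name in sets})
    truth = PlantedTruth(enriched_term_ids=["TERM_ENRICHED"])
    return gsc, truth
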