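"""Confidence-weighted graphs, seed-pair shortest paths, interior-gene
betweenness and permutation significance.

Edge confidence scores are transformed to strictly positive path costs that
decrease in confidence (default: w = C_max - score, so stronger
interactions are cheaper to traverse). Dijkstra's algorithm traces the
cheapest route between every unordered pair of seed genes; non-seed genes
lying on those routes are ranked by their seed-pair betweenness — the
number of seed-pair paths passing through them — and assigned a permutation
p-value: the fraction of random seed sets of the same size under which the
gene attains at least its observed betweenness.

Equal-cost ties are resolved deterministically by always choosing the
lexicographically smallest node sequence among co-optimal paths; an
optional mode counts a gene for a pair if it lies on any co-optimal path.
"""

from __future__ import annotations

import itertools
import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

from .containers import BetweennessTable, EdgeTable, PathRecord

logger = logging.getLogger(__name__)

_REL_TOL = 1e-9

WEIGHT_TRANSFORMS = {
    "complement": lambda score, cmax: cmax - score,
    "reciprocal": lambda score, cmax: cmax / score,
}


def build_graph(edge_table: EdgeTable,
                transform: str = "complement") -> nx.Graph:
    """Undirected weighted graph with cost = transform(confidence).

    The default complement transform is w = 1000 - score on the thousand
    scale (1 - score on the unit scale); weights are strictly positive and
    strictly decreasing in confidence. Scores at or above C_max are
    rejected because their weight would not be positive.
    """
    if transform not in WEIGHT_TRANSFORMS:
        raise ValueError(f"unknown weight transform {transform!r}; "
                         f"choose from {sorted(WEIGHT_TRANSFORMS)}")
    cmax = 1000.0 if edge_table.scale == "thousand" else 1.0
    fn = WEIGHT_TRANSFORMS[transform]
    g = nx.Graph()
    for row in edge_table.edges.itertuples():
        if row.score >= cmax:
            raise ValueError(
                f"score {row.score} >= {cmax} would give a non-positive "
                f"weight for edge ({row.node_a}, {row.node_b})")
        g.add_edge(row.node_a, row.node_b, weight=float(fn(row.score, cmax)),
                   score=float(row.score))
    return g


def _lex_shortest_path(g: nx.Graph, dist_s: dict, dist_t: dict,
                       s: str, t: str) -> list[str]:
    """Reconstruct the lexicographically smallest cost-minimal s-t path from
    the two single-source Dijkstra distance maps."""
    total = dist_s[t]
    path = [s]
    cur = s
    acc = 0.0
    while cur != t:
        best = None
        for u in g.neighbors(cur):
            if u in path:
                continue
            via = acc + g[cur][u]["weight"] + dist_t.get(u, math.inf)
            if math.isclose(via, total, rel_tol=_REL_TOL, abs_tol=1e-12):
                if best is None or str(u) < str(best):
                    best = u
        if best is None:  # numerical dead end; cannot happen on exact costs
            raise RuntimeError(f"path reconstruction failed at {cur}")
        acc += g[cur][best]["weight"]
        path.append(best)
        cur = best
    return path


def seed_pair_shortest_paths(g: nx.Graph, seeds: list[str],
                             tie_mode: str = "lexicographic"
                             ) -> list[PathRecord]:
    """One cost-minimal path per unordered seed pair (k seeds -> C(k,2)).

    ``tie_mode`` "lexicographic" records the lexicographically smallest
    co-optimal node sequence; "all" records every co-optimal path in the
    ``all_paths`` attribute of the record (the node sequence still holds
    the lexicographic representative). Disconnected pairs yield records
    flagged unreachable and a logged warning.
    """
    if tie_mode not in ("lexicographic", "all"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    missing = [s for s in seeds if s not in g]
    if missing:
        raise KeyError(f"seed gene(s) not in graph: {missing}")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seed genes must be distinct")
    dist = {s: nx.single_source_dijkstra_path_length(g, s) for s in seeds}
    records: list[PathRecord] = []
    for s, t in itertools.combinations(seeds, 2):
        if t not in dist[s]:
            logger.warning("seed pair (%s, %s) is disconnected", s, t)
            records.append(PathRecord(s, t, [], math.inf, reachable=False))
            continue
        path = _lex_shortest_path(g, dist[s], dist[t], s, t)
        rec = PathRecord(s, t, path, float(dist[s][t]))
        if tie_mode == "all":
            rec.all_paths = [list(p) for p in  # type: ignore[attr-defined]
                             nx.all_shortest_paths(g, s, t, weight="weight")]
        records.append(rec)
    return records


def path_gene_betweenness(records: list[PathRecord],
                          seeds: list[str]) -> BetweennessTable:
    """Count, for each non-seed gene, the seed-pair paths it lies on.

    With "all" tie-mode records a gene counts once per pair if it lies on
    any co-optimal path of that pair. Genes on no path are omitted; seeds
    are never listed.
    """
    seed_set = set(seeds)
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.reachable:
            continue
        paths = getattr(rec, "all_paths", None) or [rec.nodes]
        on_any: set[str] = set()
        for path in paths:
            on_any.update(path[1:-1])
        for gene in on_any - seed_set:
            counts[gene] = counts.get(gene, 0) + 1
    df = pd.DataFrame({"gene": list(counts),
                       "betweenness": list(counts.values())})
    if df.empty:
        df = pd.DataFrame({"gene": pd.Series(dtype=str),
                           "betweenness": pd.Series(dtype=int)})
    return BetweennessTable(df)


def _betweenness_counts(g: nx.Graph, seeds: list[str],
                        genes: set[str]) -> dict[str, int]:
    """Betweenness counts restricted to ``genes`` for one seed set."""
    dist = {s: nx.single_source_dijkstra_path_length(g, s) for s in seeds}
    counts = dict.fromkeys(genes, 0)
    seed_set = set(seeds)
    for s, t in itertools.combinations(seeds, 2):
        if t not in dist[s]:
            continue
        path = _lex_shortest_path(g, dist[s], dist[t], s, t)
        for gene in set(path[1:-1]) - seed_set:
            if gene in counts:
                counts[gene] += 1
    return counts


def permutation_test(g: nx.Graph, k: int, observed: BetweennessTable,
                     n_perm: int = 5000, rng_seed: int = 0,
                     strict: bool = False,
                     exclude: list[str] | None = None) -> BetweennessTable:
    """Permutation p-values for observed seed-pair betweenness counts.

    Each permutation draws ``k`` distinct genes uniformly from the graph
    nodes (optionally excluding ``exclude``, e.g. the original seeds),
    retraces their pairwise shortest paths, and recomputes betweenness.
    For a gene with observed count b, p = (#permutations with permuted
    betweenness >= b) / n_perm (strictly greater with ``strict=True``).
    p = 0 therefore means "below 1/n_perm"; no pseudo-count is added.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    pool = sorted(g.nodes)
    if exclude:
        pool = [n for n in pool if n not in set(exclude)]
    if k > len(pool):
        raise ValueError(f"cannot draw {k} distinct genes from "
                         f"{len(pool)} available nodes")
    genes = observed.table["gene"].tolist()
    b_obs = dict(zip(genes, observed.table["betweenness"]))
    rng = np.random.default_rng(rng_seed)
    exceed = dict.fromkeys(genes, 0)
    gene_set = set(genes)
    for _ in range(n_perm):
        draw = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        counts = _betweenness_counts(g, draw, gene_set)
        for gene in genes:
            b = counts.get(gene, 0)
            if (b > b_obs[gene]) if strict else (b >= b_obs[gene]):
                exceed[gene] += 1
    df = observed.table.copy()
    df["p_value"] = [exceed[gene] / n_perm for gene in df["gene"]]
    return BetweennessTable(df)


def exact_permutation_pvalues(g: nx.Graph, k: int,
                              observed: BetweennessTable,
                              strict: bool = False) -> BetweennessTable:
    """Exact p-values by enumerating every k-subset of graph nodes.

    Brute-force reference for small graphs; complexity C(|V|, k)."""
    pool = sorted(g.nodes)
    genes = observed.table["gene"].tolist()
    b_obs = dict(zip(genes, observed.table["betweenness"]))
    gene_set = set(genes)
    exceed = dict.fromkeys(genes, 0)
    total = 0
    for draw in itertools.combinations(pool, k):
        total += 1
        counts = _betweenness_counts(g, list(draw), gene_set)
        for gene in genes:
            b = counts.get(gene, 0)
            if (b > b_obs[gene]) if strict else (b >= b_obs[gene]):
                exceed[gene] += 1
    df = observed.table.copy()
    df["p_value"] = [exceed[gene] / total for gene in df["gene"]]
    return BetweennessTable(df)
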