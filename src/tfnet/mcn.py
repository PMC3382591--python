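"""Minimal connected network (MCN) extraction and significance testing.

Given a set of seed proteins and an undirected interactome, the MCN
procedure keeps every direct seed-seed interaction and, for each seed
pair at graph distance exactly two, every common neighbor together with
its two incident edges (one tolerated intermediate). The largest
connected component of the resulting subnetwork — by interaction count —
is the MCN. Its node-level betweenness, degree ("connections") and
clustering-coefficient distributions are compared, with two-sample
Kolmogorov-Smirnov tests, to the pooled distributions from the MCNs of
random node sets of the same size, and a negative control repeats the
extraction on random TF lists drawn from the catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, PreconditionError

log = logging.getLogger(__name__)

METRICS = ("betweenness", "connections", "clustering")


class PpiNetwork:
    """Undirected simple protein-protein interaction graph.

    Edges carry an integer ``evidence`` count (number of experimental
    evidences); :meth:`filtered` returns the view used by the pipeline,
    keeping edges with at least ``min_evidence`` evidences (default 2).
    Self-loops are rejected.
    """

    def __init__(self, edges: Iterable[tuple[str, str, int]]) -> None:
        g = nx.Graph()
        for a, b, ev in edges:
            if a == b:
                raise ConfigError(f"self-loop on {a!r}")
            if ev < 1:
                raise ConfigError(f"evidence count < 1 on edge {a}-{b}")
            if g.has_edge(a, b):
                g[a][b]["evidence"] = max(g[a][b]["evidence"], int(ev))
            else:
                g.add_edge(a, b, evidence=int(ev))
        self.graph = g

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PpiNetwork":
        return cls(df[["a", "b", "evidence"]].itertuples(index=False, name=None))

    def filtered(self, min_evidence: int = 2) -> nx.Graph:
        keep = [(a, b) for a, b, d in self.graph.edges(data=True)
                if d["evidence"] >= min_evidence]
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(keep)
        return g

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class McnResult:
    seeds: frozenset[str]
    mapped_seeds: frozenset[str]
    unmapped_seeds: frozenset[str]
    subnetwork: nx.Graph
    components: list[nx.Graph]
    mcn: nx.Graph
    node_metrics: pd.DataFrame  # index: mcn nodes; betweenness/connections/clustering/is_seed
    significance: Optional[dict] = None


def _adjacency(graph: nx.Graph) -> dict:
    return {n: set(graph[n]) for n in graph}


def _mcn_edges(adj: Mapping[str, set], seeds: Sequence[str]) -> set[tuple[str, str]]:
    """Edge set of the one-intermediate shortest-path subnetwork."""
    edges: set[tuple[str, str]] = set()
    seeds = [s for s in seeds if s in adj]
    for a, b in combinations(seeds, 2):
        if b in adj[a]:  # distance 1: direct edge only
            edges.add((a, b) if a <= b else (b, a))
        else:  # distance 2 iff a common neighbor exists
            for w in adj[a] & adj[b]:
                edges.add((a, w) if a <= w else (w, a))
                edges.add((b, w) if b <= w else (w, b))
    return edges


def _largest_component(edges: set[tuple[str, str]]) -> tuple[nx.Graph, list[nx.Graph]]:
    sub = nx.Graph()
    sub.add_edges_from(edges)
    comps = [sub.subgraph(c).copy() for c in nx.connected_components(sub)]
    comps.sort(key=lambda g: (-g.number_of_edges(), -g.number_of_nodes(), min(g.nodes)))
    mcn = comps[0] if comps else nx.Graph()
    return mcn, comps


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (pairs counted once,
    fractional credit shared among multiple shortest paths)."""
    return nx.betweenness_centrality(graph, normalized=False)


def clustering_coefficient(graph: nx.Graph, node=None):
    """Fraction of a node's neighbor pairs that are connected (0 when the
    degree is < 2)."""
    return nx.clustering(graph, node)


def _metric_table(mcn: nx.Graph, seeds: frozenset[str]) -> pd.DataFrame:
    nodes = sorted(mcn.nodes)
    btw = betweenness(mcn)
    clu = nx.clustering(mcn)
    return pd.DataFrame({
        "is_seed": [n in seeds for n in nodes],
        "betweenness": [btw[n] for n in nodes],
        "connections": [mcn.degree(n) for n in nodes],
        "clustering": [clu[n] for n in nodes],
    }, index=pd.Index(nodes, name="node"))


def minimal_connected_network(seeds: Iterable[str], graph: nx.Graph) -> McnResult:
    """Extract the MCN of ``seeds`` over ``graph`` (no significance yet).

    ``graph`` should already be evidence-filtered (see
    :meth:`PpiNetwork.filtered`). Seeds absent from the graph are
    reported in ``unmapped_seeds`` and the run proceeds with the rest;
    fewer than two mapped seeds is an error.
    """
    seeds = frozenset(seeds)
    if graph.number_of_nodes() == 0:
        raise PreconditionError("empty PPI graph")
    mapped = frozenset(s for s in seeds if s in graph)
    unmapped = seeds - mapped
    if unmapped:
        log.warning("minimal_connected_network: %d/%d seeds not in the interactome",
                    len(unmapped), len(seeds))
    if len(mapped) < 2:
        raise PreconditionError(f"only {len(mapped)} seed(s) map onto the graph; need >= 2")
    adj = _adjacency(graph)
    edges = _mcn_edges(adj, sorted(mapped))
    mcn_graph, comps = _largest_component(edges)
    metrics = _metric_table(mcn_graph, mapped)
    return McnResult(seeds=seeds, mapped_seeds=mapped, unmapped_seeds=unmapped,
                     subnetwork=nx.Graph(edges), components=comps, mcn=mcn_graph,
                     node_metrics=metrics)


def _random_pool(adj: Mapping[str, set], nodes: np.ndarray, set_size: int,
                 n_random: int, rng: np.random.Generator
                 ) -> dict[str, list[np.ndarray]]:
    """Per-draw node metrics over the MCNs of ``n_random`` uniform node
    sets (draws whose subnetwork is empty are dropped)."""
    pool: dict[str, list[np.ndarray]] = {m: [] for m in METRICS}
    n_empty = 0
    for _ in range(n_random):
        sample = nodes[rng.choice(len(nodes), size=set_size, replace=False)]
        edges = _mcn_edges(adj, sorted(sample))
        if not edges:
            n_empty += 1
            continue
        g, _ = _largest_component(edges)
        btw = nx.betweenness_centrality(g, normalized=False)
        clu = nx.clustering(g)
        pool["betweenness"].append(np.fromiter(btw.values(), dtype=float))
        pool["connections"].append(np.array([d for _, d in g.degree], dtype=float))
        pool["clustering"].append(np.fromiter(clu.values(), dtype=float))
    if n_empty:
        log.debug("random MCN pool: %d/%d random sets gave an empty subnetwork",
                  n_empty, n_random)
    return pool


def _ks_stat(x: np.ndarray, ref_sorted: np.ndarray) -> float:
    """Two-sample KS statistic of ``x`` against a pre-sorted reference."""
    x = np.sort(x)
    n, m = len(x), len(ref_sorted)
    grid = np.concatenate([x, ref_sorted])
    fx = np.searchsorted(x, grid, side="right") / n
    fr = np.searchsorted(ref_sorted, grid, side="right") / m
    return float(np.abs(fx - fr).max())


def subnetwork_significance(result: McnResult, graph: nx.Graph,
                            n_random: int = 1000,
                            rng_seed: Optional[int] = None,
                            method: str = "ks") -> dict[str, float]:
    """Significance of the MCN's node metrics against random-set MCNs.

    Draws ``n_random`` uniform node sets of the same size as the mapped
    seed set, extracts each set's MCN and pools the node-level
    betweenness, connections and clustering values across all random
    MCNs. With ``method='ks'`` (default) each metric's p-value is the
    raw two-sided two-sample KS test of the observed MCN's values
    against the pool. Because node metrics within one MCN are dependent
    and heavily tied, the raw KS p is not calibrated (anti-conservative
    for betweenness, conservative for the discrete metrics);
    ``method='empirical'`` instead ranks the observed KS statistic among
    the random MCNs' own leave-self-out KS statistics, which is
    calibrated by exchangeability.
    """
    if n_random <= 0:
        raise ConfigError("n_random must be positive")
    if method not in ("ks", "empirical"):
        raise ConfigError(f"unknown significance method {method!r}")
    if result.mcn.number_of_nodes() == 0:
        raise PreconditionError("observed MCN is empty")
    rng = np.random.default_rng(rng_seed)
    adj = _adjacency(graph)
    nodes = np.array(sorted(graph.nodes), dtype=object)
    pool = _random_pool(adj, nodes, len(result.mapped_seeds), n_random, rng)
    pvalues: dict[str, float] = {}
    for metric in METRICS:
        obs = result.node_metrics[metric].to_numpy(dtype=float)
        draws = pool[metric]
        if not draws:
            log.warning("significance: degenerate background for %s", metric)
            pvalues[metric] = float("nan")
            continue
        ref = np.concatenate(draws)
        if method == "ks":
            pvalues[metric] = float(stats.ks_2samp(obs, ref, method="asymp").pvalue)
        else:
            # leave-self-out references over draws + observed make the
            # units exchangeable, so the rank p below is exact
            units = draws + [obs]
            ref_all = np.concatenate(units)
            counts = np.array([len(d) for d in units])
            offsets = np.concatenate([[0], np.cumsum(counts)])
            d_units = np.empty(len(units))
            for i, d in enumerate(units):
                mask = np.ones(len(ref_all), dtype=bool)
                mask[offsets[i]:offsets[i + 1]] = False
                d_units[i] = _ks_stat(d, np.sort(ref_all[mask]))
            d_obs = d_units[-1]
            n_gt = int((d_units[:-1] > d_obs).sum())
            n_eq = int((d_units[:-1] == d_obs).sum())
            # randomized tie-broken rank p: exactly uniform under the null
            u = float(rng.random())
            pvalues[metric] = float((n_gt + u * (n_eq + 1)) / (1 + len(draws)))
    result.significance = pvalues
    return pvalues


def negative_control(tf_universe: Sequence[str], graph: nx.Graph,
                     observed: McnResult, list_size: int, n_lists: int = 100,
                     rng_seed: Optional[int] = None) -> float:
    """KS p-value of the observed MCN betweenness vs random-TF-list MCNs.

    Draws ``n_lists`` random lists of ``list_size`` distinct TFs from the
    catalogue universe, extracts each list's MCN, pools their node
    betweenness values, and compares the observed MCN's betweenness
    distribution to the pool with a two-sided KS test. Controls for false
    positives upstream of the seed list.
    """
    tf_universe = sorted(set(tf_universe))
    if list_size > len(tf_universe):
        raise PreconditionError(
            f"list_size {list_size} exceeds TF universe size {len(tf_universe)}")
    if n_lists <= 0:
        raise ConfigError("n_lists must be positive")
    rng = np.random.default_rng(rng_seed)
    adj = _adjacency(graph)
    universe = np.array(tf_universe, dtype=object)
    pool: list[float] = []
    for _ in range(n_lists):
        sample = universe[rng.choice(len(universe), size=list_size, replace=False)]
        edges = _mcn_edges(adj, sorted(s for s in sample if s in adj))
        if not edges:
            continue
        g, _ = _largest_component(edges)
        pool.extend(nx.betweenness_centrality(g, normalized=False).values())
    obs = observed.node_metrics["betweenness"].to_numpy(dtype=float)
    if not pool:
        log.warning("negative_control: all random lists gave empty MCNs")
        return float("nan")
    return float(stats.ks_2samp(obs, np.asarray(pool), method="asymp").pvalue)


@dataclass
class CentralNodes:
    above_average: frozenset[str]
    top: list[str]
    top_share: float  # fraction of total betweenness carried by the top list


def central_nodes(metrics: pd.DataFrame, k: int = 10) -> CentralNodes:
    """Central MCN nodes by betweenness.

    ``above_average`` holds nodes strictly above the mean betweenness;
    ``top`` the k highest (ties broken by degree, then node id) together
    with their share of the total betweenness.
    """
    if k > len(metrics):
        log.info("central_nodes: k=%d clamped to %d nodes", k, len(metrics))
        k = len(metrics)
    btw = metrics["betweenness"]
    above = frozenset(btw.index[btw > btw.mean()])
    order = sorted(metrics.index,
                   key=lambda n: (-btw[n], -metrics.loc[n, "connections"], n))
    top = order[:k]
    total = float(btw.sum())
    share = float(btw[top].sum() / total) if total > 0 else 0.0
    return CentralNodes(above_average=above, top=top, top_share=share)
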