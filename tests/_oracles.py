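"""Independent reference implementations used to check the package.

These deliberately use different algorithms from the code under test:
exact rational arithmetic for the hypergeometric tail, exhaustive
simple-path enumeration for betweenness, pair counting for clustering,
and a vectorized label-permutation null for the log-rank test.
"""

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np


def exact_hypergeom_tail(n_universe, n_targets, n_query, k):
    """P(X >= k) for the hypergeometric over-representation tail, as an
    exact rational number."""
    total = math.comb(n_universe, n_query)
    acc = Fraction(0)
    for j in range(k, min(n_targets, n_query) + 1):
        acc += Fraction(math.comb(n_targets, j)
                        * math.comb(n_universe - n_targets, n_query - j), total)
    return acc


def brute_force_betweenness(g):
    """Enumerate every shortest path explicitly; award interior nodes
    fractional credit per path."""
    score = {n: 0.0 for n in g}
    for u, v in itertools.combinations(sorted(g.nodes), 2):
        if not nx.has_path(g, u, v):
            continue
        d = nx.shortest_path_length(g, u, v)
        paths = [p for p in nx.all_simple_paths(g, u, v, cutoff=d) if len(p) == d + 1]
        for p in paths:
            for node in p[1:-1]:
                score[node] += 1.0 / len(paths)
    return score


def brute_force_clustering(g, node):
    nbrs = sorted(g[node])
    if len(nbrs) < 2:
        return 0.0
    pairs = list(itertools.combinations(nbrs, 2))
    return sum(g.has_edge(a, b) for a, b in pairs) / len(pairs)


def _logrank_stats_two_group(z, events):
    """Vectorized 1-df log-rank chi-square for permutation matrices.

    ``z``: (P, N) 0/1 group-1 indicators aligned to time-sorted patients
    (distinct event times assumed); ``events``: (N,) event flags.
    """
    n = z.shape[1]
    at_risk = np.arange(n, 0, -1, dtype=float)           # n_j
    n1 = np.cumsum(z[:, ::-1], axis=1)[:, ::-1]          # group-1 at risk
    p1 = n1 / at_risk
    e = events.astype(bool)
    obs = (z[:, e]).sum(axis=1)
    exp = p1[:, e].sum(axis=1)
    var = (p1 * (1 - p1))[:, e].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (obs - exp) ** 2 / var
    return np.where(var > 0, stat, 0.0)


def _logrank_stats_three_group(z1, z2, events):
    """Vectorized 2-df log-rank chi-square (three groups, no ties)."""
    n = z1.shape[1]
    at_risk = np.arange(n, 0, -1, dtype=float)
    p1 = np.cumsum(z1[:, ::-1], axis=1)[:, ::-1] / at_risk
    p2 = np.cumsum(z2[:, ::-1], axis=1)[:, ::-1] / at_risk
    e = events.astype(bool)
    u1 = z1[:, e].sum(axis=1) - p1[:, e].sum(axis=1)
    u2 = z2[:, e].sum(axis=1) - p2[:, e].sum(axis=1)
    v11 = (p1 * (1 - p1))[:, e].sum(axis=1)
    v22 = (p2 * (1 - p2))[:, e].sum(axis=1)
    v12 = -(p1 * p2)[:, e].sum(axis=1)
    det = v11 * v22 - v12 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (v22 * u1 ** 2 - 2 * v12 * u1 * u2 + v11 * u2 ** 2) / det
    return np.where(det > 0, stat, 0.0)


def permutation_logrank_p(times, events, labels, n_perm=100_000, seed=0,
                          block=20_000):
    """Permutation p-value of the k-group log-rank statistic.

    Shuffles group labels over patients while keeping (time, event)
    pairs fixed; returns P(stat_perm >= stat_obs). Supports 2 or 3
    groups; event times must be distinct.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    order = np.argsort(times)
    times, events, labels = times[order], events[order], labels[order]
    groups = np.unique(labels)
    rng = np.random.default_rng(seed)

    def stats_for(label_matrix):
        if len(groups) == 2:
            return _logrank_stats_two_group((label_matrix == groups[0]).astype(float),
                                            events)
        z1 = (label_matrix == groups[0]).astype(float)
        z2 = (label_matrix == groups[1]).astype(float)
        return _logrank_stats_three_group(z1, z2, events)

    stat_obs = float(stats_for(labels[None, :])[0])
    n_ge = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = np.array([rng.permutation(labels) for _ in range(b)])
        n_ge += int((stats_for(perm) >= stat_obs - 1e-12).sum())
        done += b
    return stat_obs, (n_ge + 1) / (n_perm + 1)
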