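"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths (and the
networkx algorithms behind them): itemsets by power-set enumeration,
centralities by explicit path enumeration over a dict adjacency, cliques
grown from all subsets, AUC by exhaustive pair counting, hypergeometric
tails by direct combinatorial summation.
"""

from __future__ import annotations

from itertools import chain, combinations
from math import comb

import numpy as np
import pytest

from effimine.markers import MarkerSpec, default_marker_specs


@pytest.fixture(scope="session")
def specs():
    return default_marker_specs()


@pytest.fixture
def fbg_spec():
    return MarkerSpec(
        name="FBG", normal_low=2, normal_high=4,
        pre_median=4.80, pre_q1=4.27, pre_q3=5.37,
    )


# ---------------------------------------------------------------------------
# itemset / rule oracles
# ---------------------------------------------------------------------------

def powerset_itemsets(record_sets, items, min_support):
    """All itemsets with support >= min_support by exhaustive enumeration."""
    n = len(record_sets)
    out = []
    for r in range(1, len(items) + 1):
        for combo in combinations(sorted(items), r):
            s = sum(1 for rec in record_sets if set(combo) <= rec) / n if n else 0.0
            if n and s >= min_support:
                out.append((frozenset(combo), s))
    out.sort(key=lambda pair: (len(pair[0]), sorted(pair[0])))
    return out


def count_rule_metrics(record_sets, x, y):
    """(support, confidence, lift) for X→Y by direct counting."""
    n = len(record_sets)
    sx = sum(1 for rec in record_sets if set(x) <= rec)
    sxy = sum(1 for rec in record_sets if set(x) | set(y) <= rec)
    sy = sum(1 for rec in record_sets if set(y) <= rec)
    support = sxy / n
    confidence = sxy / sx if sx else float("nan")
    # lift is reported as 0 when the consequent never occurs
    lift = confidence / (sy / n) if sx and sy else 0.0
    return support, confidence, lift


def random_record_sets(rng, n_records, n_items):
    items = [chr(ord("A") + i) for i in range(n_items)]
    return [
        {item for item in items if rng.random() < 0.5} for _ in range(n_records)
    ], items


# ---------------------------------------------------------------------------
# graph oracles (dict adjacency; no networkx algorithms)
# ---------------------------------------------------------------------------

def adjacency(graph):
    adj = {v: set() for v in graph.nodes()}
    for u, v in graph.edges():
        adj[u].add(v)
        adj[v].add(u)
    return adj


def all_simple_paths(adj, s, t):
    """Every simple path s→t by depth-first enumeration."""
    paths, stack = [], [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nxt in sorted(adj[node]):
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return paths

def brute_betweenness(graph):
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    adj = adjacency(graph)
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_simple_paths(adj, s, t)
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / len(shortest)
    return bc


def brute_harmonic_closeness(graph):
    """Sum of reciprocal shortest-path lengths, distances by hand BFS."""
    adj = adjacency(graph)
    out = {}
    for s in adj:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[s] = sum(1.0 / d for v, d in dist.items() if v != s)
    return out


def brute_maximal_cliques(graph):
    """All maximal cliques, grown from every subset of the node set."""
    adj = adjacency(graph)
    nodes = sorted(adj)
    cliques = []
    subsets = chain.from_iterable(
        combinations(nodes, r) for r in range(1, len(nodes) + 1)
    )
    for sub in subsets:
        sub = set(sub)
        if all(u in adj[v] for u, v in combinations(sub, 2)):
            extendable = any(
                sub <= adj[w] for w in nodes if w not in sub
            )
            if not extendable:
                cliques.append(frozenset(sub))
    return set(cliques)


def brute_mcc(graph):
    from math import factorial

    scores = {v: 0 for v in graph.nodes()}
    for clique in brute_maximal_cliques(graph):
        for v in clique:
            scores[v] += factorial(len(clique) - 1)
    return scores


# ---------------------------------------------------------------------------
# AUC and hypergeometric oracles
# ---------------------------------------------------------------------------

def pair_count_auc(case, control):
    """(concordant + half ties) / all case-control pairs."""
    wins = ties = 0
    for a in case:
        for b in control:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(case) * len(control))


def hypergeom_tail_sum(N, K, n, k):
    """P(X >= k) by direct summation of the hypergeometric mass."""
    total = comb(N, n)
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
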