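"""Hub- and core-gene discovery on interaction networks, plus ROC screening.

Given an undirected protein–protein interaction graph, this module

* computes per-node degree, harmonic closeness and (unnormalized)
  betweenness centrality — harmonic closeness is used because interaction
  subnetworks are routinely disconnected, and betweenness is left
  unnormalized because only ranks feed the selection;
* selects *hub genes* as the intersection of the top-k lists under the
  three centralities (deterministic score-desc, symbol-asc tie-break);
* scores *core genes* with the maximal-clique centrality
  MCC(v) = Σ_{maximal cliques S ∋ v} (|S| − 1)!  — the flagship ranking
  of Cytoscape-style hub plugins — via full maximal-clique enumeration;
* screens single-gene biomarkers by the rank-based ROC AUC (probability
  a random case sample exceeds a random control sample), with the
  orientation fixed as case-high = positive so that AUC < 0.5 stays
  visible rather than being silently flipped.
"""

from __future__ import annotations

import logging
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def read_network(path) -> nx.Graph:
    """Read an edge list (two-column TSV) or SIF file into a simple graph.

    SIF lines are ``source  relation  target [target ...]``; two-column
    lines are taken as plain edges.  Self-loops are dropped.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2:
                u, v = parts
                targets = [v]
            elif len(parts) >= 3:
                u, targets = parts[0], parts[2:]
            else:
                graph.add_node(parts[0])
                continue
            for v in targets:
                if u != v:
                    graph.add_edge(u, v)
    return graph


def _check_simple(net: nx.Graph) -> nx.Graph:
    if net.number_of_nodes() < 1:
        raise ValueError("network must have at least one node")
    if any(u == v for u, v in net.edges()):
        raise ValueError("network must not contain self-loops")
    return net


def compute_centralities(net: nx.Graph, clique_budget: int = 10**6) -> pd.DataFrame:
    """Per-node degree, harmonic closeness, betweenness and MCC score.

    Returns a DataFrame indexed by node with columns
    ``degree, closeness, betweenness, clique_score``; all deterministic
    for a fixed graph.
    """
    _check_simple(net)
    degree = dict(net.degree())
    closeness = nx.harmonic_centrality(net)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    clique = mcc_scores(net, clique_budget=clique_budget)
    nodes = sorted(net.nodes())
    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "clique_score": [clique[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _top_k(series: pd.Series, k: int) -> list:
    """Top-k labels by (score desc, symbol asc)."""
    order = sorted(series.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [label for label, _ in order[:k]]


def select_hub_genes(table: pd.DataFrame, k: int = 10) -> list:
    """Intersection of the top-k lists under degree, closeness, betweenness."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) < k:
        logger.warning(
            "graph has %d nodes < k=%d; every node enters each top list",
            len(table), k,
        )
    tops = [
        set(_top_k(table[col], k))
        for col in ("degree", "closeness", "betweenness")
    ]
    hubs = tops[0] & tops[1] & tops[2]
    # order the result by degree rank for readability
    ranked = _top_k(table["degree"], len(table))
    return [v for v in ranked if v in hubs]


def mcc_scores(net: nx.Graph, clique_budget: int = 10**6) -> dict:
    """Maximal-clique centrality: Σ over maximal cliques S ∋ v of (|S|−1)!.

    An isolated node's only maximal clique is itself, scoring 0! = 1.
    Enumeration aborts beyond ``clique_budget`` maximal cliques.
    """
    _check_simple(net)
    scores = {v: 0 for v in net.nodes()}
    for count, clique in enumerate(nx.find_cliques(net), start=1):
        if count > clique_budget:
            raise RuntimeError(
                f"maximal-clique enumeration exceeded the budget of "
                f"{clique_budget}; raise clique_budget or reduce the graph"
            )
        weight = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += weight
    return scores


def score_core_genes(net: nx.Graph, top: int = 5, clique_budget: int = 10**6) -> list:
    """Top nodes by maximal-clique centrality (score desc, symbol asc)."""
    scores = pd.Series(mcc_scores(net, clique_budget=clique_budget))
    return _top_k(scores, top)


def rank_auc(case: np.ndarray, control: np.ndarray) -> float:
    """ROC AUC via the rank statistic: (concordant + ½ ties) / (n₁ n₂).

    Equivalent to the Mann–Whitney U statistic divided by n₁·n₂, with
    case-high oriented as positive.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([case, control])
    ranks = stats.rankdata(combined)
    r1 = ranks[: case.size].sum()
    u = r1 - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def roc_auc_biomarker(
    matrix: pd.DataFrame,
    groups: pd.Series,
    genes: list[str],
    auc_threshold: float = 0.7,
) -> pd.DataFrame:
    """Screen genes as single-gene diagnostic biomarkers by ROC AUC.

    Genes absent from the matrix are skipped with a warning.  Returns a
    DataFrame (gene, auc, candidate) where ``candidate`` flags
    auc > auc_threshold.
    """
    groups = pd.Series(groups)
    case_ids = groups.index[groups == "case"]
    ctrl_ids = groups.index[groups == "control"]
    if len(case_ids) == 0 or len(ctrl_ids) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for gene in genes:
        if gene not in matrix.index:
            logger.warning("gene %r absent from the matrix; skipped", gene)
            continue
        auc = rank_auc(
            matrix.loc[gene, case_ids].to_numpy(),
            matrix.loc[gene, ctrl_ids].to_numpy(),
        )
        rows.append({"gene": gene, "auc": auc, "candidate": auc > auc_threshold})
    return pd.DataFrame(rows, columns=["gene", "auc", "candidate"])
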