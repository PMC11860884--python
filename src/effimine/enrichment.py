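"""Local over-representation analysis against user-supplied gene sets.

Enrichment of a query gene list in an annotation set is scored by the
one-sided hypergeometric upper tail: with a background universe of N
genes, K of which carry the annotation, a query of n genes overlapping
the set in k, the p-value is P(X ≥ k) for X ~ Hypergeom(N, K, n).

The default background is the set of measured genes (the expression
matrix), not the genome — the conservative convention when the true
assay universe is known.  Significance is flagged on raw p < 0.05 by
default (the screening convention this pipeline mirrors); a
Benjamini–Hochberg q-value mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import normalize_symbol

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """A background universe plus named annotation sets.

    Set members outside the universe are dropped on construction with a
    logged count; all symbols are normalized (trimmed, upper-cased).
    """

    universe: set
    sets: dict[str, set] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        self.universe = {normalize_symbol(g) for g in self.universe}
        cleaned = {}
        dropped = 0
        for name, members in self.sets.items():
            norm = {normalize_symbol(g) for g in members}
            dropped += len(norm - self.universe)
            cleaned[name] = norm & self.universe
        if dropped:
            logger.info("dropped %d set members outside the universe", dropped)
        self.sets = cleaned

    @classmethod
    def from_gmt(cls, path, universe=None, category: str = "") -> "GeneSetCollection":
        """Read GMT (name, description, tab-separated members).

        When ``universe`` is None the union of all set members is used.
        """
        sets: dict[str, set] = {}
        categories: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = {g for g in parts[2:] if g.strip()}
                categories[parts[0]] = category or parts[1]
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(universe=set(universe), sets=sets, categories=categories)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                desc = self.categories.get(name, "na") or "na"
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{desc}\t{members}\n")


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X ≥ k), X ~ Hypergeom(N, K, n); exactly 1 at k = 0."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query,
    collection: GeneSetCollection,
    report_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Score every annotation set against the query.

    Query genes outside the universe are dropped with a logged count.
    Sets with zero overlap are hidden unless ``report_zero_overlap``.
    Returns columns ``term, category, k, K, n, N, p_value`` sorted by
    (p, term).
    """
    norm_query = {normalize_symbol(g) for g in query}
    inside = norm_query & collection.universe
    dropped = len(norm_query) - len(inside)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    if not inside:
        raise ValueError("query has no genes inside the universe")
    N = len(collection.universe)
    n = len(inside)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        K = len(members)
        k = len(members & inside)
        if k == 0 and not report_zero_overlap:
            continue
        rows.append(
            {
                "term": term,
                "category": collection.categories.get(term, ""),
                "k": k, "K": K, "n": n, "N": N,
                "p_value": hypergeom_pvalue(N, K, n, k),
            }
        )
    frame = pd.DataFrame(rows, columns=["term", "category", "k", "K", "n", "N", "p_value"])
    return frame.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)


def adjust_bh(
    rows: pd.DataFrame, alpha: float = 0.05, mode: str = "raw"
) -> pd.DataFrame:
    """Attach Benjamini–Hochberg q-values and a significance flag.

    ``mode="raw"`` flags significance on p < 0.05 (the screening
    convention); ``mode="bh"`` flags on q < alpha.
    """
    if mode not in ("raw", "bh"):
        raise ValueError("mode must be 'raw' or 'bh'")
    out = rows.copy()
    if len(out) == 0:
        out["q_value"] = []
        out["significant"] = []
        return out
    _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["q_value"] = q
    if mode == "raw":
        out["significant"] = out["p_value"] < 0.05
    else:
        out["significant"] = out["q_value"] < alpha
    return out


def rank_terms(rows: pd.DataFrame, by: str = "p", top: int | None = 10) -> pd.DataFrame:
    """Deterministically order terms by p, fold enrichment, or gene count.

    ``by="p"`` ascends in p (i.e. descends in −log10 p); ``by="fold"``
    descends in (k/n)/(K/N); ``by="count"`` descends in k.  Ties break
    alphabetically on the term name.
    """
    if len(rows) == 0:
        raise ValueError("no enrichment rows to rank")
    out = rows.copy()
    if by == "p":
        key = out["p_value"]
        ascending = True
    elif by == "fold":
        key = -(out["k"] / out["n"]) / (out["K"] / out["N"])
        ascending = True
    elif by == "count":
        key = -out["k"].astype(float)
        ascending = True
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    out["_key"] = key
    out = out.sort_values(["_key", "term"], ascending=[ascending, True], kind="mergesort")
    out = out.drop(columns="_key").reset_index(drop=True)
    return out.head(top) if top is not None else out
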