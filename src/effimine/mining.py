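"""Improvement-transaction coding and association-rule mining.

Clinical records are coded into binary transactions: one item flags
exposure to the herbal formula (default label ``"XFC"``), and one item
per laboratory marker flags whether that marker moved in its beneficial
direction after treatment.  Treatment→improvement rules are then mined
with a level-wise Apriori and scored by

* support(X→Y)   = σ(X∪Y) / N
* confidence(X→Y) = σ(X∪Y) / σ(X)
* lift(X→Y)      = confidence(X→Y) / support(Y)

where σ(·) counts the records containing every item of a set and N is
the total record count.  A rule is labelled *strong* when its confidence
exceeds 60% and its lift exceeds 1; *moderate* when only the lift bound
holds; *weak* otherwise.

Supports and confidences are stored as fractions in [0, 1]; rendering
multiplies by 100 for percent columns, which keeps the metric identities
(support ≤ confidence, lift·support(Y) = confidence) exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .markers import MarkerSpec

TREATMENT_ITEM = "XFC"
STRONG, MODERATE, WEAK = "strong", "moderate", "weak"


@dataclass
class PatientRecord:
    """One patient's exposure flag and pre/post marker values."""

    patient_id: str
    treated: bool
    marker_values: dict[str, tuple[float, float]]


@dataclass
class TransactionTable:
    """Binary item × record matrix with the counting function σ."""

    items: list[str]
    records: np.ndarray  # (N, n_items) boolean

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=bool)
        if self.records.ndim != 2 or self.records.shape[1] != len(self.items):
            raise ValueError("records must be an (N, n_items) binary matrix")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item labels must be unique")
        self._index = {item: j for j, item in enumerate(self.items)}

    @property
    def n(self) -> int:
        return self.records.shape[0]

    def _mask(self, itemset) -> np.ndarray:
        cols = [self._index[item] for item in itemset]
        if not cols:
            return np.ones(self.n, dtype=bool)
        return self.records[:, cols].all(axis=1)

    def sigma(self, itemset) -> int:
        """σ(X): number of records containing every item of X."""
        for item in itemset:
            if item not in self._index:
                raise KeyError(f"unknown item {item!r}")
        return int(self._mask(itemset).sum())

    def support(self, itemset) -> float:
        """σ(X)/N as a fraction; 0 on an empty table."""
        if self.n == 0:
            return 0.0
        return self.sigma(itemset) / self.n

    @classmethod
    def from_record_sets(cls, record_sets, items=None) -> "TransactionTable":
        """Build from an iterable of item sets, one per record."""
        record_sets = [set(r) for r in record_sets]
        if items is None:
            items = sorted(set().union(*record_sets)) if record_sets else []
        matrix = np.zeros((len(record_sets), len(items)), dtype=bool)
        index = {item: j for j, item in enumerate(items)}
        for i, rec in enumerate(record_sets):
            for item in rec:
                if item in index:
                    matrix[i, index[item]] = True
        return cls(items=list(items), records=matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records.astype(int), columns=self.items)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransactionTable":
        return cls(items=list(frame.columns), records=frame.to_numpy(dtype=bool))


# ---------------------------------------------------------------------------
# coding
# ---------------------------------------------------------------------------

def code_improvement(
    record: PatientRecord,
    specs: list[MarkerSpec],
    tolerance: float = 0.0,
    treatment_item: str = TREATMENT_ITEM,
) -> set[str]:
    """Code one patient into a transaction item set.

    Emits ``treatment_item`` iff the patient was treated and, per marker,
    ``"<marker>_improved"`` iff the post value moved in the beneficial
    direction by more than the relative ``tolerance`` (strict inequality;
    a tie is never an improvement).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_name = {spec.name: spec for spec in specs}
    items: set[str] = set()
    if record.treated:
        items.add(treatment_item)
    for marker, (pre, post) in record.marker_values.items():
        spec = by_name.get(marker)
        if spec is None:
            raise KeyError(f"marker {marker!r} missing from the marker specs")
        if not (np.isfinite(pre) and np.isfinite(post) and pre > 0 and post > 0):
            raise ValueError(
                f"marker {marker!r}: pre/post values must be finite and positive"
            )
        if spec.improves_downward:
            improved = post < pre * (1.0 - tolerance)
        else:
            improved = post > pre * (1.0 + tolerance)
        if improved:
            items.add(f"{marker}_improved")
    return items


def transactions_from_cohort(
    cohort: pd.DataFrame,
    specs: list[MarkerSpec],
    tolerance: float = 0.0,
    treatment_item: str = TREATMENT_ITEM,
) -> TransactionTable:
    """Code a cohort table (as produced by ``gen_cohort``) into transactions.

    A patient lacking the pre/post pair for a marker contributes no item
    for that marker but still counts in N.
    """
    markers = [s.name for s in specs if f"{s.name}_pre" in cohort.columns]
    items = [treatment_item] + [f"{m}_improved" for m in markers]
    record_sets = []
    for row in cohort.to_dict("records"):
        values = {}
        for m in markers:
            pre, post = row.get(f"{m}_pre"), row.get(f"{m}_post")
            if pre is not None and post is not None and np.isfinite(pre) and np.isfinite(post):
                values[m] = (float(pre), float(post))
        rec = PatientRecord(
            patient_id=str(row.get("patient_id", "")),
            treated=bool(row["treated"]),
            marker_values=values,
        )
        record_sets.append(code_improvement(rec, specs, tolerance, treatment_item))
    return TransactionTable.from_record_sets(record_sets, items=items)


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------

def mine_frequent_itemsets(
    table: TransactionTable, min_support: float
) -> list[tuple[frozenset, float]]:
    """Level-wise Apriori with downward-closure pruning.

    Returns exactly the itemsets whose support is ≥ ``min_support``,
    sorted by (size, lexicographic item order).
    """
    if not 0.0 <= min_support <= 1.0:
        raise ValueError("min_support must be in [0, 1]")
    results: list[tuple[frozenset, float]] = []
    if table.n == 0:
        return results
    # level 1
    frequent = []
    for item in table.items:
        s = table.support([item])
        if s >= min_support:
            frequent.append(frozenset([item]))
            results.append((frozenset([item]), s))
    level = frequent
    k = 2
    while level:
        prev = set(level)
        # candidate generation: join sets sharing k-2 items, prune subsets
        candidates = set()
        for a, b in combinations(level, 2):
            union = a | b
            if len(union) == k and all(
                frozenset(sub) in prev for sub in combinations(union, k - 1)
            ):
                candidates.add(union)
        level = []
        for cand in sorted(candidates, key=lambda c: sorted(c)):
            s = table.support(cand)
            if s >= min_support:
                level.append(cand)
                results.append((cand, s))
        k += 1
    results.sort(key=lambda pair: (len(pair[0]), sorted(pair[0])))
    return results


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

@dataclass
class AssociationRule:
    """A mined rule X→Y with its three metrics and a strength label."""

    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float
    strength: str = field(default="")

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")
        if not self.strength:
            self.strength = classify_rule_strength(self.confidence, self.lift)


def classify_rule_strength(confidence: float, lift: float) -> str:
    """strong iff confidence > 0.60 and lift > 1; moderate iff lift > 1; else weak."""
    if confidence > 0.60 and lift > 1.0:
        return STRONG
    if lift > 1.0:
        return MODERATE
    return WEAK


def derive_rules(
    table: TransactionTable,
    antecedents: list[str] | None = None,
    consequents: list[str] | None = None,
    min_support: float = 0.01,
    min_confidence: float = 0.0,
    full_search: bool = False,
) -> list[AssociationRule]:
    """Enumerate rules X→Y over the given item filters and score them.

    By default X and Y are single items drawn from ``antecedents`` and
    ``consequents`` (the form clinical rule tables report); with
    ``full_search`` every non-empty subset split is considered.  Pairs
    with X∩Y ≠ ∅ or σ(X) = 0 are skipped; if the filters admit no
    disjoint pair at all, a ValueError is raised.
    """
    if not 0.0 <= min_support <= 1.0 or not 0.0 <= min_confidence <= 1.0:
        raise ValueError("thresholds must be in [0, 1]")
    if antecedents is None:
        antecedents = [TREATMENT_ITEM] if TREATMENT_ITEM in table.items else []
    if consequents is None:
        consequents = [i for i in table.items if i not in antecedents]
    if not antecedents or not consequents:
        raise ValueError("antecedent and consequent filters must be non-empty")
    for item in list(antecedents) + list(consequents):
        if item not in table.items:
            raise KeyError(f"unknown item {item!r}")

    if full_search:
        ant_sets = [
            frozenset(c)
            for r in range(1, len(antecedents) + 1)
            for c in combinations(sorted(antecedents), r)
        ]
        con_sets = [
            frozenset(c)
            for r in range(1, len(consequents) + 1)
            for c in combinations(sorted(consequents), r)
        ]
    else:
        ant_sets = [frozenset([a]) for a in sorted(set(antecedents))]
        con_sets = [frozenset([c]) for c in sorted(set(consequents))]

    rules: list[AssociationRule] = []
    admissible = 0
    for x in ant_sets:
        for y in con_sets:
            if x & y:
                continue
            admissible += 1
            sigma_x = table.sigma(x)
            if sigma_x == 0:
                continue
            sigma_xy = table.sigma(x | y)
            support = sigma_xy / table.n
            confidence = sigma_xy / sigma_x
            support_y = table.support(y)
            lift = confidence / support_y if support_y > 0 else 0.0
            if support >= min_support and confidence >= min_confidence:
                rules.append(
                    AssociationRule(
                        antecedent=x, consequent=y,
                        support=support, confidence=confidence, lift=lift,
                    )
                )
    if admissible == 0:
        raise ValueError(
            "antecedent/consequent filters force overlapping rules; no "
            "disjoint (X, Y) pair exists"
        )
    rules.sort(key=lambda r: (-r.confidence, -r.support, sorted(r.consequent)))
    return rules


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    """Render rules in the familiar LHS/RHS percent layout."""
    rows = [
        {
            "LHS": " & ".join(sorted(r.antecedent)),
            "RHS": " & ".join(sorted(r.consequent)),
            "support_pct": 100.0 * r.support,
            "confidence_pct": 100.0 * r.confidence,
            "lift": r.lift,
            "strength": r.strength,
        }
        for r in rules
    ]
    return pd.DataFrame(
        rows, columns=["LHS", "RHS", "support_pct", "confidence_pct", "lift", "strength"]
    )


class AssociationRuleMiner:
    """Model-style wrapper: mine rules from a transaction table.

    Examples
    --------
    >>> miner = AssociationRuleMiner(table)
    >>> res = miner.fit(min_support=0.01)
    >>> res.frame()  # LHS/RHS table with percent columns
    """

    def __init__(
        self,
        table: TransactionTable,
        antecedents: list[str] | None = None,
        consequents: list[str] | None = None,
    ):
        self.table = table
        self.antecedents = antecedents
        self.consequents = consequents

    def fit(
        self,
        min_support: float = 0.01,
        min_confidence: float = 0.0,
        full_search: bool = False,
    ) -> "RuleResults":
        rules = derive_rules(
            self.table, self.antecedents, self.consequents,
            min_support=min_support, min_confidence=min_confidence,
            full_search=full_search,
        )
        return RuleResults(model=self, rules=rules)


@dataclass
class RuleResults:
    """Mined rules plus rendering helpers."""

    model: AssociationRuleMiner
    rules: list[AssociationRule]

    def frame(self) -> pd.DataFrame:
        return rules_to_frame(self.rules)

    def summary(self) -> str:
        frame = self.frame()
        lines = [
            f"Association rules  (N={self.model.table.n} records, "
            f"{len(self.rules)} rules)",
            frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)
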