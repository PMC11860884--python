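"""Two-group differential expression and target-set intersection.

Screens a case/control expression matrix gene-by-gene with an
unequal-variance (Welch) t-test on log2-scale values, reporting
log2 fold change = mean(case) − mean(control) and a two-sided p-value;
genes pass at the conventional microarray thresholds p < 0.05 and
|log2FC| > 2 (both strict).  The classic moderated-variance
(empirical-Bayes) test is deliberately not used: this stage only feeds
threshold-based screening, and a plain per-gene test keeps it simple and
dependency-free.

No multiple-testing correction is applied by default, mirroring the raw
p < 0.05 screening convention; a Benjamini–Hochberg column is available
via ``bh_adjust=True``.

:func:`intersect_targets` performs the Venn step: the union of
compound-target lists is intersected with the differential genes, with
case-insensitive, whitespace-trimmed symbol matching.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive, whitespace-trimmed gene-symbol key."""
    return str(symbol).strip().upper()


def _collapse_duplicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate symbols to the row with maximal mean expression."""
    keys = matrix.index.map(normalize_symbol)
    if keys.has_duplicates:
        order = matrix.mean(axis=1).to_numpy()
        frame = matrix.copy()
        frame["_key"] = keys
        frame["_mean"] = order
        frame = frame.sort_values("_mean", ascending=False)
        frame = frame[~frame["_key"].duplicated(keep="first")]
        frame = frame.drop(columns=["_key", "_mean"])
        return frame.loc[[g for g in matrix.index if g in frame.index]]
    return matrix


def _maybe_log2(matrix: pd.DataFrame, log_transform) -> pd.DataFrame:
    if log_transform == "auto":
        log_transform = bool(matrix.to_numpy().max() > 50)
        if log_transform:
            logger.info("value range suggests linear scale; applying log2(x+1)")
    if log_transform:
        return np.log2(matrix + 1.0)
    return matrix


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    log_transform="auto",
    collapse_duplicates: bool = True,
) -> pd.DataFrame:
    """Per-gene Welch test of case vs control on a log2-scale matrix.

    Parameters
    ----------
    matrix : DataFrame
        Genes in rows, samples in columns.
    groups : Series
        Sample → ``"case"`` / ``"control"``.
    log_transform : "auto" | bool
        Apply log2(x+1) first; "auto" triggers on a value range typical
        of linear-scale data.

    Returns a table with columns ``gene, log2fc, p_value, degenerate``.
    Zero within-group variance in both groups yields p = 1 when the
    means agree and p = 0 (flagged degenerate) when they differ.
    """
    groups = pd.Series(groups)
    case_ids = groups.index[groups == "case"]
    ctrl_ids = groups.index[groups == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    missing = set(case_ids) | set(ctrl_ids)
    missing -= set(matrix.columns)
    if missing:
        raise ValueError(f"samples missing from the matrix: {sorted(missing)}")

    if collapse_duplicates:
        matrix = _collapse_duplicates(matrix)
    matrix = _maybe_log2(matrix, log_transform)

    case = matrix[case_ids].to_numpy(dtype=float)
    ctrl = matrix[ctrl_ids].to_numpy(dtype=float)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    var0 = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    degenerate = var0 & (log2fc != 0)
    p = np.where(var0, np.where(log2fc == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "log2fc": log2fc,
            "p_value": p,
            "degenerate": degenerate,
        }
    ).reset_index(drop=True)


def select_degs(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> tuple[list[str], list[str]]:
    """Partition significant genes into (up, down) lists.

    A gene is significant iff p_value < p_threshold and
    |log2fc| > fc_threshold, both strict; direction follows the sign of
    log2fc.
    """
    if p_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    sig = (table["p_value"] < p_threshold) & (table["log2fc"].abs() > fc_threshold)
    up = table.loc[sig & (table["log2fc"] > 0), "gene"].tolist()
    down = table.loc[sig & (table["log2fc"] < 0), "gene"].tolist()
    logger.info(
        "%d significant genes (%d upregulated, %d downregulated)",
        len(up) + len(down), len(up), len(down),
    )
    return up, down


def intersect_targets(
    deg_genes, target_lists: dict[str, list[str]]
) -> dict:
    """Intersect differential genes with the union of target lists.

    Symbols are matched case-insensitively after trimming; duplicate
    symbols within and across lists count once.  Returns a dict with the
    deduplicated target ``union``, the ``consensus`` genes (union ∩ DEGs,
    reported with the DEG spelling), and per-list Venn counts.
    """
    deg_keys = {}
    for g in deg_genes:
        deg_keys.setdefault(normalize_symbol(g), str(g).strip())
    if not deg_keys:
        warnings.warn("empty differential gene set; consensus is empty")
    per_list = {}
    union_keys: dict[str, str] = {}
    for name, genes in target_lists.items():
        keys = {normalize_symbol(g): str(g).strip() for g in genes}
        per_list[name] = {
            "size": len(keys),
            "overlap_with_degs": len(set(keys) & set(deg_keys)),
        }
        for k, v in keys.items():
            union_keys.setdefault(k, v)
    consensus_keys = sorted(set(union_keys) & set(deg_keys))
    return {
        "union": sorted(union_keys.values(), key=normalize_symbol),
        "union_size": len(union_keys),
        "consensus": [deg_keys[k] for k in consensus_keys],
        "consensus_size": len(consensus_keys),
        "per_list": per_list,
        "n_degs": len(deg_keys),
    }


class DifferentialExpression:
    """Model-style front end: ``DifferentialExpression(matrix, groups).fit()``."""

    def __init__(self, matrix: pd.DataFrame, groups: pd.Series, log_transform="auto"):
        self.matrix = matrix
        self.groups = pd.Series(groups)
        self.log_transform = log_transform

    def fit(self) -> "DEGResults":
        table = differential_expression(
            self.matrix, self.groups, log_transform=self.log_transform
        )
        return DEGResults(model=self, table=table)


class DEGResults:
    """Per-gene statistics with threshold selection and a text summary."""

    def __init__(self, model: DifferentialExpression, table: pd.DataFrame):
        self.model = model
        self.table = table

    def select(self, p_threshold: float = 0.05, fc_threshold: float = 2.0):
        return select_degs(self.table, p_threshold, fc_threshold)

    def summary(self, p_threshold: float = 0.05, fc_threshold: float = 2.0) -> str:
        up, down = self.select(p_threshold, fc_threshold)
        n_p = int((self.table["p_value"] < p_threshold).sum())
        return (
            f"Differential expression: {len(self.table)} genes tested; "
            f"{n_p} at p < {p_threshold}; "
            f"{len(up) + len(down)} with |log2FC| > {fc_threshold} "
            f"({len(up)} upregulated, {len(down)} downregulated)"
        )
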