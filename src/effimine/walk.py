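"""Cumulative-efficacy walks and fluctuation analysis.

Per-patient treatment outcomes, coded ±1 (improved / not improved) and
taken in admission order, define a walk y(l) = Σ increments.  The walk's
fluctuation function

    F²(l) = mean(Δy_l²) − mean(Δy_l)²,   Δy_l = y(l₀+l) − y(l₀)

is the variance of the l-step displacement over all overlapping start
points l₀.  For memoryless (exchangeable) outcomes F²(l) grows linearly
in l, so F(l) = √F²(l) ∼ l^½; persistent trends in efficacy push the
scaling exponent α of F(l) ∼ l^α away from ½.

Note on conventions: some write the scaling law on F²(l) directly, in
which case the memoryless exponent is 1 rather than ½.  This module
defines α on F(l) = √F²(l) throughout, so the memoryless null is α = ½.

Departure from the null is assessed by a permutation test: shuffling the
increments destroys serial structure while preserving the outcome
marginal, so the observed α̂ is compared against the α̂ distribution over
shuffles.  The permutation route is preferred to the regression standard
error, which is anti-conservative because F²(l) values at overlapping
lags are strongly dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mining import TransactionTable


@dataclass
class EfficacyWalk:
    """A cumulative outcome walk.

    ``increments`` are the per-record outcome steps (±1 when built from
    transactions; synthetic fixtures may carry integer-valued steps).
    ``y`` is the cumulative path with y(0) = 0 prepended.
    """

    increments: np.ndarray

    def __post_init__(self) -> None:
        self.increments = np.asarray(self.increments, dtype=float)
        if self.increments.ndim != 1 or self.increments.size == 0:
            raise ValueError("increments must be a non-empty 1-D sequence")

    @property
    def n(self) -> int:
        return self.increments.size

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.increments)])

    @classmethod
    def from_transactions(
        cls, table: TransactionTable, outcome_item: str, order=None
    ) -> "EfficacyWalk":
        """Step +1 if the record contains ``outcome_item``, −1 otherwise.

        Records are taken in ``order`` (an index permutation) or file
        order, standing in for the admission sequence.
        """
        if table.n == 0:
            raise ValueError("cannot build a walk from an empty table")
        if outcome_item not in table.items:
            raise KeyError(f"unknown item {outcome_item!r}")
        col = table.records[:, table.items.index(outcome_item)]
        if order is not None:
            col = col[np.asarray(order)]
        return cls(increments=np.where(col, 1.0, -1.0))


def default_lags(n: int, lo: int = 4, max_points: int = 12) -> np.ndarray:
    """Log-spaced lag grid from ``lo`` to n/4 with at most ``max_points`` lags.

    Small lags are dominated by step discreteness and lags beyond n/4 by
    estimator noise, so both ends are avoided by default.
    """
    hi = max(n // 4, lo)
    grid = np.unique(np.geomspace(lo, hi, max_points).round().astype(int))
    return grid[(grid >= 1) & (grid <= n // 2)]


@dataclass
class FluctuationResult:
    """Fluctuation function, fitted exponent and permutation-test verdict."""

    lags: np.ndarray
    F2: np.ndarray
    alpha_hat: float | None = None
    alpha_se: float | None = None
    fit_lags: np.ndarray | None = None
    null_rejected: bool | None = None
    p_value: float | None = None
    n_shuffles: int = 0
    null_alphas: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = ["Fluctuation analysis"]
        lines.append(f"  lags: {self.lags.tolist()}")
        with np.errstate(divide="ignore"):
            lines.append(
                "  F2:   " + ", ".join(f"{v:.4g}" for v in self.F2)
            )
        if self.alpha_hat is not None:
            lines.append(
                f"  alpha_hat = {self.alpha_hat:.4f}  (se {self.alpha_se:.4f}; "
                f"memoryless null alpha = 0.5)"
            )
        if self.null_rejected is not None:
            verdict = "REJECTED" if self.null_rejected else "not rejected"
            lines.append(
                f"  permutation test ({self.n_shuffles} shuffles): "
                f"p = {self.p_value:.4f}, null {verdict}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, path=None):
        """log F(l) vs log l with the fitted line."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        keep = self.F2 > 0
        ax.loglog(self.lags[keep], np.sqrt(self.F2[keep]), "o", label="F(l)")
        if self.alpha_hat is not None and self.fit_lags is not None:
            xs = np.asarray(self.fit_lags, dtype=float)
            i0 = np.searchsorted(self.lags, xs[0])
            anchor = np.sqrt(self.F2[i0])
            ax.loglog(
                xs, anchor * (xs / xs[0]) ** self.alpha_hat, "-",
                label=rf"fit $\alpha$ = {self.alpha_hat:.3f}",
            )
        ax.set_xlabel("lag l")
        ax.set_ylabel("F(l)")
        ax.legend()
        if path is not None:
            ax.figure.savefig(path, dpi=120)
        return ax


def fluctuation_function(walk: EfficacyWalk, lags) -> FluctuationResult:
    """F²(l) over all overlapping start points, per lag.

    For each l the displacements Δy_l = y(l₀+l) − y(l₀) are taken over
    every start l₀ ∈ {0, …, n−l}; F²(l) is their variance, computed as
    the second raw moment minus the squared mean.
    """
    lags = np.asarray(sorted(set(int(l) for l in np.atleast_1d(lags))))
    if lags.size == 0 or lags[0] < 1:
        raise ValueError("lags must be >= 1")
    if lags[-1] > walk.n // 2:
        raise ValueError(
            f"maximum lag {lags[-1]} exceeds n/2 = {walk.n // 2} "
            "(averaging would be unstable)"
        )
    y = walk.y
    F2 = np.empty(lags.size)
    for i, l in enumerate(lags):
        d = y[l:] - y[:-l]
        F2[i] = float(np.mean(d * d) - np.mean(d) ** 2)
    F2 = np.maximum(F2, 0.0)  # guard tiny negative round-off
    return FluctuationResult(lags=lags, F2=F2)


def fit_scaling_exponent(
    result: FluctuationResult, fit_range=None
) -> FluctuationResult:
    """Least-squares slope of log F(l) = ½ log F²(l) against log l.

    Lags with F² = 0 are dropped with a warning; at least 3 must survive.
    """
    if fit_range is None:
        fit_range = result.lags
    fit_range = np.asarray(sorted(set(int(l) for l in np.atleast_1d(fit_range))))
    mask = np.isin(result.lags, fit_range)
    lags = result.lags[mask]
    F2 = result.F2[mask]
    keep = F2 > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} lag(s) with F²=0 from the fit",
            stacklevel=2,
        )
    lags, F2 = lags[keep], F2[keep]
    if lags.size < 3:
        raise ValueError("need at least 3 lags with F² > 0 to fit the exponent")
    fit = stats.linregress(np.log(lags), 0.5 * np.log(F2))
    result.alpha_hat = float(fit.slope)
    result.alpha_se = float(fit.stderr)
    result.fit_lags = lags
    return result


def _alpha_of(increments: np.ndarray, lags: np.ndarray) -> float:
    res = fluctuation_function(EfficacyWalk(increments), lags)
    return fit_scaling_exponent(res).alpha_hat


def test_alpha_null(
    walk: EfficacyWalk,
    n_shuffles: int = 199,
    level: float = 0.05,
    seed: int = 0,
    lags=None,
    fit_range=None,
) -> FluctuationResult:
    """Permutation test of the memoryless null α = ½.

    The null distribution of α̂ is obtained by refitting the exponent on
    ``n_shuffles`` independent permutations of the increments (which
    preserve the step marginal but destroy serial order); the null is
    rejected when the observed α̂ falls outside the empirical
    (level/2, 1−level/2) range of the null.  The two-sided p-value uses
    the add-one Monte-Carlo convention — the observed statistic counts as
    a member of its own reference set — which makes the test exact at the
    nominal level under exchangeability rather than slightly
    anti-conservative.
    """
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be >= 99")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if np.all(walk.increments == walk.increments[0]):
        raise ValueError(
            "degenerate walk: all increments equal, F² is identically 0 "
            "under every shuffle"
        )
    if lags is None:
        lags = default_lags(walk.n)
    result = fluctuation_function(walk, lags)
    result = fit_scaling_exponent(result, fit_range=fit_range)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    inc = walk.increments
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_shuffles):
            null[b] = _alpha_of(rng.permutation(inc), np.asarray(lags))
    a = result.alpha_hat
    p_lo = (1 + int((null <= a).sum())) / (n_shuffles + 1)
    p_hi = (1 + int((null >= a).sum())) / (n_shuffles + 1)
    result.p_value = min(1.0, 2.0 * min(p_lo, p_hi))
    result.null_rejected = bool(result.p_value <= level)
    result.n_shuffles = n_shuffles
    result.null_alphas = null
    return result


class FluctuationModel:
    """Model-style front end for the fluctuation analysis.

    Parameters
    ----------
    data : EfficacyWalk or 1-D sequence of increments
    lags : lag grid, or None for the default log-spaced grid

    ``fit()`` computes F²(l) and the scaling exponent; ``fit(test_null=True)``
    additionally runs the permutation test.
    """

    def __init__(self, data, lags=None):
        self.walk = data if isinstance(data, EfficacyWalk) else EfficacyWalk(data)
        self.lags = np.asarray(lags) if lags is not None else default_lags(self.walk.n)

    def fit(
        self,
        fit_range=None,
        test_null: bool = False,
        n_shuffles: int = 199,
        level: float = 0.05,
        seed: int = 0,
    ) -> FluctuationResult:
        if test_null:
            return test_alpha_null(
                self.walk, n_shuffles=n_shuffles, level=level, seed=seed,
                lags=self.lags, fit_range=fit_range,
            )
        result = fluctuation_function(self.walk, self.lags)
        return fit_scaling_exponent(result, fit_range=fit_range)
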