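"""Seeded generators for every input the pipeline consumes.

The study this package operationalises rests on data that cannot be
redistributed: a hospital cohort with pre/post laboratory values, a
two-group synovial expression matrix, compound-target lists, a
protein-interaction network and annotation catalogs.  This module
generates statistically structured stand-ins for all of them, so the
whole pipeline is exercisable and testable offline:

* :func:`gen_cohort` — patients with treatment exposure and pre/post
  marker values; pre values follow a log-normal solved from the marker's
  printed median and quartiles, post values apply a configurable
  conditional-improvement effect.
* :func:`gen_improvement_sequence` — ±1 outcome sequences (i.i.d.,
  drifted, doubly-integrated, constant) for the fluctuation model.
* :func:`gen_expression` — two-group matrix with spiked differential
  genes and known ground truth.
* :func:`gen_network` — simple undirected graphs, optionally with a
  planted dominant hub.
* :func:`gen_genesets` — named gene sets, optionally with a planted set.

All generators are bit-identical under a fixed seed.  Seeds are expanded
through named substreams (:func:`substream_rng`) so that adding one
generator call never perturbs another's output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .markers import MarkerSpec

# 75th-percentile z-score of the standard normal; sets the log-normal
# sigma from the printed inter-quartile ratio.
_Z75 = float(stats.norm.ppf(0.75))

SEQUENCE_KINDS = ("iid", "drifted", "integrated", "constant")
NETWORK_MODELS = ("scale_free_like", "erdos_like")


def substream_rng(seed: int, stream: str) -> np.random.Generator:
    """A generator for the named substream of a master seed.

    The stream name is hashed (CRC-32) into the seed sequence, so streams
    are independent and stable across runs and call order.
    """
    tag = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Configuration of the synthetic pre/post cohort.

    ``effect_map`` maps a marker name to the pair
    ``(p_improve_treated, p_improve_untreated)`` — the conditional
    probability that the marker moves in its beneficial direction after
    treatment.  Markers absent from the map get (0.5, 0.5), i.e. no
    treatment effect and a coin-flip improvement.

    ``improve_factor`` / ``worsen_factor`` bound the uniform multiplicative
    change applied to the pre value (for a high-is-bad marker an improving
    patient's post value is pre × U(0.60, 0.97), shrinking toward the
    reference range; a non-improving one gets pre × U(1.00, 1.15); the
    low-is-bad direction uses the reciprocals).  ``noise_cv`` adds
    mean-one multiplicative log-normal measurement noise on top.
    """

    n_patients: int
    treated_fraction: float = 0.5
    effect_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_cv: float = 0.0
    seed: int = 0
    improve_factor: tuple[float, float] = (0.60, 0.97)
    worsen_factor: tuple[float, float] = (1.00, 1.15)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.treated_fraction <= 1.0:
            raise ValueError("treated_fraction must be in [0, 1]")
        for marker, probs in self.effect_map.items():
            pt, pu = probs
            if not (0.0 <= pt <= 1.0 and 0.0 <= pu <= 1.0):
                raise ValueError(
                    f"effect_map[{marker!r}]: probabilities must be in [0, 1]"
                )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def lognormal_params(spec: MarkerSpec) -> tuple[float, float]:
    """(mu, sigma) of the log-normal matching a marker's median and IQR.

    The median fixes mu = ln(median); the quartile ratio fixes
    sigma = ln(q3/q1) / (2 z_.75).  Raises if the quartiles are not
    strictly ordered (the triple is then unsolvable).
    """
    if not (spec.pre_q1 < spec.pre_q3 and spec.pre_q1 > 0):
        raise ValueError(
            f"marker {spec.name!r}: cannot solve log-normal from "
            f"quartiles ({spec.pre_q1}, {spec.pre_q3})"
        )
    if spec.pre_median <= 0:
        raise ValueError(f"marker {spec.name!r}: median must be positive")
    mu = float(np.log(spec.pre_median))
    sigma = float(np.log(spec.pre_q3 / spec.pre_q1) / (2.0 * _Z75))
    return mu, sigma


def gen_cohort(config: CohortConfig, specs: list[MarkerSpec]) -> pd.DataFrame:
    """Simulate a pre/post cohort table.

    Returns one row per patient with columns ``patient_id``, ``treated``
    and ``<marker>_pre`` / ``<marker>_post`` for every marker in `specs`.
    Deterministic under a fixed ``config.seed``.
    """
    if not specs:
        raise ValueError("at least one MarkerSpec is required")
    # validate all quantile triples up front so errors name the marker
    params = {spec.name: lognormal_params(spec) for spec in specs}

    n = config.n_patients
    columns: dict[str, np.ndarray] = {}
    columns["patient_id"] = np.array([f"P{i:05d}" for i in range(n)])
    rng = substream_rng(config.seed, "cohort/treated")
    treated = rng.random(n) < config.treated_fraction
    columns["treated"] = treated

    for spec in specs:
        mu, sigma = params[spec.name]
        rng_m = substream_rng(config.seed, f"cohort/marker/{spec.name}")
        pre = np.exp(rng_m.normal(mu, sigma, size=n))
        pt, pu = config.effect_map.get(spec.name, (0.5, 0.5))
        p_improve = np.where(treated, pt, pu)
        improved = rng_m.random(n) < p_improve
        lo_i, hi_i = config.improve_factor
        lo_w, hi_w = config.worsen_factor
        f_improve = rng_m.uniform(lo_i, hi_i, size=n)
        f_worsen = rng_m.uniform(lo_w, hi_w, size=n)
        factor = np.where(improved, f_improve, f_worsen)
        if not spec.improves_downward:
            factor = 1.0 / factor
        post = pre * factor
        if config.noise_cv > 0:
            # mean-one log-normal noise with the requested CV
            s2 = np.log1p(config.noise_cv**2)
            noise = np.exp(rng_m.normal(-s2 / 2.0, np.sqrt(s2), size=n))
            post = post * noise
        columns[f"{spec.name}_pre"] = pre
        columns[f"{spec.name}_post"] = post

    return pd.DataFrame(columns)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "treated" in frame.columns:
        frame["treated"] = frame["treated"].astype(bool)
    return frame


# ---------------------------------------------------------------------------
# improvement sequences for the walk model
# ---------------------------------------------------------------------------

def gen_improvement_sequence(
    n: int, kind: str = "iid", p: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Generate an outcome-increment sequence of length ``n``.

    Kinds
    -----
    ``iid``
        Independent ±1 steps, P(+1) = p.
    ``drifted``
        Alias of ``iid`` with p ≠ 0.5 expected (a biased walk).
    ``integrated``
        Increments are themselves the cumulative sum of i.i.d. ±1 steps,
        giving a super-diffusive walk (displacement variance ∝ l³).
    ``constant``
        All +1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if kind not in SEQUENCE_KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {SEQUENCE_KINDS}")
    if kind == "constant":
        return np.ones(n, dtype=np.int64)
    rng = substream_rng(seed, f"sequence/{kind}")
    steps = np.where(rng.random(n) < p, 1, -1).astype(np.int64)
    if kind == "integrated":
        return np.cumsum(steps)
    return steps


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def gen_expression(
    n_genes: int,
    n_per_group: int,
    n_spiked: int,
    spike_log2fc: float = 3.0,
    sigma: float = 1.0,
    seed: int = 0,
    base_mean: float = 8.0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate a two-group log2-scale expression matrix with spiked genes.

    Background genes share the same mean in both groups; the first
    ``n_spiked`` genes differ by ``spike_log2fc`` in the case group, with
    alternating sign so both up- and down-regulation occur.  Gaussian
    noise with standard deviation ``sigma`` is added per measurement.

    Returns ``(matrix, groups, spiked_genes)`` where ``matrix`` has genes
    in rows and samples in columns, ``groups`` maps sample to
    ``"case"``/``"control"``, and ``spiked_genes`` is the ground truth.
    """
    if n_genes <= 0 or n_per_group <= 0:
        raise ValueError("n_genes and n_per_group must be positive")
    if n_spiked > n_genes or n_spiked < 0:
        raise ValueError("n_spiked must be in [0, n_genes]")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"case_{i}" for i in range(n_per_group)] + [
        f"control_{i}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["case"] * n_per_group + ["control"] * n_per_group,
        index=samples, name="group",
    )

    rng = substream_rng(seed, "expression")
    means = np.full((n_genes, 2 * n_per_group), base_mean)
    signs = np.where(np.arange(n_spiked) % 2 == 0, 1.0, -1.0)
    means[:n_spiked, :n_per_group] += signs[:, None] * spike_log2fc
    values = means + rng.normal(0.0, sigma, size=means.shape)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.index.name = "gene"
    return matrix, groups, genes[:n_spiked]


def write_expression(matrix: pd.DataFrame, groups: pd.Series, matrix_path, groups_path) -> None:
    matrix.to_csv(matrix_path, sep="\t")
    groups.rename("group").to_csv(groups_path, sep="\t", header=True, index_label="sample")


def read_expression(matrix_path, groups_path) -> tuple[pd.DataFrame, pd.Series]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return matrix, groups


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------

def gen_network(
    n_nodes: int,
    model: str = "scale_free_like",
    planted_hub: str | int | None = None,
    seed: int = 0,
    edge_prob: float = 0.1,
    attach: int = 2,
) -> nx.Graph:
    """Simulate a simple undirected gene-interaction graph.

    ``scale_free_like`` uses preferential attachment (heavy-tailed
    degrees, as protein-interaction networks show); ``erdos_like`` wires
    each pair independently with probability ``edge_prob``.  When
    ``planted_hub`` names a node, that node is connected to every other
    node and competing full-degree nodes are trimmed, so its degree is
    the unique maximum.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if model not in NETWORK_MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {NETWORK_MODELS}")
    names = [f"g{i}" for i in range(n_nodes)]
    rng = substream_rng(seed, f"network/{model}")
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if model == "erdos_like":
        graph = nx.gnp_random_graph(n_nodes, edge_prob, seed=nx_seed)
    else:
        m = min(attach, max(1, n_nodes - 1))
        if n_nodes == 1:
            graph = nx.empty_graph(1)
        else:
            graph = nx.barabasi_albert_graph(n_nodes, m, seed=nx_seed)
    graph = nx.relabel_nodes(graph, dict(zip(range(n_nodes), names)))

    if planted_hub is not None:
        hub = f"g{planted_hub}" if isinstance(planted_hub, int) else str(planted_hub)
        if hub not in graph:
            raise ValueError(f"planted_hub {hub!r} outside node range")
        for other in names:
            if other != hub:
                graph.add_edge(hub, other)
        # trim competing saturated nodes so the hub degree is strictly maximal
        for other in names:
            if other == hub:
                continue
            if graph.degree(other) >= graph.degree(hub):
                nbrs = sorted(v for v in graph.neighbors(other) if v != hub)
                if nbrs:  # on a 2-node graph the tie cannot be broken
                    graph.remove_edge(other, nbrs[0])
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(map(lambda e: tuple(sorted(e)), graph.edges())):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def gen_genesets(
    universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 50),
    planted_set: list[str] | None = None,
    seed: int = 0,
    category: str = "pathway",
) -> dict[str, list[str]]:
    """Sample named gene sets from a universe.

    Set sizes are uniform over ``set_size_range`` (inclusive).  When
    ``planted_set`` is given it is included verbatim under the name
    ``"PLANTED"``.  Raises on an empty universe or sizes exceeding it.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid set_size_range")
    if hi > len(universe):
        raise ValueError("set sizes must not exceed the universe size")
    rng = substream_rng(seed, "genesets")
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"{category.upper()}_{i:03d}"] = [universe[j] for j in sorted(members)]
    if planted_set is not None:
        sets["PLANTED"] = list(planted_set)
    return sets
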