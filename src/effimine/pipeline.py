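"""End-to-end orchestration with a single validated config.

``run_all`` executes the stages in study order — cohort mining → walk
model → differential expression → target intersection → network hub/core
discovery → ROC screening → enrichment — writing every intermediate as
TSV/JSON into an output directory and returning a machine-readable run
report.  A single master seed is expanded into named per-stage
substreams, so toggling one stage never shifts another's randomness, and
the report is identical under an identical seed + config (timing fields
aside).
"""

from __future__ import annotations

import difflib
import json
import logging
import time
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrichment as enr
from . import expression as expr
from . import mining, network, synthetic, walk as walkmod
from .markers import default_marker_specs, load_marker_specs

logger = logging.getLogger("effimine.pipeline")

#: full default configuration; unknown keys anywhere are rejected.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True, "mine": True, "walk": True, "dge": True,
        "intersect": True, "net": True, "roc": True, "enrich": True,
    },
    "cohort": {
        "n_patients": 1283,
        "treated_fraction": 0.5,
        "effect_marker": "Hs-CRP",
        "p_improve_treated": 0.8,
        "p_improve_untreated": 0.5,
        "noise_cv": 0.05,
        "tolerance": 0.0,
    },
    "mine": {"min_support": 0.01, "min_confidence": 0.0},
    "walk": {"outcome_item": None, "n_shuffles": 199, "level": 0.05, "lags": "auto"},
    "expression": {
        "n_genes": 2000, "n_per_group": 10, "n_spiked": 50,
        "spike_log2fc": 3.0, "sigma": 1.0,
        "p_threshold": 0.05, "fc_threshold": 2.0,
    },
    "targets": {"n_lists": 2, "list_size": 60},
    "network": {"top_k": 10, "top_core": 5},
    "roc": {"auc_threshold": 0.7},
    "enrich": {"n_sets": 20, "set_size_min": 10, "set_size_max": 50,
               "mode": "raw", "alpha": 0.05},
    "inputs": {
        "cohort": None, "markers": None, "matrix": None, "groups": None,
        "target_lists": [], "edges": None, "gmt": None, "genes": None,
    },
}

_RANGES = {
    ("mine", "min_support"): (0.0, 1.0),
    ("mine", "min_confidence"): (0.0, 1.0),
    ("cohort", "treated_fraction"): (0.0, 1.0),
    ("cohort", "p_improve_treated"): (0.0, 1.0),
    ("cohort", "p_improve_untreated"): (0.0, 1.0),
    ("walk", "level"): (0.0, 1.0),
    ("roc", "auc_threshold"): (0.0, 1.0),
    ("enrich", "alpha"): (0.0, 1.0),
}


class ConfigError(ValueError):
    """Raised with every collected config violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


def _merge(defaults: dict, override: dict, path: str, errors: list[str]) -> dict:
    out = deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            candidates = difflib.get_close_matches(str(key), defaults.keys(), n=1)
            hint = f" (did you mean {candidates[0]!r}?)" if candidates else ""
            errors.append(f"unknown key {path}{key!r}{hint}")
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.", errors)
        else:
            out[key] = value
    return out


def validate_config(source=None) -> dict:
    """Load, default-fill and range-check a run configuration.

    ``source`` may be None (all defaults), a mapping, or a path to a
    YAML file (an empty file yields the all-defaults config).  Every
    violation is collected and reported together in a
    :class:`ConfigError`.
    """
    if source is None:
        override: dict = {}
    elif isinstance(source, dict):
        override = source
    else:
        text = Path(source).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError([f"config file {source} must contain a mapping"])
        override = loaded

    errors: list[str] = []
    config = _merge(DEFAULT_CONFIG, override, "", errors)

    for (section, key), (lo, hi) in _RANGES.items():
        value = config[section][key]
        if not isinstance(value, (int, float)) or not lo <= value <= hi:
            errors.append(
                f"{section}.{key} = {value!r} outside permitted range [{lo}, {hi}]"
            )
    if config["cohort"]["n_patients"] < 0:
        errors.append("cohort.n_patients must be >= 0")
    if config["walk"]["n_shuffles"] < 99:
        errors.append("walk.n_shuffles must be >= 99")
    if config["enrich"]["mode"] not in ("raw", "bh"):
        errors.append("enrich.mode must be 'raw' or 'bh'")
    stages = config["stages"]
    if not stages["dge"] and stages["net"] and not (
        config["inputs"]["edges"] or config["inputs"]["genes"]
    ):
        errors.append(
            "network stage requires an explicit gene list or edge file "
            "when the DEG stage is disabled"
        )
    if errors:
        raise ConfigError(errors)
    return config


def _stage_seed(master: int, stage: str) -> int:
    rng = synthetic.substream_rng(master, f"pipeline/{stage}")
    return int(rng.integers(0, 2**31 - 1))


def run_all(config=None, outdir="effimine_run") -> dict:
    """Execute the pipeline per config; write artifacts; return the report.

    A failing stage raises with the stage name; artifacts written by
    earlier stages are preserved in ``outdir``.
    """
    config = validate_config(config) if not _is_validated(config) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    report: dict = {"config": config, "version": __version__, "stages": {}}
    elapsed: dict = {}

    specs = (
        load_marker_specs(config["inputs"]["markers"])
        if config["inputs"]["markers"] else default_marker_specs()
    )

    state: dict = {}
    order = ["simulate", "mine", "walk", "dge", "intersect", "net", "roc", "enrich"]
    runners = {
        "simulate": _stage_simulate, "mine": _stage_mine, "walk": _stage_walk,
        "dge": _stage_dge, "intersect": _stage_intersect, "net": _stage_net,
        "roc": _stage_roc, "enrich": _stage_enrich,
    }
    for name in order:
        if not stages[name]:
            continue
        t0 = time.perf_counter()
        logger.info("[%s] starting", name)
        try:
            block = runners[name](config, specs, seed, state, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        elapsed[name] = round(time.perf_counter() - t0, 3)
        if block is not None:
            report["stages"][name] = block
        logger.info("[%s] done in %.2fs", name, elapsed[name])

    report["elapsed"] = elapsed
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _is_validated(config) -> bool:
    return isinstance(config, dict) and set(config) == set(DEFAULT_CONFIG)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, specs, seed, state, outdir):
    c = config["cohort"]
    effect = {c["effect_marker"]: (c["p_improve_treated"], c["p_improve_untreated"])}
    cc = synthetic.CohortConfig(
        n_patients=int(c["n_patients"]),
        treated_fraction=c["treated_fraction"],
        effect_map=effect,
        noise_cv=c["noise_cv"],
        seed=_stage_seed(seed, "cohort"),
    )
    state["cohort"] = synthetic.gen_cohort(cc, specs)
    synthetic.write_cohort(state["cohort"], outdir / "cohort.csv")

    e = config["expression"]
    matrix, groups, spiked = synthetic.gen_expression(
        n_genes=int(e["n_genes"]), n_per_group=int(e["n_per_group"]),
        n_spiked=int(e["n_spiked"]), spike_log2fc=e["spike_log2fc"],
        sigma=e["sigma"], seed=_stage_seed(seed, "expression"),
    )
    state["matrix"], state["groups"], state["spiked"] = matrix, groups, spiked
    synthetic.write_expression(
        matrix, groups, outdir / "expression.tsv", outdir / "groups.tsv"
    )

    t = config["targets"]
    rng = synthetic.substream_rng(seed, "pipeline/targets")
    genes = list(matrix.index)
    lists = {}
    for i in range(int(t["n_lists"])):
        # bias target lists toward truly perturbed genes, as curated
        # compound-target lists are enriched for disease biology
        n_spike_part = min(len(spiked), int(t["list_size"]) // 2)
        picked = set(rng.choice(spiked, size=n_spike_part, replace=False)) if spiked else set()
        rest = [g for g in genes if g not in picked]
        fill = rng.choice(len(rest), size=int(t["list_size"]) - len(picked), replace=False)
        members = sorted(picked | {rest[j] for j in fill})
        lists[f"compound_{i}"] = members
        with open(outdir / f"targets_compound_{i}.txt", "w") as fh:
            fh.write("\n".join(members) + "\n")
    state["target_lists"] = lists
    return {
        "n_patients": int(len(state["cohort"])),
        "n_genes": int(len(matrix)),
        "n_spiked": len(spiked),
        "target_list_sizes": {k: len(v) for k, v in lists.items()},
    }


def _load_cohort(config, state):
    if "cohort" not in state:
        path = config["inputs"]["cohort"]
        if not path:
            raise ValueError("no cohort available: enable simulation or set inputs.cohort")
        state["cohort"] = synthetic.read_cohort(path)
    return state["cohort"]


def _load_matrix(config, state):
    if "matrix" not in state:
        mpath, gpath = config["inputs"]["matrix"], config["inputs"]["groups"]
        if not (mpath and gpath):
            raise ValueError(
                "no expression data: enable simulation or set inputs.matrix/groups"
            )
        state["matrix"], state["groups"] = synthetic.read_expression(mpath, gpath)
    return state["matrix"], state["groups"]


def _stage_mine(config, specs, seed, state, outdir):
    cohort = _load_cohort(config, state)
    table = mining.transactions_from_cohort(
        cohort, specs, tolerance=config["cohort"]["tolerance"]
    )
    state["transactions"] = table
    table.to_frame().to_csv(outdir / "transactions.csv", index=False)
    results = mining.AssociationRuleMiner(table).fit(
        min_support=config["mine"]["min_support"],
        min_confidence=config["mine"]["min_confidence"],
    )
    frame = results.frame()
    frame.to_csv(outdir / "rules.tsv", sep="\t", index=False)
    state["rules"] = results.rules
    return {"n_records": table.n, "n_rules": len(results.rules),
            "rules": frame.to_dict("records")}


def _stage_walk(config, specs, seed, state, outdir):
    w = config["walk"]
    item = w["outcome_item"] or f"{config['cohort']['effect_marker']}_improved"
    table = state.get("transactions")
    if table is None:
        raise ValueError("walk stage needs the mining stage (transactions)")
    ew = walkmod.EfficacyWalk.from_transactions(table, item)
    lags = None if w["lags"] == "auto" else [int(x) for x in str(w["lags"]).split(",")]
    model = walkmod.FluctuationModel(ew, lags=lags)
    res = model.fit(
        test_null=True, n_shuffles=int(w["n_shuffles"]), level=w["level"],
        seed=_stage_seed(seed, "walk"),
    )
    pd.DataFrame({"lag": res.lags, "F2": res.F2}).to_csv(
        outdir / "fluctuation.tsv", sep="\t", index=False
    )
    block = {
        "outcome_item": item,
        "alpha_hat": res.alpha_hat, "alpha_se": res.alpha_se,
        "null_rejected": res.null_rejected, "n_shuffles": res.n_shuffles,
        "terminal_y_over_n": float(ew.y[-1] / ew.n),
    }
    with open(outdir / "walk_summary.json", "w") as fh:
        json.dump(block, fh, indent=2)
    return block


def _stage_dge(config, specs, seed, state, outdir):
    matrix, groups = _load_matrix(config, state)
    e = config["expression"]
    res = expr.DifferentialExpression(matrix, groups).fit()
    res.table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
    up, down = res.select(e["p_threshold"], e["fc_threshold"])
    state["deg_table"] = res.table
    state["degs"] = up + down
    return {
        "n_genes": int(len(res.table)),
        "n_p_significant": int((res.table["p_value"] < e["p_threshold"]).sum()),
        "n_significant": len(up) + len(down),
        "n_up": len(up), "n_down": len(down),
    }


def _stage_intersect(config, specs, seed, state, outdir):
    degs = state.get("degs")
    if degs is None:
        path = config["inputs"]["genes"]
        if not path:
            raise ValueError("intersect stage needs the DEG stage or inputs.genes")
        degs = [line.strip() for line in open(path) if line.strip()]
    lists = state.get("target_lists")
    if lists is None:
        lists = {}
        for path in config["inputs"]["target_lists"]:
            name = Path(path).stem
            lists[name] = [line.strip() for line in open(path) if line.strip()]
        if not lists:
            raise ValueError("intersect stage needs target lists")
    venn = expr.intersect_targets(degs, lists)
    state["consensus"] = venn["consensus"]
    with open(outdir / "consensus_genes.txt", "w") as fh:
        fh.write("\n".join(venn["consensus"]) + "\n")
    with open(outdir / "venn_counts.json", "w") as fh:
        json.dump(venn, fh, indent=2)
    return {k: venn[k] for k in ("union_size", "consensus_size", "per_list", "n_degs")}


def _stage_net(config, specs, seed, state, outdir):
    if config["inputs"]["edges"]:
        graph = network.read_network(config["inputs"]["edges"])
    else:
        genes = state.get("consensus") or state.get("degs")
        if not genes:
            raise ValueError("network stage needs consensus genes or inputs.edges")
        graph = synthetic.gen_network(
            n_nodes=len(genes), model="scale_free_like",
            planted_hub=0, seed=_stage_seed(seed, "network"),
        )
        graph = _relabel(graph, sorted(genes))
        synthetic.write_edge_list(graph, outdir / "network_edges.tsv")
    table = network.compute_centralities(graph)
    table.to_csv(outdir / "centralities.tsv", sep="\t")
    hubs = network.select_hub_genes(table, k=int(config["network"]["top_k"]))
    core = network.score_core_genes(graph, top=int(config["network"]["top_core"]))
    state["core_genes"] = core
    with open(outdir / "hub_genes.txt", "w") as fh:
        fh.write("\n".join(hubs) + "\n")
    with open(outdir / "core_genes.txt", "w") as fh:
        fh.write("\n".join(core) + "\n")
    return {
        "n_nodes": graph.number_of_nodes(), "n_edges": graph.number_of_edges(),
        "hub_genes": hubs, "core_genes": core,
    }


def _relabel(graph, names):
    import networkx as nx

    mapping = {f"g{i}": names[i] for i in range(len(names))}
    return nx.relabel_nodes(graph, mapping)


def _stage_roc(config, specs, seed, state, outdir):
    matrix, groups = _load_matrix(config, state)
    genes = state.get("core_genes")
    if not genes:
        path = config["inputs"]["genes"]
        if not path:
            raise ValueError("roc stage needs core genes or inputs.genes")
        genes = [line.strip() for line in open(path) if line.strip()]
    screen = network.roc_auc_biomarker(
        matrix, groups, genes, auc_threshold=config["roc"]["auc_threshold"]
    )
    screen.to_csv(outdir / "biomarkers.tsv", sep="\t", index=False)
    return {"screen": screen.to_dict("records")}


def _stage_enrich(config, specs, seed, state, outdir):
    e = config["enrich"]
    query = state.get("consensus") or state.get("degs")
    if not query:
        raise ValueError("enrich stage needs a query gene set")
    if config["inputs"]["gmt"]:
        collection = enr.GeneSetCollection.from_gmt(config["inputs"]["gmt"])
    else:
        matrix, _ = _load_matrix(config, state)
        universe = list(matrix.index)
        sets = synthetic.gen_genesets(
            universe, n_sets=int(e["n_sets"]),
            set_size_range=(int(e["set_size_min"]), int(e["set_size_max"])),
            planted_set=state.get("spiked"),
            seed=_stage_seed(seed, "genesets"),
        )
        collection = enr.GeneSetCollection(universe=set(universe), sets=sets)
    rows = enr.hypergeom_enrich(query, collection)
    rows = enr.adjust_bh(rows, alpha=e["alpha"], mode=e["mode"])
    rows.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {
        "n_terms": int(len(rows)),
        "n_significant": int(rows["significant"].sum()),
        "top_terms": rows.head(5).to_dict("records"),
    }
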