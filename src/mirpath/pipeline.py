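"""End-to-end orchestration: targets -> enrichment -> null -> activity ->
phenotype -> network, with every artefact written to an output directory.

The pipeline is a pure function of (input files, config, seed): rerunning
with the same configuration reproduces every output byte for byte.  The
run log therefore records versions, the seed and a parameter echo, but no
wall-clock information (timings go to the logging stream only).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, activity, data_io, enrichment, network, null_model, phenotype, targets
from .errors import MirpathError, PipelineError

logger = logging.getLogger(__name__)

DEFAULTS = {
    "min_tools": 2,
    "tail": "gt",
    "run_null": True,
    "null_iterations": 50,
    "null_size_min": 4,
    "null_size_max": 50,
    "seed": 0,
    "q_threshold": 0.05,
    "network_format": "sif",
    "correlation_method": "pearson",
    "survival": True,
    "n_top_correlations": 10,
}

_INPUT_KEYS = ("predictions", "pathways", "mrna_expression", "mirna_expression", "phenotypes")


def load_config(path: str | Path) -> dict:
    """Read a flat key:value YAML config file."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise PipelineError(f"{path}: config must be a flat mapping")
    return raw


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except MirpathError as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every stage on the configured inputs and return the report dict."""
    cfg = {**DEFAULTS, **config}
    missing = [k for k in _INPUT_KEYS if k not in cfg]
    if missing:
        raise PipelineError(f"config missing required input path(s): {missing}")
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"config": {k: cfg[k] for k in sorted(cfg)}, "version": __version__}

    # --- inputs ------------------------------------------------------------
    db = _stage("read_pathways")(data_io.read_gmt, cfg["pathways"])
    if cfg.get("interactions"):
        db = _stage("read_interactions")(data_io.read_interactions, cfg["interactions"], db)
    predictions = _stage("read_predictions")(data_io.read_predictions, cfg["predictions"])
    mrna = _stage("read_mrna")(data_io.read_expression, cfg["mrna_expression"])
    mirna_expr = _stage("read_mirna")(data_io.read_expression, cfg["mirna_expression"])
    phen = _stage("read_phenotypes")(data_io.read_phenotypes, cfg["phenotypes"])

    # --- targets -> enrichment --------------------------------------------
    pairs = _stage("filter_min_tools")(targets.filter_min_tools, predictions, int(cfg["min_tools"]))
    pairs = _stage("restrict_to_universe")(targets.restrict_to_universe, pairs, db)
    records = _stage("associate_all")(enrichment.associate_all, db, pairs, tail=cfg["tail"])
    enrichment.write_associations(records, out / "associations.tsv")
    assoc_frame = enrichment.associations_to_frame(records)
    scored = assoc_frame[assoc_frame["mirna_id"] != ""]
    report["associations"] = {
        "n_pathways": len(db),
        "n_supported_pairs": len(pairs),
        "universe_size": pairs.universe_size,
        "n_scored": int(len(scored)),
        "top": scored.head(10).to_dict(orient="records"),
    }

    # --- null model (optional) --------------------------------------------
    if cfg["run_null"]:
        nulls = _stage("null_distribution")(
            null_model.null_distribution,
            db.gene_universe, pairs,
            n_iterations=int(cfg["null_iterations"]),
            n_pathways=len(db),
            size_min=int(cfg["null_size_min"]),
            size_max=int(cfg["null_size_max"]),
            seed=seed, tail=cfg["tail"],
        )
        null_q = null_model.pooled_null_qvalues(nulls)
        observed_q = scored["q_value"].to_numpy(dtype=float)
        t_stat, p_val = null_model.compare_observed_vs_null(observed_q, null_q)
        pd.DataFrame(
            {
                "iteration": np.repeat([r.iteration for r in nulls],
                                       [len(r.q_values) for r in nulls]),
                "q_value": null_q,
            }
        ).to_csv(out / "null_qvalues.tsv", sep="\t", index=False, float_format="%.6g")
        report["null_model"] = {
            "n_iterations": int(cfg["null_iterations"]),
            "observed_median_q": float(np.median(observed_q)),
            "null_median_q": float(np.median(null_q)),
            "welch_t": t_stat,
            "welch_p": p_val,
        }
        with open(out / "null_summary.json", "w", encoding="utf-8") as handle:
            json.dump(report["null_model"], handle, indent=2, sort_keys=True)
            handle.write("\n")

    # --- activity ----------------------------------------------------------
    states = _stage("fit_gene_states")(activity.fit_gene_states, mrna)
    act = _stage("pathway_activity")(activity.pathway_activity, db, states)
    activity.write_activity(act, out / "activity.tsv")
    report["activity"] = {
        "n_pathways_scored": int((~act.values.isna().all(axis=1)).sum()),
        "n_low_coverage": int(act.low_coverage.sum()),
        "n_degenerate_genes": int(states.degenerate.sum()),
    }

    # --- phenotype ----------------------------------------------------------
    group_a = cfg.get("group_a")
    group_b = cfg.get("group_b")
    if group_a is None or group_b is None:
        groups = phen.groups
        if len(groups) != 2:
            raise PipelineError(
                "config must name group_a and group_b when the phenotype "
                f"table has {len(groups)} levels"
            )
        group_a, group_b = groups
    strat = _stage("scan_stratification")(
        phenotype.scan_stratification, act.values, phen, group_a, group_b
    )
    strat.to_csv(out / "stratification.tsv", sep="\t", index=False, float_format="%.6g")
    report["stratification"] = {
        "groups": [group_a, group_b],
        "n_tested": int(len(strat)),
        "top": strat.head(5).to_dict(orient="records"),
    }

    if cfg["survival"] and phen.has_survival:
        surv_rows = []
        for pathway_id in act.values.index:
            row = act.values.loc[pathway_id]
            if row.isna().all() or row.nunique() < 2:
                continue
            res = phenotype.survival_split_test(row, phen)
            surv_rows.append((res.pathway_id, res.statistic, res.p_value))
        surv = pd.DataFrame(surv_rows, columns=["pathway_id", "logrank_statistic", "p_value"])
        if len(surv):
            surv["q_value"] = enrichment.storey_qvalues(surv["p_value"].to_numpy())
            surv = surv.sort_values(["p_value", "pathway_id"], kind="stable").reset_index(drop=True)
        surv.to_csv(out / "survival.tsv", sep="\t", index=False, float_format="%.6g")
        report["survival"] = {
            "n_tested": int(len(surv)),
            "top": surv.head(5).to_dict(orient="records"),
        }

    # Differential correlation for the strongest associations.
    corr_results = []
    mirna_index = set(mirna_expr.values.index)
    for _, rec in scored.head(int(cfg["n_top_correlations"])).iterrows():
        if rec["mirna_id"] not in mirna_index:
            logger.warning("miRNA %s absent from miRNA expression; skipped", rec["mirna_id"])
            continue
        act_row = act.values.loc[rec["pathway_id"]]
        if act_row.isna().all():
            continue
        corr_results.append(
            phenotype.group_correlation(
                mirna_expr.values.loc[rec["mirna_id"]], act_row, phen,
                (group_a, group_b), method=cfg["correlation_method"],
                mirna_id=rec["mirna_id"], pathway_id=rec["pathway_id"],
            )
        )
    corr_frame = phenotype.correlations_to_frame(corr_results, (group_a, group_b))
    corr_frame.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
    report["correlations"] = {
        "n_tested": int(len(corr_frame)),
        "records": corr_frame.to_dict(orient="records"),
    }

    # --- network ------------------------------------------------------------
    net = _stage("build_network")(network.build_network, records, float(cfg["q_threshold"]))
    network.export_network(net, out / ("network." + cfg["network_format"]), cfg["network_format"])
    report["network"] = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "q_threshold": float(cfg["q_threshold"]),
    }

    with open(out / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
    with open(out / "run_log.json", "w", encoding="utf-8") as handle:
        json.dump(
            {
                "version": __version__,
                "seed": seed,
                "parameters": {k: cfg[k] for k in sorted(cfg) if not isinstance(cfg[k], Path)},
            },
            handle, indent=2, sort_keys=True, default=str,
        )
        handle.write("\n")
    return report
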