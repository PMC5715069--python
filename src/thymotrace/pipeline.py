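"""Config-driven orchestration of the full analysis chain.

Runs simulate -> stage -> cluster -> lineage -> screen -> repertoire ->
emigration on a YAML config, writing each step's outputs plus a JSON run
manifest (parameter values, seeds, SHA-256 checksums of every file
written). Reruns with the same config reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import (
    clustering_embedding as ce,
    cytometry_staging as cs,
    emigration_analysis as ea,
    lineage_inference as li,
    repertoire as rp,
    synthetic_data as sd,
    transcriptome_screen as ts,
)

logger = logging.getLogger("thymotrace.pipeline")

ALL_STEPS = (
    "simulate", "stage", "cluster", "lineage", "screen", "repertoire", "emigration",
)

DEFAULT_CONFIG: dict = {
    "outdir": "thymotrace_run",
    "steps": list(ALL_STEPS),
    "seed": 0,
    "simulate": {"n_events": 10_000, "n_genes": 500, "total_reads": 10_000},
    "stage": {"cofactor": 150.0, "threshold_method": "valley"},
    "cluster": {"grid_rows": 10, "grid_cols": 10, "epochs": 20, "k": 7},
    "lineage": {"method": "mst", "subset": "Vg1.1"},
    "screen": {"group_a": "C", "group_b": "E", "member_fraction": 0.3},
    "repertoire": {"n_target": 1200, "motifs": {"demo_motif": "WG.Q"}},
    "emigration": {"min_fold_late": 3.0, "min_growth_ratio": 1.5},
}


def load_config(path: str | Path | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the configured steps in dependency order; return the manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    steps = list(config.get("steps", ALL_STEPS))
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "seed": seed,
        "steps_run": [],
        "skipped": [s for s in ALL_STEPS if s not in steps],
        "outputs": {},
    }
    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, sep: str = "\t") -> None:
        path = outdir / name
        frame.to_csv(path, sep=sep)
        written[name] = path

    state: dict = {}
    for step in ALL_STEPS:
        if step not in steps:
            continue
        try:
            _run_step(step, config, seed, state, emit)
        except Exception as exc:
            for name, path in written.items():
                path.rename(path.with_suffix(path.suffix + ".partial"))
            raise RuntimeError(f"pipeline step {step!r} failed: {exc}") from exc
        manifest["steps_run"].append(step)
    for name, path in written.items():
        manifest["outputs"][name] = _sha256(path)
    if "terminal_stages" in state:
        manifest["terminal_stages"] = sorted(state["terminal_stages"])
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_step(step: str, config: dict, seed: int, state: dict, emit) -> None:
    if step == "simulate":
        sim = config["simulate"]
        cyto_cfg = sd.CytometrySimConfig(
            n_events=int(sim.get("n_events", 10_000)),
            treatment_effects=sd.DEFAULT_TREATMENT_EFFECTS,
            seed=seed,
        )
        state["events"] = sd.gen_cytometry_events(cyto_cfg)
        expr_cfg = sd.ExpressionSimConfig(
            n_genes=int(sim.get("n_genes", 500)), seed=seed + 1
        )
        state["expr"], state["expr_truth"] = sd.gen_expression_matrix(expr_cfg)
        rep_cfg = sd.RepertoireSimConfig(
            total_reads=int(sim.get("total_reads", 10_000)),
            planted_motifs=(("WGIQ", 0.3),),
            seed=seed + 2,
        )
        state["clonotypes"], state["rep_truth"] = sd.gen_clonotype_table(rep_cfg)
        state["go_map"] = sd.gen_go_annotation(
            list(state["expr"].genes),
            member_fraction=float(config["screen"].get("member_fraction", 0.3)),
            seed=seed + 3,
        )
    elif step == "stage":
        pars = config["stage"]
        transformed = cs.arcsinh_transform(
            state["events"], cofactor=float(pars.get("cofactor", 150.0))
        )
        thresholds = cs.fit_positivity_thresholds(
            transformed, method=pars.get("threshold_method", "valley")
        )
        labels = cs.assign_stages(transformed, thresholds)
        state.update(transformed=transformed, thresholds=thresholds, stage_labels=labels)
        emit("stage_labels.tsv", labels.to_frame())
        comp = cs.stage_composition(labels, transformed.annotations, as_="fraction")
        emit("stage_composition.tsv", comp)
        counts = cs.stage_composition(labels, transformed.annotations, as_="count")
        state["stage_counts"] = counts
        emit("stage_counts.tsv", counts)
    elif step == "cluster":
        pars = config["cluster"]
        som = ce.train_som(
            state["transformed"],
            grid_rows=int(pars.get("grid_rows", 10)),
            grid_cols=int(pars.get("grid_cols", 10)),
            epochs=int(pars.get("epochs", 20)),
            seed=seed,
        )
        node_labels = ce.metacluster(som, int(pars.get("k", 7)))
        event_labels = ce.cluster_events(som, state["transformed"], node_labels)
        profile = ce.cluster_profile(state["transformed"], event_labels)
        mapping = ce.match_clusters_to_stages(profile, state["thresholds"])
        emit("cluster_profile.csv", profile.means, sep=",")
        emit(
            "cluster_stage_map.tsv",
            pd.DataFrame(
                {"cluster": list(mapping), "stage": list(mapping.values())}
            ).set_index("cluster"),
        )
        state["cluster_labels"] = event_labels
    elif step == "lineage":
        pars = config["lineage"]
        dm = li.distance_matrix(state["expr"], subset=pars.get("subset"))
        graph = li.build_lineage_graph(
            dm, method=pars.get("method", "mst"), k=pars.get("k")
        )
        emit("distance_matrix.csv", dm.to_frame(), sep=",")
        emit("lineage_edges.tsv", graph.to_edge_list().set_index("node1"))
        state["lineage_graph"] = graph
    elif step == "screen":
        pars = config["screen"]
        expr = state["expr"]
        a, b = pars.get("group_a", "C"), pars.get("group_b", "E")
        mask = expr.sample_meta["stage"].isin([a, b])
        sub = ts.ExpressionMatrix(
            expr.values.loc[:, mask.to_numpy()], expr.sample_meta[mask]
        )
        screen = ts.differential_f_test(sub, sub.sample_meta["stage"])
        screen["q"] = ts.bh_adjust(screen["p"].to_numpy())
        result = ts.candidate_filter(screen, state["go_map"])
        emit("screen_results.tsv", result.table)
        state["screen_result"] = result
    elif step == "repertoire":
        pars = config["repertoire"]
        table = rp.filter_in_frame(state["clonotypes"])
        n_target = int(pars.get("n_target", 1200))
        if table.total_reads >= n_target:
            table = rp.downsample_reads(table, n_target, seed=seed)
        rows = []
        for name, pattern in pars.get("motifs", {}).items():
            rows.append(
                {"motif": name, "fraction": rp.motif_fraction(table, pattern)}
            )
        usage = rp.segment_usage(table, "v")
        emit("motif_fractions.tsv", pd.DataFrame(rows).set_index("motif"))
        emit(
            "v_usage.tsv",
            pd.DataFrame(
                {"v": list(usage), "fraction": list(usage.values())}
            ).set_index("v"),
        )
        emit(
            "diversity.tsv",
            pd.DataFrame(
                {"statistic": ["inverse_simpson"], "value": [rp.inverse_simpson(table)]}
            ).set_index("statistic"),
        )
    elif step == "emigration":
        pars = config["emigration"]
        counts = state["stage_counts"]
        by_group = counts.T.groupby(level="group").sum().T
        result = ea.fold_changes(by_group, baseline="untreated")
        terminal = ea.call_terminal_stages(
            result,
            min_fold_late=float(pars.get("min_fold_late", 3.0)),
            min_growth_ratio=float(pars.get("min_growth_ratio", 1.5)),
        )
        out = result.folds.copy()
        out["terminal"] = [s in terminal for s in out.index]
        emit("accumulation.tsv", out)
        state["terminal_stages"] = terminal
    else:  # pragma: no cover
        raise ValueError(f"unknown step {step!r}")
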