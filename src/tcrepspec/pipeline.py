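"""End-to-end pipeline orchestration from a single config mapping.

Stages, in order: ``simulate`` (or load user tables), ``parse`` (QC),
``build_db``, ``publicity``, ``cluster``, ``enrich``, ``train``,
``annotate``, ``associate``. Every stage writes its tables under the output
directory and registers itself, with the parameters actually used, in
``manifest.json``. All randomness derives from the single root seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, cohort, enrichment, epitope_db, io, model, simulate

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "ratio_threshold": 100.0,
    "bpr_threshold": 1e-4,
    "min_gene_count": 2,
    "alpha": 0.05,
    "neg_ratio": 5.0,
    "n_background": 10_000,
    "background_size": 60_000,
    "n_estimators": 100,
    "contaminant_epitopes": [simulate.DEFAULT_CONTROL_EPITOPE],
    "dialect": "simple",
    "simulate": {},
    "inputs": {},
    "stages": None,
    "association_groups": ["complete remission", "relapse"],
}

ALL_STAGES = ["simulate", "parse", "build_db", "publicity", "cluster",
              "enrich", "train", "annotate", "associate"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_runs_from_manifest(manifest_path: str, dialect: str):
    man = pd.read_csv(manifest_path)
    runs = []
    for row in man.itertuples(index=False):
        records = io.read_clonotype_table(row.path, dialect=dialect,
                                          donor_id=str(row.donor_id),
                                          epitope=str(row.epitope))
        runs.append((str(row.donor_id), str(row.epitope), records))
    return runs


def run_pipeline(config: dict | None, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the output directory."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"] or ALL_STAGES
    seed = int(cfg["seed"])
    gen_cfg = simulate.GeneratorConfig(seed=seed, **cfg["simulate"])
    rng = gen_cfg.rng()
    manifest: dict = {"stages": [], "parameters": {
        k: cfg[k] for k in ("seed", "ratio_threshold", "bpr_threshold",
                            "min_gene_count", "alpha", "neg_ratio",
                            "n_background", "n_estimators",
                            "contaminant_epitopes")
    }}
    state: dict = {}

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})

    def run_stage(stage: str, fn):
        if stage not in stages:
            return
        try:
            fn()
        except Exception as exc:  # re-raise with stage context
            raise PipelineError(stage, exc) from exc

    def st_simulate():
        inputs = cfg["inputs"]
        if inputs.get("runs_manifest"):
            state["runs"] = _load_runs_from_manifest(
                inputs["runs_manifest"], cfg["dialect"])
            truth = None
        else:
            state["runs"], truth = simulate.gen_sorted_runs(gen_cfg, rng=rng)
        if inputs.get("background"):
            state["background_raw"] = io.read_clonotype_table(
                inputs["background"], dialect=cfg["dialect"])
        else:
            state["background_raw"] = simulate.gen_background(
                gen_cfg, int(cfg["background_size"]), rng)
        record("simulate", synthetic=truth is not None,
               n_runs=len(state["runs"]),
               background_size=len(state["background_raw"]))

    def st_parse():
        parsed = []
        reports = {}
        for donor, epitope, records in state["runs"]:
            passed, rep = io.qc_clonotypes(records)
            passed = [c.replace(donor_id=donor, epitope=epitope) for c in passed]
            parsed.append((donor, epitope, passed))
            reports[f"{donor}/{epitope}"] = dataclasses.asdict(rep)
        state["parsed_runs"] = parsed
        (out / "parse_reports.json").write_text(json.dumps(reports, indent=2))
        record("parse", n_runs=len(parsed))

    def st_build_db():
        db = epitope_db.build_epitope_db(
            state["parsed_runs"],
            ratio_threshold=float(cfg["ratio_threshold"]),
            control_epitopes=cfg["contaminant_epitopes"],
        )
        state["db"] = db
        db.to_frame().to_csv(out / "epitope_db.tsv", sep="\t", index=False)
        sizes = {e: db.size(e) for e in db.epitopes}
        (out / "epitope_db_manifest.json").write_text(json.dumps({
            "epitopes": db.epitopes, "unique_cdr3s": sizes,
            "ratio_threshold": cfg["ratio_threshold"],
            "control_epitopes": list(cfg["contaminant_epitopes"]),
        }, indent=2))
        record("build_db", unique_cdr3s=sizes)

    def st_publicity():
        db = state["db"]
        stats = {}
        for e in db.epitopes:
            table, hist = epitope_db.publicity(db, e)
            table.to_csv(out / f"publicity_{e}.csv", index=False)
            stats[e] = {"n_public": int(table.public.sum()),
                        "n_total": len(table), "histogram": hist}
        state["publicity"] = stats
        record("publicity", **{e: s["n_public"] for e, s in stats.items()})

    def st_cluster():
        db = state["db"]
        info = {}
        for e in db.epitopes:
            per_cdr3_donors: dict[str, set] = {}
            for c in db.entries[e]:
                per_cdr3_donors.setdefault(c.cdr3_aa, set()).add(c.donor_id)
            cg = clustering.hamming1_graph(
                per_cdr3_donors,
                metadata={s: {"donor_ids": d} for s, d in per_cdr3_donors.items()},
            )
            summary = clustering.cluster_summary(cg)
            summary.to_csv(out / f"clusters_{e}.csv", index=False)
            if len(summary):
                largest = summary.sort_values(
                    ["size", "cluster_id"], ascending=[False, True]).iloc[0]
                pfm = clustering.cluster_pfm(cg.clusters[largest.cluster_id])
                pfm.to_csv(out / f"pfm_largest_{e}.tsv", sep="\t")
            info[e] = {"fraction_clustered": cg.fraction_clustered,
                       "n_clusters": len(cg.clusters),
                       "n_multi_donor": int((summary.n_donors >= 2).sum())}
        state["cluster_info"] = info
        record("cluster", **{e: i["n_clusters"] for e, i in info.items()})

    def st_enrich():
        db = state["db"]
        background, _ = io.qc_clonotypes(state["background_raw"])
        background = enrichment.build_background([background])
        state["background"] = background
        for e in db.epitopes:
            focal = db.unique_clonotypes(e)
            for segment in ("v", "j"):
                for level in ("gene", "family"):
                    res = enrichment.enrich(
                        focal, background, segment=segment, level=level,
                        min_count=int(cfg["min_gene_count"]),
                        alpha=float(cfg["alpha"]))
                    res.to_csv(out / f"enrichment_{e}_{segment}_{level}.csv",
                               index=False)
        record("enrich", background_size=len(background))

    def st_train():
        db = state["db"]
        background = state.get("background")
        if background is None:
            background, _ = io.qc_clonotypes(state["background_raw"])
            background = enrichment.build_background([background])
        models, metrics = {}, {}
        for e in db.epitopes:
            positives = epitope_db.dedup_cdr3(db.unique_clonotypes(e))
            m, cv = model.train_model(
                positives, background, epitope=e,
                neg_ratio=float(cfg["neg_ratio"]),
                n_background=int(cfg["n_background"]),
                seed=int(rng.integers(2**31)),
                n_estimators=int(cfg["n_estimators"]),
            )
            models[e] = m
            metrics[e] = {
                "n_positives": len(positives),
                "balanced_accuracy": cv.balanced_accuracy,
                "auroc": cv.auroc,
                "average_precision": cv.average_precision,
            }
            cv.roc_points.to_csv(out / f"roc_{e}.csv", index=False)
            cv.pr_points.to_csv(out / f"pr_{e}.csv", index=False)
        state["models"] = models
        (out / "cv_metrics.json").write_text(json.dumps(metrics, indent=2))
        record("train", **{e: round(m["auroc"][0], 4) for e, m in metrics.items()})

    def st_annotate():
        db = state["db"]
        cohort_manifest = cfg["inputs"].get("cohort_manifest")
        if cohort_manifest:
            man = pd.read_csv(cohort_manifest)
            reps = []
            for ind, sub in man.groupby("individual_id", sort=True):
                samples = [
                    io.qc_clonotypes(
                        io.read_clonotype_table(p, dialect=cfg["dialect"])
                    )[0]
                    for p in sub["path"]
                ]
                reps.append(cohort.Repertoire.from_samples(
                    str(ind), str(sub["group"].iloc[0]), samples))
        else:
            reps, _truth = simulate.gen_cohort(gen_cfg, db, rng)
        state["repertoires"] = reps
        summary, identified = cohort.annotate_cohort(
            reps, db, list(state.get("models", {}).values()),
            threshold=float(cfg["bpr_threshold"]))
        state["identified"] = identified
        summary.to_csv(out / "cohort_summary.csv", index=False)
        cg, table, dots = cohort.joint_cluster_annotate(reps, identified)
        state["cluster_group_table"] = table
        table.to_csv(out / "annotated_clusters.csv", index=False)
        dots.to_csv(out / "cluster_dotplot.csv", index=False)
        record("annotate", n_individuals=len(reps),
               n_annotated_clusters=len(table))

    def st_associate():
        table = state["cluster_group_table"]
        groups = tuple(cfg["association_groups"])
        try:
            stat, dof, p, _ = cohort.group_cluster_association(table, groups)
            result = {"statistic": stat, "dof": dof, "p": p, "groups": groups}
        except ValueError as exc:
            result = {"error": str(exc), "groups": groups}
        (out / "association.json").write_text(json.dumps(result, indent=2))
        record("associate", **{k: v for k, v in result.items() if k != "groups"})

    for stage, fn in [
        ("simulate", st_simulate), ("parse", st_parse), ("build_db", st_build_db),
        ("publicity", st_publicity), ("cluster", st_cluster),
        ("enrich", st_enrich), ("train", st_train),
        ("annotate", st_annotate), ("associate", st_associate),
    ]:
        run_stage(stage, fn)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
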