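"""End-to-end pipeline: simulate? -> optimize -> extract -> subtype -> classify.

Stages are driven by a single YAML/dict config, executed in order, each
consuming the previous stage's file outputs, and recorded in a JSON run
manifest (config hash, seeds, per-stage file digests, package version).
Re-running with an unchanged config resumes after the last completed stage
and reproduces byte-identical outputs for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (DEFAULT_ANCHORS, GeneSet, binarize_response,
                 deduplicate_by_latest_timepoint, load_expression_matrix,
                 load_gene_set, load_response_table, save_gene_set)
from .optimize import GeneSetOptimizer
from .signatures import extract_signatures, label_signatures, select_rank
from .simulate import simulate_bfsig_dataset, simulate_drug_response
from .subtypes import cluster_samples
from .classify import repeated_split_evaluate

__all__ = ["run_pipeline", "KNOWN_STAGES"]

KNOWN_STAGES = ("simulate", "optimize", "extract", "subtype", "classify")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir, resume: bool = True) -> dict:
    """Execute the configured stages and return the run manifest.

    `config` keys: ``stages`` (ordered subset of simulate, optimize,
    extract, subtype, classify), ``seed``, and one sub-dict of options per
    stage.  File-producing stages write under `outdir`; the manifest is
    saved as ``manifest.json`` there.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
    order = [s for s in KNOWN_STAGES if s in stages]
    seed = int(config.get("seed", 0))

    manifest_path = outdir / "manifest.json"
    manifest = {"config_hash": _config_hash(config), "seed": seed,
                "package_version": __version__, "stages": {}}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest["stages"] = old.get("stages", {})

    def done(stage):
        rec = manifest["stages"].get(stage)
        if not rec:
            return False
        return all(Path(p).exists() and _digest(Path(p)) == d
                   for p, d in rec["outputs"].items())

    def record(stage, outputs):
        manifest["stages"][stage] = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {str(p): _digest(Path(p)) for p in outputs},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def require(path, stage, what):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {what} at {path}; "
                "run the producing stage first or point the config at an existing file"
            )
        return path

    paths = {
        "expr": outdir / "expression.tsv",
        "genes": outdir / "genes.txt",
        "response": outdir / "response.tsv",
        "optimized": outdir / "optimized_genes.txt",
        "audit": outdir / "optimization.json",
        "sigdir": outdir / "signatures",
        "subtypes": outdir / "subtypes.tsv",
        "predictions": outdir / "predictions.tsv",
        "evaluation": outdir / "evaluation.json",
    }
    cfg = {s: dict(config.get(s, {})) for s in KNOWN_STAGES}

    if "simulate" in order and not done("simulate"):
        opts = cfg["simulate"]
        expr, genes, truth = simulate_bfsig_dataset(
            seed=opts.pop("seed", seed), **{k: v for k, v in opts.items()
                                            if k not in ("response",)})
        resp_opts = cfg["simulate"].get("response", {})
        resp = simulate_drug_response(truth, expr.sample_ids,
                                      seed=seed + 1, **resp_opts)
        expr.save(paths["expr"])
        save_gene_set(genes, paths["genes"])
        resp.save(paths["response"])
        truth_out = {"anchor_factor": truth.anchor_factor,
                     "gene_roles": truth.gene_roles,
                     "sample_group": truth.sample_group.tolist(),
                     "config": truth.config}
        (outdir / "truth.json").write_text(json.dumps(truth_out, indent=2))
        record("simulate", [paths["expr"], paths["genes"], paths["response"],
                            outdir / "truth.json"])

    if "optimize" in order and not done("optimize"):
        opts = cfg["optimize"]
        expr = load_expression_matrix(require(opts.get("expr", paths["expr"]),
                                              "optimize", "an expression matrix"))
        pool = load_gene_set(require(opts.get("genes", paths["genes"]),
                                     "optimize", "a gene pool"),
                             format=opts.get("genes_format", "list"),
                             anchors=opts.get("anchors", DEFAULT_ANCHORS))
        optimizer = GeneSetOptimizer(
            k=opts.get("k", 3), v_folds=opts.get("v_folds", 5),
            restarts=opts.get("restarts", 2), patience=opts.get("patience", 0.0),
            batch_remove=opts.get("batch_remove", False),
            random_state=opts.get("seed", seed))
        optimizer.fit(expr, pool)
        with open(paths["optimized"], "w") as fh:
            fh.write("\n".join(optimizer.selected_genes_) + "\n")
        optimizer.result_.to_json(paths["audit"])
        record("optimize", [paths["optimized"], paths["audit"]])

    if "extract" in order and not done("extract"):
        opts = cfg["extract"]
        expr = load_expression_matrix(require(opts.get("expr", paths["expr"]),
                                              "extract", "an expression matrix"))
        gene_file = require(opts.get("genes", paths["optimized"]),
                            "extract", "the optimized gene list")
        genes = [ln.strip() for ln in open(gene_file) if ln.strip()]
        sub = expr.subset_genes(genes)
        rank = opts.get("rank")
        paths["sigdir"].mkdir(exist_ok=True)
        if rank is None:
            lo, hi = opts.get("ranks", (2, 6))
            kwargs = {}
            if "drop_tol" in opts:
                kwargs["drop_tol"] = opts["drop_tol"]
            report = select_rank(sub, range(lo, hi + 1),
                                 n_runs=opts.get("n_runs", 20),
                                 seed=opts.get("seed", seed), **kwargs)
            report.to_json(paths["sigdir"] / "rank_report.json")
            for k, cons in report.consensus.items():
                pd.DataFrame(cons).to_csv(paths["sigdir"] / f"consensus_k{k}.tsv",
                                          sep="\t", index=False)
            rank = report.chosen_rank
        sigs = extract_signatures(sub, rank, restarts=opts.get("restarts", 5),
                                  seed=opts.get("seed", seed))
        sigs = label_signatures(sigs, anchors=opts.get("anchors", DEFAULT_ANCHORS))
        sigs.save(paths["sigdir"])
        record("extract", [paths["sigdir"] / "W_norm.tsv", paths["sigdir"] / "H.tsv",
                           paths["sigdir"] / "labels.json"])

    if "subtype" in order and not done("subtype"):
        opts = cfg["subtype"]
        H = pd.read_csv(require(opts.get("h", paths["sigdir"] / "H.tsv"),
                                "subtype", "the activity matrix H"),
                        sep="\t", index_col=0)
        assignment = cluster_samples(H, n_clusters=opts.get("n_clusters", H.shape[0]))
        assignment.save(paths["subtypes"])
        record("subtype", [paths["subtypes"]])

    if "classify" in order and not done("classify"):
        opts = cfg["classify"]
        H = pd.read_csv(require(opts.get("h", paths["sigdir"] / "H.tsv"),
                                "classify", "the activity matrix H"),
                        sep="\t", index_col=0)
        resp = load_response_table(require(opts.get("response", paths["response"]),
                                           "classify", "a response table"))
        drug = opts.get("drug", "venetoclax")
        resp = binarize_response(resp, drug,
                                 sensitive_max=opts.get("sensitive_max", 1.0),
                                 resistant_min=opts.get("resistant_min", 10.0))
        resp = deduplicate_by_latest_timepoint(resp)
        rows = resp.data[resp.data["binary_class"] != "excluded"]
        rows = rows[rows["sample_id"].isin(H.columns)]
        y = (rows["binary_class"] == "sensitive").astype(int).to_numpy()
        feats = pd.DataFrame(H[rows["sample_id"]].to_numpy().T,
                             index=list(rows["sample_id"]), columns=list(H.index))
        ev = repeated_split_evaluate(feats, y,
                                     n_repeats=opts.get("n_repeats", 10),
                                     train_frac=opts.get("train_frac", 0.7),
                                     seed=opts.get("seed", seed))
        pred = pd.DataFrame({"probability": ev.sample_probability,
                             "label": y}, index=feats.index)
        pred.to_csv(paths["predictions"], sep="\t", index_label="sample_id")
        (paths["evaluation"]).write_text(json.dumps({
            "pooled_auroc": ev.pooled_auroc,
            "ci95": list(ev.pooled_ci),
            "rank_test_p": ev.rank_test_p,
            "n": int(len(y)),
            "drug": drug,
        }, indent=2))
        record("classify", [paths["predictions"], paths["evaluation"]])

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
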