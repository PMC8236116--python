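"""End-to-end orchestration: simulate/load -> preprocess -> tune -> fit ->
stability-select -> downstream statistics -> validate.

A single YAML config drives the run; every stage persists its outputs under
the run directory and the manifest records the config, per-stage seeds and
output paths.  The global seed spawns per-stage seeds by hashing the stage
name, so inserting a stage never perturbs the randomness of earlier ones,
and re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .blocks import MultiOmicsDataset
from .downstream import (
    GeneSetCollection,
    component_trait_correlations,
    differential_expression,
    gsoa,
)
from .model_selection import ModelSpec, TuningGrid, stratified_kfold_cv, tune
from .preprocess import PreprocessParams, preprocess_dataset
from .signature import ResamplePlan, finalize_signature, stability_select
from .simulate import SimulationConfig, generate_multiomics
from .splsda import make_design
from .validation import ValidationSpec, evaluate_signature

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2**31)


@dataclass
class RunConfig:
    """Parsed run configuration; see ``from_yaml`` for the schema."""

    raw: dict
    path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(raw, str(path))

    def get(self, key: str, default=None):
        return self.raw.get(key, default)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate_inputs(self) -> None:
        """Every referenced file must exist before any computation starts."""
        missing = []
        inputs = self.raw.get("inputs", {}) or {}
        for p in (inputs.get("blocks", {}) or {}).values():
            if not Path(p).exists():
                missing.append(p)
        for key in ("metadata", "traits", "symbol_map"):
            p = inputs.get(key)
            if p and not Path(p).exists():
                missing.append(p)
        gmt = self.raw.get("gmt")
        if gmt and not Path(gmt).exists():
            missing.append(gmt)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _load_or_simulate(cfg: RunConfig, outdir: Path, seed: int):
    sim = cfg.get("simulate")
    if sim is not None:
        sim = dict(sim)
        sim.setdefault("seed", seed)
        block_specs = [tuple(b) for b in sim.get("block_specs", [])]
        if block_specs:
            sim["block_specs"] = block_specs
        trait_specs = [tuple(t) for t in sim.get("trait_specs", [])]
        if trait_specs:
            sim["trait_specs"] = trait_specs
        sc = SimulationConfig(**sim)
        data, truth = generate_multiomics(sc)
        pio.save_dataset(data, outdir / "data")
        pio.write_symbol_map(truth.symbol_map, outdir / "data" / "symbol_map.tsv")
        truth.to_json(outdir / "data" / "ground_truth.json")
        return data, truth.symbol_map
    inputs = cfg.get("inputs") or {}
    data = pio.load_dataset(
        {k: v for k, v in inputs["blocks"].items()},
        inputs["metadata"],
        inputs.get("traits"),
        positive_label=cfg.get("positive_label"),
    )
    symbol_map = (
        pio.read_symbol_map(inputs["symbol_map"]) if inputs.get("symbol_map") else None
    )
    return data, symbol_map


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order; returns (and persists) the manifest."""
    t0 = time.time()
    cfg.validate_inputs()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "global_seed": seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **info):
        manifest["stages"][stage] = {"seed": stage_seed(seed, stage), **info}
        logger.info("stage %s done (%.1fs elapsed)", stage, time.time() - t0)

    # -- data ------------------------------------------------------------
    data, symbol_map = _load_or_simulate(cfg, outdir, stage_seed(seed, "simulate"))
    if symbol_map is None:
        symbol_map = {str(f): str(f) for b in data.blocks for f in b.feature_ids}
    record("data", n_samples=data.n_samples, blocks={b.name: b.n_features for b in data.blocks})

    # -- preprocess ------------------------------------------------------
    pp_cfg = cfg.get("preprocess", {}) or {}
    params = PreprocessParams(
        max_missing_frac=pp_cfg.get("max_missing_frac", 0.5),
        knn_k=pp_cfg.get("knn_k", 7),
        top_n_variance=pp_cfg.get("top_n_variance"),
    )
    data, report = preprocess_dataset(data, params)
    pio.dump_json(report, outdir / "preprocess_report.json")
    manifest["outputs"]["preprocess_report"] = str(outdir / "preprocess_report.json")
    record("preprocess", **{b: e["n_features_out"] for b, e in report["blocks"].items()})

    # -- design ----------------------------------------------------------
    d_cfg = cfg.get("design", {}) or {}
    design = make_design(
        data.block_names,
        omics_omics_weight=d_cfg.get("omics_omics", 0.1),
        omics_outcome_weight=d_cfg.get("omics_outcome", 1.0),
    )

    # -- tune ------------------------------------------------------------
    t_cfg = cfg.get("tune", {}) or {}
    grid = TuningGrid(
        keepx_candidates=t_cfg.get("keepx_candidates", [5, 10, 20]),
        ncomp_candidates=t_cfg.get("ncomp_candidates", [1, 2]),
        mode="integrative",
    )
    tuned = tune(
        data,
        grid,
        design=design,
        n_folds=t_cfg.get("n_folds", 5),
        n_repeats=t_cfg.get("n_repeats", 5),
        seed=stage_seed(seed, "tune"),
    )
    tuned.surface.to_csv(outdir / "cv_surface.tsv", sep="\t", index=False)
    pio.dump_json(
        {"ncomp": tuned.ncomp, "keep_x": tuned.keep_x, "best_ber": tuned.best_ber},
        outdir / "optimal_params.json",
    )
    manifest["outputs"]["cv_surface"] = str(outdir / "cv_surface.tsv")
    manifest["outputs"]["optimal_params"] = str(outdir / "optimal_params.json")
    record("tune", ncomp=tuned.ncomp, keep_x=tuned.keep_x)

    # -- fit + performance ----------------------------------------------
    spec = ModelSpec(kind="multiblock", ncomp=tuned.ncomp, keep_x=tuned.keep_x, design=design)
    fitted = spec.fit(data)
    fitted.to_json(outdir / "model.json")
    manifest["outputs"]["model"] = str(outdir / "model.json")
    perf = stratified_kfold_cv(
        data,
        spec,
        n_folds=t_cfg.get("n_folds", 5),
        n_repeats=int(cfg.get("performance_repeats", 20)),
        seed=stage_seed(seed, "performance"),
    ).summary()
    pio.dump_json(
        {
            "accuracy_mean": perf.accuracy_mean,
            "accuracy_sd": perf.accuracy_sd,
            "auc_mean": perf.auc_mean,
            "auc_sd": perf.auc_sd,
            "n_repeats": perf.n_repeats,
            "n_folds": perf.n_folds,
        },
        outdir / "model_performance.json",
    )
    manifest["outputs"]["model_performance"] = str(outdir / "model_performance.json")
    record("fit", ncomp=tuned.ncomp, auc_mean=perf.auc_mean)

    # -- stability selection --------------------------------------------
    s_cfg = cfg.get("select", {}) or {}
    plan = ResamplePlan(
        n_copies=s_cfg.get("n_copies", 100),
        coverage_frac=s_cfg.get("coverage_frac", 0.8),
        base_seed=stage_seed(seed, "select"),
    )
    importance = stability_select(data, spec, plan)
    importance.to_tsv(outdir / "feature_importance.tsv")
    sig = finalize_signature(importance, tuned.keep_x, symbol_map, name="MULTI")
    sig.to_tsv(outdir / "signature.tsv")
    sig.write_symbol_list(outdir / "signature_symbols.txt")
    sig1 = sig.restrict_components({1}, name="MULTI 1")
    sig1.to_tsv(outdir / "signature_comp1.tsv")
    manifest["outputs"]["feature_importance"] = str(outdir / "feature_importance.tsv")
    manifest["outputs"]["signature"] = str(outdir / "signature.tsv")
    record("select", n_copies=plan.n_copies, signature_size=len(sig))

    # -- downstream ------------------------------------------------------
    de_block = cfg.get("diffexp_block", "gene")
    de = differential_expression(
        data.block(de_block), data.y, data.positive_label, paired_by=data.patient_id
    )
    de.to_csv(outdir / "differential_expression.tsv", sep="\t")
    manifest["outputs"]["differential_expression"] = str(
        outdir / "differential_expression.tsv"
    )
    if data.traits is not None:
        scores = fitted.average_scores()
        cors = component_trait_correlations(scores, data.traits)
        cors.to_csv(outdir / "component_trait_correlations.tsv", sep="\t", index=False)
        manifest["outputs"]["component_trait_correlations"] = str(
            outdir / "component_trait_correlations.tsv"
        )
    gmt_path = cfg.get("gmt")
    if gmt_path:
        sets = pio.read_gmt(gmt_path)
        universe = set(symbol_map.values())
        enr = gsoa(sig.symbols, GeneSetCollection(sets, universe))
        enr.to_csv(outdir / "gsoa.tsv", sep="\t", index=False)
        manifest["outputs"]["gsoa"] = str(outdir / "gsoa.tsv")
    record("downstream", n_de_features=len(de))

    # -- validation ------------------------------------------------------
    v_cfg = cfg.get("validate", {}) or {}
    cohort_block = v_cfg.get("cohort_block", de_block)
    rows = []
    for clf in v_cfg.get("classifiers", ["logistic"]):
        vs = ValidationSpec(
            cohort=data.block(cohort_block),
            y=data.y,
            signature=sig,
            classifier=clf,
            symbol_map=symbol_map,
            n_folds=v_cfg.get("n_folds", 5),
            n_repeats=v_cfg.get("n_repeats", 20),
            seed=stage_seed(seed, "validate"),
            positive_label=data.positive_label,
        )
        summ = evaluate_signature(vs)
        rows.append(
            {
                "classifier": clf,
                "accuracy_mean": summ.accuracy_mean,
                "accuracy_sd": summ.accuracy_sd,
                "auc_mean": summ.auc_mean,
                "auc_sd": summ.auc_sd,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "validation.tsv", sep="\t", index=False)
    manifest["outputs"]["validation"] = str(outdir / "validation.tsv")
    record("validate", classifiers=v_cfg.get("classifiers", ["logistic"]))

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    pio.dump_json(manifest, outdir / "manifest.json")
    return manifest
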