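"""End-to-end orchestration: simulate -> label -> screen -> network -> train -> evaluate.

One YAML config drives the whole run; section keys use the configuration
vocabulary of the screen and the training stage (SUBSET_SIZE, TARGET_AUC,
LAMBDA_GRAPH, ...) so parameter tables can be transcribed directly. Every run writes a ``manifest.json``
(config snapshot, seeds, content hashes of inputs and outputs, per-stage
timings, package version) sufficient to rerun bit-identically.

Stages can be skipped (``skip: true`` in a section) when their inputs are
supplied as files; a failure is reported with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import kfold_evaluate
from .expression import read_tpm, write_tpm, zscore_genes, read_gene_list
from .io import read_bags, read_labels, write_bags, write_labels
from .labeling import assign_subtypes, labels_to_frame, moffitt_score, ssgsea_scores
from .morphology import MorphologyGeneModel, TrainConfig
from .network import CoexpressionNetwork
from .sampler import GeneModuleScreen, SamplerConfig
from .simulate import SimConfig, simulate_expression, simulate_slides

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "label", "sample", "network", "train", "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _section(config: dict, name: str) -> dict:
    sec = dict(config.get(name, {}) or {})
    sec.pop("skip", None)
    return {k.lower(): v for k, v in sec.items()}


def _build(cls, sec: dict, **overrides):
    names = {f.name for f in dc_fields(cls)}
    unknown = set(sec) - names - set(overrides)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{**{k: v for k, v in sec.items() if k in names}, **overrides})


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None) -> RunManifest:
    """Execute the configured stages in order; returns the run manifest."""
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text()) or {}
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    unknown = set(config) - set(STAGES) - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")
    seed = int(seed if seed is not None else config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "genemorph_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=seed)
    manifest.input_hashes[str(config_path)] = _sha(config_path)

    def skipped(name: str) -> bool:
        return bool((config.get(name) or {}).get("skip", False))

    def run_stage(name: str, fn):
        t0 = time.time()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            raise PipelineError(name, exc) from exc
        manifest.timings[name] = round(time.time() - t0, 3)

    state: dict = {}

    # -- simulate -----------------------------------------------------------
    def do_simulate():
        sec = _section(config, "simulate")
        cfg = _build(SimConfig, sec, seed=seed)
        expr, labels, truth = simulate_expression(cfg)
        state.update(expr=expr, truth_labels=labels, truth=truth, sim_cfg=cfg)
        write_tpm(expr, out / "expr.tsv")
        write_labels(labels, out / "truth_labels.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest.outputs["expr"] = str(out / "expr.tsv")
        manifest.outputs["truth_labels"] = str(out / "truth_labels.tsv")
        manifest.outputs["truth"] = str(out / "truth.json")

    def load_inputs():
        sec = _section(config, "simulate")
        expr_path = Path(sec["expr"])
        state["expr"] = read_tpm(expr_path)
        manifest.input_hashes[str(expr_path)] = _sha(expr_path)
        if "labels" in sec:
            state["truth_labels"] = read_labels(sec["labels"])

    if skipped("simulate"):
        run_stage("simulate", load_inputs)
    else:
        run_stage("simulate", do_simulate)

    # -- label --------------------------------------------------------------
    def do_label():
        sec = _section(config, "label")
        expr = state["expr"]
        if "classical_genes" in sec:
            classical = read_gene_list(sec["classical_genes"])
            basal = read_gene_list(sec["basal_genes"])
        elif "truth" in state:
            # simulated run: planted module is the classical signature; a
            # seeded draw of background genes stands in for the basal one
            classical = state["truth"]["planted_genes"]
            rng = np.random.default_rng(seed + 7)
            bg = [g for g in expr.gene_ids if g.startswith(("BG", "CBG"))]
            basal = list(rng.choice(bg, size=min(len(classical), len(bg)), replace=False))
        else:
            raise ValueError("label stage needs classical_genes/basal_genes files")
        w = float(sec.get("weight_exponent", 0.25))
        zt = float(sec.get("z_threshold", 1.0))
        score = moffitt_score(
            ssgsea_scores(expr, classical, w), ssgsea_scores(expr, basal, w)
        )
        calls = assign_subtypes(score, threshold=zt)
        df = labels_to_frame(calls)
        df["label"] = (df["zscore"] > 0).astype(int)  # Classical = 1
        state["labels"] = df
        write_labels(df, out / "labels.tsv")
        manifest.outputs["labels"] = str(out / "labels.tsv")

    if not skipped("label"):
        run_stage("label", do_label)
    elif "truth_labels" in state:
        state["labels"] = state["truth_labels"]
    else:
        raise PipelineError("label", ValueError("no labels available"))

    # -- sample (gene screen) ----------------------------------------------
    def do_sample():
        sec = _section(config, "sample")
        n_folds = int(sec.pop("n_folds", 5))
        refine_draws = sec.pop("refine_draws", None)
        cfg = _build(SamplerConfig, sec, seed=seed)
        df = state["labels"]
        hc = df[df["high_confidence"]]
        labels = dict(zip(hc.iloc[:, 0].astype(str), hc["label"].astype(int)))
        screen = GeneModuleScreen(state["expr"], labels, cfg)
        res = screen.fit(
            n_folds=n_folds,
            refine_draws=None if refine_draws is None else int(refine_draws),
        )
        state["screen"] = res
        module = res.refined_module
        (out / "module.json").write_text(json.dumps({
            "gene_ids": module.gene_ids,
            "auc": module.auc,
            "sensitivity": module.sensitivity,
            "specificity": module.specificity,
            "threshold": module.threshold,
            "orientation": module.orientation,
            "stage": module.stage,
            "seed": cfg.seed,
            "module_hash": module.module_hash,
        }, indent=1))
        res.trace.to_frame().to_csv(out / "trace.tsv", sep="\t", index=False)
        manifest.outputs["module"] = str(out / "module.json")
        manifest.outputs["trace"] = str(out / "trace.tsv")

    if not skipped("sample"):
        run_stage("sample", do_sample)

    # -- network ------------------------------------------------------------
    def do_network():
        sec = _section(config, "network")
        genes = state["screen"].refined_module.gene_ids
        z = state["screen"].zscored
        net = CoexpressionNetwork.from_expression(
            z, genes,
            min_non_na=int(sec.get("min_non_na", 2)),
            abs_min=float(sec.get("abs_min", 0.0)),
            topk_edges=int(sec.get("topk_edges", 0)),
        )
        state["network"] = net
        net.to_json(out / "network.json")
        net.edge_list().to_csv(out / "edges.tsv", sep="\t", index=False)
        manifest.outputs["network"] = str(out / "network.json")

    if not skipped("network"):
        run_stage("network", do_network)

    # -- train (morphology) --------------------------------------------------
    def do_train():
        sec = _section(config, "train")
        cfg = _build(TrainConfig, sec, seed=seed)
        net = state["network"]
        sim = state.get("sim_cfg") or _build(SimConfig, _section(config, "simulate"), seed=seed)
        labels = state["labels"]
        bags = simulate_slides(labels.rename(columns={labels.columns[0]: "sample_id"}),
                               net, sim)
        state["bags"] = bags
        write_bags(bags, out / "bags.h5")
        hc = labels[labels["high_confidence"]]
        ymap = dict(zip(hc.iloc[:, 0].astype(str), hc["label"].astype(int)))
        hc_bags = [b for b in bags if b.slide_id in ymap]
        model = MorphologyGeneModel(hc_bags, net, cfg, labels=ymap)
        res = model.fit()
        state["morph"] = res
        res.params.to_npz(out / "model.npz")
        res.history.to_csv(out / "history.tsv", sep="\t", index=False)
        manifest.outputs["model"] = str(out / "model.npz")
        manifest.outputs["history"] = str(out / "history.tsv")

    if not skipped("train"):
        run_stage("train", do_train)

    # -- evaluate -------------------------------------------------------------
    def do_evaluate():
        sec = _section(config, "evaluate")
        k = int(sec.get("k", 5))
        cfg = _build(TrainConfig, _section(config, "train"), seed=seed)
        labels = state["labels"].rename(columns={state["labels"].columns[0]: "slide_id"})
        folds = kfold_evaluate(state["bags"], labels, state["network"], cfg, k=k)
        folds.to_csv(out / "folds.tsv", sep="\t", index=False)
        state["folds"] = folds
        manifest.outputs["folds"] = str(out / "folds.tsv")

    if not skipped("evaluate"):
        run_stage("evaluate", do_evaluate)

    for key, p in manifest.outputs.items():
        manifest.input_hashes[p] = _sha(Path(p))
    manifest.to_json(out / "manifest.json")
    return manifest
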