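"""End-to-end run orchestration: prepare -> pseudo -> train -> deconvolve -> evaluate.

A run is described by a single validated configuration (YAML on disk,
pydantic in memory, unknown keys rejected).  Every run writes a fixed set
of artifacts into the output directory — pseudo.h5ad, model.ckpt,
trace.csv, proportions.csv, report.json, run.log — and a manifest stamping
each with the configuration content hash, so any output can be traced back
to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import data_io
from .data_io import CellTypeLabels, ExpressionMatrix
from .metrics import ProportionMatrix, evaluate
from .networks import ModelConfig, SpaDAMAModel
from .pseudo_spots import PseudoSpotBatch, PseudoSpotParams, generate_pseudo_spots
from .synthetic_fixtures import FixtureSpec, holdout_split, make_ground_truth_st, make_reference
from .training import TrainingConfig, infer, train


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class FixtureSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    K: int = 5
    G: int = 200
    markers_per_type: int = 20
    cells_per_type: int = 200
    n_spots: int = 500
    signal: float = 8.0
    noise: float = 0.25
    alpha: float = 1.0
    spatial_pattern: str = "random"


class PseudoSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_spots: int = 10000
    mu_t: float = 10.0
    sigma_t: float = 5.0
    mu_c: float = 4.0
    sigma_c: float = 2.0
    t_min: int = 2
    t_max: int = 30


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = 200
    batch_size: int = 2048
    learning_rate: float = 0.01
    rho: float = Field(default=0.3, ge=0.0, le=1.0)
    lambda_: float = Field(default=0.5, ge=0.0, le=1.0)
    latent_split: float = 0.5
    grad_clip: float | None = 5.0
    latent_dim: int = 128
    enc_hidden: int = 512
    dec_hidden: tuple[int, int] = (256, 512)
    clf_hidden: int = 64
    pred_hidden: int = 64
    leaky_slope: float = 0.01


class RunConfig(BaseModel):
    """Full run description; unknown keys are rejected at load time."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "spadama_run"
    seed: int = 0
    # file inputs (ignored when a fixture section is present)
    ref_path: str | None = None
    st_path: str | None = None
    labels_path: str | None = None
    label_key: str = "cell_type"
    truth_path: str | None = None
    n_top_markers: int = 200
    target_sum: float = 1e4
    fixture: FixtureSection | None = None
    pseudo: PseudoSection = PseudoSection()
    training: TrainingSection = TrainingSection()

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def _logger(out: Path) -> logging.Logger:
    log = logging.getLogger(f"spadama.{out}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.FileHandler(out / "run.log"), logging.StreamHandler(sys.stderr)):
        handler.setFormatter(fmt)
        log.addHandler(handler)
    return log


def write_pseudo_h5ad(batch: PseudoSpotBatch, path: Path, config_hash: str = "") -> None:
    adata = ad.AnnData(
        X=batch.X_S.values,
        obs=pd.DataFrame(index=pd.Index(batch.X_S.obs_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(batch.X_S.gene_ids, name="gene_id")),
    )
    adata.obsm["proportions"] = batch.Y_r
    adata.uns["type_names"] = list(batch.type_names)
    if config_hash:
        adata.uns["config_hash"] = config_hash
    adata.write_h5ad(path)


def write_proportions_csv(pm: ProportionMatrix, path: Path) -> None:
    df = pd.DataFrame(pm.values, index=pd.Index(pm.spot_ids, name="spot_id"),
                      columns=pm.type_names)
    df.to_csv(path, float_format="%.6f")


def read_proportions_csv(path: str | Path) -> ProportionMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(float)
    # re-project onto the simplex: 6-decimal rounding may offset row sums
    vals = vals / vals.sum(axis=1, keepdims=True)
    return ProportionMatrix(vals, list(df.columns), [str(i) for i in df.index])


def _training_config(cfg: RunConfig) -> TrainingConfig:
    t = cfg.training
    return TrainingConfig(
        epochs=t.epochs, batch_size=t.batch_size, learning_rate=t.learning_rate,
        rho=t.rho, lambda_=t.lambda_, seed=cfg.seed, latent_split=t.latent_split,
        grad_clip=t.grad_clip,
        model=ModelConfig(
            latent_dim=t.latent_dim, enc_hidden=t.enc_hidden, dec_hidden=t.dec_hidden,
            clf_hidden=t.clf_hidden, pred_hidden=t.pred_hidden,
            leaky_slope=t.leaky_slope, latent_split=t.latent_split, seed=cfg.seed,
        ),
    )


def pseudo_params(cfg: RunConfig) -> PseudoSpotParams:
    p = cfg.pseudo
    return PseudoSpotParams(
        n_spots=p.n_spots, mu_t=p.mu_t, sigma_t=p.sigma_t, mu_c=p.mu_c,
        sigma_c=p.sigma_c, t_bounds=(p.t_min, p.t_max), seed=cfg.seed,
        target_sum=cfg.target_sum,
    )


def load_inputs(
    cfg: RunConfig,
) -> tuple[ExpressionMatrix, CellTypeLabels, ExpressionMatrix, ProportionMatrix | None]:
    """Return (reference, labels, raw ST, optional truth).

    In fixture mode the reference handed to training is the half of the
    simulated cells disjoint from those used to build the ground-truth
    spots.
    """
    if cfg.fixture is not None:
        spec = FixtureSpec(seed=cfg.seed, **cfg.fixture.model_dump())
        ref_full, labels_full = make_reference(spec)
        train_idx, _ = holdout_split(spec, labels_full)
        st, truth = make_ground_truth_st(spec, ref_full, labels_full)
        ref = ExpressionMatrix(
            ref_full.values[train_idx],
            [ref_full.obs_ids[i] for i in train_idx],
            list(ref_full.gene_ids), "cells",
        )
        labels = CellTypeLabels(
            [labels_full.labels[i] for i in train_idx], list(labels_full.type_names)
        )
        return ref, labels, st, truth
    if cfg.ref_path is None or cfg.st_path is None:
        raise ValueError("config must provide either a fixture section or ref/st paths")
    ref = data_io.read_expression(cfg.ref_path, obs_kind="cells")
    if cfg.labels_path is not None:
        labels = data_io.read_labels(cfg.labels_path, cfg.label_key)
    else:
        adata = ad.read_h5ad(cfg.ref_path)
        values = adata.obs[cfg.label_key].astype(str).tolist()
        labels = CellTypeLabels(values, sorted(set(values)))
    st = data_io.read_expression(cfg.st_path, obs_kind="spots")
    truth = read_proportions_csv(cfg.truth_path) if cfg.truth_path else None
    return ref, labels, st, truth


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _logger(out)
    chash = cfg.content_hash()
    log.info("config hash %s", chash)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.model_dump()))
    artifacts: dict[str, str] = {}

    def stage(name: str):
        log.info("stage %s", name)

    try:
        stage("load")
        ref, labels, st_raw, truth = load_inputs(cfg)
        if truth is not None:
            write_proportions_csv(truth, out / "truth.csv")
            artifacts["truth.csv"] = chash
    except Exception as e:
        raise PipelineError("load", e) from e

    try:
        stage("prepare")
        markers = data_io.select_marker_genes(ref, labels, n_top=cfg.n_top_markers)
        st_sub, ref_sub = data_io.intersect_and_subset(st_raw, ref, markers)
        st_norm = data_io.normalize(st_sub, target_sum=cfg.target_sum)
        log.info("shared gene panel: %d genes", st_sub.n_genes)
    except Exception as e:
        raise PipelineError("prepare", e) from e

    try:
        stage("pseudo")
        batch = generate_pseudo_spots(ref_sub, labels, pseudo_params(cfg))
        write_pseudo_h5ad(batch, out / "pseudo.h5ad", chash)
        artifacts["pseudo.h5ad"] = chash
    except Exception as e:
        raise PipelineError("pseudo", e) from e

    try:
        stage("train")
        model, trace = train(st_norm, batch, _training_config(cfg))
        model.save(out / "model.ckpt")
        artifacts["model.ckpt"] = chash
        df = trace.to_dataframe()
        df.to_csv(out / "trace.csv", index=False)
        artifacts["trace.csv"] = chash
        if len(df):
            log.info("final losses: %s", df.iloc[-1].to_dict())
    except Exception as e:
        raise PipelineError("train", e) from e

    try:
        stage("deconvolve")
        pred = infer(st_norm, model)
        write_proportions_csv(pred, out / "proportions.csv")
        artifacts["proportions.csv"] = chash
    except Exception as e:
        raise PipelineError("deconvolve", e) from e

    try:
        stage("evaluate")
        report: dict = {"config_hash": chash, "n_spots": st_norm.n_obs,
                        "n_genes": st_norm.n_genes, "cell_types": list(labels.type_names)}
        if truth is not None:
            rep = evaluate(truth, pred)
            report["metrics"] = rep.to_dict()
            log.info("mean metrics: %s", rep.means)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        artifacts["report.json"] = chash
    except Exception as e:
        raise PipelineError("evaluate", e) from e

    (out / "manifest.json").write_text(
        json.dumps({"config_hash": chash, "artifacts": sorted(artifacts)}, indent=2)
    )
    log.info("done: %s", out)
    return out
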