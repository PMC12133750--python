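"""Run configuration schema and the end-to-end pipeline.

A :class:`RunConfig` validates strictly (unknown keys rejected) and
round-trips losslessly through YAML/JSON.  ``run_pipeline`` executes
simulate -> preprocess -> connectivity -> train -> evaluate -> explain,
checkpointing each stage into the run directory and writing a manifest
with the config hash and the per-stage seeds (one global seed fans out
by fixed offsets, so every stage is independently reproducible).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .bands import default_bands
from .connectivity import (
    adjacency_from_distance,
    adjacency_from_plv,
    adjacency_hybrid,
    mean_plv_matrix,
    plv_matrix,
)
from .model import ModelConfig, save_checkpoint
from .preprocess import EpochSet, FilterSpec, preprocess_recording, save_epochs_h5
from .synth import SynthSpec, default_erd_map, generate_recording, save_recording_h5
from .train_eval import TrainSpec, evaluate, stratified_split, train
from .interpret import attribute, band_attribution, joint_report

__all__ = ["RunConfig", "run_pipeline", "load_config", "config_hash"]

_STAGE_SEED_OFFSETS = {"simulate": 0, "ica": 101, "split": 202, "train": 303, "explain": 404}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Strict):
    n_trials_per_class: int = 10
    fs: float = 1000.0
    trial_len: float = 4.0
    snr: float = 1.0
    noise_exponent: float = 1.0
    erd_factor: float = 0.5
    coupling_strength: float = 0.8


class PreprocessSection(_Strict):
    order: int = 4
    low: float = 0.5
    high: float = 100.0
    fs_out: float = 128.0
    ica: bool = False
    corr_threshold: float = 0.8
    kurtosis_threshold: float = 8.0
    t_start: float = -0.5
    t_end: float = 1.5


class AdjacencySection(_Strict):
    builder: str = "hybrid"  # distance | plv | hybrid
    d: float = 0.35
    percentile: float = 75.0
    weighted: bool = True
    band: str = "Beta"  # for the plv builder; "mean" averages all bands


class ModelSection(_Strict):
    gat_heads: int = 4
    gat_low_layers: int = 2
    d_low: int = 16
    d_spatial: int = 32
    gru_hidden: int = 128
    transformer_layers: int = 2
    attn_heads: int = 4
    d_time: int = 64
    ff_width: int = 256
    temporal_pool: int = 1
    conv_channels: int = 8
    dropout: float = 0.3


class TrainSection(_Strict):
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    train_frac: float = 0.8
    patience: int | None = None


class InterpretSection(_Strict):
    method: str = "sampling-shapley"
    n_permutations: int = 50
    n_trials: int = 20
    k_top: int = 5


class RunConfig(_Strict):
    seed: int = 0
    synth: SynthSection = SynthSection()
    preprocess: PreprocessSection = PreprocessSection()
    adjacency: AdjacencySection = AdjacencySection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    interpret: InterpretSection = InterpretSection()


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _build_synth_spec(cfg: RunConfig) -> SynthSpec:
    return SynthSpec(
        n_trials_per_class=cfg.synth.n_trials_per_class,
        fs=cfg.synth.fs,
        trial_len=cfg.synth.trial_len,
        erd_channels=default_erd_map(cfg.synth.erd_factor),
        coupling_pairs=(("C3", "C4", "Beta", cfg.synth.coupling_strength),),
        noise_exponent=cfg.synth.noise_exponent,
        snr=cfg.synth.snr,
        seed=cfg.seed + _STAGE_SEED_OFFSETS["simulate"],
    )


def _build_adjacency(cfg: RunConfig, train_set: EpochSet):
    if cfg.adjacency.builder == "distance":
        return adjacency_from_distance(train_set.montage, cfg.adjacency.d)
    if cfg.adjacency.band.lower() == "mean":
        plvm = mean_plv_matrix(train_set)
    else:
        band = next(
            b for b in default_bands(train_set.fs) if b.name.lower() == cfg.adjacency.band.lower()
        )
        plvm = plv_matrix(train_set, band)
    if cfg.adjacency.builder == "plv":
        return adjacency_from_plv(plvm, cfg.adjacency.percentile, cfg.adjacency.weighted)
    if cfg.adjacency.builder == "hybrid":
        return adjacency_hybrid(train_set.montage, plvm, cfg.adjacency.d)
    raise ValueError(f"unknown adjacency builder {cfg.adjacency.builder!r}")


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns paths of the written artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest = {
        "config_hash": chash,
        "config": cfg.model_dump(),
        "seeds": {k: cfg.seed + v for k, v in _STAGE_SEED_OFFSETS.items()},
        "stages": [],
    }
    artifacts: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"].append({"name": name, "status": "ok"})
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        spec = _build_synth_spec(cfg)
        state["rec"] = generate_recording(spec)
        save_recording_h5(state["rec"], out / "recording.h5")
        artifacts["recording"] = str(out / "recording.h5")

    @stage("preprocess")
    def _preprocess():
        p = cfg.preprocess
        ep = preprocess_recording(
            state["rec"],
            filter_spec=FilterSpec(order=p.order, low=p.low, high=p.high),
            fs_out=p.fs_out,
            ica=p.ica,
            corr_threshold=p.corr_threshold,
            kurtosis_threshold=p.kurtosis_threshold,
            t_start=p.t_start,
            t_end=p.t_end,
            ica_seed=cfg.seed + _STAGE_SEED_OFFSETS["ica"],
        )
        state["epochs"] = ep
        save_epochs_h5(ep, out / "epochs.h5")
        artifacts["epochs"] = str(out / "epochs.h5")

    @stage("split")
    def _split():
        ep = state["epochs"]
        tr, te = stratified_split(
            np.asarray(ep.labels), cfg.train.train_frac, cfg.seed + _STAGE_SEED_OFFSETS["split"]
        )
        mk = lambda idx: EpochSet(
            data=ep.data[idx], labels=np.asarray(ep.labels)[idx],
            fs=ep.fs, window=ep.window, montage=ep.montage,
        )
        state["train_set"], state["test_set"] = mk(tr), mk(te)

    @stage("connectivity")
    def _connectivity():
        train_set = state["train_set"]
        state["adjacency"] = _build_adjacency(cfg, train_set)
        state["plvs"] = [plv_matrix(train_set, b) for b in default_bands(train_set.fs)]
        for plvm in state["plvs"]:
            plvm.to_frame().to_csv(out / f"plv_{plvm.band.name.lower()}.csv")
        artifacts["plv"] = str(out)

    @stage("train")
    def _train():
        m = cfg.model
        ep = state["train_set"]
        model_cfg = ModelConfig(
            n_channels=ep.n_channels,
            n_time=ep.n_times,
            n_classes=len(np.unique(ep.labels)),
            gat_heads=m.gat_heads,
            gat_low_layers=m.gat_low_layers,
            d_low=m.d_low,
            d_spatial=m.d_spatial,
            gru_hidden=m.gru_hidden,
            transformer_layers=m.transformer_layers,
            attn_heads=m.attn_heads,
            d_time=m.d_time,
            ff_width=m.ff_width,
            temporal_pool=m.temporal_pool,
            conv_channels=m.conv_channels,
            dropout=m.dropout,
            bands=tuple((b.name, b.low, b.high) for b in default_bands(ep.fs)),
            seed=cfg.seed + _STAGE_SEED_OFFSETS["train"],
        )
        spec = TrainSpec(
            epochs=cfg.train.epochs,
            batch_size=cfg.train.batch_size,
            learning_rate=cfg.train.learning_rate,
            train_frac=cfg.train.train_frac,
            seed=cfg.seed + _STAGE_SEED_OFFSETS["train"],
            patience=cfg.train.patience,
        )
        model, history = train(
            model_cfg, ep, spec, adjacency=state["adjacency"], validation=state["test_set"]
        )
        state["model"] = model
        save_checkpoint(model, out / "model.npz", out / "model.json")
        import pandas as pd

        pd.DataFrame(history).to_csv(out / "history.csv", index=False)
        artifacts["model"] = str(out / "model.npz")

    @stage("evaluate")
    def _evaluate():
        report = evaluate(state["model"], state["test_set"])
        payload = dict(report.to_dict(), config_hash=chash)
        (out / "prediction_report.json").write_text(json.dumps(payload, indent=2))
        artifacts["prediction_report"] = str(out / "prediction_report.json")

    @stage("explain")
    def _explain():
        i = cfg.interpret
        test_set = state["test_set"]
        n = min(i.n_trials, test_set.n_trials)
        sub = EpochSet(
            data=test_set.data[:n], labels=np.asarray(test_set.labels)[:n],
            fs=test_set.fs, window=test_set.window, montage=test_set.montage,
        )
        attr = attribute(
            state["model"], sub, state["train_set"], method=i.method,
            n_permutations=i.n_permutations, seed=cfg.seed + _STAGE_SEED_OFFSETS["explain"],
        )
        bands = default_bands(test_set.fs)
        attr.band_summary = band_attribution(state["model"], sub, bands, state["train_set"])
        jr = joint_report(attr, state["plvs"], k_top=i.k_top)
        payload = {
            "config_hash": chash,
            "channel_summary": dict(zip(attr.channel_names, attr.channel_summary.tolist())),
            "band_summary": attr.band_summary,
            "top_channels": jr.top_channels,
            "top_bands": jr.top_bands,
            "concordance": jr.concordance,
        }
        (out / "joint_report.json").write_text(json.dumps(payload, indent=2))
        (out / "joint_report.txt").write_text(jr.summary() + "\n")
        artifacts["joint_report"] = str(out / "joint_report.json")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return artifacts
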