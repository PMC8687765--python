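"""End-to-end pipeline plumbing: config, dataset building, experiment grids.

A :class:`PipelineConfig` captures everything needed to reproduce a run
(generator, denoiser, segmentation, split, training and tree-regularization
settings).  :func:`run_experiment_grid` sweeps segment length and
regularizer choices and returns one result row per grid cell; every run
writes a manifest (config hash, seed, package version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, bilstm_core, evaluation, preprocessing, synthetic_ecg
from . import heartbeat_dataset as hbd
from . import tree_regularization as treg
from .bilstm_core import TrainConfig
from .tree_regularization import TregSchedule

__all__ = [
    "PipelineConfig",
    "build_dataset",
    "train_model",
    "evaluate_model",
    "run_experiment_grid",
    "write_manifest",
]

DEFAULT_T_GRID = (1, 5, 10, 15, 20, 25, 30)
DEFAULT_REG_GRID = ("none", "L1", "L2", "tree")


@dataclasses.dataclass
class PipelineConfig:
    fs: float = 360.0
    n_beats: int = 3000
    noise: synthetic_ecg.NoiseSpec = dataclasses.field(
        default_factory=synthetic_ecg.NoiseSpec)
    denoise: bool = True
    wavelet: preprocessing.WaveletConfig = dataclasses.field(
        default_factory=preprocessing.WaveletConfig)
    timestep: int = 15
    t_grid: Sequence[int] = DEFAULT_T_GRID
    reg_grid: Sequence[str] = DEFAULT_REG_GRID
    split: hbd.SplitConfig = dataclasses.field(default_factory=hbd.SplitConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    schedule: TregSchedule = dataclasses.field(default_factory=TregSchedule)
    seed: int = 0

    def __post_init__(self):
        if not self.t_grid or not self.reg_grid:
            raise ValueError("experiment grids must be non-empty")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "noise" in kw and isinstance(kw["noise"], dict):
            kw["noise"] = synthetic_ecg.NoiseSpec(**kw["noise"])
        if "wavelet" in kw and isinstance(kw["wavelet"], dict):
            kw["wavelet"] = preprocessing.WaveletConfig(**kw["wavelet"])
        if "split" in kw and isinstance(kw["split"], dict):
            kw["split"] = hbd.SplitConfig(**kw["split"])
        if "train" in kw and isinstance(kw["train"], dict):
            kw["train"] = TrainConfig(**kw["train"])
        if "schedule" in kw and isinstance(kw["schedule"], dict):
            sch = dict(kw["schedule"])
            if "tree_constraints" in sch and isinstance(sch["tree_constraints"], dict):
                sch["tree_constraints"] = treg.TreeConstraints(**sch["tree_constraints"])
            kw["schedule"] = TregSchedule(**sch)
        return cls(**kw)


def config_hash(cfg: PipelineConfig) -> str:
    text = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_manifest(out_dir, cfg: PipelineConfig, extra: Optional[dict] = None):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "rhythmbeat",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def build_dataset(cfg: PipelineConfig) -> list[hbd.Beat]:
    """Generate the benchmark records, optionally denoise, cut into beats."""
    records = synthetic_ecg.make_benchmark(cfg.n_beats, fs=cfg.fs,
                                           seed=cfg.seed, noise=cfg.noise)
    beats: list[hbd.Beat] = []
    for rec in records:
        sig = preprocessing.denoise(rec.signal, cfg.wavelet) if cfg.denoise else None
        beats.extend(hbd.build_beats(rec, signal=sig))
    return beats


def train_model(train_segments, cfg: PipelineConfig, regularizer: str,
                timestep: int):
    tcfg = dataclasses.replace(cfg.train, regularizer=regularizer,
                               timestep=timestep, seed=cfg.seed,
                               lam=(cfg.schedule.lam if regularizer == "tree"
                                    else cfg.train.lam))
    if regularizer == "tree":
        params, tree, history = treg.train_bilstm_treg(train_segments, tcfg,
                                                       cfg.schedule)
        return params, tree, history
    params, history = bilstm_core.train_bilstm(train_segments, tcfg)
    return params, None, history


def evaluate_model(segments, params) -> dict:
    y_true, y_pred, _ = bilstm_core.predict_beats(segments, params)
    cm = evaluation.confusion_matrix(y_true, y_pred)
    result = evaluation.metrics(cm)
    result["confusion"] = cm
    return result


def run_experiment_grid(cfg: PipelineConfig,
                        t_grid: Optional[Sequence[int]] = None,
                        reg_grid: Optional[Sequence[str]] = None,
                        out_dir=None) -> pd.DataFrame:
    """One result row per (timestep, regularizer) cell; seed-deterministic."""
    t_grid = tuple(t_grid if t_grid is not None else cfg.t_grid)
    reg_grid = tuple(reg_grid if reg_grid is not None else cfg.reg_grid)
    beats = build_dataset(cfg)
    rows = []
    for t in t_grid:
        segments = hbd.assemble_segments(beats, t)
        split_cfg = dataclasses.replace(cfg.split, seed=cfg.seed)
        train_seg, test_seg = hbd.split_dataset(segments, split_cfg)
        for reg in reg_grid:
            params, _, _ = train_model(train_seg, cfg, reg, t)
            result = evaluate_model(test_seg, params)
            row = {"timestep": t, "regularizer": reg,
                   "overall_accuracy": result["overall_accuracy"]}
            for name in evaluation.CLASS_NAMES:
                m = result[name]
                row[f"Se_{name}"] = m.se
                row[f"PPV_{name}"] = m.ppv
            rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "grid_results.csv", index=False)
        write_manifest(out_dir, cfg, {"t_grid": list(t_grid),
                                      "reg_grid": list(reg_grid)})
    return table
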