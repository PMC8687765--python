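"""Dataset and model checkpoint serialization (NumPy archives + JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .aami import AAMIClass
from .bilstm_core import BiLSTMParams, TrainConfig, init_bilstm_params
from .heartbeat_dataset import Beat

__all__ = ["save_beats", "load_beats", "save_model", "load_model"]


def save_beats(beats: list[Beat], path, fs: float = 360.0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        X=np.stack([b.samples for b in beats]),
        labels=np.array([int(b.label) for b in beats]),
        records=np.array([b.source_record for b in beats]),
        positions=np.array([b.position_in_record for b in beats]),
        r_index=np.array([b.r_index_in_window for b in beats]),
        fs=np.array([fs]),
    )


def load_beats(path) -> tuple[list[Beat], float]:
    with np.load(path, allow_pickle=False) as z:
        beats = [Beat(samples=x, label=AAMIClass(int(lab)),
                      r_index_in_window=int(ri), source_record=str(rec),
                      position_in_record=int(pos))
                 for x, lab, rec, pos, ri in zip(z["X"], z["labels"],
                                                 z["records"], z["positions"],
                                                 z["r_index"])]
        return beats, float(z["fs"][0])


def save_model(params: BiLSTMParams, cfg: TrainConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(dataclasses.asdict(cfg),
                input_dim=params.forward_cell.input_size,
                n_classes=params.n_classes,
                combined=(params.head_W.shape[1]
                          if params.combine_mode == "weighted_sum" else None))
    np.savez_compressed(path, weights=params.flatten(),
                        meta=np.array([json.dumps(meta)]))


def load_model(path) -> tuple[BiLSTMParams, TrainConfig]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"][0]))
        weights = z["weights"]
    input_dim = meta.pop("input_dim")
    meta.pop("n_classes", None)
    combined = meta.pop("combined", None)
    cfg = TrainConfig(**meta)
    params = init_bilstm_params(input_dim, cfg.hidden_size,
                                combined_size=combined,
                                combine_mode=cfg.combine_mode)
    params.set_flat(weights)
    return params, cfg
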