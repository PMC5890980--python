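"""Model checkpoint archive: all weight arrays + hyperparameters + vocabulary hash."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .model import ContentParams, GruWeights
from .recognition import RecognitionParams
from .training import FitResult, TrainConfig, named_arrays

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(fit_result: FitResult, path: str | Path) -> None:
    arrays = named_arrays(fit_result.params, fit_result.rec_params)
    meta = {
        "config": asdict(fit_result.config),
        "vocab_hash": fit_result.vocab_hash,
        "best_epoch": fit_result.best_epoch,
        "history": fit_result.history,
        "has_recognition": fit_result.rec_params is not None,
        "n_codes": fit_result.params.n_codes,
    }
    np.savez(
        path,
        __meta__=np.array(json.dumps(meta)),
        **{k: np.asarray(v) for k, v in arrays.items()},
    )


def load_checkpoint(path: str | Path) -> FitResult:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        a = {k: data[k] for k in data.files if k != "__meta__"}
    config = TrainConfig(**meta["config"])
    gru = GruWeights(
        U_z=a["U_z"], U_r=a["U_r"], U_h=a["U_h"],
        W_z=a["W_z"], W_r=a["W_r"], W_h=a["W_h"],
        b_z=a["b_z"], b_r=a["b_r"], b_h=a["b_h"],
    )
    params = ContentParams(W_v=a["W_v"], gru=gru, Q=a["Q"], q0=a["q0"], B=a["B"])
    rec_params = None
    if meta["has_recognition"]:
        rec_params = RecognitionParams(
            W_r1=a["W_r1"], b_r1=a["b_r1"], W_r2=a["W_r2"], b_r2=a["b_r2"],
            W_mu=a["W_mu"], b_mu=a["b_mu"], W_sigma=a["W_sigma"], b_sigma=a["b_sigma"],
        )
    return FitResult(
        params=params,
        rec_params=rec_params,
        config=config,
        history=meta["history"],
        best_epoch=meta["best_epoch"],
        vocab_hash=meta["vocab_hash"],
    )
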