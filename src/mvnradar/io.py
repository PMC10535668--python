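"""HDF5 persistence for recordings, window datasets, and model checkpoints."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import MVNConfig, RadarConfig, SceneSpec, VitalSignProfile
from .evaluation import WindowDataset
from .mvn.model import MaskedAutoencoder, MVNModel, build_mvn
from .radar_sim import GroundTruth, IFRecording

__all__ = [
    "save_recording", "load_recording", "save_windows", "load_windows",
    "save_mae", "load_mae", "save_mvn", "load_mvn",
]


def save_recording(path: str | Path, rec: IFRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("if_data", data=rec.data.astype(np.complex64))
        truth = f.create_group("truth")
        truth.create_dataset("displacement", data=rec.truth.displacement)
        truth.create_dataset("heart_freq", data=rec.truth.heart_freq)
        f.attrs["config"] = json.dumps(rec.config.to_dict())
        if rec.scene is not None:
            f.attrs["scene"] = json.dumps(rec.scene.to_dict())
        if rec.profile is not None:
            f.attrs["profile"] = json.dumps(rec.profile.to_dict())
        if rec.seed is not None:
            f.attrs["seed"] = rec.seed
        f.attrs["recording_id"] = rec.recording_id


def load_recording(path: str | Path) -> IFRecording:
    with h5py.File(path, "r") as f:
        config = RadarConfig(**json.loads(f.attrs["config"]))
        truth = GroundTruth(
            displacement=f["truth/displacement"][:],
            heart_freq=f["truth/heart_freq"][:],
            frame_rate=config.frame_rate,
        )
        scene = profile = None
        if "scene" in f.attrs:
            d = json.loads(f.attrs["scene"])
            d["static_clutter"] = tuple(tuple(c) for c in d["static_clutter"])
            d["dc_offset"] = complex(*d["dc_offset"])
            scene = SceneSpec(**d)
        if "profile" in f.attrs:
            d = json.loads(f.attrs["profile"])
            d["respiration_harmonics"] = tuple(tuple(h) for h in d["respiration_harmonics"])
            d["heart_band"] = tuple(d["heart_band"])
            profile = VitalSignProfile(**d)
        return IFRecording(
            data=f["if_data"][:].astype(np.complex128),
            config=config,
            truth=truth,
            scene=scene,
            profile=profile,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            recording_id=str(f.attrs.get("recording_id", "")),
        )


def save_windows(path: str | Path, dataset: WindowDataset) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("windows")
        g.create_dataset("phase", data=dataset.X.astype(np.float32))
        g.create_dataset("label_bpm", data=dataset.y)
        g.create_dataset("meta", data=np.array(dataset.rec_ids, dtype="S64"))
        f.attrs["frame_rate"] = dataset.frame_rate


def load_windows(path: str | Path) -> WindowDataset:
    with h5py.File(path, "r") as f:
        return WindowDataset(
            X=f["windows/phase"][:].astype(np.float64),
            y=f["windows/label_bpm"][:],
            rec_ids=f["windows/meta"][:].astype(str),
            frame_rate=float(f.attrs["frame_rate"]),
        )


def _save_params(f: h5py.File, module, prefix: str) -> None:
    for i, p in enumerate(module.parameters()):
        f.create_dataset(f"{prefix}/p{i:04d}", data=p.data)


def _load_params(f: h5py.File, module, prefix: str) -> None:
    params = module.parameters()
    for i, p in enumerate(params):
        p.data[...] = f[f"{prefix}/p{i:04d}"][:]


def save_mae(path: str | Path, mae: MaskedAutoencoder) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = mae.cfg.to_json()
        f.attrs["n_tokens"] = mae.n_tokens
        _save_params(f, mae, "mae")


def load_mae(path: str | Path) -> MaskedAutoencoder:
    with h5py.File(path, "r") as f:
        cfg = MVNConfig.from_dict(json.loads(f.attrs["config"]))
        mae = MaskedAutoencoder(cfg, int(f.attrs["n_tokens"]), np.random.default_rng(0))
        _load_params(f, mae, "mae")
        return mae


def save_mvn(path: str | Path, model: MVNModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = model.cfg.to_json()
        f.attrs["n_tokens"] = model.n_tokens
        f.attrs["head"] = model.head_kind
        f.attrs["encoder_frozen"] = model.encoder_frozen
        _save_params(f, model, "mvn")


def load_mvn(path: str | Path) -> MVNModel:
    from .mvn.model import MAEEncoder

    with h5py.File(path, "r") as f:
        cfg = MVNConfig.from_dict(json.loads(f.attrs["config"]))
        n_tokens = int(f.attrs["n_tokens"])
        encoder = MAEEncoder(cfg, n_tokens, np.random.default_rng(0))
        model = build_mvn(encoder, cfg, n_tokens, head=str(f.attrs["head"]),
                          encoder_frozen=bool(f.attrs["encoder_frozen"]))
        _load_params(f, model, "mvn")
        return model
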