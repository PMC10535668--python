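"""Configuration dataclasses shared across the pipeline.

All physical quantities are SI unless the name says otherwise (BPM, dB).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

C_LIGHT = 299_792_458.0  # m/s


@dataclass(frozen=True)
class RadarConfig:
    """FMCW chirp/frame parameters.

    Defaults follow a 77 GHz automotive-style vital-sign setup: 3.99 GHz
    sweep bandwidth, 256 ADC samples per chirp, 50 Hz frame rate, 60 s
    recordings.  One chirp is synthesized per frame (the downstream method
    consumes one phase sample per frame).
    """

    start_frequency: float = 77e9  # f_c, Hz
    bandwidth: float = 3.99e9  # B, Hz
    chirp_duration: float = 64e-6  # T_c, s
    adc_samples: int = 256  # N, fast-time samples per chirp
    frame_rate: float = 50.0  # Hz (slow-time sampling rate)
    duration: float = 60.0  # s

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.adc_samples < 2:
            raise ValueError("adc_samples must be >= 2")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength λ_c = c / f_c (m)."""
        return C_LIGHT / self.start_frequency

    @property
    def range_resolution(self) -> float:
        """Range-bin spacing l_res = c / (2B) (m)."""
        return C_LIGHT / (2.0 * self.bandwidth)

    @property
    def n_frames(self) -> int:
        frames = self.duration * self.frame_rate
        rounded = round(frames)
        if rounded <= 0 or abs(frames - rounded) > 1e-9:
            raise ValueError(
                f"duration*frame_rate must be a positive integer, got {frames}"
            )
        return rounded

    @property
    def max_range(self) -> float:
        """Unambiguous range N * l_res (m)."""
        return self.adc_samples * self.range_resolution

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class VitalSignProfile:
    """Chest-kinematics model: respiration (with harmonics) + heartbeat.

    Respiration displacement is A_r * sum_k a_k sin(2π k f_r t + θ_k) where
    ``respiration_harmonics`` lists (order k, relative amplitude a_k,
    phase θ_k) including the fundamental.  The heartbeat is a single tone of
    amplitude A_h whose frequency may drift as a bounded random walk
    (``heart_drift_std`` is the per-second standard deviation; the walk is
    reflected at ``heart_band``).
    """

    respiration_rate: float = 0.3  # f_r, Hz
    respiration_amplitude: float = 0.003  # A_r, m
    respiration_harmonics: tuple = ((1, 1.0, 0.0), (2, 0.09, 0.0), (3, 0.027, 0.0))
    heart_rate: float = 1.3  # f_h, Hz (initial value when drifting)
    heart_amplitude: float = 0.0003  # A_h, m
    heart_phase: float = 0.0  # θ_h, rad
    heart_drift_std: float = 0.005  # Hz per sqrt(second); 0 disables drift
    heart_band: tuple = (1.0, 1.7)  # Hz, reflecting band for the drift walk

    def __post_init__(self) -> None:
        if not 0 < self.respiration_rate < self.heart_rate:
            raise ValueError("need 0 < respiration_rate < heart_rate")
        if self.heart_amplitude < 0 or self.respiration_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.heart_amplitude > self.respiration_amplitude and self.respiration_amplitude > 0:
            raise ValueError("heart amplitude must not exceed respiration amplitude")
        lo, hi = self.heart_band
        if not lo <= self.heart_rate <= hi:
            raise ValueError("heart_rate must lie inside heart_band")

    @staticmethod
    def random(rng: np.random.Generator) -> "VitalSignProfile":
        """Draw a resting-physiology profile.

        f_r ~ U[0.2, 0.4] Hz, A_r ~ U[1, 5] mm, two respiration harmonics
        with relative amplitudes 0.3^k, f_h ~ U[1.0, 1.7] Hz,
        A_h ~ U[0.1, 0.5] mm, phases uniform on [0, 2π).
        """
        f_r = rng.uniform(0.2, 0.4)
        a_r = rng.uniform(1e-3, 5e-3)
        harm = tuple(
            (k, 1.0 if k == 1 else 0.3 ** k, float(rng.uniform(0, 2 * np.pi)))
            for k in (1, 2, 3)
        )
        f_h = rng.uniform(1.0, 1.7)
        a_h = rng.uniform(0.1e-3, 0.5e-3)
        return VitalSignProfile(
            respiration_rate=f_r,
            respiration_amplitude=a_r,
            respiration_harmonics=harm,
            heart_rate=f_h,
            heart_amplitude=a_h,
            heart_phase=rng.uniform(0, 2 * np.pi),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["respiration_harmonics"] = [list(h) for h in self.respiration_harmonics]
        d["heart_band"] = list(self.heart_band)
        return d


@dataclass(frozen=True)
class SceneSpec:
    """Reflector geometry seen by the radar.

    ``subject_reflectivity`` scales the chest echo; ``static_clutter`` is a
    list of (distance m, reflectivity) point reflectors that do not move;
    ``snr_db`` sets additive circular complex Gaussian noise power relative
    to the subject echo power (``inf`` means noise-free).
    """

    subject_distance: float = 0.75  # l_chest, m
    subject_reflectivity: float = 1.0
    static_clutter: tuple = ()  # ((distance_m, reflectivity), ...)
    dc_offset: complex = 0.0 + 0.0j
    snr_db: float = float("inf")

    def __post_init__(self) -> None:
        if self.subject_distance <= 0:
            raise ValueError("subject_distance must be positive")
        if not (np.isfinite(self.snr_db) or self.snr_db == float("inf")):
            raise ValueError("snr_db must be finite or +inf")

    def validate_against(self, config: RadarConfig) -> None:
        if self.subject_distance >= config.max_range:
            raise ValueError("subject beyond unambiguous range")
        for dist, _ in self.static_clutter:
            if not 0 < dist < config.max_range:
                raise ValueError(f"clutter at {dist} m outside unambiguous range")

    @staticmethod
    def random(rng: np.random.Generator, snr_db: float = float("inf"),
               n_clutter: int = 2) -> "SceneSpec":
        """Subject at 0.5–1.0 m with a few static clutter reflectors."""
        clutter = tuple(
            (float(rng.uniform(0.3, 2.0)), float(rng.uniform(0.5, 5.0)))
            for _ in range(n_clutter)
        )
        return SceneSpec(
            subject_distance=float(rng.uniform(0.5, 1.0)),
            subject_reflectivity=1.0,
            static_clutter=clutter,
            dc_offset=complex(rng.normal(0, 0.5), rng.normal(0, 0.5)),
            snr_db=snr_db,
        )

    def to_dict(self) -> dict:
        return {
            "subject_distance": self.subject_distance,
            "subject_reflectivity": self.subject_reflectivity,
            "static_clutter": [list(c) for c in self.static_clutter],
            "dc_offset": [self.dc_offset.real, self.dc_offset.imag],
            "snr_db": self.snr_db,
        }


@dataclass
class MVNConfig:
    """Architecture and training hyperparameters for the MVN.

    Defaults are the full-size network: an 8-layer/128-dim MAE encoder, a
    5-layer/64-dim MAE decoder, a 5-layer/64-dim ViT regression head, 16
    attention heads, feed-forward width 2048, 40% token masking, Adam at
    5e-5.  ``desk_scale`` returns a reduced profile for CPU-scale runs.
    """

    enc_layers: int = 8
    enc_dim: int = 128
    dec_layers: int = 5
    dec_dim: int = 64
    vit_layers: int = 5
    vit_dim: int = 64
    heads: int = 16
    ffn_dim: int = 2048
    mask_ratio: float = 0.40
    patch_len: int = 8  # frames per token; tokens are patch_len x 5 bins
    learning_rate: float = 5e-5
    pretrain_learning_rate: float | None = None  # None: use learning_rate
    pretrain_epochs: int = 300
    finetune_epochs: int = 300
    batch_size: int = 64
    seed: int = 0
    label_scale: float = 200.0  # BPM divisor for the regression target
    loss_on_masked_only: bool = True
    n_bins: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.mask_ratio < 1:
            raise ValueError("mask_ratio must be in (0, 1)")
        if self.enc_dim % self.heads or self.dec_dim % self.heads or self.vit_dim % self.heads:
            raise ValueError("model dims must be divisible by heads")
        for name in ("enc_layers", "dec_layers", "vit_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def patch_dim(self) -> int:
        return self.n_bins * self.patch_len

    @classmethod
    def desk_scale(cls, **overrides) -> "MVNConfig":
        """Reduced 4-layer-encoder profile for single-CPU experiments."""
        base = dict(
            enc_layers=4, enc_dim=32, dec_layers=2, dec_dim=32,
            vit_layers=2, vit_dim=32, heads=4, ffn_dim=64,
            learning_rate=1e-3, pretrain_learning_rate=3e-3,
            pretrain_epochs=120, finetune_epochs=300,
            batch_size=64,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "MVNConfig":
        return cls(**d)


def load_run_config(path) -> dict:
    """Load a YAML run configuration; unknown top-level keys are rejected.

    Recognized sections: ``radar`` (RadarConfig fields), ``mvn`` (MVNConfig
    fields), and scalar pipeline settings (``seed``, ``n_recordings``,
    ``duration``, ``snr_db``, ``window_seconds``, ``stride_seconds``,
    ``label_density``, ``variants``).
    """
    import yaml

    raw = yaml.safe_load(open(path)) or {}
    allowed = {"radar", "mvn", "seed", "n_recordings", "duration", "snr_db",
               "window_seconds", "stride_seconds", "label_density", "variants"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "radar" in raw:
        raw["radar"] = RadarConfig(**raw["radar"])
    if "mvn" in raw:
        raw["mvn"] = MVNConfig(**raw["mvn"])
    return raw


VARIANTS = ("full", "no_pretrain", "no_vit", "labeled_only", "spectral_baseline")


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of the ablation / label-density study."""

    window_seconds: float = 2.56
    stride_seconds: float = 1.28
    label_density: float = 0.16
    train_fraction: float = 0.8
    variant: str = "full"
    split_level: str = "recording"  # or "window"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.label_density <= 1:
            raise ValueError("label_density must be in (0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.split_level not in ("recording", "window"):
            raise ValueError("split_level must be 'recording' or 'window'")
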