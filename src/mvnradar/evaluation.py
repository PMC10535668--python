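"""Metrics, the classic spectral-peak baseline, and the experiment harness.

The harness reproduces the ablation / label-density protocol: an 8:2
train/test split (at recording level by default, so overlapping windows of
one recording never straddle the split), masked pretraining on all training
windows, finetuning on a seeded labeled fraction, and AAEP/MSE on the full
test set for each model variant plus the classic band-limited spectral-peak
estimator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ExperimentSpec, MVNConfig
from .mvn.model import MaskedAutoencoder, build_mvn
from .mvn.training import clone_encoder, finetune, predict, pretrain
from .phase_prep import PhaseWindow

__all__ = ["WindowDataset", "mse", "aaep", "spectral_hr_baseline",
           "augment_windows", "run_experiment", "run_ablation"]


@dataclass
class WindowDataset:
    """Stack of preprocessed phase windows with labels and provenance."""

    X: np.ndarray  # (n, n_bins, W) float
    y: np.ndarray  # (n,) BPM
    rec_ids: np.ndarray  # (n,) str
    frame_rate: float = 50.0

    @classmethod
    def from_windows(cls, windows: list[PhaseWindow], frame_rate: float = 50.0) -> "WindowDataset":
        if not windows:
            raise ValueError("no windows")
        return cls(
            X=np.stack([w.matrix for w in windows]).astype(np.float64),
            y=np.array([w.label for w in windows], dtype=float),
            rec_ids=np.array([w.recording_id for w in windows]),
            frame_rate=frame_rate,
        )

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "WindowDataset":
        return WindowDataset(self.X[idx], self.y[idx], self.rec_ids[idx], self.frame_rate)


def mse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error (1/m) Σ (y_i − ŷ_i)²."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("need equal, nonzero-length vectors")
    return float(np.mean((y - y_hat) ** 2))


def aaep(f: np.ndarray, F: np.ndarray) -> float:
    """Average absolute error percentage: 100 · mean(|f − F| / F)."""
    f, F = np.asarray(f, float), np.asarray(F, float)
    if f.shape != F.shape or f.size == 0:
        raise ValueError("need equal, nonzero-length vectors")
    if np.any(F <= 0):
        raise ValueError("reference values must be positive")
    return float(100.0 * np.mean(np.abs(f - F) / F))


def spectral_hr_baseline(
    series: np.ndarray,
    frame_rate: float,
    band_hz: tuple[float, float] = (0.8, 2.5),
    grid_hz: float = 0.01,
) -> float:
    """Classic estimator: band-limited zero-padded spectral peak in BPM.

    ``series`` is a differenced-phase slow-time series.  It is band-limited
    to ``band_hz`` (defaults cover 48–150 BPM) with a zero-phase 4th-order
    Butterworth band-pass — a time-domain filter, so the strong out-of-band
    respiration fundamental cannot leak into the heart band — then
    Hann-windowed, zero-padded to a grid of at most ``grid_hz``, and the
    in-band argmax frequency is returned as 60 × f.
    """
    from scipy.signal import butter, filtfilt

    series = np.asarray(series, dtype=float)
    n = series.size
    if n < frame_rate / band_hz[0]:
        raise ValueError("series shorter than one period of the band's low edge")
    sos_b, sos_a = butter(4, band_hz, btype="bandpass", fs=frame_rate)
    filtered = filtfilt(sos_b, sos_a, series - series.mean())
    nfft = 1
    while frame_rate / nfft > grid_hz or nfft < n:
        nfft *= 2
    windowed = filtered * np.hanning(n)
    spectrum = np.abs(np.fft.rfft(windowed, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / frame_rate)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(in_band):
        raise ValueError("band contains no frequency bins")
    f_peak = freqs[in_band][np.argmax(spectrum[in_band])]
    return 60.0 * float(f_peak)


def _split(dataset: WindowDataset, spec: ExperimentSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    if spec.split_level == "recording":
        recs = np.unique(dataset.rec_ids)
        rng.shuffle(recs)
        n_train = int(round(spec.train_fraction * len(recs)))
        if n_train == 0 or n_train == len(recs):
            raise ValueError("split leaves train or test empty")
        train_recs = set(recs[:n_train])
        mask = np.array([r in train_recs for r in dataset.rec_ids])
    else:
        perm = rng.permutation(len(dataset))
        n_train = int(round(spec.train_fraction * len(dataset)))
        mask = np.zeros(len(dataset), dtype=bool)
        mask[perm[:n_train]] = True
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def _label_subset(n_train: int, density: float, seed: int) -> np.ndarray:
    n_labeled = int(round(density * n_train))
    if n_labeled == 0:
        raise ValueError(f"label density {density} yields zero labeled windows")
    rng = np.random.default_rng(seed + 17)
    return rng.choice(n_train, size=n_labeled, replace=False)


def _evaluate(pred: np.ndarray, truth: np.ndarray) -> dict:
    return {"aaep": aaep(pred, truth), "mse": mse(truth, pred)}


def augment_windows(X: np.ndarray, y: np.ndarray,
                    groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency-preserving 4x augmentation: time reversal and sign flip.

    Both transforms leave the magnitude spectrum — hence the heart rate —
    unchanged, so labels are reused verbatim.
    """
    X = np.asarray(X)
    Xa = np.concatenate([X, X[:, :, ::-1], -X, -X[:, :, ::-1]])
    return Xa, np.tile(y, 4), np.tile(groups, 4)


def run_ablation(
    dataset: WindowDataset,
    spec: ExperimentSpec,
    variants: list[str],
    mvn_cfg: MVNConfig | None = None,
    pretrain_epochs: int | None = None,
    finetune_epochs: int | None = None,
    augment: bool = True,
) -> pd.DataFrame:
    """Run several variants on one shared split/pretraining; one row each.

    ``augment`` applies the frequency-preserving 4x augmentation to the
    labeled finetuning set (all learned variants, identically).
    """
    cfg = mvn_cfg if mvn_cfg is not None else MVNConfig.desk_scale(seed=spec.seed)
    cfg.seed = spec.seed
    train_idx, test_idx = _split(dataset, spec)
    train, test = dataset.subset(train_idx), dataset.subset(test_idx)
    labeled_idx = _label_subset(len(train), spec.label_density, spec.seed)
    X_lab, y_lab = train.X[labeled_idx], train.y[labeled_idx]
    g_lab = train.rec_ids[labeled_idx]
    n_labeled = len(labeled_idx)
    if augment:
        X_lab, y_lab, g_lab = augment_windows(X_lab, y_lab, g_lab)

    pretrained: MaskedAutoencoder | None = None
    if any(v in ("full", "no_vit") for v in variants):
        pretrained, _ = pretrain(train.X, cfg, epochs=pretrain_epochs)
    n_tokens = test.X.shape[2] // cfg.patch_len

    rows = []
    for variant in variants:
        if variant == "spectral_baseline":
            center = test.X.shape[1] // 2
            pred = np.array([
                spectral_hr_baseline(x[center], dataset.frame_rate) for x in test.X
            ])
        elif variant in ("full", "no_vit"):
            head = "vit" if variant == "full" else "linear"
            model = build_mvn(clone_encoder(pretrained.encoder), cfg, n_tokens,
                              head=head, encoder_frozen=True)
            model, _ = finetune(model, X_lab, y_lab, cfg, epochs=finetune_epochs,
                                groups=g_lab)
            pred = predict(model, test.X)
        elif variant == "no_pretrain":
            rng = np.random.default_rng(cfg.seed)
            mae = MaskedAutoencoder(cfg, n_tokens, np.random.default_rng(rng.integers(2**31)))
            model = build_mvn(mae.encoder, cfg, n_tokens, head="vit",
                              encoder_frozen=False)
            model, _ = finetune(model, X_lab, y_lab, cfg, epochs=finetune_epochs,
                                groups=g_lab)
            pred = predict(model, test.X)
        elif variant == "labeled_only":
            mae_lab, _ = pretrain(X_lab, cfg, epochs=pretrain_epochs)
            model = build_mvn(mae_lab.encoder, cfg, n_tokens, head="vit",
                              encoder_frozen=True)
            model, _ = finetune(model, X_lab, y_lab, cfg, epochs=finetune_epochs,
                                groups=g_lab)
            pred = predict(model, test.X)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        row = {"variant": variant, "window_s": spec.window_seconds,
               "density": spec.label_density, "seed": spec.seed,
               "n_train": len(train), "n_labeled": n_labeled,
               "n_test": len(test)}
        row.update(_evaluate(pred, test.y))
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(
    dataset: WindowDataset,
    spec: ExperimentSpec,
    mvn_cfg: MVNConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Single-variant experiment (see :func:`run_ablation`)."""
    return run_ablation(dataset, spec, [spec.variant], mvn_cfg=mvn_cfg, **kwargs)
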