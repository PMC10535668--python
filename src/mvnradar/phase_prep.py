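"""Phase extraction, unwrapping, differencing, jump smoothing, and window
cutting.

The subject-bin complex series carries chest displacement in its angle.
Unwrapping removes the ±2π wrap artifacts; first differencing removes
baseline drift and strongly attenuates the low-frequency respiration
component relative to the heartbeat; inward interpolation replaces isolated
jump samples by the mean of their original neighbours.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radar_sim import GroundTruth

__all__ = [
    "PhaseWindow",
    "extract_phase",
    "unwrap_phase",
    "phase_diff",
    "jump_threshold",
    "smooth_jumps",
    "preprocess_bins",
    "make_windows",
]


@dataclass
class PhaseWindow:
    """Preprocessed phase block: ``matrix`` is (n_bins x W) real, optional BPM label."""

    matrix: np.ndarray
    label: float | None = None
    recording_id: str = ""
    start_frame: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite phase window")
        if self.label is not None and self.label <= 0:
            raise ValueError("label must be positive BPM")


def extract_phase(series: np.ndarray) -> np.ndarray:
    """Four-quadrant angle of each complex sample, in (-π, π]."""
    series = np.asarray(series)
    zero = np.flatnonzero(np.abs(series) == 0)
    if zero.size:
        raise ValueError(f"zero-magnitude sample at index {zero[0]}: phase undefined")
    return np.angle(series)


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Sequential ±2π correction of wrap jumps.

    Whenever the step from the previous (already corrected) sample exceeds
    +π the current and all later samples are shifted by −2π, and by +2π for
    steps below −π; corrections accumulate along the series.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if wrapped.ndim != 1 or wrapped.size < 1:
        raise ValueError("need a 1-D series of length >= 1")
    steps = np.diff(wrapped)
    correction = np.zeros_like(steps)
    correction[steps > np.pi] = -2 * np.pi
    correction[steps < -np.pi] = 2 * np.pi
    out = wrapped.copy()
    out[1:] += np.cumsum(correction)
    return out


def phase_diff(unwrapped: np.ndarray) -> np.ndarray:
    """First difference φ(p+1) − φ(p); length T−1."""
    unwrapped = np.asarray(unwrapped, dtype=float)
    if unwrapped.size < 2:
        raise ValueError("need at least 2 samples to difference")
    return np.diff(unwrapped)


def jump_threshold(diff: np.ndarray, k: float = 3.0) -> float:
    """Scale-free jump threshold: k x median absolute deviation of the series."""
    diff = np.asarray(diff, dtype=float)
    mad = float(np.median(np.abs(diff - np.median(diff))))
    return k * mad


def smooth_jumps(
    diff: np.ndarray,
    threshold: float | None = None,
    trigger: str = "value",
) -> np.ndarray:
    """Inward interpolation of jump samples in the differenced phase.

    Interior samples whose magnitude exceeds ``threshold`` (default:
    3 x MAD of the series) are replaced by the mean of their ORIGINAL
    neighbours in a single left-to-right pass; endpoints and all other
    samples are returned bit-unchanged.  ``trigger="step"`` tests the step
    from the previous sample instead of the sample's own magnitude.
    """
    diff = np.asarray(diff, dtype=float)
    if threshold is None:
        threshold = jump_threshold(diff)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = diff.copy()
    if diff.size < 3:
        return out
    if trigger == "value":
        flag = np.abs(diff[1:-1]) > threshold
    elif trigger == "step":
        flag = np.abs(diff[1:-1] - diff[:-2]) > threshold
    else:
        raise ValueError(f"unknown trigger {trigger!r}")
    idx = np.flatnonzero(flag) + 1
    out[idx] = 0.5 * (diff[idx - 1] + diff[idx + 1])
    return out


def preprocess_bins(
    submatrix: np.ndarray,
    threshold: float | None = None,
    trigger: str = "value",
) -> np.ndarray:
    """Per-bin extract → unwrap → difference → smooth; (T x k) complex in,
    (T−1 x k) real out with columns aligned."""
    submatrix = np.asarray(submatrix)
    if submatrix.ndim != 2 or submatrix.shape[0] < 3:
        raise ValueError("need a (frames x bins) matrix with >= 3 frames")
    cols = []
    for b in range(submatrix.shape[1]):
        try:
            phase = extract_phase(submatrix[:, b])
            d = phase_diff(unwrap_phase(phase))
            cols.append(smooth_jumps(d, threshold=threshold, trigger=trigger))
        except ValueError as exc:
            raise ValueError(f"bin {b}: {exc}") from exc
    return np.stack(cols, axis=1)


def make_windows(
    matrix: np.ndarray,
    truth: GroundTruth,
    window_seconds: float,
    stride_seconds: float,
    frame_rate: float | None = None,
    recording_id: str = "",
    normalize: bool = True,
) -> list[PhaseWindow]:
    """Cut the preprocessed (T−1 x k) matrix into labelled sliding windows.

    Window ``matrix`` blocks are transposed to (k x W) and z-scored per
    window; the label is the ground-truth mean BPM over the original frame
    interval [s, s+W] covered by the W differenced samples starting at s.
    """
    matrix = np.asarray(matrix, dtype=float)
    fr = frame_rate if frame_rate is not None else truth.frame_rate
    w = int(round(window_seconds * fr))
    stride = int(round(stride_seconds * fr))
    if stride < 1:
        raise ValueError("stride must cover at least one frame")
    n = matrix.shape[0]
    if w > n:
        raise ValueError(f"window of {w} samples longer than series of {n}")
    windows = []
    for s in range(0, n - w + 1, stride):
        block = matrix[s : s + w].T.copy()
        if normalize:
            std = block.std()
            block = (block - block.mean()) / (std if std > 0 else 1.0)
        label = truth.mean_bpm(s, min(s + w + 1, len(truth.heart_freq)))
        windows.append(
            PhaseWindow(
                matrix=block.astype(np.float32),
                label=label,
                recording_id=recording_id,
                start_frame=s,
            )
        )
    return windows
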