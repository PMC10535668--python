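"""Range processing and subject localization.

A Hanning-windowed FFT over fast time turns each IF frame into a range
spectrum; stacking frames gives the range/slow-time matrix.  Static clutter
and DC are constant along slow time, so subtracting each range bin's
slow-time mean removes them while the periodically moving chest survives;
the subject bin is then the one with the largest residual energy.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import RadarConfig
from .radar_sim import IFRecording

__all__ = ["RangeTimeMatrix", "range_fft", "mean_reduce", "locate_subject", "select_bins"]


@dataclass
class RangeTimeMatrix:
    """Complex matrix with rows = frames (slow time), columns = range bins."""

    values: np.ndarray
    bin_spacing: float  # l_res, m
    frame_rate: float
    config: RadarConfig | None = None
    reduced: bool = False

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_of_distance(self, distance: float) -> int:
        return int(round(distance / self.bin_spacing))


def range_fft(recording: IFRecording) -> RangeTimeMatrix:
    """Per-frame Hanning window + N-point FFT over fast time."""
    data = recording.data
    if data.size == 0:
        raise ValueError("empty recording")
    n = data.shape[1]
    window = np.hanning(n)
    spectra = np.fft.fft(data * window[None, :], axis=1)
    return RangeTimeMatrix(
        values=spectra,
        bin_spacing=recording.config.range_resolution,
        frame_rate=recording.config.frame_rate,
        config=recording.config,
    )


def mean_reduce(m: RangeTimeMatrix) -> RangeTimeMatrix:
    """Subtract each range bin's complex slow-time mean.

    Removes DC and static clutter; raises on single-frame input, which the
    reduction would zero out entirely.
    """
    if m.n_frames < 2:
        raise ValueError("mean reduction needs at least 2 frames")
    reduced = m.values - m.values.mean(axis=0, keepdims=True)
    return replace(m, values=reduced, reduced=True)


def _band_bins(m: RangeTimeMatrix, search_range: tuple[float, float]) -> np.ndarray:
    lo_m, hi_m = search_range
    bins = np.arange(1, m.n_bins)  # bin 0 always excluded
    dists = bins * m.bin_spacing
    keep = bins[(dists >= lo_m) & (dists <= hi_m)]
    if keep.size == 0:
        raise ValueError(f"search range {search_range} m contains no range bins")
    return keep


def locate_subject(
    m: RangeTimeMatrix,
    search_range: tuple[float, float] = (0.3, 2.0),
    statistic: str = "mean_magnitude",
) -> int:
    """Bin index of the subject within ``search_range`` (metres).

    Expects a mean-reduced matrix.  The default statistic is the mean
    slow-time magnitude of the reduced matrix; ``"variance"`` scores by
    slow-time variance instead.
    """
    if not m.reduced:
        raise ValueError("locate_subject expects a mean-reduced matrix")
    bins = _band_bins(m, search_range)
    if statistic == "mean_magnitude":
        score = np.abs(m.values[:, bins]).mean(axis=0)
    elif statistic == "variance":
        score = np.var(m.values[:, bins], axis=0).real
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return int(bins[np.argmax(score)])


def select_bins(m: RangeTimeMatrix | np.ndarray, center: int, k: int = 5) -> np.ndarray:
    """The ``k`` columns centred on ``center`` (clamped at the matrix edges).

    Returns a (frames x k) complex matrix with ascending bin order; near an
    edge the block is shifted inward so exactly k in-matrix bins are kept.
    """
    values = m.values if isinstance(m, RangeTimeMatrix) else m
    n_bins = values.shape[1]
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be odd and positive")
    if k > n_bins:
        raise ValueError(f"k={k} exceeds {n_bins} bins")
    if not 0 <= center < n_bins:
        raise ValueError(f"center bin {center} out of range")
    start = min(max(center - k // 2, 0), n_bins - k)
    return values[:, start : start + k]
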