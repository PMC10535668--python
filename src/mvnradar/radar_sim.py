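"""Synthetic FMCW intermediate-frequency (IF) recordings of a breathing,
beating chest.

The generator follows the standard FMCW beat-signal model: after mixing,
each point reflector at distance ``l`` contributes a fast-time complex
exponential at beat frequency ``f_b = 2 B l / (c T_c)`` with phase
``4π l / λ_c``.  Chest motion is small compared to the range resolution, so
the displacement modulates only the phase term (the beat frequency is
evaluated at the static chest distance); this is the small-displacement
approximation the whole phase-based method rests on, and it makes the
subject-bin phase obey the closed form ``φ(p) = 4π (l_chest + h(p)) / λ_c``
exactly in the noise-free case.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import C_LIGHT, RadarConfig, SceneSpec, VitalSignProfile

__all__ = [
    "GroundTruth",
    "IFRecording",
    "chest_displacement",
    "heart_frequency_path",
    "synthesize_if_frame",
    "synthesize_recording",
    "window_truth",
]


@dataclass
class GroundTruth:
    """Per-frame chest displacement and instantaneous heart frequency."""

    displacement: np.ndarray  # m, one per frame
    heart_freq: np.ndarray  # Hz, one per frame
    frame_rate: float

    def __post_init__(self) -> None:
        if len(self.displacement) != len(self.heart_freq):
            raise ValueError("displacement and heart_freq lengths differ")

    def mean_bpm(self, start_frame: int, stop_frame: int) -> float:
        """Mean heart rate in BPM over frames [start_frame, stop_frame)."""
        n = len(self.heart_freq)
        if not 0 <= start_frame < stop_frame <= n:
            raise IndexError(
                f"frame interval [{start_frame}, {stop_frame}) outside recording of {n} frames"
            )
        return 60.0 * float(np.mean(self.heart_freq[start_frame:stop_frame]))


@dataclass
class IFRecording:
    """Complex IF frame cube: rows = frames (slow time), cols = ADC samples."""

    data: np.ndarray  # complex, (n_frames, adc_samples)
    config: RadarConfig
    truth: GroundTruth
    scene: SceneSpec | None = None
    profile: VitalSignProfile | None = None
    seed: int | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        if self.data.shape != (self.config.n_frames, self.config.adc_samples):
            raise ValueError(
                f"data shape {self.data.shape} != "
                f"({self.config.n_frames}, {self.config.adc_samples})"
            )
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("non-finite IF samples")


def heart_frequency_path(
    profile: VitalSignProfile, n_frames: int, frame_rate: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Instantaneous heart frequency per frame (Hz).

    A reflected random walk inside ``profile.heart_band`` with per-second
    standard deviation ``heart_drift_std``; constant when the drift is 0 or
    no generator is supplied.
    """
    if profile.heart_drift_std == 0 or rng is None:
        return np.full(n_frames, profile.heart_rate)
    dt = 1.0 / frame_rate
    steps = rng.normal(0.0, profile.heart_drift_std * np.sqrt(dt), size=n_frames - 1)
    path = profile.heart_rate + np.concatenate([[0.0], np.cumsum(steps)])
    lo, hi = profile.heart_band
    # reflect into [lo, hi]
    span = hi - lo
    folded = np.mod(path - lo, 2 * span)
    return lo + np.where(folded <= span, folded, 2 * span - folded)


def chest_displacement(
    profile: VitalSignProfile,
    t: np.ndarray | float,
    heart_freq: np.ndarray | None = None,
) -> np.ndarray | float:
    """Chest displacement h(t) in metres.

    ``h(t) = A_r Σ_k a_k sin(2π k f_r t + θ_k) + A_h sin(Θ_h(t))`` where the
    heart phase is ``Θ_h(t) = θ_h + 2π f_h t`` for a constant rate, or the
    trapezoid integral of a supplied per-sample instantaneous frequency path
    (which reduces to the former when the path is constant).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    resp = np.zeros_like(t_arr)
    for k, a_k, theta_k in profile.respiration_harmonics:
        resp += a_k * np.sin(2 * np.pi * k * profile.respiration_rate * t_arr + theta_k)
    resp *= profile.respiration_amplitude
    if heart_freq is None:
        heart_phase = 2 * np.pi * profile.heart_rate * t_arr + profile.heart_phase
    else:
        hf = np.asarray(heart_freq, dtype=float)
        if hf.shape != t_arr.shape:
            raise ValueError("heart_freq must match t in shape")
        heart_phase = profile.heart_phase + 2 * np.pi * _cumtrapz0(hf, t_arr)
    out = resp + profile.heart_amplitude * np.sin(heart_phase)
    return out if np.ndim(t) else float(out[0])


def _cumtrapz0(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    if len(y) > 1:
        out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def _reflector_matrix(
    config: RadarConfig,
    distances: np.ndarray,
    reflectivities: np.ndarray,
    phase_distances: np.ndarray,
) -> np.ndarray:
    """Sum of beat exponentials; rows follow ``phase_distances`` rows.

    ``distances`` sets the beat frequency; ``phase_distances`` (possibly
    time-varying, shape (frames, n_refl)) sets the phase term.
    """
    n = config.adc_samples
    t_fast = np.arange(n) * config.chirp_duration / n
    f_b = 2.0 * config.bandwidth * distances / (C_LIGHT * config.chirp_duration)
    fast_phase = 2 * np.pi * np.outer(f_b, t_fast)  # (n_refl, N)
    slow_phase = 4 * np.pi * phase_distances / config.wavelength  # (frames, n_refl)
    # (frames, n_refl, N) summed over reflectors
    return np.einsum(
        "fr,rn->fn",
        reflectivities * np.exp(1j * slow_phase),
        np.exp(1j * fast_phase),
    )


def synthesize_if_frame(
    config: RadarConfig,
    scene: SceneSpec,
    displacement: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One IF frame (complex vector of length ``adc_samples``).

    The subject sits at ``scene.subject_distance``; ``displacement`` offsets
    its echo phase by ``4π·displacement/λ_c``.  Static clutter, the DC
    offset, and (if ``snr_db`` is finite) circular complex Gaussian noise
    scaled relative to the subject echo power are added.
    """
    if not np.isfinite(displacement):
        raise ValueError("displacement must be finite")
    scene.validate_against(config)
    dists = [scene.subject_distance] + [d for d, _ in scene.static_clutter]
    refl = [scene.subject_reflectivity] + [r for _, r in scene.static_clutter]
    phase_d = np.array([[scene.subject_distance + displacement] + [d for d, _ in scene.static_clutter]])
    frame = _reflector_matrix(config, np.array(dists), np.array(refl), phase_d)[0]
    frame += scene.dc_offset
    if np.isfinite(scene.snr_db):
        if rng is None:
            raise ValueError("rng required for finite snr_db")
        frame += _noise(scene, (config.adc_samples,), rng)
    return frame


def _noise(scene: SceneSpec, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    noise_power = scene.subject_reflectivity**2 / 10 ** (scene.snr_db / 10)
    sigma = np.sqrt(noise_power / 2)
    return sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


def synthesize_recording(
    config: RadarConfig,
    scene: SceneSpec,
    profile: VitalSignProfile,
    seed: int,
    recording_id: str = "",
) -> IFRecording:
    """Full recording: one chirp per frame period, ground truth attached.

    All stochastic draws (heart-rate drift, noise) flow from a single
    ``numpy`` generator seeded with ``seed``, so identical arguments give
    bit-identical recordings.
    """
    scene.validate_against(config)
    rng = np.random.default_rng(seed)
    n_frames = config.n_frames
    t = np.arange(n_frames) / config.frame_rate
    heart_freq = heart_frequency_path(profile, n_frames, config.frame_rate, rng)
    disp = chest_displacement(profile, t, heart_freq=heart_freq)

    dists = [scene.subject_distance] + [d for d, _ in scene.static_clutter]
    refl = [scene.subject_reflectivity] + [r for _, r in scene.static_clutter]
    phase_d = np.tile(np.array(dists), (n_frames, 1))
    phase_d[:, 0] += disp
    data = _reflector_matrix(config, np.array(dists), np.array(refl), phase_d)
    data += scene.dc_offset
    if np.isfinite(scene.snr_db):
        data += _noise(scene, data.shape, rng)
    truth = GroundTruth(displacement=disp, heart_freq=heart_freq, frame_rate=config.frame_rate)
    return IFRecording(
        data=data, config=config, truth=truth, scene=scene,
        profile=profile, seed=seed, recording_id=recording_id or f"rec-{seed}",
    )


def window_truth(truth: GroundTruth, start_frame: int, window_frames: int) -> float:
    """Reference heart rate (BPM) over ``window_frames`` starting at ``start_frame``."""
    if window_frames <= 0:
        raise ValueError("window_frames must be positive")
    return truth.mean_bpm(start_frame, start_frame + window_frames)
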