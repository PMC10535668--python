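"""Phase extraction/unwrapping/differencing/smoothing and window cutting."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvnradar import (RadarConfig, SceneSpec, extract_phase, make_windows,
                      phase_diff, preprocess_bins, smooth_jumps,
                      synthesize_recording, unwrap_phase)
from mvnradar.localization import mean_reduce, range_fft, select_bins
from mvnradar.phase_prep import jump_threshold
from mvnradar.radar_sim import GroundTruth


class TestExtractPhase:
    @pytest.mark.parametrize("z,expected", [
        (1 + 0j, 0.0),
        (0 + 1j, np.pi / 2),
        (np.exp(2.5j), 2.5),
    ])
    def test_known_angles(self, z, expected):
        assert extract_phase(np.array([z]))[0] == pytest.approx(expected)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="index 1"):
            extract_phase(np.array([1 + 1j, 0j, 2j]))

    @given(st.lists(st.tuples(st.floats(0.1, 10), st.floats(-10, 10)), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_output_always_in_wrapped_interval(self, polar):
        z = np.array([r * np.exp(1j * a) for r, a in polar])
        phases = extract_phase(z)
        assert np.all((phases > -np.pi) & (phases <= np.pi))


class TestUnwrapPhase:
    def test_single_wrap_corrected(self):
        out = unwrap_phase(np.array([3.0, -3.0]))
        assert out == pytest.approx([3.0, -3.0 + 2 * np.pi])

    def test_small_steps_unchanged(self):
        x = np.array([0.0, 0.5, -0.4, 0.9, 0.2])
        assert np.array_equal(unwrap_phase(x), x)

    def test_rewrapped_random_walks_recovered(self):
        # oracle: cumulative sum of the true steps; wrap, unwrap, compare
        rng = np.random.default_rng(99)
        for _ in range(200):
            steps = rng.uniform(-np.pi + 1e-9, np.pi - 1e-9, size=rng.integers(2, 300))
            true = np.concatenate([[rng.uniform(-np.pi, np.pi)], steps]).cumsum()
            wrapped = np.angle(np.exp(1j * true))
            recovered = unwrap_phase(wrapped)
            offset = recovered[0] - true[0]
            assert offset / (2 * np.pi) == pytest.approx(round(offset / (2 * np.pi)), abs=1e-9)
            assert np.allclose(recovered - offset, true, atol=1e-9)

    def test_agrees_with_numpy_unwrap(self):
        rng = np.random.default_rng(5)
        wrapped = np.angle(np.exp(1j * rng.uniform(-20, 20, 500).cumsum()))
        assert np.allclose(unwrap_phase(wrapped), np.unwrap(wrapped), atol=1e-9)


class TestPhaseDiff:
    def test_simple_difference(self):
        assert np.array_equal(phase_diff(np.array([0.0, 1.0, 3.0])), [1.0, 2.0])

    def test_affine_trend_becomes_constant(self):
        p = np.arange(100) * 0.37 + 5.0
        assert np.allclose(phase_diff(p), 0.37)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            phase_diff(np.array([1.0]))

    def test_differenced_series_independent_of_subject_distance(self, steady_profile):
        config = RadarConfig(duration=5.0)
        diffs = []
        for dist in (0.6, 0.9):
            scene = SceneSpec(subject_distance=dist, static_clutter=(), dc_offset=0j)
            rec = synthesize_recording(config, scene, steady_profile, seed=3)
            m = range_fft(rec)
            b = round(dist / config.range_resolution)
            diffs.append(phase_diff(unwrap_phase(extract_phase(m.values[:, b]))))
        assert np.allclose(diffs[0], diffs[1], atol=1e-9)


class TestSmoothJumps:
    def test_jump_replaced_by_neighbour_mean(self):
        out = smooth_jumps(np.array([0.1, 5.0, 0.3]), threshold=1.0)
        assert out == pytest.approx([0.1, 0.2, 0.3])

    def test_idempotent_below_threshold(self):
        x = np.array([0.1, 0.2, -0.1, 0.3])
        assert np.array_equal(smooth_jumps(x, threshold=1.0), x)

    def test_original_neighbours_used_and_endpoints_kept(self):
        # two adjacent jumps: each replaced from ORIGINAL values
        x = np.array([0.0, 4.0, 4.0, 0.0, 0.0])
        out = smooth_jumps(x, threshold=1.0)
        assert out == pytest.approx([0.0, 2.0, 2.0, 0.0, 0.0])

    def test_replacement_fraction_matches_brute_force(self):
        rng = np.random.default_rng(8)
        x = rng.standard_t(df=3, size=2000)
        tau = jump_threshold(x)
        out = smooth_jumps(x, threshold=tau)
        brute = np.abs(x[1:-1]) > tau
        changed = out[1:-1] != x[1:-1]
        assert np.array_equal(changed, brute)
        assert out[0] == x[0] and out[-1] == x[-1]

    def test_untouched_samples_bit_identical(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=500)
        tau = jump_threshold(x)
        out = smooth_jumps(x, threshold=tau)
        keep = np.abs(x) <= tau
        keep[0] = keep[-1] = True
        assert np.array_equal(out[keep], x[keep])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            smooth_jumps(np.array([1.0, 2.0, 3.0]), threshold=0.0)


class TestPreprocessBins:
    def test_identical_bins_give_identical_columns(self):
        rng = np.random.default_rng(1)
        col = np.exp(1j * rng.uniform(-3, 3, 100))
        sub = np.tile(col[:, None], (1, 5))
        out = preprocess_bins(sub)
        assert out.shape == (99, 5)
        for b in range(1, 5):
            assert np.array_equal(out[:, 0], out[:, b])

    def test_heart_rate_dominates_differenced_spectrum(self, short_config, clean_scene, steady_profile):
        # differencing suppresses respiration: in-band spectral peak sits at
        # f_h even though respiration has 10x the displacement amplitude
        rec = synthesize_recording(short_config, clean_scene, steady_profile, seed=6)
        reduced = mean_reduce(range_fft(rec))
        out = preprocess_bins(select_bins(reduced, 20, 5))
        col = out[:, 2]
        spectrum = np.abs(np.fft.rfft(col * np.hanning(len(col)), 8192))
        freqs = np.fft.rfftfreq(8192, 1 / 50.0)
        band = freqs > 0.6
        peak = freqs[band][np.argmax(spectrum[band])]
        assert peak == pytest.approx(steady_profile.heart_rate, abs=0.05)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            preprocess_bins(np.ones((2, 5), dtype=complex))


class TestMakeWindows:
    def _truth(self, n=3000):
        freq = np.linspace(1.1, 1.3, n)
        return GroundTruth(np.zeros(n), freq, 50.0)

    def test_non_overlapping_count_on_60s_recording(self):
        # 2999-sample differenced series, 128-frame windows, stride 128:
        # floor((2999-128)/128)+1 = 23
        truth = self._truth()
        windows = make_windows(np.zeros((2999, 5)), truth, 2.56, 2.56,
                               frame_rate=50.0, normalize=False)
        assert len(windows) == 23
        starts = [w.start_frame for w in windows]
        assert starts == list(range(0, 23 * 128, 128))

    def test_labels_track_ground_truth_band(self):
        truth = self._truth()
        windows = make_windows(np.random.default_rng(0).normal(size=(2999, 5)),
                               truth, 2.56, 1.28, frame_rate=50.0)
        labels = np.array([w.label for w in windows])
        assert np.all((labels >= 60 * 1.1) & (labels <= 60 * 1.3))
        # non-decreasing drift means non-decreasing labels
        assert np.all(np.diff(labels) >= 0)

    def test_zscore_normalization(self):
        truth = self._truth(300)
        windows = make_windows(np.random.default_rng(2).normal(size=(299, 5)) * 7 + 3,
                               truth, 2.56, 2.56, frame_rate=50.0)
        for w in windows:
            assert w.matrix.mean() == pytest.approx(0.0, abs=1e-5)
            assert w.matrix.std() == pytest.approx(1.0, abs=1e-4)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            make_windows(np.zeros((100, 5)), self._truth(300), 2.56, 1.28,
                         frame_rate=50.0)
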