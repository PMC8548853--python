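import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanosieve.errors import DegenerateSignalError, ValidationError
from nanosieve.preprocess import (
    ReadTooShortError,
    mad_normalize,
    modified_zscores,
    preprocess_read,
    replace_outliers,
    trim_window,
)
from nanosieve.signal_io import Squiggle


class TestTrimWindow:
    def test_training_skip_extracts_expected_range(self):
        sig = np.arange(6000)
        out = trim_window(sig, skip=1500, length=3000)
        np.testing.assert_array_equal(out, np.arange(1500, 4500))

    def test_one_sample_short_is_excluded(self):
        with pytest.raises(ReadTooShortError):
            trim_window(np.arange(4499), skip=1500, length=3000)

    def test_inference_skip_extracts_expected_range(self):
        out = trim_window(np.arange(4500), skip=1000, length=3000)
        np.testing.assert_array_equal(out, np.arange(1000, 4000))

    def test_invalid_arguments_are_hard_errors(self):
        with pytest.raises(ValidationError):
            trim_window(np.arange(10), skip=-1, length=3)


class TestReplaceOutliers:
    def test_hand_computed_spike_replacement(self):
        # median 10.5, MAD 1.5; z(100) = 0.6745*89.5/1.5 = 40.2 > 3.5
        window = np.array([8, 9, 10, 11, 12, 100, 12, 11, 10, 9], dtype=float)
        repaired, count = replace_outliers(window)
        assert count == 1
        assert repaired[5] == pytest.approx(12.0)  # mean of neighbors 12, 12
        np.testing.assert_array_equal(np.delete(repaired, 5), np.delete(window, 5))

    def test_clean_window_untouched(self):
        window = np.array([1, 2, 3, 4, 5], dtype=float)
        assert np.abs(modified_zscores(window)).max() == pytest.approx(1.349)
        repaired, count = replace_outliers(window)
        assert count == 0
        np.testing.assert_array_equal(repaired, window)

    def test_constant_window_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            replace_outliers(np.full(10, 7.0))

    def test_run_of_outliers_resolves_to_bracketing_inliers(self):
        window = np.array([1, 2, 3, 2, 500, 600, 3, 2, 1, 2], dtype=float)
        repaired, count = replace_outliers(window)
        assert count == 2
        assert repaired[4] == pytest.approx((2 + 3) / 2)
        assert repaired[5] == pytest.approx((2 + 3) / 2)

    def test_edge_outlier_uses_single_neighbor(self):
        window = np.array([900, 2, 3, 2, 3, 2, 3, 2], dtype=float)
        repaired, count = replace_outliers(window)
        assert count == 1
        assert repaired[0] == pytest.approx(2.0)

    def test_count_matches_flags_on_input(self, rng):
        for _ in range(20):
            window = rng.normal(size=200)
            window[rng.integers(0, 200, size=3)] += 50
            flagged = int((np.abs(modified_zscores(window)) > 3.5).sum())
            _, count = replace_outliers(window)
            assert count == flagged


class TestMadNormalize:
    def test_hand_computed_example(self):
        out = mad_normalize(np.array([1, 2, 3, 4, 5], dtype=float))
        np.testing.assert_allclose(out.values, [-2, -1, 0, 1, 2])
        assert out.stats.median == 3 and out.stats.mad == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), shift=st.floats(-1e4, 1e4))
    def test_affine_invariance(self, scale, shift):
        x = np.sin(np.arange(100) * 0.7) * 5 + np.cos(np.arange(100))
        base = mad_normalize(x).values
        moved = mad_normalize(scale * x + shift).values
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_constant_window_rejected(self):
        with pytest.raises(DegenerateSignalError):
            mad_normalize(np.full(8, 3.0))

    def test_postconditions_on_random_window(self, rng):
        out = mad_normalize(rng.normal(50, 4, size=3000))
        assert abs(np.median(out.values)) < 1e-6
        assert abs(np.median(np.abs(out.values)) - 1) < 1e-6


class TestPreprocessRead:
    def _squiggle(self, raw, calibration):
        return Squiggle(read_id="r", raw=raw, **calibration)

    def test_full_pipeline_postconditions(self, rng, calibration):
        raw = rng.integers(300, 700, size=6000)
        win = preprocess_read(self._squiggle(raw, calibration), skip=1500,
                              length=3000)
        assert len(win) == 3000
        assert abs(np.median(win.values)) < 1e-6
        assert abs(np.median(np.abs(win.values)) - 1) < 1e-6

    def test_short_read_excluded(self, rng, calibration):
        raw = rng.integers(300, 700, size=4000)
        with pytest.raises(ReadTooShortError):
            preprocess_read(self._squiggle(raw, calibration), skip=1500,
                            length=3000)

    def test_deterministic(self, rng, calibration):
        raw = rng.integers(300, 700, size=6000)
        sq = self._squiggle(raw, calibration)
        a = preprocess_read(sq)
        b = preprocess_read(sq)
        np.testing.assert_array_equal(a.values, b.values)

    def test_idempotent_on_normalized_window(self, rng):
        clean = mad_normalize(rng.normal(size=3000)).values
        again, count = replace_outliers(clean, threshold=1e9)
        renorm = mad_normalize(again)
        assert count == 0
        np.testing.assert_allclose(renorm.values, clean, atol=1e-9)

    def test_spike_robustness(self, rng):
        # smooth signal with bounded noise: no samples near the 3.5 threshold,
        # so the only flagged position is the injected spike
        x = 90 + 10 * np.sin(np.arange(3000) * 0.05) + rng.uniform(-2, 2, 3000)
        repaired0, count0 = replace_outliers(x)
        assert count0 == 0
        base = mad_normalize(repaired0).values
        spiked = x.copy()
        mad = np.median(np.abs(x - np.median(x)))
        spiked[1234] += 100 * mad
        repaired, count = replace_outliers(spiked)
        assert count == 1
        out = mad_normalize(repaired).values
        mask = np.ones(3000, bool)
        mask[1234] = False
        rms = np.sqrt(np.mean((out[mask] - base[mask]) ** 2))
        assert rms < 1e-2
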