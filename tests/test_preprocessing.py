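"""Filtering, normalization, segmentation and block-labeling behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from falldet.io_formats import AnnotatedTrial, RawTrial
from falldet.labels import ClassLabel
from falldet.preprocessing import (
    FilteringError,
    NormalizationStats,
    PreprocessConfig,
    butterworth_gain,
    label_block,
    lowpass_filter,
    normalize,
    segment_blocks,
)


def _trial(samples, labels=None, fs=200.0):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1:
        samples = samples.T
    raw = RawTrial(
        subject_id="SA01", subject_group="young", activity_code="D01",
        activity_class="ADL", trial_index=1, samples=samples,
        sample_rate_hz=fs,
    )
    if labels is None:
        labels = np.zeros(samples.shape[0], dtype=np.int8)
    return AnnotatedTrial(raw, labels)


class TestLowpassFilter:
    def test_unity_dc_gain_on_constant_signal(self):
        trial = _trial(np.full((500, 3), 2.5))
        out = lowpass_filter(trial, PreprocessConfig())
        np.testing.assert_allclose(out.trial.samples, 2.5, rtol=1e-9)

    def test_stopband_sinusoid_attenuated_per_closed_form(self):
        cfg = PreprocessConfig()  # 4th order, 5 Hz cutoff
        fs, f_sig = 200.0, 50.0
        t = np.arange(4000) / fs
        trial = _trial(np.sin(2 * np.pi * f_sig * t))
        out = lowpass_filter(trial, cfg).trial.samples[:, 0]
        # compare mid-section amplitude with the squared Butterworth response
        mid = out[1000:3000]
        expected = butterworth_gain(cfg, f_sig, fs)
        assert np.abs(mid).max() < 0.05          # < 5% of input amplitude
        assert np.abs(mid).max() == pytest.approx(expected, rel=0.5, abs=1e-6)

    def test_labels_and_length_untouched(self):
        labels = np.tile([0, 1, 2, 0], 100).astype(np.int8)
        trial = _trial(np.random.default_rng(0).normal(size=(400, 6)), labels)
        out = lowpass_filter(trial, PreprocessConfig())
        assert out.trial.n_samples == 400
        np.testing.assert_array_equal(out.labels, labels)

    def test_too_short_trial_raises(self):
        trial = _trial(np.ones((4, 3)))
        with pytest.raises(FilteringError):
            lowpass_filter(trial, PreprocessConfig(filter_order=4))


class TestNormalize:
    def _stats(self):
        tr = _trial(np.random.default_rng(1).normal(2.0, 3.0, size=(5000, 2)))
        return NormalizationStats.from_trials([tr]), tr

    def test_training_mean_maps_to_zero(self):
        stats, _ = self._stats()
        trial = _trial(np.tile(stats.mean, (100, 1)))
        out = normalize(trial, stats, PreprocessConfig())
        np.testing.assert_allclose(out.trial.samples, 0.0, atol=1e-12)

    def test_extreme_value_clips_to_one(self):
        stats, _ = self._stats()
        trial = _trial(np.tile(stats.mean + 10 * stats.std, (10, 1)))
        out = normalize(trial, stats, PreprocessConfig())
        np.testing.assert_allclose(out.trial.samples, 1.0)

    def test_minmax_endpoints(self):
        stats, _ = self._stats()
        cfg = PreprocessConfig(normalization="minmax")
        lo = normalize(_trial(np.tile(stats.minimum, (5, 1))), stats, cfg)
        hi = normalize(_trial(np.tile(stats.maximum, (5, 1))), stats, cfg)
        np.testing.assert_allclose(lo.trial.samples, -1.0)
        np.testing.assert_allclose(hi.trial.samples, 1.0)

    @pytest.mark.parametrize("mode", ["zscore_clip", "minmax", "zscore_tanh"])
    def test_output_always_within_unit_interval(self, mode):
        stats, _ = self._stats()
        x = np.random.default_rng(2).normal(0, 50, size=(300, 2))
        out = normalize(_trial(x), stats, PreprocessConfig(normalization=mode))
        assert out.trial.samples.min() >= -1.0
        assert out.trial.samples.max() <= 1.0

    def test_zero_std_channel_substitutes_unit_sigma(self):
        tr = _trial(np.column_stack([np.ones(100), np.arange(100.0)]))
        stats = NormalizationStats.from_trials([tr])
        assert stats.zero_std_channels == (0,)
        assert stats.std[0] == 1.0


class TestSegmentBlocks:
    def test_half_overlap_window_starts(self):
        labels = np.zeros(1024, dtype=np.int8)
        trial = _trial(np.zeros((1024, 6)), labels)
        blocks = segment_blocks(trial, PreprocessConfig())
        assert len(blocks) == 7
        assert [b.start_index for b in blocks] == [0, 128, 256, 384, 512, 640, 768]

    def test_exact_and_short_trials(self):
        cfg = PreprocessConfig()
        one = segment_blocks(_trial(np.zeros((256, 6))), cfg)
        none = segment_blocks(_trial(np.zeros((255, 6))), cfg)
        assert len(one) == 1 and one[0].start_index == 0
        assert none == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        T=st.integers(2, 700),
        W=st.integers(2, 300),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_window_count_matches_brute_force(self, T, W, overlap):
        cfg = PreprocessConfig(block_width=W, overlap_fraction=overlap)
        trial = _trial(np.zeros((T, 3)))
        got = [b.start_index for b in segment_blocks(trial, cfg)]
        stride = cfg.stride
        expected = [s for s in range(0, max(T - W + 1, 0), 1)
                    if s % stride == 0 and s + W <= T]
        assert got == expected

    def test_provenance_travels_with_blocks(self, small_cohort):
        cfg = PreprocessConfig()
        t = small_cohort.trials[0]
        for b in segment_blocks(t, cfg):
            assert b.subject_id == t.trial.subject_id
            assert b.source_trial == t.trial.trial_id


class TestLabelBlock:
    def test_majority_wins(self):
        window = np.array([2] * 200 + [1] * 56)
        assert label_block(window) is ClassLabel.FALL

    def test_tie_resolved_by_severity(self):
        window = np.array([2] * 128 + [0] * 128)
        assert label_block(window) is ClassLabel.FALL
        window = np.array([1] * 128 + [0] * 128)
        assert label_block(window) is ClassLabel.PRE_FALL

    def test_unanimous_window(self):
        assert label_block(np.zeros(256, dtype=int)) is ClassLabel.NON_FALL

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=64), st.randoms())
    def test_permutation_invariant(self, labels, pyrandom):
        before = label_block(np.asarray(labels))
        pyrandom.shuffle(labels)
        assert label_block(np.asarray(labels)) is before


def test_filter_commutes_with_segmentation(small_cohort):
    """Filtering is whole-trial, so filter-then-segment == segment windows
    of the filtered trial (same starts, same values)."""
    cfg = PreprocessConfig()
    trial = small_cohort.trials[1]
    filtered = lowpass_filter(trial, cfg)
    blocks = segment_blocks(filtered, cfg)
    for b in blocks:
        np.testing.assert_array_equal(
            b.samples, filtered.trial.samples[b.start_index:b.start_index + 256]
        )
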