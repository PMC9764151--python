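"""Preprocessing: FIR band-pass behaviour, automated QC, R-peak detection
against generator ground truth, beat segmentation geometry and potassium
labelling."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkecg.errors import InvalidArgumentError, MissingDataError
from hkecg.preprocess import (BEAT_LENGTH, FIDUCIAL_POSITION, FilterSpec, Label,
                              detect_rpeaks, extract_excerpt, fir_filter,
                              label_potassium, quality_check, segment_beats)
from hkecg.synthetic_cohort import (DEFAULT_TEMPLATE, generate_cohort,
                                    render_beat, r_sample_offset,
                                    separable_config)

FS = 125.0


def _sine(freq, seconds=30.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestFirFilter:
    def test_stopband_sine_attenuated(self):
        x = _sine(0.1)
        y = fir_filter(x, FS)
        # ignore edges; measure steady-state amplitude
        core = slice(x.size // 4, 3 * x.size // 4)
        assert np.max(np.abs(y[core])) < 0.1 * np.max(np.abs(x[core]))

    def test_passband_sine_preserved(self):
        x = _sine(10.0)
        y = fir_filter(x, FS)
        core = slice(x.size // 4, 3 * x.size // 4)
        assert np.max(np.abs(y[core])) > 0.9 * np.max(np.abs(x[core]))

    def test_zero_in_zero_out_and_length(self):
        x = np.zeros(1000)
        y = fir_filter(x, FS)
        assert y.shape == x.shape
        np.testing.assert_array_equal(y, 0.0)

    def test_band_must_fit_below_nyquist(self):
        with pytest.raises(InvalidArgumentError):
            fir_filter(np.ones(1000), 60.0, FilterSpec(low_hz=0.5, high_hz=40.0))

    def test_even_tap_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fir_filter(np.ones(1000), FS, FilterSpec(taps=256))


class TestQualityCheck:
    def test_clean_noiseless_record_passes(self):
        ((_, records),) = generate_cohort(
            separable_config(n_subjects=1, records_per_class=1, duration_s=20.0))
        assert quality_check(records[0].signal, FS).passed

    def test_flatline_fails_with_reason(self):
        result = quality_check(np.full(4000, 0.7), FS)
        assert not result.passed
        assert result.reason == "flat"

    def test_heavy_white_noise_fails_power_ratio(self):
        ((_, records),) = generate_cohort(
            separable_config(n_subjects=1, records_per_class=1, duration_s=20.0))
        x = records[0].signal
        rng = np.random.default_rng(0)
        noisy = x + rng.normal(0.0, 5.0 * np.std(x), x.size)
        result = quality_check(noisy, FS)
        assert not result.passed
        assert result.reason == "out_of_band_noise"

    def test_irregular_rhythm_fails_rr_cv(self):
        """Identical beats separated by wildly varying pauses (an AF-like
        irregular rhythm) trip the RR-regularity check."""
        rng = np.random.default_rng(1)
        beat = render_beat(DEFAULT_TEMPLATE, 0.0, 0.7, FS)
        chunks = []
        for _ in range(40):
            gap_n = int(rng.uniform(0.0, 1.2) * FS)
            t = np.arange(gap_n) / FS
            chunks.append(beat)
            chunks.append(0.05 * np.sin(2 * np.pi * 2.0 * t))  # non-flat gap
        x = np.concatenate(chunks)
        result = quality_check(x, FS)
        assert not result.passed
        assert result.reason == "irregular_rhythm"


class TestDetectRpeaks:
    def test_recall_precision_on_noiseless_cohort(self):
        """>= 0.99 recall and precision against generator ground truth."""
        cfg = separable_config(n_subjects=4, records_per_class=2,
                               duration_s=30.0)
        tp = fp = fn = 0
        for _, records in generate_cohort(cfg):
            for rec in records:
                detected = detect_rpeaks(fir_filter(rec.signal, FS), FS)
                truth = set(rec.r_peaks.tolist())
                matched = set()
                for d in detected:
                    hit = next((t for t in truth if abs(t - d) <= 2
                                and t not in matched), None)
                    if hit is None:
                        fp += 1
                    else:
                        matched.add(hit)
                        tp += 1
                fn += len(truth) - len(matched)
        assert tp / (tp + fp) >= 0.99
        assert tp / (tp + fn) >= 0.99

    def test_sixty_bpm_ten_seconds(self):
        tpl = DEFAULT_TEMPLATE
        beats = [render_beat(tpl, 0.0, 1.0, FS) for _ in range(10)]
        x = np.concatenate(beats)
        peaks = detect_rpeaks(fir_filter(x, FS), FS)
        assert abs(len(peaks) - 10) <= 1
        truth = [i * 125 + r_sample_offset(tpl, 1.0, FS) for i in range(10)]
        inner = [p for p in peaks if truth[0] <= p <= truth[-1] + 2]
        for p in inner:
            assert min(abs(p - t) for t in truth) <= 2

    def test_flatline_yields_no_peaks(self):
        assert detect_rpeaks(np.zeros(2000), FS).size == 0

    def test_single_centered_beat(self):
        beat = render_beat(DEFAULT_TEMPLATE, 0.0, 0.8, FS)
        pad = np.zeros(200)
        x = np.concatenate([pad, beat, pad])
        peaks = detect_rpeaks(x, FS)
        expected = 200 + r_sample_offset(DEFAULT_TEMPLATE, 0.8, FS)
        assert peaks.size == 1
        assert abs(int(peaks[0]) - expected) <= 2

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_rpeaks(np.ones(10), FS)


class TestSegmentBeats:
    def test_geometry_fixed_at_120_samples_fiducial_41(self):
        x = np.arange(1000, dtype=float)
        beats = segment_beats(x, np.array([100, 500]))
        for r, beat in zip((100, 500), beats):
            assert beat.samples.size == BEAT_LENGTH
            assert beat.r_position == FIDUCIAL_POSITION
            # 1-based position 41 holds the fiducial sample
            assert beat.samples[FIDUCIAL_POSITION - 1] == x[r]

    def test_boundary_rule_drops_edge_peaks(self):
        x = np.zeros(1000)
        assert segment_beats(x, np.array([10])) == []
        assert len(segment_beats(x, np.array([100, 500, 950]))) == 2

    def test_beat_count_bounded_by_peak_count(self):
        x = np.zeros(3000)
        rpeaks = np.arange(50, 2990, 97)
        assert len(segment_beats(x, rpeaks)) <= rpeaks.size

    def test_non_increasing_peaks_rejected(self):
        with pytest.raises(InvalidArgumentError):
            segment_beats(np.zeros(500), np.array([100, 100]))


class TestLabelPotassium:
    @pytest.mark.parametrize("potassium,expected", [
        (6.3, Label.HYPER),      # hyperkalemic class mean
        (4.3, Label.NORMO),      # normokalemic class mean
        (5.2, Label.EXCLUDED),   # inside the exclusion band
        (5.0, Label.NORMO),      # boundary: 5.0 still normokalemic
        (5.5, Label.EXCLUDED),   # boundary: "above 5.5" is strict
        (3.5, Label.NORMO),
        (3.2, Label.EXCLUDED),   # hypokalemia out of study scope
    ])
    def test_band_assignment(self, potassium, expected):
        assert label_potassium(potassium) is expected

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidArgumentError):
            label_potassium(-1.0)

    @given(st.floats(min_value=0.5, max_value=10.0))
    @settings(max_examples=200, derandomize=True)
    def test_label_partition_is_total_and_exclusive(self, potassium):
        labels = [label_potassium(potassium)]
        assert len(labels) == 1
        assert labels[0] in (Label.HYPER, Label.NORMO, Label.EXCLUDED)
        if labels[0] is Label.HYPER:
            assert potassium > 5.5
        if labels[0] is Label.NORMO:
            assert 3.5 <= potassium <= 5.0


class TestExtractExcerpt:
    def test_full_window(self):
        start = datetime(2020, 1, 1, 0, 0, 0)
        signal = np.arange(20 * 60 * int(FS), dtype=float)
        excerpt, short = extract_excerpt(signal, FS, start,
                                         start + timedelta(minutes=15))
        assert not short
        assert excerpt.size == int(600 * FS)
        assert excerpt[0] == signal[int(5 * 60 * FS)]

    def test_draw_before_recording_raises(self):
        start = datetime(2020, 1, 1, 12, 0, 0)
        with pytest.raises(MissingDataError):
            extract_excerpt(np.zeros(1000), FS, start,
                            start - timedelta(minutes=1))

    def test_short_coverage_flagged(self):
        start = datetime(2020, 1, 1, 0, 0, 0)
        signal = np.zeros(8 * 60 * int(FS))
        excerpt, short = extract_excerpt(signal, FS, start,
                                         start + timedelta(minutes=8))
        assert short
        assert excerpt.size == signal.size
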