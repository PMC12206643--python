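"""Feature-stage contracts: filter selectivity, the Gaussian DE law, grid
mapping conservation, 4D stacking, and per-subject normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfusion import (BandDefinition, RawRecording, assemble_4d,
                       bandpass_filter, compute_de_tensor, default_bands,
                       differential_entropy, extract_features, map_to_grid,
                       normalize_per_subject, segment_windows)
from eegfusion.errors import (DegenerateInputError, InsufficientWindowsError,
                              InvalidArgumentError, InvalidBandError,
                              MappingError)
from eegfusion.features4d import histogram_entropy, seed62_grid
from eegfusion.synthetic_eeg import SEED62_CHANNELS

HALF_LN_2PIE = 0.5 * math.log(2 * math.pi * math.e)


def _tone(freq, fs=200.0, duration=10.0, channels=2):
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (channels, 1))
    return RawRecording(data=data, fs=fs, channel_names=("C3", "C4")[:channels],
                        subject_id="S", label="x", trial_id="t")


def _fft_power(x):
    return float(np.sum(np.abs(np.fft.rfft(x)) ** 2))


class TestBandpassFilter:
    @pytest.mark.parametrize("band", default_bands(), ids=lambda b: b.name)
    def test_passband_tone_preserved(self, band):
        tone = _tone(0.5 * (band.low_hz + band.high_hz))
        out = bandpass_filter(tone, band)
        assert _fft_power(out.data[0]) >= 0.95 * _fft_power(tone.data[0])

    @pytest.mark.parametrize("band", default_bands(), ids=lambda b: b.name)
    def test_nonadjacent_band_suppressed(self, band):
        bands = default_bands()
        idx = [b.name for b in bands].index(band.name)
        for j, other in enumerate(bands):
            if abs(j - idx) < 2:
                continue
            tone = _tone(0.5 * (other.low_hz + other.high_hz))
            out = bandpass_filter(tone, band)
            assert _fft_power(out.data[0]) <= 0.01 * _fft_power(tone.data[0])

    def test_zero_signal_stays_zero(self):
        rec = _tone(10)
        rec = RawRecording(data=np.zeros_like(rec.data), fs=rec.fs,
                           channel_names=rec.channel_names, subject_id="S",
                           label="x", trial_id="t")
        out = bandpass_filter(rec, default_bands()[1])
        assert np.allclose(out.data, 0.0)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(InvalidBandError):
            bandpass_filter(_tone(10), BandDefinition("bad", 30, 120))

    def test_inverted_band_rejected(self):
        with pytest.raises(InvalidBandError):
            BandDefinition("bad", 13, 8)


class TestSegmentWindows:
    def test_window_counts(self):
        rec = _tone(10, fs=200, duration=60)
        assert segment_windows(rec, 1.0, 1.0).shape == (60, 2, 200)

    def test_overlapping_count(self):
        rec = _tone(10, fs=200, duration=10)
        # floor((2000 - 200) / 100) + 1
        assert segment_windows(rec, 1.0, 0.5).shape[0] == 19

    def test_values_preserved(self):
        rec = _tone(10, fs=200, duration=4)
        win = segment_windows(rec, 1.0, 1.0)
        assert np.array_equal(win[2], rec.data[:, 400:600])

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(InvalidArgumentError):
            segment_windows(_tone(10, duration=60), 70.0)


class TestDifferentialEntropy:
    def test_standard_normal_matches_closed_form(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        assert differential_entropy(x) == pytest.approx(HALF_LN_2PIE, abs=0.02)

    def test_scaling_adds_log_a_exactly(self):
        x = np.random.default_rng(1).standard_normal(500)
        assert differential_entropy(2 * x) - differential_entropy(x) == \
            pytest.approx(math.log(2), abs=1e-12)

    def test_histogram_oracle_agrees(self):
        x = np.random.default_rng(2).standard_normal(100_000)
        assert differential_entropy(x) == pytest.approx(
            histogram_entropy(x), abs=0.05)

    def test_constant_window_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            differential_entropy(np.full(100, 3.14))

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_scale(self, a):
        x = np.random.default_rng(3).standard_normal(200)
        de_x = differential_entropy(x)
        de_ax = differential_entropy(a * x)
        assert de_ax == pytest.approx(de_x + math.log(a), abs=1e-9)


class TestGridMapping:
    def test_seed62_occupancy(self):
        mask = seed62_grid().structural_mask()
        assert mask.sum() == 62
        assert (~mask).sum() == 10

    def test_single_channel_placement(self):
        grid = seed62_grid()
        out = map_to_grid(np.array([5.0]), ("CZ",), grid)
        r, c = grid.cell("CZ")
        assert out[r, c] == 5.0
        assert out.sum() == 5.0

    def test_sum_conservation(self, rng):
        vals = rng.standard_normal(62)
        out = map_to_grid(vals, SEED62_CHANNELS, seed62_grid())
        assert out.sum() == pytest.approx(vals.sum(), rel=1e-12)

    def test_unknown_channel_named_in_error(self):
        with pytest.raises(MappingError, match="XX"):
            map_to_grid(np.array([1.0]), ("XX",), seed62_grid())


class TestAssemble4D:
    def _de(self, n_windows):
        rng = np.random.default_rng(0)
        rec = RawRecording(
            data=rng.standard_normal((62, n_windows * 200)), fs=200.0,
            channel_names=SEED62_CHANNELS, subject_id="S", label="x",
            trial_id="t")
        return compute_de_tensor(rec, default_bands(), window_s=1.0)

    def test_sample_counts(self):
        de = self._de(12)
        assert len(assemble_4d(de, seed62_grid(), T=6, stride=1)) == 7
        assert len(assemble_4d(de, seed62_grid(), T=6, stride=6)) == 2

    def test_too_few_windows_rejected(self):
        with pytest.raises(InsufficientWindowsError):
            assemble_4d(self._de(5), seed62_grid(), T=6)

    def test_element_correspondence(self):
        de = self._de(8)
        grid = seed62_grid()
        samples = assemble_4d(de, grid, T=6, stride=1)
        r, c = grid.cell("CZ")
        ch = de.channel_names.index("CZ")
        # sample 1 starts at window 1; time step 2 is window 3, band 1
        assert samples[1].tensor[2, r, c, 1] == de.values[3, ch, 1]


class TestNormalization:
    def test_mean_zero_sd_one_per_subject(self, small_features):
        mask = small_features.structural_mask
        for sid in set(small_features.subjects):
            sel = small_features.subjects == sid
            cells = small_features.features[sel][:, :, mask, :]
            assert cells.mean() == pytest.approx(0.0, abs=1e-6)
            assert cells.std() == pytest.approx(1.0, abs=1e-6)

    def test_structural_zeros_preserved(self, small_features):
        mask = small_features.structural_mask
        assert np.all(small_features.features[:, :, ~mask, :] == 0.0)

    def test_single_sample_subject_rejected(self, small_features):
        from eegfusion import Feature4DSample
        s = Feature4DSample(tensor=small_features.features[0],
                            label="x", subject_id="only")
        with pytest.raises(InvalidArgumentError):
            normalize_per_subject([s], small_features.structural_mask)

    def test_constant_subject_rejected(self, small_features):
        from eegfusion import Feature4DSample
        ss = [Feature4DSample(tensor=np.zeros_like(small_features.features[0]),
                              label="x", subject_id="flat") for _ in range(3)]
        with pytest.raises(DegenerateInputError):
            normalize_per_subject(ss, small_features.structural_mask)


class TestExtractFeatures:
    def test_sample_shape(self, small_features):
        assert small_features.features.shape[1:] == (6, 8, 9, 4)

    def test_alpha_boost_raises_alpha_de(self, small_dataset):
        """Before normalization, the posterior-alpha-boosted class carries
        strictly higher mean alpha-band DE than the alpha-suppressed one —
        DE is monotone in band variance."""
        fs = extract_features(small_dataset, grid=seed62_grid(),
                              normalize=False)
        alpha = fs.band_names.index("alpha")
        pos = fs.features[fs.labels == fs.class_names.index("positive")]
        neg = fs.features[fs.labels == fs.class_names.index("negative")]
        mask = fs.structural_mask
        assert pos[:, :, mask, alpha].mean() > neg[:, :, mask, alpha].mean()

    def test_empty_dataset_gives_empty_set(self):
        fs = extract_features([])
        assert len(fs) == 0

    def test_pipeline_deterministic(self, small_dataset):
        a = extract_features(small_dataset, grid=seed62_grid())
        b = extract_features(small_dataset, grid=seed62_grid())
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)


class TestFeatureIO:
    def test_round_trip(self, small_features, tmp_path):
        from eegfusion.features4d import load_features, save_features
        path = tmp_path / "feats.h5"
        save_features(small_features, path)
        back = load_features(path)
        assert np.array_equal(back.features, small_features.features)
        assert np.array_equal(back.labels, small_features.labels)
        assert back.class_names == small_features.class_names
        assert np.array_equal(back.structural_mask,
                              small_features.structural_mask)
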