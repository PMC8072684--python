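"""Synthetic stream generation, segmentation regimes and dataset I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitceds import data as gdata
from gaitceds.data import (
    DatasetFormatError,
    GaitSample,
    InvalidConfigError,
    SegmentationConfig,
    SensorStream,
    SyntheticConfig,
    generate_streams,
    interpolate_to_length,
    load_dataset,
    save_dataset,
    segment_cycle_emulated,
    segment_fixed_length,
    split_stream_train_test,
)
from helpers import count_windows_bruteforce


def _stream(values, rate=50.0, subject=0, cadence=None):
    return SensorStream(values=values, rate_hz=rate, subject_id=subject,
                        cadence_hz=cadence)


class TestGenerateStreams:
    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(n_subjects=3, stream_seconds_per_subject=5.0, seed=7)
        a = generate_streams(cfg)
        b = generate_streams(cfg)
        for sa, sb in zip(a, b):
            assert sa.values.tobytes() == sb.values.tobytes()
            assert sa.cadence_hz == sb.cadence_hz

    def test_different_seeds_differ(self):
        base = dict(n_subjects=2, stream_seconds_per_subject=5.0)
        a = generate_streams(SyntheticConfig(seed=1, **base))
        b = generate_streams(SyntheticConfig(seed=2, **base))
        assert not np.array_equal(a[0].values, b[0].values)

    def test_stream_count_and_length(self):
        cfg = SyntheticConfig(n_subjects=10, stream_seconds_per_subject=60.0,
                              rate_hz=50.0)
        streams = generate_streams(cfg)
        assert len(streams) == 10
        assert all(s.values.shape == (6, 3000) for s in streams)
        assert [s.subject_id for s in streams] == list(range(10))

    def test_noiseless_streams_are_periodic(self):
        # without noise each channel repeats at the subject's gait period:
        # autocorrelation at the period lag stays near the zero-lag peak
        cfg = SyntheticConfig(n_subjects=3, stream_seconds_per_subject=30.0,
                              rate_hz=200.0, noise_sd=0.0, seed=3)
        for s in generate_streams(cfg):
            period = int(round(s.rate_hz / s.cadence_hz))
            for row in s.values:
                r = np.corrcoef(row[:-period], row[period:])[0, 1]
                assert r > 0.95

    @pytest.mark.parametrize("bad", [
        dict(n_subjects=1),
        dict(stream_seconds_per_subject=0.0),
        dict(rate_hz=-50.0),
        dict(noise_sd=-0.1),
        dict(n_harmonics=0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(**bad)


class TestFixedLengthSegmentation:
    @pytest.mark.parametrize("n_t,overlap,expected", [
        (3000, 0.50, 45),   # stride 64
        (128, 0.00, 1),
        (128, 0.50, 1),
        (256, 0.00, 2),
        (127, 0.00, 0),     # shorter than one window: empty, not an error
    ])
    def test_window_counts(self, rng, n_t, overlap, expected):
        stream = _stream(rng.normal(size=(6, n_t)))
        seg = SegmentationConfig(window_len=128, overlap_fraction=overlap)
        assert len(segment_fixed_length(stream, seg)) == expected

    def test_full_length_window_is_identity(self, rng):
        stream = _stream(rng.normal(size=(6, 128)))
        out = segment_fixed_length(stream, SegmentationConfig(overlap_fraction=0.5))
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].values, stream.values)

    def test_zero_overlap_windows_tile_the_stream(self, rng):
        stream = _stream(rng.normal(size=(6, 256)))
        out = segment_fixed_length(stream, SegmentationConfig())
        np.testing.assert_array_equal(out[0].values, stream.values[:, :128])
        np.testing.assert_array_equal(out[1].values, stream.values[:, 128:])

    def test_all_windows_carry_subject_id(self, rng):
        stream = _stream(rng.normal(size=(6, 1000)), subject=4)
        out = segment_fixed_length(stream, SegmentationConfig(overlap_fraction=0.5))
        assert all(s.subject_id == 4 for s in out)

    def test_degenerate_stride_rejected(self):
        with pytest.raises(InvalidConfigError):
            seg = SegmentationConfig(window_len=2, overlap_fraction=0.9)
            segment_fixed_length(_stream(np.zeros((6, 10))), seg)

    @given(
        n_t=st.integers(min_value=1, max_value=10_000),
        window_len=st.integers(min_value=2, max_value=512),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.61, 0.75]),
    )
    @settings(max_examples=200, deadline=None)
    def test_window_count_matches_enumeration(self, n_t, window_len, overlap):
        stride = int(round(window_len * (1.0 - overlap)))
        if stride < 1:
            return
        assert gdata.n_fixed_windows(n_t, window_len, stride) == \
            count_windows_bruteforce(n_t, window_len, stride)


class TestInterpolateToLength:
    def test_identity_at_target_length(self, rng):
        seg = rng.normal(size=(6, 128))
        np.testing.assert_array_equal(interpolate_to_length(seg), seg)

    def test_affine_rows_are_exact(self):
        for length in (3, 50, 200, 500):
            row = 2.5 * np.arange(length) - 7.0
            out = interpolate_to_length(np.tile(row, (6, 1)))
            expected = 2.5 * np.linspace(0, length - 1, 128) - 7.0
            np.testing.assert_allclose(out, np.tile(expected, (6, 1)), atol=1e-9)

    def test_triangle_closed_form(self):
        # row (0, 1, 0): piecewise-linear hat over index range [0, 2]
        seg = np.tile([0.0, 1.0, 0.0], (6, 1))
        out = interpolate_to_length(seg)
        g = np.linspace(0.0, 2.0, 128)
        expected = np.where(g <= 1.0, g, 2.0 - g)
        np.testing.assert_allclose(out, np.tile(expected, (6, 1)), atol=1e-12)
        assert out[0, 0] == 0.0 and out[0, -1] == 0.0

    def test_too_short_input_rejected(self):
        with pytest.raises(InvalidConfigError):
            interpolate_to_length(np.zeros((6, 1)))


class TestCycleEmulatedSegmentation:
    def test_two_cycle_spans_from_cadence(self, rng):
        # period 100 samples at 100 Hz / 1.0 Hz cadence, T=1000 -> 5 spans
        stream = _stream(rng.normal(size=(6, 1000)), rate=100.0, cadence=1.0)
        seg = SegmentationConfig(mode="cycle_emulated")
        out = segment_cycle_emulated(stream, seg)
        assert len(out) == 5
        assert all(s.values.shape == (6, 128) for s in out)
        np.testing.assert_allclose(
            out[0].values, interpolate_to_length(stream.values[:, :200])
        )

    def test_half_overlap_doubles_count_minus_one(self, rng):
        stream = _stream(rng.normal(size=(6, 1000)), rate=100.0, cadence=1.0)
        n0 = len(segment_cycle_emulated(stream, SegmentationConfig(mode="cycle_emulated")))
        n5 = len(segment_cycle_emulated(
            stream, SegmentationConfig(mode="cycle_emulated", overlap_fraction=0.5)))
        assert n5 == 2 * n0 - 1

    def test_exact_window_needs_no_resampling(self, rng):
        # period 64 and T=128: one span, 128 -> 128 resampling is identity
        stream = _stream(rng.normal(size=(6, 128)), rate=64.0, cadence=1.0)
        out = segment_cycle_emulated(stream, SegmentationConfig(mode="cycle_emulated"))
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].values, stream.values)

    def test_missing_cycle_information_rejected(self, rng):
        stream = _stream(rng.normal(size=(6, 1000)))
        with pytest.raises(InvalidConfigError, match="cadence"):
            segment_cycle_emulated(stream, SegmentationConfig(mode="cycle_emulated"))

    def test_explicit_boundaries(self, rng):
        stream = _stream(rng.normal(size=(6, 600)))
        out = segment_cycle_emulated(
            stream, SegmentationConfig(mode="cycle_emulated"),
            cycle_boundaries=[0, 90, 210, 300, 410, 500],
        )
        assert len(out) == 2  # spans [0,210) and [210,410)
        np.testing.assert_allclose(
            out[1].values, interpolate_to_length(stream.values[:, 210:410])
        )


class TestTrainTestSeparation:
    def test_windows_never_overlap_across_split(self, rng):
        stream = _stream(rng.normal(size=(6, 4000)))
        train, test = split_stream_train_test(stream, test_fraction=0.25)
        seg = SegmentationConfig(overlap_fraction=0.5)
        n_train = len(segment_fixed_length(train, seg))
        stride, length = seg.stride, seg.window_len
        # absolute index ranges: train windows end before the cut,
        # test windows start at it
        cut = train.n_samples
        last_train_end = (n_train - 1) * stride + length
        assert last_train_end <= cut
        np.testing.assert_array_equal(test.values, stream.values[:, cut:])


class TestDatasetIO:
    def test_npz_round_trip(self, rng, tmp_path):
        samples = [GaitSample(values=rng.normal(size=(6, 128)), subject_id=i % 5)
                   for i in range(100)]
        path = tmp_path / "set.npz"
        save_dataset(path, samples)
        loaded = load_dataset(path)
        assert len(loaded) == 100
        for a, b in zip(samples, loaded):
            np.testing.assert_allclose(a.values, b.values, atol=1e-6)
            assert a.subject_id == b.subject_id

    def test_save_empty_rejected(self, tmp_path):
        with pytest.raises(InvalidConfigError):
            save_dataset(tmp_path / "x.npz", [])

    def test_text_round_trip_with_sidecar(self, rng, tmp_path):
        stream = _stream(rng.normal(size=(6, 50)), subject=3)
        path = tmp_path / "rec.txt"
        gdata.write_text_stream(path, stream)
        sidecar = tmp_path / "labels.txt"
        sidecar.write_text("0 30 3\n30 50 4\n")
        streams = gdata.read_text_stream(path, rate_hz=50.0, sidecar=sidecar)
        assert [s.subject_id for s in streams] == [3, 4]
        np.testing.assert_allclose(streams[0].values, stream.values[:, :30], rtol=1e-6)

    def test_malformed_row_cites_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1 2 3 4 5 6\n1 2 3 4 5\n")
        with pytest.raises(DatasetFormatError, match="line 2"):
            gdata.read_text_stream(path, rate_hz=50.0)

    def test_bad_sidecar_span_rejected(self, rng, tmp_path):
        path = tmp_path / "rec.txt"
        gdata.write_text_stream(path, _stream(rng.normal(size=(6, 20))))
        sidecar = tmp_path / "labels.txt"
        sidecar.write_text("0 30 1\n")
        with pytest.raises(DatasetFormatError, match="outside"):
            gdata.read_text_stream(path, rate_hz=50.0, sidecar=sidecar)


class TestTypeInvariants:
    def test_stream_requires_six_rows(self):
        with pytest.raises(InvalidConfigError):
            SensorStream(values=np.zeros((5, 100)), rate_hz=50.0, subject_id=0)

    def test_sample_requires_6x128_finite(self):
        with pytest.raises(InvalidConfigError):
            GaitSample(values=np.zeros((6, 100)), subject_id=0)
        bad = np.zeros((6, 128))
        bad[0, 0] = np.nan
        with pytest.raises(InvalidConfigError):
            GaitSample(values=bad, subject_id=0)

    def test_overlap_bounds(self):
        with pytest.raises(InvalidConfigError):
            SegmentationConfig(overlap_fraction=1.0)
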