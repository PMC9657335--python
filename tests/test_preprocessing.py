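"""Signal conditioning: filters, segmentation, balancing, scaling, split."""

import numpy as np
import pytest
from scipy import signal as sps

from emglesion.preprocessing import (
    FilterSpec,
    SegmentDataset,
    balance_oversample,
    bandpass_filter,
    minmax_normalize,
    notch_filter,
    segment_signal,
    split_train_test,
)

FS = 1000.0


def sine(freq, fs=FS, duration=10.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def interior_rms_ratio(out, ref):
    """RMS ratio over the interior 80 % of samples (edge transients excluded)."""
    n = len(out)
    sl = slice(n // 10, n - n // 10)
    return np.sqrt(np.mean(out[sl] ** 2)) / np.sqrt(np.mean(ref[sl] ** 2))


def analytic_bandpass_gain(freq, spec=FilterSpec(), fs=FS):
    """|H|^2 of the Butterworth band-pass (forward-backward squares |H|)."""
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq / fs])
    return np.abs(h[0]) ** 2


class TestBandpass:
    def test_zero_input(self):
        assert np.allclose(bandpass_filter(np.zeros(2000), FS), 0.0)

    def test_passband_100hz(self):
        x = sine(100)
        ratio = interior_rms_ratio(bandpass_filter(x, FS), x)
        assert 0.95 <= ratio <= 1.05
        assert analytic_bandpass_gain(100) == pytest.approx(1.0, abs=0.01)

    def test_stopband_1hz(self):
        x = sine(1)
        assert interior_rms_ratio(bandpass_filter(x, FS), x) < 0.05
        assert analytic_bandpass_gain(1) < 0.05

    def test_same_length(self):
        x = np.random.default_rng(0).normal(size=1234)
        assert len(bandpass_filter(x, FS)) == 1234

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(2000), 800.0)


class TestNotch:
    def test_zero_input(self):
        assert np.allclose(notch_filter(np.zeros(2000), FS), 0.0)

    def test_rejects_60hz(self):
        x = sine(60)
        assert interior_rms_ratio(notch_filter(x, FS), x) < 0.1

    def test_passes_30hz(self):
        x = sine(30)
        ratio = interior_rms_ratio(notch_filter(x, FS), x)
        assert 0.9 <= ratio <= 1.1

    def test_analytic_response(self):
        b, a = sps.iirnotch(60.0, 30.0, fs=FS)
        _, h60 = sps.freqz(b, a, worN=[2 * np.pi * 60 / FS])
        _, h30 = sps.freqz(b, a, worN=[2 * np.pi * 30 / FS])
        assert np.abs(h60[0]) ** 2 < 0.01
        assert np.abs(h30[0]) ** 2 > 0.9


def test_zero_phase_no_lag():
    """Cross-correlation of a 50 Hz sine with its filtered version peaks at lag 0."""
    x = sine(50, duration=2.0)
    y = bandpass_filter(x, FS)
    n = len(x)
    sl = slice(n // 10, n - n // 10)
    lags = np.arange(-5, 6)
    corr = [np.dot(x[sl], np.roll(y, lag)[sl]) for lag in lags]
    assert lags[int(np.argmax(corr))] == 0


class TestSegmentation:
    @pytest.mark.parametrize(
        "length,window,rows", [(5000, 1000, 5), (2500, 1000, 2), (999, 1000, 0)]
    )
    def test_floor_rule(self, length, window, rows):
        out = segment_signal(np.arange(length, dtype=float), window)
        assert out.shape == (rows, window)

    def test_rows_concatenate_to_prefix(self):
        x = np.random.default_rng(1).normal(size=2500)
        rows = segment_signal(x, 1000)
        np.testing.assert_array_equal(rows.ravel(), x[:2000])

    def test_bad_window(self):
        with pytest.raises(ValueError):
            segment_signal(np.zeros(10), 0)


class TestOversample:
    def test_equalizes_counts(self):
        seg = np.arange(8, dtype=float).reshape(8, 1)
        lab = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        out_seg, out_lab = balance_oversample(seg, lab, seed=0)
        assert len(out_lab) == 10
        assert (out_lab == 0).sum() == (out_lab == 1).sum() == 5

    def test_already_balanced_unchanged(self):
        seg = np.arange(8, dtype=float).reshape(8, 1)
        lab = np.array([0, 1] * 4)
        out_seg, out_lab = balance_oversample(seg, lab, seed=0)
        np.testing.assert_array_equal(out_seg, seg)
        np.testing.assert_array_equal(out_lab, lab)

    def test_originals_preserved_and_duplicates_from_minority(self):
        rng = np.random.default_rng(2)
        seg = rng.normal(size=(202, 4))
        lab = np.array([0] * 2 + [1] * 200)
        out_seg, out_lab = balance_oversample(seg, lab, seed=3)
        # all original rows appear (prefix is the original data)
        np.testing.assert_array_equal(out_seg[:202], seg)
        # every appended row equals one of the two original minority rows
        for row in out_seg[202:]:
            assert any(np.array_equal(row, seg[i]) for i in range(2))
        assert (out_lab[202:] == 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_oversample(np.zeros((3, 2)), np.array([1, 1, 1]))

    def test_seed_determinism(self):
        seg = np.random.default_rng(0).normal(size=(10, 3))
        lab = np.array([0] * 3 + [1] * 7)
        a = balance_oversample(seg, lab, seed=5)
        b = balance_oversample(seg, lab, seed=5)
        np.testing.assert_array_equal(a[0], b[0])


class TestMinMaxNormalize:
    def test_affine_identity(self):
        np.testing.assert_allclose(
            minmax_normalize(np.array([-1.0, 0.0, 1.0])), [0.0, 0.5, 1.0]
        )

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(
            minmax_normalize(np.array([5.0, 5.0, 5.0])), np.zeros(3)
        )

    def test_direct_evaluation(self):
        np.testing.assert_allclose(
            minmax_normalize(np.array([2.0, 4.0, 6.0, 8.0])),
            [0.0, 1 / 3, 2 / 3, 1.0],
        )

    def test_matrix_rows_independent(self):
        m = np.array([[0.0, 2.0], [10.0, 30.0]])
        out = minmax_normalize(m)
        np.testing.assert_allclose(out, [[0.0, 1.0], [0.0, 1.0]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.empty(0))


class TestSplit:
    def make_dataset(self, n0=50, n1=50):
        rng = np.random.default_rng(7)
        labels = np.array([0] * n0 + [1] * n1)
        return SegmentDataset(rng.normal(size=(n0 + n1, 10)), labels, 10)

    def test_sizes_stratified(self):
        train, test = split_train_test(self.make_dataset(), 0.2, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert (test.labels == 0).sum() == 10 and (test.labels == 1).sum() == 10

    def test_partition_exact(self):
        ds = self.make_dataset(30, 40)
        train, test = split_train_test(ds, 0.2, seed=1)
        combined = np.concatenate([train.segments, test.segments])
        # every input row appears exactly once across the two outputs
        assert combined.shape[0] == len(ds)
        all_rows = {tuple(r) for r in ds.segments}
        out_rows = {tuple(r) for r in combined}
        assert all_rows == out_rows

    def test_seed_determinism(self):
        ds = self.make_dataset()
        a_train, a_test = split_train_test(ds, 0.2, seed=3)
        b_train, b_test = split_train_test(ds, 0.2, seed=3)
        np.testing.assert_array_equal(a_train.segments, b_train.segments)
        np.testing.assert_array_equal(a_test.segments, b_test.segments)

    def test_bad_fraction_and_tiny_class(self):
        ds = self.make_dataset()
        with pytest.raises(ValueError):
            split_train_test(ds, 0.0)
        tiny = SegmentDataset(np.zeros((3, 2)), np.array([0, 1, 1]), 2)
        with pytest.raises(ValueError):
            split_train_test(tiny, 0.5)


def test_preprocess_recordings_contract(small_split):
    train, test = small_split
    for ds in (train, test):
        assert ds.segments.shape[1] == 1000
        assert ds.segments.min() >= 0.0 and ds.segments.max() <= 1.0
        assert set(np.unique(ds.labels)) <= {0, 1}
    # balanced overall
    labels = np.concatenate([train.labels, test.labels])
    assert (labels == 0).sum() == (labels == 1).sum()


def test_dataset_npz_roundtrip(tmp_path, toy_dataset):
    path = tmp_path / "ds.npz"
    toy_dataset.save(path)
    back = SegmentDataset.load(path)
    np.testing.assert_array_equal(back.segments, toy_dataset.segments)
    np.testing.assert_array_equal(back.labels, toy_dataset.labels)
    assert back.window_length == toy_dataset.window_length
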