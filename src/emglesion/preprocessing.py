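"""Signal conditioning and dataset preparation.

The conditioning chain, in order: zero-phase band-pass filtering
(fourth-order Butterworth, 10–450 Hz), zero-phase 60 Hz notch filtering,
segmentation into disjoint 1000 ms windows, class balancing by random
over-sampling of the minority class, per-segment min–max normalization to
[0, 1], and a stratified 80:20 train/test split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .synthetic import EMGRecording

__all__ = [
    "FilterSpec",
    "SegmentDataset",
    "bandpass_filter",
    "notch_filter",
    "segment_signal",
    "balance_oversample",
    "minmax_normalize",
    "split_train_test",
    "preprocess_recordings",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch filter parameters.

    ``order`` is the Butterworth prototype order passed to the band-pass
    design (the MATLAB ``butter(4, ...)`` idiom).  Both filters are applied
    forward and backward (zero net phase).  The notch quality factor of 30
    gives a narrow stop band that leaves neighbouring frequencies intact.
    """

    order: int = 4
    low_hz: float = 10.0
    high_hz: float = 450.0
    notch_hz: float = 60.0
    notch_q: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be > 0")


def _check_nyquist(fs: float, high_hz: float) -> None:
    if fs <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {fs} Hz violates the Nyquist requirement: "
            f"must exceed twice the {high_hz} Hz upper band edge"
        )


def bandpass_filter(
    samples: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter (forward–backward)."""
    _check_nyquist(fs, spec.high_hz)
    samples = np.asarray(samples, dtype=float)
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, samples)
    return sps.sosfilt(sos, samples)


def notch_filter(
    samples: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase 60 Hz notch filter (forward–backward) for line noise."""
    _check_nyquist(fs, spec.high_hz)
    samples = np.asarray(samples, dtype=float)
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    if spec.zero_phase:
        return sps.filtfilt(b, a, samples)
    return sps.lfilter(b, a, samples)


def segment_signal(samples: np.ndarray, window_length: int) -> np.ndarray:
    """Cut a signal into disjoint consecutive windows of ``window_length``.

    Returns ``floor(len(samples) / window_length)`` rows; the trailing
    remainder shorter than one window is discarded.
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    samples = np.asarray(samples, dtype=float)
    n_rows = len(samples) // window_length
    return samples[: n_rows * window_length].reshape(n_rows, window_length).copy()


@dataclass
class SegmentDataset:
    """Fixed-length segments with labels and per-segment provenance.

    ``source_index`` holds one ``(recording_id, offset)`` pair per row, so
    every segment can be traced back to its source recording and sample
    offset (over-sampled duplicates share the provenance of their original).
    """

    segments: np.ndarray
    labels: np.ndarray
    window_length: int
    source_index: np.ndarray = field(default=None)  # (n, 2) int

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.segments.ndim != 2 or self.segments.shape[1] != self.window_length:
            raise ValueError("segments must be (n, window_length)")
        if len(self.labels) != len(self.segments):
            raise ValueError("labels length must match segments")
        if self.source_index is None:
            self.source_index = np.full((len(self.labels), 2), -1, dtype=int)
        self.source_index = np.asarray(self.source_index, dtype=int)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices: np.ndarray) -> "SegmentDataset":
        indices = np.asarray(indices)
        return SegmentDataset(
            self.segments[indices],
            self.labels[indices],
            self.window_length,
            self.source_index[indices],
        )

    def save(self, path) -> None:
        np.savez(
            path,
            segments=self.segments,
            labels=self.labels,
            window_length=self.window_length,
            source_index=self.source_index,
        )

    @classmethod
    def load(cls, path) -> "SegmentDataset":
        with np.load(path) as z:
            return cls(
                z["segments"],
                z["labels"],
                int(z["window_length"]),
                z["source_index"],
            )


def balance_oversample(
    segments: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    source_index: Optional[np.ndarray] = None,
):
    """Equalize class counts by random over-sampling of the minority class.

    All original rows are kept; duplicates are drawn uniformly with
    replacement from the minority class and appended.  Deterministic under
    ``seed``.  Returns ``(segments, labels)`` or
    ``(segments, labels, source_index)`` when provenance is supplied.
    """
    segments = np.asarray(segments)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        extra_idx = np.empty(0, dtype=int)
    else:
        rng = np.random.default_rng(seed)
        minority_rows = np.flatnonzero(labels == minority)
        extra_idx = rng.choice(minority_rows, size=deficit, replace=True)
    out_segments = np.concatenate([segments, segments[extra_idx]])
    out_labels = np.concatenate([labels, labels[extra_idx]])
    if source_index is not None:
        source_index = np.asarray(source_index)
        return out_segments, out_labels, np.concatenate(
            [source_index, source_index[extra_idx]]
        )
    return out_segments, out_labels


def minmax_normalize(segment: np.ndarray) -> np.ndarray:
    """Min–max normalize to [0, 1]; a constant segment maps to all zeros.

    Accepts a 1-D segment or a 2-D matrix of segments (normalized per row).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("segment must be non-empty")
    if segment.ndim == 1:
        lo, hi = segment.min(), segment.max()
        if hi == lo:
            return np.zeros_like(segment)
        return (segment - lo) / (hi - lo)
    lo = segment.min(axis=1, keepdims=True)
    hi = segment.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (segment - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


def split_train_test(
    dataset: SegmentDataset, test_fraction: float = 0.2, seed: int = 0
):
    """Stratified random split into disjoint, exhaustive train/test sets.

    Per class, ``round(test_fraction * n_class)`` rows go to the test set.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = dataset.labels
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        if len(rows) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        perm = rng.permutation(rows)
        n_test = int(round(test_fraction * len(rows)))
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return dataset.subset(train), dataset.subset(test)


def preprocess_recordings(
    recordings: Sequence[EMGRecording],
    spec: FilterSpec = FilterSpec(),
    window_length: int = 1000,
    test_fraction: float = 0.2,
    seed: int = 0,
    split_by_recording: bool = False,
) -> tuple[SegmentDataset, SegmentDataset]:
    """Run the full conditioning chain and return (train, test) datasets.

    Order of operations: filter -> segment -> balance -> normalize -> split.
    With ``split_by_recording`` the split keeps all segments of a recording
    on the same side (leakage-free evaluation); the default splits at the
    segment level.
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    fs0 = recordings[0].sampling_rate
    all_segments, all_labels, provenance = [], [], []
    for rec_id, rec in enumerate(recordings):
        if rec.sampling_rate != fs0:
            raise ValueError("mismatched sampling rates are not resampled")
        filtered = bandpass_filter(rec.samples, rec.sampling_rate, spec)
        filtered = notch_filter(filtered, rec.sampling_rate, spec)
        rows = segment_signal(filtered, window_length)
        for j in range(len(rows)):
            provenance.append((rec_id, j * window_length))
        all_segments.append(rows)
        all_labels.extend([int(rec.label)] * len(rows))
    segments = np.concatenate(all_segments)
    labels = np.asarray(all_labels, dtype=int)
    source_index = np.asarray(provenance, dtype=int)

    segments, labels, source_index = balance_oversample(
        segments, labels, seed=seed, source_index=source_index
    )
    segments = minmax_normalize(segments)
    dataset = SegmentDataset(segments, labels, window_length, source_index)

    if split_by_recording:
        return _split_by_recording(dataset, test_fraction, seed)
    return split_train_test(dataset, test_fraction, seed)


def _split_by_recording(dataset: SegmentDataset, test_fraction: float, seed: int):
    """Group-aware split: whole recordings assigned to train or test."""
    rng = np.random.default_rng(seed)
    rec_ids = dataset.source_index[:, 0]
    test_rows: list[int] = []
    train_rows: list[int] = []
    for cls in np.unique(dataset.labels):
        cls_recs = np.unique(rec_ids[dataset.labels == cls])
        perm = rng.permutation(cls_recs)
        n_test = max(1, int(round(test_fraction * len(cls_recs))))
        test_recs = set(perm[:n_test].tolist())
        for i in np.flatnonzero(dataset.labels == cls):
            (test_rows if rec_ids[i] in test_recs else train_rows).append(i)
    return dataset.subset(np.sort(train_rows)), dataset.subset(np.sort(test_rows))
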