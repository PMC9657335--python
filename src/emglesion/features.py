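"""Hand-crafted EMG amplitude features for the kNN arm.

Four classical time-domain features per segment, in fixed column order:
area (integrated rectified value), root mean square, turn count and
zero-crossing count.  Feature scaling is z-score standardization followed
by min–max rescaling to [0, 1], both fitted on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocessing import SegmentDataset

__all__ = [
    "FEATURE_NAMES",
    "FeatureScaling",
    "FeatureMatrix",
    "feature_area",
    "feature_rms",
    "feature_zero_crossings",
    "feature_turns",
    "extract_features",
    "build_feature_matrix",
    "default_turns_threshold",
]

FEATURE_NAMES = ("area", "rms", "turns", "zero_crossings")


def _as_segment(segment) -> np.ndarray:
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("segment must be non-empty")
    return segment


def feature_area(segment) -> float:
    """Integrated rectified value: sum of absolute sample values."""
    return float(np.abs(_as_segment(segment)).sum())


def feature_rms(segment) -> float:
    """Root mean square of the samples."""
    x = _as_segment(segment)
    return float(np.sqrt(np.mean(x * x)))


def feature_zero_crossings(segment, threshold: float = 0.0) -> int:
    """Count thresholded sign changes between adjacent samples.

    A pair ``(x_i, x_{i+1})`` counts when the signs differ and
    ``|x_i - x_{i+1}| > threshold``.  Exact zeros carry the previous
    nonzero sign, so touching zero without crossing does not count.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        return 0
    signs = np.sign(x)
    # propagate the previous nonzero sign onto exact zeros (vectorized ffill)
    nonzero = signs != 0
    idx = np.where(nonzero, np.arange(len(signs)), -1)
    idx = np.maximum.accumulate(idx)
    signs = np.where(idx >= 0, signs[np.maximum(idx, 0)], 0.0)
    flips = signs[:-1] * signs[1:] < 0
    big = np.abs(np.diff(x)) > threshold
    return int(np.count_nonzero(flips & big))


def feature_turns(segment, threshold: float = 0.0) -> int:
    """Count local extrema whose amplitude change exceeds ``threshold``.

    Classical turns analysis: an interior sample where the slope changes
    sign is a candidate turn; it counts when its amplitude differs from the
    previously counted turn (or the segment start) by more than the
    threshold.  On physical units the classical Willison threshold is
    100 µV; on min–max normalized segments the default used by the pipeline
    is 0.1 x the training amplitude range.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        return 0
    d = np.diff(x)
    count = 0
    reference = x[0]
    for i in range(1, len(x) - 1):
        if d[i - 1] * d[i] < 0:  # slope sign change: local extremum
            if abs(x[i] - reference) > threshold:
                count += 1
                reference = x[i]
    return count


def default_turns_threshold(train_segments: np.ndarray) -> float:
    """0.1 x the overall amplitude range of the training segments."""
    train_segments = np.asarray(train_segments)
    return 0.1 * float(train_segments.max() - train_segments.min())


def extract_features(
    segments: np.ndarray,
    turns_threshold: float = 0.1,
    zc_threshold: float = 0.0,
) -> np.ndarray:
    """Raw (unscaled) feature matrix: one row per segment, 4 columns."""
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    out = np.empty((len(segments), 4))
    for i, seg in enumerate(segments):
        out[i, 0] = feature_area(seg)
        out[i, 1] = feature_rms(seg)
        out[i, 2] = feature_turns(seg, turns_threshold)
        out[i, 3] = feature_zero_crossings(seg, zc_threshold)
    return out


@dataclass
class FeatureScaling:
    """Per-column scaling parameters fitted on training rows only.

    ``mean``/``std`` are the z-score parameters; ``zmin``/``zmax`` the
    min–max extremes of the standardized training values.
    """

    mean: np.ndarray
    std: np.ndarray
    zmin: np.ndarray
    zmax: np.ndarray

    @classmethod
    def fit(cls, raw: np.ndarray) -> "FeatureScaling":
        mean = raw.mean(axis=0)
        std = raw.std(axis=0)  # population std: {1, 3} -> {-1, +1}
        degenerate = std == 0
        if degenerate.any():
            names = [FEATURE_NAMES[i] for i in np.flatnonzero(degenerate)]
            warnings.warn(
                f"zero-variance feature column(s) {names}: mapped to 0",
                stacklevel=3,
            )
        safe_std = np.where(degenerate, 1.0, std)
        z = (raw - mean) / safe_std
        zmin = z.min(axis=0)
        zmax = z.max(axis=0)
        return cls(mean=mean, std=std, zmin=zmin, zmax=zmax)

    def transform(self, raw: np.ndarray) -> np.ndarray:
        degenerate = self.std == 0
        safe_std = np.where(degenerate, 1.0, self.std)
        z = (raw - self.mean) / safe_std
        span = self.zmax - self.zmin
        safe_span = np.where(span == 0, 1.0, span)
        scaled = (z - self.zmin) / safe_span
        scaled[:, degenerate | (span == 0)] = 0.0
        return scaled


@dataclass
class FeatureMatrix:
    """Scaled per-segment feature table plus the scaling that produced it."""

    values: np.ndarray  # (n, 4)
    scaling: FeatureScaling
    labels: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.values)


def build_feature_matrix(
    dataset: SegmentDataset,
    thresholds: tuple[float, float] | None = None,
    scaling: Optional[FeatureScaling] = None,
) -> FeatureMatrix:
    """Compute scaled features for a dataset.

    With ``scaling=None`` the scaling is fitted on these rows (training
    usage); otherwise the supplied training scaling is applied, so test
    values may fall outside [0, 1].  ``thresholds`` is
    ``(turns_threshold, zc_threshold)``; by default the turns threshold is
    0.1 x the dataset amplitude range and the zero-crossing threshold 0.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if thresholds is None:
        thresholds = (default_turns_threshold(dataset.segments), 0.0)
    raw = extract_features(dataset.segments, *thresholds)
    if scaling is None:
        scaling = FeatureScaling.fit(raw)
    return FeatureMatrix(
        values=scaling.transform(raw), scaling=scaling, labels=dataset.labels.copy()
    )


def export_csv(fm: FeatureMatrix, path) -> None:
    """Write the feature table as CSV: area,rms,turns,zero_crossings,label."""
    import pandas as pd

    df = pd.DataFrame(fm.values, columns=list(FEATURE_NAMES))
    if fm.labels is not None:
        df["label"] = fm.labels
    df.to_csv(path, index=False)
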