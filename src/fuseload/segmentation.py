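"""Marker-driven segmentation of multi-stream recordings.

Usable markers are selected with Boolean masks; for each surviving marker
an 8-second window of data *preceding* the marker is cut from every
stream at its native rate (the contemplation leading up to an action is
what carries workload information, and the haemodynamic response peaks
5-8 s after onset).  Markers are discarded when

* their nearest sample index coincides with another marker's in any
  signal stream (all colliding markers are removed, symmetrically),
* any stream lacks a full window of data before them, or
* their window intersects a detected missing-data gap.

Quality statistics are advisory only: noisy samples are reported, never
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .streams import SessionRecording, StreamSeries, find_gaps
from .synth import puzzle_of_marker

__all__ = [
    "SegmentationConfig",
    "MultimodalSample",
    "SampleSet",
    "QualityStats",
    "nearest_index",
    "select_markers",
    "extract_window",
    "build_sample_set",
    "sample_stats",
]


@dataclass
class SegmentationConfig:
    """Window length in seconds plus gap-detection thresholds."""

    window_length: float = 8.0
    gap_min_duration: float = 0.2   # seconds; shorter holes are tolerated
    gap_factor: float = 5.0         # x median inter-sample interval

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")


@dataclass
class MultimodalSample:
    """Four synchronised per-modality windows plus one label in [0, 1]."""

    windows: dict[str, np.ndarray]   # modality -> (time x channels)
    label: float
    participant_id: str
    puzzle_id: int
    marker_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.label <= 1.0:
            raise ValueError(f"label must lie in [0, 1], got {self.label}")


@dataclass
class SampleSet:
    """The labelled dataset assembled from one or more recordings."""

    samples: list[MultimodalSample]
    labelling_scheme: str = "individual"
    label_counts: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_counts:
            counts: dict[float, int] = {}
            for s in self.samples:
                counts[s.label] = counts.get(s.label, 0) + 1
            self.label_counts = counts
        if sum(self.label_counts.values()) != len(self.samples):
            raise ValueError("label counts must sum to the number of samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.float64)

    def to_arrays(self, modalities=None) -> dict[str, np.ndarray]:
        """Stack per-modality windows into (n, time, channels) arrays."""
        if not self.samples:
            raise ValueError("empty sample set")
        modalities = modalities or list(self.samples[0].windows)
        return {
            m: np.stack([s.windows[m] for s in self.samples]).astype(np.float32)
            for m in modalities
        }

    def subset(self, indices) -> "SampleSet":
        return SampleSet(
            samples=[self.samples[i] for i in indices],
            labelling_scheme=self.labelling_scheme,
        )

    @staticmethod
    def concat(sets: list["SampleSet"]) -> "SampleSet":
        if not sets:
            return SampleSet(samples=[])
        scheme = sets[0].labelling_scheme
        return SampleSet(
            samples=[s for ss in sets for s in ss.samples], labelling_scheme=scheme
        )


@dataclass
class QualityStats:
    """Per-channel mean/variance/max/min summaries per modality."""

    per_channel: dict[str, dict[str, np.ndarray]]  # modality -> stat -> (channels,)


# ---------------------------------------------------------------------------


def nearest_index(timestamps: np.ndarray, t: float) -> int:
    """Index of the timestamp nearest to ``t``; ties go to the lower index."""
    timestamps = np.asarray(timestamps)
    if timestamps.size == 0:
        raise ValueError("nearest_index on empty timestamps")
    j = int(np.searchsorted(timestamps, t))
    if j == 0:
        i = 0
    elif j == timestamps.size:
        i = j - 1
    else:
        # strictly closer wins; exact midpoint goes to the lower index
        i = j - 1 if abs(t - timestamps[j - 1]) <= abs(timestamps[j] - t) else j
    # distinct timestamps can still round to equal distances; ties go low
    while i > 0 and abs(timestamps[i - 1] - t) == abs(timestamps[i] - t):
        i -= 1
    return i


def _index_at_or_before(timestamps: np.ndarray, t: float) -> int:
    return int(np.searchsorted(timestamps, t, side="right")) - 1


def select_markers(
    recording: SessionRecording, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Boolean usability mask over the recording's markers.

    A marker survives only if, in every signal stream, (a) its nearest
    sample index is unique among all markers, (b) a full window of data
    precedes it, and (c) its window does not straddle a missing-data gap.
    All members of a nearest-index collision are removed, not just the
    later ones.
    """
    config = config or SegmentationConfig()
    n = len(recording.markers)
    mask = np.ones(n, dtype=bool)
    if n == 0:
        return mask
    times = np.array([m.timestamp for m in recording.markers])
    for stream in recording.streams.values():
        if stream.nominal_rate <= 0 or stream.n_samples == 0:
            continue
        idx = np.array([nearest_index(stream.timestamps, t) for t in times])
        _, inverse, counts = np.unique(idx, return_inverse=True, return_counts=True)
        mask &= counts[inverse] == 1
        rows = int(round(config.window_length * stream.nominal_rate))
        gaps = find_gaps(stream, config.gap_min_duration, config.gap_factor)
        for i, t in enumerate(times):
            if not mask[i]:
                continue
            end = _index_at_or_before(stream.timestamps, t)
            if end - rows + 1 < 0:
                mask[i] = False
                continue
            w_start = stream.timestamps[end - rows + 1]
            for g0, gdur in gaps:
                if g0 < t and g0 + gdur > w_start:
                    mask[i] = False
                    break
    return mask


def extract_window(
    stream: StreamSeries, marker_time: float, window_length: float = 8.0
) -> np.ndarray:
    """Cut ``round(window_length * rate)`` rows ending at the sample
    at-or-before ``marker_time``; channel order preserved."""
    rows = int(round(window_length * stream.nominal_rate))
    end = _index_at_or_before(stream.timestamps, marker_time)
    start = end - rows + 1
    if end < 0 or start < 0:
        raise ValueError(
            f"stream {stream.name!r}: insufficient data before t={marker_time:.3f} "
            f"for a {window_length} s window"
        )
    return stream.samples[start : end + 1]


def build_sample_set(
    recording: SessionRecording,
    ratings: dict[int, float],
    config: SegmentationConfig | None = None,
    labelling_scheme: str = "individual",
    puzzle_resolver=puzzle_of_marker,
    mask: np.ndarray | None = None,
) -> SampleSet:
    """Assemble one labelled multimodal sample per selected marker.

    ``ratings`` maps puzzle id to the label in [0, 1] (the puzzle's
    difficulty rating after label mapping).  ``puzzle_resolver`` recovers
    the puzzle id from a marker (default: parse the action id).
    """
    config = config or SegmentationConfig()
    if mask is None:
        mask = select_markers(recording, config)
    samples: list[MultimodalSample] = []
    for keep, marker in zip(mask, recording.markers):
        if not keep:
            continue
        pid = puzzle_resolver(marker)
        if pid not in ratings:
            raise KeyError(f"no rating for puzzle {pid!r} referenced by marker "
                           f"{marker.action_id!r}")
        windows = {
            name: np.asarray(
                extract_window(s, marker.timestamp, config.window_length)
            )
            for name, s in recording.streams.items()
            if s.nominal_rate > 0
        }
        samples.append(
            MultimodalSample(
                windows=windows,
                label=float(ratings[pid]),
                participant_id=marker.participant_id,
                puzzle_id=pid,
                marker_time=marker.timestamp,
            )
        )
    return SampleSet(samples=samples, labelling_scheme=labelling_scheme)


def sample_stats(sample_set: SampleSet):
    """Label distribution and per-channel quality statistics.

    Returns ``(table, QualityStats)`` where ``table`` lists per-label
    counts and percentages of the total.  Statistics are advisory; no
    samples are rejected here.
    """
    if len(sample_set) == 0:
        raise ValueError("sample_stats on empty sample set")
    n = len(sample_set)
    table = {
        label: {"count": c, "percent": 100.0 * c / n}
        for label, c in sorted(sample_set.label_counts.items())
    }
    arrays = sample_set.to_arrays()
    per_channel = {}
    for m, arr in arrays.items():  # (n, time, channels)
        per_channel[m] = {
            "mean": arr.mean(axis=(0, 1)),
            "variance": arr.var(axis=(0, 1)),
            "max": arr.max(axis=(0, 1)),
            "min": arr.min(axis=(0, 1)),
        }
    return table, QualityStats(per_channel=per_channel)
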