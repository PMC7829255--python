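"""Multi-stream recording containers and clock hygiene.

A session recording bundles several independently clocked signal streams
(GSR, PPG, eye tracking, fNIRS) with an irregular marker stream, mirroring
the LabStreamingLayer/XDF recording model: each stream carries its own
timestamps, nominal sampling rate and channel metadata.  This module owns

* the in-memory containers (:class:`StreamSeries`, :class:`MarkerEvent`,
  :class:`SessionRecording`),
* a portable HDF5 container with the same per-stream schema as XDF,
* clock regularisation (least-squares de-jitter), realized-rate checks,
  missing-data gap detection and an inter-stream drift audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: Canonical modality order used everywhere a deterministic ordering is
#: needed (fusion concatenation, serialization).
MODALITIES = ("PPG", "GSR", "ET", "fNIRS")

#: Native channel counts per modality.
CHANNELS = {"GSR": 1, "PPG": 1, "ET": 4, "fNIRS": 54}

#: Default nominal sampling rates in Hz.
DEFAULT_RATES = {"GSR": 256.0, "PPG": 256.0, "ET": 120.0, "fNIRS": 10.0}

MARKER_STATUSES = ("correct", "incorrect", "checked")


class MissingStreamError(KeyError):
    """A required stream (e.g. the marker stream) is absent from a container."""


@dataclass
class StreamSeries:
    """One timestamped multichannel signal at a nominal rate.

    ``nominal_rate == 0`` denotes an irregular stream (markers); signal
    streams must declare a strictly positive rate.
    """

    name: str
    nominal_rate: float
    timestamps: np.ndarray
    samples: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.samples = np.asarray(self.samples)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.nominal_rate < 0:
            raise ValueError("nominal_rate must be >= 0")
        if self.timestamps.shape[0] != self.samples.shape[0]:
            raise ValueError(
                f"stream {self.name!r}: {self.timestamps.shape[0]} timestamps "
                f"vs {self.samples.shape[0]} sample rows"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"stream {self.name!r}: timestamps must be strictly ascending")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[1])]
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError("channel_labels length must match sample columns")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[1])

    def equals(self, other: "StreamSeries") -> bool:
        return (
            self.name == other.name
            and self.nominal_rate == other.nominal_rate
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.samples, other.samples)
            and self.channel_labels == other.channel_labels
        )


@dataclass
class MarkerEvent:
    """One stimulus-software action event.

    Markers carry the participant id, the action timestamp, the type of
    action, the action id and a status flag.
    """

    timestamp: float
    participant_id: str
    action_type: str
    action_id: str
    status: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.timestamp):
            raise ValueError("marker timestamp must be finite")


@dataclass
class SessionRecording:
    """All signal streams plus the marker stream for one participant."""

    streams: dict[str, StreamSeries]
    markers: list[MarkerEvent]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.streams:
            raise ValueError("a recording needs at least one signal stream")
        # Markers outside the union of stream time ranges are legal but
        # suspicious; flag them in metadata rather than failing.
        if self.markers:
            lo = min(s.timestamps[0] for s in self.streams.values() if s.n_samples)
            hi = max(s.timestamps[-1] for s in self.streams.values() if s.n_samples)
            out = [m for m in self.markers if not (lo <= m.timestamp <= hi)]
            if out:
                self.metadata.setdefault("flags", []).append(
                    f"{len(out)} marker(s) outside stream time range [{lo:.3f}, {hi:.3f}]"
                )

    @property
    def participant_id(self) -> str:
        return str(self.metadata.get("participant_id", ""))


@dataclass
class DriftReport:
    """Per-stream clock drift in milliseconds plus session summary.

    Drift of a stream is the absolute difference between its realized time
    span and the span expected from its nominal rate and sample count.
    """

    per_stream: dict[str, float]
    mean_ms: float
    sd_ms: float


# ---------------------------------------------------------------------------
# clock operations


def effective_rate(stream: StreamSeries) -> float:
    """Realized sampling rate ``(n - 1) / (t_last - t_first)`` in Hz."""
    if stream.n_samples < 2:
        raise ValueError("effective_rate needs at least 2 samples")
    span = stream.timestamps[-1] - stream.timestamps[0]
    return (stream.n_samples - 1) / span


def dejitter_timestamps(stream: StreamSeries) -> StreamSeries:
    """Replace jittered timestamps by their least-squares uniform grid.

    Fits ``t_k = t0 + k * dt`` by ordinary least squares over the sample
    index ``k`` and substitutes the fitted grid; sample values are left
    untouched.  Idempotent: a uniform grid is its own fit.
    """
    if stream.nominal_rate <= 0:
        raise ValueError("cannot de-jitter an irregular (rate 0) stream")
    if stream.n_samples < 2:
        raise ValueError("de-jitter needs at least 2 samples")
    k = np.arange(stream.n_samples, dtype=np.float64)
    dt, t0 = np.polyfit(k, stream.timestamps, 1)
    return replace(stream, timestamps=t0 + k * dt)


def drift_report(recording: SessionRecording) -> DriftReport:
    """Audit clock drift: realized vs nominal time span per signal stream."""
    per: dict[str, float] = {}
    for name, s in recording.streams.items():
        if s.nominal_rate <= 0 or s.n_samples < 2:
            continue
        realized = s.timestamps[-1] - s.timestamps[0]
        expected = (s.n_samples - 1) / s.nominal_rate
        per[name] = abs(realized - expected) * 1e3
    vals = np.array(list(per.values())) if per else np.array([0.0])
    return DriftReport(per_stream=per, mean_ms=float(vals.mean()), sd_ms=float(vals.std(ddof=0)))


def find_gaps(
    stream: StreamSeries, min_duration: float = 0.2, factor: float = 5.0
) -> list[tuple[float, float]]:
    """Detect missing-data gaps as abnormally long inter-sample intervals.

    An interval counts as a gap when it exceeds both ``min_duration``
    seconds and ``factor`` times the median interval (so ordinary clock
    jitter never triggers it).  Returns ``(start, duration)`` pairs.
    """
    if stream.n_samples < 2:
        return []
    dt = np.diff(stream.timestamps)
    thresh = max(min_duration, factor * float(np.median(dt)))
    idx = np.nonzero(dt > thresh)[0]
    return [(float(stream.timestamps[i]), float(dt[i])) for i in idx]


# ---------------------------------------------------------------------------
# container I/O (portable HDF5 layout with XDF stream semantics)


def write_recording(recording: SessionRecording, path) -> None:
    """Write a recording to the portable multi-stream container.

    Layout: one HDF5 group per stream holding ``timestamps`` (float64) and
    ``samples`` datasets plus ``nominal_rate`` / ``channel_labels``
    attributes; markers as a dedicated group of aligned columns; recording
    metadata as root attributes.  Lossless for timestamps and samples.
    """
    try:
        f = h5py.File(path, "w")
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write recording to {path!r}: {exc}") from exc
    with f:
        for key, val in recording.metadata.items():
            if isinstance(val, (str, int, float)):
                f.attrs[key] = val
        g = f.create_group("streams")
        for name, s in recording.streams.items():
            sg = g.create_group(name)
            sg.attrs["nominal_rate"] = float(s.nominal_rate)
            sg.attrs["channel_labels"] = [str(c) for c in s.channel_labels]
            sg.create_dataset("timestamps", data=s.timestamps, dtype=np.float64)
            sg.create_dataset("samples", data=s.samples)
        mg = f.create_group("markers")
        str_dt = h5py.string_dtype(encoding="utf-8")
        mg.create_dataset("timestamp", data=np.array([m.timestamp for m in recording.markers]))
        for col in ("participant_id", "action_type", "action_id", "status"):
            mg.create_dataset(
                col, data=[getattr(m, col) for m in recording.markers], dtype=str_dt
            )


def read_recording(
    path, rate_tolerance: float = 0.01, dejitter: bool = True
) -> SessionRecording:
    """Read a recording, check indicated vs realized rates, de-jitter.

    Mirrors the import behaviour of an XDF loader: for every regular
    stream the realized rate is compared with the declared nominal rate
    and, when the relative deviation exceeds ``rate_tolerance`` (default
    1 %), the stream's timestamps are regularised onto their least-squares
    grid.  The check result is logged either way.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot read recording container {path!r}: {exc}") from exc
    with f:
        metadata = {k: (v.item() if hasattr(v, "item") else v) for k, v in f.attrs.items()}
        streams: dict[str, StreamSeries] = {}
        for name, sg in f["streams"].items():
            labels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in sg.attrs["channel_labels"]
            ]
            s = StreamSeries(
                name=name,
                nominal_rate=float(sg.attrs["nominal_rate"]),
                timestamps=sg["timestamps"][...],
                samples=sg["samples"][...],
                channel_labels=labels,
            )
            if s.nominal_rate > 0 and s.n_samples >= 2:
                realized = effective_rate(s)
                dev = abs(realized - s.nominal_rate) / s.nominal_rate
                if dev > rate_tolerance and dejitter:
                    logger.info(
                        "stream %s: realized %.3f Hz vs nominal %.3f Hz "
                        "(%.2f%% off) -> de-jittering",
                        name, realized, s.nominal_rate, 100 * dev,
                    )
                    s = dejitter_timestamps(s)
                else:
                    logger.debug(
                        "stream %s: realized %.3f Hz within %.1f%% of nominal",
                        name, realized, 100 * rate_tolerance,
                    )
            streams[name] = s
        if "markers" not in f:
            raise MissingStreamError("recording has no 'markers' stream")
        mg = f["markers"]
        decode = lambda b: b.decode() if isinstance(b, bytes) else str(b)  # noqa: E731
        markers = [
            MarkerEvent(
                timestamp=float(t),
                participant_id=decode(p),
                action_type=decode(a),
                action_id=decode(i),
                status=decode(st),
            )
            for t, p, a, i, st in zip(
                mg["timestamp"][...], mg["participant_id"][...],
                mg["action_type"][...], mg["action_id"][...], mg["status"][...],
            )
        ]
    return SessionRecording(streams=streams, markers=markers, metadata=metadata)
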