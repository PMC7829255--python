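"""Container round-trips, de-jitter, rate checks, drift and gap audits."""

import numpy as np
import pytest

from fuseload.streams import (
    MarkerEvent,
    MissingStreamError,
    SessionRecording,
    StreamSeries,
    dejitter_timestamps,
    drift_report,
    effective_rate,
    find_gaps,
    read_recording,
    write_recording,
)


def _recording(markers=True, n=200, rate=100.0, n_channels=3, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    if jitter:
        t = np.sort(t + rng.normal(0, jitter, n))
    stream = StreamSeries(
        name="sig",
        nominal_rate=rate,
        timestamps=t,
        samples=rng.normal(size=(n, n_channels)),
        channel_labels=[f"c{i}" for i in range(n_channels)],
    )
    mk = (
        [MarkerEvent(0.5, "p1", "select_answer", "p0:0", "correct"),
         MarkerEvent(1.0, "p1", "select_hint", "p0:1", "checked")]
        if markers else []
    )
    return SessionRecording(streams={"sig": stream}, markers=mk,
                            metadata={"participant_id": "p1"})


class TestRoundTrip:
    def test_field_by_field_identity(self, tmp_path):
        rec = _recording()
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        back = read_recording(p)
        assert back.streams["sig"].equals(rec.streams["sig"])
        assert len(back.markers) == len(rec.markers)
        for a, b in zip(back.markers, rec.markers):
            assert (a.timestamp, a.participant_id, a.action_type, a.action_id,
                    a.status) == (b.timestamp, b.participant_id, b.action_type,
                                  b.action_id, b.status)
        assert back.metadata["participant_id"] == "p1"

    def test_empty_marker_list_roundtrips(self, tmp_path):
        rec = _recording(markers=False)
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        assert read_recording(p).markers == []

    def test_54_channel_order_and_bit_exact_floats(self, tmp_path):
        rng = np.random.default_rng(1)
        labels = [f"CH{i}_O2Hb" for i in range(27)] + [f"CH{i}_HHb" for i in range(27)]
        s = StreamSeries("fNIRS", 10.0, np.arange(50) / 10.0,
                         rng.normal(size=(50, 54)), labels)
        rec = SessionRecording(streams={"fNIRS": s}, markers=[])
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        back = read_recording(p).streams["fNIRS"]
        assert back.channel_labels == labels
        assert back.samples.tobytes() == s.samples.tobytes()

    def test_missing_marker_stream_is_structured_error(self, tmp_path):
        import h5py
        rec = _recording()
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        with h5py.File(p, "a") as f:
            del f["markers"]
        with pytest.raises(MissingStreamError, match="markers"):
            read_recording(p)

    def test_unreadable_path_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_recording(tmp_path / "nope.h5")


class TestDejitter:
    def test_uniform_grid_is_fixed_point(self):
        s = StreamSeries("s", 10.0, np.arange(40) / 10.0, np.zeros((40, 1)))
        out = dejitter_timestamps(s)
        np.testing.assert_allclose(out.timestamps, s.timestamps, atol=1e-12)

    def test_least_squares_grid_matches_closed_form(self):
        t = np.array([0.0, 0.11, 0.19, 0.30])
        s = StreamSeries("s", 10.0, t, np.zeros((4, 1)))
        out = dejitter_timestamps(s)
        # closed-form least squares on k = 0..3 computed independently
        k = np.arange(4.0)
        dt = (np.sum((k - k.mean()) * (t - t.mean()))) / np.sum((k - k.mean()) ** 2)
        t0 = t.mean() - dt * k.mean()
        np.testing.assert_allclose(out.timestamps, t0 + k * dt, atol=1e-12)
        assert abs(dt - 0.1) < 0.025 * 0.1  # closed form gives 0.098 exactly

    def test_idempotent_and_value_preserving(self):
        rng = np.random.default_rng(3)
        t = np.sort(np.arange(100) / 50.0 + rng.normal(0, 0.002, 100))
        vals = rng.normal(size=(100, 2))
        s = StreamSeries("s", 50.0, t, vals)
        once = dejitter_timestamps(s)
        twice = dejitter_timestamps(once)
        np.testing.assert_allclose(once.timestamps, twice.timestamps, atol=1e-12)
        assert np.array_equal(once.samples, vals)

    def test_irregular_stream_rejected(self):
        s = StreamSeries("markers", 0.0, np.array([0.0, 1.0]), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            dejitter_timestamps(s)


class TestEffectiveRate:
    def test_definition(self):
        s = StreamSeries("s", 256.0, np.linspace(0, 8, 2048), np.zeros((2048, 1)))
        assert effective_rate(s) == pytest.approx(2047 / 8)  # 255.875 Hz

    def test_uniform_grid(self):
        s = StreamSeries("s", 120.0, np.arange(240) / 120.0, np.zeros((240, 1)))
        assert effective_rate(s) == pytest.approx(120.0)

    def test_too_few_samples_rejected(self):
        s = StreamSeries("s", 10.0, np.array([0.0]), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            effective_rate(s)


class TestRateCheckOnRead:
    def test_small_rate_mismatch_accepted_without_dejitter(self, tmp_path):
        # stream declares 256 Hz but realizes 255.9 Hz: within the 1% default
        t = np.arange(512) / 255.9
        s = StreamSeries("sig", 256.0, t, np.zeros((512, 1)))
        rec = SessionRecording(streams={"sig": s}, markers=[])
        p = tmp_path / "r.h5"
        write_recording(rec, p)
        back = read_recording(p)
        np.testing.assert_array_equal(back.streams["sig"].timestamps, t)

    def test_jittered_stream_regularised_on_read(self, tmp_path):
        rng = np.random.default_rng(0)
        rate = 10.0
        base = np.arange(300) / rate
        t = np.sort(base + rng.normal(0, 0.02, 300))  # 20 ms jitter at 10 Hz
        s = StreamSeries("sig", rate, t, np.zeros((300, 1)))
        p = tmp_path / "r.h5"
        write_recording(SessionRecording(streams={"sig": s}, markers=[]), p)
        back = read_recording(p, rate_tolerance=0.0).streams["sig"]
        k = np.arange(300)
        dt, t0 = np.polyfit(k, t, 1)
        dev = np.abs(back.timestamps - (t0 + k * dt)).max()
        assert dev < 1.0 / rate


class TestDriftAndGaps:
    def test_perfect_clock_zero_drift(self):
        rec = _recording()
        assert drift_report(rec).per_stream["sig"] == 0.0

    def test_mean_is_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        streams = {}
        for i, drift in enumerate([0.1, 0.3]):
            n, rate = 100, 10.0
            t = np.arange(n) / rate * (1 + drift / ((n - 1) / rate))
            streams[f"s{i}"] = StreamSeries(f"s{i}", rate, t,
                                            rng.normal(size=(n, 1)))
        rep = drift_report(SessionRecording(streams=streams, markers=[]))
        vals = list(rep.per_stream.values())
        assert rep.mean_ms == pytest.approx(np.mean(vals))
        assert rep.sd_ms == pytest.approx(np.std(vals))

    def test_injected_gap_recovered_within_one_period(self):
        rate = 50.0
        t = np.arange(500) / rate
        keep = ~((t >= 4.0) & (t < 5.5))
        s = StreamSeries("s", rate, t[keep], np.zeros((keep.sum(), 1)))
        gaps = find_gaps(s)
        assert len(gaps) == 1
        start, dur = gaps[0]
        assert abs(dur - 1.5) <= 1.0 / rate + 1e-9
        assert abs(start - 4.0) <= 1.0 / rate + 1e-9

    def test_clean_stream_has_no_gaps(self):
        s = StreamSeries("s", 50.0, np.arange(500) / 50.0, np.zeros((500, 1)))
        assert find_gaps(s) == []
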