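"""Marker selection, window extraction, sample assembly, quality stats."""

import numpy as np
import pytest

from fuseload.records import load_sample_set, save_shards
from fuseload.segmentation import (
    MultimodalSample,
    SampleSet,
    SegmentationConfig,
    build_sample_set,
    extract_window,
    nearest_index,
    sample_stats,
    select_markers,
)
from fuseload.streams import MarkerEvent, SessionRecording, StreamSeries
from fuseload.labels import individual_label


def _stream(rate, duration, n_channels=1, name="sig", seed=0):
    n = int(round(rate * duration))
    rng = np.random.default_rng(seed)
    return StreamSeries(name, rate, np.arange(n) / rate,
                        rng.normal(size=(n, n_channels)))


def _rec(marker_times, rate=10.0, duration=60.0, extra_streams=()):
    streams = {"sig": _stream(rate, duration)}
    for s in extra_streams:
        streams[s.name] = s
    markers = [
        MarkerEvent(t, "p1", "select_answer", f"p0:{i}", "correct")
        for i, t in enumerate(marker_times)
    ]
    return SessionRecording(streams=streams, markers=markers)


class TestNearestIndex:
    @pytest.mark.parametrize(
        "timestamps,t,expected",
        [
            ([0, 0.1, 0.2], 0.14, 1),
            ([0, 0.1, 0.2], 0.1, 1),     # exact hit
            ([0, 0.1], 0.05, 0),          # midpoint tie -> lower index
            ([0, 0.1, 0.2], -5.0, 0),
            ([0, 0.1, 0.2], 9.0, 2),
        ],
    )
    def test_examples(self, timestamps, t, expected):
        assert nearest_index(np.array(timestamps, dtype=float), t) == expected

    def test_agrees_with_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ts = np.sort(rng.uniform(0, 10, rng.integers(1, 30)))
            t = float(rng.uniform(-1, 11))
            d = np.abs(ts - t)
            oracle = int(np.flatnonzero(d == d.min())[0])
            assert nearest_index(ts, t) == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nearest_index(np.array([]), 1.0)


class TestSelectMarkers:
    def test_well_separated_markers_pass(self):
        rec = _rec([20.0, 25.0], rate=256.0)
        assert select_markers(rec).tolist() == [True, True]

    def test_nearest_index_collision_removes_all_members(self):
        # two markers 1 ms apart share an index on a 10 Hz stream
        rec = _rec([20.0, 20.001], rate=10.0)
        assert select_markers(rec).tolist() == [False, False]

    def test_insufficient_preceding_data(self):
        rec = _rec([3.0, 30.0], rate=10.0)
        assert select_markers(rec).tolist() == [False, True]

    def test_marker_window_straddling_gap_removed(self):
        rate = 10.0
        t = np.arange(600) / rate
        keep = ~((t >= 25.0) & (t < 27.0))
        s = StreamSeries("sig", rate, t[keep], np.zeros((keep.sum(), 1)))
        rec = SessionRecording(
            streams={"sig": s},
            markers=[MarkerEvent(30.0, "p", "a", "p0:0", "correct"),
                     MarkerEvent(50.0, "p", "a", "p0:1", "correct")],
        )
        assert select_markers(rec).tolist() == [False, True]

    def test_agrees_with_brute_force_on_synthetic_sessions(self):
        # all-pairs nearest-index comparison oracle, sessions of <= 20 markers
        rng = np.random.default_rng(1)
        for trial in range(10):
            rates = [10.0, 50.0]
            duration = 60.0
            streams = [_stream(r, duration, name=f"s{r}", seed=trial) for r in rates]
            n_mark = int(rng.integers(2, 21))
            times = np.sort(rng.uniform(6.0, duration - 0.5, n_mark))
            rec = SessionRecording(
                streams={s.name: s for s in streams},
                markers=[MarkerEvent(float(t), "p", "a", f"p0:{i}", "correct")
                         for i, t in enumerate(times)],
            )
            cfg = SegmentationConfig(window_length=5.0)
            mask = select_markers(rec, cfg)
            expected = np.ones(n_mark, dtype=bool)
            for s in streams:
                idx = [nearest_index(s.timestamps, t) for t in times]
                for i in range(n_mark):
                    for j in range(n_mark):
                        if i != j and idx[i] == idx[j]:
                            expected[i] = False
                rows = int(round(5.0 * s.nominal_rate))
                for i, t in enumerate(times):
                    end = int(np.searchsorted(s.timestamps, t, side="right")) - 1
                    if end - rows + 1 < 0:
                        expected[i] = False
            assert mask.tolist() == expected.tolist()

    def test_adding_marker_never_rescues_existing_ones(self):
        rec1 = _rec([20.0, 30.0], rate=10.0)
        mask1 = select_markers(rec1)
        rec2 = _rec([20.0, 30.0, 30.001], rate=10.0)
        mask2 = select_markers(rec2)[:2]
        assert np.all(mask2 <= mask1)


class TestExtractWindow:
    @pytest.mark.parametrize("rate,rows", [(256.0, 2048), (120.0, 960), (10.0, 80)])
    def test_row_counts_at_native_rates(self, rate, rows):
        s = _stream(rate, 20.0)
        w = extract_window(s, 15.0, 8.0)
        assert w.shape[0] == rows

    def test_contents_match_index_arithmetic_oracle(self):
        s = _stream(10.0, 30.0, n_channels=3)
        t_mark = 21.037
        w = extract_window(s, t_mark, 8.0)
        end = int(np.searchsorted(s.timestamps, t_mark, side="right")) - 1
        np.testing.assert_array_equal(w, s.samples[end - 79 : end + 1])

    def test_insufficient_data_is_structured_error(self):
        s = _stream(10.0, 20.0)
        with pytest.raises(ValueError, match="insufficient"):
            extract_window(s, 3.0, 8.0)


class TestBuildSampleSet:
    def test_sample_count_equals_selected_markers(self, small_session):
        _, rec, truth = small_session
        mask = select_markers(rec)
        ratings = {p: individual_label(r) for p, r in truth.ratings.items()}
        ss = build_sample_set(rec, ratings)
        assert len(ss) == int(mask.sum())
        assert sum(ss.label_counts.values()) == len(ss)

    def test_window_shapes_at_native_rates(self, small_sample_set):
        s = small_sample_set.samples[0]
        assert s.windows["GSR"].shape == (2048, 1)
        assert s.windows["PPG"].shape == (2048, 1)
        assert s.windows["ET"].shape == (960, 4)
        assert s.windows["fNIRS"].shape == (80, 54)

    def test_zero_markers_gives_empty_set(self):
        rec = _rec([], rate=10.0)
        assert len(build_sample_set(rec, {})) == 0

    def test_missing_rating_names_puzzle(self, small_session):
        _, rec, _ = small_session
        with pytest.raises(KeyError, match="puzzle"):
            build_sample_set(rec, {0: 0.5})  # puzzles 1, 2 unrated

    def test_label_out_of_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="label"):
            MultimodalSample(windows={}, label=1.5, participant_id="p",
                             puzzle_id=0, marker_time=0.0)


class TestSampleStats:
    def _fake_set(self, counts):
        samples = []
        for label, c in counts.items():
            for _ in range(c):
                samples.append(
                    MultimodalSample(windows={"GSR": np.zeros((2, 1))},
                                     label=label, participant_id="p",
                                     puzzle_id=0, marker_time=10.0)
                )
        return SampleSet(samples=samples)

    def test_single_label_is_100_percent(self):
        table, _ = sample_stats(self._fake_set({0.5: 4}))
        assert table[0.5]["percent"] == 100.0

    def test_percentages_sum_to_100(self, small_sample_set):
        table, stats = sample_stats(small_sample_set)
        assert sum(r["percent"] for r in table.values()) == pytest.approx(100.0)
        for per_stat in stats.per_channel.values():
            assert np.all(per_stat["min"] <= per_stat["mean"] + 1e-9)
            assert np.all(per_stat["mean"] <= per_stat["max"] + 1e-9)

    def test_study_distribution_share(self):
        # a 4,082-sample set with 87 rating-1 samples reports 2.131% for it
        counts = {0.0: 87, 1 / 6: 350, 2 / 6: 479, 3 / 6: 611,
                  4 / 6: 1275, 5 / 6: 902, 1.0: 378}
        table, _ = sample_stats(self._fake_set(counts))
        assert sum(c for c in counts.values()) == 4082
        assert table[0.0]["percent"] == pytest.approx(2.131, abs=5e-4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sample_stats(SampleSet(samples=[]))


class TestRecordShards:
    def test_roundtrip(self, tmp_path, small_sample_set):
        sub = small_sample_set.subset(range(7))
        save_shards(sub, tmp_path / "shards", shard_size=3)
        back = load_sample_set(tmp_path / "shards")
        assert len(back) == 7
        assert back.labelling_scheme == sub.labelling_scheme
        for a, b in zip(back.samples, sub.samples):
            assert a.label == b.label and a.puzzle_id == b.puzzle_id
            for m in a.windows:
                np.testing.assert_allclose(a.windows[m],
                                           b.windows[m].astype(np.float32))
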