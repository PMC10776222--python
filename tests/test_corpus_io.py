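"""Corpus reading, song/call classification and unit-table round trips."""

import numpy as np
import pytest

from rookvoc import corpus_io
from rookvoc.corpus_io import (
    Corpus,
    LabelParseError,
    SchemaError,
    VocalUnitRecord,
    classify_call_vs_song,
    filter_analysable,
    read_audio,
    read_label_track,
    read_unit_table,
    write_audio,
    write_unit_table,
)


def _unit(uid, start, end, individual="bird", type_tag="t1", **kw):
    return VocalUnitRecord(
        unit_id=uid,
        recording_id="rec",
        start_s=start,
        end_s=end,
        individual=individual,
        type_tag=type_tag,
        **kw,
    )


class TestLabelTrack:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "labels.txt"
        p.write_text("")
        assert read_label_track(p, "rec") == []

    def test_parses_times_and_individual(self, tmp_path):
        p = tmp_path / "labels.txt"
        p.write_text("1.250\t1.810\tMerlin\n")
        (rec,) = read_label_track(p, "rec")
        assert rec.start_s == 1.25 and rec.end_s == 1.81
        assert rec.individual == "Merlin"
        assert rec.unit_type == "unassigned"

    def test_parses_type_and_context(self, tmp_path):
        p = tmp_path / "labels.txt"
        p.write_text("0.5\t0.9\tMerlin;caw;foraging\n")
        (rec,) = read_label_track(p, "rec")
        assert (rec.individual, rec.type_tag, rec.context) == ("Merlin", "caw", "foraging")

    def test_inverted_interval_is_validation_error(self, tmp_path):
        p = tmp_path / "labels.txt"
        p.write_text("2.0\t1.0\tX\n")
        with pytest.raises(LabelParseError, match=":1"):
            read_label_track(p, "rec")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "labels.txt"
        p.write_text("0.0\t1.0\tA\nnot-a-time\toops\n")
        with pytest.raises(LabelParseError, match=":2"):
            read_label_track(p, "rec")

    def test_roundtrip_through_writer(self, tmp_path):
        recs = [_unit("rec#1", 0.5, 0.8, "A", "caw"), _unit("rec#2", 12.0, 12.4, "B", "gull")]
        corpus_io.write_label_track(recs, tmp_path / "l.txt")
        back = read_label_track(tmp_path / "l.txt", "rec")
        assert [(r.start_s, r.end_s, r.individual, r.type_tag) for r in back] == [
            (0.5, 0.8, "A", "caw"),
            (12.0, 12.4, "B", "gull"),
        ]


class TestAudio:
    def test_mono_second_at_48k(self, tmp_path):
        wave = np.sin(2 * np.pi * 440 * np.arange(48_000) / 48_000) * 0.5
        write_audio(tmp_path / "a.wav", wave)
        back, sr = read_audio(tmp_path / "a.wav")
        assert sr == 48_000
        assert back.shape == (1, 48_000)
        assert np.max(np.abs(back[0] - wave)) < 1e-3  # 16-bit quantization

    def test_four_channels(self, tmp_path):
        wave = np.random.default_rng(0).normal(size=(4, 48_000)) * 0.1
        write_audio(tmp_path / "a.wav", wave)
        back, sr = read_audio(tmp_path / "a.wav")
        assert back.shape == (4, 48_000)

    def test_non_wav_raises_io_error(self, tmp_path):
        p = tmp_path / "a.wav"
        p.write_text("this is not audio")
        with pytest.raises(IOError):
            read_audio(p)

    def test_off_rate_file_warns(self, tmp_path):
        write_audio(tmp_path / "a.wav", np.zeros(1000), sample_rate=44_100)
        with pytest.warns(UserWarning, match="44100"):
            read_audio(tmp_path / "a.wav")


def _sequence(n, types, gap, start=0.0, duration=0.4, individual="bird"):
    recs = []
    t = start
    for i in range(n):
        recs.append(_unit(f"u{start}:{i}", t, t + duration, individual, types[i % len(types)]))
        t += duration + gap
    return recs


class TestSongRule:
    @pytest.mark.parametrize(
        "n, types, gap, expected",
        [
            (5, ["a", "b"], 1.0, "song"),  # minimum qualifying run
            (4, ["a", "b"], 1.0, "call"),  # below minimum unit count
            (6, ["a"], 1.0, "call"),  # below minimum type count
        ],
    )
    def test_run_thresholds(self, n, types, gap, expected):
        out = classify_call_vs_song(_sequence(n, types, gap))
        assert [r.unit_type for r in out] == [expected] * n

    def test_ten_second_gap_splits_runs(self):
        first = _sequence(4, ["a", "b"], 1.0)
        # a gap of exactly 10 s after unit 4 breaks the run (strict < rule)
        second = _sequence(6, ["a", "b"], 1.0, start=first[-1].end_s + 10.0)
        out = classify_call_vs_song(first + second)
        assert [r.unit_type for r in out[:4]] == ["call"] * 4
        assert [r.unit_type for r in out[4:]] == ["song"] * 6

    def test_gap_just_below_threshold_joins(self):
        first = _sequence(3, ["a", "b"], 1.0)
        second = _sequence(2, ["a", "b"], 1.0, start=first[-1].end_s + 9.99)
        out = classify_call_vs_song(first + second)
        assert [r.unit_type for r in out] == ["song"] * 5

    def test_individuals_are_independent(self):
        a = _sequence(5, ["a", "b"], 1.0, individual="A")
        b = _sequence(5, ["a"], 1.0, individual="B", start=0.1)
        out = classify_call_vs_song(a + b)
        by_ind = {r.individual: r.unit_type for r in out}
        assert by_ind == {"A": "song", "B": "call"}

    def test_order_invariant_and_idempotent(self, rng):
        recs = _sequence(5, ["a", "b"], 1.0) + _sequence(3, ["a", "b"], 1.0, start=100.0)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        out_sorted = {r.unit_id: r.unit_type for r in classify_call_vs_song(recs)}
        out_shuffled = {r.unit_id: r.unit_type for r in classify_call_vs_song(shuffled)}
        assert out_sorted == out_shuffled
        twice = classify_call_vs_song(classify_call_vs_song(recs))
        assert {r.unit_id: r.unit_type for r in twice} == out_sorted

    def test_every_unit_labelled(self):
        recs = _sequence(7, ["a", "b", "c"], 0.5) + _sequence(2, ["a"], 0.2, start=500.0)
        out = classify_call_vs_song(recs)
        n_song = sum(r.unit_type == "song" for r in out)
        n_call = sum(r.unit_type == "call" for r in out)
        assert n_song + n_call == len(recs)

    def test_missing_type_tag_is_configuration_error(self):
        recs = [_unit("u0", 0.0, 0.5, type_tag="")]
        with pytest.raises(ValueError, match="type_tag"):
            classify_call_vs_song(recs)


class TestFilters:
    def test_clean_records_unchanged(self):
        recs = [_unit("u0", 0, 1), _unit("u1", 2, 3)]
        assert filter_analysable(recs) == recs

    def test_overlapped_removed(self):
        recs = [_unit("u0", 0, 1), _unit("u1", 2, 3, overlapped=True), _unit("u2", 4, 5)]
        assert [r.unit_id for r in filter_analysable(recs)] == ["u0", "u2"]

    def test_unidentified_removed(self):
        recs = [_unit("u0", 0, 1, identified=False), _unit("u1", 2, 3)]
        assert [r.unit_id for r in filter_analysable(recs)] == ["u1"]

    def test_all_overlapped_warns_and_empties(self):
        recs = [_unit("u0", 0, 1, overlapped=True)]
        with pytest.warns(UserWarning, match="no analysable"):
            assert filter_analysable(recs) == []


class TestUnitTable:
    def test_roundtrip_identity(self, tmp_path):
        recs = [
            _unit("u0", 0.5, 1.0, "A", "caw", sex="F", colony="S", context="foraging"),
            _unit("u1", 2.0, 2.5, "B", "gull", sex="M", colony="C", overlapped=True),
        ]
        write_unit_table(recs, tmp_path / "units.csv")
        back = read_unit_table(tmp_path / "units.csv")
        assert back.records == recs

    def test_missing_column_is_schema_error(self, tmp_path):
        (tmp_path / "bad.csv").write_text("unit_id,start_s,end_s\nu0,0,1\n")
        with pytest.raises(SchemaError, match="individual"):
            read_unit_table(tmp_path / "bad.csv")

    def test_empty_table_with_header(self, tmp_path):
        write_unit_table([], tmp_path / "units.csv")
        assert len(read_unit_table(tmp_path / "units.csv")) == 0


class TestInvariants:
    def test_record_rejects_bad_interval(self):
        with pytest.raises(ValueError):
            _unit("u0", 1.0, 1.0)
        with pytest.raises(ValueError):
            _unit("u0", -0.5, 1.0)

    def test_corpus_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            Corpus(records=[_unit("u0", 0, 1), _unit("u0", 2, 3)])

    def test_corpus_requires_resolvable_recordings(self, tmp_path):
        with pytest.raises(ValueError, match="without audio"):
            Corpus(records=[_unit("u0", 0, 1)], audio_index={"other": tmp_path / "x.wav"})
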