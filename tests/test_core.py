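"""Pitch conversions, n-gram windows, domain-type invariants, file round-trips."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_melody
from singrec.core import (
    Melody,
    NoteEvent,
    PitchTrack,
    cents_deviation,
    extract_ngrams,
    hz_to_midi,
    intervals,
    midi_to_hz,
    round_midi,
)
from singrec.io import (
    ParseError,
    read_midi_melody,
    read_note_track,
    read_pitch_track,
    write_note_track,
    write_pitch_track,
)


class TestPitchConversion:
    @pytest.mark.parametrize(
        "hz,midi", [(440.0, 69.0), (880.0, 81.0), (220.0, 57.0), (466.16, 70.00)]
    )
    def test_reference_pitches(self, hz, midi):
        assert hz_to_midi(hz) == pytest.approx(midi, abs=0.01)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            hz_to_midi(0.0)
        with pytest.raises(ValueError):
            hz_to_midi(-100.0)

    @given(st.floats(min_value=50.0, max_value=2000.0))
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_identity(self, f0):
        assert midi_to_hz(hz_to_midi(f0)) == pytest.approx(f0, abs=1e-9)

    @pytest.mark.parametrize(
        "x,expected", [(60.4, 60), (60.5, 61), (-0.5, -1), (59.5, 60), (60.0, 60)]
    )
    def test_round_half_away_from_zero(self, x, expected):
        assert round_midi(x) == expected

    @pytest.mark.parametrize(
        "f0,target,cents", [(440.0, 69, 0.0), (440.0, 68, 100.0), (450.0, 69, 38.9)]
    )
    def test_cents_deviation(self, f0, target, cents):
        assert cents_deviation(f0, target) == pytest.approx(cents, abs=0.1)


class TestSequences:
    @pytest.mark.parametrize(
        "pitches,expected",
        [([60, 62, 64], [2, 2]), ([60, 60], [0]), ([67, 60, 64], [-7, 4])],
    )
    def test_intervals(self, pitches, expected):
        m = Melody.from_pitches(pitches)
        assert list(intervals(m)) == expected

    def test_intervals_single_note(self):
        with pytest.raises(ValueError):
            intervals(Melody.from_pitches([60]))

    @pytest.mark.parametrize(
        "seq,n,expected",
        [
            ([2, 2, -1], 2, [(2, 2), (2, -1)]),
            ([5], 3, []),
            ([1, 2, 3, 4], 3, [(1, 2, 3), (2, 3, 4)]),
        ],
    )
    def test_extract_ngrams(self, seq, n, expected):
        assert extract_ngrams(seq, n) == expected

    def test_ngram_invalid_n(self):
        with pytest.raises(ValueError):
            extract_ngrams([1, 2], 0)

    @given(st.lists(st.integers(-5, 5), max_size=20), st.integers(1, 8))
    @settings(max_examples=200, derandomize=True)
    def test_ngram_count_matches_window_formula(self, seq, n):
        grams = extract_ngrams(seq, n)
        assert len(grams) == max(0, len(seq) - n + 1)
        # brute-force enumeration oracle
        assert grams == [tuple(seq[i : i + n]) for i in range(max(0, len(seq) - n + 1))]


class TestDomainTypes:
    def test_note_event_validation(self):
        with pytest.raises(ValueError):
            NoteEvent(0.0, 0.0, 60.0)
        with pytest.raises(ValueError):
            NoteEvent(-1.0, 0.5, 60.0)
        with pytest.raises(ValueError):
            NoteEvent(0.0, 0.5, 200.0)

    def test_melody_requires_sorted_onsets(self):
        notes = (NoteEvent(1.0, 0.5, 60), NoteEvent(0.0, 0.5, 62))
        with pytest.raises(ValueError):
            Melody(notes)

    def test_empty_melody_rejected(self):
        with pytest.raises(ValueError):
            Melody(())

    def test_pitch_track_marks_nonpositive_f0_unvoiced(self):
        track = PitchTrack(np.array([0.0, 0.01, 0.02]), np.array([440.0, 0.0, 220.0]))
        assert track.n_voiced == 2
        assert np.isnan(track.f0[1])

    def test_pitch_track_monotone_times(self):
        with pytest.raises(ValueError):
            PitchTrack(np.array([0.0, 0.0]), np.array([440.0, 440.0]))


class TestFileRoundTrips:
    def test_note_track_roundtrip(self, rng, tmp_path):
        for i in range(10):
            m = random_melody(rng, rhythmic=True, id=f"m{i}")
            p = tmp_path / f"m{i}.csv"
            write_note_track(m, p)
            back = read_note_track(p)
            assert len(back) == len(m)
            assert np.allclose(back.pitches, m.pitches, atol=1e-9)
            assert np.allclose(back.onsets, m.onsets, atol=1e-9)
            assert np.allclose(back.durations, m.durations, atol=1e-9)

    def test_pitch_track_roundtrip_preserves_unvoiced(self, tmp_path):
        t = np.arange(0, 0.05, 0.01)
        f0 = np.array([440.0, np.nan, 441.0, 0.0, 439.5])
        track = PitchTrack(t, f0)
        p = tmp_path / "track.csv"
        write_pitch_track(track, p)
        back = read_pitch_track(p)
        assert back.n_voiced == 3
        assert np.allclose(back.times, t)
        _, v = back.voiced()
        assert np.allclose(v, [440.0, 441.0, 439.5])

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("onset,dur,freq,note\n0.0,0.25,440,69\nnot,a,row,!\n")
        with pytest.raises(ParseError, match="bad.csv:3"):
            read_note_track(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("onset,freq\n0.0,440\n")
        with pytest.raises(ParseError, match="dur"):
            read_note_track(p)

    def test_nonmonotone_onset_rejected(self, tmp_path):
        p = tmp_path / "mono.csv"
        p.write_text("onset,dur,freq,note\n1.0,0.25,440,69\n0.5,0.25,440,69\n")
        with pytest.raises(ParseError, match="mono.csv:3"):
            read_note_track(p)


def _write_midi(path, notes, division=480, tempo=500000):
    """Minimal format-0 writer used only to exercise the reader."""
    events = b""
    prev_tick = 0

    def varlen(v):
        out = [v & 0x7F]
        v >>= 7
        while v:
            out.append(0x80 | (v & 0x7F))
            v >>= 7
        return bytes(reversed(out))

    events += b"\x00\xff\x51\x03" + tempo.to_bytes(3, "big")
    timeline = []
    for onset, dur, pitch in notes:
        timeline.append((onset, 0x90, pitch))
        timeline.append((onset + dur, 0x80, pitch))
    timeline.sort(key=lambda e: (e[0], e[1]))
    for tick, status, pitch in timeline:
        events += varlen(tick - prev_tick) + bytes([status, pitch, 64])
        prev_tick = tick
    events += b"\x00\xff\x2f\x00"
    track = b"MTrk" + struct.pack(">I", len(events)) + events
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, division)
    path.write_bytes(header + track)


class TestMidiReader:
    def test_simple_melody(self, tmp_path):
        p = tmp_path / "m.mid"
        _write_midi(p, [(0, 480, 60), (480, 480, 62), (960, 960, 64)])
        m = read_midi_melody(p)
        assert list(m.rounded_pitches) == [60, 62, 64]
        # 480 ticks at 500000 us/quarter and 480 tpq = 0.5 s
        assert m.onsets == pytest.approx([0.0, 0.5, 1.0])
        assert m.durations == pytest.approx([0.5, 0.5, 1.0])

    def test_overlap_truncated_at_next_onset(self, tmp_path):
        p = tmp_path / "o.mid"
        _write_midi(p, [(0, 960, 60), (480, 480, 62)])
        m = read_midi_melody(p)
        assert m.durations[0] == pytest.approx(0.5)

    def test_not_midi(self, tmp_path):
        p = tmp_path / "x.mid"
        p.write_bytes(b"RIFF....")
        with pytest.raises(ParseError):
            read_midi_melody(p)
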