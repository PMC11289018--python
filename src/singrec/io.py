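"""Readers/writers for note-event tables, pitch-track tables and MIDI files.

Two delimited-text dialects are supported, matching the pYIN /
Sonic-Annotator outputs the scoring pipeline consumes:

* note track — header ``onset,dur,freq,note`` (seconds, seconds, Hz,
  integer MIDI);
* pitch track — header ``time,freq`` (seconds, Hz), where an empty or
  non-positive ``freq`` marks an unvoiced frame.

Standard MIDI files (format 0/1) can be ingested for corpus building; only
the first track containing notes is read and it is assumed monophonic
(overlapping notes are truncated at the next onset).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .core import Melody, NoteEvent, PitchTrack, hz_to_midi, midi_to_hz, round_midi

__all__ = [
    "ParseError",
    "read_note_track",
    "write_note_track",
    "read_pitch_track",
    "write_pitch_track",
    "read_midi_melody",
]


class ParseError(ValueError):
    """A malformed input row; carries the path and 1-based line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _split_header(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [c.strip().lower() for c in line.rstrip("\n").split(sep)], sep


def read_note_track(path, id=None, is_rhythmic=True) -> Melody:
    """Read a note-event table into a :class:`Melody`.

    Pitch is taken from the ``freq`` column (Hz -> real MIDI); the integer
    ``note`` column is redundant on read and checked only for presence.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    header, sep = _split_header(lines[0])
    required = ["onset", "dur", "freq"]
    for col in required:
        if col not in header:
            raise ParseError(path, 1, f"missing column {col!r} in header {header}")
    idx = {c: header.index(c) for c in header}
    notes = []
    prev_onset = -np.inf
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        try:
            onset = float(cells[idx["onset"]])
            dur = float(cells[idx["dur"]])
            freq = float(cells[idx["freq"]])
        except (ValueError, IndexError) as exc:
            raise ParseError(path, line_no, f"unparsable row: {line!r}") from exc
        if onset < prev_onset:
            raise ParseError(path, line_no, f"onset {onset} decreases (previous {prev_onset})")
        prev_onset = onset
        try:
            notes.append(NoteEvent(onset, dur, hz_to_midi(freq)))
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from exc
    if not notes:
        raise ParseError(path, len(lines), "no note rows")
    return Melody(tuple(notes), id=id if id is not None else path.stem, is_rhythmic=is_rhythmic)


def write_note_track(melody: Melody, path) -> None:
    path = Path(path)
    rows = ["onset,dur,freq,note"]
    for n in melody.notes:
        rows.append(
            f"{n.onset!r},{n.duration!r},{midi_to_hz(n.pitch)!r},{round_midi(n.pitch)}"
        )
    path.write_text("\n".join(rows) + "\n")


def read_pitch_track(path) -> PitchTrack:
    """Read a frame-level (time, f0) table; empty/non-positive f0 -> unvoiced."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    header, sep = _split_header(lines[0])
    for col in ("time", "freq"):
        if col not in header:
            raise ParseError(path, 1, f"missing column {col!r} in header {header}")
    t_idx, f_idx = header.index("time"), header.index("freq")
    times, f0 = [], []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        try:
            t = float(cells[t_idx])
            f_cell = cells[f_idx].strip() if len(cells) > f_idx else ""
            f = float(f_cell) if f_cell else np.nan
        except ValueError as exc:
            raise ParseError(path, line_no, f"unparsable row: {line!r}") from exc
        times.append(t)
        f0.append(f)
    if len(times) < 2:
        raise ParseError(path, len(lines), "pitch track needs at least 2 frames")
    try:
        return PitchTrack(np.array(times), np.array(f0))
    except ValueError as exc:
        raise ParseError(path, 2, str(exc)) from exc


def write_pitch_track(track: PitchTrack, path) -> None:
    path = Path(path)
    rows = ["time,freq"]
    for t, f in zip(track.times, track.f0):
        rows.append(f"{float(t)!r}," + ("" if np.isnan(f) else repr(float(f))))
    path.write_text("\n".join(rows) + "\n")


# --- minimal standard-MIDI-file reader (format 0/1, monophonic melodies) ---

def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def read_midi_melody(path, id=None, is_rhythmic=True) -> Melody:
    """Read a monophonic melody from a standard MIDI file (format 0 or 1).

    The first track containing note events is used.  Tempo changes are
    honoured when converting ticks to seconds; overlapping notes are
    truncated at the next note's onset.
    """
    path = Path(path)
    data = path.read_bytes()
    if data[:4] != b"MThd":
        raise ParseError(path, 1, "not a standard MIDI file (missing MThd)")
    hlen, fmt, ntracks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ParseError(path, 1, "SMPTE time division is not supported")
    pos = 8 + hlen

    # collect (tick, tempo) changes across all tracks, then the note track
    tempo_changes = [(0, 500000)]  # default 120 bpm
    note_events = None  # list of (onset_tick, pitch) / offs
    for _ in range(ntracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ParseError(path, 1, "malformed track chunk")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        track = data[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen

        tick = 0
        p = 0
        status = 0
        ons, offs = [], []
        while p < len(track):
            delta, p = _read_varlen(track, p)
            tick += delta
            b = track[p]
            if b == 0xFF:  # meta
                meta_type = track[p + 1]
                length, q = _read_varlen(track, p + 2)
                payload = track[q : q + length]
                if meta_type == 0x51 and length == 3:
                    tempo_changes.append((tick, int.from_bytes(payload, "big")))
                p = q + length
            elif b in (0xF0, 0xF7):  # sysex
                length, q = _read_varlen(track, p + 1)
                p = q + length
            else:
                if b & 0x80:
                    status = b
                    p += 1
                kind = status & 0xF0
                if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                    d1, d2 = track[p], track[p + 1]
                    p += 2
                    if kind == 0x90 and d2 > 0:
                        ons.append((tick, d1))
                    elif kind == 0x80 or (kind == 0x90 and d2 == 0):
                        offs.append((tick, d1))
                elif kind in (0xC0, 0xD0):
                    p += 1
                else:
                    raise ParseError(path, 1, f"unexpected status byte {status:#x}")
        if ons and note_events is None:
            note_events = (ons, offs)
    if note_events is None:
        raise ParseError(path, 1, "no note events in any track")

    tempo_changes.sort()

    def tick_to_seconds(t: int) -> float:
        seconds = 0.0
        for (t0, tempo), nxt in zip(tempo_changes, tempo_changes[1:] + [(None, None)]):
            t1 = nxt[0] if nxt[0] is not None else t
            seg_end = min(t, t1)
            if seg_end > t0:
                seconds += (seg_end - t0) * tempo / (division * 1e6)
            if t <= t1:
                break
        return seconds

    ons, offs = note_events
    offs_by_pitch: dict[int, list[int]] = {}
    for t, pch in offs:
        offs_by_pitch.setdefault(pch, []).append(t)
    for v in offs_by_pitch.values():
        v.sort()

    notes = []
    for i, (on_tick, pch) in enumerate(sorted(ons)):
        cands = [t for t in offs_by_pitch.get(pch, []) if t > on_tick]
        off_tick = cands[0] if cands else on_tick + division
        if i + 1 < len(ons):
            off_tick = min(off_tick, sorted(ons)[i + 1][0])  # monophonic truncation
        onset = tick_to_seconds(on_tick)
        offset = tick_to_seconds(off_tick)
        if offset <= onset:
            continue
        notes.append(NoteEvent(onset, offset - onset, float(pch)))
    if not notes:
        raise ParseError(path, 1, "no playable notes after monophonic reduction")
    return Melody(tuple(notes), id=id if id is not None else path.stem, is_rhythmic=is_rhythmic)
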