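"""Domain types and pitch/sequence primitives.

Melodies are ordered note-event sequences (onset, duration, pitch); pitch
tracks are frame-level (time, f0) series as produced by pYIN-style
transcribers.  Pitch is carried as a real-valued MIDI number
(69 = A4 = 440 Hz, 12-tone equal temperament); rounding to the nearest
integer MIDI pitch is always an explicit, separate step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NoteEvent",
    "Melody",
    "PitchTrack",
    "hz_to_midi",
    "midi_to_hz",
    "round_midi",
    "cents_deviation",
    "intervals",
    "extract_ngrams",
]

A4_HZ = 440.0
A4_MIDI = 69.0


def hz_to_midi(f0):
    """Convert frequency in Hz to a real-valued MIDI number.

    12-TET mapping with A4 = 440 Hz = MIDI 69.  Accepts scalars or arrays;
    raises ``ValueError`` for non-positive frequencies.
    """
    f0_arr = np.asarray(f0, dtype=float)
    if np.any(f0_arr <= 0):
        raise ValueError("frequency must be positive to map to a MIDI number")
    out = A4_MIDI + 12.0 * np.log2(f0_arr / A4_HZ)
    return float(out) if np.isscalar(f0) or out.ndim == 0 else out


def midi_to_hz(midi):
    """Inverse of :func:`hz_to_midi`."""
    midi_arr = np.asarray(midi, dtype=float)
    out = A4_HZ * np.power(2.0, (midi_arr - A4_MIDI) / 12.0)
    return float(out) if np.isscalar(midi) or out.ndim == 0 else out


def round_midi(midi):
    """Round a real MIDI number to the nearest integer pitch.

    Uses round-half-away-from-zero, so x.5 always moves away from zero
    rather than to the nearest even integer.
    """
    arr = np.asarray(midi, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    out = out.astype(int)
    return int(out) if np.isscalar(midi) or out.ndim == 0 else out


def cents_deviation(f0, target_midi):
    """Signed deviation of ``f0`` (Hz) from an integer target MIDI pitch, in cents."""
    return 100.0 * (hz_to_midi(f0) - np.asarray(target_midi, dtype=float))


@dataclass(frozen=True)
class NoteEvent:
    """A single sung or notated note: onset and duration in seconds, pitch in MIDI."""

    onset: float
    duration: float
    pitch: float

    def __post_init__(self):
        object.__setattr__(self, "onset", float(self.onset))
        object.__setattr__(self, "duration", float(self.duration))
        object.__setattr__(self, "pitch", float(self.pitch))
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (0.0 <= self.pitch <= 127.0):
            raise ValueError(f"pitch must lie in [0, 127], got {self.pitch}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Melody:
    """An ordered monophonic sequence of note events.

    ``is_rhythmic`` distinguishes rhythmic stimuli (heterogeneous durations)
    from arhythmic ones, which are rendered with a uniform note duration.
    """

    notes: tuple[NoteEvent, ...]
    id: str = ""
    is_rhythmic: bool = True

    def __post_init__(self):
        notes = tuple(self.notes)
        object.__setattr__(self, "notes", notes)
        if len(notes) == 0:
            raise ValueError("a Melody needs at least one note")
        onsets = [n.onset for n in notes]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("notes must be sorted by onset")

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([n.pitch for n in self.notes], dtype=float)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([n.onset for n in self.notes], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([n.duration for n in self.notes], dtype=float)

    @property
    def rounded_pitches(self) -> np.ndarray:
        return round_midi(self.pitches)

    @property
    def total_duration(self) -> float:
        return float(self.notes[-1].offset - self.notes[0].onset)

    def transposed(self, semitones: float) -> "Melody":
        """Return a copy with every pitch shifted by ``semitones``."""
        notes = tuple(replace(n, pitch=n.pitch + semitones) for n in self.notes)
        return Melody(notes, id=self.id, is_rhythmic=self.is_rhythmic)

    @classmethod
    def from_arrays(cls, onsets, durations, pitches, id="", is_rhythmic=True):
        notes = tuple(
            NoteEvent(float(o), float(d), float(p))
            for o, d, p in zip(onsets, durations, pitches)
        )
        return cls(notes, id=id, is_rhythmic=is_rhythmic)

    @classmethod
    def from_pitches(cls, pitches, note_duration=0.25, id="", is_rhythmic=False):
        """Build an isochronous (arhythmic-style) melody from a pitch list."""
        pitches = list(pitches)
        onsets = [i * note_duration for i in range(len(pitches))]
        durations = [note_duration] * len(pitches)
        return cls.from_arrays(onsets, durations, pitches, id=id, is_rhythmic=is_rhythmic)


@dataclass(frozen=True)
class PitchTrack:
    """Frame-level fundamental-frequency series.

    ``f0`` is in Hz; unvoiced frames are NaN.  Frames with f0 <= 0 on input
    are treated as unvoiced, never silently dropped: dropping them would
    bias variance and autocorrelation statistics downstream.
    """

    times: np.ndarray
    f0: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        f0 = np.asarray(self.f0, dtype=float)
        if times.shape != f0.shape or times.ndim != 1:
            raise ValueError("times and f0 must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        f0 = np.where(f0 <= 0, np.nan, f0)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f0", f0)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def voiced_mask(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def n_voiced(self) -> int:
        return int(self.voiced_mask.sum())

    def voiced(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, f0) restricted to voiced frames."""
        m = self.voiced_mask
        return self.times[m], self.f0[m]


def intervals(melody: Melody) -> np.ndarray:
    """Signed semitone intervals between successive rounded MIDI pitches."""
    if len(melody) < 2:
        raise ValueError("intervals need a melody of at least two notes")
    return np.diff(melody.rounded_pitches)


def extract_ngrams(seq: Sequence, n: int) -> list[tuple]:
    """All contiguous length-``n`` windows of ``seq``, in order.

    Returns an empty list when the sequence is shorter than ``n``.
    """
    if n < 1:
        raise ValueError(f"n-gram length must be >= 1, got {n}")
    seq = list(seq)
    return [tuple(seq[i : i + n]) for i in range(len(seq) - n + 1)]
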