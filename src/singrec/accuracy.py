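"""Low-level singing accuracy and precision measures.

These are the Pfordresher-style note/interval accuracy and precision
statistics, plus the proportion-of-correct-note-events score used as the
rehearsal-paradigm outcome.  Alignment between target and sung melody is
positional (index by index up to the shorter length); edit-based alignment
is deliberately left to the similarity measures so the two measurement
families stay independent.  All pitch deviations are expressed in cents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Melody, round_midi

__all__ = [
    "AccuracyMeasures",
    "proportion_of_correct_note_events",
    "note_measures",
    "interval_measures",
    "accuracy_measures",
]


@dataclass(frozen=True)
class AccuracyMeasures:
    melody_note_accuracy: float
    melody_note_precision: float  # NaN when no target pitch recurs
    interval_accuracy: float
    interval_precision: float  # NaN when no target interval recurs
    proportion_of_correct_note_events: float


def proportion_of_correct_note_events(target: Melody, sung: Melody,
                                      octave_equivalent: bool = False) -> float:
    """Share of sung notes whose rounded MIDI pitch occurs in the target.

    "Correct" means membership of the target's rounded pitch set (not
    positional agreement), so the measure is invariant to the order of the
    sung notes.  With ``octave_equivalent`` membership is tested on pitch
    classes instead of absolute MIDI numbers.
    """
    if len(sung) == 0:
        raise ValueError("sung melody is empty")
    t = round_midi(target.pitches)
    s = round_midi(sung.pitches)
    if octave_equivalent:
        t, s = t % 12, s % 12
    target_set = set(int(p) for p in np.atleast_1d(t))
    hits = sum(1 for p in np.atleast_1d(s) if int(p) in target_set)
    return hits / len(sung)


def _acc_prec(target_vals: np.ndarray, sung_vals: np.ndarray) -> tuple[float, float]:
    """Positional accuracy (mean |dev| in cents) and precision.

    Precision is the mean, over target values occurring at least twice in
    the aligned region, of the standard deviation (in cents, ddof=1) of the
    sung values produced for that target value; NaN when nothing recurs.
    """
    m = min(len(target_vals), len(sung_vals))
    if m == 0:
        raise ValueError("no aligned pairs")
    t, s = target_vals[:m], sung_vals[:m]
    accuracy = float(np.mean(np.abs(s - t)) * 100.0)
    sds = []
    for val in np.unique(np.round(t).astype(int)):
        sel = np.round(t).astype(int) == val
        if sel.sum() >= 2:
            sds.append(np.std(s[sel] * 100.0, ddof=1))
    precision = float(np.mean(sds)) if sds else float("nan")
    return accuracy, precision


def note_measures(target: Melody, sung: Melody) -> tuple[float, float]:
    """(melody_note_accuracy, melody_note_precision) in cents."""
    return _acc_prec(target.pitches, sung.pitches)


def interval_measures(target: Melody, sung: Melody) -> tuple[float, float]:
    """(interval_accuracy, interval_precision) in cents, on unrounded intervals."""
    if len(target) < 2 or len(sung) < 2:
        raise ValueError("interval measures need at least two notes in each melody")
    return _acc_prec(np.diff(target.pitches), np.diff(sung.pitches))


def accuracy_measures(target: Melody, sung: Melody) -> AccuracyMeasures:
    """All five accuracy/precision measures for one target/recall pair."""
    na, np_ = note_measures(target, sung)
    ia, ip = interval_measures(target, sung)
    return AccuracyMeasures(
        melody_note_accuracy=na,
        melody_note_precision=np_,
        interval_accuracy=ia,
        interval_precision=ip,
        proportion_of_correct_note_events=proportion_of_correct_note_events(target, sung),
    )
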