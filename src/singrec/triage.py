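"""Input triage: signal-to-noise gating and vocal-range transposition.

Online singing data is only usable when the recording environment is
quiet enough for pitch transcription — pYIN accuracy degrades sharply
below an SNR of about 14 dB, which is the default gate.  Stimuli are
transposed so their mean pitch sits at the centre of the participant's
sung vocal range, estimated robustly (median of voiced frames) from a low
note and a high note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Melody, PitchTrack, hz_to_midi, round_midi

__all__ = [
    "SNRResult",
    "VocalRange",
    "rms",
    "compute_snr",
    "estimate_range",
    "transpose_to_range",
    "SNR_THRESHOLD_DB",
]

SNR_THRESHOLD_DB = 14.0


@dataclass(frozen=True)
class SNRResult:
    rms_signal: float
    rms_noise: float
    snr_db: float
    passes: bool


@dataclass(frozen=True)
class VocalRange:
    low_midi: int
    high_midi: int

    def __post_init__(self):
        if self.low_midi >= self.high_midi:
            raise ValueError(
                f"vocal range inverted or empty: low {self.low_midi} >= high {self.high_midi}"
            )

    @property
    def mean_midi(self) -> float:
        return (self.low_midi + self.high_midi) / 2.0


def rms(samples) -> float:
    """Root mean square of a sample vector."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty vector")
    return float(np.sqrt(np.mean(x * x)))


def compute_snr(signal, noise, threshold: float = SNR_THRESHOLD_DB) -> SNRResult:
    """SNR in dB: 20*log10(RMS_signal / RMS_noise), gated at ``threshold``.

    A silent noise recording (zero RMS) makes the ratio undefined and is
    reported as such, distinctly from a below-threshold failure.
    """
    rs, rn = rms(signal), rms(noise)
    if rn == 0:
        raise ZeroDivisionError("noise recording is silent: SNR undefined, re-record")
    snr = 20.0 * np.log10(rs / rn)
    return SNRResult(rms_signal=rs, rms_noise=rn, snr_db=float(snr), passes=bool(snr >= threshold))


def estimate_range(low_track: PitchTrack, high_track: PitchTrack,
                   min_voiced: int = 10) -> VocalRange:
    """Vocal range from a sung low note and high note.

    Each endpoint is the rounded median MIDI pitch of that track's voiced
    frames — the median survives a sprinkling of octave-error frames.  An
    inverted result (high <= low) is an input error, typically the notes
    sung in the wrong order.
    """
    ends = []
    for name, track in (("low", low_track), ("high", high_track)):
        if track.n_voiced < min_voiced:
            raise ValueError(f"{name}-note track has fewer than {min_voiced} voiced frames")
        _, f0 = track.voiced()
        ends.append(round_midi(float(np.median(hz_to_midi(f0)))))
    return VocalRange(low_midi=ends[0], high_midi=ends[1])


def transpose_to_range(melody: Melody, vocal_range: VocalRange) -> Melody:
    """Shift a melody by whole semitones so its mean pitch matches the range centre.

    The shift is round-half-away-from-zero of (range mean - melody mean),
    keeping all intervals exactly intact.  A melody already within half a
    semitone of the range centre is left alone, which also makes the
    operation idempotent at exact half-semitone residuals.  Pitches pushed
    outside the MIDI range [0, 127] are an error.
    """
    diff = vocal_range.mean_midi - float(np.mean(melody.pitches))
    shift = 0 if abs(diff) <= 0.5 else round_midi(diff)
    out = melody.transposed(float(shift))
    if np.any(out.pitches < 0) or np.any(out.pitches > 127):
        raise ValueError("transposition pushes pitches outside the MIDI range [0, 127]")
    return out
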