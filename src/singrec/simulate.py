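"""Synthetic singers and synthetic studies.

Every scoring and modelling stage in the package can be exercised without
recorded audio: ``simulate_recall`` produces an error-laden sung version
of a target melody (Gaussian pitch error in cents, note deletions and
insertions, log-normal duration jitter); ``simulate_long_note`` produces a
sustained-note pitch track with drift, an exponential onset "scoop",
vibrato and frame noise; ``simulate_study`` generates a whole
multi-participant trial table in which a latent per-participant ability
and item features jointly drive the outcome, matching the structure of
the explanatory item-response models fitted downstream.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Melody, NoteEvent, PitchTrack, midi_to_hz
from .features import ItemFeatures
from .itembank import DifficultyModel, ItemBankEntry, predict_item_score

__all__ = [
    "SingerParams",
    "LongNoteParams",
    "simulate_recall",
    "simulate_long_note",
    "simulate_study",
]

LONG_NOTE_DURATION_S = 5.0  # recorded sustained-note trials are 5000 ms
DEFAULT_FRAME_RATE_HZ = 100.0


@dataclass(frozen=True)
class SingerParams:
    """Error profile of a simulated singer for melodic recall."""

    pitch_sd: float = 50.0  # cents
    p_delete: float = 0.0
    p_insert: float = 0.0
    duration_jitter_sd: float = 0.0  # SD of log duration multiplier
    seed: int = 0

    def __post_init__(self):
        if self.pitch_sd < 0 or self.duration_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for p in (self.p_delete, self.p_insert):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class LongNoteParams:
    """Shape of a simulated sustained-note pitch track.

    The deviation from the target (in cents) is
    drift*t - scoop_depth*exp(-t/scoop_tau) + vibrato + white noise;
    the scoop term reproduces the under-pitched onset glide the second
    changepoint is meant to pick up.
    """

    target_midi: int = 60
    duration: float = LONG_NOTE_DURATION_S
    frame_rate: float = DEFAULT_FRAME_RATE_HZ
    noise_sd: float = 0.0  # cents
    drift: float = 0.0  # cents / s
    scoop_depth: float = 0.0  # cents
    scoop_tau: float = 0.3  # s
    vibrato_amp: float = 0.0  # cents
    vibrato_rate: float = 5.5  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")


def simulate_recall(target: Melody, params: SingerParams) -> Melody:
    """A noisy sung rendition of ``target``.

    Per note: delete with p_delete; otherwise perturb the pitch by
    N(0, pitch_sd) cents and the duration multiplicatively by
    exp(N(0, duration_jitter_sd)); then, with p_insert, add an extra note
    at a uniformly chosen pitch near the melody's register.  If every note
    is deleted the draw is retried once before failing.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = float(target.pitches.min()) - 5, float(target.pitches.max()) + 5
    for _ in range(2):
        events = []
        for note in target.notes:
            if rng.random() < params.p_delete:
                continue
            pitch = note.pitch + rng.normal(0.0, params.pitch_sd) / 100.0
            dur = note.duration * np.exp(rng.normal(0.0, params.duration_jitter_sd))
            events.append((pitch, dur))
            if rng.random() < params.p_insert:
                events.append((rng.uniform(lo, hi), dur))
        if events:
            break
    else:
        raise ValueError("simulated singer deleted every note (twice); lower p_delete")
    onset = 0.0
    notes = []
    for pitch, dur in events:
        notes.append(NoteEvent(onset, dur, float(np.clip(pitch, 0.0, 127.0))))
        onset += dur
    return Melody(tuple(notes), id=f"{target.id}~recall", is_rhythmic=target.is_rhythmic)


def simulate_long_note(params: LongNoteParams) -> PitchTrack:
    """A sustained-note pitch track around ``target_midi`` (all frames voiced)."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    cents = (
        params.drift * t
        - params.scoop_depth * np.exp(-t / params.scoop_tau)
        + params.vibrato_amp * np.sin(2 * np.pi * params.vibrato_rate * t)
        + rng.normal(0.0, params.noise_sd, size=n)
    )
    f0 = midi_to_hz(params.target_midi + cents / 100.0)
    return PitchTrack(t, f0)


def simulate_study(
    n_participants: int,
    items: list[ItemBankEntry],
    ability_sd: float = 0.1,
    model: DifficultyModel | str = "arhythmic",
    noise_sd: float = 0.1,
    seed: int = 0,
    trial_type: str = "arhythmic",
) -> pd.DataFrame:
    """A full synthetic trial table under an explanatory item-response model.

    Participant abilities are N(0, ability_sd); each participant attempts
    every item once and the outcome is
    clip(intercept + sum(beta*feature) + ability, 0, 1) plus truncated-
    normal noise, kept inside [0, 1] to match the linear-model analysis.
    Columns mirror the trial-record layout consumed by the analysis module.
    """
    for it in items:
        if it.features is None:
            raise ValueError(f"item {it.item_id} has no features")
    rng = np.random.default_rng(seed)
    abilities = rng.normal(0.0, ability_sd, size=n_participants)
    rows = []
    for p in range(n_participants):
        for it in items:
            mu = predict_item_score(it.features, model, melody_type=trial_type)
            mu_lin = float(np.clip(mu + abilities[p], 0.0, 1.0))
            # truncated-normal noise keeps the outcome on the [0,1] scale
            for _ in range(1000):
                outcome = mu_lin + rng.normal(0.0, noise_sd) if noise_sd > 0 else mu_lin
                if 0.0 <= outcome <= 1.0:
                    break
            else:
                outcome = float(np.clip(mu_lin, 0.0, 1.0))
            f = it.features
            rows.append(
                {
                    "participant_id": f"p{p:04d}",
                    "item_id": it.item_id,
                    "trial_type": trial_type,
                    "attempt": 1,
                    "N": f.N,
                    "i_entropy": f.i_entropy,
                    "d_entropy": f.d_entropy,
                    "tonalness": f.tonalness,
                    "step_cont_loc_var": f.step_cont_loc_var,
                    "log_freq": f.log_freq,
                    "outcome": float(np.clip(outcome, 0.0, 1.0)),
                    "ability_true": abilities[p],
                }
            )
    return pd.DataFrame(rows)
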