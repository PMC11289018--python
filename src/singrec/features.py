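"""Melodic structure features used as item covariates in difficulty models.

Five features: note count N, normalised interval entropy (i_entropy),
normalised duration-class entropy (d_entropy), tonalness (peak Krumhansl
key correlation), local step-contour variation, and the corpus-relative
log frequency of the item's interval sequence.  Entropies are normalised
to [0, 1]; tonalness is a Pearson correlation; step_cont_loc_var follows
the FANTASTIC convention of sampling a duration-weighted pitch step
function at 64 equidistant points.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, log2

import numpy as np

from .core import Melody, intervals
from .similarity import _best_key, _pc_profile, fuzzify_durations, key_label

__all__ = [
    "ItemFeatures",
    "i_entropy",
    "d_entropy",
    "tonalness",
    "step_cont_loc_var",
    "ngram_log_freq",
    "item_features",
]

INTERVAL_CLAMP = 12  # intervals clamped to [-12, +12]: 25 classes
N_DURATION_CLASSES = 5
CONTOUR_SAMPLES = 64


@dataclass(frozen=True)
class ItemFeatures:
    N: int
    i_entropy: float
    d_entropy: float
    tonalness: float
    step_cont_loc_var: float
    log_freq: float


def _norm_entropy(counts: np.ndarray, n_classes: int) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    h = -np.sum(p * np.log2(p))
    return float(h / log2(n_classes))


def i_entropy(melody: Melody) -> float:
    """Normalised Shannon entropy of the interval distribution.

    Intervals are clamped to +/-12 semitones (25 classes); the entropy is
    divided by log2(25) so the value lies in [0, 1].
    """
    iv = np.clip(intervals(melody), -INTERVAL_CLAMP, INTERVAL_CLAMP)
    _, counts = np.unique(iv, return_counts=True)
    return _norm_entropy(counts, 2 * INTERVAL_CLAMP + 1)


def d_entropy(melody: Melody) -> float:
    """Normalised entropy of the fuzzified duration-class distribution."""
    classes = fuzzify_durations(melody.durations)
    _, counts = np.unique(classes, return_counts=True)
    return _norm_entropy(counts, N_DURATION_CLASSES)


def tonalness(melody: Melody) -> tuple[float, str]:
    """Peak correlation with the 24 Krumhansl key profiles, plus the key.

    The melody's duration-weighted pitch-class profile is correlated with
    every rotated major/minor profile; the maximum is the tonalness and
    the argmax key is returned as e.g. ``"C major"``.  A single-pitch-class
    profile has no variance and no defined correlation.
    """
    contrib = [(int(round(n.pitch)) % 12, n.duration) for n in melody.notes]
    profile = _pc_profile(contrib)
    if np.count_nonzero(profile) < 2:
        raise ValueError("tonalness undefined: melody uses a single pitch class")
    tonic, mode, corr = _best_key(profile)
    if np.isnan(corr):
        # perfectly flat multi-class profile: no key preference at all
        return 0.0, key_label(tonic, mode)
    return float(corr), key_label(tonic, mode)


def step_contour(melody: Melody, samples: int = CONTOUR_SAMPLES) -> np.ndarray:
    """Duration-weighted pitch step function sampled at equidistant points."""
    bounds = np.concatenate([[melody.notes[0].onset], [n.offset for n in melody.notes]])
    # normalised time grid over the melody's span
    t = np.linspace(bounds[0], bounds[-1], samples, endpoint=False)
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(melody) - 1)
    return melody.pitches[idx]


def step_cont_loc_var(melody: Melody, samples: int = CONTOUR_SAMPLES) -> float:
    """Mean absolute difference between adjacent step-contour samples (semitones)."""
    if len(melody) < 2:
        raise ValueError("step_cont_loc_var needs at least two notes")
    c = step_contour(melody, samples)
    return float(np.mean(np.abs(np.diff(c))))


def ngram_log_freq(melody: Melody, corpus_counts: dict) -> float:
    """Natural-log relative frequency of the item's interval sequence.

    ``corpus_counts`` maps interval-sequence tuples (all of one length) to
    their corpus counts.  Items unseen in the corpus get a 0.5 pseudo-count
    so the log stays finite.
    """
    if not corpus_counts:
        raise ValueError("empty corpus count table")
    key = tuple(int(v) for v in intervals(melody))
    total = sum(corpus_counts.values())
    count = corpus_counts.get(key, 0)
    return log((count if count > 0 else 0.5) / total)


def item_features(melody: Melody, corpus_counts: dict | None = None) -> ItemFeatures:
    """The full feature vector for one item.

    log_freq is NaN unless a corpus count table for the item's length is
    supplied.
    """
    ton, _ = tonalness(melody)
    return ItemFeatures(
        N=len(melody),
        i_entropy=i_entropy(melody),
        d_entropy=d_entropy(melody),
        tonalness=ton,
        step_cont_loc_var=step_cont_loc_var(melody),
        log_freq=(
            ngram_log_freq(melody, corpus_counts) if corpus_counts is not None else float("nan")
        ),
    )
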