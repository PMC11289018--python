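"""Melodic similarity: the opti3 score and its three components.

opti3 is a weighted combination of three complementary similarity measures
between a target melody and a sung recall:

* ``ngrukkon`` — Ukkonen-style similarity of interval n-gram count
  profiles (interval content);
* ``rhythfuzz`` — normalised edit distance over coarse ("fuzzified")
  duration classes (rhythm);
* ``harmcore`` — normalised edit distance over per-segment implied
  key labels from the Krumhansl–Schmuckler key-finding algorithm
  (implied harmony).

The published weights are 3.027, 2.502 and 1.439.  Because the raw
weighted sum reaches 6.968 for identical melodies while the score is
modelled on [0, 1], the combination is divided by the weight sum by
default (``normalize=True``), so identity maps to 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .core import Melody, extract_ngrams, intervals

__all__ = [
    "SimilarityWeights",
    "SimilarityResult",
    "KRUMHANSL_MAJOR",
    "KRUMHANSL_MINOR",
    "edit_distance",
    "edit_sim",
    "ngrukkon",
    "fuzzify_durations",
    "rhythfuzz",
    "implied_harmony",
    "key_label",
    "harmcore",
    "opti3",
]

# Krumhansl (1990) probe-tone key profiles, C-rooted.
KRUMHANSL_MAJOR = np.array(
    [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88]
)
KRUMHANSL_MINOR = np.array(
    [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
)

_PC_NAMES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]

DURATION_CLASS_NAMES = ("very short", "short", "medium", "long", "very long")
_FUZZ_BOUNDARIES = np.array([-1.5, -0.5, 0.5, 1.5])


@dataclass(frozen=True)
class SimilarityWeights:
    """Component weights of the opti3 combination."""

    w_ngrukkon: float = 3.027
    w_rhythfuzz: float = 2.502
    w_harmcore: float = 1.439
    normalize: bool = True

    def __post_init__(self):
        if min(self.w_ngrukkon, self.w_rhythfuzz, self.w_harmcore) <= 0:
            raise ValueError("similarity weights must be positive")

    @property
    def total(self) -> float:
        return self.w_ngrukkon + self.w_rhythfuzz + self.w_harmcore


@dataclass(frozen=True)
class SimilarityResult:
    ngrukkon: float
    rhythfuzz: float
    harmcore: float
    opti3: float


def edit_distance(a, b) -> int:
    """Levenshtein distance with unit insert/delete/substitute costs."""
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i]
        for j, y in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def edit_sim(a, b) -> float:
    """Length-normalised edit similarity: 1 - d(a,b)/max(|a|,|b|)."""
    a, b = list(a), list(b)
    longer = max(len(a), len(b))
    if longer == 0:
        raise ValueError("edit_sim is undefined for two empty sequences")
    return 1.0 - edit_distance(a, b) / longer


def _ngram_profile(melody: Melody, n: int) -> Counter:
    return Counter(extract_ngrams([int(v) for v in intervals(melody)], n))


def ngrukkon(a: Melody, b: Melody, n: int = 3) -> float:
    """Ukkonen similarity of interval n-gram count profiles.

    1 - sum_tau |f_a(tau) - f_b(tau)| / (N_a + N_b) where N_x counts the
    n-gram tokens of melody x.  When either melody is too short for the
    requested n, n falls back to the shorter melody's interval count so
    that 2–3-note items remain scorable.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ngrukkon needs melodies of at least two notes")
    n_eff = min(n, len(a) - 1, len(b) - 1)
    fa, fb = _ngram_profile(a, n_eff), _ngram_profile(b, n_eff)
    total = sum(fa.values()) + sum(fb.values())
    diff = sum(abs(fa[t] - fb[t]) for t in set(fa) | set(fb))
    return 1.0 - diff / total


def fuzzify_durations(durations) -> np.ndarray:
    """Map note durations to 5 coarse classes (0..4, very short .. very long).

    Classes are assigned by log2(d / median(d)) against boundaries
    -1.5, -0.5, +0.5, +1.5, so the classification is invariant to uniform
    tempo scaling.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("fuzzify_durations needs at least one duration")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    ratio = np.log2(d / np.median(d))
    return np.searchsorted(_FUZZ_BOUNDARIES, ratio, side="left").astype(int)


def rhythfuzz(a: Melody, b: Melody) -> float:
    """Edit similarity of the two melodies' duration-class sequences."""
    return edit_sim(fuzzify_durations(a.durations), fuzzify_durations(b.durations))


def _key_correlations(pc_weights: np.ndarray) -> np.ndarray:
    """Pearson correlation of a 12-dim pitch-class profile with all 24 keys.

    Returns shape (24,): index k < 12 -> major key with tonic k,
    k >= 12 -> minor key with tonic k-12.
    """
    out = np.empty(24)
    x = pc_weights - pc_weights.mean()
    xn = np.linalg.norm(x)
    for mode, profile in enumerate((KRUMHANSL_MAJOR, KRUMHANSL_MINOR)):
        for tonic in range(12):
            p = np.roll(profile, tonic)
            y = p - p.mean()
            denom = xn * np.linalg.norm(y)
            out[mode * 12 + tonic] = np.nan if denom == 0 else float(x @ y) / denom
    return out


def _best_key(pc_weights: np.ndarray) -> tuple[int, str, float]:
    """(tonic pitch class, mode, correlation) of the best-matching key.

    Ties break deterministically: lowest tonic pitch class first, major
    before minor at the same tonic.
    """
    corr = _key_correlations(pc_weights)
    if np.all(np.isnan(corr)):
        return 0, "major", np.nan
    best = (-np.inf, 0, 0)
    for tonic in range(12):
        for mode_i in range(2):  # major first
            c = corr[mode_i * 12 + tonic]
            if not np.isnan(c) and c > best[0] + 1e-12:
                best = (c, tonic, mode_i)
    return best[1], ("major", "minor")[best[2]], best[0]


def key_label(tonic: int, mode: str) -> str:
    return f"{_PC_NAMES[tonic % 12]} {mode}"


def _pc_profile(notes) -> np.ndarray:
    w = np.zeros(12)
    for pc, dur in notes:
        w[pc % 12] += dur
    return w


def implied_harmony(melody: Melody, segment_length: float = 2.0) -> list[tuple[int, str]]:
    """Per-segment implied key labels via the Krumhansl–Schmuckler algorithm.

    The melody is cut into contiguous time windows of ``segment_length``
    seconds (the last may be shorter).  Within each window the
    duration-weighted pitch-class profile (note durations clipped to the
    window) is correlated with the 24 rotated Krumhansl profiles and the
    argmax key is emitted as a (tonic pitch class, mode) pair.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    t0 = melody.notes[0].onset
    t_end = max(n.offset for n in melody.notes)
    labels = []
    seg_start = t0
    while seg_start < t_end - 1e-12:
        seg_end = seg_start + segment_length
        contrib = []
        for note in melody.notes:
            overlap = min(note.offset, seg_end) - max(note.onset, seg_start)
            if overlap > 1e-12:
                contrib.append((int(round(note.pitch)) % 12, overlap))
        if contrib:
            tonic, mode, _ = _best_key(_pc_profile(contrib))
            labels.append((tonic, mode))
        seg_start = seg_end
    if not labels:  # degenerate: single very short note
        tonic, mode, _ = _best_key(_pc_profile([(int(round(melody.notes[0].pitch)) % 12, 1.0)]))
        labels.append((tonic, mode))
    return labels


def harmcore(a: Melody, b: Melody, segment_length: float = 2.0) -> float:
    """Edit similarity of the two melodies' implied-harmony label sequences."""
    return edit_sim(implied_harmony(a, segment_length), implied_harmony(b, segment_length))


def opti3(
    a: Melody,
    b: Melody,
    weights: SimilarityWeights | None = None,
    n: int = 3,
    segment_length: float = 2.0,
    average_ngram_lengths: bool = False,
) -> SimilarityResult:
    """The combined melodic-similarity score between target and recall.

    With ``average_ngram_lengths`` the ngrukkon component is averaged over
    n-gram lengths 3..8 (lengths the melodies can support); otherwise the
    single length ``n`` (default 3, with short-melody fallback) is used.
    """
    w = weights if weights is not None else SimilarityWeights()
    if average_ngram_lengths:
        ns = range(3, 9)
        vals = [ngrukkon(a, b, n=k) for k in ns]
        ng = float(np.mean(vals))
    else:
        ng = ngrukkon(a, b, n=n)
    rf = rhythfuzz(a, b)
    hc = harmcore(a, b, segment_length)
    score = w.w_ngrukkon * ng + w.w_rhythfuzz * rf + w.w_harmcore * hc
    if w.normalize:
        score /= w.total
    return SimilarityResult(ngrukkon=ng, rhythfuzz=rf, harmcore=hc, opti3=float(score))
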