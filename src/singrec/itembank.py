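"""Corpus tokenization into a feature-annotated, difficulty-predicted item bank.

A melody corpus is split into all contiguous n-note sub-melodies
(n = 3..15 by default, 15 notes being a practical upper bound on
short-term memory span for unknown melodies), duplicates are removed on a
transposition-robust key (the interval sequence; rhythmic banks
additionally require an identical duration-class sequence), and every
surviving item is annotated with its melodic features and with predicted
performance scores for arhythmic and rhythmic presentation.  Predicted
score is a fixed-effects linear predictor from published mixed-model
coefficients; lower predicted score means a harder item.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Melody, intervals
from .features import ItemFeatures, item_features
from .similarity import fuzzify_durations

__all__ = [
    "DifficultyModel",
    "ARHYTHMIC_MODEL",
    "RHYTHMIC_MODEL",
    "COMBINED_MODEL",
    "ItemBankEntry",
    "tokenize_corpus",
    "build_corpus_counts",
    "predict_item_score",
    "build_bank",
    "read_bank",
]


@dataclass(frozen=True)
class DifficultyModel:
    """Fixed-effects coefficients of an item-difficulty regression.

    ``coefficients`` maps feature names (fields of ItemFeatures, plus the
    indicator/interaction terms of the combined model) to their weights.
    """

    intercept: float
    coefficients: dict

    def required_features(self) -> list[str]:
        return list(self.coefficients)


# published fixed-effects estimates for the three model specifications
ARHYTHMIC_MODEL = DifficultyModel(
    intercept=0.74,
    coefficients={"N": -0.01, "step_cont_loc_var": -0.32, "tonalness": 0.13, "log_freq": 0.02},
)
RHYTHMIC_MODEL = DifficultyModel(
    intercept=0.37,
    coefficients={
        "N": -0.01,
        "step_cont_loc_var": -0.50,
        "log_freq": -0.02,
        "d_entropy": -0.26,
        "i_entropy": -0.19,
    },
)
# combined model over both trial types, with a melody_type main effect and
# a melody_type x d_entropy interaction
COMBINED_MODEL = DifficultyModel(
    intercept=0.64,
    coefficients={
        "N": -0.01,
        "step_cont_loc_var": -0.38,
        "tonalness": 0.10,
        "log_freq": 0.01,
        "melody_type_rhythmic": -0.15,
        "arhythmic_x_d_entropy": -0.08,
        "rhythmic_x_d_entropy": -0.28,
    },
)

_MODELS = {"arhythmic": ARHYTHMIC_MODEL, "rhythmic": RHYTHMIC_MODEL, "combined": COMBINED_MODEL}


@dataclass(frozen=True)
class ItemBankEntry:
    item_id: str
    source_melody_id: str
    start_index: int
    melody: Melody
    features: ItemFeatures | None = None
    predicted_score_arhythmic: float = float("nan")
    predicted_score_rhythmic: float = float("nan")


def _sub_melody(melody: Melody, start: int, n: int) -> Melody:
    notes = melody.notes[start : start + n]
    shift = notes[0].onset
    from .core import NoteEvent

    shifted = tuple(NoteEvent(nt.onset - shift, nt.duration, nt.pitch) for nt in notes)
    return Melody(shifted, id=f"{melody.id}:{start}:{n}", is_rhythmic=melody.is_rhythmic)


def tokenize_corpus(
    corpus: list[Melody],
    n_min: int = 3,
    n_max: int = 15,
    rhythmic: bool = False,
    deduplicate: bool = True,
) -> list[ItemBankEntry]:
    """All contiguous n-note windows of every corpus melody, deduplicated.

    The dedup key is the interval sequence; for rhythmic banks the
    duration-class sequence is part of the key as well, since rhythm then
    carries item identity.  First occurrence wins; ordering is
    deterministic (corpus order, start index, length).
    """
    if n_min < 2:
        raise ValueError("n_min must be >= 2 (an item needs at least one interval)")
    if n_max < n_min:
        raise ValueError("n_max must be >= n_min")
    seen: set = set()
    entries: list[ItemBankEntry] = []
    for melody in corpus:
        L = len(melody)
        for start in range(L):
            for n in range(n_min, n_max + 1):
                if start + n > L:
                    break
                sub = _sub_melody(melody, start, n)
                key: tuple = tuple(int(v) for v in intervals(sub))
                if rhythmic:
                    key = (key, tuple(int(c) for c in fuzzify_durations(sub.durations)))
                if deduplicate:
                    if key in seen:
                        continue
                    seen.add(key)
                entries.append(
                    ItemBankEntry(
                        item_id=f"item{len(entries):06d}",
                        source_melody_id=melody.id,
                        start_index=start,
                        melody=sub,
                    )
                )
    return entries


def build_corpus_counts(corpus: list[Melody], n_min: int = 3, n_max: int = 15) -> dict[int, Counter]:
    """Per-length frequency tables of interval sequences over all corpus windows."""
    tables: dict[int, Counter] = {n: Counter() for n in range(n_min, n_max + 1)}
    for melody in corpus:
        iv = [int(v) for v in intervals(melody)] if len(melody) >= 2 else []
        for n in range(n_min, n_max + 1):
            k = n - 1  # interval-sequence length for an n-note window
            for i in range(len(iv) - k + 1):
                tables[n][tuple(iv[i : i + k])] += 1
    return tables


def predict_item_score(features: ItemFeatures, model: DifficultyModel | str,
                       melody_type: str | None = None) -> float:
    """Fixed-effects linear predictor of expected performance, clipped to [0, 1].

    ``model`` may be a DifficultyModel or one of "arhythmic", "rhythmic",
    "combined"; the combined model additionally needs ``melody_type``.
    """
    if isinstance(model, str):
        model = _MODELS[model]
    x = model.intercept
    for name, beta in model.coefficients.items():
        if name == "melody_type_rhythmic":
            x += beta * (1.0 if melody_type == "rhythmic" else 0.0)
        elif name == "arhythmic_x_d_entropy":
            x += beta * (features.d_entropy if melody_type == "arhythmic" else 0.0)
        elif name == "rhythmic_x_d_entropy":
            x += beta * (features.d_entropy if melody_type == "rhythmic" else 0.0)
        else:
            val = getattr(features, name, None)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise ValueError(f"missing feature {name!r} for difficulty prediction")
            x += beta * float(val)
    return float(np.clip(x, 0.0, 1.0))


_BANK_COLUMNS = [
    "item_id", "source", "start", "length", "pitches", "durations",
    "N", "i_entropy", "d_entropy", "tonalness", "step_cont_loc_var", "log_freq",
    "predicted_score_arhythmic", "predicted_score_rhythmic",
]


def build_bank(
    corpus: list[Melody],
    out_path=None,
    n_min: int = 3,
    n_max: int = 15,
    rhythmic: bool = False,
) -> pd.DataFrame:
    """Tokenize, annotate and difficulty-predict a corpus into a bank table.

    Items whose tonalness is undefined (single pitch class) are annotated
    with NaN tonalness and skipped by the arhythmic prediction, which
    requires it.  The result is deterministic for fixed inputs; writing the
    same corpus twice yields byte-identical files.
    """
    entries = tokenize_corpus(corpus, n_min=n_min, n_max=n_max, rhythmic=rhythmic)
    counts = build_corpus_counts(corpus, n_min=n_min, n_max=n_max)
    rows = []
    for e in entries:
        table = counts[len(e.melody)]
        try:
            feats = item_features(e.melody, table)
        except ValueError:  # single-pitch-class item: tonalness undefined
            from .features import ItemFeatures as IF, d_entropy, i_entropy, ngram_log_freq, step_cont_loc_var

            feats = IF(
                N=len(e.melody),
                i_entropy=i_entropy(e.melody),
                d_entropy=d_entropy(e.melody),
                tonalness=float("nan"),
                step_cont_loc_var=step_cont_loc_var(e.melody),
                log_freq=ngram_log_freq(e.melody, table),
            )
        try:
            pa = predict_item_score(feats, ARHYTHMIC_MODEL)
        except ValueError:
            pa = float("nan")
        pr = predict_item_score(feats, RHYTHMIC_MODEL)
        rows.append(
            {
                "item_id": e.item_id,
                "source": e.source_melody_id,
                "start": e.start_index,
                "length": len(e.melody),
                "pitches": " ".join(repr(float(p)) for p in e.melody.pitches),
                "durations": " ".join(repr(float(d)) for d in e.melody.durations),
                "N": feats.N,
                "i_entropy": feats.i_entropy,
                "d_entropy": feats.d_entropy,
                "tonalness": feats.tonalness,
                "step_cont_loc_var": feats.step_cont_loc_var,
                "log_freq": feats.log_freq,
                "predicted_score_arhythmic": pa,
                "predicted_score_rhythmic": pr,
            }
        )
    df = pd.DataFrame(rows, columns=_BANK_COLUMNS)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False, float_format="%.10g")
    return df


def read_bank(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sample_items(
    entries: list[ItemBankEntry],
    lengths: list[int],
    vocal_range=None,
    seed: int = 0,
) -> list[Melody]:
    """Draw one bank item per requested length, optionally range-transposed.

    With a :class:`~singrec.triage.VocalRange`, every drawn melody is
    shifted so its mean pitch sits at the range centre (within half a
    semitone), keeping intervals intact.
    """
    from .triage import transpose_to_range

    rng = np.random.default_rng(seed)
    by_len: dict[int, list[ItemBankEntry]] = {}
    for e in entries:
        by_len.setdefault(len(e.melody), []).append(e)
    out = []
    for L in lengths:
        pool = by_len.get(L)
        if not pool:
            raise ValueError(f"no bank items of length {L}")
        melody = pool[int(rng.integers(len(pool)))].melody
        if vocal_range is not None:
            melody = transpose_to_range(melody, vocal_range)
        out.append(melody)
    return out


def bank_entry_melody(row) -> Melody:
    """Reconstruct the Melody of one bank-table row."""
    pitches = [float(v) for v in str(row["pitches"]).split()]
    durations = [float(v) for v in str(row["durations"]).split()]
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return Melody.from_arrays(onsets, durations, pitches, id=str(row["item_id"]))
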