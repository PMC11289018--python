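import numpy as np
import pytest

from singrec.core import Melody

MAJOR_SCALE = np.array([0, 2, 4, 5, 7, 9, 11])


def random_melody(rng, n_notes=None, rhythmic=False, diatonic=False, id=""):
    """A random test melody around middle C."""
    n = int(n_notes if n_notes is not None else rng.integers(3, 12))
    if diatonic:
        pitches = 60 + MAJOR_SCALE[rng.integers(0, 7, n)] + 12 * rng.integers(-1, 1, n)
    else:
        pitches = 60 + rng.integers(-12, 13, n)
    if rhythmic:
        durations = rng.choice([0.125, 0.25, 0.5, 1.0], n)
        onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return Melody.from_arrays(onsets, durations, pitches, id=id, is_rhythmic=True)
    return Melody.from_pitches(pitches, 0.25, id=id)


def random_corpus(rng, n_melodies=10, min_len=10, max_len=20):
    return [
        random_melody(rng, n_notes=int(rng.integers(min_len, max_len + 1)),
                      diatonic=True, id=f"c{i}")
        for i in range(n_melodies)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
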