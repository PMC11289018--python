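"""Central configuration: every tunable default in one validated object.

Defaults reflect the production assessment settings: a 14 dB SNR gate,
250 ms notes for arhythmic stimuli, 5000 ms sustained-note trials,
interval trigram similarity, item lengths 3–15 notes, 64 contour samples,
and the communality thresholds of the two composite pipelines.  Values
can be overridden from a JSON file (unknown keys are rejected) and by
SINGREC_* environment variables.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["Config", "load_config"]


@dataclass(frozen=True)
class Config:
    snr_threshold_db: float = 14.0
    arhythmic_note_duration_s: float = 0.25
    long_note_duration_s: float = 5.0
    ngram_n: int = 3
    n_min: int = 3
    n_max: int = 15
    contour_samples: int = 64
    pca_h2_threshold_longnote: float = 0.75
    pca_h2_threshold_accuracy: float = 0.30
    opti3_w_ngrukkon: float = 3.027
    opti3_w_rhythfuzz: float = 2.502
    opti3_w_harmcore: float = 1.439
    opti3_normalize: bool = True
    harmcore_segment_length_s: float = 2.0
    longnote_min_voiced: int = 10

    def __post_init__(self):
        if self.snr_threshold_db < 0:
            raise ValueError("snr_threshold_db must be >= 0")
        for name in ("arhythmic_note_duration_s", "long_note_duration_s",
                     "harmcore_segment_length_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (2 <= self.n_min <= self.n_max):
            raise ValueError("need 2 <= n_min <= n_max")
        if self.ngram_n < 1 or self.contour_samples < 2:
            raise ValueError("ngram_n >= 1 and contour_samples >= 2 required")
        for name in ("pca_h2_threshold_longnote", "pca_h2_threshold_accuracy"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


_FIELD_TYPES = {f.name: f.type for f in fields(Config)}


def _coerce(name: str, value):
    target = Config.__dataclass_fields__[name].default
    if isinstance(target, bool):
        if isinstance(value, str):
            return value.lower() in ("1", "true", "yes")
        return bool(value)
    return type(target)(value)


def load_config(path=None, env: dict | None = None) -> Config:
    """Build a Config from defaults, an optional JSON file, and SINGREC_* vars.

    Unknown keys in the file are an error — silently ignoring a misspelt
    setting is worse than failing.
    """
    values: dict = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must contain a JSON object")
        unknown = set(data) - set(_FIELD_TYPES)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update({k: _coerce(k, v) for k, v in data.items()})
    env = os.environ if env is None else env
    for name in _FIELD_TYPES:
        var = f"SINGREC_{name.upper()}"
        if var in env:
            values[name] = _coerce(name, env[var])
    return Config(**values)
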