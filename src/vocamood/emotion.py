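"""Per-utterance emotion scores: the data contract and a stand-in scorer.

The upstream emotion-recognition engine is a proprietary black box; this
package's boundary is its *output contract*: for every utterance, five
integer scores in 0..10 — anger, joy, sorrow, calmness, excitement — where
0 means the emotion is absent and 10 that it is strongest. Scores normally
arrive as a CSV table (:func:`read_emotion_table`).

:func:`proxy_score` is a deterministic acoustic stand-in that maps simple
per-utterance features (RMS energy, zero-crossing rate, energy slope) to
the five integers through documented monotone binnings. It exists so the
audio-to-indices pipeline can be exercised end to end without the engine;
it makes no claim of emotional validity, and all scientific evaluation uses
reader-backed or synthetic scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .audio import AudioRecording
from .segmentation import UtteranceSpan

__all__ = [
    "EMOTION_NAMES",
    "UtteranceEmotion",
    "read_emotion_table",
    "write_emotion_table",
    "emotions_to_frame",
    "proxy_score",
]

EMOTION_NAMES = ("anger", "joy", "sorrow", "calmness", "excitement")

_TABLE_COLUMNS = ["subject_id", "session_id", "utterance_index", *EMOTION_NAMES]


class EmotionTableError(ValueError):
    """Raised when a score table violates the 0-10 integer contract."""


@dataclass(frozen=True)
class UtteranceEmotion:
    """Five integer emotion components (each 0-10) for one utterance."""

    anger: int
    joy: int
    sorrow: int
    calmness: int
    excitement: int
    utterance_index: int = 0
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        for name in EMOTION_NAMES:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise EmotionTableError(f"{name} must be an integer, got {v!r}")
            if not 0 <= v <= 10:
                raise EmotionTableError(f"{name}={v} outside the 0-10 contract")


def read_emotion_table(path: str | Path) -> list[UtteranceEmotion]:
    """Read and validate an emotion-score CSV.

    Expects header columns ``subject_id, session_id, utterance_index,
    anger, joy, sorrow, calmness, excitement``. Every score must be an
    integer in 0..10 and each (subject, session, utterance_index) must be
    unique. Rows are returned ordered by (subject, session, index).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise EmotionTableError(f"{path}: missing columns {missing}")
    for col in EMOTION_NAMES:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0) | (numeric < 0) | (numeric > 10)
        if bad.any():
            row = int(bad.idxmax())
            raise EmotionTableError(
                f"{path}: row {row}, column {col!r}: value {vals.iloc[row]!r} "
                "violates the integer 0-10 contract")
    keys = ["subject_id", "session_id", "utterance_index"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise EmotionTableError(
            f"{path}: duplicate (subject, session, utterance_index) at row {int(dup.idxmax())}")
    df = df.sort_values(keys, kind="stable").reset_index(drop=True)
    return [
        UtteranceEmotion(
            anger=int(r.anger), joy=int(r.joy), sorrow=int(r.sorrow),
            calmness=int(r.calmness), excitement=int(r.excitement),
            utterance_index=int(r.utterance_index),
            subject_id=str(r.subject_id), session_id=str(r.session_id),
        )
        for r in df.itertuples()
    ]


def emotions_to_frame(emotions: Sequence[UtteranceEmotion]) -> pd.DataFrame:
    """Tabulate utterance emotions with the canonical column order."""
    return pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "session_id": e.session_id,
                "utterance_index": e.utterance_index,
                **{name: getattr(e, name) for name in EMOTION_NAMES},
            }
            for e in emotions
        ],
        columns=_TABLE_COLUMNS,
    )


def frame_to_emotions(df: pd.DataFrame) -> list[UtteranceEmotion]:
    """Validate a DataFrame in the canonical schema into emotion records."""
    return [
        UtteranceEmotion(
            anger=int(r.anger), joy=int(r.joy), sorrow=int(r.sorrow),
            calmness=int(r.calmness), excitement=int(r.excitement),
            utterance_index=int(r.utterance_index),
            subject_id=str(r.subject_id), session_id=str(r.session_id),
        )
        for r in df.itertuples()
    ]


def write_emotion_table(path: str | Path, emotions: Sequence[UtteranceEmotion]) -> None:
    """Write utterance emotions to CSV in the canonical schema."""
    emotions_to_frame(emotions).to_csv(path, index=False)


def _bin(value: float, lo: float, hi: float) -> int:
    """Monotone map of value in [lo, hi] onto the integer range 0..10."""
    if hi <= lo:
        return 5
    return int(np.clip(round(10.0 * (value - lo) / (hi - lo)), 0, 10))


def proxy_score(recording: AudioRecording,
                spans: Sequence[UtteranceSpan]) -> list[UtteranceEmotion]:
    """Deterministic acoustic stand-in scorer.

    Monotone binnings, each onto 0..10:

    - excitement: utterance RMS energy over [0, 0.5];
    - calmness:   10 - excitement's bin of RMS (louder -> less calm);
    - joy:        positive slope of frame energy (rising intensity) over
      [-0.5, 0.5] RMS/s;
    - sorrow:     10 - joy's bin (falling intensity);
    - anger:      RMS x zero-crossing-rate product over [0, 0.25]
      (loud and harsh).

    A pure function of the span samples and duration: identical inputs give
    identical scores.
    """
    out: list[UtteranceEmotion] = []
    sr = recording.sample_rate
    x = recording.samples
    for span in spans:
        a, b = round(span.start_s * sr), round(span.end_s * sr)
        seg = x[a:b]
        if seg.size == 0:
            seg = np.zeros(1)
        rms = float(np.sqrt(np.mean(seg ** 2)))
        zcr = float(np.mean(np.abs(np.diff(np.signbit(seg).astype(np.int8))))) if seg.size > 1 else 0.0
        half = max(1, seg.size // 2)
        rms_a = float(np.sqrt(np.mean(seg[:half] ** 2)))
        rms_b = float(np.sqrt(np.mean(seg[half:] ** 2)))
        slope = (rms_b - rms_a) / span.duration_s
        excitement = _bin(rms, 0.0, 0.5)
        joy = _bin(slope, -0.5, 0.5)
        out.append(UtteranceEmotion(
            anger=_bin(rms * zcr, 0.0, 0.25),
            joy=joy,
            sorrow=10 - joy,
            calmness=10 - excitement,
            excitement=excitement,
            utterance_index=span.index,
            subject_id=recording.subject_id,
            session_id=recording.session_id,
        ))
    return out
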