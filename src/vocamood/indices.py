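"""Mood indices from emotion components.

Per utterance, two component ratios are formed from four of the five
emotion scores:

    vivacity   = joy / (joy + sorrow)
    relaxation = calmness / (calmness + excitement)

Both are in [0, 1]; a ratio whose denominator is zero is *missing* for that
utterance and excluded from aggregation (imputing 0.5 would bias vitality
toward the middle). Per recording, vivacity and relaxation are the
unweighted means over utterances, and the short-term mood index is their
weighted mean

    vitality = 0.60 * vivacity + 0.40 * relaxation,

with weights fixed by the separating line 0.60X + 0.40Y = 0.52 between
healthy and patient groups in the vivacity/relaxation plane. The long-term
index accumulates recordings per subject:

    mental_activity = 0.75 * mean(vitality) + 0.25 * mean(vitality SD),

where vitality SD is the per-recording standard deviation of utterance
vitalities (dispersion carries signal: healthy voices vary more), and the
companion boundary is 0.75X + 0.25Y = 0.426.

:func:`fit_separating_weights` reproduces the line-fitting step on data:
a grid search over convex weight pairs maximizing balanced accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .emotion import UtteranceEmotion

__all__ = [
    "IndexWeights",
    "UtteranceIndices",
    "RecordingIndices",
    "SubjectSeries",
    "utterance_indices",
    "recording_indices",
    "subject_series",
    "recording_indices_table",
    "subject_series_table",
    "fit_separating_weights",
]

logger = logging.getLogger(__name__)


class EmptyRecordingError(ValueError):
    """Raised when a recording has no utterance with computable vitality."""


@dataclass(frozen=True)
class IndexWeights:
    """Weights and decision boundaries of the two linear indices.

    ``w_viv + w_rel = 1`` and ``w_meanvit + w_sd = 1``. Defaults are the
    published constants: vitality = 0.60*vivacity + 0.40*relaxation with
    boundary 0.52; mental activity = 0.75*mean vitality + 0.25*mean
    vitality SD with boundary 0.426. ``sd_ddof=1`` selects the sample
    (n-1) standard deviation for per-recording vitality dispersion.
    """

    w_viv: float = 0.60
    w_rel: float = 0.40
    vitality_boundary: float = 0.52
    w_meanvit: float = 0.75
    w_sd: float = 0.25
    activity_boundary: float = 0.426
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if not math.isclose(self.w_viv + self.w_rel, 1.0, abs_tol=1e-9):
            raise ValueError("w_viv + w_rel must equal 1")
        if not math.isclose(self.w_meanvit + self.w_sd, 1.0, abs_tol=1e-9):
            raise ValueError("w_meanvit + w_sd must equal 1")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")


@dataclass(frozen=True)
class UtteranceIndices:
    """Vivacity, relaxation and vitality for one utterance; None = missing."""

    vivacity: float | None
    relaxation: float | None
    vitality: float | None


@dataclass(frozen=True)
class RecordingIndices:
    """Aggregated indices for one acquired voice."""

    mean_vivacity: float
    mean_relaxation: float
    vitality: float
    vitality_sd: float
    n_utterances_used: int
    n_utterances_excluded: int
    subject_id: str = ""
    session_id: str = ""


@dataclass(frozen=True)
class SubjectSeries:
    """A subject's accumulated recordings and the long-term activity index."""

    subject_id: str
    recordings: tuple[RecordingIndices, ...]
    mean_vitality: float
    mean_vitality_sd: float
    mental_activity: float


def utterance_indices(e: UtteranceEmotion, w: IndexWeights | None = None) -> UtteranceIndices:
    """Vivacity, relaxation and vitality for one utterance.

    vivacity = joy/(joy+sorrow), relaxation = calmness/(calmness+excitement);
    a zero denominator leaves that index (and hence vitality) missing.
    """
    w = w or IndexWeights()
    viv = e.joy / (e.joy + e.sorrow) if e.joy + e.sorrow > 0 else None
    rel = e.calmness / (e.calmness + e.excitement) if e.calmness + e.excitement > 0 else None
    vit = w.w_viv * viv + w.w_rel * rel if viv is not None and rel is not None else None
    return UtteranceIndices(vivacity=viv, relaxation=rel, vitality=vit)


def recording_indices(us: Sequence[UtteranceIndices], w: IndexWeights | None = None,
                      subject_id: str = "", session_id: str = "") -> RecordingIndices:
    """Aggregate utterance indices over one acquired voice.

    Means are unweighted over utterances with the relevant index present;
    vitality_sd is the standard deviation (``w.sd_ddof``) of per-utterance
    vitalities, 0.0 when a single utterance is usable.
    """
    w = w or IndexWeights()
    vivs = [u.vivacity for u in us if u.vivacity is not None]
    rels = [u.relaxation for u in us if u.relaxation is not None]
    vits = [u.vitality for u in us if u.vitality is not None]
    if not vits:
        raise EmptyRecordingError("no utterance with both components present")
    n_excluded = len(us) - len(vits)
    if n_excluded:
        logger.info("recording %s/%s: %d of %d utterances excluded (zero-denominator ratio)",
                    subject_id, session_id, n_excluded, len(us))
    sd = float(np.std(vits, ddof=w.sd_ddof)) if len(vits) > 1 else 0.0
    return RecordingIndices(
        mean_vivacity=float(np.mean(vivs)),
        mean_relaxation=float(np.mean(rels)),
        vitality=float(np.mean(vits)),
        vitality_sd=sd,
        n_utterances_used=len(vits),
        n_utterances_excluded=n_excluded,
        subject_id=subject_id,
        session_id=session_id,
    )


def subject_series(rs: Sequence[RecordingIndices], w: IndexWeights | None = None,
                   subject_id: str | None = None) -> SubjectSeries:
    """Accumulate a subject's recordings into the long-term activity index.

    Each recording counts once regardless of its utterance count;
    mental_activity = w_meanvit * mean(vitality) + w_sd * mean(vitality_sd).
    """
    w = w or IndexWeights()
    if not rs:
        raise ValueError("at least one recording is required")
    if subject_id is None:
        subject_id = rs[0].subject_id
    mv = float(np.mean([r.vitality for r in rs]))
    msd = float(np.mean([r.vitality_sd for r in rs]))
    return SubjectSeries(
        subject_id=subject_id,
        recordings=tuple(rs),
        mean_vitality=mv,
        mean_vitality_sd=msd,
        mental_activity=w.w_meanvit * mv + w.w_sd * msd,
    )


def recording_indices_table(emotions: "Sequence[UtteranceEmotion] | pd.DataFrame",
                            w: IndexWeights | None = None) -> pd.DataFrame:
    """Per-(subject, session) RecordingIndices as a DataFrame.

    Groups the utterance stream by (subject_id, session_id) and aggregates
    each group with :func:`recording_indices`. Accepts either emotion
    records or a DataFrame in the canonical emotion-table schema.
    """
    if isinstance(emotions, pd.DataFrame):
        from .emotion import frame_to_emotions
        emotions = frame_to_emotions(emotions)
    w = w or IndexWeights()
    groups: dict[tuple[str, str], list[UtteranceIndices]] = {}
    for e in emotions:
        groups.setdefault((e.subject_id, e.session_id), []).append(utterance_indices(e, w))
    rows = []
    for (subj, sess), us in groups.items():
        r = recording_indices(us, w, subject_id=subj, session_id=sess)
        rows.append({
            "subject_id": subj, "session_id": sess,
            "mean_vivacity": r.mean_vivacity, "mean_relaxation": r.mean_relaxation,
            "vitality": r.vitality, "vitality_sd": r.vitality_sd,
            "n_utterances_used": r.n_utterances_used,
            "n_utterances_excluded": r.n_utterances_excluded,
        })
    return pd.DataFrame(rows)


def subject_series_table(recordings: pd.DataFrame,
                         w: IndexWeights | None = None) -> pd.DataFrame:
    """Per-subject SubjectSeries fields from a recording-indices table."""
    w = w or IndexWeights()
    rows = []
    for subj, grp in recordings.groupby("subject_id", sort=True):
        mv = float(grp["vitality"].mean())
        msd = float(grp["vitality_sd"].mean())
        rows.append({
            "subject_id": subj,
            "n_recordings": len(grp),
            "mean_vitality": mv,
            "mean_vitality_sd": msd,
            "mental_activity": w.w_meanvit * mv + w.w_sd * msd,
        })
    return pd.DataFrame(rows)


def fit_separating_weights(x: Sequence[float], y: Sequence[float],
                           labels: Sequence[int | bool],
                           grid_step: float = 0.01) -> tuple[float, float, float, float]:
    """Fit a convex-weight separating line w_x*x + (1-w_x)*y = boundary.

    Grid search over w_x in {0, grid_step, ..., 1}; for each weight the
    boundary is the midpoint of the adjacent sorted scores whose split
    maximizes balanced accuracy (positive label = score above boundary).
    Ties are broken toward w_x closest to 0.5, then toward smaller w_x.

    Parameters
    ----------
    x, y : sequences of float in [0, 1]
    labels : 1 (or True) for the high-score group, 0 otherwise.

    Returns
    -------
    (w_x, w_y, boundary, balanced_accuracy)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if not lab.any() or lab.all():
        raise ValueError("both groups must be represented")
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    best = None  # (bal_acc, -|w-0.5|, -w, w_x, boundary)
    n_steps = round(1.0 / grid_step)
    for k in range(n_steps + 1):
        w_x = k * grid_step
        s = w_x * x + (1.0 - w_x) * y
        order = np.argsort(s, kind="stable")
        s_sorted, lab_sorted = s[order], lab[order]
        # cumulative counts below each split position
        pos_below = np.concatenate(([0], np.cumsum(lab_sorted)))
        neg_below = np.concatenate(([0], np.cumsum(~lab_sorted)))
        # split i: first i points below the boundary
        sens = (n_pos - pos_below) / n_pos      # positives above boundary
        spec = neg_below / n_neg                # negatives below boundary
        bal = (sens + spec) / 2.0
        i = int(np.argmax(bal))
        if 0 < i < len(s_sorted):
            boundary = float((s_sorted[i - 1] + s_sorted[i]) / 2.0)
        elif i == 0:
            boundary = float(s_sorted[0]) - 1e-9
        else:
            boundary = float(s_sorted[-1]) + 1e-9
        cand = (float(bal[i]), -abs(w_x - 0.5), -w_x, w_x, boundary)
        if best is None or cand > best:
            best = cand
    bal_acc, _, _, w_x, boundary = best
    return (round(w_x, 10), round(1.0 - w_x, 10), boundary, bal_acc)
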