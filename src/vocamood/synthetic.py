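"""Synthetic cohorts and audio fixtures.

Real patient recordings cannot be redistributed and the upstream emotion
engine is proprietary, so every pipeline stage is exercised on synthetic
data with the statistical structure the method assumes:

- per-utterance emotion scores drawn independently from group-specific
  Gaussians, rounded and clipped to the integer 0-10 contract;
- HAM-D severity drawn per group from truncated Gaussians that respect the
  Zimmerman ranges (no depression <= 7, depression >= 8), with defaults
  matching the reported group summaries 3.1 +/- 2.3 and 16.1 +/- 7.4;
- default group emotion means calibrated once by Monte-Carlo so that
  recording-vitality means land near 0.60 (healthy), 0.55 (no depression)
  and 0.49 (depression) — calibration targets, not a claim that the
  marginal score distributions match the real engine;
- optional subject-level random effect (an additive shift of the group's
  joy/sorrow/calm/excitement means, resampled per subject) for realism in
  longitudinal tests.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .audio import AudioRecording, REFERENCE_SAMPLE_RATE
from .emotion import EMOTION_NAMES

__all__ = ["GroupEmotionMeans", "CohortSpec", "simulate_cohort",
           "simulate_vitality_cohort", "simulate_audio_fixture"]

#: order: (anger, joy, sorrow, calmness, excitement)
DEFAULT_EMOTION_MEANS: dict[str, tuple[float, ...]] = {
    # calibrated so recording-vitality means ~ 0.60 / 0.55 / 0.49 at sd=2.0
    "healthy": (3.0, 5.9, 3.1, 4.5, 4.5),
    "no_depression": (3.0, 5.33, 3.67, 4.3, 4.7),
    "depression": (3.0, 4.7, 4.3, 4.05, 4.95),
}

DEFAULT_HAMD_PARAMS: dict[str, tuple[float, float, int, int]] = {
    # (mean, sd, low, high): truncation by rejection within the group's range
    "no_depression": (3.1, 2.3, 0, 7),
    "depression": (16.1, 7.4, 8, 52),
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort.

    ``sessions_per_subject`` and ``utterances_per_session`` are either an
    int or an inclusive (low, high) range sampled uniformly. ``subject_sd``
    is the SD of the optional subject-level additive shift of emotion means
    (0 disables it).
    """

    n_healthy: int = 14
    n_no_depression: int = 24
    n_depression: int = 22
    sessions_per_subject: int | tuple[int, int] = 1
    utterances_per_session: int | tuple[int, int] = (20, 40)
    emotion_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_MEANS))
    emotion_sd: float = 2.0
    # subject-level shift of +/-delta on (joy, calm) vs (sorrow, excite)
    # moves vitality by ~delta/9; 0.9 yields between-subject vitality SD
    # ~0.10, the spread implied by the reported group standard errors
    subject_sd: float = 0.9
    hamd_params: dict[str, tuple[float, float, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HAMD_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_healthy, self.n_no_depression, self.n_depression):
            if n < 0:
                raise ValueError("group sizes must be >= 0")
        for g, means in self.emotion_means.items():
            if len(means) != 5 or not all(0 <= m <= 10 for m in means):
                raise ValueError(f"emotion means for {g!r} must be five values in [0, 10]")
        if self.emotion_sd < 0 or self.subject_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def _draw_count(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def _truncated_hamd(rng: np.random.Generator, mean: float, sd: float,
                    lo: int, hi: int, max_tries: int = 10_000) -> int:
    """Rejection-sample an integer HAM-D score within [lo, hi]."""
    for _ in range(max_tries):
        v = int(round(rng.normal(mean, sd)))
        if lo <= v <= hi:
            return v
    raise ValueError(
        f"HAM-D params (mean={mean}, sd={sd}) almost never land in [{lo}, {hi}]")


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate emotion-score and cohort-metadata tables.

    Returns
    -------
    emotions : DataFrame
        Canonical emotion-table schema, one row per utterance: scores drawn
        from N(group mean, emotion_sd), rounded and clipped to 0..10.
    metadata : DataFrame
        One row per subject: subject_id, group, is_patient, hamd (pandas NA
        for healthy subjects).
    """
    rng = np.random.default_rng(spec.seed)
    emo_rows: list[dict] = []
    meta_rows: list[dict] = []
    counts = {"healthy": spec.n_healthy, "no_depression": spec.n_no_depression,
              "depression": spec.n_depression}
    for group in ("healthy", "no_depression", "depression"):
        if counts[group] == 0:
            continue
        means = np.asarray(spec.emotion_means[group], dtype=float)
        for k in range(counts[group]):
            subject_id = f"{group[:4]}{k:03d}"
            if group == "healthy":
                hamd = None
            else:
                m, s, lo, hi = spec.hamd_params[group]
                hamd = _truncated_hamd(rng, m, s, lo, hi)
            meta_rows.append({"subject_id": subject_id, "group": group,
                              "is_patient": group != "healthy", "hamd": hamd})
            subj_means = means
            if spec.subject_sd > 0:
                shift = rng.normal(0.0, spec.subject_sd)
                subj_means = means + np.array([0.0, shift, -shift, shift, -shift])
            n_sessions = _draw_count(rng, spec.sessions_per_subject)
            for sess in range(n_sessions):
                n_utt = _draw_count(rng, spec.utterances_per_session)
                scores = rng.normal(subj_means, spec.emotion_sd, size=(n_utt, 5))
                scores = np.clip(np.round(scores), 0, 10).astype(int)
                for u in range(n_utt):
                    emo_rows.append({
                        "subject_id": subject_id,
                        "session_id": f"s{sess:02d}",
                        "utterance_index": u,
                        **dict(zip(EMOTION_NAMES, scores[u])),
                    })
    emotions = pd.DataFrame(emo_rows, columns=["subject_id", "session_id",
                                               "utterance_index", *EMOTION_NAMES])
    metadata = pd.DataFrame(meta_rows).convert_dtypes()
    return emotions, metadata


def simulate_vitality_cohort(d: float, n_per_group: int, seed: int = 0,
                             healthy_mean: float = 0.60, sd: float = 0.08
                             ) -> pd.DataFrame:
    """Cohort table with a specified standardized vitality gap.

    Draws healthy and depression vitality from unit-SD-scaled Gaussians
    separated by ``d`` pooled SDs (the no_depression group sits halfway).
    Useful for calibration checks: the expected AUC is Phi(d / sqrt(2)).
    """
    rng = np.random.default_rng(seed)
    rows = []
    means = {"healthy": healthy_mean,
             "no_depression": healthy_mean - 0.5 * d * sd,
             "depression": healthy_mean - d * sd}
    hamd = {"healthy": None, "no_depression": 4, "depression": 16}
    for g, mu in means.items():
        v = rng.normal(mu, sd, n_per_group)
        for i, vi in enumerate(v):
            rows.append({"subject_id": f"{g[:4]}{i:03d}", "session_id": "s00",
                         "group": g, "hamd": hamd[g], "vitality": float(vi)})
    df = pd.DataFrame(rows)
    # severity loosely consistent with vitality within the patient groups
    pat = df["group"] != "healthy"
    df.loc[pat, "hamd"] = np.where(
        df.loc[pat, "group"] == "depression",
        np.clip(np.round(16 - 40 * (df.loc[pat, "vitality"] - means["depression"])), 8, 52),
        np.clip(np.round(4 - 20 * (df.loc[pat, "vitality"] - means["no_depression"])), 0, 7),
    ).astype(int)
    return df


def simulate_audio_fixture(layout: Sequence[tuple], sample_rate: int = REFERENCE_SAMPLE_RATE,
                           subject_id: str = "fixture", session_id: str = "s00"
                           ) -> AudioRecording:
    """Deterministic tone/silence waveform for segmentation tests.

    ``layout`` is a sequence of segments ``("tone", duration_s, amplitude,
    frequency_hz)`` or ``("silence", duration_s)``; each segment occupies
    exactly ``round(duration_s * sample_rate)`` samples.
    """
    parts = []
    for seg in layout:
        kind, duration = seg[0], float(seg[1])
        if duration <= 0:
            raise ValueError("segment durations must be > 0")
        n = round(duration * sample_rate)
        if kind == "silence":
            parts.append(np.zeros(n))
        elif kind == "tone":
            amplitude, freq = float(seg[2]), float(seg[3])
            t = np.arange(n) / sample_rate
            parts.append(amplitude * np.sin(2 * np.pi * freq * t))
        else:
            raise ValueError(f"unknown segment kind {kind!r}")
    return AudioRecording(samples=np.concatenate(parts), sample_rate=sample_rate,
                          subject_id=subject_id, session_id=session_id)
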