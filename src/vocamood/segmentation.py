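"""Energy-threshold utterance segmentation.

An utterance is a stretch of continuous voice delimited by breaths. It is
detected from the signal volume: the recording is framed, each frame's RMS
amplitude is compared with a threshold, and maximal runs of supra-threshold
frames become utterances. A silence gap shorter than ``min_silence_s`` does
not terminate an utterance, and speech runs shorter than
``min_utterance_s`` are discarded — speech must continue "for a certain
period" to count.

The threshold is ideally set per recording by hand (recording conditions
vary); :func:`auto_threshold` provides a documented automatic surrogate for
unattended runs and logs whenever it is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio import AudioRecording

__all__ = [
    "SegmentationParams",
    "UtteranceSpan",
    "frame_rms",
    "auto_threshold",
    "segment_utterances",
]

logger = logging.getLogger(__name__)

AUTO = "auto"


class DegenerateInputError(ValueError):
    """Raised when automatic thresholding is impossible (constant volume)."""


@dataclass(frozen=True)
class SegmentationParams:
    """Framing and state-machine parameters, all durations in seconds.

    Attributes
    ----------
    frame_length_s : float
        RMS analysis window, default 30 ms.
    hop_length_s : float
        Hop between successive frames, default 10 ms.
    volume_threshold : float | "auto"
        RMS amplitude separating silence from speech, in (0, 1) when
        numeric; ``"auto"`` invokes :func:`auto_threshold`.
    min_utterance_s : float
        Shortest speech run kept as an utterance (default 0.3 s,
        breath-group scale).
    min_silence_s : float
        Shortest silence gap that terminates an utterance (default 0.3 s).
    """

    frame_length_s: float = 0.030
    hop_length_s: float = 0.010
    volume_threshold: float | str = AUTO
    min_utterance_s: float = 0.3
    min_silence_s: float = 0.3

    def __post_init__(self) -> None:
        for name in ("frame_length_s", "hop_length_s", "min_utterance_s", "min_silence_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.frame_length_s < self.hop_length_s:
            raise ValueError("frame_length_s must be >= hop_length_s")
        thr = self.volume_threshold
        if isinstance(thr, str):
            if thr != AUTO:
                raise ValueError(f"volume_threshold must be numeric or 'auto', got {thr!r}")
        elif not (0.0 < thr < 1.0):
            raise ValueError("numeric volume_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class UtteranceSpan:
    """Half-open utterance interval [start_s, end_s) within a recording."""

    start_s: float
    end_s: float
    index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError("require 0 <= start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def frame_rms(recording: AudioRecording, params: SegmentationParams) -> tuple[np.ndarray, np.ndarray]:
    """Framewise RMS amplitude.

    Returns
    -------
    times : ndarray
        Frame start times in seconds, one per hop.
    rms : ndarray
        RMS amplitude of each frame; a constant-amplitude ``a`` signal
        yields ``|a|`` in every frame.
    """
    x = recording.samples
    if x.size == 0:
        raise ValueError("recording is empty")
    sr = recording.sample_rate
    flen = max(1, round(params.frame_length_s * sr))
    hop = max(1, round(params.hop_length_s * sr))
    if flen > x.size:
        logger.info("frame (%d samples) longer than recording (%d); using one whole-signal frame",
                    flen, x.size)
        return np.array([0.0]), np.array([np.sqrt(np.mean(x ** 2))])
    n_frames = 1 + (x.size - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    times = hop * np.arange(n_frames) / sr
    return times, rms


def auto_threshold(recording: AudioRecording, params: SegmentationParams) -> float:
    """Automatic volume threshold: geometric midpoint of the 10th and 90th
    framewise-RMS percentiles (i.e. their midpoint on a log scale).

    Raises
    ------
    DegenerateInputError
        When the framewise RMS is (near-)constant, e.g. all silence; an
        explicit threshold must then be supplied.
    """
    _, rms = frame_rms(recording, params)
    lo, hi = np.percentile(rms, [10.0, 90.0])
    floor = 1e-8
    lo, hi = max(lo, floor), max(hi, floor)
    if hi / lo < 1.0 + 1e-9:
        raise DegenerateInputError(
            "framewise RMS is constant; supply an explicit volume_threshold")
    thr = float(np.sqrt(lo * hi))
    logger.info("auto threshold in use: %.4g (RMS p10=%.4g, p90=%.4g)", thr, lo, hi)
    return thr


def segment_utterances(recording: AudioRecording,
                       params: SegmentationParams | None = None) -> list[UtteranceSpan]:
    """Split a recording into utterances by the volume-threshold state machine.

    A silence-to-speech transition opens an utterance; it closes once
    silence persists for at least ``min_silence_s``. Speech runs shorter
    than ``min_utterance_s`` are discarded. Returns spans sorted, disjoint,
    with times in seconds.
    """
    params = params or SegmentationParams()
    if recording.samples.size == 0:
        return []
    times, rms = frame_rms(recording, params)
    thr = params.volume_threshold
    if thr == AUTO:
        thr = auto_threshold(recording, params)
    speech = rms > thr
    if not speech.any():
        return []

    hop = float(times[1] - times[0]) if times.size > 1 else params.hop_length_s
    # frame-run extraction: starts/ends of maximal True runs
    padded = np.concatenate(([False], speech, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_starts, run_ends = edges[::2], edges[1::2]  # end exclusive

    # bridge silence gaps shorter than min_silence_s
    min_sil_frames = max(1, round(params.min_silence_s / hop))
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < min_sil_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # Frames longer than the hop smooth detection but quantize the edges to
    # the frame length. Refine each run's edges against non-overlapping
    # hop-length subwindows so boundaries are accurate to within one hop.
    sr = recording.sample_rate
    hop_n = max(1, round(params.hop_length_s * sr))
    flen_s = max(1, round(params.frame_length_s * sr)) / sr
    x = recording.samples
    n_sub = x.size // hop_n
    sub_rms = (np.sqrt(np.mean(x[: n_sub * hop_n].reshape(n_sub, hop_n) ** 2, axis=1))
               if n_sub else np.array([]))
    sub_t = hop_n * np.arange(n_sub) / sr

    def _refine(t_lo: float, t_hi: float, fallback: tuple[float, float]) -> tuple[float, float]:
        mask = (sub_t + hop_n / sr > t_lo) & (sub_t < t_hi) & (sub_rms > thr)
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            return fallback
        return float(sub_t[hits[0]]), float(sub_t[hits[-1]] + hop_n / sr)

    spans: list[UtteranceSpan] = []
    duration = recording.duration_s
    for s, e in merged:
        frame_lo, frame_hi = times[s], times[e - 1] + flen_s
        start_s, end_s = _refine(max(frame_lo - flen_s, 0.0), frame_hi,
                                 (frame_lo, frame_hi))
        end_s = min(end_s, duration)
        if end_s - start_s < params.min_utterance_s:
            continue
        spans.append(UtteranceSpan(start_s=float(start_s), end_s=float(end_s),
                                   index=len(spans)))
    return spans
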