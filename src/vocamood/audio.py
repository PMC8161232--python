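"""Reading and writing mono PCM WAV recordings.

Recordings are represented as float arrays normalized to [-1, 1] together
with their sampling rate. The reference acquisition setup is linear PCM at
11,025 Hz with 16-bit quantization; other rates and bit depths are accepted
(a notice is logged when the rate differs from the reference) because all
downstream segmentation parameters are expressed in seconds, not samples.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AudioRecording", "load_wav", "write_wav", "REFERENCE_SAMPLE_RATE"]

logger = logging.getLogger(__name__)

#: Sampling rate (Hz) of the reference acquisition protocol.
REFERENCE_SAMPLE_RATE = 11_025

_WIDTH_DTYPES = {1: np.uint8, 2: np.dtype("<i2"), 4: np.dtype("<i4")}


class AudioFormatError(ValueError):
    """Raised for non-PCM, corrupt, or empty WAV input."""


@dataclass
class AudioRecording:
    """A mono audio signal with amplitudes normalized to [-1, 1].

    Parameters
    ----------
    samples : ndarray of float
        Mono amplitude sequence in [-1, 1].
    sample_rate : int
        Sampling rate in Hz; must be positive.
    subject_id, session_id : str
        Opaque identifiers carried through the pipeline.
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ValueError("amplitudes must lie within [-1, 1]")

    @property
    def duration_s(self) -> float:
        """Duration in seconds: sample count / sample_rate."""
        return self.samples.size / self.sample_rate


def load_wav(path: str | Path, subject_id: str = "", session_id: str = "") -> AudioRecording:
    """Load a PCM WAV file as a normalized mono recording.

    Integer PCM samples are normalized by 2**(bits-1) so that thresholds
    downstream are bit-depth independent. Multi-channel input is downmixed
    to mono by averaging channels.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    AudioFormatError
        For non-PCM/corrupt containers or zero-length audio.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with wave.open(str(path), "rb") as wf:
            n_channels = wf.getnchannels()
            width = wf.getsampwidth()
            rate = wf.getframerate()
            n_frames = wf.getnframes()
            raw = wf.readframes(n_frames)
    except (wave.Error, EOFError) as exc:
        raise AudioFormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if width not in _WIDTH_DTYPES:
        raise AudioFormatError(f"{path}: unsupported sample width {width} bytes")
    if n_frames == 0 or not raw:
        raise AudioFormatError(f"{path}: zero-length audio")

    data = np.frombuffer(raw, dtype=_WIDTH_DTYPES[width]).astype(np.float64)
    if width == 1:  # 8-bit WAV is unsigned, offset binary
        data = data - 128.0
        data /= 128.0
    else:
        data /= float(2 ** (8 * width - 1))
    if n_channels > 1:
        data = data.reshape(-1, n_channels).mean(axis=1)
    if rate != REFERENCE_SAMPLE_RATE:
        logger.info(
            "%s: sample rate %d Hz differs from the reference %d Hz; "
            "segmentation parameters are in seconds, so this is fine",
            path, rate, REFERENCE_SAMPLE_RATE,
        )
    return AudioRecording(samples=data, sample_rate=rate,
                          subject_id=subject_id, session_id=session_id)


def write_wav(path: str | Path, recording: AudioRecording) -> None:
    """Write a recording as 16-bit mono PCM WAV.

    Quantizes by rounding to the nearest 16-bit code; a subsequent
    :func:`load_wav` reproduces the samples within one LSB (1/32768).
    """
    samples = np.clip(recording.samples, -1.0, 1.0)
    codes = np.clip(np.round(samples * 32768.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(recording.sample_rate)
        wf.writeframes(codes.tobytes())
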