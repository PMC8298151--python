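"""Reading, resampling, segmenting and framing of sustained-vowel recordings.

The analysis protocol expects mono PCM WAV input (nominally 44.1 kHz, 16-bit),
decimated to a 16 kHz analysis rate, with a two-second segment taken from the
middle of each sustained vowel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

from .errors import InputError

__all__ = [
    "Recording",
    "FrameSequence",
    "read_wav",
    "write_wav",
    "decimate_to_16k",
    "extract_central_segment",
    "frame_signal",
]


@dataclass
class Recording:
    """A mono waveform with its sample rate.

    ``samples`` are dimensionless amplitudes in [-1, 1]; ``rate`` is in Hz.
    """

    samples: np.ndarray
    rate: int
    source_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InputError("Recording.samples must be one-dimensional")
        if self.rate <= 0:
            raise InputError("Recording.rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("Recording contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class FrameSequence:
    """Fixed-length windowed frames cut from a recording."""

    frames: np.ndarray  # (n_frames, frame_len)
    frame_len: int
    hop: int
    window_name: str = "hamming"

    def __post_init__(self):
        if self.hop < 1:
            raise InputError("hop must be >= 1")
        if self.frames.ndim != 2 or self.frames.shape[1] != self.frame_len:
            raise InputError("frames must be (n_frames, frame_len)")

    def __len__(self) -> int:
        return self.frames.shape[0]


def read_wav(path) -> Recording:
    """Read a PCM WAV file into a :class:`Recording` scaled to [-1, 1].

    Multichannel files are reduced to their first channel with a warning.
    Integer PCM is scaled by the full-scale value of its width (so the most
    positive 16-bit sample maps to 32767/32768).
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # unreadable / truncated
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"empty WAV file: {path}")
    if data.ndim > 1:
        warnings.warn(f"{path.name}: multichannel input, taking channel 1")
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float WAV
        samples = data.astype(np.float64)
    return Recording(samples=samples, rate=int(rate), source_id=path.stem)


def write_wav(path, rec: Recording) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    x = np.clip(rec.samples, -1.0, 1.0)
    data = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), rec.rate, data)


def decimate_to_16k(rec: Recording, target_rate: int = 16000) -> Recording:
    """Resample a recording down to the 16 kHz analysis rate.

    Uses polyphase resampling with its built-in anti-alias FIR lowpass;
    content below 7 kHz is preserved to well within 0.5 dB.  Input already at
    the target rate is returned unchanged; upsampling is refused.
    """
    if rec.rate < target_rate:
        raise InputError(
            f"cannot upsample: rate {rec.rate} Hz < target {target_rate} Hz")
    if rec.rate == target_rate:
        return rec
    frac = Fraction(target_rate, rec.rate)
    y = resample_poly(rec.samples, frac.numerator, frac.denominator)
    return Recording(samples=y, rate=target_rate, source_id=rec.source_id)


def extract_central_segment(rec: Recording, duration_s: float = 2.0) -> Recording:
    """Extract a ``duration_s`` segment centred on the midpoint of the recording.

    For odd leftover length the window is biased one sample to the left
    (``start = floor((N - L) / 2)``).
    """
    n = len(rec.samples)
    length = round(duration_s * rec.rate)
    if n < length:
        raise InputError(
            f"recording of {n / rec.rate:.3f} s shorter than requested "
            f"{duration_s:.3f} s segment")
    start = (n - length) // 2
    return Recording(samples=rec.samples[start:start + length].copy(),
                     rate=rec.rate, source_id=rec.source_id)


def frame_signal(rec: Recording, frame_len: int, hop: int,
                 window_name: str = "hamming") -> FrameSequence:
    """Cut a recording into overlapping windowed frames.

    Yields ``floor((N - frame_len) / hop) + 1`` frames; any trailing partial
    frame is discarded.
    """
    n = len(rec.samples)
    if frame_len > n:
        raise InputError(f"frame_len {frame_len} exceeds signal length {n}")
    if hop < 1:
        raise InputError("hop must be >= 1")
    n_frames = (n - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = rec.samples[idx]
    if window_name not in (None, "rectangular", "boxcar"):
        frames = frames * get_window(window_name, frame_len, fftbins=True)
        name = window_name
    else:
        name = "rectangular"
    return FrameSequence(frames=frames, frame_len=frame_len, hop=hop,
                         window_name=name)
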