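"""WAV recordings with ICBHI-style label sidecars, and fixed-length segmentation.

Recordings are mono 16-bit PCM WAV (8000 Hz in the acquisition protocol this
package targets); each ``<stem>.wav`` may be paired with a ``<stem>.txt``
holding a single integer class label (0 Normal, 1 Rhonchi, 2 Tachypnea,
3 Noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "CLASS_NAMES",
    "AudioRecording",
    "LabeledSegment",
    "read_wav",
    "write_wav",
    "read_label_file",
    "write_label_file",
    "segment_recording",
]

CLASS_NAMES = {0: "Normal", 1: "Rhonchi", 2: "Tachypnea", 3: "Noise"}

_INT16_SCALE = 32768.0


@dataclass
class AudioRecording:
    """A labelled mono waveform, amplitudes in [-1, 1]."""

    samples: np.ndarray
    rate: int
    record_id: str = ""
    label: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording holds mono audio only")
        if self.label is not None and self.label not in CLASS_NAMES:
            raise ValueError(f"label must be in {sorted(CLASS_NAMES)}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class LabeledSegment:
    """A fixed-duration window cut from a recording."""

    samples: np.ndarray
    rate: int
    start_time: float
    label: int | None
    source_id: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.start_time < 0:
            raise ValueError("start_time must be non-negative")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def read_wav(path: str | Path, label: int | None = None) -> AudioRecording:
    """Read a mono 16-bit PCM WAV into [-1, 1] floats.

    Raises on multi-channel files rather than mixing down: channel identity
    (left vs right lung) must be decided by the caller.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path.name}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _INT16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path.name}: unsupported sample format {data.dtype}")
    return AudioRecording(samples, int(rate), record_id=path.stem, label=label)


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write as 16-bit PCM; float amplitudes are clipped to [-1, 1)."""
    scaled = np.clip(rec.samples * _INT16_SCALE, -32768, 32767)
    wavfile.write(Path(path), rec.rate, scaled.astype(np.int16))


def read_label_file(path: str | Path) -> int:
    """Read the single-integer class label from a sidecar ``.txt`` file."""
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty label file")
    first = text.splitlines()[0].strip()
    try:
        label = int(first)
    except ValueError as exc:
        raise ValueError(f"{path}: label is not an integer: {first!r}") from exc
    if label not in CLASS_NAMES:
        raise ValueError(f"{path}: label {label} outside {sorted(CLASS_NAMES)}")
    return label


def write_label_file(path: str | Path, label: int) -> None:
    if label not in CLASS_NAMES:
        raise ValueError(f"label {label} outside {sorted(CLASS_NAMES)}")
    Path(path).write_text(f"{label}\n")


def segment_recording(
    rec: AudioRecording, duration_s: float = 10.0, overlap: float = 0.5
) -> list[LabeledSegment]:
    """Cut into fixed-duration windows with fractional ``overlap``.

    Window k starts at ``k * duration_s * (1 - overlap)``; only windows that
    fit entirely inside the recording are emitted (incomplete tails are
    discarded, not padded), so a recording shorter than one window yields an
    empty list.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    win = int(round(duration_s * rec.rate))
    hop = int(round(duration_s * (1.0 - overlap) * rec.rate))
    if hop == 0:
        raise ValueError("overlap too close to 1 for this duration/rate")
    segments = []
    start = 0
    k = 0
    n = len(rec.samples)
    while start + win <= n:
        segments.append(
            LabeledSegment(
                samples=rec.samples[start : start + win].copy(),
                rate=rec.rate,
                start_time=start / rec.rate,
                label=rec.label,
                source_id=rec.record_id,
            )
        )
        k += 1
        start = k * hop
    return segments
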