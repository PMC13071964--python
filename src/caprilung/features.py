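"""Gammatone filterbank features (gammatonegrams) and model-input conversion.

The gammatone filter models cochlear frequency analysis; its impulse
response is

    g(t) = a * t**(n-1) * exp(-2*pi*b*ERB(fc)*t) * cos(2*pi*fc*t + phi)

with order ``n`` (4 here), decay factor ``b = 1.019`` and the Glasberg-Moore
equivalent rectangular bandwidth ERB(f) = 24.7 * (4.37 * f / 1000 + 1).
Centre frequencies are spaced uniformly on the ERB-rate scale, which gives
the dense low-frequency resolution that suits lung sounds (50-2000 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from skimage.transform import resize

from .audio_io import LabeledSegment

__all__ = [
    "GammatoneFilterSpec",
    "Gammatonegram",
    "ModelInput",
    "erb_bandwidth",
    "erb_rate",
    "erb_rate_inverse",
    "gammatone_impulse_response",
    "make_filterbank",
    "filterbank_firs",
    "compute_gammatonegram",
    "resize_values",
    "standardize_image",
    "to_model_input",
]

LOG_FLOOR = 1e-10
DEFAULT_IR_LENGTH_S = 0.128  # FIR truncation; envelope is < -80 dB by then


def erb_bandwidth(fc: float | np.ndarray) -> float | np.ndarray:
    """Glasberg-Moore ERB in Hz: 24.7 * (4.37 * fc / 1000 + 1)."""
    fc = np.asarray(fc, dtype=np.float64)
    if np.any(fc < 0):
        raise ValueError("centre frequency must be non-negative")
    out = 24.7 * (4.37 * fc / 1000.0 + 1.0)
    return float(out) if out.ndim == 0 else out


def erb_rate(f: float | np.ndarray) -> float | np.ndarray:
    """ERB-rate (ERB-number) scale: 21.4 * log10(4.37 * f / 1000 + 1)."""
    f = np.asarray(f, dtype=np.float64)
    out = 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)
    return float(out) if out.ndim == 0 else out


def erb_rate_inverse(e: float | np.ndarray) -> float | np.ndarray:
    e = np.asarray(e, dtype=np.float64)
    out = (10.0 ** (e / 21.4) - 1.0) * 1000.0 / 4.37
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GammatoneFilterSpec:
    fc: float
    a: float = 1.0
    n: int = 4
    b: float = 1.019
    phi: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("filter order must be >= 1")
        if self.b <= 0 or self.fc <= 0:
            raise ValueError("decay factor and centre frequency must be positive")

    @property
    def erb_fc(self) -> float:
        return erb_bandwidth(self.fc)


def gammatone_impulse_response(spec: GammatoneFilterSpec, t) -> np.ndarray:
    """Evaluate g(t) for t >= 0."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("impulse response is causal; t must be >= 0")
    env = spec.a * t ** (spec.n - 1) * np.exp(-2.0 * np.pi * spec.b * spec.erb_fc * t)
    return env * np.cos(2.0 * np.pi * spec.fc * t + spec.phi)


def make_filterbank(
    n_filters: int = 64,
    f_low: float = 50.0,
    f_high: float = 2000.0,
    rate: float = 8000.0,
) -> list[GammatoneFilterSpec]:
    """Centre frequencies equally spaced on the ERB-rate scale, ascending;
    the first and last centres sit exactly at ``f_low`` and ``f_high``."""
    if n_filters < 2:
        raise ValueError("need at least two filters")
    if not 0 < f_low < f_high < rate / 2:
        raise ValueError("need 0 < f_low < f_high < Nyquist")
    centres = erb_rate_inverse(np.linspace(erb_rate(f_low), erb_rate(f_high), n_filters))
    centres[0], centres[-1] = f_low, f_high  # pin endpoints against round-off
    return [GammatoneFilterSpec(fc=float(fc)) for fc in centres]


def filterbank_firs(
    bank: list[GammatoneFilterSpec],
    rate: float,
    ir_length_s: float = DEFAULT_IR_LENGTH_S,
) -> np.ndarray:
    """FIR realization (n_filters, taps): truncated impulse responses with
    gain normalized to unity at each filter's centre frequency."""
    taps = int(round(ir_length_s * rate))
    t = np.arange(taps) / rate
    firs = np.stack([gammatone_impulse_response(spec, t) for spec in bank])
    fcs = np.array([spec.fc for spec in bank])
    # response at fc: H(fc) = sum_k h[k] exp(-2i pi fc k / rate)
    phases = np.exp(-2j * np.pi * np.outer(fcs, np.arange(taps)) / rate)
    gains = np.abs((firs * phases).sum(axis=1))
    return firs / gains[:, None]


@dataclass
class Gammatonegram:
    """Log-energy matrix, one row per filter (ascending centre frequency)."""

    values: np.ndarray
    center_freqs: np.ndarray
    frame_s: float
    hop_s: float
    label: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.center_freqs = np.asarray(self.center_freqs, dtype=np.float64)
        if self.values.shape[0] != len(self.center_freqs):
            raise ValueError("one centre frequency per row required")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("centre frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gammatonegram values must be finite")


def compute_gammatonegram(
    seg: LabeledSegment,
    bank: list[GammatoneFilterSpec],
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    ir_length_s: float = DEFAULT_IR_LENGTH_S,
    firs: np.ndarray | None = None,
) -> Gammatonegram:
    """Filter, square, frame-average and log-compress.

    Cell (k, m) is ``log10(eps + mean energy of filter k over frame m)`` with
    eps = 1e-10; the frame count is ``floor((N - frame) / hop) + 1``.
    Passing precomputed ``firs`` skips re-normalizing the bank per call.
    """
    if not frame_s > hop_s > 0:
        raise ValueError("need frame_s > hop_s > 0")
    frame = int(round(frame_s * seg.rate))
    hop = int(round(hop_s * seg.rate))
    n = len(seg.samples)
    if n < frame:
        raise ValueError("segment shorter than one analysis frame")
    if firs is None:
        firs = filterbank_firs(bank, seg.rate, ir_length_s)
    # causal FIR filtering via one shared FFT of the signal; single precision
    # here is ~7 significant digits, far below the log-energy resolution
    fft_n = next_fast_len(n + firs.shape[1] - 1)
    spectrum = rfft(seg.samples.astype(np.float32), fft_n)
    fir_spectra = rfft(firs.astype(np.float32), fft_n, axis=-1)
    filtered = irfft(fir_spectra * spectrum, fft_n, axis=-1)[:, :n]
    energy = filtered.astype(np.float64) ** 2
    windows = np.lib.stride_tricks.sliding_window_view(energy, frame, axis=-1)
    frame_energy = windows[:, ::hop, :].mean(axis=-1)
    return Gammatonegram(
        values=np.log10(LOG_FLOOR + frame_energy),
        center_freqs=np.array([spec.fc for spec in bank]),
        frame_s=frame_s,
        hop_s=hop_s,
        label=seg.label,
    )


@dataclass
class ModelInput:
    """Standardized 3-channel square image (channels, side, side)."""

    values: np.ndarray
    label: int | None = None


def resize_values(gtg: Gammatonegram, side: int) -> np.ndarray:
    """Bilinear resize of the log-energy matrix to ``side x side``; row order
    (ascending frequency) is preserved."""
    if gtg.values.shape[1] < 2:
        raise ValueError("gammatonegram must have at least two frames")
    return resize(gtg.values, (side, side), order=1, mode="edge", anti_aliasing=False)


def standardize_image(img: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance per sample, with a variance floor so a
    constant image maps to all zeros."""
    std = img.std()
    if std < 1e-8:
        return np.zeros_like(img)
    return (img - img.mean()) / std


def to_model_input(gtg: Gammatonegram, side: int = 224) -> ModelInput:
    """Bilinear resize to ``side x side``, per-sample standardization, and
    replication to three identical channels."""
    img = standardize_image(resize_values(gtg, side))
    return ModelInput(values=np.repeat(img[None, :, :], 3, axis=0), label=gtg.label)
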