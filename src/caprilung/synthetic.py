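"""Class-conditional synthetic goat lung-sound generator.

Emulates the acoustic structure the four classes are defined by, so the full
pipeline is testable without field recordings:

* **Normal** — band-limited breath noise (energy concentrated 50-800 Hz)
  amplitude-modulated by a respiratory cycle at 12-30 breaths/min with an
  inspiration-dominant envelope, over a faint ambient floor.
* **Rhonchi** — the normal structure plus a continuous low-pitched tonal
  component (80-300 Hz, snoring-like) whose amplitude exceeds the breath
  noise, giving elevated low-band energy.
* **Tachypnea** — the normal structure at a clearly elevated rate
  (40-80 breaths/min).
* **Noise** — pink ambient noise with Poisson-timed friction transients and
  the breath component attenuated by >= 12 dB.

These are caricatures of auscultation acoustics, not goat physiology; they
encode the class-separating structure (rate, tonality, noise dominance) and
nothing subtler.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .audio_io import AudioRecording, write_label_file, write_wav

__all__ = [
    "SynthesisParams",
    "breath_envelope",
    "synth_recording",
    "draw_params",
    "generate_dataset",
]

NORMAL_BPM_RANGE = (12.0, 30.0)
TACHYPNEA_BPM_RANGE = (40.0, 80.0)
RHONCHI_TONE_RANGE = (80.0, 300.0)


@dataclass(frozen=True)
class SynthesisParams:
    label: int
    rate: int = 8000
    duration_s: float = 10.0
    breaths_per_min: float = 20.0
    rhonchi_tone_hz: float = 150.0
    rhonchi_gain: float = 2.0
    snr_db: float = 15.0
    noise_burst_rate: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration must be positive")
        if self.label not in (0, 1, 2, 3):
            raise ValueError("label must be in {0,1,2,3}")
        if self.label == 2 and self.breaths_per_min <= NORMAL_BPM_RANGE[1]:
            raise ValueError("tachypnea requires breaths_per_min above the normal range")
        if self.label == 1 and self.rhonchi_gain <= 1:
            raise ValueError("rhonchi tonal gain must exceed 1")


def breath_envelope(params: SynthesisParams, t: np.ndarray) -> np.ndarray:
    """Smooth periodic respiratory gain with an inspiration-dominant cycle.

    Within each cycle (phase in [0, 1)): a strong Gaussian bump for
    inspiration around phase 0.2, a weaker one for expiration around 0.55,
    over a small baseline.  More than 60% of the per-cycle envelope integral
    falls in the inspiratory phase (first 40% of the cycle).
    """
    phase = np.mod(t * params.breaths_per_min / 60.0, 1.0)
    insp = np.exp(-0.5 * ((phase - 0.20) / 0.08) ** 2)
    exp_ = 0.30 * np.exp(-0.5 * ((phase - 0.55) / 0.12) ** 2)
    return 0.05 + insp + exp_


def _band_noise(rng, n, rate, low, high, order=4):
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return signal.sosfilt(sos, rng.standard_normal(n))


def _pink_noise(rng, n):
    """1/f-shaped noise via spectral shaping of white noise."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    pink = np.fft.irfft(spectrum / np.sqrt(freqs), n)
    return pink / pink.std()


def _rms(x):
    return float(np.sqrt(np.mean(x**2)))


def synth_recording(params: SynthesisParams, record_id: str | None = None) -> AudioRecording:
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate))
    t = np.arange(n) / params.rate

    env = breath_envelope(params, t)
    breath = _band_noise(rng, n, params.rate, 50.0, 800.0) * env
    breath_rms = _rms(breath)
    ambient = _pink_noise(rng, n)
    ambient *= breath_rms / (10.0 ** (params.snr_db / 20.0))

    if params.label in (0, 2):  # normal / tachypnea share the structure
        out = breath + ambient
    elif params.label == 1:  # rhonchi: continuous AM tone over the breath base
        tone = np.sin(2.0 * np.pi * params.rhonchi_tone_hz * t + rng.uniform(0, 2 * np.pi))
        tone *= (0.35 + 0.65 * env / env.max())  # continuous, breath-modulated
        tone *= params.rhonchi_gain * breath_rms / _rms(tone)
        out = breath + tone + ambient
    else:  # noise class: ambient-dominated with friction transients
        pink = _pink_noise(rng, n) * breath_rms
        bursts = np.zeros(n)
        n_bursts = rng.poisson(params.noise_burst_rate * params.duration_s)
        for _ in range(n_bursts):
            start = rng.integers(0, max(1, n - params.rate // 10))
            width = rng.integers(params.rate // 50, params.rate // 10)  # 20-100 ms
            burst = _band_noise(rng, int(width), params.rate, 100.0, 3000.0)
            burst *= np.hanning(len(burst))
            stop = min(n, start + len(burst))
            bursts[start:stop] += burst[: stop - start] * rng.uniform(2.0, 5.0)
        attenuated = breath * 10.0 ** (-14.0 / 20.0)  # breath content >= 12 dB down
        out = pink + bursts * breath_rms + attenuated

    peak = np.abs(out).max()
    if peak > 0:
        out = out * (0.9 / peak)
    rid = record_id if record_id is not None else f"synth_{params.label}_{params.seed}"
    return AudioRecording(out, params.rate, record_id=rid, label=params.label)


def draw_params(
    label: int, rng: np.random.Generator, duration_s: float = 10.0, rate: int = 8000
) -> SynthesisParams:
    """Draw class-conditional parameters; all randomness comes from ``rng``."""
    bpm_lo, bpm_hi = TACHYPNEA_BPM_RANGE if label == 2 else NORMAL_BPM_RANGE
    return SynthesisParams(
        label=label,
        rate=rate,
        duration_s=duration_s,
        breaths_per_min=float(rng.uniform(bpm_lo, bpm_hi)),
        rhonchi_tone_hz=float(rng.uniform(*RHONCHI_TONE_RANGE)),
        rhonchi_gain=float(rng.uniform(1.5, 3.0)),
        snr_db=float(rng.uniform(10.0, 20.0)),
        noise_burst_rate=float(rng.uniform(1.0, 3.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n_per_class: dict[int, int] | tuple[int, int, int, int],
    out_dir: str | Path,
    seed: int,
    duration_s: float = 10.0,
    rate: int = 8000,
    write_audio: bool = True,
) -> pd.DataFrame:
    """Generate WAV + label-sidecar files and return the manifest.

    One ``SeedSequence`` spawned per file keeps the manifest reproducible for
    a given ``seed`` regardless of generation order.
    """
    if not isinstance(n_per_class, dict):
        n_per_class = dict(enumerate(n_per_class))
    out_dir = Path(out_dir)
    if write_audio:
        out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(n_per_class):
        for i in range(n_per_class[label]):
            params = draw_params(label, rng, duration_s=duration_s, rate=rate)
            stem = f"goat{label}{i:05d}"
            rec = synth_recording(params, record_id=stem)
            if write_audio:
                write_wav(out_dir / f"{stem}.wav", rec)
                write_label_file(out_dir / f"{stem}.txt", label)
            rows.append(
                {
                    "file": f"{stem}.wav",
                    "label": label,
                    "duration_s": duration_s,
                    "breaths_per_min": params.breaths_per_min,
                    "rhonchi_tone_hz": params.rhonchi_tone_hz,
                    "rhonchi_gain": params.rhonchi_gain,
                    "snr_db": params.snr_db,
                    "noise_burst_rate": params.noise_burst_rate,
                    "seed": params.seed,
                }
            )
    manifest = pd.DataFrame(rows)
    if write_audio:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
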