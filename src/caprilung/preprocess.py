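"""Bandpass filtering of lung-sound segments and SMOTE class balancing.

Lung-sound energy lives in roughly 50-2000 Hz; a fourth-order Butterworth
bandpass strips DC drift, mains rumble and high-frequency hiss.  Class
imbalance is handled by SMOTE in feature space: each synthetic vector is
``x_i + u * (x_nn - x_i)`` with ``u ~ U[0, 1]`` and ``x_nn`` one of the k
nearest same-class neighbours of ``x_i``, so no raw waveform is ever
manipulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.neighbors import NearestNeighbors

from .audio_io import LabeledSegment

__all__ = [
    "BandpassSpec",
    "ClassFeatureTable",
    "design_bandpass",
    "apply_bandpass",
    "smote_balance",
]


@dataclass(frozen=True)
class BandpassSpec:
    order: int = 4
    low_hz: float = 50.0
    high_hz: float = 2000.0
    rate: float = 8000.0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= self.rate / 2:
            raise ValueError("high cutoff must be below Nyquist")


def design_bandpass(spec: BandpassSpec) -> np.ndarray:
    """Butterworth bandpass as second-order sections (numerically stable)."""
    return signal.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=spec.rate,
        output="sos",
    )


def bandpass_response_db(spec: BandpassSpec, freqs_hz) -> np.ndarray:
    """Single-pass magnitude response in dB at the given frequencies."""
    sos = design_bandpass(spec)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=spec.rate)
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(np.abs(h))


def apply_bandpass(seg: LabeledSegment, spec: BandpassSpec) -> LabeledSegment:
    """Zero-phase (forward-backward) filtering; preserves length and label."""
    if seg.rate != spec.rate:
        raise ValueError(f"segment rate {seg.rate} != filter rate {spec.rate}")
    sos = design_bandpass(spec)
    filtered = signal.sosfiltfilt(sos, seg.samples)
    return LabeledSegment(
        samples=filtered,
        rate=seg.rate,
        start_time=seg.start_time,
        label=seg.label,
        source_id=seg.source_id,
    )


@dataclass
class ClassFeatureTable:
    """Per-class collections of equal-length feature vectors."""

    vectors: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        dims = set()
        for label, arr in self.vectors.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"class {label}: expected a 2-D (n, d) array")
            self.vectors[label] = arr
            dims.add(arr.shape[1])
        if len(dims) > 1:
            raise ValueError("all classes must share one feature dimension")

    @property
    def counts(self) -> dict[int, int]:
        return {label: arr.shape[0] for label, arr in self.vectors.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def smote_balance(
    table: ClassFeatureTable, k_neighbors: int = 5, seed: int | None = None
) -> ClassFeatureTable:
    """Oversample every minority class up to the majority-class count.

    Original vectors are kept untouched and come first in each class block.
    Parents are drawn uniformly from the minority class; for each, one of its
    k nearest same-class neighbours (excluding itself) is chosen uniformly
    and the synthetic point is a uniform interpolation between the two.
    """
    rng = np.random.default_rng(seed)
    target = max(table.counts.values())
    out: dict[int, np.ndarray] = {}
    for label in sorted(table.vectors):
        X = table.vectors[label]
        n = X.shape[0]
        need = target - n
        if need == 0:
            out[label] = X.copy()
            continue
        if n <= k_neighbors:
            raise ValueError(
                f"class {label} has {n} members; needs > k_neighbors={k_neighbors}"
            )
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
        _, idx = nn.kneighbors(X)  # column 0 is the point itself
        parents = rng.integers(0, n, size=need)
        picks = rng.integers(0, k_neighbors, size=need)
        gaps = rng.uniform(0.0, 1.0, size=need)
        neighbours = idx[parents, picks + 1]
        synth = X[parents] + gaps[:, None] * (X[neighbours] - X[parents])
        out[label] = np.vstack([X, synth])
    return ClassFeatureTable(out)
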