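"""End-to-end glue: directory of labelled WAV segments -> features -> k-fold
cross-validated training -> per-fold metrics.

SMOTE balancing, when enabled, is applied inside each training fold after
the split (the test fold stays untouched), on flattened gammatonegram
feature matrices; synthetic matrices are reshaped back into images for the
classifier.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio_io, features, preprocess
from .evaluation import (
    TrainSpec,
    compute_metrics,
    evaluate_model,
    make_folds,
    train_model,
)
from .model import ModelConfig, reduced_config

__all__ = ["load_directory", "prepare_feature_matrices", "matrices_to_inputs",
           "cross_validate_directory", "config_for_side"]


def load_directory(data_dir: str | Path) -> list[audio_io.AudioRecording]:
    """Read every ``<stem>.wav`` with its ``<stem>.txt`` label sidecar."""
    data_dir = Path(data_dir)
    recs = []
    for wav in sorted(data_dir.glob("*.wav")):
        label = audio_io.read_label_file(wav.with_suffix(".txt"))
        recs.append(audio_io.read_wav(wav, label=label))
    if not recs:
        raise ValueError(f"no labelled WAV files in {data_dir}")
    return recs


def prepare_feature_matrices(
    recs: list[audio_io.AudioRecording],
    side: int,
    n_filters: int = 64,
    bandpass: preprocess.BandpassSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bandpass + gammatonegram + bilinear resize for every recording.

    Returns ``(matrices (N, side, side), labels (N,), sources (N,) str)``.
    """
    rate = recs[0].rate
    spec = bandpass or preprocess.BandpassSpec(rate=rate)
    bank = features.make_filterbank(n_filters, spec.low_hz, spec.high_hz, rate)
    firs = features.filterbank_firs(bank, rate)
    mats, labels, sources = [], [], []
    for rec in recs:
        seg = audio_io.LabeledSegment(rec.samples, rec.rate, 0.0, rec.label, rec.record_id)
        seg = preprocess.apply_bandpass(seg, spec)
        gtg = features.compute_gammatonegram(seg, bank, firs=firs)
        mats.append(features.resize_values(gtg, side))
        labels.append(rec.label)
        sources.append(rec.record_id)
    return np.stack(mats), np.array(labels), np.array(sources)


def matrices_to_inputs(mats: np.ndarray) -> np.ndarray:
    """Standardize each matrix and replicate to three channels."""
    out = np.empty((len(mats), 3, mats.shape[1], mats.shape[2]))
    for i, m in enumerate(mats):
        out[i] = features.standardize_image(m)[None].repeat(3, axis=0)
    return out


def config_for_side(side: int, **overrides) -> ModelConfig:
    """Full tiny backbone at 224, the depth-reduced CPU configuration else.

    The window size must divide every stage's token-grid side (after the
    small-stage clamp), so it is picked from the post-embedding grid.
    """
    if side == 224:
        return ModelConfig(**overrides)
    grid = side // 4
    overrides.setdefault("window", 6 if grid % 3 == 0 else 4)
    return reduced_config(input_side=side, **overrides)


def _balance_fold(mats, labels, k_neighbors, seed):
    from .preprocess import ClassFeatureTable, smote_balance

    flat = {int(c): mats[labels == c].reshape((labels == c).sum(), -1)
            for c in np.unique(labels)}
    balanced = smote_balance(ClassFeatureTable(flat), k_neighbors=k_neighbors, seed=seed)
    side = mats.shape[1]
    out_mats, out_labels = [], []
    for c in sorted(balanced.vectors):
        block = balanced.vectors[c].reshape(-1, side, side)
        out_mats.append(block)
        out_labels.append(np.full(len(block), c))
    return np.concatenate(out_mats), np.concatenate(out_labels)


def cross_validate_directory(
    data_dir: str | Path,
    k: int = 5,
    seed: int = 0,
    epochs: int = 50,
    lr: float = 1e-4,
    batch_size: int = 32,
    side: int = 96,
    smote: bool = True,
    smote_k: int = 5,
    out_dir: str | Path | None = None,
    group_by_source: bool = True,
) -> dict:
    """Grouped stratified k-fold cross-validation over a segment directory."""
    recs = load_directory(data_dir)
    mats, labels, sources = prepare_feature_matrices(recs, side)
    groups = sources if group_by_source else None
    plan = make_folds(labels, k=k, seed=seed, group_ids=groups)
    cfg = config_for_side(side)
    per_fold = []
    for fold in range(k):
        test_idx = np.array(plan.test_indices[fold])
        train_idx = plan.train_indices(fold, len(labels))
        tr_mats, tr_labels = mats[train_idx], labels[train_idx]
        if smote:
            tr_mats, tr_labels = _balance_fold(tr_mats, tr_labels, smote_k, seed + fold)
        net, _ = train_model(
            cfg,
            TrainSpec(lr=lr, batch_size=batch_size, epochs=epochs, seed=seed + fold),
            matrices_to_inputs(tr_mats),
            tr_labels,
        )
        confusion = evaluate_model(net, matrices_to_inputs(mats[test_idx]), labels[test_idx])
        metrics = compute_metrics(confusion)
        per_fold.append({
            "fold": fold,
            "accuracy": metrics.accuracy,
            "se": metrics.se,
            "sp": metrics.sp,
            "score": metrics.score,
        })
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(confusion.matrix).to_csv(out / f"confusion_fold{fold}.csv")
    summary = {
        key: {
            "mean": float(np.mean([f[key] for f in per_fold])),
            "std": float(np.std([f[key] for f in per_fold])),
        }
        for key in ("accuracy", "se", "sp", "score")
    }
    report = {"folds": per_fold, "summary": summary, "k": k, "seed": seed}
    if out_dir is not None:
        Path(out_dir, "metrics.json").write_text(json.dumps(report, indent=2))
    return report
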