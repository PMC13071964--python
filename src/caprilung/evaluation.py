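"""Cross-validated training and the respiratory-sound evaluation metrics.

The four metrics follow the ICBHI-style convention for this four-class
problem: with per-class totals Nl (Normal), W (Rhonchi), T (Tachypnea),
Ne (Noise) and correct counts Nl_nl, W_w, T_t, Ne_ne,

    Accuracy = (Nl_nl + W_w + T_t + Ne_ne) / (Nl + W + T + Ne)
    Se       = (W_w + T_t) / (W + T)          (abnormal classes)
    Sp       = Nl_nl / Nl                      (normal class)
    Score    = (Se + Sp) / 2

Noise recordings count toward Accuracy only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .model.config import ModelConfig
from .model.network import CapriLungNet, build_model
from .nn import Adam, cross_entropy, no_grad

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "MetricsReport",
    "TrainSpec",
    "make_folds",
    "train_model",
    "evaluate_model",
    "compute_metrics",
    "score_from_se_sp",
    "round_half_up",
]


@dataclass(frozen=True)
class FoldPlan:
    k: int
    test_indices: tuple[tuple[int, ...], ...]
    seed: int
    stratified: bool = True
    grouped: bool = False

    def train_indices(self, fold: int, n: int) -> np.ndarray:
        test = set(self.test_indices[fold])
        return np.array([i for i in range(n) if i not in test])


def make_folds(
    labels,
    k: int = 5,
    seed: int = 0,
    group_ids=None,
) -> FoldPlan:
    """Stratified k-fold split; with ``group_ids`` all samples of one source
    recording stay in a single fold (leakage guard for overlapping segments)."""
    labels = np.asarray(labels)
    n = len(labels)
    if k > n:
        raise ValueError("more folds than samples")
    counts = np.bincount(labels)
    if np.any(counts[counts > 0] < k):
        raise ValueError("every class needs at least k members for stratification")
    if group_ids is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels, groups=np.asarray(group_ids))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels)
    tests = tuple(tuple(int(i) for i in test) for _, test in splits)
    return FoldPlan(k=k, test_indices=tests, seed=seed, grouped=group_ids is not None)


@dataclass(frozen=True)
class TrainSpec:
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("lr and batch_size must be positive, epochs >= 0")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_model(
    cfg: ModelConfig,
    spec: TrainSpec,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> tuple[CapriLungNet, TrainHistory]:
    """Adam + cross-entropy training; returns the best-validation-epoch
    weights (last epoch when no validation split is given).

    Divergence (non-finite loss) raises rather than returning silently.
    """
    if len(train_x) == 0:
        raise ValueError("empty training set")
    net = build_model(cfg, seed=spec.seed)
    history = TrainHistory()
    if spec.epochs == 0:
        return net, history
    opt = Adam(net.parameters(), lr=spec.lr)
    rng = np.random.default_rng(spec.seed)
    best_state, best_val = None, -np.inf
    n = len(train_x)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, spec.batch_size):
            idx = order[lo : lo + spec.batch_size]
            logits = net.forward(train_x[idx])
            loss = cross_entropy(logits, train_y[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            correct += int((np.argmax(logits.data, -1) == train_y[idx]).sum())
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(correct / n)
        if val_x is not None and len(val_x):
            val_acc = float(np.mean(net.predict(val_x) == val_y))
            history.val_acc.append(val_acc)
            if val_acc > best_val:
                best_val, best_state = val_acc, net.state_dict()
                history.best_epoch = epoch
        else:
            history.best_epoch = epoch
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


@dataclass
class ConfusionCounts:
    """4x4 confusion matrix, rows = true class, columns = predicted."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (4, 4):
            raise ValueError("confusion matrix must be 4x4")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if len(y_true) == 0:
            raise ValueError("empty evaluation set")
        m = np.zeros((4, 4), dtype=np.int64)
        np.add.at(m, (y_true, y_pred), 1)
        return cls(m)

    @property
    def class_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def correct(self) -> np.ndarray:
        return np.diag(self.matrix)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    se: float
    sp: float
    score: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding (the convention of printed tables); float
    noise is quantized away at 6 dp first so e.g. 88.064999... -> 88.07."""
    q = Decimal(f"{x:.6f}").quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP)
    return float(q)


def score_from_se_sp(se: float, sp: float) -> float:
    """Score = (Se + Sp) / 2, on the percentage scale."""
    return (se + sp) / 2.0


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy/Se/Sp/Score in percent; raises on empty denominators."""
    totals = c.class_totals
    nl, w, t, _ = totals
    if totals.sum() == 0:
        raise ValueError("no samples")
    if w + t == 0:
        raise ValueError("sensitivity undefined: no abnormal samples")
    if nl == 0:
        raise ValueError("specificity undefined: no normal samples")
    correct = c.correct
    accuracy = 100.0 * correct.sum() / totals.sum()
    se = 100.0 * (correct[1] + correct[2]) / (w + t)
    sp = 100.0 * correct[0] / nl
    return MetricsReport(
        accuracy=accuracy, se=se, sp=sp, score=score_from_se_sp(se, sp)
    )


def evaluate_model(network: CapriLungNet, test_x: np.ndarray, test_y: np.ndarray) -> ConfusionCounts:
    if len(test_x) == 0:
        raise ValueError("empty test set")
    with no_grad():
        preds = network.predict(test_x)
    return ConfusionCounts.from_predictions(test_y, preds)
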