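"""Classifier validation harness: does refined data help chaos detection?

Builds three training-set styles from a simulated corpus and its refined
sets — *refined* (the extracted subsequences), *original* (consecutive
non-overlapping windows of the source signals) and *augmented* (their
union) — trains the small LSTM classifier on each, and evaluates on
length-n windows chopped from held-out source signals never used for
training.  The comparison of final test accuracies across styles is the
harness's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import SignalSeries
from .lstm import FitHistory, LSTMClassifier
from .refine import RefinedSet

LABEL_TO_CLASS = {"non-chaotic": 0, "chaotic": 1}
CLASS_NAMES = ("non-chaotic", "chaotic")


@dataclass(frozen=True)
class HarnessConfig:
    """Training configuration of the validation experiment.

    Defaults follow the reference setup (Adam, lr 0.001, batch 64, softmax
    cross-entropy); ``epochs`` defaults to a reduced desk-scale profile of
    200 — set 1000 for the full-length run.
    """

    series_length: int = 100
    hidden_units: int = 16
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 0.001
    standardize: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.series_length < 1 or self.hidden_units < 1 or self.batch_size < 1:
            raise ValueError("series_length, hidden_units and batch_size must be >= 1")


@dataclass
class DatasetSplit:
    """Length-n training/test series with integer class labels."""

    train_X: np.ndarray  # (n_train, n, 1)
    train_y: np.ndarray
    test_X: np.ndarray   # (n_test, n, 1)
    test_y: np.ndarray
    provenance: str      # refined | original | augmented
    composition: dict = field(default_factory=dict)


@dataclass
class TrainResult:
    history: FitHistory
    final_test_accuracy: float
    final_test_loss: float
    provenance: str
    config: HarnessConfig
    composition: dict = field(default_factory=dict)


def _label_class(label: str) -> int:
    try:
        return LABEL_TO_CLASS[label]
    except KeyError:
        raise ValueError(f"series label {label!r} is not chaotic/non-chaotic") from None


def _windows(series: SignalSeries, n: int) -> list[np.ndarray]:
    """Consecutive non-overlapping length-n windows (tail remainder dropped)."""
    m = len(series) // n
    return [series.samples[k * n:(k + 1) * n] for k in range(m)]


def build_splits(refined_sets: Sequence[RefinedSet],
                 source_corpus: Sequence[SignalSeries],
                 mode: str, n: int = 100, seed: int = 0) -> DatasetSplit:
    """Assemble a train/test split in one of the three styles.

    Training material comes from the sources of ``refined_sets``; every
    member of ``source_corpus`` whose name does not match one of those
    sources is held out and chopped into test windows, so no test window's
    source signal ever appears in training.
    """
    if mode not in ("refined", "original", "augmented"):
        raise ValueError(f"unknown mode {mode!r}")
    if not refined_sets:
        raise ValueError("refined_sets must be non-empty")

    train_names = {r.source.name for r in refined_sets}
    held_out = [s for s in source_corpus if s.name not in train_names]
    if not held_out:
        raise ValueError("no held-out source signals remain for the test set")

    train: list[tuple[np.ndarray, int]] = []
    counts = {"refined": 0, "original": 0}
    if mode in ("refined", "augmented"):
        for r in refined_sets:
            cls = _label_class(r.source.label)
            for sub in r.subsequences:
                if sub.samples.size != n:
                    raise ValueError(
                        f"refined subsequence length {sub.samples.size} != n={n}")
                train.append((sub.samples, cls))
                counts["refined"] += 1
    if mode in ("original", "augmented"):
        for r in refined_sets:
            cls = _label_class(r.source.label)
            for win in _windows(r.source, n):
                train.append((win, cls))
                counts["original"] += 1

    test: list[tuple[np.ndarray, int]] = []
    for s in held_out:
        cls = _label_class(s.label)
        for win in _windows(s, n):
            test.append((win, cls))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    train_X = np.stack([train[i][0] for i in order])[:, :, None]
    train_y = np.array([train[i][1] for i in order])
    test_X = np.stack([w for w, _ in test])[:, :, None]
    test_y = np.array([c for _, c in test])

    for y, part in ((train_y, "train"), (test_y, "test")):
        present = set(np.unique(y))
        if present != {0, 1}:
            missing = [CLASS_NAMES[c] for c in {0, 1} - present]
            raise ValueError(f"{part} set is missing label(s) {missing}")

    composition = {
        "mode": mode, "n": n,
        "train_total": len(train_y), "test_total": len(test_y),
        "train_chaotic": int((train_y == 1).sum()),
        "train_non_chaotic": int((train_y == 0).sum()),
        "test_chaotic": int((test_y == 1).sum()),
        "test_non_chaotic": int((test_y == 0).sum()),
        **{f"train_{k}": v for k, v in counts.items()},
    }
    return DatasetSplit(train_X=train_X, train_y=train_y, test_X=test_X,
                        test_y=test_y, provenance=mode, composition=composition)


def _preprocess(X: np.ndarray, standardize: bool) -> np.ndarray:
    if not standardize:
        return X
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def train_classifier(split: DatasetSplit, config: HarnessConfig | None = None) -> TrainResult:
    """Train the LSTM on a split and record train/test curves per epoch."""
    config = config or HarnessConfig()
    Xtr = _preprocess(split.train_X, config.standardize)
    Xte = _preprocess(split.test_X, config.standardize)
    model = LSTMClassifier(n_hidden=config.hidden_units, n_classes=2,
                           n_features=split.train_X.shape[2],
                           learning_rate=config.learning_rate, seed=config.seed)
    history = model.fit(Xtr, split.train_y, epochs=config.epochs,
                        batch_size=config.batch_size,
                        X_val=Xte, y_val=split.test_y)
    return TrainResult(history=history,
                       final_test_accuracy=history.val_accuracy[-1],
                       final_test_loss=history.val_loss[-1],
                       provenance=split.provenance, config=config,
                       composition=dict(split.composition))


def compare_runs(results: Sequence[TrainResult],
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Tabulate runs (and optionally write table + learning-curve figure).

    The returned frame has one row per run with provenance, hidden units,
    epochs, composition counts and final test accuracy; the ``best`` column
    flags the run(s) with the highest accuracy.
    """
    if not results:
        raise ValueError("results must be non-empty")
    rows = []
    for r in results:
        rows.append({
            "provenance": r.provenance,
            "hidden_units": r.config.hidden_units,
            "epochs": r.config.epochs,
            "seed": r.config.seed,
            "train_total": r.composition.get("train_total"),
            "train_chaotic": r.composition.get("train_chaotic"),
            "train_non_chaotic": r.composition.get("train_non_chaotic"),
            "test_total": r.composition.get("test_total"),
            "final_test_accuracy": r.final_test_accuracy,
            "final_test_loss": r.final_test_loss,
        })
    table = pd.DataFrame(rows)
    table["best"] = table["final_test_accuracy"] == table["final_test_accuracy"].max()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
        curves = []
        for k, r in enumerate(results):
            h = r.history
            for epoch in range(len(h.train_loss)):
                curves.append({
                    "run": k, "provenance": r.provenance, "epoch": epoch + 1,
                    "train_loss": h.train_loss[epoch],
                    "train_accuracy": h.train_accuracy[epoch],
                    "test_loss": h.val_loss[epoch] if h.val_loss else None,
                    "test_accuracy": h.val_accuracy[epoch] if h.val_accuracy else None,
                })
        pd.DataFrame(curves).to_csv(out_dir / "curves.tsv", sep="\t", index=False)
        if curves:
            _plot_curves(results, out_dir / "curves.png")
    return table


def _plot_curves(results: Sequence[TrainResult], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(10, 4))
    for k, r in enumerate(results):
        h = r.history
        epochs = np.arange(1, len(h.train_loss) + 1)
        label = f"{r.provenance} (U={r.config.hidden_units}, seed {r.config.seed})"
        ax_loss.plot(epochs, h.train_loss, label=f"{label} train")
        ax_acc.plot(epochs, h.train_accuracy, label=f"{label} train")
        if h.val_loss:
            ax_loss.plot(epochs, h.val_loss, "--", label=f"{label} test")
            ax_acc.plot(epochs, h.val_accuracy, "--", label=f"{label} test")
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("cross-entropy loss")
    ax_acc.set_xlabel("epoch")
    ax_acc.set_ylabel("accuracy")
    ax_acc.set_ylim(0, 1.02)
    ax_acc.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
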