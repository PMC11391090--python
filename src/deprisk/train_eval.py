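"""Stratified splitting, BCE training with early stopping, macro-averaged
evaluation, and the strategy x rate x encoder sweep runner.

The unit of batching is the user.  Training minimizes binary cross-entropy
on the sigmoid classifier's logits with Adam (learning rate 1e-3 by
default), shuffles user order each epoch with the run seed, and keeps the
checkpoint with the best validation macro-F1.  Evaluation reports accuracy
and macro-averaged precision/recall/F1 over the two cohorts, with any
0/0-undefined per-class metric set to 0.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from . import nn
from .corpus_io import Corpus, Lexicon
from .sampling import SampledView, sample_corpus

SPLITS = ("train", "validation", "test")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 10
    patience: int = 5
    seed: int = 0
    optimizer: str = "adam"
    dropout_in_train: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]
    confusion: dict[str, int]

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall, "macro_f1": self.macro_f1}


def split_corpus(corpus: Corpus, per_class_counts: tuple[int, int, int],
                 seed: int = 0) -> Corpus:
    """Stratified split with exactly the requested per-class counts.

    Deterministic given the seed; raises if a class has too few users.
    """
    n_train, n_val, n_test = per_class_counts
    need = n_train + n_val + n_test
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in ("depressed", "control"):
        ids = sorted(u.user_id for u in corpus.by_label(label))
        if len(ids) < need:
            raise ValueError(f"class {label!r} has {len(ids)} users, "
                             f"needs {need} for the requested split")
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            if rank < n_train:
                assignment[ids[idx]] = "train"
            elif rank < n_train + n_val:
                assignment[ids[idx]] = "validation"
            elif rank < need:
                assignment[ids[idx]] = "test"
            else:
                assignment[ids[idx]] = "unused"
    return Corpus(users=list(corpus.users), split_assignment=assignment)


def _pairs_for_split(corpus: Corpus, views: dict[str, SampledView], split: str):
    users = corpus.split(split)
    missing = [u.user_id for u in users if u.user_id not in views]
    if missing:
        raise ValueError(f"no view for users {missing[:5]} in split {split!r}")
    return [(u, views[u.user_id]) for u in users]


def _predict_logits(model, pairs, batch_size: int = 64) -> np.ndarray:
    logits = []
    model.set_train(None)
    with nn.no_grad():
        for i in range(0, len(pairs), batch_size):
            batch = model.prepare_batch(pairs[i:i + batch_size])
            logits.append(model.forward(batch).data)
    return np.concatenate(logits)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Accuracy + macro P/R/F1 for binary cohort labels (1 = depressed)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty split")
    acc = accuracy_score(y_true, y_pred)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average=None, zero_division=0)
    per_class = {name: {"precision": float(p[i]), "recall": float(r[i]),
                        "f1": float(f1[i])}
                 for i, name in enumerate(("control", "depressed"))}
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return MetricsReport(
        accuracy=float(acc),
        macro_precision=float(p.mean()), macro_recall=float(r.mean()),
        macro_f1=float(f1.mean()), per_class=per_class,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn})


def evaluate(model, corpus: Corpus, views: dict[str, SampledView],
             split: str = "test", threshold: float = 0.5) -> MetricsReport:
    pairs = _pairs_for_split(corpus, views, split)
    logits = _predict_logits(model, pairs)
    y_true = np.array([1 if u.label == "depressed" else 0 for u, _ in pairs])
    y_pred = (1.0 / (1.0 + np.exp(-logits)) >= threshold).astype(int)
    return compute_metrics(y_true, y_pred)


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -1.0


def train(model, corpus: Corpus, views: dict[str, SampledView],
          config: TrainConfig) -> TrainLog:
    """Minimize BCE on the train split; keep the best-validation checkpoint.

    Deterministic given ``config.seed`` (seeded shuffling, seeded dropout).
    ``max_epochs == 0`` leaves the model parameters untouched.
    """
    rng = np.random.default_rng(config.seed)
    train_pairs = _pairs_for_split(corpus, views, "train")
    val_pairs = _pairs_for_split(corpus, views, "validation")
    params = model.parameters()
    opt = (nn.Adam(params, lr=config.learning_rate)
           if config.optimizer == "adam" else nn.SGD(params, lr=config.learning_rate))
    log = TrainLog()
    best_state: list[np.ndarray] | None = None
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_pairs))
        model.set_train(int(rng.integers(2**31)) if config.dropout_in_train else None)
        epoch_loss, n_batches = 0.0, 0
        t0 = time.perf_counter()
        for start in range(0, len(order), config.batch_size):
            batch_pairs = [train_pairs[i] for i in order[start:start + config.batch_size]]
            batch = model.prepare_batch(batch_pairs)
            logits = model.forward(batch)
            loss = nn.bce_with_logits(logits, batch["labels"])
            if not math.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        val_logits = _predict_logits(model, val_pairs)
        y_true = np.array([1 if u.label == "depressed" else 0 for u, _ in val_pairs])
        val = compute_metrics(y_true, (val_logits >= 0.0).astype(int))
        log.epochs.append({"epoch": epoch,
                           "train_loss": epoch_loss / max(n_batches, 1),
                           "val_accuracy": val.accuracy,
                           "val_macro_f1": val.macro_f1,
                           "seconds": time.perf_counter() - t0})
        if val.macro_f1 > log.best_val_f1:
            log.best_val_f1 = val.macro_f1
            log.best_epoch = epoch
            best_state = [p.data.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data = saved
    model.set_train(None)
    return log


def run_grid(corpus: Corpus, lexicon: Lexicon, model_factory,
             strategies=("none", "random", "retrieval"),
             rates=(0.5,), seeds=(0,),
             train_config: TrainConfig | None = None,
             csv_path: str | None = None) -> pd.DataFrame:
    """One row of test metrics per (strategy, rate, encoder-model, seed).

    ``model_factory(seed)`` must return a fresh untrained model exposing the
    shared interface.  Strategy ``none`` ignores the rate (one row per
    seed).  Cell failures are recorded (``error`` column) and the grid
    continues.
    """
    base_cfg = train_config or TrainConfig()
    rows = []
    for strategy in strategies:
        strat_rates = [1.0] if strategy == "none" else list(rates)
        for rate in strat_rates:
            for seed in seeds:
                row = {"strategy": strategy, "rate": rate, "seed": seed}
                try:
                    views = sample_corpus(corpus, strategy, rate=rate,
                                          lexicon=lexicon, seed=seed)
                    model = model_factory(seed)
                    cfg = replace(base_cfg, seed=seed)
                    train(model, corpus, views, cfg)
                    report = evaluate(model, corpus, views, "test")
                    row.update(accuracy=report.accuracy,
                               macro_p=report.macro_precision,
                               macro_r=report.macro_recall,
                               macro_f1=report.macro_f1, error="")
                except Exception as exc:  # keep sweeping, record the failure
                    row.update(accuracy=np.nan, macro_p=np.nan, macro_r=np.nan,
                               macro_f1=np.nan, error=f"{type(exc).__name__}: {exc}")
                rows.append(row)
    frame = pd.DataFrame(rows)
    if csv_path:
        frame.to_csv(csv_path, index=False)
    return frame


def summarize_grid(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each metric over seeds, per (strategy, rate)."""
    ok = frame[frame["error"] == ""]
    return (ok.groupby(["strategy", "rate"])
              .agg(macro_f1_mean=("macro_f1", "mean"),
                   macro_f1_sd=("macro_f1", "std"),
                   accuracy_mean=("accuracy", "mean"),
                   n=("seed", "count"))
              .reset_index())
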