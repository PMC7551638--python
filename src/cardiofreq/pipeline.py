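"""End-to-end experiment orchestration on synthetic ECG data.

Replicates the study design at its stated scale: 400 training and 100
evaluation streams per class (1200 / 300 windows), features extracted
per 256-sample window after validity filtering, a [8, 9, 9, 9, 3]
sigmoid MLP trained by per-sample gradient descent at learning rate
0.02 for 45 epochs, and confusion-matrix / F-measure / ROC evaluation
on the held-out streams.  Every random choice derives from one master
seed, so a full report is reproducible byte for byte.

The original recordings behind the study were never deposited;
replication here is defined over the seeded synthetic generator, which
is stated prominently in every report header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cardiofreq.signal_io import DEFAULT_WINDOW_LEN, frame_windows, validity_filter
from cardiofreq.synthetic_ecg import CLASS_LABELS, LabeledStream, generate_dataset
from cardiofreq.spectral_features import N_SECTIONS, extract_features_batch
from cardiofreq.neural_net import (
    DEFAULT_LAYER_SIZES,
    MlpModel,
    TrainConfig,
    TrainHistory,
    forward,
    init_network,
    train,
)
from cardiofreq.evaluation import (
    ConfusionMatrix,
    Metrics,
    RocCurve,
    compute_metrics,
    confusion,
    roc_one_vs_rest,
)

#: offset separating the evaluation streams' seed block from training's
_EVAL_SEED_OFFSET = 1_000_000


@dataclass(frozen=True)
class ExperimentConfig:
    """Study-scale defaults: 400/100 streams per class, alpha 0.02, 45 epochs."""

    train_per_class: int = 400
    eval_per_class: int = 100
    stream_duration_s: float = 3.0
    window_len: int = DEFAULT_WINDOW_LEN
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    train: TrainConfig = field(default_factory=TrainConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.train_per_class < 0 or self.eval_per_class < 0:
            raise ValueError("per-class counts must be >= 0")


@dataclass
class ExperimentReport:
    """Everything one replication run produced, traceable to its seeds."""

    config: ExperimentConfig
    train_history: TrainHistory
    confusion_matrix: ConfusionMatrix
    metrics: Metrics
    roc: dict[str, RocCurve]
    reduction_ratio: float
    n_train_examples: int
    n_eval_examples: int
    n_degenerate_windows: int
    n_filtered_samples: int

    def to_json(self, indent: int = 1) -> str:
        doc = {
            "note": "synthetic-data replication; original recordings are not public",
            "master_seed": self.config.master_seed,
            "config": {
                "train_per_class": self.config.train_per_class,
                "eval_per_class": self.config.eval_per_class,
                "stream_duration_s": self.config.stream_duration_s,
                "window_len": self.config.window_len,
                "layer_sizes": list(self.config.layer_sizes),
                "alpha": self.config.train.alpha,
                "epochs": self.config.train.epochs,
                "update_mode": self.config.train.update_mode,
            },
            "reduction_ratio": self.reduction_ratio,
            "n_train_examples": self.n_train_examples,
            "n_eval_examples": self.n_eval_examples,
            "n_degenerate_windows": self.n_degenerate_windows,
            "n_filtered_samples": self.n_filtered_samples,
            "train_history": {
                "mean_cost": self.train_history.mean_cost,
                "train_accuracy": self.train_history.train_accuracy,
            },
            "confusion_matrix": self.confusion_matrix.counts.tolist(),
            "metrics": {
                "accuracy": self.metrics.accuracy,
                "precision": self.metrics.precision,
                "recall": self.metrics.recall,
                "f_measure": self.metrics.f_measure,
                "macro_precision": self.metrics.macro_precision,
                "macro_recall": self.metrics.macro_recall,
                "macro_f": self.metrics.macro_f,
            },
            "roc_auc": {c: self.roc[c].auc for c in CLASS_LABELS},
        }
        return json.dumps(doc, indent=indent, sort_keys=True)


def streams_to_features(
    streams: Sequence[LabeledStream], window_len: int = DEFAULT_WINDOW_LEN
) -> tuple[pd.DataFrame, int, int]:
    """Filter, frame and featurize streams into one table.

    Returns (table, n_degenerate_windows_dropped, n_samples_filtered).
    The table has columns r1..r8, label, stream_index, window_index; one
    row per complete non-degenerate window.
    """
    sample_rows: list[np.ndarray] = []
    meta: list[tuple[str, int, int]] = []
    n_filtered = 0
    for si, ls in enumerate(streams):
        filtered, removed = validity_filter(ls.stream)
        n_filtered += removed
        for wi, w in enumerate(frame_windows(filtered, window_len)):
            sample_rows.append(w.samples)
            meta.append((ls.label, si, wi))
    if not sample_rows:
        cols = [f"r{j + 1}" for j in range(N_SECTIONS)] + ["label", "stream_index", "window_index"]
        return pd.DataFrame(columns=cols), 0, n_filtered
    ratios, degenerate = extract_features_batch(np.vstack(sample_rows))
    n_degen = int(degenerate.sum())
    keep = ~degenerate
    df = pd.DataFrame(ratios[keep], columns=[f"r{j + 1}" for j in range(N_SECTIONS)])
    kept_meta = [m for m, ok in zip(meta, keep) if ok]
    df["label"] = [m[0] for m in kept_meta]
    df["stream_index"] = [m[1] for m in kept_meta]
    df["window_index"] = [m[2] for m in kept_meta]
    return df, n_degen, n_filtered


def one_hot(labels: Sequence[str]) -> np.ndarray:
    idx = [CLASS_LABELS.index(label) for label in labels]
    out = np.zeros((len(idx), len(CLASS_LABELS)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def build_dataset(config: ExperimentConfig) -> tuple[list[LabeledStream], list[LabeledStream]]:
    """Training and held-out evaluation streams from disjoint seed blocks."""
    train_streams = generate_dataset(
        {c: config.train_per_class for c in CLASS_LABELS},
        base_seed=config.master_seed,
        duration_s=config.stream_duration_s,
    )
    eval_streams = generate_dataset(
        {c: config.eval_per_class for c in CLASS_LABELS},
        base_seed=config.master_seed + _EVAL_SEED_OFFSET,
        duration_s=config.stream_duration_s,
    )
    return train_streams, eval_streams


def evaluate_model(
    model: MlpModel, features: np.ndarray, labels: Sequence[str], strict: bool = True
) -> tuple[ConfusionMatrix, Metrics, dict[str, RocCurve], np.ndarray]:
    """Predict every example and compute confusion, metrics and per-class ROC."""
    scores = np.vstack([forward(model, x)[0] for x in np.asarray(features, dtype=float)])
    predicted = [CLASS_LABELS[i] for i in scores.argmax(axis=1)]
    cm = confusion(list(labels), predicted)
    metrics = compute_metrics(cm, strict=strict)
    roc = {c: roc_one_vs_rest(scores, list(labels), c) for c in CLASS_LABELS}
    return cm, metrics, roc, scores


def run_experiment(config: ExperimentConfig = ExperimentConfig()) -> ExperimentReport:
    """simulate -> filter -> window -> extract -> train -> evaluate."""
    train_streams, eval_streams = build_dataset(config)
    train_df, degen_train, filt_train = streams_to_features(train_streams, config.window_len)
    eval_df, degen_eval, filt_eval = streams_to_features(eval_streams, config.window_len)

    feat_cols = [f"r{j + 1}" for j in range(N_SECTIONS)]
    X_train = train_df[feat_cols].to_numpy()
    Y_train = one_hot(train_df["label"].tolist())

    model = init_network(config.layer_sizes, seed=config.master_seed)
    train_cfg = TrainConfig(
        alpha=config.train.alpha,
        epochs=config.train.epochs,
        shuffle_seed=config.master_seed,
        update_mode=config.train.update_mode,
    )
    model, history = train(model, X_train, Y_train, train_cfg)

    X_eval = eval_df[feat_cols].to_numpy()
    cm, metrics, roc, _ = evaluate_model(model, X_eval, eval_df["label"].tolist())

    return ExperimentReport(
        config=config,
        train_history=history,
        confusion_matrix=cm,
        metrics=metrics,
        roc=roc,
        reduction_ratio=config.window_len / N_SECTIONS,
        n_train_examples=int(X_train.shape[0]),
        n_eval_examples=int(X_eval.shape[0]),
        n_degenerate_windows=degen_train + degen_eval,
        n_filtered_samples=filt_train + filt_eval,
    )


def run_sweep(
    config: ExperimentConfig = ExperimentConfig(),
    learning_rates: Sequence[float] = (0.005, 0.01, 0.02),
    epoch_checkpoints: Sequence[int] = tuple(range(5, 55, 5)),
) -> pd.DataFrame:
    """Learning-rate x epoch grid: evaluation accuracy at each checkpoint.

    For each rate one model is trained incrementally and evaluated at
    every checkpoint, tracing an accuracy-versus-epochs curve per rate.
    """
    train_streams, eval_streams = build_dataset(config)
    train_df, _, _ = streams_to_features(train_streams, config.window_len)
    eval_df, _, _ = streams_to_features(eval_streams, config.window_len)
    feat_cols = [f"r{j + 1}" for j in range(N_SECTIONS)]
    X_train = train_df[feat_cols].to_numpy()
    Y_train = one_hot(train_df["label"].tolist())
    X_eval = eval_df[feat_cols].to_numpy()
    eval_labels = eval_df["label"].tolist()

    checkpoints = sorted(set(int(e) for e in epoch_checkpoints))
    rows = []
    for rate in learning_rates:
        model = init_network(config.layer_sizes, seed=config.master_seed)
        done = 0
        for cp in checkpoints:
            step = TrainConfig(
                alpha=rate, epochs=cp - done, shuffle_seed=config.master_seed + done,
                update_mode=config.train.update_mode,
            )
            model, _ = train(model, X_train, Y_train, step)
            done = cp
            cm, metrics, _, _ = evaluate_model(model, X_eval, eval_labels, strict=False)
            rows.append(
                {
                    "learning_rate": rate,
                    "epochs": cp,
                    "accuracy": metrics.accuracy,
                    "macro_recall": metrics.macro_recall,
                    "macro_f": metrics.macro_f,
                }
            )
    return pd.DataFrame(rows)
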