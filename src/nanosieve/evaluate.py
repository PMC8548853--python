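"""Batch inference over read sets and the binary classification metric suite.

Metrics follow the standard confusion-matrix definitions with a
configurable positive class (the enrichment target), and AUROC is the
Mann-Whitney rank statistic: the probability that a random positive read
outscores a random negative one, ties counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from nanosieve.errors import ValidationError
from nanosieve.model import Network
from nanosieve.preprocess import preprocess_batch, DEFAULT_SKIP_INFER, DEFAULT_WINDOW
from nanosieve.signal_io import Squiggle

__all__ = ["Prediction", "Metrics", "classify_reads", "compute_metrics",
           "accuracy_by_group", "auroc", "predictions_frame"]


@dataclass
class Prediction:
    read_id: str
    probabilities: np.ndarray
    predicted: int
    truth: int | None = None


@dataclass
class Metrics:
    """Confusion counts and derived rates; undefined rates are NaN."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    tpr: float
    tnr: float
    precision: float
    auroc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def classify_reads(network: Network, squiggles: list[Squiggle],
                   skip: int = DEFAULT_SKIP_INFER, length: int = DEFAULT_WINDOW,
                   batch_size: int = 512
                   ) -> tuple[list[Prediction], list[tuple[str, str]]]:
    """Preprocess and classify reads; ties go to the lower class index.

    Returns (predictions, exclusions); excluded reads carry the reason
    (too short, degenerate signal).  Raises if nothing is classifiable.
    """
    windows, excluded = preprocess_batch(squiggles, skip=skip, length=length)
    if not windows:
        raise ValidationError(
            f"no classifiable reads: all {len(excluded)} excluded")
    labels = {sq.read_id: sq.label for sq in squiggles}
    X = np.stack([w.values for w in windows]).astype(np.float32)
    preds: list[Prediction] = []
    for start in range(0, len(X), batch_size):
        probs = network.forward(X[start:start + batch_size], training=False)
        for w, p in zip(windows[start:start + batch_size], probs):
            preds.append(Prediction(read_id=w.read_id, probabilities=p,
                                    predicted=int(np.argmax(p)),
                                    truth=labels.get(w.read_id)))
    return preds, excluded


def auroc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-statistic AUROC: P(positive score > negative score), ties = 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        return math.nan
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def compute_metrics(predictions: list[Prediction], positive_class: int = 1
                    ) -> Metrics:
    """Confusion counts, accuracy/TPR/TNR/precision and AUROC.

    Every prediction must carry a true label.  Rates whose denominator is
    empty (a class absent from the truth) come back as NaN rather than 0.
    """
    if any(p.truth is None for p in predictions):
        missing = [p.read_id for p in predictions if p.truth is None]
        raise ValidationError(f"predictions without truth labels: {missing[:5]}")
    truth = np.array([p.truth == positive_class for p in predictions])
    called = np.array([p.predicted == positive_class for p in predictions])
    scores = np.array([p.probabilities[positive_class] for p in predictions])

    tp = int(np.sum(truth & called))
    fp = int(np.sum(~truth & called))
    tn = int(np.sum(~truth & ~called))
    fn = int(np.sum(truth & ~called))
    total = tp + fp + tn + fn

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return Metrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_ratio(tp + tn, total),
        tpr=_ratio(tp, tp + fn),
        tnr=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        auroc=auroc(scores[truth], scores[~truth]),
    )


def accuracy_by_group(predictions: list[Prediction],
                      grouping: dict[str, str]) -> pd.DataFrame:
    """Per-group accuracy breakdown (e.g. per species), sorted by group label."""
    unmapped = [p.read_id for p in predictions if p.read_id not in grouping]
    if unmapped:
        raise ValidationError(f"read_ids without a group: {unmapped[:10]}")
    df = pd.DataFrame({
        "group": [grouping[p.read_id] for p in predictions],
        "correct": [p.predicted == p.truth for p in predictions],
    })
    out = (df.groupby("group")["correct"].agg(n="size", accuracy="mean")
           .reset_index().sort_values("group").reset_index(drop=True))
    return out


def predictions_frame(predictions: list[Prediction]) -> pd.DataFrame:
    """Long-format table: read_id, per-class probabilities, pred, truth."""
    n_classes = predictions[0].probabilities.size if predictions else 0
    data = {"read_id": [p.read_id for p in predictions]}
    for c in range(n_classes):
        data[f"p_class{c}"] = [float(p.probabilities[c]) for p in predictions]
    data["pred"] = [p.predicted for p in predictions]
    data["truth"] = [p.truth for p in predictions]
    return pd.DataFrame(data)
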