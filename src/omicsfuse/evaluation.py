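"""Endpoint metrics: classification scores, Harrell's C-index, and the
paired-latent Euclidean-distance consensus analysis.

The concordance index is authored here from its defining probability —
over ordered pairs (i, j) with ``T_i < T_j`` and sample i an observed
event, the fraction where the earlier-failing sample received the higher
hazard, with ties in hazard counting 1/2 (Harrell's convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_score, recall_score

__all__ = [
    "classification_metrics", "concordance_index",
    "paired_hidden_distance", "MetricsReport",
]


def classification_metrics(y_pred, y_true) -> tuple[float, float, float]:
    """(accuracy, weighted precision, weighted recall).

    Precision/recall are per-class values averaged with weights equal to
    each class's true support; a class absent from the predictions
    contributes precision 0 at its support weight.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.size == 0 or y_pred.shape != y_true.shape:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    acc = accuracy_score(y_true, y_pred)
    prec = precision_score(y_true, y_pred, average="weighted", zero_division=0)
    rec = recall_score(y_true, y_pred, average="weighted", zero_division=0)
    return float(acc), float(prec), float(rec)


def concordance_index(h, times, events) -> float:
    """Harrell's concordance index for right-censored survival data.

    ``h`` is the predicted log relative hazard (higher = earlier expected
    failure). Comparable pairs are ordered pairs (i, j) with
    ``T_i < T_j`` and ``event_i == 1``; each contributes 1 if
    ``h_i > h_j``, 1/2 if tied, else 0.
    """
    h = np.asarray(h, dtype=np.float64).reshape(-1)
    times = np.asarray(times, dtype=np.float64).reshape(-1)
    events = np.asarray(events).reshape(-1).astype(int)
    if not (h.shape == times.shape == events.shape):
        raise ValueError("h, times and events must have equal lengths")
    # pair (i, j) comparable iff T_i < T_j and C_i = 1
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs: concordance index undefined")
    hi = h[:, None]
    hj = h[None, :]
    score = np.where(hi > hj, 1.0, np.where(hi == hj, 0.5, 0.0))
    return float((score * comparable).sum() / n_pairs)


def paired_hidden_distance(z_a: np.ndarray, z_b: np.ndarray
                           ) -> tuple[np.ndarray, dict]:
    """Per-sample Euclidean distance between paired hidden features.

    Returns the distance vector and a summary dict (mean, std and
    quartiles) suitable for violin/bar-style reporting of cross-modality
    consensus.
    """
    z_a = np.atleast_2d(np.asarray(z_a, dtype=np.float64))
    z_b = np.atleast_2d(np.asarray(z_b, dtype=np.float64))
    if z_a.shape != z_b.shape:
        raise ValueError("paired latents must have identical shapes")
    d = np.linalg.norm(z_a - z_b, axis=1)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    summary = {"mean": float(d.mean()), "std": float(d.std()),
               "q1": float(q1), "median": float(med), "q3": float(q3)}
    return d, summary


@dataclass
class MetricsReport:
    """Per-fold metric values with the mean ± std reporting convention."""

    metric_name: str
    endpoint: str
    fold_values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_values))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_values))

    def __str__(self) -> str:
        return f"{round(self.mean, 3)} ± {round(self.std, 3)}"

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"fold": i, "metric": self.metric_name,
                 "endpoint": self.endpoint, "value": v}
                for i, v in enumerate(self.fold_values)]
        return pd.DataFrame(rows)
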