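"""Per-item classification metric suite (accuracy / precision / recall /
F1 / ROC-AUC, one-vs-rest)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from ..errors import ConfigError
from .items import ITEM_CODES
from .training import DiagnosisResult


@dataclass(frozen=True)
class MetricReport:
    per_item: dict  # item -> {accuracy, precision, recall, f1, roc_auc}

    def macro(self, metric: str) -> float:
        vals = [m[metric] for m in self.per_item.values() if m[metric] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def as_dict(self) -> dict:
        return {item: dict(m) for item, m in self.per_item.items()}


def _coerce(results, truth, items):
    if len(results) != len(truth):
        raise ConfigError("results and truth must cover the same recordings")
    if results and isinstance(results[0], DiagnosisResult):
        probs = np.asarray(
            [[r.probabilities[i] for i in items] for r in results]
        )
        thr = results[0].threshold
    else:
        probs = np.asarray(results, dtype=float)
        thr = 0.5
    if truth and isinstance(truth[0], (set, frozenset, list, tuple)):
        y = np.asarray([[1.0 if i in t else 0.0 for i in items] for t in truth])
    else:
        y = np.asarray(truth, dtype=float)
    if probs.shape != y.shape:
        raise ConfigError(f"shape mismatch: probs {probs.shape} vs truth {y.shape}")
    return probs, y, thr


def evaluate(results, truth, items=None, threshold: float | None = None) -> MetricReport:
    """Compute the per-item metric suite.

    ``results`` is a list of :class:`DiagnosisResult` or an (n, k)
    probability array; ``truth`` a list of item sets or an (n, k) binary
    array.  ROC-AUC is reported as ``None`` for items whose truth column is
    single-class (undefined).
    """
    if items is None:
        items = list(ITEM_CODES)
    probs, y, thr = _coerce(list(results), list(truth), items)
    if threshold is not None:
        thr = threshold
    calls = probs >= thr

    per_item = {}
    for j, item in enumerate(items):
        yj, cj, pj = y[:, j], calls[:, j], probs[:, j]
        tp = float(np.sum(cj & (yj == 1)))
        tn = float(np.sum(~cj & (yj == 0)))
        fp = float(np.sum(cj & (yj == 0)))
        fn = float(np.sum(~cj & (yj == 1)))
        accuracy = (tp + tn) / len(yj)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        if 0 < yj.sum() < len(yj):
            auc = float(roc_auc_score(yj, pj))
        else:
            auc = None
        per_item[item] = {
            "accuracy": accuracy,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "roc_auc": auc,
        }
    return MetricReport(per_item=per_item)
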