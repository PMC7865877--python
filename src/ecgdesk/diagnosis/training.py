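"""Training and inference for the diagnosis / reverse-lead networks."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError, UnknownItemError
from ..records import ECGRecord
from . import nn
from .items import ITEM_CODES
from .network import ECGNet, segment_recording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16


@dataclass(frozen=True)
class DiagnosisResult:
    """Per-item probabilities and threshold calls for one recording."""

    probabilities: dict
    calls: dict
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "probabilities": {k: float(v) for k, v in self.probabilities.items()},
            "calls": {k: bool(v) for k, v in self.calls.items()},
            "threshold": self.threshold,
        }


def labels_to_vector(labels, n_classes: int) -> np.ndarray:
    """Encode a label set (item codes, or 0/1 for the reverse-lead task)."""
    y = np.zeros(n_classes)
    if n_classes == 1:
        if labels in (0, 1, True, False):
            y[0] = float(labels)
            return y
        raise ConfigError(f"reverse-lead label must be 0 or 1, got {labels!r}")
    for code in labels:
        if code not in ITEM_CODES:
            raise UnknownItemError(f"unknown diagnosis item {code!r}")
        y[ITEM_CODES.index(code)] = 1.0
    return y


def _to_segments(network: ECGNet, record) -> np.ndarray:
    if isinstance(record, ECGRecord):
        return segment_recording(record, network.config)
    x = np.asarray(record, dtype=np.float64)
    if x.ndim == 1:
        return segment_recording(
            ECGRecord(samples=x, provenance=frozenset({"raw"})), network.config
        )
    return x


def train(
    network: ECGNet,
    dataset,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> list[float]:
    """Train in place with Adam on mean per-class binary cross-entropy.

    ``dataset`` is a sequence of ``(record, labels)`` pairs where ``record``
    is an :class:`ECGRecord` or a 1-D sample array and ``labels`` is a set
    of item codes (or 0/1 for the reverse-lead variant).  Batches group
    recordings with equal segment counts.  Returns the per-epoch mean loss
    trace; fully deterministic for a given (network seed, ``seed``) pair.
    """
    config = config or TrainConfig()
    dataset = list(dataset)
    if not dataset:
        raise ConfigError("training dataset is empty")

    n_classes = network.config.n_classes
    X = [_to_segments(network, rec) for rec, _ in dataset]
    Y = np.stack([labels_to_vector(labels, n_classes) for _, labels in dataset])

    rng = np.random.default_rng(seed)
    network.seed_dropout(rng)
    opt = nn.Adam(network.params(), lr=config.learning_rate)

    order0 = np.arange(len(dataset))
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(order0)
        # Group shuffled indices by segment count so each batch is rectangular.
        by_len: dict[int, list[int]] = {}
        for i in order:
            by_len.setdefault(X[i].shape[0], []).append(i)
        batches = []
        for idxs in by_len.values():
            for j in range(0, len(idxs), config.batch_size):
                batches.append(idxs[j : j + config.batch_size])

        total, count = 0.0, 0
        for batch in batches:
            xb = np.stack([X[i] for i in batch])
            yb = Y[batch]
            opt.zero_grad()
            probs = network.forward(xb, train=True)
            loss, dlogits = nn.bce_loss_and_grad(probs, yb)
            network.backward(dlogits)
            opt.step()
            total += loss * len(batch)
            count += len(batch)
        trace.append(total / count)
    network.trained = True
    return trace


def predict(
    network: ECGNet, record, threshold: float = 0.5
) -> DiagnosisResult:
    """Run inference on one recording; calls use probability >= threshold."""
    if not network.trained:
        warnings.warn("network has not been trained; outputs are untrained",
                      stacklevel=2)
    segs = _to_segments(network, record)
    probs = network.forward(segs[None, :, :], train=False)[0]
    if network.config.n_classes == 1:
        keys = ["reversed"]
    else:
        keys = list(ITEM_CODES)
    prob_map = {k: float(p) for k, p in zip(keys, probs)}
    calls = {k: bool(p >= threshold) for k, p in prob_map.items()}
    return DiagnosisResult(probabilities=prob_map, calls=calls, threshold=threshold)


def predict_proba(network: ECGNet, records) -> np.ndarray:
    """Probabilities for many recordings, shape (n_records, n_classes)."""
    out = []
    for rec in records:
        segs = _to_segments(network, rec)
        out.append(network.forward(segs[None, :, :], train=False)[0])
    return np.asarray(out)
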