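"""The hybrid residual CNN-RNN multilabel diagnosis network.

A long recording is split into fixed-length segments; each segment passes
through 32 stacked 1-D convolutional layers (8 stages of 4, kernel size 16,
weights shared across segments).  Every two convolutions form a
pre-activation residual block; the first convolution of each stage halves
the temporal length while its shortcut max-pools by 2, and the filter count
doubles every two stages.  Global average pooling yields one embedding per
segment, a recurrent (GRU) layer consumes the segment sequence, and a dense
head produces one per-class probability through a sigmoid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..errors import ConfigError
from ..records import ECGRecord
from . import nn
from .items import ITEM_CODES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    n_stages: int = 8
    convs_per_stage: int = 4
    kernel_size: int = 16
    base_filters: int = 32
    segment_length: int = 1280
    dropout_rate: float = 0.2
    recurrent_hidden: int = 64
    n_classes: int = 20
    rnn_output: str = "last"  # "last" or "mean"

    def validate(self) -> None:
        if self.n_stages * self.convs_per_stage != 32:
            raise ConfigError("n_stages x convs_per_stage must equal 32")
        if self.convs_per_stage % 2:
            raise ConfigError("convs_per_stage must be even (residual pairs)")
        if self.segment_length % (2**self.n_stages):
            raise ConfigError(
                f"segment_length must be divisible by {2**self.n_stages}"
            )
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.rnn_output not in ("last", "mean"):
            raise ConfigError("rnn_output must be 'last' or 'mean'")

    def filters_for_stage(self, stage: int) -> int:
        return self.base_filters * 2 ** (stage // 2)


def segment_recording(record: ECGRecord, config: NetworkConfig) -> np.ndarray:
    """Split a record into consecutive ``segment_length`` windows.

    Returns an ``(n_segments, segment_length)`` array; the final partial
    segment is zero-padded.  A record shorter than one segment yields a
    single zero-padded segment with a logged warning.
    """
    x = record.samples
    seg_len = config.segment_length
    n_segments = max(1, int(np.ceil(x.size / seg_len)))
    if x.size < seg_len:
        log.warning(
            "record %r (%d samples) shorter than one segment (%d); zero-padding",
            record.record_id, x.size, seg_len,
        )
    out = np.zeros((n_segments, seg_len))
    flat = out.reshape(-1)
    flat[: x.size] = x
    return out


class _ResidualBlock:
    """Two pre-activation convolutions plus a shortcut.

    The shortcut max-pools when the block downsamples and zero-pads the
    channel axis when the filter count grows, so the only convolutional
    layers in the network are the 32 kernel-16 main-path ones.
    """

    def __init__(self, in_c, out_c, stride, config: NetworkConfig, rng, first=False):
        k = config.kernel_size
        self.first = first
        self.stride = stride
        if not first:
            self.bn1 = nn.BatchNorm1d(in_c)
            self.relu1 = nn.ReLU()
            self.drop1 = nn.Dropout(config.dropout_rate)
        self.conv1 = nn.Conv1d(in_c, out_c, k, stride=stride, rng=rng)
        self.bn2 = nn.BatchNorm1d(out_c)
        self.relu2 = nn.ReLU()
        self.drop2 = nn.Dropout(config.dropout_rate)
        self.conv2 = nn.Conv1d(out_c, out_c, k, stride=1, rng=rng)
        self.pool = nn.MaxPool1d() if stride == 2 else None
        self.pad = nn.ChannelPad(out_c - in_c) if out_c != in_c else None

    def layers(self):
        out = []
        if not self.first:
            out += [self.bn1, self.relu1, self.drop1]
        out += [self.conv1, self.bn2, self.relu2, self.drop2, self.conv2]
        return out

    def params(self):
        return [p for layer in self.layers() for p in layer.params()]

    def forward(self, x, train=False):
        h = x
        if not self.first:
            h = self.drop1.forward(self.relu1.forward(self.bn1.forward(h, train)),
                                   train)
        h = self.conv1.forward(h, train)
        h = self.drop2.forward(self.relu2.forward(self.bn2.forward(h, train)), train)
        h = self.conv2.forward(h, train)
        sc = x
        if self.pool is not None:
            sc = self.pool.forward(sc, train)
        if self.pad is not None:
            sc = self.pad.forward(sc, train)
        return h + sc

    def backward(self, gy):
        gsc = gy
        if self.pad is not None:
            gsc = self.pad.backward(gsc)
        if self.pool is not None:
            gsc = self.pool.backward(gsc)
        g = self.conv2.backward(gy)
        g = self.bn2.backward(self.relu2.backward(self.drop2.backward(g)))
        g = self.conv1.backward(g)
        if not self.first:
            g = self.bn1.backward(self.relu1.backward(self.drop1.backward(g)))
        return g + gsc


class ECGNet:
    """Instantiated network; see module docstring for the architecture."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.trained = False
        rng = np.random.default_rng(seed)

        self.blocks: list[_ResidualBlock] = []
        in_c = 1
        blocks_per_stage = config.convs_per_stage // 2
        for stage in range(config.n_stages):
            out_c = config.filters_for_stage(stage)
            for block_i in range(blocks_per_stage):
                stride = 2 if block_i == 0 else 1
                first = stage == 0 and block_i == 0
                self.blocks.append(
                    _ResidualBlock(in_c, out_c, stride, config, rng, first=first)
                )
                in_c = out_c
        self.final_bn = nn.BatchNorm1d(in_c)
        self.final_relu = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.gru = nn.GRU(in_c, config.recurrent_hidden, rng=rng)
        self.head = nn.Dense(config.recurrent_hidden, config.n_classes, rng=rng)
        self.seed_dropout(np.random.default_rng(seed + 1))

    # -- introspection -----------------------------------------------------
    def conv_layers(self) -> list:
        """All 1-D convolutional layers of the backbone, in forward order."""
        return [
            layer
            for block in self.blocks
            for layer in (block.conv1, block.conv2)
        ]

    def params(self):
        out = []
        for block in self.blocks:
            out += block.params()
        out += self.final_bn.params() + self.gru.params() + self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def seed_dropout(self, rng: np.random.Generator):
        drops = [
            d
            for block in self.blocks
            for d in ([block.drop2] if block.first else [block.drop1, block.drop2])
        ]
        seeds = rng.integers(0, 2**31, size=len(drops))
        for d, s in zip(drops, seeds):
            d.rng = np.random.default_rng(int(s))

    # -- forward / backward ------------------------------------------------
    def forward(self, segments: np.ndarray, train: bool = False) -> np.ndarray:
        """``segments``: (batch, n_segments, segment_length) -> (batch, n_classes)
        per-class probabilities in [0, 1]."""
        n, s, length = segments.shape
        if length != self.config.segment_length:
            raise ConfigError(
                f"segments of length {length}, expected {self.config.segment_length}"
            )
        h = segments.reshape(n * s, 1, length)
        for block in self.blocks:
            h = block.forward(h, train)
        h = self.final_relu.forward(self.final_bn.forward(h, train), train)
        h = self.gap.forward(h, train)  # (n*s, channels)
        h = h.reshape(n, s, -1)
        h = self.gru.forward(h, train)  # (n, hidden) final state
        logits = self.head.forward(h, train)
        self._shape = (n, s)
        probs = nn.sigmoid(logits)
        return probs

    def backward(self, dlogits: np.ndarray) -> None:
        n, s = self._shape
        g = self.head.backward(dlogits)
        g = self.gru.backward(g)
        g = g.reshape(n * s, -1)
        g = self.gap.backward(g)
        g = self.final_bn.backward(self.final_relu.backward(g))
        for block in reversed(self.blocks):
            g = block.backward(g)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i}"] = p.value
        bns = [b.bn1 for b in self.blocks if not b.first]
        bns += [b.bn2 for b in self.blocks] + [self.final_bn]
        for i, bn in enumerate(bns):
            state[f"bn_mean_{i}"] = bn.running_mean
            state[f"bn_var_{i}"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.asarray(state[f"param_{i}"], dtype=np.float64)
        bns = [b.bn1 for b in self.blocks if not b.first]
        bns += [b.bn2 for b in self.blocks] + [self.final_bn]
        for i, bn in enumerate(bns):
            bn.running_mean = np.asarray(state[f"bn_mean_{i}"])
            bn.running_var = np.asarray(state[f"bn_var_{i}"])

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        sidecar = asdict(self.config)
        sidecar["trained"] = self.trained
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "ECGNet":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        trained = sidecar.pop("trained", False)
        net = cls(NetworkConfig(**sidecar))
        with np.load(path.with_suffix(".npz")) as state:
            net.load_state_arrays(dict(state))
        net.trained = trained
        return net


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> ECGNet:
    """Build the 20-class multilabel diagnosis network."""
    config = config or NetworkConfig()
    if config.n_classes != len(ITEM_CODES):
        raise ConfigError(
            f"diagnosis network needs {len(ITEM_CODES)} classes, "
            f"got {config.n_classes}"
        )
    return ECGNet(config, seed=seed)


def build_reverse_lead_network(
    config: NetworkConfig | None = None, seed: int = 0
) -> ECGNet:
    """Build the binary reverse-lead variant (single sigmoid output;
    label convention: 1 = reversed, 0 = correct)."""
    if config is None:
        config = NetworkConfig(n_classes=1)
    if config.n_classes != 1:
        raise ConfigError("reverse-lead network needs n_classes = 1")
    return ECGNet(config, seed=seed)
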