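"""Window-classifier architecture: four conv blocks, BiLSTM, dense head."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (DTYPE, AvgPool1D, BatchNorm1D, BiLSTM, Conv1D, Dense,
                     Dropout, LeakyReLU, sigmoid)

__all__ = ["ConvBlockSpec", "ModelSpec", "EventClassifier",
           "build_classifier", "count_parameters"]


@dataclass(frozen=True)
class ConvBlockSpec:
    filters: int
    kernel_size: int
    pool_size: int | None = None  # None -> no pooling layer in this block


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the event classifier.

    Defaults give successive feature-map lengths 600 -> 200 -> 100 -> 50
    and a scalar sigmoid output per window.
    """

    window_len: int = 600
    conv_blocks: tuple = field(default_factory=lambda: (
        ConvBlockSpec(32, 9, 3),
        ConvBlockSpec(48, 7, 2),
        ConvBlockSpec(64, 5, 2),
        ConvBlockSpec(80, 3, None),
    ))
    leaky_alpha: float = 0.3
    lstm_units: int = 96
    lstm_dropout: float = 0.2
    dense_units: int = 128
    dense_dropout: float = 0.2

    def validate(self) -> None:
        length = self.window_len
        for i, blk in enumerate(self.conv_blocks):
            if blk.pool_size:
                if length % blk.pool_size:
                    raise ValueError(
                        f"feature length {length} at conv block {i + 1} is not "
                        f"divisible by pool size {blk.pool_size}; adjust "
                        f"window_len")
                length //= blk.pool_size


class EventClassifier:
    """CNN-BiLSTM binary classifier over fixed-length scaled windows.

    The forward pass maps a (batch, window_len) array to per-window
    event probabilities in [0, 1].
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.conv_block_layers: list = []  # feature-extractor layers
        layers = []
        in_ch = 1
        for i, blk in enumerate(spec.conv_blocks, start=1):
            conv = Conv1D(in_ch, blk.filters, blk.kernel_size, rng,
                          name=f"conv{i}")
            bn = BatchNorm1D(blk.filters, name=f"bn{i}")
            block = [conv, bn, LeakyReLU(spec.leaky_alpha)]
            if blk.pool_size:
                block.append(AvgPool1D(blk.pool_size))
            layers.extend(block)
            self.conv_block_layers.extend([conv, bn])
            in_ch = blk.filters

        self.lstm = BiLSTM(in_ch, spec.lstm_units, spec.lstm_dropout, rng)
        self.dense1 = Dense(spec.lstm_units, spec.dense_units, rng, "dense1")
        self.head_act = LeakyReLU(spec.leaky_alpha)
        self.head_dropout = Dropout(spec.dense_dropout)
        self.dense2 = Dense(spec.dense_units, 1, rng, "dense_out")
        layers.extend([self.lstm, self.dense1, self.head_act,
                       self.head_dropout, self.dense2])
        self.layers = layers
        self.history: dict = {}
        self.provenance: dict = {"seed": seed}

    # ------------------------------------------------------------------
    @property
    def window_len(self) -> int:
        return self.spec.window_len

    def parameters(self) -> list:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def conv_parameters(self) -> list:
        out = []
        for layer in self.conv_block_layers:
            out.extend(layer.params)
        return out

    def freeze_conv_blocks(self) -> None:
        """Exclude all conv-block tensors (conv + batch-norm) from training."""
        for layer in self.conv_block_layers:
            for p in layer.params:
                p.trainable = False
            if isinstance(layer, BatchNorm1D):
                layer.frozen = True

    def get_weights(self) -> list:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match model parameters")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value = np.asarray(w, dtype=DTYPE).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # ------------------------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.window_len:
            raise ValueError(
                f"expected input of shape (batch, {self.window_len}); "
                f"got {x.shape}; resample windows to the model window length")
        h = np.asarray(x, dtype=DTYPE)[:, :, None]
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
        return h[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dy = np.asarray(dlogits, dtype=DTYPE)[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Inference-mode probabilities for a (batch, window_len) array."""
        x = np.asarray(x, dtype=DTYPE)
        out = np.empty(x.shape[0], dtype=np.float64)
        for start in range(0, x.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            out[sl] = sigmoid(self.forward_logits(x[sl]))
        return out


def build_classifier(spec: ModelSpec | None = None, seed: int = 0
                     ) -> EventClassifier:
    """Instantiate an untrained classifier with seeded initialization."""
    return EventClassifier(spec or ModelSpec(), seed=seed)


def count_parameters(model: EventClassifier, trainable_only: bool = True
                     ) -> int:
    """Count model parameters.

    With ``trainable_only`` the batch-norm moving statistics (and any
    frozen tensors) are excluded.
    """
    return sum(p.size for p in model.parameters()
               if p.trainable or not trainable_only)
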