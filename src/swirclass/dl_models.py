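"""Classifier architectures for 1-D reflectance spectra.

Four deep architectures are provided:

* ``cnn``        -- a modified 1-D AlexNet: five valid convolutions
  (64/11/4, 64/5/1, 92/3/1, 92/3/1, 64/3/1), batch normalization before the
  first three, ReLU after each, no pooling, a single hidden fully connected
  layer with dropout 0.5, and a two-class output layer.
* ``lstm``       -- the spectrum read as an ordered sequence by a single LSTM
  layer (hidden size 10), dropout 0.3, two-class output.
* ``cnn_lstm``   -- the CNN's convolutional stack produces a sequence of
  channel vectors (one per position along the reduced spectral axis) that is
  consumed by the LSTM; dropout 0.3 on the final hidden state, then the
  output layer.
* ``alexnet1d``  / ``alexnet_lstm`` -- classical AlexNet-style references
  keeping max pooling (size 3, stride 2 after conv layers 1, 2 and 5) and two
  hidden fully connected layers.

All builders validate the convolution length chain eagerly and name the
failing layer when the input is too short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from swirclass.nn.layers import (
    LSTM,
    AddChannel,
    BatchNorm1d,
    ChannelsToSequence,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    ReLU,
    Sequential,
    _sigmoid,
    conv_output_length,
)

MODEL_KINDS = ("cnn", "lstm", "cnn_lstm", "alexnet1d", "alexnet_lstm")


@dataclass(frozen=True)
class ConvLayerSpec:
    """One 1-D convolution: channel count, window length, step."""

    filters: int
    kernel_size: int
    stride: int
    batch_norm_before: bool = False
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.filters < 1 or self.kernel_size < 1 or self.stride < 1:
            raise ValueError("filters, kernel_size and stride must be >= 1")


def default_conv_layers() -> tuple[ConvLayerSpec, ...]:
    """The five-layer convolutional stack of the modified 1-D CNN."""
    return (
        ConvLayerSpec(64, 11, 4, batch_norm_before=True),
        ConvLayerSpec(64, 5, 1, batch_norm_before=True),
        ConvLayerSpec(92, 3, 1, batch_norm_before=True),
        ConvLayerSpec(92, 3, 1, batch_norm_before=False),
        ConvLayerSpec(64, 3, 1, batch_norm_before=False),
    )


@dataclass(frozen=True)
class CNNSpec:
    """Architecture of the modified 1-D CNN classifier."""

    conv_layers: tuple[ConvLayerSpec, ...] = field(default_factory=default_conv_layers)
    fc_width: int = 128
    dropout_rate: float = 0.5
    n_classes: int = 2


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier to build, plus its recurrent hyperparameters."""

    kind: str = "cnn_lstm"
    cnn: CNNSpec = field(default_factory=CNNSpec)
    lstm_hidden: int = 10
    lstm_dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


@dataclass
class LSTMCellParams:
    """Weights of one LSTM cell over the concatenation [h_{t-1}, x_t]."""

    Wc: np.ndarray
    Wf: np.ndarray
    Wi: np.ndarray
    Wo: np.ndarray
    bc: np.ndarray
    bf: np.ndarray
    bi: np.ndarray
    bo: np.ndarray

    def __post_init__(self) -> None:
        h = self.Wc.shape[0]
        for name in ("Wc", "Wf", "Wi", "Wo"):
            W = getattr(self, name)
            if W.shape != self.Wc.shape:
                raise ValueError(f"{name} shape {W.shape} != Wc shape {self.Wc.shape}")
        for name in ("bc", "bf", "bi", "bo"):
            b = getattr(self, name)
            if b.shape != (h,):
                raise ValueError(f"{name} must have length {h}")

    @property
    def hidden_size(self) -> int:
        return self.Wc.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wc.shape[1] - self.Wc.shape[0]


@dataclass
class LSTMState:
    """Hidden activation h_t and memory cell C_t."""

    h: np.ndarray
    c: np.ndarray


def lstm_cell_step(params: LSTMCellParams, x_t: np.ndarray, prev: LSTMState) -> LSTMState:
    """One LSTM cell update.

    Candidate memory c~_t = tanh(Wc [h_{t-1}, x_t] + bc); forget, update and
    output gates are logistic sigmoids of the corresponding affine maps;
    C_t = f_t * C_{t-1} + i_t * c~_t and h_t = o_t * tanh(C_t), with *
    elementwise.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.input_size,):
        raise ValueError(f"x_t must have length {params.input_size}, got {x_t.shape}")
    if prev.h.shape != (params.hidden_size,) or prev.c.shape != (params.hidden_size,):
        raise ValueError(f"state vectors must have length {params.hidden_size}")
    z = np.concatenate([prev.h, x_t])
    c_tilde = np.tanh(params.Wc @ z + params.bc)
    f = _sigmoid(params.Wf @ z + params.bf)
    i = _sigmoid(params.Wi @ z + params.bi)
    o = _sigmoid(params.Wo @ z + params.bo)
    c = f * prev.c + i * c_tilde
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


def _conv_chain(layers, input_len: int, pools_after: frozenset[int] = frozenset(),
                pool_size: int = 3, pool_stride: int = 2) -> list[int]:
    """Lengths after each conv (and pool) layer; raises naming the failing layer."""
    lengths = []
    length = input_len
    for idx, spec in enumerate(layers, start=1):
        try:
            length = conv_output_length(length, spec.kernel_size, spec.stride)
        except ValueError:
            raise ValueError(
                f"input too short: conv layer {idx} "
                f"(kernel {spec.kernel_size}, stride {spec.stride}) "
                f"cannot consume length {length}"
            ) from None
        if idx in pools_after:
            try:
                length = conv_output_length(length, pool_size, pool_stride)
            except ValueError:
                raise ValueError(
                    f"input too short: pool after conv layer {idx} "
                    f"cannot consume length {length}"
                ) from None
        lengths.append(length)
    return lengths


def conv_stack_output_shape(spec: CNNSpec, input_len: int) -> tuple[int, int]:
    """(channels, length) emitted by the conv stack of the modified CNN."""
    lengths = _conv_chain(spec.conv_layers, input_len)
    return spec.conv_layers[-1].filters, lengths[-1]


def _conv_stack(spec: CNNSpec, input_len: int, rng: np.random.Generator,
                dtype=np.float32) -> list:
    _conv_chain(spec.conv_layers, input_len)  # validate, with layer named on failure
    layers: list = [AddChannel()]
    c_in = 1
    for conv in spec.conv_layers:
        if conv.batch_norm_before:
            layers.append(BatchNorm1d(c_in, dtype=dtype))
        layers.append(Conv1d(c_in, conv.filters, conv.kernel_size, conv.stride, rng, dtype=dtype))
        layers.append(ReLU())
        c_in = conv.filters
    return layers


def build_cnn1d(spec: CNNSpec = CNNSpec(), input_len: int = 2151, seed: int = 0,
                dtype=np.float32) -> Sequential:
    """Modified 1-D AlexNet: conv stack, one hidden FC layer, 2-class output."""
    rng = np.random.default_rng(seed)
    channels, length = conv_stack_output_shape(spec, input_len)
    layers = _conv_stack(spec, input_len, rng, dtype)
    layers += [
        Flatten(),
        Dense(channels * length, spec.fc_width, rng, dtype=dtype),
        ReLU(),
        Dropout(spec.dropout_rate),
        Dense(spec.fc_width, spec.n_classes, rng, dtype=dtype),
    ]
    return Sequential(layers)


def build_lstm(hidden: int = 10, dropout: float = 0.3, input_len: int = 2151,
               seed: int = 0, dtype=np.float32) -> Sequential:
    """Spectrum-as-sequence LSTM classifier (one value per time step)."""
    rng = np.random.default_rng(seed)
    return Sequential([
        AddChannel(),
        ChannelsToSequence(),
        LSTM(1, hidden, rng, dtype=dtype),
        Dropout(dropout),
        Dense(hidden, 2, rng, dtype=dtype),
    ])


def build_cnn_lstm(spec: ModelSpec = ModelSpec(kind="cnn_lstm"), input_len: int = 2151,
                   seed: int = 0, dtype=np.float32) -> Sequential:
    """Hybrid: CNN conv stack -> sequence of channel vectors -> LSTM -> output."""
    if spec.kind != "cnn_lstm":
        raise ValueError(f"spec.kind must be 'cnn_lstm', got {spec.kind!r}")
    rng = np.random.default_rng(seed)
    channels, _ = conv_stack_output_shape(spec.cnn, input_len)
    layers = _conv_stack(spec.cnn, input_len, rng, dtype)
    layers += [
        ChannelsToSequence(),
        LSTM(channels, spec.lstm_hidden, rng, dtype=dtype),
        Dropout(spec.lstm_dropout),
        Dense(spec.lstm_hidden, 2, rng, dtype=dtype),
    ]
    return Sequential(layers)


_ALEXNET_POOL_AFTER = frozenset({1, 2, 5})


def _alexnet_conv_stack(spec: CNNSpec, input_len: int, rng: np.random.Generator,
                        dtype=np.float32) -> tuple[list, int, int]:
    lengths = _conv_chain(spec.conv_layers, input_len, pools_after=_ALEXNET_POOL_AFTER)
    layers: list = [AddChannel()]
    c_in = 1
    for idx, conv in enumerate(spec.conv_layers, start=1):
        layers.append(Conv1d(c_in, conv.filters, conv.kernel_size, conv.stride, rng, dtype=dtype))
        layers.append(ReLU())
        if idx in _ALEXNET_POOL_AFTER:
            layers.append(MaxPool1d(3, 2))
        c_in = conv.filters
    return layers, c_in, lengths[-1]


def build_variant(kind: str, input_len: int = 2151, seed: int = 0,
                  lstm_hidden: int = 10, lstm_dropout: float = 0.3,
                  dtype=np.float32) -> Sequential:
    """AlexNet-style reference models: ``alexnet1d`` or ``alexnet_lstm``.

    ``alexnet1d`` keeps the classical layout: ReLU after each convolution,
    max pooling (size 3, stride 2) after conv layers 1, 2 and 5, and two
    hidden fully connected layers (widths 256 and 128, dropout 0.5 each)
    before the two-class output.  ``alexnet_lstm`` feeds the pooled conv
    sequence into the LSTM instead.
    """
    rng = np.random.default_rng(seed)
    spec = CNNSpec()
    if kind == "alexnet1d":
        layers, channels, length = _alexnet_conv_stack(spec, input_len, rng, dtype)
        layers += [
            Flatten(),
            Dense(channels * length, 256, rng, dtype=dtype),
            ReLU(),
            Dropout(0.5),
            Dense(256, 128, rng, dtype=dtype),
            ReLU(),
            Dropout(0.5),
            Dense(128, 2, rng, dtype=dtype),
        ]
        return Sequential(layers)
    if kind == "alexnet_lstm":
        layers, channels, _ = _alexnet_conv_stack(spec, input_len, rng, dtype)
        layers += [
            ChannelsToSequence(),
            LSTM(channels, lstm_hidden, rng, dtype=dtype),
            Dropout(lstm_dropout),
            Dense(lstm_hidden, 2, rng, dtype=dtype),
        ]
        return Sequential(layers)
    raise ValueError(f"unknown variant kind {kind!r}; expected 'alexnet1d' or 'alexnet_lstm'")


def build_model(spec: ModelSpec, input_len: int, seed: int = 0,
                dtype=np.float32) -> Sequential:
    """Dispatch on ``spec.kind`` to the matching builder."""
    if spec.kind == "cnn":
        return build_cnn1d(spec.cnn, input_len, seed, dtype)
    if spec.kind == "lstm":
        return build_lstm(spec.lstm_hidden, spec.lstm_dropout, input_len, seed, dtype)
    if spec.kind == "cnn_lstm":
        return build_cnn_lstm(spec, input_len, seed, dtype)
    return build_variant(spec.kind, input_len, seed, spec.lstm_hidden, spec.lstm_dropout, dtype)
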