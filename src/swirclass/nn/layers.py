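"""Layers with explicit forward/backward passes.

Array conventions: convolutional blocks operate on (batch, channels, length);
dense layers on (batch, features); the LSTM on (batch, time, features).
Every layer caches what its backward pass needs during a training forward
pass; inference-mode forward passes (``training=False``) are pure functions.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class; layers without parameters inherit the defaults."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class AddChannel(Layer):
    """(N, L) -> (N, 1, L): treat each spectrum as a one-channel signal."""

    def forward(self, x, training=False):
        return x[:, None, :]

    def backward(self, grad):
        return grad[:, 0, :]


class ChannelsToSequence(Layer):
    """(N, C, L) -> (N, L, C): channel vectors become a length-L sequence."""

    def forward(self, x, training=False):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, grad):
        return np.ascontiguousarray(grad.transpose(0, 2, 1))


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Dense(Layer):
    """Affine map (N, D_in) -> (N, D_out); He-normal initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        if x.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"dense layer expects width {self.W.shape[0]}, got {x.shape[1]}"
            )
        x = np.asarray(x, dtype=self.W.dtype)
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


def conv_output_length(input_len: int, kernel_size: int, stride: int) -> int:
    """Output length of a valid (unpadded) 1-D convolution.

    floor((input_len - kernel_size) / stride) + 1; requires
    input_len >= kernel_size.
    """
    if kernel_size < 1 or stride < 1:
        raise ValueError("kernel_size and stride must be >= 1")
    if input_len < kernel_size:
        raise ValueError(
            f"input length {input_len} shorter than kernel size {kernel_size}"
        )
    return (input_len - kernel_size) // stride + 1


class Conv1d(Layer):
    """Valid 1-D convolution via im2col; (N, C_in, L) -> (N, C_out, L_out)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int,
                 rng: np.random.Generator, dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        self.kernel_size, self.stride = kernel_size, stride
        fan_in = c_in * kernel_size
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, C, L) -> (N, L_out, C * k)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel_size, axis=2)
        win = win[:, :, :: self.stride, :]  # (N, C, L_out, k)
        n, c, l_out, k = win.shape
        return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n, l_out, c * k)

    def forward(self, x, training=False):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[1]}")
        x = np.asarray(x, dtype=self.W.dtype)
        conv_output_length(x.shape[2], self.kernel_size, self.stride)
        cols = self._im2col(x)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.W.T + self.b  # (N, L_out, C_out)
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, grad):
        n, _, l_out = grad.shape
        g = grad.transpose(0, 2, 1)  # (N, L_out, C_out)
        self.dW[...] = g.reshape(-1, self.c_out).T @ self._cols.reshape(-1, self._cols.shape[2])
        self.db[...] = g.sum(axis=(0, 1))
        dcols = (g @ self.W).reshape(n, l_out, self.c_in, self.kernel_size)
        dx = np.zeros(self._in_shape, dtype=self.W.dtype)
        for j in range(self.kernel_size):
            dx[:, :, j : j + self.stride * l_out : self.stride] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class BatchNorm1d(Layer):
    """Per-channel batch normalization on (N, C, L) activations."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=self.gamma.dtype)
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if training:
            self._xhat, self._inv_std, self._m = xhat, inv_std, x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2))
        self.dbeta[...] = grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]


class MaxPool1d(Layer):
    """Valid 1-D max pooling on (N, C, L)."""

    def __init__(self, size: int, stride: int):
        self.size, self.stride = size, stride

    def forward(self, x, training=False):
        conv_output_length(x.shape[2], self.size, self.stride)
        win = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=2)
        win = win[:, :, :: self.stride, :]  # (N, C, L_out, size)
        self._argmax = win.argmax(axis=3)
        self._in_shape = x.shape
        return win.max(axis=3)

    def backward(self, grad):
        n, c, l_out = grad.shape
        dx = np.zeros(self._in_shape)
        ni, ci, pi = np.indices((n, c, l_out))
        pos = pi * self.stride + self._argmax
        np.add.at(dx, (ni, ci, pos), grad)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class LSTM(Layer):
    """Single-layer LSTM over (N, T, D); returns the last hidden state (N, H).

    Gate weights act on the concatenation [h_{t-1}, x_t]:

        c~_t = tanh(Wc [h,x] + bc)         (candidate memory)
        f_t  = sigmoid(Wf [h,x] + bf)      (forget / "oblivion" gate)
        i_t  = sigmoid(Wi [h,x] + bi)      (update gate)
        o_t  = sigmoid(Wo [h,x] + bo)      (output gate)
        C_t  = f_t * C_{t-1} + i_t * c~_t
        h_t  = o_t * tanh(C_t)

    Forget-gate bias is initialized to 1 so early training retains memory.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float64):
        if hidden < 1:
            raise ValueError("hidden size must be >= 1")
        self.d_in, self.hidden = d_in, hidden
        bound = 1.0 / np.sqrt(hidden)
        shape = (hidden, hidden + d_in)
        self.Wc = rng.uniform(-bound, bound, shape).astype(dtype)
        self.Wf = rng.uniform(-bound, bound, shape).astype(dtype)
        self.Wi = rng.uniform(-bound, bound, shape).astype(dtype)
        self.Wo = rng.uniform(-bound, bound, shape).astype(dtype)
        self.bc = np.zeros(hidden, dtype=dtype)
        self.bf = np.ones(hidden, dtype=dtype)
        self.bi = np.zeros(hidden, dtype=dtype)
        self.bo = np.zeros(hidden, dtype=dtype)
        self._grads = [np.zeros_like(p) for p in self.parameters()]

    def parameters(self):
        return [self.Wc, self.Wf, self.Wi, self.Wo, self.bc, self.bf, self.bi, self.bo]

    def gradients(self):
        return self._grads

    def forward(self, x, training=False):
        if x.ndim != 3 or x.shape[2] != self.d_in:
            raise ValueError(f"LSTM expects (N, T, {self.d_in}) input, got {x.shape}")
        x = np.asarray(x, dtype=self.Wc.dtype)
        n, t_len, _ = x.shape
        h = np.zeros((n, self.hidden), dtype=self.Wc.dtype)
        c = np.zeros((n, self.hidden), dtype=self.Wc.dtype)
        cache = []
        for t in range(t_len):
            z = np.concatenate([h, x[:, t, :]], axis=1)
            c_tilde = np.tanh(z @ self.Wc.T + self.bc)
            f = _sigmoid(z @ self.Wf.T + self.bf)
            i = _sigmoid(z @ self.Wi.T + self.bi)
            o = _sigmoid(z @ self.Wo.T + self.bo)
            c_prev = c
            c = f * c_prev + i * c_tilde
            tanh_c = np.tanh(c)
            h = o * tanh_c
            if training:
                cache.append((z, c_tilde, f, i, o, c_prev, tanh_c))
        if training:
            self._cache, self._x_shape = cache, x.shape
        return h

    def backward(self, grad):
        n, t_len, _ = self._x_shape
        dWc, dWf, dWi, dWo, dbc, dbf, dbi, dbo = (np.zeros_like(g) for g in self._grads)
        dx = np.zeros(self._x_shape, dtype=self.Wc.dtype)
        dh = np.asarray(grad, dtype=self.Wc.dtype)
        dc = np.zeros_like(dh)
        for t in range(t_len - 1, -1, -1):
            z, c_tilde, f, i, o, c_prev, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            df = dc * c_prev
            di = dc * c_tilde
            dct = dc * i
            # pre-activation grads
            ao = do * o * (1 - o)
            af = df * f * (1 - f)
            ai = di * i * (1 - i)
            ac = dct * (1.0 - c_tilde**2)
            dWc += ac.T @ z
            dWf += af.T @ z
            dWi += ai.T @ z
            dWo += ao.T @ z
            dbc += ac.sum(axis=0)
            dbf += af.sum(axis=0)
            dbi += ai.sum(axis=0)
            dbo += ao.sum(axis=0)
            dz = ac @ self.Wc + af @ self.Wf + ai @ self.Wi + ao @ self.Wo
            dh = dz[:, : self.hidden]
            dx[:, t, :] = dz[:, self.hidden :]
            dc = dc * f
        for g, new in zip(self._grads, (dWc, dWf, dWi, dWo, dbc, dbf, dbi, dbo)):
            g[...] = new
        return dx


class Sequential(Layer):
    """Ordered layer container with end-to-end forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]

    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def seed_dropout(self, rng: np.random.Generator) -> None:
        """Point every dropout layer at a shared training RNG."""
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng
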