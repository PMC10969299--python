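"""Minimal feed-forward / recurrent network primitives in numpy.

Implements exactly what the two deep models need: 1-D convolution,
max-pooling, dense layers, dropout, an LSTM layer with forward and recurrent
dropout, the Adam optimizer and binary cross-entropy.  Layers expose
``forward(x, train)`` and ``backward(grad)`` and carry their parameters and
gradients as parallel lists, so a model is a list of layers plus one Adam
instance.  All randomness flows through an explicit numpy Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1D", "MaxPool1D", "Dropout", "Flatten", "LSTMLayer",
           "Sequential", "Adam", "bce_loss", "sigmoid"]


def sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                    np.exp(np.clip(x, -500, 500)) / (1.0 + np.exp(np.clip(x, -500, 500))))


def _hard_sigmoid(x):
    return np.clip(0.2 * x + 0.5, 0.0, 1.0)


def _hard_sigmoid_grad(x):
    return np.where((x > -2.5) & (x < 2.5), 0.2, 0.0)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer with optional activation ('relu', 'sigmoid', None)."""

    def __init__(self, n_in: int, n_out: int, activation: str | None, rng):
        super().__init__()
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self.x = x
        z = x @ self.W + self.b
        self.z = z
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "sigmoid":
            self.a = sigmoid(z)
            return self.a
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self.z > 0)
        elif self.activation == "sigmoid":
            grad = grad * self.a * (1.0 - self.a)
        self.grads[0][...] = self.x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1D(Layer):
    """Valid 1-D convolution over (batch, length, channels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = rng.standard_normal((kernel, c_in, c_out)) * scale
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self.x = x
        n, L, _ = x.shape
        Lo = L - self.kernel + 1
        z = np.broadcast_to(self.b, (n, Lo, self.W.shape[2])).copy()
        for i in range(self.kernel):
            z += x[:, i:i + Lo, :] @ self.W[i]
        self.z = z
        return np.maximum(z, 0.0)  # ReLU in every convolutional layer

    def backward(self, grad):
        grad = grad * (self.z > 0)
        n, Lo, _ = grad.shape
        dx = np.zeros_like(self.x)
        for i in range(self.kernel):
            self.grads[0][i][...] = np.einsum("nlc,nlf->cf", self.x[:, i:i + Lo, :], grad)
            dx[:, i:i + Lo, :] += grad @ self.W[i].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        n, L, c = x.shape
        Lo = L // self.size
        self.in_len = L
        xr = x[:, :Lo * self.size, :].reshape(n, Lo, self.size, c)
        self.argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        n, Lo, c = grad.shape
        dx = np.zeros((n, Lo, self.size, c))
        idx = np.indices((n, Lo, c))
        dx[idx[0], idx[1], self.argmax, idx[2]] = grad
        dx = dx.reshape(n, Lo * self.size, c)
        if Lo * self.size < self.in_len:
            dx = np.concatenate([dx, np.zeros((n, self.in_len - Lo * self.size, c))], axis=1)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class Flatten(Layer):
    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.shape)


class LSTMLayer(Layer):
    """Single LSTM layer returning the final hidden state.

    tanh cell activation, hard-sigmoid gate (recurrent) activation, and
    Keras-style dropout: one input mask and one recurrent mask per batch,
    shared across time steps.
    """

    def __init__(self, n_in: int, n_hidden: int, rng,
                 dropout: float = 0.2, recurrent_dropout: float = 0.2):
        super().__init__()
        h = n_hidden
        self.Wx = rng.standard_normal((n_in, 4 * h)) / np.sqrt(n_in)
        self.Wh = rng.standard_normal((h, 4 * h)) / np.sqrt(h)
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # forget-gate bias
        self.h = h
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        self.rng = rng
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        n, T, _ = x.shape
        h = self.h
        if train and self.dropout > 0:
            self.mx = (self.rng.random((n, x.shape[2])) >= self.dropout) / (1 - self.dropout)
        else:
            self.mx = np.ones((n, x.shape[2]))
        if train and self.recurrent_dropout > 0:
            self.mh = (self.rng.random((n, h)) >= self.recurrent_dropout) / (1 - self.recurrent_dropout)
        else:
            self.mh = np.ones((n, h))
        self.x = x
        self.cache = []
        hs = np.zeros((n, h))
        cs = np.zeros((n, h))
        for t in range(T):
            xt = x[:, t, :] * self.mx
            hd = hs * self.mh
            z = xt @ self.Wx + hd @ self.Wh + self.b
            zi, zf, zo, zg = z[:, :h], z[:, h:2 * h], z[:, 2 * h:3 * h], z[:, 3 * h:]
            i_g, f_g, o_g = _hard_sigmoid(zi), _hard_sigmoid(zf), _hard_sigmoid(zo)
            g = np.tanh(zg)
            cs_new = f_g * cs + i_g * g
            tan_c = np.tanh(cs_new)
            hs_new = o_g * tan_c
            self.cache.append((xt, hd, zi, zf, zo, i_g, f_g, o_g, g, cs, cs_new, tan_c))
            hs, cs = hs_new, cs_new
        return hs

    def backward(self, dh_last):
        n, T, n_in = self.x.shape
        h = self.h
        for gr in self.grads:
            gr[...] = 0.0
        dx = np.zeros_like(self.x)
        dh, dc = dh_last, np.zeros((n, h))
        for t in reversed(range(T)):
            xt, hd, zi, zf, zo, i_g, f_g, o_g, g, c_prev, c_new, tan_c = self.cache[t]
            do = dh * tan_c
            dc = dc + dh * o_g * (1.0 - tan_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i_g
            dzi = di * _hard_sigmoid_grad(zi)
            dzf = df * _hard_sigmoid_grad(zf)
            dzo = do * _hard_sigmoid_grad(zo)
            dzg = dg * (1.0 - g**2)
            dz = np.concatenate([dzi, dzf, dzo, dzg], axis=1)
            self.grads[0] += xt.T @ dz
            self.grads[1] += hd.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t, :] = (dz @ self.Wx.T) * self.mx
            dh = (dz @ self.Wh.T) * self.mh
            dc = dc * f_g
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(p, y):
    """Binary cross-entropy and its gradient w.r.t. the probability input."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    grad = (p - y) / (p * (1 - p)) / len(y)
    return loss, grad
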