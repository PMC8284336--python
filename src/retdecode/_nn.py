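"""Minimal numpy neural-network layers with reverse-mode gradients.

Only what the CNN encoding model needs: valid 2-D convolution (im2col),
parametric ReLU, batch normalization, dropout, a dense layer, a softplus
output to keep predicted rates positive for the Poisson likelihood, and the
Adam optimizer. Shapes follow the (batch, channels, height, width)
convention; stimulus frames enter as channels.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "PReLU", "BatchNorm", "Dropout", "Flatten", "Dense",
           "Softplus", "Sequential", "Adam"]


class Layer:
    #: (param, grad) pairs, populated by subclasses
    def params(self):
        return []

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution; weights (out_ch, in_ch*k*k), He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.k, self.stride = k, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train: bool):
        B, C, H, W = x.shape
        k, s = self.k, self.stride
        if H < k or W < k:
            raise ValueError(f"{H}x{W} input smaller than {k}x{k} filter")
        v = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,k,k
        self.Ho, self.Wo = v.shape[2], v.shape[3]
        cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(-1, C * k * k)
        self.cols = cols
        self.x_shape = x.shape
        out = cols @ self.W.T + self.b
        return out.reshape(B, self.Ho, self.Wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g):
        B, C, H, W = self.x_shape
        k, s = self.k, self.stride
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.gW[...] = g2.T @ self.cols
        self.gb[...] = g2.sum(axis=0)
        gcols = (g2 @ self.W).reshape(B, self.Ho, self.Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros(self.x_shape)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + s * self.Ho : s, j : j + s * self.Wo : s] += gcols[..., i, j]
        return gx


class PReLU(Layer):
    """Parametric rectifier with one learnable slope per layer."""

    def __init__(self, init: float = 0.25):
        self.a = np.array([float(init)])
        self.ga = np.zeros(1)

    def params(self):
        return [(self.a, self.ga)]

    def forward(self, x, train: bool):
        self.x = x
        return np.where(x > 0, x, self.a[0] * x)

    def backward(self, g):
        neg = self.x <= 0
        self.ga[0] = np.sum(g * self.x * neg)
        return g * np.where(neg, self.a[0], 1.0)


class BatchNorm(Layer):
    """Channel-wise batch normalization for (B, C, H, W) activations."""

    def __init__(self, n_ch: int, momentum: float = 0.5, eps: float = 1e-5):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.ggamma = np.zeros(n_ch)
        self.gbeta = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, train: bool):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        sh = (1, -1, 1, 1)
        self.inv = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean.reshape(sh)) * self.inv.reshape(sh)
        self.n = x.shape[0] * x.shape[2] * x.shape[3]
        self.train_mode = train
        return self.gamma.reshape(sh) * self.xhat + self.beta.reshape(sh)

    def backward(self, g):
        axes = (0, 2, 3)
        sh = (1, -1, 1, 1)
        self.ggamma[...] = (g * self.xhat).sum(axis=axes)
        self.gbeta[...] = g.sum(axis=axes)
        if not self.train_mode:
            return g * (self.gamma * self.inv).reshape(sh)
        gxhat = g * self.gamma.reshape(sh)
        gx = (
            gxhat
            - gxhat.mean(axis=axes).reshape(sh)
            - self.xhat * (gxhat * self.xhat).mean(axis=axes).reshape(sh)
        ) * self.inv.reshape(sh)
        return gx


class Dropout(Layer):
    def __init__(self, p: float, rng=None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train: bool):
        if not train or self.p == 0.0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self.mask

    def backward(self, g):
        return g if self.mask is None else g * self.mask


class Flatten(Layer):
    def forward(self, x, train: bool):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self.shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train: bool):
        self.x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self.x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T


class Softplus(Layer):
    """log(1 + exp(x)): keeps predicted rates positive for the Poisson loss."""

    def forward(self, x, train: bool):
        self.x = x
        return np.logaddexp(0.0, x)

    def backward(self, g):
        return g / (1.0 + np.exp(-self.x))


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def weight_matrices(self):
        """Conv/Dense weight matrices (the ones under L2 regularization)."""
        return [l.W for l in self.layers if isinstance(l, (Conv2D, Dense))]


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
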