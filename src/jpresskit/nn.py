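"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly what the JPRESS encoder/decoder needs: dense layers,
gated dilated convolutions (kernel size 2) with residual/skip wiring, a GRU,
the Adam optimizer and a cosine-annealing learning-rate schedule.  All
tensors are float32; every layer caches its forward activations and returns
input gradients from ``backward``.  Gradient correctness is established by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Dense", "GatedDilatedConv", "GRU", "Adam", "cosine_lr"]

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "v", "g")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.v = np.asarray(value, dtype=DTYPE)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g[...] = 0


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape or (fan_in, fan_out)).astype(DTYPE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """Affine map on the trailing axis, with optional tanh activation."""

    def __init__(self, name: str, n_in: int, n_out: int,
                 rng: np.random.Generator, activation: str | None = None,
                 bias_init: float = 0.0):
        self.w = Param(f"{name}/w", _glorot(rng, n_in, n_out))
        self.b = Param(f"{name}/b", np.full(n_out, bias_init, dtype=DTYPE))
        self.activation = activation
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.w.v + self.b.v
        if self.activation == "tanh":
            z = np.tanh(z)
        self._cache = (x, z)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, z = self._cache
        if self.activation == "tanh":
            dout = dout * (1.0 - z * z)
        flat_x = x.reshape(-1, x.shape[-1])
        flat_d = dout.reshape(-1, dout.shape[-1])
        self.w.g += flat_x.T @ flat_d
        self.b.g += flat_d.sum(axis=0)
        return dout @ self.w.v.T


class GatedDilatedConv:
    """Kernel-2 dilated convolution with a gated activation unit.

    Taps at positions ``p`` and ``p + d`` (zero-padded past the end), a
    tanh x sigmoid gate, and a linear output projection that feeds both the
    residual sum and the skip path:  ``out = x + r``, ``skip = r``.
    """

    def __init__(self, name: str, channels: int, dilation: int,
                 rng: np.random.Generator):
        f = channels
        self.dilation = int(dilation)
        self.w = Param(f"{name}/w", _glorot(rng, 2 * f, 2 * f))
        self.b = Param(f"{name}/b", np.zeros(2 * f, dtype=DTYPE))
        self.wo = Param(f"{name}/wo", _glorot(rng, f, f))
        self.bo = Param(f"{name}/bo", np.zeros(f, dtype=DTYPE))
        self.channels = f
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b, self.wo, self.bo]

    def forward(self, x: np.ndarray):
        """x: (n, p, f) -> (residual out (n, p, f), skip (n, p, f))."""
        d, f = self.dilation, self.channels
        tap2 = np.zeros_like(x)
        if d < x.shape[1]:
            tap2[:, :-d, :] = x[:, d:, :]
        xt = np.concatenate([x, tap2], axis=-1)
        z = xt @ self.w.v + self.b.v
        filt = np.tanh(z[..., :f])
        gate = _sigmoid(z[..., f:])
        h = filt * gate
        r = h @ self.wo.v + self.bo.v
        self._cache = (x, xt, filt, gate, h)
        return x + r, r

    def backward(self, dout: np.ndarray, dskip: np.ndarray | None = None) -> np.ndarray:
        x, xt, filt, gate, h = self._cache
        d, f = self.dilation, self.channels
        dr = dout if dskip is None else dout + dskip
        flat_h = h.reshape(-1, f)
        flat_dr = dr.reshape(-1, f)
        self.wo.g += flat_h.T @ flat_dr
        self.bo.g += flat_dr.sum(axis=0)
        dh = dr @ self.wo.v.T
        dfilt = dh * gate
        dgate = dh * filt
        dz = np.concatenate([dfilt * (1.0 - filt * filt),
                             dgate * gate * (1.0 - gate)], axis=-1)
        flat_xt = xt.reshape(-1, 2 * f)
        flat_dz = dz.reshape(-1, 2 * f)
        self.w.g += flat_xt.T @ flat_dz
        self.b.g += flat_dz.sum(axis=0)
        dxt = dz @ self.w.v.T
        dx = dout + dxt[..., :f]
        if d < x.shape[1]:
            dx[:, d:, :] += dxt[:, :-d, f:]
        return dx


class GRU:
    """Gated recurrent unit over the leading (sequence) axis.

    Input/hidden width ``f``; update convention
    ``h_t = (1 - z_t) h_{t-1} + z_t n_t``.  Setting the recurrent weights to
    zero makes each step depend on its own input only.
    """

    def __init__(self, name: str, f: int, rng: np.random.Generator):
        self.f = f
        self.wx = Param(f"{name}/wx", _glorot(rng, f, 3 * f, (f, 3 * f)))
        self.wh = Param(f"{name}/wh", _glorot(rng, f, 3 * f, (f, 3 * f)))
        self.b = Param(f"{name}/b", np.zeros(3 * f, dtype=DTYPE))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (s, n, f) -> hidden sequence (s, n, f), h_0 = 0."""
        s, n, f = x.shape
        h = np.zeros((n, f), dtype=DTYPE)
        out = np.empty_like(x)
        steps = []
        for tstep in range(s):
            xt = x[tstep]
            gx = xt @ self.wx.v + self.b.v
            gh = h @ self.wh.v
            z = _sigmoid(gx[:, :f] + gh[:, :f])
            r = _sigmoid(gx[:, f:2 * f] + gh[:, f:2 * f])
            hn = gh[:, 2 * f:]
            ncand = np.tanh(gx[:, 2 * f:] + r * hn)
            h_new = (1.0 - z) * h + z * ncand
            steps.append((xt, h, z, r, ncand, hn))
            h = h_new
            out[tstep] = h
        self._cache = steps
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        steps = self._cache
        s = len(steps)
        f = self.f
        dx = np.empty((s,) + steps[0][0].shape, dtype=DTYPE)
        dh_next = np.zeros_like(steps[0][1])
        for tstep in range(s - 1, -1, -1):
            xt, h_prev, z, r, ncand, hn = steps[tstep]
            dh = dout[tstep] + dh_next
            dz = dh * (ncand - h_prev)
            dn = dh * z
            dh_prev = dh * (1.0 - z)
            dpre_n = dn * (1.0 - ncand * ncand)
            dr = dpre_n * hn
            dhn = dpre_n * r
            dpre_z = dz * z * (1.0 - z)
            dpre_r = dr * r * (1.0 - r)
            dgx = np.concatenate([dpre_z, dpre_r, dpre_n], axis=-1)
            dgh = np.concatenate([dpre_z, dpre_r, dhn], axis=-1)
            self.wx.g += xt.T @ dgx
            self.wh.g += h_prev.T @ dgh
            self.b.g += dgx.sum(axis=0)
            dx[tstep] = dgx @ self.wx.v.T
            dh_next = dh_prev + dgh @ self.wh.v.T
        return dx


def cosine_lr(step: int, total_steps: int, max_lr: float, min_lr: float = 0.0) -> float:
    """Cosine annealing from ``max_lr`` to ``min_lr`` over ``total_steps``."""
    frac = min(step / max(total_steps, 1), 1.0)
    return min_lr + 0.5 * (max_lr - min_lr) * (1.0 + np.cos(np.pi * frac))


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.v) for p in params]
        self.vv = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.g ** 2).sum()) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    p.g *= scale
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.vv):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.g
            v[...] = self.beta2 * v + (1 - self.beta2) * p.g ** 2
            p.v -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
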