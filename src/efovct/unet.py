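"""A compact numpy U-Net with hand-written backpropagation.

The estimator network is small by design: single-channel 256^2 images,
a configurable number of down/up levels with channel doubling, 3x3
convolutions with Leaky-ReLU activations, 2x2 average pooling, nearest-
neighbour upsampling, skip concatenation, and a residual 1x1 output head
(the network predicts a correction to its input, which makes the
untrained network close to the identity and speeds up convergence on the
completion task).

All parameters are float64 numpy arrays; the optimizer is Adam.  Forward
passes cache the im2col matrices needed by the backward pass, so the
object is stateful between ``forward`` and ``backward`` calls.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "Adam"]


_DTYPE = np.float32


class _Conv3x3:
    """Same-padded 3x3 convolution computed as nine shifted (Co, Ci)
    matmuls; avoids the memory traffic of an explicit im2col buffer."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        # He initialization for leaky-relu fan-in
        std = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, std, (c_out, c_in, 3, 3)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._cache = xp
        out = np.zeros((n, self.w.shape[0], h, w), dtype=_DTYPE)
        for ki in range(3):
            for kj in range(3):
                patch = xp[:, :, ki : ki + h, kj : kj + w].reshape(n, c, h * w)
                out += np.matmul(self.w[:, :, ki, kj], patch).reshape(n, -1, h, w)
        return out + self.b[None, :, None, None]

    def backward(self, gy: np.ndarray):
        xp = self._cache
        n, co, h, w = gy.shape
        ci = xp.shape[1]
        g = gy.reshape(n, co, h * w)
        self.gw = np.empty_like(self.w)
        gxp = np.zeros_like(xp)
        for ki in range(3):
            for kj in range(3):
                patch = xp[:, :, ki : ki + h, kj : kj + w].reshape(n, ci, h * w)
                # sum over batch and pixels
                self.gw[:, :, ki, kj] = np.einsum("ncp,nkp->ck", g, patch)
                gxp[:, :, ki : ki + h, kj : kj + w] += np.matmul(
                    self.w[:, :, ki, kj].T, g
                ).reshape(n, ci, h, w)
        self.gb = g.sum(axis=(0, 2))
        return gxp[:, :, 1 : 1 + h, 1 : 1 + w]


class _Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, (c_out, c_in)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return np.einsum("oc,nchw->nohw", self.w, x) + self.b[None, :, None, None]

    def backward(self, gy: np.ndarray):
        x = self._cache
        self.gw = np.einsum("nohw,nchw->oc", gy, x)
        self.gb = gy.sum(axis=(0, 2, 3))
        return np.einsum("oc,nohw->nchw", self.w, gy)


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def _pool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_grad(gy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) * 0.25


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_grad(gy: np.ndarray) -> np.ndarray:
    n, c, h, w = gy.shape
    return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """U-Net mapping (N, 1, H, W) -> (N, 1, H, W), values nominally [0, 1].

    Parameters
    ----------
    depth :
        Number of pooling steps (encoder levels below the top).
    base_channels :
        Channels of the top level; doubled at each level down.
    leaky_slope :
        Negative-side slope of the Leaky-ReLU activations.
    stem_pool :
        1 runs the body at full resolution; 2 average-pools the input
        once, runs the body at half resolution and upsamples the
        correction before the residual sum.  The completion task is
        dominated by low spatial frequencies, so the default trades top-
        level resolution for a ~4x cheaper CPU pass.
    """

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 8,
        leaky_slope: float = 0.01,
        seed: int = 0,
        stem_pool: int = 2,
    ):
        if stem_pool not in (1, 2):
            raise ValueError("stem_pool must be 1 or 2")
        self.depth = depth
        self.base = base_channels
        self.slope = leaky_slope
        self.stem_pool = stem_pool
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2**k for k in range(depth + 1)]
        self.enc = []
        c_in = 1
        for c in ch[:-1]:
            self.enc.append((_Conv3x3(c_in, c, rng), _Conv3x3(c, c, rng)))
            c_in = c
        self.bottom = (_Conv3x3(ch[-2], ch[-1], rng), _Conv3x3(ch[-1], ch[-1], rng))
        self.dec = []
        c_up = ch[-1]
        for c in reversed(ch[:-1]):
            self.dec.append((_Conv3x3(c_up + c, c, rng), _Conv3x3(c, c, rng)))
            c_up = c
        self.head = _Conv1x1(ch[0], 1, rng)

    # ------------------------------------------------------------------
    def _convs(self):
        for pair in self.enc:
            yield from pair
        yield from self.bottom
        for pair in self.dec:
            yield from pair

    def parameters(self) -> list:
        layers = list(self._convs()) + [self.head]
        return layers

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.parameters()):
            out[f"l{i}_w"] = layer.w
            out[f"l{i}_b"] = layer.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.parameters()):
            layer.w = np.array(state[f"l{i}_w"])
            layer.b = np.array(state[f"l{i}_b"])

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        self._acts = []  # pre-activation caches for leaky backward
        self._skips = []
        self._input = x
        h = _pool2(x) if self.stem_pool == 2 else x

        def conv_act(conv, h):
            z = conv.forward(h)
            self._acts.append(z)
            return _leaky(z, self.slope)

        for c1, c2 in self.enc:
            h = conv_act(c2, conv_act(c1, h))
            self._skips.append(h)
            h = _pool2(h)
        h = conv_act(self.bottom[1], conv_act(self.bottom[0], h))
        for (c1, c2), skip in zip(self.dec, reversed(self._skips)):
            h = np.concatenate([_up2(h), skip], axis=1)
            h = conv_act(c2, conv_act(c1, h))
        corr = self.head.forward(h)
        if self.stem_pool == 2:
            corr = _up2(corr)
        return corr + x  # residual head

    def backward(self, gout: np.ndarray) -> np.ndarray:
        """Backprop; returns gradient w.r.t. the input."""
        gout = np.ascontiguousarray(gout, dtype=_DTYPE)
        acts = list(self._acts)
        gx_residual = gout.copy()
        ghead = _up2_grad(gout) if self.stem_pool == 2 else gout
        g = self.head.backward(ghead)

        def act_back(conv, g):
            z = acts.pop()
            return conv.backward(g * _leaky_grad(z, self.slope))

        # decoder backward runs top level first; dec[i] (deepest first)
        # consumed skip[depth-1-i], so iteration k here touches skip[k]
        gskips = []
        for c1, c2 in reversed(self.dec):
            g = act_back(c1, act_back(c2, g))
            c_up = g.shape[1] - self._skips[len(gskips)].shape[1]
            g_up, g_skip = g[:, :c_up], g[:, c_up:]
            gskips.append(g_skip)
            g = _up2_grad(g_up)
        g = act_back(self.bottom[0], act_back(self.bottom[1], g))
        for (c1, c2), g_skip in zip(reversed(self.enc), reversed(gskips)):
            g = _pool2_grad(g) + g_skip
            g = act_back(c1, act_back(c2, g))
        if self.stem_pool == 2:
            g = _pool2_grad(g)
        return g + gx_residual

    __call__ = forward


class Adam:
    """Adam optimizer over the network's conv layers."""

    def __init__(self, net: UNet, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {"w": np.zeros_like(l.w), "b": np.zeros_like(l.b)} for l in net.parameters()
        ]
        self.v = [
            {"w": np.zeros_like(l.w), "b": np.zeros_like(l.b)} for l in net.parameters()
        ]

    def step(self) -> None:
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for layer, m, v in zip(self.net.parameters(), self.m, self.v):
            for name, grad in (("w", layer.gw), ("b", layer.gb)):
                m[name] = self.b1 * m[name] + (1 - self.b1) * grad
                v[name] = self.b2 * v[name] + (1 - self.b2) * grad * grad
                update = (m[name] / corr1) / (np.sqrt(v[name] / corr2) + self.eps)
                p = getattr(layer, name)
                setattr(layer, name, p - self.lr * update)
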