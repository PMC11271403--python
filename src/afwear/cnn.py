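"""A small 1D convolutional network in NumPy, with Adam and dropout.

Architecture, defaults and training recipe follow the wearables
discriminator: three valid-padding 1D convolutions (8, 20 and 32 filters,
kernel 21 minutes) with ReLU, max pooling of size and stride 2 after the
first convolution only, global average pooling to a 32-vector, dropout
(p=0.5) on that vector during training, and a single sigmoid output unit
trained with binary cross-entropy, Adam (lr 3e-4) and L2 weight decay
1e-8 on every non-bias parameter.

Implementation notes: convolutions use an im2col formulation
(``sliding_window_view`` + matmul); all randomness flows through an
explicit ``numpy.random.Generator``, so runs are reproducible seed-for-
seed on one thread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CNNSpec:
    """Hyper-parameters of the discriminator network."""

    conv_filters: tuple[int, int, int] = (8, 20, 32)
    kernel_size: int = 21
    pool_size: int = 2
    pool_stride: int = 2
    dropout_p: float = 0.5
    learning_rate: float = 3e-4
    l2_weight: float = 1e-8
    n_channels: int = 3

    @property
    def embedding_dim(self) -> int:
        return self.conv_filters[-1]

    def min_input_len(self) -> int:
        k = self.kernel_size
        # conv1 valid -> pool/2 -> conv2 valid -> conv3 valid, each needs >= 1 output
        return ((k - 1) + (k - 1) + 1) * self.pool_stride + (k - 1) + 1


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class ConvNet1D:
    """3-channel time series -> scalar probability, with a pre-head embedding.

    Weight layout: conv weights ``W{i}`` have shape (kernel, in_ch, out_ch);
    the dense head ``Wd`` maps the pooled embedding to a logit.
    """

    def __init__(self, spec: CNNSpec | None = None, input_len: int = 240,
                 seed: int = 0):
        self.spec = spec or CNNSpec()
        s = self.spec
        if input_len < s.min_input_len():
            raise ValueError(
                f"input length {input_len} shorter than the receptive chain; "
                f"minimum is {s.min_input_len()} minutes")
        self.input_len = input_len
        rng = np.random.default_rng(seed)
        k = s.kernel_size
        f1, f2, f3 = s.conv_filters
        c = s.n_channels
        self.params = {
            "W1": _he_init(rng, (k, c, f1), k * c), "b1": np.zeros(f1),
            "W2": _he_init(rng, (k, f1, f2), k * f1), "b2": np.zeros(f2),
            "W3": _he_init(rng, (k, f2, f3), k * f2), "b3": np.zeros(f3),
            "Wd": _he_init(rng, (f3,), f3), "bd": np.zeros(1),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    # -- primitive ops -----------------------------------------------------
    @staticmethod
    def _im2col(x: np.ndarray, K: int) -> np.ndarray:
        """(B, L, C) -> contiguous (B, L-K+1, K*C) patch matrix."""
        win = sliding_window_view(x, K, axis=1)          # (B, L', C, K)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], x.shape[1] - K + 1, K * x.shape[2])

    @classmethod
    def _conv(cls, x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Valid 1D conv: (B, L, C) x (K, C, F) -> (B, L-K+1, F)."""
        K, C, F = W.shape
        return cls._im2col(x, K) @ W.reshape(K * C, F) + b

    @classmethod
    def _conv_input_grad(cls, dz: np.ndarray, W: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. conv input: full correlation with flipped kernel."""
        K, C, F = W.shape
        dzp = np.pad(dz, ((0, 0), (K - 1, K - 1), (0, 0)))
        cols = cls._im2col(dzp, K)                       # (B, L, K*F)
        Wf = np.ascontiguousarray(W[::-1]).transpose(0, 2, 1).reshape(K * F, C)
        return cols @ Wf

    @classmethod
    def _conv_weight_grad(cls, x: np.ndarray, dz: np.ndarray, K: int) -> np.ndarray:
        cols = cls._im2col(x, K)                         # (B, L', K*C)
        B, Lp, KC = cols.shape
        F = dz.shape[2]
        g = cols.reshape(B * Lp, KC).T @ dz.reshape(B * Lp, F)
        return g.reshape(K, x.shape[2], F)

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Probabilities for a batch of (B, L, 3) windows."""
        p, cache = self._forward_full(x, train=train, rng=rng)
        self._cache = cache
        return p

    def _forward_full(self, x, train, rng):
        P = self.params
        s = self.spec
        z1 = self._conv(x, P["W1"], P["b1"])
        a1 = np.maximum(z1, 0.0)
        # max pool size/stride 2 (drop trailing odd element)
        Lp = (a1.shape[1] // s.pool_stride) * s.pool_stride
        pooled_in = a1[:, :Lp].reshape(a1.shape[0], Lp // 2, 2, a1.shape[2])
        argmax = pooled_in.argmax(axis=2)
        a1p = pooled_in.max(axis=2)
        z2 = self._conv(a1p, P["W2"], P["b2"])
        a2 = np.maximum(z2, 0.0)
        z3 = self._conv(a2, P["W3"], P["b3"])
        a3 = np.maximum(z3, 0.0)
        g = a3.mean(axis=1)                               # global average pool
        if train and s.dropout_p > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = (rng.random(g.shape) >= s.dropout_p) / (1.0 - s.dropout_p)
        else:
            keep = np.ones_like(g)
        gd = g * keep
        logit = gd @ P["Wd"] + P["bd"][0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        cache = dict(x=x, z1=z1, pooled_in=pooled_in, argmax=argmax, a1p=a1p,
                     z2=z2, a2=a2, z3=z3, a3=a3, g=g, keep=keep, gd=gd,
                     prob=prob, Lp=Lp)
        return prob, cache

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Post-pooling embedding (B, F3): dropout and the head removed."""
        p, cache = self._forward_full(x, train=False, rng=None)
        return cache["g"]

    # -- backward / update ---------------------------------------------------
    def train_batch(self, x: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator) -> float:
        """One BCE + Adam step on a batch; returns the batch loss."""
        loss, grads = self._backward(x, y, rng)
        self._adam_step(grads)
        return loss

    def _backward(self, x: np.ndarray, y: np.ndarray,
                  rng: np.random.Generator) -> tuple[float, dict]:
        P = self.params
        s = self.spec
        prob, c = self._forward_full(x, train=True, rng=rng)
        B = x.shape[0]
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps)
                              + (1 - y) * np.log(1 - prob + eps)))

        dlogit = (prob - y) / B                          # (B,)
        g = {}
        g["Wd"] = c["gd"].T @ dlogit
        g["bd"] = np.array([dlogit.sum()])
        dgd = np.outer(dlogit, P["Wd"])
        dg = dgd * c["keep"]
        da3 = np.repeat(dg[:, None, :], c["a3"].shape[1], axis=1) / c["a3"].shape[1]
        dz3 = da3 * (c["z3"] > 0)
        g["W3"] = self._conv_weight_grad(c["a2"], dz3, s.kernel_size)
        g["b3"] = dz3.sum(axis=(0, 1))
        da2 = self._conv_input_grad(dz3, P["W3"])
        dz2 = da2 * (c["z2"] > 0)
        g["W2"] = self._conv_weight_grad(c["a1p"], dz2, s.kernel_size)
        g["b2"] = dz2.sum(axis=(0, 1))
        da1p = self._conv_input_grad(dz2, P["W2"])
        # un-pool: route gradient to argmax positions
        dpool = np.zeros_like(c["pooled_in"])
        bidx, tidx, fidx = np.meshgrid(np.arange(dpool.shape[0]),
                                       np.arange(dpool.shape[1]),
                                       np.arange(dpool.shape[3]), indexing="ij")
        dpool[bidx, tidx, c["argmax"], fidx] = da1p
        da1 = np.zeros_like(c["z1"])
        da1[:, :c["Lp"]] = dpool.reshape(dpool.shape[0], c["Lp"], dpool.shape[3])
        dz1 = da1 * (c["z1"] > 0)
        g["W1"] = self._conv_weight_grad(c["x"], dz1, s.kernel_size)
        g["b1"] = dz1.sum(axis=(0, 1))

        for name in ("W1", "W2", "W3", "Wd"):            # L2 on non-bias params
            g[name] = g[name] + s.l2_weight * P[name]
        return loss, g

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        lr = self.spec.learning_rate
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- utilities -----------------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(BCE loss, accuracy) without dropout."""
        prob = self.forward(x, train=False)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        acc = float(np.mean((prob >= 0.5) == (y >= 0.5)))
        return loss, acc

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


def build_cnn(spec: CNNSpec | None = None, input_len: int = 240,
              seed: int = 0) -> ConvNet1D:
    """Construct the discriminator; raises if the input is too short,
    reporting the minimum feasible length."""
    return ConvNet1D(spec=spec, input_len=input_len, seed=seed)
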