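"""Minimal convolutional network engine (numpy, manual backprop).

Implements exactly the pieces the splice-site classifier needs: unpadded
1-D convolution, ReLU, inverted dropout, max-pooling (size 2, stride 2),
dense layers, softmax cross-entropy and the Adamax update rule.  Everything
is float32 and deterministic given the seeding generator.

The convolution is im2col-based: patches are gathered with a stride-tricks
sliding window and the layer reduces to one matmul, which keeps training a
~150k-parameter model tractable on a single CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D:
    """Unpadded ("valid") 1-D convolution, stride 1, with ReLU activation."""

    def __init__(self, rng: np.random.Generator, in_channels: int,
                 out_channels: int, kernel: int):
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = kernel * in_channels
        self.W = glorot_uniform(rng, fan_in, out_channels, (fan_in, out_channels))
        self.b = np.zeros(out_channels, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def out_length(self, L: int) -> int:
        return L - self.kernel + 1

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        # x: (N, L, Cin) -> a: (N, Lout, Cout), ReLU applied
        K = self.kernel
        cols = sliding_window_view(x, K, axis=1)          # (N, Lout, Cin, K)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
        N, Lout = cols.shape[:2]
        cols = cols.reshape(N, Lout, K * self.in_channels)
        z = cols @ self.W + self.b
        a = np.maximum(z, 0.0)
        if cache is not None:
            cache["cols"] = cols
            cache["relu_mask"] = z > 0.0
            cache["in_length"] = x.shape[1]
        return a

    def backward(self, da: np.ndarray, cache: dict,
                 grads: dict | None = None) -> np.ndarray:
        dz = da * cache["relu_mask"]
        cols = cache["cols"]
        N, Lout, KC = cols.shape
        if grads is not None:
            grads["W"] = cols.reshape(-1, KC).T @ dz.reshape(-1, self.out_channels)
            grads["b"] = dz.sum(axis=(0, 1))
        dcols = dz @ self.W.T                              # (N, Lout, K*Cin)
        dcols = dcols.reshape(N, Lout, self.kernel, self.in_channels)
        dx = np.zeros((N, cache["in_length"], self.in_channels), dtype=np.float32)
        for k in range(self.kernel):
            dx[:, k:k + Lout, :] += dcols[:, :, k, :]
        return dx


class MaxPool2:
    """Max-pooling of size 2 with stride 2; an odd trailing position is dropped."""

    @staticmethod
    def out_length(L: int) -> int:
        return L // 2

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        N, L, C = x.shape
        Lp = L // 2
        xr = x[:, :2 * Lp].reshape(N, Lp, 2, C)
        idx = xr.argmax(axis=2)
        out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if cache is not None:
            cache["idx"] = idx
            cache["in_length"] = L
        return out

    def backward(self, dy: np.ndarray, cache: dict) -> np.ndarray:
        N, Lp, C = dy.shape
        dxr = np.zeros((N, Lp, 2, C), dtype=np.float32)
        np.put_along_axis(dxr, cache["idx"][:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((N, cache["in_length"], C), dtype=np.float32)
        dx[:, :2 * Lp] = dxr.reshape(N, 2 * Lp, C)
        return dx


class Dropout:
    """Inverted dropout; identity when inactive (inference)."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None,
                cache: dict | None = None) -> np.ndarray:
        if rng is None or self.rate == 0.0:
            if cache is not None:
                cache["mask"] = None
            return x
        mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        if cache is not None:
            cache["mask"] = mask
        return x * mask

    def backward(self, dy: np.ndarray, cache: dict) -> np.ndarray:
        mask = cache["mask"]
        return dy if mask is None else dy * mask


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 relu: bool):
        self.relu = relu
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        z = x @ self.W + self.b
        a = np.maximum(z, 0.0) if self.relu else z
        if cache is not None:
            cache["x"] = x
            cache["relu_mask"] = (z > 0.0) if self.relu else None
        return a

    def backward(self, da: np.ndarray, cache: dict,
                 grads: dict | None = None) -> np.ndarray:
        dz = da * cache["relu_mask"] if self.relu else da
        if grads is not None:
            grads["W"] = cache["x"].T @ dz
            grads["b"] = dz.sum(axis=0)
        return dz @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(-np.log(p).mean())


class Adamax:
    """Adamax: Adam with an infinity-norm second moment.

    theta <- theta - (lr / (1 - beta1^t)) * m / (u + eps)
    """

    def __init__(self, params: list[dict], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params  # list of {"layer": obj, "name": "W"|"b"}
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(getattr(p["layer"], p["name"])) for p in params]
        self.u = [np.zeros_like(getattr(p["layer"], p["name"])) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bias = 1.0 - self.beta1 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.u[i] = np.maximum(self.beta2 * self.u[i], np.abs(g))
            theta = getattr(p["layer"], p["name"])
            theta -= (self.lr / bias) * self.m[i] / (self.u[i] + self.eps)


class ConvNet:
    """The splice-site network: conv blocks (conv+ReLU -> dropout -> pool),
    flatten, dense(ReLU), dense(softmax).

    ``conv_filters``/``conv_kernels`` may be shorter than the canonical three
    blocks when the input is too short for the full stack.
    """

    def __init__(self, input_length: int, conv_filters: tuple[int, ...],
                 conv_kernels: tuple[int, ...], dropout_rate: float,
                 dense_units: int, n_classes: int, seed: int):
        rng = np.random.Generator(np.random.PCG64(seed))
        self.input_length = input_length
        self.dropout = Dropout(dropout_rate)
        self.convs: list[Conv1D] = []
        L, C = input_length, 4
        for filters, kernel in zip(conv_filters, conv_kernels):
            if L < kernel:
                raise ValueError(
                    f"spatial length {L} too short for kernel {kernel}")
            conv = Conv1D(rng, C, filters, kernel)
            self.convs.append(conv)
            L = MaxPool2.out_length(conv.out_length(L))
            C = filters
            if L < 1:
                raise ValueError("network collapsed to zero spatial positions")
        self.pool = MaxPool2()
        self.flat_width = L * C
        self.conv_out_length = L
        self.dense1 = Dense(rng, self.flat_width, dense_units, relu=True)
        self.dense2 = Dense(rng, dense_units, n_classes, relu=False)

    # -- parameter plumbing --------------------------------------------------
    def _layers_with_params(self) -> list:
        return [*self.convs, self.dense1, self.dense2]

    def param_refs(self) -> list[dict]:
        return [{"layer": layer, "name": name}
                for layer in self._layers_with_params() for name in ("W", "b")]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self._layers_with_params())

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, conv in enumerate(self.convs):
            out[f"conv{i}_W"], out[f"conv{i}_b"] = conv.W, conv.b
        out["dense1_W"], out["dense1_b"] = self.dense1.W, self.dense1.b
        out["dense2_W"], out["dense2_b"] = self.dense2.W, self.dense2.b
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self.convs):
            conv.W = weights[f"conv{i}_W"].astype(np.float32).copy()
            conv.b = weights[f"conv{i}_b"].astype(np.float32).copy()
        self.dense1.W = weights["dense1_W"].astype(np.float32).copy()
        self.dense1.b = weights["dense1_b"].astype(np.float32).copy()
        self.dense2.W = weights["dense2_W"].astype(np.float32).copy()
        self.dense2.b = weights["dense2_b"].astype(np.float32).copy()

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train_rng: np.random.Generator | None = None,
                caches: list[dict] | None = None) -> np.ndarray:
        """x: (N, W, 4) -> logits (N, n_classes).  Dropout only when a
        training rng is supplied."""
        h = x
        for conv in self.convs:
            c_conv, c_drop, c_pool = {}, {}, {}
            h = conv.forward(h, c_conv if caches is not None else None)
            h = self.dropout.forward(h, train_rng, c_drop if caches is not None else None)
            h = self.pool.forward(h, c_pool if caches is not None else None)
            if caches is not None:
                caches.append((c_conv, c_drop, c_pool))
        N = h.shape[0]
        flat = h.reshape(N, -1)
        c_d1, c_d2 = {}, {}
        h1 = self.dense1.forward(flat, c_d1 if caches is not None else None)
        logits = self.dense2.forward(h1, c_d2 if caches is not None else None)
        if caches is not None:
            caches.append((c_d1, c_d2, h.shape))
        return logits

    def backward(self, dlogits: np.ndarray, caches: list) -> list[np.ndarray]:
        """Return parameter gradients in the order of :meth:`param_refs`."""
        c_d1, c_d2, conv_out_shape = caches[-1]
        g_d2: dict = {}
        dh1 = self.dense2.backward(dlogits, c_d2, g_d2)
        g_d1: dict = {}
        dflat = self.dense1.backward(dh1, c_d1, g_d1)
        dh = dflat.reshape(conv_out_shape)
        conv_grads: list[dict] = []
        for conv, (c_conv, c_drop, c_pool) in zip(reversed(self.convs),
                                                  reversed(caches[:-1])):
            dh = self.pool.backward(dh, c_pool)
            dh = self.dropout.backward(dh, c_drop)
            g: dict = {}
            dh = conv.backward(dh, c_conv, g)
            conv_grads.append(g)
        conv_grads.reverse()
        grads: list[np.ndarray] = []
        for g in conv_grads:
            grads.extend([g["W"], g["b"]])
        grads.extend([g_d1["W"], g_d1["b"], g_d2["W"], g_d2["b"]])
        return grads

    def predict_proba(self, x: np.ndarray, chunk: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(x), chunk):
            out.append(softmax(self.forward(x[i:i + chunk])))
        return np.concatenate(out, axis=0)

    def last_conv_receptive_field(self) -> tuple[int, int]:
        """(stride, width) of the last conv layer's units in input coordinates.

        Walking down from the last conv: crossing a 2/2 max-pool doubles both
        the receptive width and the stride; crossing a conv adds kernel-1 to
        the width.  For the canonical 200-nt stack this yields stride 4,
        width 40.
        """
        r, s = self.convs[-1].kernel, 1
        for conv in reversed(self.convs[:-1]):
            r, s = 2 * r, 2 * s          # pool between blocks
            r = r + conv.kernel - 1
        return s, r

    # -- Grad-CAM ------------------------------------------------------------
    def gradcam_raw(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """Per-sample class-activation maps at the last conv layer.

        Returns an (N, L_conv) array: ReLU of the gradient-weighted channel
        sum of the last convolutional activation map (post-ReLU, pre-pool),
        computed from the pre-softmax logit of ``target_class``.
        """
        caches: list = []
        logits = self.forward(x, train_rng=None, caches=caches)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        c_d1, c_d2, conv_out_shape = caches[-1]
        dh1 = self.dense2.backward(dlogits, c_d2, None)
        dflat = self.dense1.backward(dh1, c_d1, None)
        dh = dflat.reshape(conv_out_shape)
        # walk back through pooling of the final block to the conv activation
        c_conv, c_drop, c_pool = caches[len(self.convs) - 1]
        dh = self.pool.backward(dh, c_pool)
        da = self.dropout.backward(dh, c_drop)       # identity at inference
        # activation of the last conv layer (post-ReLU), from cached columns
        z = c_conv["cols"] @ self.convs[-1].W + self.convs[-1].b
        act = np.maximum(z, 0.0)                     # (N, L_conv, C)
        alpha = da.mean(axis=1, keepdims=True)       # (N, 1, C) channel weights
        cam = np.maximum((alpha * act).sum(axis=2), 0.0)  # (N, L_conv)
        return cam
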