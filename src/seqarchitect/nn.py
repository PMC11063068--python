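"""Numpy training backend for architecture plans.

Implements the layer vocabulary the builder emits — same-padded dilated 1-D
convolution, batch normalization, leaky ReLU, strided max-pooling, global
average pooling, LSTM/GRU stacks, dense layers with dropout — together with
manual backpropagation and the four stochastic optimizers (Adam, Adagrad,
RMSprop, SGD).  Activations flow as (batch, channels, length) arrays;
gradients accumulate into each layer's ``grads`` dict, which lets the
shared-weight two-strand (reverse-complement) trunk backpropagate by simply
running backward once per strand.

Correctness of every backward pass is pinned by numeric gradient checks in
the test suite.
"""

from __future__ import annotations

import numpy as np

from .build import ArchitecturePlan, GapHead, RnnHead, count_parameters, embedding_width
from .errors import BuildError

_EPS = 1e-5


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameters and accumulated gradients live in two dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self):
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1d(Layer):
    """Same-padded dilated cross-correlation along the sequence axis."""

    def __init__(self, in_ch, out_ch, kernel, dilation, rng):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.dilation = kernel, dilation
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.params["W"] = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.params["b"] = np.zeros(out_ch)
        self.zero_grads()

    def _window_view(self, xp, L):
        """Zero-copy (B, C, L, K) sliding-window view of the padded input."""
        B, C, _ = xp.shape
        sB, sC, sL = xp.strides
        return np.lib.stride_tricks.as_strided(
            xp, (B, C, L, self.kernel), (sB, sC, sL, sL * self.dilation), writeable=False
        )

    def forward(self, x, training=False, rng=None):
        B, C, L = x.shape
        ext = self.dilation * (self.kernel - 1) + 1
        pl = (ext - 1) // 2
        pr = ext - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = self._window_view(xp, L)
        y = np.einsum("bclt,oct->bol", cols, self.params["W"], optimize=True)
        y += self.params["b"][None, :, None]
        return y, (xp, x.shape, pl)

    def backward(self, dy, cache):
        xp, xshape, pl = cache
        B, C, L = xshape
        cols = self._window_view(xp, L)
        self.grads["b"] += dy.sum(axis=(0, 2))
        self.grads["W"] += np.einsum("bclt,bol->oct", cols, dy, optimize=True)
        dcols = np.einsum("bol,oct->bclt", dy, self.params["W"], optimize=True)
        dxp = np.zeros_like(xp)
        for t in range(self.kernel):
            lo = t * self.dilation
            dxp[:, :, lo : lo + L] += dcols[:, :, :, t]
        return dxp[:, :, pl : pl + L]


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and positions.

    ``momentum`` follows the Keras convention: running statistics are
    updated as running = momentum * running + (1 - momentum) * batch.
    """

    def __init__(self, channels, momentum):
        super().__init__()
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        y = self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]
        return y, (xhat, inv, training)

    def backward(self, dy, cache):
        xhat, inv, training = cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] += dy.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None] * inv[None, :, None]
        if not training:
            return dy * g
        m = dy.mean(axis=(0, 2), keepdims=True)
        mx = (dy * xhat).mean(axis=(0, 2), keepdims=True)
        return g * (dy - m - xhat * mx)


class LeakyReLU(Layer):
    def __init__(self, alpha):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        y = np.where(x > 0, x, self.alpha * x)
        return y, (x > 0)

    def backward(self, dy, cache):
        return dy * np.where(cache, 1.0, self.alpha)


class MaxPool1d(Layer):
    """Non-overlapping max pooling with stride = kernel = factor."""

    def __init__(self, factor):
        super().__init__()
        self.factor = factor

    def forward(self, x, training=False, rng=None):
        B, C, L = x.shape
        f = self.factor
        Lo = L // f
        if Lo < 1:
            raise BuildError(f"cannot pool length {L} by factor {f}")
        xt = x[:, :, : Lo * f].reshape(B, C, Lo, f)
        idx = xt.argmax(axis=-1)
        y = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
        return y, (idx, x.shape)

    def backward(self, dy, cache):
        idx, xshape = cache
        B, C, L = xshape
        f = self.factor
        Lo = L // f
        dxt = np.zeros((B, C, Lo, f), dtype=dy.dtype)
        np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(xshape, dtype=dy.dtype)
        dx[:, :, : Lo * f] = dxt.reshape(B, C, Lo * f)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, training=False, rng=None):
        return x.mean(axis=2), x.shape

    def backward(self, dy, cache):
        B, C, L = cache
        return np.repeat(dy[:, :, None], L, axis=2) / L


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.params["W"] = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim)
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, dy, cache):
        x = cache
        self.grads["W"] += x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Activation(Layer):
    def __init__(self, kind):
        super().__init__()
        self.kind = kind

    def forward(self, x, training=False, rng=None):
        if self.kind == "relu":
            y = np.maximum(x, 0.0)
        elif self.kind == "tanh":
            y = np.tanh(x)
        elif self.kind == "sigmoid":
            y = _sigmoid(x)
        else:
            raise ValueError(f"unknown activation {self.kind!r}")
        return y, (x, y)

    def backward(self, dy, cache):
        x, y = cache
        if self.kind == "relu":
            return dy * (x > 0)
        if self.kind == "tanh":
            return dy * (1.0 - y * y)
        return dy * y * (1.0 - y)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0.0:
            return x, None
        keep = 1.0 - self.rate
        mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * mask, mask

    def backward(self, dy, cache):
        if cache is None:
            return dy
        return dy * cache


class _RecurrentDirection(Layer):
    """One direction of an LSTM or GRU layer, full BPTT."""

    def __init__(self, cell, in_dim, units, rng):
        super().__init__()
        self.cell = cell
        self.units = units
        g = 4 if cell == "lstm" else 3
        k = np.sqrt(1.0 / units)
        self.params["Wx"] = rng.uniform(-k, k, size=(in_dim, g * units))
        self.params["Wh"] = rng.uniform(-k, k, size=(units, g * units))
        self.params["b"] = np.zeros(g * units)
        if cell == "lstm":
            self.params["b"][units : 2 * units] = 1.0  # forget-gate bias
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        # x: (B, L, in_dim); returns hs: (B, L, units)
        B, L, _ = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, u), dtype=x.dtype)
        hs = np.empty((B, L, u), dtype=x.dtype)
        steps = []
        if self.cell == "lstm":
            c = np.zeros((B, u), dtype=x.dtype)
            for t in range(L):
                z = x[:, t] @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :u])
                f = _sigmoid(z[:, u : 2 * u])
                g = np.tanh(z[:, 2 * u : 3 * u])
                o = _sigmoid(z[:, 3 * u :])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h = o * tc
                hs[:, t] = h
                steps.append((x[:, t], i, f, g, o, c, tc))
                c = c_new
        else:
            for t in range(L):
                az = x[:, t] @ Wx[:, :u] + h @ Wh[:, :u] + b[:u]
                ar = x[:, t] @ Wx[:, u : 2 * u] + h @ Wh[:, u : 2 * u] + b[u : 2 * u]
                zt = _sigmoid(az)
                rt = _sigmoid(ar)
                hWhn = h @ Wh[:, 2 * u :]
                an = x[:, t] @ Wx[:, 2 * u :] + rt * hWhn + b[2 * u :]
                nt = np.tanh(an)
                h_new = (1.0 - zt) * nt + zt * h
                hs[:, t] = h_new
                steps.append((x[:, t], zt, rt, nt, hWhn, h))
                h = h_new
        return hs, (steps, x.shape)

    def backward(self, dhs, cache):
        steps, xshape = cache
        B, L, in_dim = xshape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dt = dhs.dtype
        dx = np.zeros(xshape, dtype=dt)
        dh_next = np.zeros((B, u), dtype=dt)
        if self.cell == "lstm":
            dc_next = np.zeros((B, u), dtype=dt)
            for t in range(L - 1, -1, -1):
                xt, i, f, g, o, c_prev, tc = steps[t]
                # h_prev = o_{t-1} * tanh(c_{t-1}), recomputed from cached pieces
                h_prev = (
                    steps[t - 1][4] * steps[t - 1][6]
                    if t > 0
                    else np.zeros((B, u), dtype=dt)
                )
                dh = dhs[:, t] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        dg * (1 - g * g),
                        do * o * (1 - o),
                    ],
                    axis=1,
                )
                self.grads["Wx"] += xt.T @ dz
                self.grads["Wh"] += h_prev.T @ dz
                self.grads["b"] += dz.sum(axis=0)
                dh_next = dz @ Wh.T
                dx[:, t] = dz @ Wx.T
        else:
            for t in range(L - 1, -1, -1):
                xt, zt, rt, nt, hWhn, h_prev = steps[t]
                dh = dhs[:, t] + dh_next
                dn = dh * (1.0 - zt)
                dz = dh * (h_prev - nt)
                dh_prev = dh * zt
                dan = dn * (1.0 - nt * nt)
                dr = dan * hWhn
                dh_prev += (dan * rt) @ Wh[:, 2 * u :].T
                self.grads["Wh"][:, 2 * u :] += h_prev.T @ (dan * rt)
                daz = dz * zt * (1 - zt)
                dar = dr * rt * (1 - rt)
                self.grads["Wx"][:, :u] += xt.T @ daz
                self.grads["Wx"][:, u : 2 * u] += xt.T @ dar
                self.grads["Wx"][:, 2 * u :] += xt.T @ dan
                self.grads["Wh"][:, :u] += h_prev.T @ daz
                self.grads["Wh"][:, u : 2 * u] += h_prev.T @ dar
                self.grads["b"][:u] += daz.sum(axis=0)
                self.grads["b"][u : 2 * u] += dar.sum(axis=0)
                self.grads["b"][2 * u :] += dan.sum(axis=0)
                dh_prev += daz @ Wh[:, :u].T + dar @ Wh[:, u : 2 * u].T
                dh_next = dh_prev
                dx[:, t] = daz @ Wx[:, :u].T + dar @ Wx[:, u : 2 * u].T + dan @ Wx[:, 2 * u :].T
        return dx


class Recurrent(Layer):
    """LSTM/GRU layer returning per-position outputs, optionally bidirectional.

    Consumes and produces (batch, channels, length) to compose with the
    convolutional trunk; channels of the output are units (× 2 if
    bidirectional).
    """

    def __init__(self, cell, in_dim, units, bidirectional, rng):
        super().__init__()
        self.bidirectional = bidirectional
        self.fwd = _RecurrentDirection(cell, in_dim, units, rng)
        self.bwd = _RecurrentDirection(cell, in_dim, units, rng) if bidirectional else None

    @property
    def directions(self):
        return [self.fwd] + ([self.bwd] if self.bwd is not None else [])

    def zero_grads(self):
        for d in self.directions:
            d.zero_grads()

    @property
    def n_params(self):
        return sum(d.n_params for d in self.directions)

    def forward(self, x, training=False, rng=None):
        xt = np.swapaxes(x, 1, 2)  # (B, L, C)
        hf, cf = self.fwd.forward(xt, training, rng)
        if self.bwd is None:
            return np.swapaxes(hf, 1, 2), (cf, None)
        hb, cb = self.bwd.forward(xt[:, ::-1], training, rng)
        h = np.concatenate([hf, hb[:, ::-1]], axis=2)
        return np.swapaxes(h, 1, 2), (cf, cb)

    def backward(self, dy, cache):
        cf, cb = cache
        dht = np.swapaxes(dy, 1, 2)  # (B, L, C)
        u = self.fwd.units
        dx = self.fwd.backward(dht[:, :, :u], cf)
        if self.bwd is not None:
            dx = dx + self.bwd.backward(dht[:, ::-1, u:], cb)[:, ::-1]
        return np.swapaxes(dx, 1, 2)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache):
        return dy.reshape(cache)


# ---------------------------------------------------------------------------
# Optimizers


class Optimizer:
    """Updates every trainable parameter of a model in place."""

    def __init__(self, model):
        self.slots = [(layer, name) for layer in model.trainable_layers for name in layer.params]
        self.state = {}

    def step(self, learning_rate):
        for key, (layer, name) in enumerate(self.slots):
            g = layer.grads[name]
            layer.params[name] -= self._delta(key, g, learning_rate)

    def _delta(self, key, g, lr):
        raise NotImplementedError


class SGD(Optimizer):
    def _delta(self, key, g, lr):
        return lr * g


class Adam(Optimizer):
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def _delta(self, key, g, lr):
        m, v, t = self.state.get(key, (0.0, 0.0, 0))
        t += 1
        m = self.beta1 * m + (1 - self.beta1) * g
        v = self.beta2 * v + (1 - self.beta2) * g * g
        self.state[key] = (m, v, t)
        mhat = m / (1 - self.beta1 ** t)
        vhat = v / (1 - self.beta2 ** t)
        return lr * mhat / (np.sqrt(vhat) + self.eps)


class Adagrad(Optimizer):
    eps = 1e-8

    def _delta(self, key, g, lr):
        acc = self.state.get(key, 0.0) + g * g
        self.state[key] = acc
        return lr * g / (np.sqrt(acc) + self.eps)


class RMSprop(Optimizer):
    rho, eps = 0.9, 1e-8

    def _delta(self, key, g, lr):
        acc = self.rho * self.state.get(key, 0.0) + (1 - self.rho) * g * g
        self.state[key] = acc
        return lr * g / (np.sqrt(acc) + self.eps)


OPTIMIZERS = {"sgd": SGD, "adam": Adam, "adagrad": Adagrad, "rmsprop": RMSprop}


def make_optimizer(name: str, model) -> Optimizer:
    try:
        return OPTIMIZERS[name.lower()](model)
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None


# ---------------------------------------------------------------------------
# Model


def _reverse_complement_onehot(x):
    """(B, L, 4) one-hot → other strand: positions reversed, A↔T / C↔G."""
    return x[:, ::-1, ::-1]


class SequenceModel:
    """A trainable network realized from an :class:`ArchitecturePlan`.

    Supports single-step fitting (``fit_step``), batch prediction with
    normalized class scores (``predict_proba``), and exposes
    ``trainable_count`` for cross-checking the closed-form parameter
    accounting.  When the plan requests reverse-complement input, both
    strands pass through the same trunk weights and the two embeddings are
    concatenated before the dense stack.
    """

    def __init__(self, plan: ArchitecturePlan, seed: int | None = 0, dtype=np.float64):
        self.plan = plan
        self.rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype)
        rng = self.rng

        self.conv_ops = []  # per conv layer: (conv, bn, act)
        self.pools = []  # per conv layer: MaxPool1d | None
        self.skip_pools = []  # per block: MaxPool1d | None
        self.skip_projs = []  # per block: Conv1d(k=1) | None

        in_ch = plan.alphabet_size
        li = 0
        for block in plan.conv_blocks:
            block_in = in_ch
            pool_prod = 1
            for layer in block.layers:
                conv = Conv1d(in_ch, layer.filters, layer.kernel, layer.dilation, rng)
                bn = BatchNorm1d(layer.filters, layer.batchnorm_momentum)
                act = LeakyReLU(layer.leaky_alpha)
                self.conv_ops.append((conv, bn, act))
                f = plan.pool_after[li]
                self.pools.append(MaxPool1d(f) if f > 1 else None)
                pool_prod *= f
                in_ch = layer.filters
                li += 1
            if block.residual:
                self.skip_pools.append(MaxPool1d(pool_prod) if pool_prod > 1 else None)
                self.skip_projs.append(
                    Conv1d(block_in, in_ch, 1, 1, rng) if block_in != in_ch else None
                )
            else:
                self.skip_pools.append(None)
                self.skip_projs.append(None)

        self.gap = GlobalAvgPool()
        self.rnn_layers = []
        if isinstance(plan.head, RnnHead):
            rnn_in = in_ch
            dirs = 2 if plan.head.bidirectional else 1
            for _ in range(plan.head.n_layers):
                self.rnn_layers.append(
                    Recurrent(plan.head.cell, rnn_in, plan.head.units, plan.head.bidirectional, rng)
                )
                rnn_in = plan.head.units * dirs
        self.flatten = Flatten()

        width = embedding_width(plan) * (2 if plan.use_reverse_complement else 1)
        self.dense_ops = []  # (dense, act, dropout)
        for spec in plan.dense_stack:
            dense = Dense(width, spec.units, rng)
            self.dense_ops.append((dense, Activation(spec.activation), Dropout(spec.dropout)))
            width = spec.units
        self.out_dense = Dense(width, plan.n_classes, rng)

        if self.dtype != np.float64:
            for layer in self.trainable_layers:
                for k in layer.params:
                    layer.params[k] = layer.params[k].astype(self.dtype)
                layer.zero_grads()
                if isinstance(layer, BatchNorm1d):
                    layer.running_mean = layer.running_mean.astype(self.dtype)
                    layer.running_var = layer.running_var.astype(self.dtype)

    # -- parameter bookkeeping ------------------------------------------------

    @property
    def trainable_layers(self):
        layers = []
        for conv, bn, _ in self.conv_ops:
            layers.extend([conv, bn])
        for proj in self.skip_projs:
            if proj is not None:
                layers.append(proj)
        for r in self.rnn_layers:
            layers.extend(r.directions)
        for dense, _, _ in self.dense_ops:
            layers.append(dense)
        layers.append(self.out_dense)
        return layers

    @property
    def trainable_count(self) -> int:
        return sum(l.n_params for l in self.trainable_layers)

    def zero_grads(self):
        for l in self.trainable_layers:
            l.zero_grads()

    # -- forward / backward ---------------------------------------------------

    def _embed_strand(self, xc, training):
        """Trunk + embedding for one (B, 4, L) strand; returns (emb, caches)."""
        plan = self.plan
        cur = xc
        block_caches = []
        block_outputs = []
        li = 0
        for bi, block in enumerate(plan.conv_blocks):
            block_in = cur
            unit_caches = []
            for _ in block.layers:
                conv, bn, act = self.conv_ops[li]
                cur, c1 = conv.forward(cur, training, self.rng)
                cur, c2 = bn.forward(cur, training, self.rng)
                cur, c3 = act.forward(cur, training, self.rng)
                pool = self.pools[li]
                if pool is not None:
                    cur, c4 = pool.forward(cur, training, self.rng)
                else:
                    c4 = None
                unit_caches.append((c1, c2, c3, c4))
                li += 1
            res_cache = None
            if block.residual:
                skip = block_in
                cps = cpr = None
                if self.skip_pools[bi] is not None:
                    skip, cps = self.skip_pools[bi].forward(skip, training, self.rng)
                if self.skip_projs[bi] is not None:
                    skip, cpr = self.skip_projs[bi].forward(skip, training, self.rng)
                cur = cur + skip
                res_cache = (cps, cpr)
            block_caches.append((unit_caches, res_cache))
            block_outputs.append(cur)

        if isinstance(plan.head, GapHead):
            parts, gcaches = [], []
            for b in plan.head.tap_blocks:
                g, gc = self.gap.forward(block_outputs[b], training, self.rng)
                parts.append(g)
                gcaches.append(gc)
            emb = np.concatenate(parts, axis=1)
            head_cache = ("gap", gcaches)
        else:
            rcaches = []
            for r in self.rnn_layers:
                cur, rc = r.forward(cur, training, self.rng)
                rcaches.append(rc)
            emb, fc = self.flatten.forward(cur, training, self.rng)
            head_cache = ("rnn", rcaches, fc)
        return emb, (block_caches, head_cache)

    def _backward_strand(self, demb, cache):
        plan = self.plan
        block_caches, head_cache = cache
        n_blocks = len(plan.conv_blocks)
        dtap = {}
        if head_cache[0] == "gap":
            _, gcaches = head_cache
            offset = 0
            for b, gc in zip(plan.head.tap_blocks, gcaches):
                width = plan.conv_blocks[b].layers[-1].filters
                dtap[b] = self.gap.backward(demb[:, offset : offset + width], gc)
                offset += width
            dcur = 0.0
        else:
            _, rcaches, fc = head_cache
            dcur = self.flatten.backward(demb, fc)
            for r, rc in zip(reversed(self.rnn_layers), reversed(rcaches)):
                dcur = r.backward(dcur, rc)

        li = sum(len(b.layers) for b in plan.conv_blocks)
        for bi in range(n_blocks - 1, -1, -1):
            unit_caches, res_cache = block_caches[bi]
            if bi in dtap:
                dcur = dcur + dtap[bi] if not np.isscalar(dcur) else dtap[bi]
            dskip = None
            if res_cache is not None:
                cps, cpr = res_cache
                dskip = dcur
                if self.skip_projs[bi] is not None:
                    dskip = self.skip_projs[bi].backward(dskip, cpr)
                if self.skip_pools[bi] is not None:
                    dskip = self.skip_pools[bi].backward(dskip, cps)
            for uc in reversed(unit_caches):
                li -= 1
                conv, bn, act = self.conv_ops[li]
                c1, c2, c3, c4 = uc
                if self.pools[li] is not None:
                    dcur = self.pools[li].backward(dcur, c4)
                dcur = act.backward(dcur, c3)
                dcur = bn.backward(dcur, c2)
                dcur = conv.backward(dcur, c1)
            if dskip is not None:
                dcur = dcur + dskip
        return dcur

    def forward(self, x, training=False):
        """x: (B, L, 4) one-hot → (logits, cache)."""
        x = np.asarray(x, dtype=self.dtype)
        xc = np.ascontiguousarray(np.swapaxes(x, 1, 2))
        emb, c_main = self._embed_strand(xc, training)
        c_rc = None
        if self.plan.use_reverse_complement:
            xrc = np.ascontiguousarray(
                np.swapaxes(_reverse_complement_onehot(x), 1, 2)
            )
            emb_rc, c_rc = self._embed_strand(xrc, training)
            emb = np.concatenate([emb, emb_rc], axis=1)

        cur = emb
        dcaches = []
        for dense, act, drop in self.dense_ops:
            cur, cd = dense.forward(cur, training, self.rng)
            cur, ca = act.forward(cur, training, self.rng)
            cur, cr = drop.forward(cur, training, self.rng)
            dcaches.append((cd, ca, cr))
        logits, cout = self.out_dense.forward(cur, training, self.rng)
        return logits, (c_main, c_rc, dcaches, cout, emb.shape[1])

    def backward(self, dlogits, cache):
        c_main, c_rc, dcaches, cout, emb_width = cache
        d = self.out_dense.backward(dlogits, cout)
        for (dense, act, drop), (cd, ca, cr) in zip(reversed(self.dense_ops), reversed(dcaches)):
            d = drop.backward(d, cr)
            d = act.backward(d, ca)
            d = dense.backward(d, cd)
        if self.plan.use_reverse_complement:
            half = emb_width // 2
            self._backward_strand(d[:, :half], c_main)
            self._backward_strand(d[:, half:], c_rc)
        else:
            self._backward_strand(d, c_main)

    # -- training / inference -------------------------------------------------

    def loss_and_grads(self, x, y):
        """Multi-class cross-entropy; fills gradient accumulators."""
        self.zero_grads()
        logits, cache = self.forward(x, training=True)
        B = logits.shape[0]
        probs = softmax(logits)
        y = np.asarray(y, dtype=int)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        self.backward(dlogits, cache)
        return loss

    def fit_step(self, x, y, optimizer: Optimizer, learning_rate: float) -> float:
        loss = self.loss_and_grads(x, y)
        optimizer.step(learning_rate)
        return loss

    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self.forward(x, training=False)
        return softmax(logits)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
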