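"""Sequence-embedding layer families built on the autograd engine.

All layers operate on (batch, positions, channels) tensors and keep
positional structure; latent reduction to a fixed-width vector happens in
:func:`reduce_to_latent`.  Recurrent layers emit position-wise states, so
a bidirectional layer returns a (batch, positions × 2, width) tensor —
the forward scan's states followed by the backward scan's states in
processing order.  A residual connection spans every sequence-embedding
layer; when the layer changes the channel width the skip path is a
learned linear projection, and when a bidirectional layer doubles the
positional length the skip input is repeated along positions before the
projection.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d

__all__ = ["ParamStore", "dense", "sequence_layer", "reduce_to_latent"]


class ParamStore:
    """Lazily created, seeded parameter container.

    Parameters are materialized on first use in a fixed forward order, so
    a given seed always yields the same initialization.  Weights use a
    Glorot-style uniform fan-based scheme; biases start at zero.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.params: dict = {}

    def get(self, name: str, shape: tuple, init: str = "glorot") -> Tensor:
        if name in self.params:
            t = self.params[name]
            if t.data.shape != tuple(shape):
                raise ValueError(
                    f"parameter {name!r} exists with shape {t.data.shape}, "
                    f"requested {tuple(shape)}"
                )
            return t
        if init == "zeros":
            data = np.zeros(shape)
        elif init == "glorot":
            fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
            fan_out = shape[-1]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            data = self.rng.uniform(-limit, limit, size=shape)
        else:
            raise ValueError(f"unknown init {init!r}")
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            if k in self.params:
                if self.params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for parameter {k!r}")
                self.params[k].data = v.astype(np.float64).copy()
            else:
                self.params[k] = Tensor(v, requires_grad=True)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def dense(store: ParamStore, name: str, x: Tensor, out_dim: int,
          activation: str | None = None) -> Tensor:
    """Affine map on the last axis, with optional nonlinearity."""
    in_dim = x.shape[-1]
    w = store.get(f"{name}.w", (in_dim, out_dim))
    b = store.get(f"{name}.b", (out_dim,), init="zeros")
    y = x @ w + b
    if activation == "relu":
        y = y.relu()
    elif activation == "tanh":
        y = y.tanh()
    elif activation == "sigmoid":
        y = y.sigmoid()
    elif activation is not None:
        raise ValueError(f"unknown activation {activation!r}")
    return y


# ---------------------------------------------------------------------------
# Recurrent cells


def _gru_scan(store: ParamStore, name: str, x: Tensor, width: int) -> Tensor:
    """Unidirectional GRU scan; returns position-wise states (B, L, width)."""
    B, L, C = x.shape
    wz = store.get(f"{name}.wz", (C, width)); uz = store.get(f"{name}.uz", (width, width))
    bz = store.get(f"{name}.bz", (width,), init="zeros")
    wr = store.get(f"{name}.wr", (C, width)); ur = store.get(f"{name}.ur", (width, width))
    br = store.get(f"{name}.br", (width,), init="zeros")
    wh = store.get(f"{name}.wh", (C, width)); uh = store.get(f"{name}.uh", (width, width))
    bh = store.get(f"{name}.bh", (width,), init="zeros")
    h = Tensor(np.zeros((B, width)))
    states = []
    for t in range(L):
        xt = x[:, t, :]
        z = (xt @ wz + h @ uz + bz).sigmoid()
        r = (xt @ wr + h @ ur + br).sigmoid()
        hb = (xt @ wh + (r * h) @ uh + bh).tanh()
        h = z * h + (1.0 - z) * hb
        states.append(h.reshape(B, 1, width))
    return concat(states, axis=1)


def _lstm_scan(store: ParamStore, name: str, x: Tensor, width: int) -> Tensor:
    """Unidirectional LSTM scan; returns position-wise hidden states."""
    B, L, C = x.shape
    gates = {}
    for g in ("i", "f", "o", "c"):
        gates[g] = (
            store.get(f"{name}.w{g}", (C, width)),
            store.get(f"{name}.u{g}", (width, width)),
            store.get(f"{name}.b{g}", (width,), init="zeros"),
        )
    h = Tensor(np.zeros((B, width)))
    c = Tensor(np.zeros((B, width)))
    states = []
    for t in range(L):
        xt = x[:, t, :]
        i = (xt @ gates["i"][0] + h @ gates["i"][1] + gates["i"][2]).sigmoid()
        f = (xt @ gates["f"][0] + h @ gates["f"][1] + gates["f"][2] + 1.0).sigmoid()
        o = (xt @ gates["o"][0] + h @ gates["o"][1] + gates["o"][2]).sigmoid()
        cb = (xt @ gates["c"][0] + h @ gates["c"][1] + gates["c"][2]).tanh()
        c = f * c + i * cb
        h = o * c.tanh()
        states.append(h.reshape(B, 1, width))
    return concat(states, axis=1)


def _bidirectional(scan, store, name, x, width) -> Tensor:
    fwd = scan(store, f"{name}.fwd", x, width)
    bwd = scan(store, f"{name}.bwd", x.flip(1), width)
    return concat([fwd, bwd], axis=1)  # (B, 2L, width)


# ---------------------------------------------------------------------------
# Attention and convolutional blocks


def _softmax_lastaxis(x: Tensor) -> Tensor:
    shift = x - np.max(x.data, axis=-1, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=-1, keepdims=True)


def _self_attention(store: ParamStore, name: str, x: Tensor, width: int,
                    n_heads: int = 4) -> Tensor:
    """Multi-head self-attention without positional encodings."""
    B, L, C = x.shape
    if width % n_heads != 0:
        raise ValueError(f"attention width {width} not divisible by {n_heads} heads")
    dk = width // n_heads
    q = dense(store, f"{name}.q", x, width)
    k = dense(store, f"{name}.k", x, width)
    v = dense(store, f"{name}.v", x, width)

    def heads(t: Tensor) -> Tensor:
        return t.reshape(B, L, n_heads, dk).swapaxes(1, 2)  # (B, H, L, dk)

    qh, kh, vh = heads(q), heads(k), heads(v)
    scores = (qh @ kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
    attn = _softmax_lastaxis(scores)
    ctx = (attn @ vh).swapaxes(1, 2).reshape(B, L, width)
    return dense(store, f"{name}.out", ctx, width)


def _conv_block(store, name, x, width, kernel, activation="relu") -> Tensor:
    C = x.shape[-1]
    w = store.get(f"{name}.w", (kernel, C, width))
    b = store.get(f"{name}.b", (width,), init="zeros")
    y = conv1d(x, w, b)
    if activation == "relu":
        y = y.relu()
    elif activation == "sigmoid":
        y = y.sigmoid()
    return y


def _inception_block(store, name, x, width, kernels=(1, 3, 5)) -> Tensor:
    branches = [
        _conv_block(store, f"{name}.k{k}", x, width, k) for k in kernels
    ]
    return concat(branches, axis=-1)


def _nettcr_block(store, name, x, n_filters=16, kernels=(1, 3, 5, 7, 9)) -> Tensor:
    """Parallel sigmoid-activated convolutions of several kernel sizes; the
    per-kernel global max-pool happens in :func:`reduce_to_latent`."""
    branches = [
        _conv_block(store, f"{name}.k{k}", x, n_filters, k, activation="sigmoid")
        for k in kernels
    ]
    return concat(branches, axis=-1)


# ---------------------------------------------------------------------------
# Stack assembly


def _residual(store, name, x: Tensor, y: Tensor) -> Tensor:
    """Skip connection x → y with projection on shape mismatch."""
    if y.shape[1] == 2 * x.shape[1]:
        x = concat([x, x], axis=1)
    elif y.shape[1] != x.shape[1]:
        raise ValueError("residual cannot reconcile positional lengths")
    if x.shape[-1] != y.shape[-1]:
        x = dense(store, f"{name}.proj", x, y.shape[-1])
    return y + x


def sequence_layer(store: ParamStore, name: str, x: Tensor, kind: str,
                   width: int, kernel_sizes=(5,), residual: bool = True,
                   n_heads: int = 4) -> Tensor:
    """One sequence-embedding layer of the requested family."""
    kind = kind.lower()
    if kind == "bigru":
        y = _bidirectional(_gru_scan, store, name, x, width)
    elif kind == "bilstm":
        y = _bidirectional(_lstm_scan, store, name, x, width)
    elif kind == "self_attention":
        y = _self_attention(store, name, x, width, n_heads=n_heads)
    elif kind == "conv":
        y = _conv_block(store, name, x, width, kernel_sizes[0])
    elif kind == "inception":
        y = _inception_block(store, name, x, width, kernels=kernel_sizes)
    elif kind == "nettcr":
        y = _nettcr_block(store, name, x, n_filters=width, kernels=kernel_sizes)
    elif kind == "linear":
        return x  # identity pass-through to the flattening step
    else:
        raise ValueError(f"unknown sequence layer kind {kind!r}")
    if residual:
        y = _residual(store, f"{name}.res", x, y)
    return y


def reduce_to_latent(acts: Tensor | None, kind: str, n_positions: int) -> Tensor:
    """Collapse positional activations into a fixed-width latent vector.

    Recurrent kinds concatenate the final-position state of each scan
    direction (dimension 2 × width, independent of input length);
    convolutional / attention / linear kinds flatten positions × channels
    (well defined because inputs are padded to fixed lengths); the NetTCR
    kind max-pools each filter over positions.
    """
    kind = kind.lower()
    if kind == "noseq":
        if acts is not None:
            raise ValueError("NOSEQ expects empty activations")
        raise ValueError("NOSEQ has no latent; handled by the model head")
    if acts is None:
        raise ValueError(f"empty activations for sequence kind {kind!r}")
    B = acts.shape[0]
    if kind in ("bigru", "bilstm"):
        L2 = acts.shape[1]
        fwd_final = acts[:, L2 // 2 - 1, :]
        bwd_final = acts[:, L2 - 1, :]
        return concat([fwd_final, bwd_final], axis=-1)
    if kind == "nettcr":
        return acts.max(axis=1)
    if kind in ("self_attention", "conv", "inception", "linear"):
        return acts.reshape(B, acts.shape[1] * acts.shape[2])
    raise ValueError(f"unknown sequence layer kind {kind!r}")
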