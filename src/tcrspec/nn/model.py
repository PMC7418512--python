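"""Model families: the categorical antigen model and the antigen-embedding
pair model.

Both families share a three-block layout: an initial amino-acid embedding
(optionally a trainable 1×1 convolution on BLOSUM channels), a
sequence-embedding stack of one of several layer kinds, and a final dense
block that integrates the sequence latent with cell-level covariates.

* CATEGORICAL head — softmax over ``n_antigens + 1`` classes (one per
  panel antigen plus a non-binding class).
* BINARY head — single sigmoid node (single-antigen tasks and the
  antigen-embedding pair model).
* COUNT head — exponentiated activations, one strictly positive output
  per modeled antigen (multi-task) or a single output (single-task).

Pair models embed the TCR CDR3β (padded to 40) and the antigen peptide
(padded to 25) either through separate stacks whose latents are
concatenated (SEPARATE) or through one stack over the appended 65-position
sequence (CONCATENATED).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from ..encoding import EmbeddingMode, EmbeddingSpec
from .autograd import Tensor, concat
from .layers import ParamStore, dense, reduce_to_latent, sequence_layer

__all__ = [
    "SequenceLayerSpec",
    "ModelSpec",
    "Model",
    "save_model",
    "load_model",
    "build_multitask_count_model",
    "build_singletask_count_models",
]

SEQ_KINDS = (
    "bigru", "bilstm", "self_attention", "conv", "inception",
    "nettcr", "linear", "noseq",
)
CHAIN_MODES = ("tra", "trb", "concat_chains")
PAIR_MODES = ("none", "separate", "concatenated")
HEADS = ("categorical", "binary", "count")


@dataclass(frozen=True)
class SequenceLayerSpec:
    """Configuration of the sequence-embedding stack."""

    kind: str = "linear"
    depth: int = 1
    width: int = 16
    kernel_sizes: tuple = (5,)
    residual: bool = True
    n_heads: int = 4

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        if kind not in SEQ_KINDS:
            raise ValueError(f"unknown sequence layer kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "kernel_sizes", tuple(self.kernel_sizes))
        if kind == "noseq" and self.depth != 0:
            object.__setattr__(self, "depth", 0)
        if any(k % 2 != 1 or k < 1 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd positive integers")
        if self.width < 1:
            raise ValueError("width must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "depth": self.depth, "width": self.width,
            "kernel_sizes": list(self.kernel_sizes),
            "residual": self.residual, "n_heads": self.n_heads,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceLayerSpec":
        d = dict(d)
        d["kernel_sizes"] = tuple(d.get("kernel_sizes", (5,)))
        return cls(**d)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a model instance."""

    chain_mode: str = "trb"
    pair_mode: str = "none"
    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    seq_layer: SequenceLayerSpec = field(default_factory=SequenceLayerSpec)
    covariate_set: tuple = ()
    head: str = "categorical"
    n_antigens: int = 1
    dense_widths: tuple = ()
    dropout: float = 0.0

    def __post_init__(self) -> None:
        for name, value, valid in (
            ("chain_mode", self.chain_mode.lower(), CHAIN_MODES),
            ("pair_mode", self.pair_mode.lower(), PAIR_MODES),
            ("head", self.head.lower(), HEADS),
        ):
            if value not in valid:
                raise ValueError(f"invalid {name} {value!r}")
            object.__setattr__(self, name, value)
        object.__setattr__(self, "covariate_set",
                           tuple(str(c).lower() for c in self.covariate_set))
        object.__setattr__(self, "dense_widths", tuple(self.dense_widths))
        if self.n_antigens < 1:
            raise ValueError("n_antigens must be >= 1")
        if self.pair_mode != "none" and self.head == "categorical":
            raise ValueError(
                "pair models embed the antigen sequence and use a BINARY head; "
                "a CATEGORICAL head is not a valid pair-model configuration"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def n_outputs(self) -> int:
        if self.head == "categorical":
            return self.n_antigens + 1
        if self.head == "binary":
            return 1
        return self.n_antigens

    def to_dict(self) -> dict:
        return {
            "chain_mode": self.chain_mode,
            "pair_mode": self.pair_mode,
            "embedding": self.embedding.to_dict(),
            "seq_layer": self.seq_layer.to_dict(),
            "covariate_set": list(self.covariate_set),
            "head": self.head,
            "n_antigens": self.n_antigens,
            "dense_widths": list(self.dense_widths),
            "dropout": self.dropout,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["embedding"] = EmbeddingSpec.from_dict(d["embedding"])
        d["seq_layer"] = SequenceLayerSpec.from_dict(d["seq_layer"])
        d["covariate_set"] = tuple(d.get("covariate_set", ()))
        d["dense_widths"] = tuple(d.get("dense_widths", ()))
        return cls(**d)

    def spec_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class Model:
    """A parameterized model instance with a seeded initializer.

    ``forward`` consumes pre-encoded sequences: a (batch, positions, 20)
    array (one-hot or BLOSUM channels), or a pair of arrays (TCR, antigen)
    for pair models.  It returns pre-activation outputs; ``predict``
    applies the head activation.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        self.store = ParamStore(seed)
        self._train_rng = np.random.default_rng(self.seed + 1)
        self._cov_width: Optional[int] = None

    # -- building blocks ---------------------------------------------------

    def _embed(self, x: np.ndarray) -> Tensor:
        """Initial amino-acid embedding (shared across all sequence inputs)."""
        t = Tensor(np.asarray(x, dtype=np.float64))
        if self.spec.embedding.mode is EmbeddingMode.LEARNED:
            w = self.store.get("embed.w", (t.shape[-1], self.spec.embedding.n_filters))
            b = self.store.get("embed.b", (self.spec.embedding.n_filters,), init="zeros")
            t = t @ w + b
        return t

    def _stack(self, prefix: str, x: Tensor) -> Optional[Tensor]:
        sl = self.spec.seq_layer
        if sl.kind == "noseq":
            return None
        acts = x
        for d in range(max(sl.depth, 1)):
            acts = sequence_layer(
                self.store, f"{prefix}.layer{d}", acts, sl.kind,
                sl.width, kernel_sizes=sl.kernel_sizes,
                residual=sl.residual, n_heads=sl.n_heads,
            )
        return acts

    def _latent(self, prefix: str, x: np.ndarray) -> Optional[Tensor]:
        if self.spec.seq_layer.kind == "noseq":
            return None
        emb = self._embed(x)
        acts = self._stack(prefix, emb)
        return reduce_to_latent(acts, self.spec.seq_layer.kind, emb.shape[1])

    def _head(self, latent: Optional[Tensor], cov: np.ndarray,
              train: bool = False) -> Tensor:
        cov_t = Tensor(np.asarray(cov, dtype=np.float64))
        if latent is None:
            h = cov_t
        elif cov_t.shape[-1] == 0:
            h = latent
        else:
            h = concat([latent, cov_t], axis=-1)
        if h.shape[-1] == 0:
            # covariate-free NOSEQ degenerates to a bias-only predictor
            h = Tensor(np.zeros((cov_t.shape[0], 1)))
        for i, width in enumerate(self.spec.dense_widths):
            h = dense(self.store, f"head.dense{i}", h, width, activation="relu")
            if train and self.spec.dropout > 0:
                mask = self._train_rng.random(h.shape) >= self.spec.dropout
                h = h * Tensor(mask / (1.0 - self.spec.dropout))
        return dense(self.store, "head.out", h, self.spec.n_outputs)

    # -- public API --------------------------------------------------------

    def forward(self, x, cov: np.ndarray, train: bool = False) -> Tensor:
        """Pre-activation outputs for a batch.

        ``x`` is a (B, L, C) array, or a (tcr, antigen) tuple for pair
        models.  ``cov`` is the (B, D) covariate design block; an all-zero
        covariate matrix is legal (imputation without covariates).
        """
        spec = self.spec
        cov = np.asarray(cov, dtype=np.float64)
        if cov.ndim != 2:
            raise ValueError("covariates must be a (batch, width) matrix")
        if self._cov_width is None:
            self._cov_width = cov.shape[1]
        elif cov.shape[1] != self._cov_width:
            raise ValueError(
                f"covariate width {cov.shape[1]} does not match model "
                f"({self._cov_width})"
            )
        if spec.pair_mode == "none":
            if isinstance(x, (tuple, list)):
                raise ValueError("this model takes a single sequence input")
            latent = self._latent("seq", x)
        elif spec.pair_mode == "separate":
            xt, xa = x
            lt = self._latent("seq_tcr", xt)
            la = self._latent("seq_ag", xa)
            latent = None if lt is None else concat([lt, la], axis=-1)
        else:  # concatenated
            xt, xa = x
            joint = np.concatenate([np.asarray(xt), np.asarray(xa)], axis=1)
            latent = self._latent("seq", joint)
        return self._head(latent, cov, train=train)

    def predict(self, x, cov: np.ndarray) -> np.ndarray:
        """Head-activated predictions: probability vectors (categorical),
        probabilities (binary) or strictly positive counts (count)."""
        out = self.forward(x, cov).data
        if self.spec.head == "categorical":
            z = out - out.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        if self.spec.head == "binary":
            return 1.0 / (1.0 + np.exp(-np.clip(out[:, 0], -500, 500)))
        return np.exp(np.clip(out, -700, 700))

    @property
    def n_parameters(self) -> int:
        return self.store.n_parameters


def save_model(model: Model, path) -> Path:
    """Serialize spec + parameters to an ``.npz`` container with an
    embedded spec hash; reload with :func:`load_model` reproduces forward
    outputs bit-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps(
        {"spec": model.spec.to_dict(), "seed": model.seed,
         "spec_hash": model.spec.spec_hash()},
        sort_keys=True,
    )
    arrays = {f"param::{k}": v for k, v in model.store.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    return path


def load_model(path) -> Model:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        spec = ModelSpec.from_dict(meta["spec"])
        if spec.spec_hash() != meta["spec_hash"]:
            raise ValueError("spec hash mismatch: corrupted model file")
        model = Model(spec, seed=meta["seed"])
        state = {
            k[len("param::"):]: npz[k] for k in npz.files if k.startswith("param::")
        }
    model.store.load_state_dict(state)
    return model


def build_multitask_count_model(spec: ModelSpec, seed: int = 0) -> Model:
    """COUNT-head model with one shared trunk and ``n_antigens`` outputs."""
    if spec.head != "count":
        raise ValueError("count-model builders require a COUNT head")
    return Model(spec, seed=seed)


def build_singletask_count_models(spec: ModelSpec, seed: int = 0) -> list:
    """One independent 1-output COUNT model per panel antigen."""
    if spec.head != "count":
        raise ValueError("count-model builders require a COUNT head")
    if spec.n_antigens < 1:
        raise ValueError("n_antigens must be >= 1")
    models = []
    for j in range(spec.n_antigens):
        sub = ModelSpec.from_dict({**spec.to_dict(), "n_antigens": 1})
        models.append(Model(sub, seed=seed + j))
    return models
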