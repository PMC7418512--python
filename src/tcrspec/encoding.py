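"""Amino-acid sequence encodings for TCR CDR3 loops and antigen peptides.

CDR3 and antigen sequences enter the models as fixed-length position ×
channel matrices.  Three initial embeddings are supported:

* ``ONEHOT`` — indicator vector over the 20 standard residues,
* ``BLOSUM`` — the residue's row of a substitution matrix (BLOSUM50 by
  default), restricted to the 20 standard residues,
* ``LEARNED`` — a trainable 1×1 convolution (position-wise affine map) on
  top of the BLOSUM encoding, reducing the channel dimension to a small
  number of filters.  The learnable map itself lives in the model; this
  module provides the deterministic contract
  (:func:`apply_learned_embedding`).

Sequences are padded to fixed lengths before encoding: 40 per CDR3 chain,
80 for concatenated α+β chains, 25 for antigen peptides.  PAD positions
encode to all-zero channel vectors in every mode; a binary mask marking
real residues is carried alongside for diagnostics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "PAD",
    "CDR3_PAD_LENGTH",
    "CONCAT_PAD_LENGTH",
    "ANTIGEN_PAD_LENGTH",
    "EmbeddingMode",
    "EmbeddingSpec",
    "PaddedSequence",
    "EncodedSequence",
    "SequenceError",
    "validate_sequence",
    "pad_sequence",
    "concat_chains",
    "encode_fixed",
    "apply_learned_embedding",
    "read_substitution_matrix",
    "load_blosum",
    "read_fasta",
]

#: The 20 standard amino acids, in the conventional NCBI matrix order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Padding token appended to short sequences.
PAD = "-"

#: Fixed padded length of a single CDR3 chain.
CDR3_PAD_LENGTH = 40
#: Fixed length of concatenated α+β CDR3 chains.
CONCAT_PAD_LENGTH = 80
#: Fixed padded length of an antigen peptide.
ANTIGEN_PAD_LENGTH = 25


class SequenceError(ValueError):
    """Raised for invalid residues or length violations."""


class EmbeddingMode(str, enum.Enum):
    ONEHOT = "onehot"
    BLOSUM = "blosum"
    LEARNED = "learned"


@dataclass(frozen=True)
class EmbeddingSpec:
    """Configuration of the initial amino-acid embedding.

    ``n_filters`` is only used in LEARNED mode, where a trainable 1×1
    convolution maps the 20 BLOSUM channels to ``n_filters`` learned
    channels.  ``allow_nonstandard`` maps unknown residue codes (e.g. 'X')
    to a zero vector instead of raising.
    """

    mode: EmbeddingMode = EmbeddingMode.LEARNED
    blosum_name: str = "BLOSUM50"
    n_filters: int = 5
    scale_blosum: bool = False
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", EmbeddingMode(self.mode))
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")

    @property
    def n_channels(self) -> int:
        """Channel count of the encoding handed to the sequence stack."""
        return 20

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "blosum_name": self.blosum_name,
            "n_filters": self.n_filters,
            "scale_blosum": self.scale_blosum,
            "allow_nonstandard": self.allow_nonstandard,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbeddingSpec":
        return cls(**d)


@dataclass(frozen=True)
class PaddedSequence:
    """A sequence padded to a fixed target length with a residue mask."""

    tokens: tuple
    mask: tuple

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.mask):
            raise SequenceError("tokens and mask lengths differ")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def sequence(self) -> str:
        """Original residues with PAD stripped (round trip of padding)."""
        return "".join(t for t, m in zip(self.tokens, self.mask) if m)


@dataclass
class EncodedSequence:
    """Position × channel numeric representation plus residue mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[0] != self.mask.shape[0]:
            raise SequenceError("values must be positions × channels matching mask")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def validate_sequence(seq: str, allow_nonstandard: bool = False) -> str:
    """Upper-case ``seq`` and check every residue is a standard code.

    With ``allow_nonstandard`` the sequence is returned as-is (non-standard
    codes later encode to zero vectors); otherwise a :class:`SequenceError`
    names the offending residue.
    """
    seq = seq.upper()
    if not allow_nonstandard:
        for ch in seq:
            if ch not in _AA_INDEX:
                raise SequenceError(
                    f"non-standard residue {ch!r} in sequence {seq!r}"
                )
    return seq


def pad_sequence(seq: str, target_len: int, allow_nonstandard: bool = False) -> PaddedSequence:
    """Right-pad ``seq`` to ``target_len`` residues.

    Raises :class:`SequenceError` if the sequence is longer than the
    target, naming the sequence.
    """
    seq = validate_sequence(seq, allow_nonstandard=allow_nonstandard)
    if len(seq) > target_len:
        raise SequenceError(
            f"sequence {seq!r} of length {len(seq)} exceeds padded length {target_len}"
        )
    n_pad = target_len - len(seq)
    return PaddedSequence(
        tokens=tuple(seq) + (PAD,) * n_pad,
        mask=(1,) * len(seq) + (0,) * n_pad,
    )


def concat_chains(padded_a: PaddedSequence, padded_b: PaddedSequence) -> PaddedSequence:
    """Concatenate two 40-padded CDR3 chains into one length-80 sequence."""
    if len(padded_a) != CDR3_PAD_LENGTH or len(padded_b) != CDR3_PAD_LENGTH:
        raise SequenceError(
            f"chain concatenation expects two length-{CDR3_PAD_LENGTH} inputs, "
            f"got {len(padded_a)} and {len(padded_b)}"
        )
    return PaddedSequence(
        tokens=padded_a.tokens + padded_b.tokens,
        mask=padded_a.mask + padded_b.mask,
    )


# ---------------------------------------------------------------------------
# Substitution matrices


def read_substitution_matrix(path_or_lines) -> tuple:
    """Parse an NCBI flat-format substitution matrix.

    Returns ``(alphabet, matrix)`` where ``matrix`` is a square float
    array over the file's full alphabet (including ambiguity codes and
    ``*`` if present).  Lines starting with ``#`` are comments.
    """
    if isinstance(path_or_lines, (str,)) and "\n" not in path_or_lines:
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    elif isinstance(path_or_lines, str):
        lines = path_or_lines.splitlines()
    else:
        lines = list(path_or_lines)
    lines = [ln.rstrip("\n") for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    alphabet = "".join(header)
    n = len(header)
    mat = np.zeros((n, n), dtype=np.float64)
    if len(lines) - 1 != n:
        raise ValueError(f"matrix has {len(lines) - 1} rows for {n} columns")
    for i, ln in enumerate(lines[1:]):
        parts = ln.split()
        if parts[0] != header[i]:
            raise ValueError(f"row label {parts[0]!r} does not match column {header[i]!r}")
        vals = [float(x) for x in parts[1:]]
        if len(vals) != n:
            raise ValueError(f"row {parts[0]!r} has {len(vals)} entries, expected {n}")
        mat[i] = vals
    return alphabet, mat


_BLOSUM_CACHE: dict = {}


def load_blosum(name: str = "BLOSUM50", scale: bool = False) -> np.ndarray:
    """Load the bundled substitution matrix restricted to the 20 standard
    residues, ordered as :data:`AMINO_ACIDS`.

    Scores are raw (half-bit integers cast to float); ``scale`` applies an
    optional global min–max rescaling to [0, 1].
    """
    key = (name, scale)
    if key in _BLOSUM_CACHE:
        return _BLOSUM_CACHE[key]
    fname = name.lower() + ".txt"
    ref = resources.files("tcrspec.data").joinpath(fname)
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled substitution matrix {name!r}")
    alphabet, full = read_substitution_matrix(ref.read_text())
    idx = [alphabet.index(aa) for aa in AMINO_ACIDS]
    sub = full[np.ix_(idx, idx)].copy()
    if scale:
        sub = (sub - sub.min()) / (sub.max() - sub.min())
    sub.setflags(write=False)
    _BLOSUM_CACHE[key] = sub
    return sub


# ---------------------------------------------------------------------------
# Encoding


def encode_fixed(padded: PaddedSequence, spec: EmbeddingSpec) -> EncodedSequence:
    """Encode a padded sequence as positions × 20 channels.

    ONEHOT rows are indicator vectors; BLOSUM (and LEARNED, whose
    trainable map is applied downstream in the model) rows are the
    substitution-matrix row of the residue against the 20 standard
    residues.  PAD and (if allowed) non-standard residues encode to zero.
    """
    L = len(padded)
    values = np.zeros((L, 20), dtype=np.float64)
    if spec.mode is EmbeddingMode.ONEHOT:
        table = np.eye(20)
    else:
        table = load_blosum(spec.blosum_name, scale=spec.scale_blosum)
    for p, (tok, m) in enumerate(zip(padded.tokens, padded.mask)):
        if not m:
            continue
        j = _AA_INDEX.get(tok)
        if j is None:
            if spec.allow_nonstandard:
                continue
            raise SequenceError(f"cannot encode non-standard residue {tok!r}")
        values[p] = table[j]
    return EncodedSequence(values=values, mask=np.asarray(padded.mask, dtype=np.int8))


def apply_learned_embedding(
    encoded_blosum: EncodedSequence, weights: np.ndarray, bias: np.ndarray
) -> EncodedSequence:
    """Position-wise affine map (1×1 convolution) of a BLOSUM encoding.

    Every position, including PAD rows, is mapped through the same
    ``20 × n_filters`` affine map; PAD rows are masked downstream.  This is
    the deterministic contract of the LEARNED embedding — in the model the
    weights are trainable.
    """
    weights = np.asarray(weights, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if encoded_blosum.n_channels != weights.shape[0]:
        raise SequenceError(
            f"channel mismatch: encoding has {encoded_blosum.n_channels} channels, "
            f"weights expect {weights.shape[0]}"
        )
    if weights.shape[1] != bias.shape[0]:
        raise SequenceError("bias length must equal number of filters")
    return EncodedSequence(
        values=encoded_blosum.values @ weights + bias,
        mask=encoded_blosum.mask.copy(),
    )


def encode_batch(sequences: Iterable[str], target_len: int, spec: EmbeddingSpec) -> np.ndarray:
    """Pad and encode a batch of sequences to (n, target_len, 20)."""
    rows = [
        encode_fixed(pad_sequence(s, target_len, spec.allow_nonstandard), spec).values
        for s in sequences
    ]
    if not rows:
        return np.zeros((0, target_len, 20))
    return np.stack(rows)


def read_fasta(path) -> dict:
    """Read a FASTA file of antigen peptides into ``{name: sequence}``."""
    seqs: dict = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
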