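"""Model-ready array datasets assembled from prepared cell records."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .encoding import (
    ANTIGEN_PAD_LENGTH,
    CDR3_PAD_LENGTH,
    EmbeddingSpec,
    concat_chains,
    encode_fixed,
    pad_sequence,
)
from .pipeline import Part, SplitAssignment, build_covariate_design, size_factor_mean
from .records import AntigenPanel, BindingPair, CellRecord, NO_BINDER

__all__ = [
    "ArrayDataset",
    "encode_cells",
    "encode_pairs",
    "categorical_labels",
    "count_matrix",
    "build_screen_datasets",
    "build_pair_datasets",
]


@dataclass
class ArrayDataset:
    """Encoded sequences, covariates and labels for one split part.

    ``x`` is a (n, positions, channels) array, or a (tcr, antigen) tuple
    for pair models.  ``y`` holds integer class labels for classifiers or
    a (n, n_antigens) count matrix for count models.
    """

    x: Union[np.ndarray, tuple]
    cov: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        x = (
            tuple(part[idx] for part in self.x)
            if isinstance(self.x, tuple)
            else self.x[idx]
        )
        return ArrayDataset(x=x, cov=self.cov[idx], y=self.y[idx])

    def zero_covariates(self) -> "ArrayDataset":
        """Imputation mode: same shapes, all covariate values zeroed."""
        return ArrayDataset(x=self.x, cov=np.zeros_like(self.cov), y=self.y)


def encode_cells(
    cells: Sequence[CellRecord], chain_mode: str, spec: EmbeddingSpec
) -> np.ndarray:
    """Encode CDR3 chains to (n, positions, 20) per the chain mode
    (``tra``/``trb``: one 40-padded chain; ``concat_chains``: α then β,
    80 positions)."""
    chain_mode = chain_mode.lower()
    rows = []
    for c in cells:
        if chain_mode == "tra":
            padded = pad_sequence(c.cdr3a or "", CDR3_PAD_LENGTH)
        elif chain_mode == "trb":
            padded = pad_sequence(c.cdr3b or "", CDR3_PAD_LENGTH)
        elif chain_mode == "concat_chains":
            padded = concat_chains(
                pad_sequence(c.cdr3a or "", CDR3_PAD_LENGTH),
                pad_sequence(c.cdr3b or "", CDR3_PAD_LENGTH),
            )
        else:
            raise ValueError(f"unknown chain mode {chain_mode!r}")
        rows.append(encode_fixed(padded, spec).values)
    L = CDR3_PAD_LENGTH * (2 if chain_mode == "concat_chains" else 1)
    return np.stack(rows) if rows else np.zeros((0, L, 20))


def encode_pairs(pairs: Sequence[BindingPair], spec: EmbeddingSpec):
    """Encode database pairs to ((n, 40, 20) TCR, (n, 25, 20) antigen,
    label vector)."""
    xt = np.stack(
        [encode_fixed(pad_sequence(p.cdr3b, CDR3_PAD_LENGTH), spec).values for p in pairs]
    ) if pairs else np.zeros((0, CDR3_PAD_LENGTH, 20))
    xa = np.stack(
        [encode_fixed(pad_sequence(p.antigen, ANTIGEN_PAD_LENGTH), spec).values for p in pairs]
    ) if pairs else np.zeros((0, ANTIGEN_PAD_LENGTH, 20))
    y = np.array([p.label for p in pairs], dtype=np.int64)
    return xt, xa, y


def categorical_labels(cells: Sequence[CellRecord], n_antigens: int) -> np.ndarray:
    """Integer class labels; the non-binding class is index ``n_antigens``."""
    return np.array(
        [n_antigens if c.binder_label is NO_BINDER else c.binder_label for c in cells],
        dtype=np.int64,
    )


def count_matrix(cells: Sequence[CellRecord]) -> np.ndarray:
    return np.array([c.pmhc_counts for c in cells], dtype=np.float64)


def build_screen_datasets(
    cells: Sequence[CellRecord],
    panel: AntigenPanel,
    split: SplitAssignment,
    chain_mode: str,
    embedding: EmbeddingSpec,
    covariate_set: Sequence = (),
    head: str = "categorical",
) -> dict:
    """Assemble per-part array datasets for a screen.

    The donor column space and the size-factor mean are frozen on the
    training part and reused for validation and test to avoid leakage.
    """
    parts = {p: split.cells_in(cells, p) for p in Part}
    train_cells = parts[Part.TRAIN]
    if not train_cells:
        raise ValueError("empty training partition")
    donors = sorted({c.donor for c in train_cells})
    mean_total = size_factor_mean(train_cells)
    out = {}
    for part, part_cells in parts.items():
        x = encode_cells(part_cells, chain_mode, embedding)
        cov = build_covariate_design(
            part_cells, covariate_set, donors=donors, mean_total=mean_total,
            nc_names=panel.nc_names or None,
        ).values
        if head == "count":
            y = count_matrix(part_cells)
        else:
            y = categorical_labels(part_cells, len(panel))
        out[part] = ArrayDataset(x=x, cov=cov, y=y)
    return out


def build_pair_datasets(
    train_pairs: Sequence[BindingPair],
    test_pairs: Sequence[BindingPair],
    embedding: EmbeddingSpec,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> dict:
    """Assemble pair-model datasets; validation pairs are carved from the
    training pairs (negatives must already be merged in)."""
    rng = np.random.default_rng(seed)
    train_pairs = list(train_pairs)
    order = rng.permutation(len(train_pairs))
    n_val = round(val_fraction * len(train_pairs))
    val_idx = set(order[:n_val].tolist())
    tr = [p for i, p in enumerate(train_pairs) if i not in val_idx]
    va = [p for i, p in enumerate(train_pairs) if i in val_idx]
    out = {}
    for part, pairs in ((Part.TRAIN, tr), (Part.VAL, va), (Part.TEST, list(test_pairs))):
        xt, xa, y = encode_pairs(pairs, embedding)
        out[part] = ArrayDataset(x=(xt, xa), cov=np.zeros((len(y), 0)), y=y)
    return out
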