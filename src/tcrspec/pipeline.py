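"""Screen preparation: binarization, doublet exclusion, clonotype handling,
negative-set construction, covariate design and clonotype-aware splits.

The processing order for single-cell screens is: doublet removal →
clonotype assignment → clonotype down-sampling → antigen selection →
(single-antigen binary tasks only) majority-class down-sampling.  Splits
are made at the clonotype level so that no TCR sequence is shared between
train, validation and test cells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import BindingPair, CellRecord, AntigenPanel, NO_BINDER

__all__ = [
    "Covariate",
    "Part",
    "DesignMatrix",
    "SplitAssignment",
    "binarize_pmhc_counts",
    "binarize_table",
    "assign_binder_labels",
    "filter_doublets",
    "assign_clonotypes_by_identity",
    "downsample_clonotypes",
    "select_frequent_antigens",
    "downsample_majority_class",
    "generate_shuffled_negatives",
    "split_by_clonotype",
    "split_leave_one_donor_out",
    "build_covariate_design",
    "size_factor_mean",
]

#: UMI count must exceed this value for a binding call.
BINARIZE_MIN_COUNT = 10
#: ... and be at least this multiple of the largest negative-control count.
BINARIZE_NC_FOLD = 5


class Covariate(str, enum.Enum):
    DONOR = "donor"
    COUNTS = "counts"
    NC = "nc"
    SURFACE = "surface"


#: Fixed column-block order of the covariate design matrix.
COVARIATE_ORDER = (Covariate.DONOR, Covariate.COUNTS, Covariate.NC, Covariate.SURFACE)


class Part(str, enum.Enum):
    TRAIN = "train"
    VAL = "val"
    TEST = "test"


# ---------------------------------------------------------------------------
# Binarization


def binarize_table(pmhc_counts: np.ndarray, nc_counts: np.ndarray) -> np.ndarray:
    """Vectorized binarization of a cells × antigens UMI count table.

    An antigen is called bound in a cell iff its count is larger than
    ``BINARIZE_MIN_COUNT`` and at least ``BINARIZE_NC_FOLD`` times the
    highest negative-control count of that cell.  If several antigens
    pass, the one with the largest count wins (ties broken by lowest
    panel index).  Returns an int vector with the binder's panel index, or
    -1 where no antigen passes.
    """
    pmhc = np.asarray(pmhc_counts)
    nc = np.asarray(nc_counts)
    if pmhc.ndim != 2 or nc.ndim != 2:
        raise ValueError("expected 2-D count tables (cells × species)")
    if pmhc.shape[1] == 0:
        raise ValueError("empty antigen panel")
    if nc.shape[1] == 0:
        raise ValueError("at least one negative-control species required")
    nc_max = nc.max(axis=1, keepdims=True)
    passes = (pmhc > BINARIZE_MIN_COUNT) & (pmhc >= BINARIZE_NC_FOLD * nc_max)
    masked = np.where(passes, pmhc, -1)
    labels = np.where(passes.any(axis=1), masked.argmax(axis=1), -1)
    return labels.astype(np.int64)


def binarize_pmhc_counts(pmhc_counts, nc_counts) -> Optional[int]:
    """Single-cell form of :func:`binarize_table`; returns the binder's
    panel index or ``None``."""
    lab = binarize_table(
        np.asarray(pmhc_counts)[None, :], np.asarray(nc_counts)[None, :]
    )[0]
    return None if lab < 0 else int(lab)


def assign_binder_labels(cells: Sequence[CellRecord]) -> list:
    """Apply binarization to every cell, setting ``binder_label`` in place."""
    for cell in cells:
        cell.binder_label = binarize_pmhc_counts(cell.pmhc_counts, cell.nc_counts)
    return list(cells)


# ---------------------------------------------------------------------------
# Filtering and clonotypes


def filter_doublets(cells: Sequence[CellRecord]):
    """Exclude cells with more than one reconstructed allele on either chain.

    Returns ``(kept, removed)`` preserving input order.
    """
    kept = [c for c in cells if not c.is_doublet]
    removed = [c for c in cells if c.is_doublet]
    return kept, removed


def assign_clonotypes_by_identity(records: Sequence, overwrite: bool = False) -> list:
    """Assign clonotype ids by exact sequence identity.

    Cell records are keyed on the (CDR3α, CDR3β) string pair; database
    pair records on the CDR3β alone.  Records with identical keys share a
    clonotype id.  For cells an id already present (e.g. from a 10x
    clonotype file) is kept unless ``overwrite`` is set.  Returns the list
    of assigned ids in input order.
    """
    keys: dict = {}
    ids = []
    for rec in records:
        if isinstance(rec, CellRecord):
            if rec.cdr3b is None and rec.cdr3a is None:
                raise ValueError(f"cell {rec.barcode} has no CDR3 sequences")
            key = (rec.cdr3a or "", rec.cdr3b or "")
        elif isinstance(rec, BindingPair):
            key = rec.cdr3b
        else:
            raise TypeError(f"cannot assign clonotypes to {type(rec).__name__}")
        if key not in keys:
            keys[key] = f"clonotype_{len(keys)}"
        cid = keys[key]
        if isinstance(rec, CellRecord) and (rec.clonotype_id is None or overwrite):
            rec.clonotype_id = cid
        ids.append(cid)
    return ids


def _require_clonotypes(cells: Sequence[CellRecord]) -> None:
    for c in cells:
        if c.clonotype_id is None:
            raise ValueError(f"cell {c.barcode} has no clonotype id assigned")


def downsample_clonotypes(
    cells: Sequence[CellRecord], max_per_clonotype: int = 10, seed: int = 0
) -> list:
    """Cap each clonotype at ``max_per_clonotype`` cells, sampled uniformly.

    Output preserves the input order of the retained cells.  Database-style
    collapsing to one observation per clonotype uses ``max_per_clonotype=1``.
    """
    if max_per_clonotype < 1:
        raise ValueError("max_per_clonotype must be >= 1")
    _require_clonotypes(cells)
    rng = np.random.default_rng(seed)
    by_clone: dict = {}
    for i, c in enumerate(cells):
        by_clone.setdefault(c.clonotype_id, []).append(i)
    keep = set()
    for cid in sorted(by_clone):
        idx = by_clone[cid]
        if len(idx) <= max_per_clonotype:
            keep.update(idx)
        else:
            keep.update(rng.choice(idx, size=max_per_clonotype, replace=False))
    return [c for i, c in enumerate(cells) if i in keep]


def select_frequent_antigens(
    cells: Sequence[CellRecord], panel: AntigenPanel, min_clonotypes: int = 100
):
    """Keep antigens with at least ``min_clonotypes`` distinct binder
    clonotypes; drop cells bound to excluded antigens.

    Cells bound to a dropped antigen are removed (not relabeled as
    non-binders, which would conflate "no dextramer passed" with "bound an
    excluded antigen").  Binder labels of the survivors are re-indexed to
    the returned sub-panel.  Returns ``(sub_panel, kept_cells,
    kept_antigen_indices)``.
    """
    _require_clonotypes(cells)
    clones_per_antigen: dict = {i: set() for i in range(len(panel))}
    for c in cells:
        if c.binder_label is not NO_BINDER:
            clones_per_antigen[c.binder_label].add(c.clonotype_id)
    kept_idx = [i for i in range(len(panel)) if len(clones_per_antigen[i]) >= min_clonotypes]
    remap = {old: new for new, old in enumerate(kept_idx)}
    kept_cells = []
    for c in cells:
        if c.binder_label is NO_BINDER:
            kept_cells.append(c)
        elif c.binder_label in remap:
            c.binder_label = remap[c.binder_label]
            kept_cells.append(c)
    return panel.subset(kept_idx), kept_cells, kept_idx


def downsample_majority_class(
    observations: Sequence, labels: Optional[Sequence[int]] = None,
    max_ratio: float = 2.0, seed: int = 0,
):
    """Cap the larger of two classes at ``max_ratio`` × the smaller class.

    Used only for single-antigen binary tasks.  ``labels`` defaults to the
    ``label`` attribute of the observations (binding pairs).  Returns the
    retained observations (with retained labels if ``labels`` was given).
    """
    obs = list(observations)
    if labels is None:
        labs = np.array([o.label for o in obs])
        with_labels = False
    else:
        labs = np.asarray(list(labels))
        with_labels = True
    if len(labs) != len(obs):
        raise ValueError("labels must match observations")
    pos = np.flatnonzero(labs == 1)
    neg = np.flatnonzero(labs == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty for class down-sampling")
    rng = np.random.default_rng(seed)
    small, large = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    cap = int(max_ratio * len(small))
    if len(large) > cap:
        large = rng.choice(large, size=cap, replace=False)
    keep = np.sort(np.concatenate([small, large]))
    kept = [obs[i] for i in keep]
    if with_labels:
        return kept, labs[keep].tolist()
    return kept


# ---------------------------------------------------------------------------
# Negative sets


def generate_shuffled_negatives(positives: Sequence[BindingPair], seed: int = 0) -> list:
    """Create one negative per positive by reassigning antigens in silico.

    Negatives are uniform draws without replacement from the unobserved
    (TCR, antigen) combinations over the positive TCR pool and positive
    antigen set; they are disjoint from the positives and from each other.
    """
    positives = list(positives)
    pos_set = {(p.cdr3b, p.antigen) for p in positives}
    tcrs = sorted({p.cdr3b for p in positives})
    antigens = sorted({p.antigen for p in positives})
    if len(antigens) < 2:
        raise ValueError("need at least 2 distinct antigens to form negatives")
    source_of = {p.cdr3b: p.source for p in positives}
    candidates = [
        (t, a) for t in tcrs for a in antigens if (t, a) not in pos_set
    ]
    n = len(positives)
    if len(candidates) < n:
        raise ValueError(
            f"cannot form {n} unobserved pairs from {len(candidates)} candidates"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [
        BindingPair(cdr3b=candidates[i][0], antigen=candidates[i][1],
                    label=0, source=source_of[candidates[i][0]])
        for i in sorted(chosen)
    ]


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitAssignment:
    """Partition of clonotypes into train/val/test."""

    partition: dict
    seed: int
    scheme: str
    held_out_donor: Optional[str] = None

    def part_of(self, clonotype_id: str) -> Part:
        return self.partition[clonotype_id]

    def clonotypes(self, part: Part) -> list:
        return [cid for cid, p in self.partition.items() if p is Part(part)]

    def cells_in(self, cells: Sequence[CellRecord], part: Part) -> list:
        part = Part(part)
        return [c for c in cells if self.partition[c.clonotype_id] is part]

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "held_out_donor": self.held_out_donor,
            "partition": {cid: p.value for cid, p in self.partition.items()},
        }


def _check_fractions(test_fraction: float, val_fraction: float) -> None:
    if not (0 < test_fraction < 1) or not (0 <= val_fraction < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if test_fraction + val_fraction >= 1:
        raise ValueError("test and validation fractions must sum to < 1")


def split_by_clonotype(
    cells: Sequence[CellRecord],
    test_fraction: float = 0.25,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> SplitAssignment:
    """Sample ``round(test_fraction × n)`` clonotypes into the test set and
    split the remainder into train/val.

    ``val_fraction`` is taken from the non-test clonotypes.  All cells of a
    clonotype share its partition; the same seed reproduces the same split
    for any model configuration.
    """
    _check_fractions(test_fraction, val_fraction)
    _require_clonotypes(cells)
    clonotypes = sorted({c.clonotype_id for c in cells})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clonotypes))
    n_test = round(test_fraction * len(clonotypes))
    n_val = round(val_fraction * (len(clonotypes) - n_test))
    partition = {}
    for rank, j in enumerate(order):
        if rank < n_test:
            part = Part.TEST
        elif rank < n_test + n_val:
            part = Part.VAL
        else:
            part = Part.TRAIN
        partition[clonotypes[j]] = part
    return SplitAssignment(partition=partition, seed=seed, scheme="clonotype_fraction")


def split_leave_one_donor_out(
    cells: Sequence[CellRecord], val_fraction: float = 0.1, seed: int = 0
) -> list:
    """One fold per donor: the held-out donor's cells form the test set,
    remaining clonotypes are split into train/val."""
    _require_clonotypes(cells)
    donors = sorted({c.donor for c in cells})
    if len(donors) < 2:
        raise ValueError("leave-one-donor-out requires at least 2 donors")
    folds = []
    for donor in donors:
        test_clones = {c.clonotype_id for c in cells if c.donor == donor}
        rest = sorted({c.clonotype_id for c in cells} - test_clones)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(rest))
        n_val = round(val_fraction * len(rest))
        partition = {cid: Part.TEST for cid in test_clones}
        for rank, j in enumerate(order):
            partition[rest[j]] = Part.VAL if rank < n_val else Part.TRAIN
        folds.append(
            SplitAssignment(
                partition=partition, seed=seed,
                scheme="leave_one_donor_out", held_out_donor=donor,
            )
        )
    return folds


# ---------------------------------------------------------------------------
# Covariates


@dataclass
class DesignMatrix:
    """Cells × covariates design matrix with named column blocks."""

    values: np.ndarray
    column_names: list
    covariate_set: tuple

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def size_factor_mean(cells: Sequence[CellRecord]) -> float:
    """Mean total mRNA count of a (training) cell population."""
    if not cells:
        raise ValueError("cannot compute a size-factor mean from no cells")
    return float(np.mean([c.total_mrna_count for c in cells]))


def build_covariate_design(
    cells: Sequence[CellRecord],
    covariate_set: Iterable,
    donors: Optional[Sequence[str]] = None,
    mean_total: Optional[float] = None,
    nc_names: Optional[Sequence[str]] = None,
    surface_names: Optional[Sequence[str]] = None,
) -> DesignMatrix:
    """Assemble the covariate design matrix in fixed block order
    DONOR | COUNTS | NC | SURFACE.

    DONOR is a one-hot encoding over ``donors`` (default: donors present,
    sorted — pass the training-set donor list for a frozen column space).
    COUNTS is the per-cell total mRNA count divided by ``mean_total``
    (default: mean over ``cells``; pass the training-set mean to avoid
    leakage).  NC and SURFACE are log(x+1)-transformed count vectors.
    An empty covariate set yields a zero-column matrix.
    """
    cov_set = tuple(Covariate(c) for c in covariate_set)
    unknown = set(cov_set) - set(COVARIATE_ORDER)
    if unknown:
        raise ValueError(f"unknown covariates: {unknown}")
    n = len(cells)
    blocks = []
    names: list = []
    if Covariate.DONOR in cov_set:
        if donors is None:
            donors = sorted({c.donor for c in cells})
        donors = list(donors)
        block = np.zeros((n, len(donors)))
        for i, c in enumerate(cells):
            if c.donor in donors:
                block[i, donors.index(c.donor)] = 1.0
        blocks.append(block)
        names += [f"donor_{d}" for d in donors]
    if Covariate.COUNTS in cov_set:
        totals = np.array([c.total_mrna_count for c in cells], dtype=np.float64)
        if mean_total is None:
            mean_total = size_factor_mean(cells)
        blocks.append((totals / mean_total)[:, None])
        names.append("size_factor")
    if Covariate.NC in cov_set:
        nc = np.log1p(np.array([c.nc_counts for c in cells], dtype=np.float64))
        blocks.append(nc.reshape(n, -1))
        k = nc.shape[1] if nc.ndim == 2 else 0
        names += [
            (nc_names[j] if nc_names else f"nc_{j}") for j in range(k)
        ]
    if Covariate.SURFACE in cov_set:
        sf = np.log1p(np.array([c.surface_counts for c in cells], dtype=np.float64))
        blocks.append(sf.reshape(n, -1))
        k = sf.shape[1] if sf.ndim == 2 else 0
        names += [
            (surface_names[j] if surface_names else f"surface_{j}") for j in range(k)
        ]
    values = np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0))
    return DesignMatrix(values=values, column_names=names, covariate_set=cov_set)
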