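"""Core data records for single-cell screens and database-style pair sets."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["NO_BINDER", "Source", "CellRecord", "AntigenPanel", "BindingPair"]

#: Sentinel label for cells where no pMHC passed the binarization thresholds.
NO_BINDER = None


class Source(str, enum.Enum):
    IEDB = "iedb"
    VDJDB = "vdjdb"
    SC = "sc"


@dataclass
class CellRecord:
    """One droplet observation from a single-cell immune-profiling screen.

    ``cdr3a_list``/``cdr3b_list`` hold one CDR3 per reconstructed allele;
    more than one allele on either chain marks a putative doublet.  Count
    vectors are stored as tuples of ints so records compare by value.
    ``binder_label`` is the index of the bound panel antigen or ``None``.
    """

    barcode: str
    donor: str
    cdr3a_list: tuple = ()
    cdr3b_list: tuple = ()
    clonotype_id: Optional[str] = None
    total_mrna_count: int = 0
    pmhc_counts: tuple = ()
    nc_counts: tuple = ()
    surface_counts: tuple = ()
    binder_label: Optional[int] = NO_BINDER

    def __post_init__(self) -> None:
        self.cdr3a_list = tuple(self.cdr3a_list)
        self.cdr3b_list = tuple(self.cdr3b_list)
        self.pmhc_counts = tuple(int(c) for c in self.pmhc_counts)
        self.nc_counts = tuple(int(c) for c in self.nc_counts)
        self.surface_counts = tuple(int(c) for c in self.surface_counts)
        for name in ("pmhc_counts", "nc_counts", "surface_counts"):
            if any(c < 0 for c in getattr(self, name)):
                raise ValueError(f"{name} must be nonnegative ({self.barcode})")
        if self.total_mrna_count < 0:
            raise ValueError(f"total_mrna_count must be nonnegative ({self.barcode})")

    @property
    def is_doublet(self) -> bool:
        return len(self.cdr3a_list) > 1 or len(self.cdr3b_list) > 1

    @property
    def cdr3a(self) -> Optional[str]:
        return self.cdr3a_list[0] if self.cdr3a_list else None

    @property
    def cdr3b(self) -> Optional[str]:
        return self.cdr3b_list[0] if self.cdr3b_list else None


@dataclass(frozen=True)
class AntigenPanel:
    """The antigen species of a screen plus its negative-control species."""

    names: tuple
    peptides: tuple
    nc_names: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "peptides", tuple(self.peptides))
        object.__setattr__(self, "nc_names", tuple(self.nc_names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("antigen names must be unique")
        if len(self.names) != len(self.peptides):
            raise ValueError("one peptide per antigen name required")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, keep: list) -> "AntigenPanel":
        keep = list(keep)
        return AntigenPanel(
            names=[self.names[i] for i in keep],
            peptides=[self.peptides[i] for i in keep],
            nc_names=self.nc_names,
        )


@dataclass(frozen=True)
class BindingPair:
    """A (CDR3β, antigen peptide) record with a binary binding label."""

    cdr3b: str
    antigen: str
    label: int = 1
    source: Source = Source.IEDB

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        object.__setattr__(self, "source", Source(self.source))
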