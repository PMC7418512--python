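"""Synthetic single-cell dextramer screens and database-style pair sets.

The generator plants a per-antigen sequence motif at a (by default fixed)
position of the CDR3β of every clonotype that truly binds that antigen —
the regime where specificity behaves as a fixed-position motif problem —
and emulates the statistical structure of a droplet screen around it:

* clonotype structure (clone sizes geometric or fixed, all cells of a
  clone share sequences and ground truth),
* donor effects on label priors and surface-count means (never on motif
  content, so covariate-benefit experiments have a clean causal path),
* per-cell log-normal size factors scaling all count modalities,
* gamma–Poisson (negative binomial) UMI counts: the bound antigen's pMHC
  counts around ``binding_mean`` × size factor, every other antigen and
  the negative controls around ``background_mean`` × size factor,
* cell doublets that acquire the chains (and counts) of a second clone.

Ground truth is recorded per barcode, so recovery rates of every pipeline
stage are measurable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .encoding import AMINO_ACIDS
from .pipeline import assign_binder_labels
from .records import AntigenPanel, BindingPair, CellRecord, Source

__all__ = [
    "MotifSpec",
    "CountModel",
    "ScreenSimConfig",
    "SimulatedScreen",
    "simulate_repertoire",
    "simulate_pmhc_counts",
    "inject_doublets",
    "simulate_screen",
    "simulate_pair_database",
    "biased_donor_priors",
    "write_fixture_files",
]


@dataclass(frozen=True)
class MotifSpec:
    """A sequence motif marking binders of one antigen.

    ``insert_position`` is the 0-based offset within the CDR3β, or None
    for a uniformly random position per clonotype.  ``mutation_rate`` is
    the per-position probability that a motif residue is replaced by a
    different random residue.
    """

    antigen_index: int
    motif: str
    insert_position: Optional[int] = 3
    mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 3 <= len(self.motif) <= 6:
            raise ValueError("motif length must be 3–6 residues")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass(frozen=True)
class CountModel:
    """Gamma–Poisson count noise around size-factor-scaled means."""

    binding_mean: float = 100.0
    background_mean: float = 1.0
    dispersion: float = 10.0
    size_factor_sigma: float = 0.5
    total_mrna_scale: float = 5000.0

    def __post_init__(self) -> None:
        if self.binding_mean < 0 or self.background_mean <= 0:
            raise ValueError(
                "background_mean must be positive and binding_mean nonnegative "
                "(binding_mean 0 is the degenerate null-signal case)"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of a simulated screen."""

    n_clonotypes: int = 1000
    clone_size: tuple = ("geometric", 0.5)  # or ("fixed", k)
    max_clone_size: Optional[int] = None
    n_antigens: int = 8
    motifs: Optional[tuple] = None  # default: one random length-4 motif per antigen
    motif_mutation_rate: float = 0.05
    n_donors: int = 4
    donor_label_bias: Optional[tuple] = None  # (n_donors, n_antigens+1) prior weights
    n_nc: int = 6
    n_surface: int = 10
    count_model: CountModel = field(default_factory=CountModel)
    doublet_rate: float = 0.0
    cdr3_length_range: tuple = (12, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cdr3_length_range
        if not (8 <= lo <= hi <= 25):
            raise ValueError("cdr3_length_range must lie within [8, 25]")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must lie in [0, 1]")
        if self.n_antigens < 1 or self.n_clonotypes < 1 or self.n_donors < 1:
            raise ValueError("counts must be positive")
        if self.motifs is not None:
            object.__setattr__(self, "motifs", tuple(self.motifs))
            for m in self.motifs:
                end = len(m.motif) + (m.insert_position or 0)
                if end > lo:
                    raise ValueError(
                        f"motif {m.motif!r} at offset {m.insert_position} does not "
                        f"fit the minimum CDR3 length {lo}"
                    )
        if self.donor_label_bias is not None:
            bias = np.asarray(self.donor_label_bias, dtype=float)
            if bias.shape != (self.n_donors, self.n_antigens + 1):
                raise ValueError("donor_label_bias must be (n_donors, n_antigens+1)")
            if np.any(bias < 0) or np.any(bias.sum(axis=1) <= 0):
                raise ValueError("donor_label_bias rows must be valid prior weights")


@dataclass
class SimulatedScreen:
    """Cells plus per-barcode ground truth and the generating config."""

    cells: list
    truth: dict  # barcode -> true antigen index | None
    panel: AntigenPanel
    config: ScreenSimConfig
    doublet_barcodes: set = field(default_factory=set)
    surface_means: Optional[np.ndarray] = None  # (n_donors, n_surface)


def biased_donor_priors(
    n_donors: int, n_antigens: int, favored_weight: float = 0.75,
    none_weight: float = 0.3,
) -> tuple:
    """Label priors where donor d strongly favors antigen d mod n_antigens.

    Each row distributes ``1 − none_weight`` over antigens with
    ``favored_weight`` of that mass on the favored antigen.
    """
    priors = np.zeros((n_donors, n_antigens + 1))
    for d in range(n_donors):
        ag = np.full(n_antigens, (1 - favored_weight) / max(n_antigens - 1, 1))
        ag[d % n_antigens] = favored_weight
        priors[d, :n_antigens] = ag * (1 - none_weight)
        priors[d, n_antigens] = none_weight
    return tuple(map(tuple, priors))


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _plant_motif(rng: np.random.Generator, backbone: str, spec: MotifSpec) -> str:
    pos = spec.insert_position
    if pos is None:
        pos = int(rng.integers(0, len(backbone) - len(spec.motif) + 1))
    if pos + len(spec.motif) > len(backbone):
        raise ValueError(
            f"motif {spec.motif!r} at position {pos} exceeds CDR3 length {len(backbone)}"
        )
    motif = list(spec.motif)
    for i, res in enumerate(motif):
        if rng.random() < spec.mutation_rate:
            alternatives = [a for a in AMINO_ACIDS if a != res]
            motif[i] = str(rng.choice(alternatives))
    return backbone[:pos] + "".join(motif) + backbone[pos + len(motif):]


def _default_motifs(rng: np.random.Generator, n_antigens: int,
                    mutation_rate: float) -> tuple:
    return tuple(
        MotifSpec(
            antigen_index=j,
            motif="".join(rng.choice(list(AMINO_ACIDS), size=4)),
            insert_position=3,
            mutation_rate=mutation_rate,
        )
        for j in range(n_antigens)
    )


def simulate_repertoire(config: ScreenSimConfig) -> SimulatedScreen:
    """Draw clonotypes, donors, ground-truth labels and CDR3 sequences.

    Counts are left empty; fill them with :func:`simulate_pmhc_counts`.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cdr3_length_range
    motifs = config.motifs
    if motifs is None:
        motifs = _default_motifs(rng, config.n_antigens, config.motif_mutation_rate)
    motif_by_antigen = {m.antigen_index: m for m in motifs}
    if config.donor_label_bias is not None:
        priors = np.asarray(config.donor_label_bias, dtype=float)
        priors = priors / priors.sum(axis=1, keepdims=True)
    else:
        priors = np.full(
            (config.n_donors, config.n_antigens + 1), 1.0 / (config.n_antigens + 1)
        )
    cells: list = []
    truth: dict = {}
    for j in range(config.n_clonotypes):
        donor = int(rng.integers(config.n_donors))
        label = int(rng.choice(config.n_antigens + 1, p=priors[donor]))
        true_label = None if label == config.n_antigens else label
        cdr3a = _random_cdr3(rng, lo, hi)
        cdr3b = _random_cdr3(rng, lo, hi)
        if true_label is not None and true_label in motif_by_antigen:
            cdr3b = _plant_motif(rng, cdr3b, motif_by_antigen[true_label])
        kind, param = config.clone_size
        if kind == "fixed":
            size = int(param)
        elif kind == "geometric":
            size = int(rng.geometric(param))
        else:
            raise ValueError(f"unknown clone size distribution {kind!r}")
        if config.max_clone_size is not None:
            size = min(size, config.max_clone_size)
        for c in range(size):
            barcode = f"cell_{j}_{c}"
            cells.append(
                CellRecord(
                    barcode=barcode,
                    donor=f"donor_{donor}",
                    cdr3a_list=(cdr3a,),
                    cdr3b_list=(cdr3b,),
                    clonotype_id=f"sim_clone_{j}",
                )
            )
            truth[barcode] = true_label
    peptides = ["".join(rng.choice(list(AMINO_ACIDS), size=9))
                for _ in range(config.n_antigens)]
    panel = AntigenPanel(
        names=tuple(f"antigen_{j}" for j in range(config.n_antigens)),
        peptides=tuple(peptides),
        nc_names=tuple(f"NC_{j}" for j in range(config.n_nc)),
    )
    return SimulatedScreen(cells=cells, truth=truth, panel=panel, config=config)


def _nb(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial draws with the given mean and dispersion
    (variance = mean + mean²/dispersion)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_pmhc_counts(
    screen: SimulatedScreen, count_model: Optional[CountModel] = None,
    seed: Optional[int] = None,
) -> SimulatedScreen:
    """Fill pMHC / negative-control / surface / total counts in place."""
    cm = count_model or screen.config.count_model
    rng = np.random.default_rng(screen.config.seed + 1 if seed is None else seed)
    n_ag = screen.config.n_antigens
    donors = sorted({c.donor for c in screen.cells})
    surface_means = rng.uniform(5, 50, size=(len(donors), screen.config.n_surface))
    donor_idx = {d: i for i, d in enumerate(donors)}
    for cell in screen.cells:
        s = rng.lognormal(mean=0.0, sigma=cm.size_factor_sigma)
        means = np.full(n_ag, s * cm.background_mean)
        label = screen.truth[cell.barcode]
        # binding_mean 0 is the null-signal case: the bound antigen's counts
        # stay at background level
        if label is not None and cm.binding_mean > 0:
            means[label] = s * cm.binding_mean
        cell.pmhc_counts = tuple(_nb(rng, means, cm.dispersion))
        cell.nc_counts = tuple(
            _nb(rng, np.full(screen.config.n_nc, s * cm.background_mean), cm.dispersion)
        )
        cell.surface_counts = tuple(
            _nb(rng, s * surface_means[donor_idx[cell.donor]], cm.dispersion)
        )
        cell.total_mrna_count = int(round(s * cm.total_mrna_scale))
    screen.surface_means = surface_means
    return screen


def inject_doublets(screen: SimulatedScreen, doublet_rate: Optional[float] = None,
                    seed: Optional[int] = None) -> SimulatedScreen:
    """Turn a seeded fraction of cells into doublets.

    Each affected cell acquires the α- and β-chain of a second random
    clonotype (always adding at least one extra allele) plus counts drawn
    for that clone's true label; it is flagged in the truth metadata.
    """
    rate = screen.config.doublet_rate if doublet_rate is None else doublet_rate
    if not 0.0 <= rate <= 1.0:
        raise ValueError("doublet rate must lie in [0, 1]")
    if rate == 0.0:
        return screen
    clonotypes = sorted({c.clonotype_id for c in screen.cells})
    if len(clonotypes) < 2:
        raise ValueError("doublet injection requires at least 2 clonotypes")
    rng = np.random.default_rng(screen.config.seed + 2 if seed is None else seed)
    by_clone: dict = {}
    for c in screen.cells:
        by_clone.setdefault(c.clonotype_id, c)
    n_doublets = round(rate * len(screen.cells))
    chosen = rng.choice(len(screen.cells), size=n_doublets, replace=False)
    cm = screen.config.count_model
    for i in chosen:
        cell = screen.cells[i]
        other_id = clonotypes[int(rng.integers(len(clonotypes)))]
        while other_id == cell.clonotype_id:
            other_id = clonotypes[int(rng.integers(len(clonotypes)))]
        other = by_clone[other_id]
        cell.cdr3a_list = cell.cdr3a_list + (other.cdr3a_list[0],)
        cell.cdr3b_list = cell.cdr3b_list + (other.cdr3b_list[0],)
        if cell.pmhc_counts:
            s = rng.lognormal(mean=0.0, sigma=cm.size_factor_sigma)
            means = np.full(screen.config.n_antigens, s * cm.background_mean)
            other_label = screen.truth[other.barcode]
            if other_label is not None:
                means[other_label] = s * cm.binding_mean
            extra = _nb(rng, means, cm.dispersion)
            cell.pmhc_counts = tuple(np.array(cell.pmhc_counts) + extra)
        screen.doublet_barcodes.add(cell.barcode)
    return screen


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Full pipeline: repertoire → counts → doublets → observed labels."""
    screen = simulate_repertoire(config)
    simulate_pmhc_counts(screen)
    inject_doublets(screen)
    assign_binder_labels(screen.cells)
    return screen


def simulate_pair_database(
    n_tcrs: int, n_antigens: int, motifs: Optional[Sequence[MotifSpec]] = None,
    seed: int = 0, cdr3_length_range: tuple = (12, 18),
    source: Source = Source.IEDB,
) -> list:
    """Positive CDR3β–antigen pairs with motif-determined specificity.

    Antigen peptides are random fixed strings of length 8–12; each TCR
    appears in exactly one positive pair.  Negatives are produced
    separately by ``generate_shuffled_negatives``.
    """
    if n_antigens < 2:
        raise ValueError("need at least 2 antigens for a pair database")
    rng = np.random.default_rng(seed)
    if motifs is None:
        motifs = _default_motifs(rng, n_antigens, mutation_rate=0.05)
    motif_by_antigen = {m.antigen_index: m for m in motifs}
    peptides = []
    seen = set()
    for _ in range(n_antigens):
        while True:
            pep = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(8, 13))))
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
                break
    lo, hi = cdr3_length_range
    pairs = []
    used_tcrs = set()
    for _ in range(n_tcrs):
        ag = int(rng.integers(n_antigens))
        while True:
            cdr3b = _random_cdr3(rng, lo, hi)
            if ag in motif_by_antigen:
                cdr3b = _plant_motif(rng, cdr3b, motif_by_antigen[ag])
            if cdr3b not in used_tcrs:
                used_tcrs.add(cdr3b)
                break
        pairs.append(BindingPair(cdr3b=cdr3b, antigen=peptides[ag], label=1,
                                 source=source))
    return pairs


def write_fixture_files(screen_or_pairs, out_dir, prefix: str = "sim"):
    """Emit the CSV/TSV dialects consumed by the readers; round trips
    through ``read_screen_tables`` / ``read_database_table`` reproduce the
    in-memory records exactly."""
    from . import io as tio

    if isinstance(screen_or_pairs, SimulatedScreen):
        screen = screen_or_pairs
        return tio.write_screen_tables(screen.cells, screen.panel, out_dir,
                                       prefix=prefix)
    return (tio.write_database_table(
        screen_or_pairs, f"{out_dir}/{prefix}_pairs.tsv"
    ),)
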