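"""Readers and writers for screen tables and database-style pair exports.

Dialects
--------
Binarized-matrix CSV (one row per droplet), comma-separated with header:

* ``barcode``, ``donor``, ``cdr3s_a``, ``cdr3s_b`` (``;``-joined allele
  lists), ``total_counts``;
* one raw UMI count column per panel antigen, named after the antigen,
  with a paired boolean ``<antigen>_binder`` column;
* negative-control columns named ``NC_*``; surface-protein columns named
  ``surface_*``.

Clonotype CSV: ``barcode,clonotype_id``.  When present it is the
authoritative clonotype assignment (sequence-identity assignment is the
fallback).

Database TSV (IEDB/VDJdb-style): columns ``cdr3b``, ``antigen``, optional
``mhc`` (used by the HLA filter) and optional ``label`` (default 1).
Column names are remappable via ``column_map`` to absorb other exports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .records import BindingPair, CellRecord, AntigenPanel, Source

__all__ = [
    "SchemaError",
    "read_screen_tables",
    "write_screen_tables",
    "read_database_table",
    "write_database_table",
    "write_split_sidecar",
]

REQUIRED_CELL_COLUMNS = ("barcode", "donor", "cdr3s_a", "cdr3s_b", "total_counts")


class SchemaError(ValueError):
    """A required column is missing or a value has the wrong type."""


def _split_alleles(value) -> tuple:
    if pd.isna(value) or value == "":
        return ()
    return tuple(str(value).split(";"))


def infer_screen_columns(columns: Sequence[str]):
    """Infer antigen / negative-control / surface columns from the header."""
    columns = list(columns)
    antigens = [c[: -len("_binder")] for c in columns if c.endswith("_binder")]
    antigens = [a for a in antigens if a in columns]
    nc = [c for c in columns if c.startswith("NC_")]
    surface = [c for c in columns if c.startswith("surface_")]
    return antigens, nc, surface


def read_screen_tables(
    binarized_matrix_path,
    clonotype_path=None,
    antigen_columns: Optional[Sequence[str]] = None,
    column_map: Optional[dict] = None,
):
    """Read a binarized-matrix CSV (and optional clonotype CSV) into cell
    records.

    Returns ``(cells, panel)``.  Binder labels are taken from the
    ``*_binder`` columns (the single flagged antigen per row); counts are
    validated as nonnegative integers.
    """
    df = pd.read_csv(binarized_matrix_path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    antigens, nc_cols, surface_cols = infer_screen_columns(df.columns)
    if antigen_columns is not None:
        antigens = list(antigen_columns)
    if not antigens:
        raise SchemaError("no antigen count columns (paired with *_binder) found")
    count_cols = antigens + nc_cols + surface_cols + ["total_counts"]
    for col in count_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            raise SchemaError(f"column {col!r} must contain nonnegative numbers")
        df[col] = vals.astype(int)

    clono_map = {}
    if clonotype_path is not None:
        cdf = pd.read_csv(clonotype_path)
        for col in ("barcode", "clonotype_id"):
            if col not in cdf.columns:
                raise SchemaError(f"clonotype table missing column {col!r}")
        clono_map = dict(zip(cdf["barcode"].astype(str), cdf["clonotype_id"].astype(str)))

    cells = []
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        binder = None
        for j, a in enumerate(antigens):
            if bool(rec.get(f"{a}_binder", False)):
                binder = j
                break
        cells.append(
            CellRecord(
                barcode=str(rec["barcode"]),
                donor=str(rec["donor"]),
                cdr3a_list=_split_alleles(rec["cdr3s_a"]),
                cdr3b_list=_split_alleles(rec["cdr3s_b"]),
                clonotype_id=clono_map.get(str(rec["barcode"])),
                total_mrna_count=int(rec["total_counts"]),
                pmhc_counts=tuple(int(rec[a]) for a in antigens),
                nc_counts=tuple(int(rec[c]) for c in nc_cols),
                surface_counts=tuple(int(rec[c]) for c in surface_cols),
                binder_label=binder,
            )
        )
    panel = AntigenPanel(names=antigens, peptides=antigens, nc_names=nc_cols)
    return cells, panel


def write_screen_tables(
    cells: Sequence[CellRecord],
    panel: AntigenPanel,
    out_dir,
    prefix: str = "screen",
    surface_names: Optional[Sequence[str]] = None,
):
    """Write cells to the binarized-matrix + clonotype CSV dialect.

    Returns ``(matrix_path, clonotype_path)``.  Binder columns mirror the
    records' ``binder_label``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_surface = len(cells[0].surface_counts) if cells else 0
    if surface_names is None:
        surface_names = [f"surface_{j}" for j in range(n_surface)]
    rows = []
    for c in cells:
        row = {
            "barcode": c.barcode,
            "donor": c.donor,
            "cdr3s_a": ";".join(c.cdr3a_list),
            "cdr3s_b": ";".join(c.cdr3b_list),
            "total_counts": c.total_mrna_count,
        }
        for j, a in enumerate(panel.names):
            row[a] = c.pmhc_counts[j]
            row[f"{a}_binder"] = c.binder_label == j
        for j, nc in enumerate(panel.nc_names):
            row[nc] = c.nc_counts[j]
        for j, s in enumerate(surface_names):
            row[s] = c.surface_counts[j]
        rows.append(row)
    matrix_path = out_dir / f"{prefix}_binarized_matrix.csv"
    pd.DataFrame(rows).to_csv(matrix_path, index=False)
    clono_path = out_dir / f"{prefix}_clonotypes.csv"
    pd.DataFrame(
        {"barcode": [c.barcode for c in cells],
         "clonotype_id": [c.clonotype_id or "" for c in cells]}
    ).to_csv(clono_path, index=False)
    return matrix_path, clono_path


def read_database_table(
    path,
    source: Source = Source.IEDB,
    hla_filter: Optional[str] = None,
    column_map: Optional[dict] = None,
    max_antigen_len: int = 25,
    max_cdr3_len: int = 40,
):
    """Read an IEDB/VDJdb-style TSV of paired CDR3β–antigen sequences.

    Rows failing the HLA filter (if given) or exceeding the padded lengths
    are dropped; the survivors become positive binding pairs unless a
    ``label`` column says otherwise.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("cdr3b", "antigen"):
        if col not in df.columns:
            raise SchemaError(f"database table missing column {col!r}")
    if hla_filter is not None:
        if "mhc" not in df.columns:
            raise SchemaError("HLA filtering requires an 'mhc' column")
        df = df[df["mhc"].astype(str) == hla_filter]
    pairs = []
    for rec in df.to_dict("records"):
        cdr3b = str(rec["cdr3b"]).upper()
        antigen = str(rec["antigen"]).upper()
        if len(cdr3b) > max_cdr3_len or len(antigen) > max_antigen_len:
            continue
        pairs.append(
            BindingPair(
                cdr3b=cdr3b,
                antigen=antigen,
                label=int(rec.get("label", 1)),
                source=source,
            )
        )
    return pairs


def write_database_table(pairs: Sequence[BindingPair], path, mhc: Optional[str] = None):
    """Write binding pairs to the database TSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"cdr3b": p.cdr3b, "antigen": p.antigen, "label": p.label,
         **({"mhc": mhc} if mhc is not None else {})}
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_split_sidecar(split, path, extra: Optional[dict] = None):
    """Persist a split assignment (plus seeds/config echo) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = split.to_dict()
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
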