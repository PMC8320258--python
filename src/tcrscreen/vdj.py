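"""Contig-table IO, per-cell chain pairing and CDR3β-keyed clonotype calling.

A 10x-style ``filtered_contig_annotations.csv`` lists one assembled V(D)J
contig per row.  This module reduces those rows to per-barcode cells and
partitions paired cells into clonotypes defined by the *nucleotide* sequence
of the CDR3β junction — the junction is diverse enough to act as a natural
clonal barcode, and nucleotide (not amino-acid) identity keeps independent
rearrangements that converge on one protein sequence apart.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: bit-exact header of the contig CSV dialect
CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "chain", "v_gene", "j_gene",
    "cdr3", "cdr3_nt", "umis", "productive",
]


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


@dataclass(frozen=True)
class ContigRecord:
    """One assembled V(D)J contig for one droplet barcode."""

    barcode: str
    chain: str            # TRA / TRB (others dropped at read)
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umis: int
    productive: bool
    contig_id: str = ""


@dataclass
class CellVDJ:
    """Productive chains of one barcode, with its pairing status.

    ``status`` is ``paired`` when exactly one distinct productive CDR3β
    nucleotide sequence is present (one or two α chains are allowed —
    dual-α T cells are common), ``mixed`` when two or more distinct
    productive β junctions are seen (doublet or chimera; excluded from
    clonotype membership), and ``undetectable`` when no productive β
    contig was recovered.
    """

    barcode: str
    beta_contigs: list[ContigRecord] = field(default_factory=list)
    alpha_contigs: list[ContigRecord] = field(default_factory=list)
    status: str = "undetectable"

    @property
    def beta_key(self) -> str | None:
        """CDR3β nucleotide clonotype key, or None unless status=paired."""
        if self.status != "paired":
            return None
        return self.beta_contigs[0].cdr3_nt


@dataclass
class Clonotype:
    """Group of cells sharing one CDR3β nucleotide sequence."""

    key: str
    v_gene: str
    j_gene: str
    cdr3b_aa: str
    alpha_variants: set[tuple[str, str, str, str]]  # (v, j, cdr3_nt, cdr3_aa)
    barcodes: set[str]

    @property
    def count(self) -> int:
        return len(self.barcodes)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() == "true"


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Read a contig annotation CSV into :class:`ContigRecord` rows.

    Rows with ``is_cell=False`` or a chain other than TRA/TRB are dropped
    (counts logged).  Unknown extra columns are tolerated; a missing
    mandatory column raises :class:`FormatError` naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in CONTIG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r} in {path}")
    records: list[ContigRecord] = []
    n_not_cell = n_other_chain = n_malformed = 0
    for i, row in enumerate(df.itertuples(index=False)):
        if not _parse_bool(row.is_cell):
            n_not_cell += 1
            continue
        chain = row.chain.strip()
        if chain not in ("TRA", "TRB"):
            n_other_chain += 1
            continue
        try:
            umis = int(row.umis)
        except ValueError:
            n_malformed += 1
            logger.warning("%s line %d: malformed umis %r", path, i + 2, row.umis)
            continue
        records.append(ContigRecord(
            barcode=row.barcode,
            chain=chain,
            v_gene=row.v_gene,
            j_gene=row.j_gene,
            cdr3_aa=row.cdr3,
            cdr3_nt=row.cdr3_nt,
            umis=umis,
            productive=_parse_bool(row.productive),
            contig_id=row.contig_id,
        ))
    logger.info(
        "%s: %d contigs kept (%d non-cell, %d non-TRA/TRB, %d malformed dropped)",
        path.name, len(records), n_not_cell, n_other_chain, n_malformed,
    )
    return records


def write_contigs(records: list[ContigRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write contigs back out in the same CSV dialect."""
    if isinstance(records, pd.DataFrame):
        df = records[CONTIG_COLUMNS]
    else:
        df = pd.DataFrame(
            [{
                "barcode": r.barcode, "is_cell": "True", "contig_id": r.contig_id,
                "chain": r.chain, "v_gene": r.v_gene, "j_gene": r.j_gene,
                "cdr3": r.cdr3_aa, "cdr3_nt": r.cdr3_nt, "umis": r.umis,
                "productive": str(r.productive),
            } for r in records],
            columns=CONTIG_COLUMNS,
        )
    df.to_csv(path, index=False, lineterminator="\n")


def filter_productive(records: list[ContigRecord]) -> list[ContigRecord]:
    """Keep productive contigs; deduplicate identical (barcode, chain, cdr3_nt).

    Among duplicates the contig with the highest UMI support wins (ties:
    lexicographically smallest contig_id, for determinism).
    """
    best: dict[tuple[str, str, str], ContigRecord] = {}
    for r in records:
        if not r.productive:
            continue
        k = (r.barcode, r.chain, r.cdr3_nt)
        cur = best.get(k)
        if cur is None or (r.umis, _neg_id(r)) > (cur.umis, _neg_id(cur)):
            best[k] = r
    return list(best.values())


def _neg_id(r: ContigRecord):
    # invert lexicographic order so max() prefers the smallest contig_id
    return tuple(-ord(c) for c in r.contig_id)


def group_cells(records: list[ContigRecord]) -> list[CellVDJ]:
    """Group productive-filtered contigs into one :class:`CellVDJ` per barcode."""
    by_bc: dict[str, CellVDJ] = {}
    for r in records:
        cell = by_bc.setdefault(r.barcode, CellVDJ(barcode=r.barcode))
        (cell.beta_contigs if r.chain == "TRB" else cell.alpha_contigs).append(r)
    for cell in by_bc.values():
        beta_keys = {c.cdr3_nt for c in cell.beta_contigs}
        if len(beta_keys) >= 2:
            cell.status = "mixed"
        elif len(beta_keys) == 1:
            cell.status = "paired"
        else:
            cell.status = "undetectable"
        cell.beta_contigs.sort(key=lambda c: (-c.umis, c.contig_id))
        cell.alpha_contigs.sort(key=lambda c: (-c.umis, c.contig_id))
    return [by_bc[b] for b in sorted(by_bc)]


def call_clonotypes(cells: list[CellVDJ]) -> list[Clonotype]:
    """Partition paired cells into clonotypes by exact CDR3β nt identity.

    Mixed and undetectable cells carry no key and are excluded.  The
    representative β annotation (V/J, amino acids) comes from the member
    contig with the highest UMI support (tie: smallest contig_id).
    """
    groups: dict[str, list[CellVDJ]] = defaultdict(list)
    for cell in cells:
        key = cell.beta_key
        if key is not None:
            groups[key].append(cell)
    out = []
    for key in sorted(groups):
        members = groups[key]
        rep = min(
            (c for cell in members for c in cell.beta_contigs),
            key=lambda c: (-c.umis, c.contig_id),
        )
        alphas = {
            (a.v_gene, a.j_gene, a.cdr3_nt, a.cdr3_aa)
            for cell in members for a in cell.alpha_contigs
        }
        out.append(Clonotype(
            key=key, v_gene=rep.v_gene, j_gene=rep.j_gene, cdr3b_aa=rep.cdr3_aa,
            alpha_variants=alphas, barcodes={c.barcode for c in members},
        ))
    return out


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate a junction nucleotide sequence with the standard code."""
    return str(Seq(cdr3_nt).translate())


def clonotypes_to_frame(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Tabulate clonotypes (sorted by descending count then key)."""
    rows = [{
        "key": c.key,
        "cdr3b_aa": c.cdr3b_aa,
        "v_gene": c.v_gene,
        "j_gene": c.j_gene,
        "n_cells": c.count,
        "n_alpha_variants": len(c.alpha_variants),
        "barcodes": ";".join(sorted(c.barcodes)),
    } for c in clonotypes]
    df = pd.DataFrame(rows, columns=[
        "key", "cdr3b_aa", "v_gene", "j_gene",
        "n_cells", "n_alpha_variants", "barcodes",
    ])
    if len(df):
        df = df.sort_values(["n_cells", "key"], ascending=[False, True],
                            ignore_index=True)
    return df


def write_clonotype_table(clonotypes: list[Clonotype], path: str | Path) -> None:
    clonotypes_to_frame(clonotypes).to_csv(path, sep="\t", index=False,
                                           lineterminator="\n")
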