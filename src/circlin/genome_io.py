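"""Readers and writers for the formats the toolkit touches.

All genome coordinates are 1-based inclusive; CDS ranks are 1-based
ordinals assigned by start coordinate. Chromosomes are treated as
circular by default, which matters for origin-spanning features and
for every downstream statistic in this package.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

HIT_COLUMNS = ["query_id", "subject_id", "evalue", "bitscore"]


@dataclass(frozen=True)
class CircularGenome:
    """A (by default circular) chromosome sequence over the alphabet A,C,G,T,N."""

    id: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = [i + 1 for i, b in enumerate(self.sequence) if b not in _VALID_BASES]
        if bad:
            shown = ", ".join(map(str, bad[:10]))
            more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
            raise ValueError(
                f"genome {self.id!r}: non-IUPAC-DNA characters at positions {shown}{more}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CDSRecord:
    """One protein-coding feature with its ordinal rank in genome order."""

    gene_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; < start only for origin-spanning features
    strand: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"CDS {self.gene_id!r}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.gene_id!r}: strand must be '+' or '-'")


@dataclass
class HitTable:
    """All-vs-all protein similarity hits, reduced to one best row per pair.

    The reduction keeps, per (query, subject), the row with the smallest
    e-value, breaking ties by the larger bit score.
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=HIT_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        if (self.rows["evalue"] < 0).any():
            raise ValueError("hit table contains negative e-values")
        self.rows = _reduce_best(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def _reduce_best(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df.reset_index(drop=True)
    df = df.sort_values(
        ["query_id", "subject_id", "evalue", "bitscore"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    df = df.drop_duplicates(["query_id", "subject_id"], keep="first")
    return df.reset_index(drop=True)


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome(
    path: str | Path, record_id: str | None = None, circular: bool = True
) -> CircularGenome:
    """Read one genome from a (possibly gzipped) FASTA file.

    Multi-record files require ``record_id`` to disambiguate.
    """
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if record_id is None:
        if len(records) > 1:
            ids = ", ".join(r.id for r in records)
            raise ValueError(
                f"{path}: multiple records ({ids}); pass record_id to select one"
            )
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"{path}: no record with id {record_id!r}")
        rec = matches[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq).upper(), is_circular=circular)


def _parse_gff3_cds(lines: Iterable[str]) -> list[tuple[str, int, int, str]]:
    out = []
    n_features = 0
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            continue
        n_features += 1
        if parts[2] != "CDS":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("Parent") or attrs.get("Name")
        if gene_id is None:
            raise ValueError(f"GFF3 CDS feature without ID attribute: {line!r}")
        out.append((gene_id, int(parts[3]), int(parts[4]), parts[6]))
    if n_features and not out:
        raise ValueError("no CDS features found in GFF3 input")
    return out


def _parse_tsv_cds(lines: Iterable[str]) -> list[tuple[str, int, int, str]]:
    out = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("gene_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"CDS TSV row with <4 columns: {line!r}")
        out.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return out


def read_cds(
    path: str | Path, genome_length: int | None = None
) -> tuple[list[CDSRecord], int]:
    """Read CDS coordinates from GFF3 or minimal 4-column TSV.

    Returns the records sorted by start (ties by end, then gene_id) with
    ranks 1..O assigned in that order, together with O. A feature with
    end < start is accepted as origin-spanning only when ``genome_length``
    is given; it is ranked by its start like any other feature.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        rest = fh.readlines()
    lines = [first] + rest
    is_gff = first.startswith("##gff") or (
        len(first.split("\t")) >= 9 and not first.startswith("#")
    )
    raw = _parse_gff3_cds(lines) if is_gff else _parse_tsv_cds(lines)
    if not raw:
        raise ValueError(f"{path}: no CDS features found")

    seen: dict[tuple[str, int, int], bool] = {}
    for gene_id, start, end, strand in raw:
        if end < start and genome_length is None:
            raise ValueError(
                f"CDS {gene_id!r}: end {end} < start {start}; pass genome_length "
                "if this feature spans the origin"
            )
        key = (gene_id, start, end)
        if key in seen:
            raise ValueError(f"duplicate CDS record {gene_id!r} at {start}-{end}")
        seen[key] = True

    raw.sort(key=lambda r: (r[1], r[2], r[0]))
    records = [
        CDSRecord(gene_id=g, start=s, end=e, strand=st, rank=i + 1)
        for i, (g, s, e, st) in enumerate(raw)
    ]
    return records, len(records)


def write_cds(records: list[CDSRecord], path: str | Path) -> None:
    """Write CDS records as the minimal TSV dialect (round-trips with read_cds)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.start}\t{r.end}\t{r.strand}\n")


def read_hit_table(path: str | Path, dialect: str = "outfmt6") -> HitTable:
    """Read a tab-delimited protein hit table.

    ``dialect='outfmt6'`` expects the 12-column BLAST tabular layout
    (e-value in column 11, bit score in column 12); ``dialect='minimal'``
    expects 4 columns: query, subject, e-value, bit score.
    """
    if dialect not in ("outfmt6", "minimal"):
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty hit table", path)
        return HitTable()
    if dialect == "outfmt6":
        if df.shape[1] < 12:
            raise ValueError(
                f"{path}: outfmt6 requires 12 columns, found {df.shape[1]}"
            )
        sub = df.iloc[:, [0, 1, 10, 11]].copy()
    else:
        if df.shape[1] < 4:
            raise ValueError(
                f"{path}: minimal dialect requires 4 columns, found {df.shape[1]}"
            )
        sub = df.iloc[:, [0, 1, 2, 3]].copy()
    sub.columns = HIT_COLUMNS
    try:
        sub["evalue"] = sub["evalue"].astype(float)
        sub["bitscore"] = sub["bitscore"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable numeric field ({exc})") from exc
    return HitTable(rows=sub)
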