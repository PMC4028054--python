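"""Readers and writers for the tabular and sequence formats the pipeline touches.

Three formats are supported, all plain text (UTF-8, LF newlines):

* BLAST tabular ``outfmt 6`` hit tables (12 tab-separated columns), the
  lingua franca carrier for similarity searches.  Coordinates follow the
  BLAST convention — 1-based, inclusive — and are normalized on input so
  that ``q_start <= q_end`` (and likewise for the subject), with explicit
  orientation flags retained.
* FASTA nucleotide files, read and written through Biopython.
* Rectangular TSV matrices with a header row of column ids and a first
  column of row ids (e.g. microarray gene x stage expression).

Parsing is strict: malformed lines raise :class:`ParseError` naming the
offending line number rather than being silently dropped.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "SeqRecord",
    "MatrixTable",
    "ParseError",
    "parse_hit_table",
    "write_hit_table",
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "write_matrix",
]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


@dataclass
class HitRecord:
    """One similarity hit (one ``outfmt 6`` line).

    Coordinates are 1-based inclusive; the constructor normalizes them so
    ``q_start <= q_end`` and ``s_start <= s_end``, recording a reversed
    orientation in :attr:`query_reversed` / :attr:`subject_reversed`.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    query_reversed: bool = False
    subject_reversed: bool = False

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("hit ids must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue!r} for {self.query_id}")
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore {self.bitscore!r} for {self.query_id}")
        if not math.isfinite(self.evalue):
            raise ValueError(f"non-finite e-value for {self.query_id}")
        if self.q_start > self.q_end:
            self.q_start, self.q_end = self.q_end, self.q_start
            self.query_reversed = True
        if self.s_start > self.s_end:
            self.s_start, self.s_end = self.s_end, self.s_start
            self.subject_reversed = True
        if self.q_start < 1 or self.s_start < 1:
            raise ValueError(f"coordinates are 1-based; got {self.q_start}, {self.s_start}")

    @property
    def q_span(self) -> int:
        """Length of the query interval covered by this hit (nt or aa)."""
        return self.q_end - self.q_start + 1

    def flipped(self) -> "HitRecord":
        """The same hit seen from the subject's side (query/subject swapped)."""
        return HitRecord(
            query_id=self.subject_id,
            subject_id=self.query_id,
            pct_identity=self.pct_identity,
            aln_length=self.aln_length,
            mismatches=self.mismatches,
            gap_opens=self.gap_opens,
            q_start=self.s_start,
            q_end=self.s_end,
            s_start=self.q_start,
            s_end=self.q_end,
            evalue=self.evalue,
            bitscore=self.bitscore,
            query_reversed=self.subject_reversed,
            subject_reversed=self.query_reversed,
        )


def parse_hit_table(path, dialect: str = "outfmt6") -> list[HitRecord]:
    """Parse a BLAST tabular (``outfmt 6``) TSV into :class:`HitRecord` objects.

    Records are returned in file order.  Lines with fewer than 12 columns
    raise :class:`ParseError`; extra columns beyond 12 are ignored with a
    logged warning.  Blank lines and ``#`` comment lines are skipped.
    """
    if dialect != "outfmt6":
        raise ValueError(f"unsupported hit-table dialect: {dialect!r}")
    records: list[HitRecord] = []
    warned_extra = False
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            if len(fields) > 12 and not warned_extra:
                logger.warning(
                    "%s: line %d has %d columns; columns beyond 12 are ignored",
                    path, lineno, len(fields),
                )
                warned_extra = True
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_hit_table(records: Iterable[HitRecord], path) -> None:
    """Write hits as 12-column ``outfmt 6`` TSV (normalized coordinates)."""
    with _open_text(path, "wt") as handle:
        for r in records:
            handle.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.pct_identity:.6g}",
                        str(r.aln_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        f"{r.evalue:.6g}",
                        f"{r.bitscore:.6g}",
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class SeqRecord:
    """A nucleotide sequence with a unique id (a contig, read or CDS)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file; ids are taken up to the first whitespace, sequences
    uppercased.  Duplicate ids and empty records are errors."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for bio in SeqIO.parse(handle, "fasta"):
            seq = str(bio.seq).upper()
            if not seq:
                raise ParseError(f"{path}: record {bio.id!r} has an empty sequence")
            if bio.id in seen:
                raise ParseError(f"{path}: duplicate sequence id {bio.id!r}")
            seen.add(bio.id)
            records.append(SeqRecord(id=bio.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    bios = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bios)


@dataclass
class MatrixTable:
    """A rectangular labelled matrix backed by a pandas DataFrame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate row ids in matrix")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate column ids in matrix")

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self):
        return self.df.to_numpy()


_BOOL_TOKENS = {"0": False, "1": True, "true": True, "false": False}


def read_matrix(path, value_kind: str = "real") -> MatrixTable:
    """Read a TSV matrix (header row of column ids, first column of row ids).

    ``value_kind`` is ``"real"`` (floats) or ``"bool"`` (0/1/true/false).
    Ragged rows and, under ``real``, non-numeric cells are errors.
    """
    if value_kind not in ("real", "bool"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    with _open_text(path) as handle:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in handle]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    ncol = len(col_ids)
    row_ids: list[str] = []
    rows: list[list] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != ncol + 1:
            raise ParseError(
                f"{path}: line {lineno}: ragged row ({len(fields) - 1} cells, expected {ncol})"
            )
        row_ids.append(fields[0])
        parsed = []
        for j, cell in enumerate(fields[1:], start=1):
            if value_kind == "real":
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric cell {cell!r} in column {j}"
                    ) from None
            else:
                token = cell.strip().lower()
                if token not in _BOOL_TOKENS:
                    raise ParseError(
                        f"{path}: line {lineno}: non-boolean cell {cell!r} in column {j}"
                    )
                parsed.append(_BOOL_TOKENS[token])
        rows.append(parsed)
    dtype = float if value_kind == "real" else bool
    df = pd.DataFrame(rows, index=row_ids, columns=col_ids, dtype=dtype)
    return MatrixTable(df)


def write_matrix(table: MatrixTable, path) -> None:
    df = table.df
    is_bool = bool(len(df.dtypes)) and all(dt == bool for dt in df.dtypes)
    with _open_text(path, "wt") as handle:
        handle.write("\t".join(["id", *df.columns]) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            if is_bool:
                cells = ["1" if v else "0" for v in row]
            else:
                cells = [f"{float(v):.6g}" for v in row]
            handle.write("\t".join([str(rid), *cells]) + "\n")
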