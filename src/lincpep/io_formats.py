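"""Readers, writers and core containers for every file format the screen touches.

All genomic coordinates are 0-based half-open internally, matching BED, the
only interval format consumed.  FASTA sequences are uppercased on read and
``U`` is mapped to ``T`` so RNA and DNA records are interchangeable.  Tabular
files are tab-separated with a required header row; qPCR CT tables are CSV
with blank cells meaning "no amplification".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomicInterval",
    "SampleInfo",
    "ExpressionMatrix",
    "TranscriptModel",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_expression_table",
    "write_expression_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_ct_table",
    "write_ct_table",
    "read_transcript_models",
    "write_transcript_models",
    "interval_from_1based",
    "interval_to_1based",
]

VALID_STRANDS = ("+", "-", ".")
VALID_ROLES = ("tumor", "normal_tissue", "nuclear", "cytoplasmic")

_FASTA_ILLEGAL = re.compile(r"[^ACGTNU]")
_SEQ_ALPHABET = re.compile(r"^[ACGTN]*$")


class FormatError(ValueError):
    """A file violated its format contract (bad coordinates, alphabet, header...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` with optional strand/label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval requires a chromosome name")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start (half-open), got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_from_1based(
    chrom: str, start1: int, end1: int, strand: str = ".", label: str = ""
) -> GenomicInterval:
    """Convert a 1-based fully-closed interval to the internal convention."""
    return GenomicInterval(chrom, start1 - 1, end1, strand, label)


def interval_to_1based(interval: GenomicInterval) -> tuple[int, int]:
    """Internal 0-based half-open -> 1-based fully-closed (start, end)."""
    return interval.start + 1, interval.end


@dataclass(frozen=True)
class SampleInfo:
    """Role and tissue of one expression sample."""

    role: str
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}, got {self.role!r}")


@dataclass
class ExpressionMatrix:
    """Transcript x sample FPKM table plus per-sample metadata.

    ``values`` is indexed by transcript id with one column per sample; every
    column must have a :class:`SampleInfo` entry and every cell must be a
    finite non-negative FPKM.
    """

    values: pd.DataFrame
    sample_meta: dict[str, SampleInfo]

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate transcript id {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        for sample in cols:
            if sample not in self.sample_meta:
                raise FormatError(f"sample {sample!r} has no metadata entry")
        numeric = self.values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() | (numeric < 0)
        if bad.to_numpy().any():
            row, col = next(zip(*bad.to_numpy().nonzero()))
            raise FormatError(
                "negative or non-numeric FPKM at transcript "
                f"{idx[row]!r}, sample {cols[col]!r}: {self.values.iat[row, col]!r}"
            )
        self.values = numeric.astype(float)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def value(self, transcript_id: str, sample_id: str) -> float:
        return float(self.values.at[transcript_id, sample_id])

    def samples_with_role(self, role: str) -> list[str]:
        if role not in VALID_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [s for s in self.values.columns if self.sample_meta[s].role == role]


@dataclass(frozen=True)
class TranscriptModel:
    """Genomic anatomy of a transcript plus its spliced sense-strand sequence.

    Exons are disjoint, sorted by start and live on ``chrom``.  The TSS is the
    first exon start on the plus strand and the last exon end minus one on the
    minus strand.  When a sequence is attached its length must equal the summed
    exon length.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    tss: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise ValueError(f"exon chromosome {exon.chrom!r} != {self.chrom!r}")
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start < left.end:
                raise ValueError(f"exons of {self.id!r} overlap or are unsorted")
        expected_tss = (
            self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1
        )
        if self.tss != expected_tss:
            raise ValueError(
                f"tss of {self.id!r} is {self.tss}, expected {expected_tss} "
                f"for strand {self.strand}"
            )
        if self.sequence is not None:
            if not _SEQ_ALPHABET.match(self.sequence):
                raise ValueError(f"sequence of {self.id!r} has characters outside ACGTN")
            span = sum(len(e) for e in self.exons)
            if len(self.sequence) != span:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != summed exon length {span} "
                    f"for {self.id!r}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly empty) FASTA file into an ordered list of (id, sequence).

    Sequences are uppercased, ``U`` becomes ``T``, and any character outside
    ``{A,C,G,T,N,U}`` raises :class:`FormatError` naming the record and offset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record {len(records) + 1} has an empty header")
        seq = str(rec.seq).upper()
        bad = _FASTA_ILLEGAL.search(seq)
        if bad is not None:
            raise FormatError(
                f"{path}: illegal character {bad.group()!r} in record "
                f"{rec.id!r} at offset {bad.start()}"
            )
        records.append((rec.id, seq.replace("U", "T")))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    path = Path(path)
    with path.open("w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3-BED6 file into validated intervals.

    The name column (4) becomes ``label``; the strand column (6) defaults to
    ``"."`` when absent.  Errors report the offending line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from exc
            label = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, label))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (score column fixed at 0)."""
    path = Path(path)
    with path.open("w") as handle:
        for iv in intervals:
            name = iv.label if iv.label else "."
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# expression tables & sample metadata
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path, sample_meta: Mapping[str, SampleInfo]
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column transcript id, header row required)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        return ExpressionMatrix(df, dict(sample_meta))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id")


def read_sample_metadata(path: str | Path) -> dict[str, SampleInfo]:
    """Read a sample-metadata TSV with columns sample_id, role, tissue."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "role", "tissue"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    meta: dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        if row["sample_id"] in meta:
            raise FormatError(f"{path}: duplicate sample id {row['sample_id']!r}")
        meta[row["sample_id"]] = SampleInfo(role=row["role"], tissue=row["tissue"])
    return meta


def write_sample_metadata(meta: Mapping[str, SampleInfo], path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "role": info.role, "tissue": info.tissue}
        for sid, info in meta.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "role", "tissue"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a CT table CSV: rows = transcripts, columns = ordered gradient fractions.

    Blank cells (no amplification) come back as NaN.  Column order is the
    gradient order, top to bottom.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() & (df.astype(str).apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        row, col = next(zip(*bad.to_numpy().nonzero()))
        raise FormatError(
            f"{path}: non-numeric CT {df.iat[row, col]!r} at "
            f"{df.index[row]!r}/{df.columns[col]!r}"
        )
    return numeric.astype(float)


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="transcript_id")


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

_MODEL_COLUMNS = ["transcript_id", "chrom", "strand", "tss", "exon_starts", "exon_ends"]


def write_transcript_models(
    models: Iterable[TranscriptModel], path: str | Path
) -> None:
    """Write transcript anatomy as a TSV (exon coordinate lists comma-joined)."""
    rows = []
    for model in models:
        rows.append(
            {
                "transcript_id": model.id,
                "chrom": model.chrom,
                "strand": model.strand,
                "tss": model.tss,
                "exon_starts": ",".join(str(e.start) for e in model.exons),
                "exon_ends": ",".join(str(e.end) for e in model.exons),
            }
        )
    pd.DataFrame(rows, columns=_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_transcript_models(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> dict[str, TranscriptModel]:
    """Read transcript anatomy written by :func:`write_transcript_models`.

    When ``sequences`` is given, matching ids get their spliced sequence
    attached (and length-checked against the exon span).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _MODEL_COLUMNS:
        raise FormatError(f"{path}: expected columns {_MODEL_COLUMNS}")
    models: dict[str, TranscriptModel] = {}
    for _, row in df.iterrows():
        starts = [int(s) for s in row["exon_starts"].split(",")]
        ends = [int(e) for e in row["exon_ends"].split(",")]
        exons = tuple(
            GenomicInterval(row["chrom"], s, e, row["strand"]) for s, e in zip(starts, ends)
        )
        seq = sequences.get(row["transcript_id"]) if sequences else None
        models[row["transcript_id"]] = TranscriptModel(
            id=row["transcript_id"],
            chrom=row["chrom"],
            strand=row["strand"],
            exons=exons,
            tss=int(row["tss"]),
            sequence=seq,
        )
    return models
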