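"""Sequence I/O, the gene catalog, and tabular persistence.

The reference transcriptome arrives as FASTA with headers carrying a
gene identifier and a transcript identifier (default ``geneid|txid``).
Because the pipeline assigns reads to *genes*, not transcripts, the
catalog keeps a single representative per gene: its longest transcript.
Reads are plain Phred+33 FASTQ.  All result tables are tab-separated
text with a deterministic row order so reruns diff cleanly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input."""


_RNA_TO_DNA = str.maketrans("Uu", "Tt")


def _clean_sequence(seq: str) -> str:
    return str(seq).translate(_RNA_TO_DNA).upper()


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript, keyed by the gene it belongs to."""

    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id or not self.transcript_id:
            raise ValueError("gene_id and transcript_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError("empty sequence for %s/%s" % (self.gene_id, self.transcript_id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HeaderSchema:
    """How to split a FASTA header into (gene_id, transcript_id).

    ``>geneA|tx1 description`` under the default schema yields
    gene ``geneA`` and transcript ``tx1``.  Headers with no transcript
    field reuse the gene id as transcript id only when
    ``require_transcript`` is off.
    """

    delimiter: str = "|"
    gene_field: int = 0
    transcript_field: int = 1
    require_transcript: bool = True

    def parse(self, header: str) -> tuple[str, str]:
        token = header.split()[0] if header.split() else ""
        parts = token.split(self.delimiter)
        n_needed = max(self.gene_field, self.transcript_field) + 1
        if len(parts) < n_needed:
            if self.require_transcript:
                raise ParseError(
                    f"header {header!r}: expected >= {n_needed} fields "
                    f"delimited by {self.delimiter!r}"
                )
            return token, token
        gene = parts[self.gene_field]
        tx = parts[self.transcript_field]
        if not gene:
            raise ParseError(f"header {header!r}: empty gene_id field")
        return gene, tx


@dataclass
class GeneCatalog:
    """Longest transcript per gene; the universe reads are assigned to."""

    entries: dict[str, TranscriptRecord]
    species_tag: str = "reference"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.entries.values())

    def gene_ids(self) -> list[str]:
        return sorted(self.entries)

    def length_of(self, gene_id: str) -> int:
        return len(self.entries[gene_id].sequence)


@dataclass
class ReadRecord:
    """A read: sequence, per-base Phred scores, mate tag, optional truth."""

    read_id: str
    sequence: str
    qualities: list[int]
    mate: str = "single"  # single | R1 | R2
    origin_gene_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ParseError(
                f"read {self.read_id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if self.qualities and (min(self.qualities) < 0 or max(self.qualities) > 60):
            raise ParseError(f"read {self.read_id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_placeholder(self) -> bool:
        return bool(self.sequence) and set(self.sequence) == {"N"}


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, schema: HeaderSchema | None = None) -> Iterator[TranscriptRecord]:
    """Stream transcripts from a FASTA file, order preserved."""
    schema = schema or HeaderSchema()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        try:
            gene_id, tx_id = schema.parse(rec.description)
        except ParseError as exc:
            raise ParseError(f"{path}, entry {i}: {exc}") from exc
        yield TranscriptRecord(gene_id, tx_id, _clean_sequence(rec.seq))


def build_gene_catalog(transcripts: Iterable[TranscriptRecord], species_tag: str = "reference") -> GeneCatalog:
    """Keep the longest transcript per gene (ties: smallest transcript_id)."""
    best: dict[str, TranscriptRecord] = {}
    for tr in transcripts:
        cur = best.get(tr.gene_id)
        if cur is None or (len(tr), _neg_lex(tr.transcript_id)) > (len(cur), _neg_lex(cur.transcript_id)):
            best[tr.gene_id] = tr
    if not best:
        raise ValueError("no transcripts supplied; cannot build an empty catalog")
    return GeneCatalog(entries=best, species_tag=species_tag)


class _neg_lex(str):
    """Reverses lexicographic order so max() prefers the smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def read_fastq(path: str | os.PathLike, mate: str = "single") -> Iterator[ReadRecord]:
    """Stream Phred+33 FASTQ records as ReadRecord objects."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield ReadRecord(
                read_id=rec.id,
                sequence=_clean_sequence(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
                mate=mate,
            )
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> int:
    """Write Phred+33 FASTQ; returns the number of records written."""
    n = 0
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
        n += 1
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return n


def write_per_gene_fasta(assignments: pd.DataFrame, reads: Mapping[str, ReadRecord], out_dir: str | os.PathLike) -> int:
    """One FASTA of assigned reads per gene; multigene reads go to every tied gene.

    Returns the number of files written (= genes with >= 1 assigned read).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bins: dict[str, list[str]] = {}
    for row in assignments.itertuples(index=False):
        for gene_id in str(row.gene_ids).split(";"):
            bins.setdefault(gene_id, []).append(row.read_id)
    for gene_id in sorted(bins):
        with open(out / f"{gene_id}.fasta", "w") as fh:
            for read_id in sorted(bins[gene_id]):
                fh.write(f">{read_id}\n{reads[read_id].sequence}\n")
    return len(bins)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """TSV with a header row, NA for missing, deterministic row order."""
    df = rows.copy()
    sort_cols = [c for c in ("gene_id", "read_id", "contig_id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
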