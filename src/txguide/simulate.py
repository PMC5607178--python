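"""Simulation of RNA-seq reads of known origin from a gene catalog.

Reads are tiled along each gene's longest transcript at a fixed
coverage, then point-mutated at a chosen divergence rate.  The single
divergence knob stands in for the processes that separate real reads
from a related reference — sequencing error, polymorphism and
inter-species divergence — and every read remembers the gene it came
from, so downstream assignment can be scored against the truth.

Also provides :func:`random_catalog`, a generator of synthetic gene
catalogs whose genes share no 9-mer on either strand (so alignment
cannot confuse them), optionally with planted paralog pairs that do.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import GeneCatalog, ReadRecord, TranscriptRecord, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

SIM_PHRED = 40  # constant quality: the simulation evaluates assignment, not QC


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation settings.

    read_length: target read length in bases (study classes 100/150/200/350).
    divergence: per-base substitution probability in [0, 1]
        (study levels 0, 0.05, 0.15, 0.30).
    coverage: mean per-base sequencing depth per gene; default 10.
    random_start: place reads uniformly at random instead of even tiling.
    """

    read_length: int = 100
    divergence: float = 0.0
    coverage: float = 10.0
    seed: int = 0
    random_start: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def gene_rng(cfg_seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene random stream derived by stable hashing of the gene id.

    Lets gene sets be simulated incrementally: a gene's reads do not
    depend on which other genes are in the catalog.
    """
    return np.random.default_rng([cfg_seed & 0x7FFFFFFF, zlib.crc32(gene_id.encode())])


def tile_reads(transcript: TranscriptRecord, cfg: SimConfig, rng: np.random.Generator) -> list[ReadRecord]:
    """Emit reads covering one transcript at ``cfg.coverage`` mean depth.

    With L the transcript length and r_eff = min(read_length, L),
    n = ceil(coverage * L / r_eff) reads are produced.  Default placement
    spaces start positions evenly over [0, L - r_eff]; transcripts shorter
    than the read length yield whole-transcript reads.
    """
    L = len(transcript.sequence)
    r_eff = min(cfg.read_length, L)
    n = math.ceil(cfg.coverage * L / r_eff)
    span = L - r_eff
    if cfg.random_start:
        starts = sorted(int(s) for s in rng.integers(0, span + 1, size=n))
    elif n == 1:
        starts = [0]
    else:
        starts = [round(i * span / (n - 1)) for i in range(n)]
    reads = []
    for i, start in enumerate(starts):
        raw = transcript.sequence[start : start + r_eff]
        seq = inject_divergence(raw, cfg.divergence, rng)
        reads.append(
            ReadRecord(
                read_id=f"{transcript.gene_id}_r{i:05d}_p{start}",
                sequence=seq,
                qualities=[SIM_PHRED] * len(seq),
                mate="single",
                origin_gene_id=transcript.gene_id,
            )
        )
    return reads


def inject_divergence(sequence: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``divergence``.

    A substituted base is drawn uniformly from the three other bases;
    length is preserved and no indels are introduced.  Non-ACGT symbols
    are left untouched.
    """
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    codes = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    hit = rng.random(len(codes)) < divergence
    shift = rng.integers(1, 4, size=len(codes))
    if divergence == 0.0:
        return sequence
    mutable = hit & (codes < 4)
    new_codes = codes.copy()
    new_codes[mutable] = (codes[mutable] + shift[mutable]) % 4
    out = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    out[mutable] = _BASES[new_codes[mutable]]
    return out.tobytes().decode()


def simulate_reads(catalog: GeneCatalog, cfg: SimConfig) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate the whole catalog; returns (reads, truth table).

    The truth table has one row per read: read_id, origin_gene_id,
    start, strand.  Genes are processed in sorted order and each gene
    uses its own hashed sub-stream, so output is deterministic under a
    fixed seed and stable under catalog growth.
    """
    reads: list[ReadRecord] = []
    rows = []
    for gene_id in catalog.gene_ids():
        tr = catalog.entries[gene_id]
        rng = gene_rng(cfg.seed, gene_id)
        for read in tile_reads(tr, cfg, rng):
            start = int(read.read_id.rsplit("_p", 1)[1])
            reads.append(read)
            rows.append((read.read_id, gene_id, start, "+"))
    truth = pd.DataFrame(rows, columns=["read_id", "origin_gene_id", "start", "strand"])
    return reads, truth


def simulate_dataset(
    catalog: GeneCatalog,
    cfg: SimConfig,
    fastq_path: str | Path,
    truth_path: str | Path,
) -> tuple[int, pd.DataFrame]:
    """Simulate and persist FASTQ + truth TSV; returns (n_reads, truth)."""
    reads, truth = simulate_reads(catalog, cfg)
    n = write_fastq(reads, fastq_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return n, truth


# ---------------------------------------------------------------------------
# Synthetic catalogs
# ---------------------------------------------------------------------------

_COMP = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G


def _canonical(kmer: tuple[int, ...]) -> tuple[int, ...]:
    rc = tuple(_COMP[b] for b in reversed(kmer))
    return min(kmer, rc)


def random_catalog(
    n_genes: int,
    gene_length: int = 1000,
    seed: int = 0,
    k: int = 9,
    paralog_pairs: int = 0,
    paralog_divergence: float = 0.05,
    species_tag: str = "synthetic",
) -> GeneCatalog:
    """A catalog of random genes sharing no ``k``-mer on either strand.

    Sequences are grown base by base; a base whose trailing k-mer (or its
    reverse complement) was already used anywhere in the catalog is
    rejected, with local backtracking when all four bases collide.  The
    screen makes genes pairwise seed-disjoint for a word size of ``k``,
    the idealised no-paralog regime.  ``paralog_pairs`` extra genes are
    then added as mutated copies of existing genes (suffix ``_par``),
    deliberately sharing k-mers with their template.
    """
    rng = np.random.default_rng(seed)
    used: set[tuple[int, ...]] = set()
    entries: dict[str, TranscriptRecord] = {}

    for g in range(n_genes):
        gene_id = f"g{g:04d}"
        seq: list[int] = []
        stalls = 0
        while len(seq) < gene_length:
            order = rng.permutation(4)
            placed = False
            for b in order:
                cand = seq + [int(b)]
                if len(cand) >= k:
                    kmer = _canonical(tuple(cand[-k:]))
                    if kmer in used:
                        continue
                seq = cand
                if len(seq) >= k:
                    used.add(_canonical(tuple(seq[-k:])))
                placed = True
                break
            if not placed:
                # dead end: drop a few bases (and their k-mers) and retry
                stalls += 1
                if stalls > 10_000:
                    raise RuntimeError("k-mer space exhausted; reduce n_genes or gene_length")
                drop = min(len(seq), k)
                for _ in range(drop):
                    if len(seq) >= k:
                        used.discard(_canonical(tuple(seq[-k:])))
                    seq.pop()
        entries[gene_id] = TranscriptRecord(gene_id, f"{gene_id}.t1", "".join("ACGT"[b] for b in seq))

    template_ids = sorted(entries)[:paralog_pairs]
    for tid in template_ids:
        par_id = f"{tid}_par"
        mut = inject_divergence(entries[tid].sequence, paralog_divergence, rng)
        entries[par_id] = TranscriptRecord(par_id, f"{par_id}.t1", mut)

    return GeneCatalog(entries=entries, species_tag=species_tag)
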