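"""Per-gene guided assembly and contig validation.

Reads assigned to a gene are assembled by a deterministic greedy
overlap-consensus assembler: the pair of contigs with the longest
suffix/prefix overlap (>= 30 bases at >= 95% identity, both
orientations considered) is merged first, with a per-column
majority-vote consensus, until no mergeable pair remains.  Every
contig — whether from this internal assembler or from an external tool
adapter — then passes the same validation step: it is annotated by
best HSP against the reference database, reverse-complemented onto the
reference plus strand when needed, re-binned to the gene its
annotation names, and discarded when no HSP passes the coverage and
identity thresholds.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .align import AdapterUnavailableError, AlignParams, Hsp, encode, local_align
from .assign import ReferenceDb, passes_thresholds
from .seqio import ReadRecord

_BASES = "ACGT"


@dataclass
class Contig:
    contig_id: str
    sequence: str
    member_read_ids: list[str]
    gene_ids: list[str] = field(default_factory=list)
    oriented: bool = False
    origin: str = "internal"  # internal | external_adapter
    hsps: dict[str, list[Hsp]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


@njit(cache=True)
def _best_overlap(a, b, min_overlap, min_identity):
    """Longest suffix(a)/prefix(b) overlap at >= min_identity; 0 if none."""
    max_o = min(len(a), len(b))
    for o in range(max_o, min_overlap - 1, -1):
        allowed = int((1.0 - min_identity) * o)
        mism = 0
        off = len(a) - o
        ok = True
        for k in range(o):
            if a[off + k] != b[k]:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            return o
    return 0


def _consensus(counts: np.ndarray) -> str:
    """Majority base per column; ties resolved to the alphabetically first."""
    return "".join(_BASES[int(np.argmax(col))] for col in counts)


def _rc_counts(counts: np.ndarray) -> np.ndarray:
    return counts[::-1, ::-1].copy()  # reverse positions, A<->T / C<->G


class _Draft:
    """Working state of one growing contig."""

    __slots__ = ("counts", "members", "key", "codes")

    def __init__(self, counts: np.ndarray, members: list[str], key: str):
        self.counts = counts
        self.members = members
        self.key = key
        self.codes = encode(_consensus(counts))


def greedy_assemble(
    reads: list[ReadRecord],
    min_overlap: int = 30,
    min_identity: float = 0.95,
    contig_prefix: str = "contig",
) -> list[Contig]:
    """Assemble reads into contigs by longest-overlap-first merging.

    Deterministic: overlap-length ties break on the lexicographically
    smallest (left read_id, right read_id, orientation) triple.
    Singleton reads come out as single-read contigs.
    """
    if not reads:
        raise ValueError("greedy_assemble requires >= 1 read")
    drafts: dict[int, _Draft] = {}
    for i, r in enumerate(sorted(reads, key=lambda r: r.read_id)):
        counts = np.zeros((len(r.sequence), 4), dtype=np.int32)
        codes = encode(r.sequence)
        for p, c in enumerate(codes):
            if c < 4:
                counts[p, c] += 1
        drafts[i] = _Draft(counts, [r.read_id], r.read_id)

    # best overlap per ordered draft pair, both orientations of the right side
    pair_best: dict[tuple[int, int], tuple[int, str]] = {}

    def compute_pair(i: int, j: int) -> None:
        a, b = drafts[i], drafts[j]
        o_plus = _best_overlap(a.codes, b.codes, min_overlap, min_identity)
        rc = encode(_consensus(_rc_counts(b.counts)))
        o_minus = _best_overlap(a.codes, rc, min_overlap, min_identity)
        if o_plus >= o_minus and o_plus > 0:
            pair_best[(i, j)] = (o_plus, "plus")
        elif o_minus > 0:
            pair_best[(i, j)] = (o_minus, "minus")
        elif (i, j) in pair_best:
            del pair_best[(i, j)]

    ids = sorted(drafts)
    for i in ids:
        for j in ids:
            if i != j:
                compute_pair(i, j)

    next_id = len(drafts)
    while pair_best:
        (i, j), (o, orient) = min(
            pair_best.items(),
            key=lambda kv: (-kv[1][0], drafts[kv[0][0]].key, drafts[kv[0][1]].key, kv[1][1]),
        )
        a, b = drafts[i], drafts[j]
        b_counts = b.counts if orient == "plus" else _rc_counts(b.counts)
        la = a.counts.shape[0]
        merged = np.concatenate(
            [
                a.counts[: la - o],
                a.counts[la - o :] + b_counts[:o],
                b_counts[o:],
            ]
        )
        new = _Draft(merged, sorted(a.members + b.members), min(a.key, b.key))
        del drafts[i], drafts[j]
        for key in [k for k in pair_best if i in k or j in k]:
            del pair_best[key]
        drafts[next_id] = new
        for other in drafts:
            if other != next_id:
                compute_pair(next_id, other)
                compute_pair(other, next_id)
        next_id += 1

    contigs = []
    for k, d in enumerate(sorted(drafts.values(), key=lambda d: d.key)):
        contigs.append(
            Contig(
                contig_id=f"{contig_prefix}_{k:03d}",
                sequence=_consensus(d.counts),
                member_read_ids=d.members,
            )
        )
    return contigs


# ---------------------------------------------------------------------------
# Annotation / validation
# ---------------------------------------------------------------------------

from .align import revcomp  # noqa: E402  (shared helper)


def annotate_contig(contig: Contig, reference: ReferenceDb, params: AlignParams | None = None) -> tuple[Contig | None, str | None]:
    """Annotate a contig by best HSP; returns (contig, None) or (None, reason).

    The best threshold-passing HSP names the gene (score ties across
    genes yield a multigene annotation).  A minus-strand best hit
    reverse-complements the contig onto the reference orientation.  All
    passing HSPs against each annotated gene are retained for the
    coverage metrics.
    """
    params = params or reference.params
    hsps = [h for h in local_align(contig.sequence, reference.index, params, query_id=contig.contig_id)
            if passes_thresholds(h)]
    if not hsps:
        return None, "no_annotation"
    best = max(h.score for h in hsps)
    top = [h for h in hsps if h.score == best]
    genes = sorted({h.subject_gene_id for h in top})
    if top[0].strand == "minus":
        contig.sequence = revcomp(contig.sequence)
        contig.oriented = True
        hsps = [h for h in local_align(contig.sequence, reference.index, params, query_id=contig.contig_id)
                if passes_thresholds(h)]
    contig.gene_ids = genes
    contig.hsps = {
        g: sorted(
            (h for h in hsps if h.subject_gene_id == g and h.strand == "plus"),
            key=lambda h: (-h.score, h.subject_start),
        )
        for g in genes
    }
    return contig, None


def guided_assembly(
    per_gene_reads: dict[str, list[ReadRecord]],
    reference: ReferenceDb,
    params: AlignParams | None = None,
    min_overlap: int = 30,
    min_identity: float = 0.95,
) -> tuple[dict[str, list[Contig]], list[tuple[str, str]]]:
    """Assemble each gene's read bin and validate the contigs.

    Contigs whose best annotation names a different gene are re-binned
    to that gene (the validation annotation is authoritative).  Returns
    (gene -> validated contigs, discard log of (contig_id, reason)).
    """
    out: dict[str, list[Contig]] = {}
    discards: list[tuple[str, str]] = []
    for gene_id in sorted(per_gene_reads):
        reads = per_gene_reads[gene_id]
        if not reads:
            continue
        contigs = greedy_assemble(reads, min_overlap, min_identity, contig_prefix=f"{gene_id}_c")
        for contig in contigs:
            annotated, reason = annotate_contig(contig, reference, params)
            if annotated is None:
                discards.append((contig.contig_id, reason or "no_annotation"))
                continue
            for target_gene in annotated.gene_ids:
                out.setdefault(target_gene, []).append(annotated)
    return out, discards


# ---------------------------------------------------------------------------
# External assembler adapters
# ---------------------------------------------------------------------------

_ADAPTER_BINARIES = {"trinity": "Trinity", "spades": "spades.py", "cap3": "cap3"}


def build_adapter_command(tool: str, bin_fasta: str | Path, out_dir: str | Path) -> list[str]:
    """The exact command line an adapter runs (normalisation, careful
    mode, auto coverage cut-off, default CAP3) for each supported tool."""
    bin_fasta, out_dir = str(bin_fasta), str(out_dir)
    if tool == "trinity":
        return [
            _ADAPTER_BINARIES[tool], "--seqType", "fa", "--single", bin_fasta,
            "--normalize_reads", "--SS_lib_type", "F", "--output", out_dir,
        ]
    if tool == "spades":
        return [
            _ADAPTER_BINARIES[tool], "-s", bin_fasta, "--careful",
            "--cov-cutoff", "auto", "-o", out_dir,
        ]
    if tool == "cap3":
        return [_ADAPTER_BINARIES[tool], bin_fasta]
    raise ValueError(f"unknown assembler adapter {tool!r}")


def external_assembler_adapter(tool: str, bin_fasta: str | Path, out_dir: str | Path) -> list[Contig]:
    """Invoke an external assembler and parse its contigs.

    Raises AdapterUnavailableError when the binary is absent — never a
    silent fallback to the internal assembler.
    """
    binary = _ADAPTER_BINARIES.get(tool)
    if binary is None:
        raise ValueError(f"unknown assembler adapter {tool!r}")
    if shutil.which(binary) is None:
        raise AdapterUnavailableError(f"{binary} not found on PATH; adapter {tool!r} unavailable")
    cmd = build_adapter_command(tool, bin_fasta, out_dir)
    subprocess.run(cmd, check=True, capture_output=True)
    outputs = {
        "trinity": Path(out_dir) / "Trinity.fasta",
        "spades": Path(out_dir) / "contigs.fasta",
        "cap3": Path(str(bin_fasta) + ".cap.contigs"),
    }
    from Bio import SeqIO

    contigs = []
    for i, rec in enumerate(SeqIO.parse(str(outputs[tool]), "fasta")):
        contigs.append(
            Contig(
                contig_id=f"{tool}_{i:04d}_{rec.id}",
                sequence=str(rec.seq).upper(),
                member_read_ids=[],
                origin="external_adapter",
            )
        )
    return contigs
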