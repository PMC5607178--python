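"""Best-hit assignment of reads to genes, with paralog tie typology.

Each read is aligned against a reference database that merges one or
more gene catalogs (and, optionally, annotated de novo contigs).  HSPs
must span more than 70% of the read (query coverage) at more than 70%
identity; among passing HSPs the maximal raw score decides the hit.
When distinct gene ids tie at the best score the read is flagged
``hit_multigene`` — the signature of paralogs and conserved domains —
and, under the default tie policy, counted in a separate multigene
tally rather than credited to any single gene.  When a single gene id
attains the best score from two or more source catalogs the read is
flagged ``hit_multispecies``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignParams, Hsp, SeedIndex
from .align import local_align as _local_align
from .seqio import GeneCatalog, ReadRecord

COVERAGE_THRESHOLD = 0.70
IDENTITY_THRESHOLD = 0.70


@dataclass
class ReferenceDb:
    """Merged, indexed alignment database over >= 1 reference sources."""

    index: SeedIndex
    species_of: dict[str, str]  # subject_id -> species_tag
    params: AlignParams

    @classmethod
    def build(
        cls,
        sources: Sequence[tuple[str, GeneCatalog] | tuple[str, list]],
        params: AlignParams | None = None,
    ) -> "ReferenceDb":
        """sources: (species_tag, GeneCatalog) or (species_tag, contig list).

        Contig entries are objects with ``contig_id``, ``sequence`` and a
        single-gene ``gene_ids`` annotation (see assemble module).
        """
        params = params or AlignParams()
        subjects: list[tuple[str, str, str]] = []
        species_of: dict[str, str] = {}
        for tag, source in sources:
            if isinstance(source, GeneCatalog):
                for gene_id in source.gene_ids():
                    tr = source.entries[gene_id]
                    sid = f"{tag}::{gene_id}::{tr.transcript_id}"
                    subjects.append((sid, gene_id, tr.sequence))
                    species_of[sid] = tag
            else:
                for contig in source:
                    for gene_id in contig.gene_ids:
                        sid = f"{tag}::{contig.contig_id}::{gene_id}"
                        subjects.append((sid, gene_id, contig.sequence))
                        species_of[sid] = tag
        return cls(index=SeedIndex(subjects, params), species_of=species_of, params=params)


@dataclass(frozen=True)
class Assignment:
    read_id: str
    gene_ids: tuple[str, ...]
    best_score: int
    hit_multigene: bool
    hit_multispecies: bool
    n_hsps_considered: int

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("an Assignment needs >= 1 gene_id")


def passes_thresholds(
    hsp: Hsp,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> bool:
    """Strict HSP acceptance: coverage > 70% of the read, identity > 70%."""
    return hsp.query_coverage > coverage_threshold and hsp.identity_fraction > identity_threshold


def assign_read(
    read: ReadRecord,
    db: ReferenceDb,
    params: AlignParams | None = None,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> Assignment | None:
    """Best-hit assignment of one read, or None if nothing passes."""
    if read.is_placeholder:
        return None
    params = params or db.params
    hsps = [h for h in _local_align(read.sequence, db.index, params, query_id=read.read_id)
            if passes_thresholds(h, coverage_threshold, identity_threshold)]
    if not hsps:
        return None
    best = max(h.score for h in hsps)
    top = [h for h in hsps if h.score == best]
    genes = sorted({h.subject_gene_id for h in top})
    multispecies = False
    for g in genes:
        tags = {db.species_of[h.subject_id] for h in top if h.subject_gene_id == g}
        if len(tags) >= 2:
            multispecies = True
    return Assignment(
        read_id=read.read_id,
        gene_ids=tuple(genes),
        best_score=best,
        hit_multigene=len(genes) > 1,
        hit_multispecies=multispecies,
        n_hsps_considered=len(hsps),
    )


def assign_dataset(
    reads: Iterable[ReadRecord],
    db: ReferenceDb,
    params: AlignParams | None = None,
    tie_policy: str = "exclude",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assign a read stream; returns (assignment table, per-gene counts, summary).

    Assignment table columns: read_id, gene_ids (';'-joined), best_score,
    hit_multigene, hit_multispecies, origin_gene_id (empty for real data).
    Per-gene counts: n_assigned per gene.  Under tie_policy="exclude"
    (default) multigene reads appear in no gene's count and are tallied
    separately; "duplicate" counts a tied read once per tied gene.
    """
    if tie_policy not in ("exclude", "duplicate"):
        raise ValueError("tie_policy must be 'exclude' or 'duplicate'")
    rows = []
    counts: dict[str, int] = {}
    n_in = n_multigene = n_unassigned = 0
    for read in reads:
        n_in += 1
        a = assign_read(read, db, params)
        if a is None:
            n_unassigned += 1
            continue
        rows.append(
            (
                a.read_id,
                ";".join(a.gene_ids),
                a.best_score,
                a.hit_multigene,
                a.hit_multispecies,
                read.origin_gene_id or "",
            )
        )
        if a.hit_multigene:
            n_multigene += 1
            if tie_policy == "duplicate":
                for g in a.gene_ids:
                    counts[g] = counts.get(g, 0) + 1
        else:
            counts[a.gene_ids[0]] = counts.get(a.gene_ids[0], 0) + 1
    table = pd.DataFrame(
        rows,
        columns=["read_id", "gene_ids", "best_score", "hit_multigene", "hit_multispecies", "origin_gene_id"],
    )
    per_gene = pd.DataFrame(
        sorted(counts.items()), columns=["gene_id", "n_assigned"]
    )
    summary = {
        "reads_in": n_in,
        "assigned": len(rows),
        "unassigned": n_unassigned,
        "multigene": n_multigene,
        "tie_policy": tie_policy,
    }
    return table, per_gene, summary
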