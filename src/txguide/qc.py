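"""Read quality control: trimming, rejection, pair parity, merging.

The rules mirror standard Illumina pre-processing for assignment-grade
reads.  A read is first end-trimmed to its Phred >= 13 core; the
trimmed read is then rejected outright if any base falls below Phred 5,
if more than 10% of bases fall below Phred 13, if its mean quality is
below 20, or if it is shorter than 30 bases.  Boundary values (exactly
5 / 10% / 20 / 30) all pass.  In paired mode a rejected mate is
replaced by a 50-base all-N placeholder so the R1/R2 files keep
record-for-record parity; placeholders contain no alignable word and
are dropped before assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .align import revcomp
from .seqio import ReadRecord


@dataclass(frozen=True)
class QcConfig:
    trim_min_phred: int = 13
    reject_any_below: int = 5
    reject_frac_threshold: float = 0.10  # fraction of bases below trim_min_phred
    reject_mean_below: float = 20.0
    min_length: int = 30
    placeholder_length: int = 50
    merge_min_overlap: int = 8
    merge_min_identity: float = 0.90
    dedupe_cap: int | None = None

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for v in (self.trim_min_phred, self.reject_any_below, self.reject_mean_below):
            if v < 0:
                raise ValueError("thresholds must be >= 0")


def trim_read(read: ReadRecord, cfg: QcConfig | None = None) -> ReadRecord:
    """Trim 5' and 3' ends up to the first base with Phred >= 13."""
    cfg = cfg or QcConfig()
    lo = 0
    hi = len(read.qualities)
    while lo < hi and read.qualities[lo] < cfg.trim_min_phred:
        lo += 1
    while hi > lo and read.qualities[hi - 1] < cfg.trim_min_phred:
        hi -= 1
    if lo == 0 and hi == len(read.qualities):
        return read
    return ReadRecord(
        read_id=read.read_id,
        sequence=read.sequence[lo:hi],
        qualities=read.qualities[lo:hi],
        mate=read.mate,
        origin_gene_id=read.origin_gene_id,
    )


def reject_read(read: ReadRecord, cfg: QcConfig | None = None) -> bool:
    """True if the (already trimmed) read fails any rejection rule."""
    cfg = cfg or QcConfig()
    n = len(read)
    if n < cfg.min_length:
        return True
    quals = read.qualities
    if min(quals) < cfg.reject_any_below:
        return True
    n_low = sum(1 for q in quals if q < cfg.trim_min_phred)
    if n_low > cfg.reject_frac_threshold * n:
        return True
    if sum(quals) / n < cfg.reject_mean_below:
        return True
    return False


def make_placeholder(read_id: str, mate: str, cfg: QcConfig | None = None) -> ReadRecord:
    cfg = cfg or QcConfig()
    return ReadRecord(
        read_id=read_id,
        sequence="N" * cfg.placeholder_length,
        qualities=[0] * cfg.placeholder_length,
        mate=mate,
    )


def filter_read(read: ReadRecord, cfg: QcConfig | None = None) -> ReadRecord | None:
    """Trim then reject; returns the surviving read or None."""
    cfg = cfg or QcConfig()
    trimmed = trim_read(read, cfg)
    if reject_read(trimmed, cfg):
        return None
    return trimmed


def filter_pairs(r1: ReadRecord, r2: ReadRecord, cfg: QcConfig | None = None) -> tuple[ReadRecord, ReadRecord]:
    """QC both mates; a rejected mate becomes an all-N placeholder."""
    cfg = cfg or QcConfig()
    out = []
    for r in (r1, r2):
        kept = filter_read(r, cfg)
        out.append(kept if kept is not None else make_placeholder(r.read_id, r.mate, cfg))
    return out[0], out[1]


def dedupe_overrepresented(reads: Iterable[ReadRecord], cfg: QcConfig | None = None) -> Iterator[ReadRecord]:
    """Cap the number of reads with an identical sequence (order stable).

    With ``dedupe_cap`` unset this is the identity: the over-representation
    criterion is data-dependent (PCR duplication vs. true over-expression),
    so filtering is opt-in.
    """
    cfg = cfg or QcConfig()
    if cfg.dedupe_cap is None:
        yield from reads
        return
    seen: dict[str, int] = {}
    for r in reads:
        c = seen.get(r.sequence, 0)
        if c < cfg.dedupe_cap:
            seen[r.sequence] = c + 1
            yield r


def merge_pair(r1: ReadRecord, r2: ReadRecord, cfg: QcConfig | None = None) -> ReadRecord | None:
    """Merge an overlapping pair into one pseudo-read, or None.

    r2 is reverse-complemented into r1's orientation; the longest
    suffix(r1)/prefix(revcomp(r2)) overlap of >= ``merge_min_overlap``
    bases at >= ``merge_min_identity`` wins.  In the overlap, each
    position takes the base of the higher-quality mate (ties: r1) and
    the maximum of the two qualities.
    """
    cfg = cfg or QcConfig()
    s2 = revcomp(r2.sequence)
    q2 = r2.qualities[::-1]
    s1, q1 = r1.sequence, r1.qualities
    best_o = 0
    for o in range(min(len(s1), len(s2)), cfg.merge_min_overlap - 1, -1):
        tail = s1[len(s1) - o :]
        head = s2[:o]
        matches = sum(1 for a, b in zip(tail, head) if a == b)
        if matches >= cfg.merge_min_identity * o:
            best_o = o
            break
    if best_o < cfg.merge_min_overlap:
        return None
    o = best_o
    seq = list(s1[: len(s1) - o])
    quals = list(q1[: len(q1) - o])
    for k in range(o):
        i1 = len(s1) - o + k
        if q2[k] > q1[i1]:
            seq.append(s2[k])
        else:
            seq.append(s1[i1])
        quals.append(max(q1[i1], q2[k]))
    seq += list(s2[o:])
    quals += list(q2[o:])
    return ReadRecord(
        read_id=r1.read_id + "/merged",
        sequence="".join(seq),
        qualities=quals,
        mate="single",
        origin_gene_id=r1.origin_gene_id,
    )


def qc_single(reads: Iterable[ReadRecord], cfg: QcConfig | None = None) -> tuple[list[ReadRecord], dict]:
    """QC a single-end stream; returns (survivors, counter summary)."""
    cfg = cfg or QcConfig()
    kept: list[ReadRecord] = []
    n_in = n_rejected = 0
    for r in dedupe_overrepresented(reads, cfg):
        n_in += 1
        out = filter_read(r, cfg)
        if out is None:
            n_rejected += 1
        else:
            kept.append(out)
    return kept, {"reads_in": n_in, "kept": len(kept), "rejected": n_rejected}


def qc_paired(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    cfg: QcConfig | None = None,
    merge: bool = False,
) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord], dict]:
    """QC a paired stream, preserving parity.

    Returns (r1_out, r2_out, assignable, summary).  r1_out/r2_out always
    have one record per input pair (placeholders included); ``assignable``
    holds the reads that go on to assignment — merged pseudo-reads when
    ``merge`` is on and the mates overlap, surviving mates otherwise.
    Pairs where both mates became placeholders contribute nothing.
    """
    cfg = cfg or QcConfig()
    r1_out: list[ReadRecord] = []
    r2_out: list[ReadRecord] = []
    assignable: list[ReadRecord] = []
    n_pairs = n_merged = n_placeholder = 0
    for a, b in pairs:
        n_pairs += 1
        fa, fb = filter_pairs(a, b, cfg)
        r1_out.append(fa)
        r2_out.append(fb)
        ok_a = not fa.is_placeholder
        ok_b = not fb.is_placeholder
        n_placeholder += (not ok_a) + (not ok_b)
        if merge and ok_a and ok_b:
            merged = merge_pair(fa, fb, cfg)
            if merged is not None:
                n_merged += 1
                assignable.append(merged)
                continue
        if ok_a:
            assignable.append(fa)
        if ok_b:
            assignable.append(fb)
    summary = {
        "pairs_in": n_pairs,
        "placeholders": n_placeholder,
        "merged": n_merged,
        "assignable": len(assignable),
    }
    return r1_out, r2_out, assignable, summary
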