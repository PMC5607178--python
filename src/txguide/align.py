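"""A blastn-like seed-and-extend local nucleotide aligner.

Assignment of reads to genes needs local alignment that stays reliable
at up to ~30% sequence divergence, where mapping-style tools give up.
The aligner here follows the classic design: exact word seeding
(default word size 9), ungapped x-drop extension around each seed
cluster, then a gapped Smith–Waterman pass restricted to a subject
window spanning the cluster's diagonals.  Scoring defaults are the
classic blastn values (+2 match, -3 mismatch, gap open 5 / extend 2,
a length-k gap costing open + k*extend).  The minus strand is searched
by aligning the reverse-complemented query against the plus-strand
index; subject coordinates are always reported on the subject plus
strand, and all coordinates are 0-based half-open.

:func:`sw_oracle` is a separate exhaustive Smith–Waterman used in tests
as an independent check on the heuristic; it shares no code with the
seeded path beyond the scoring constants.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)
_REVCOMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP_TABLE)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Seeding and scoring parameters (blastn-style)."""

    word_size: int = 9
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    x_drop: int = 20
    window_pad: int = 50
    max_diag_gap: int = 20
    min_ungapped_score: int = 0  # clusters scoring below this skip gapped DP

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")


@dataclass(frozen=True)
class Hsp:
    """One high-scoring pair between a query and a subject sequence."""

    query_id: str
    subject_id: str
    subject_gene_id: str
    strand: str  # "plus" | "minus"
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    alignment_length: int
    identities: int
    score: int
    query_length: int

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.alignment_length

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_length


# ---------------------------------------------------------------------------
# Numba DP kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_full(q, s, match, mismatch, gap_open, gap_extend):
    """Exhaustive SW, affine gaps, score only; returns (best, end_i, end_j).

    end coordinates are 1-based exclusive (row/col of the best cell).
    Rolling single-row arrays: E has an in-row dependency, F is kept
    per column.
    """
    m, n = len(q), len(s)
    NEG = -10_000_000
    h_prev = np.zeros(n + 1, dtype=np.int64)
    h_cur = np.zeros(n + 1, dtype=np.int64)
    f_col = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        e = NEG
        h_cur[0] = 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(h_cur[j - 1] - gap_open - gap_extend, e - gap_extend)
            f_col[j] = max(h_prev[j] - gap_open - gap_extend, f_col[j] - gap_extend)
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            h = h_prev[j - 1] + sub
            if e > h:
                h = e
            if f_col[j] > h:
                h = f_col[j]
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        h_prev, h_cur = h_cur, h_prev
    return best, bi, bj


@njit(cache=True)
def _sw_traceback(q, s, match, mismatch, gap_open, gap_extend):
    """Full SW with affine-state traceback on a (small) DP rectangle.

    Returns (score, qs, qe, ss, se, identities, aln_len) with 0-based
    half-open intervals.  Pointer bits per cell: for H, the source state
    (0 stop, 1 diag, 2 E, 3 F); for E/F, whether the gap was opened (0)
    or extended (1).
    """
    m, n = len(q), len(s)
    NEG = -10_000_000
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    ph = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pe = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pf = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pe[i, j] = 0
            else:
                E[i, j] = e_ext
                pe[i, j] = 1
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pf[i, j] = 0
            else:
                F[i, j] = f_ext
                pf[i, j] = 1
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            src = 0
            if diag > h:
                h = diag
                src = 1
            if E[i, j] > h:
                h = E[i, j]
                src = 2
            if F[i, j] > h:
                h = F[i, j]
                src = 3
            H[i, j] = h
            ph[i, j] = src
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i, j = bi, bj
    identities = 0
    aln_len = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            src = ph[i, j]
            if src == 0:
                break
            if src == 1:
                aln_len += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    identities += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E: gap consuming subject
            aln_len += 1
            opened = pe[i, j] == 0
            j -= 1
            state = 0 if opened else 1
        else:  # F: gap consuming query
            aln_len += 1
            opened = pf[i, j] == 0
            i -= 1
            state = 0 if opened else 2
    return best, i, bi, j, bj, identities, aln_len


@njit(cache=True)
def _ungapped_xdrop(q, s, qpos, spos, w, match, mismatch, x_drop):
    """Ungapped x-drop extension around an exact seed of length w.

    Returns (score, q_start, q_end) of the extended segment.
    """
    score = w * match
    # right
    best = score
    cur = score
    i = qpos + w
    j = spos + w
    qe = i
    while i < len(q) and j < len(s):
        cur += match if (q[i] == s[j] and q[i] < 4) else mismatch
        if cur > best:
            best = cur
            qe = i + 1
        if best - cur > x_drop:
            break
        i += 1
        j += 1
    score = best
    # left
    best = score
    cur = score
    i = qpos - 1
    j = spos - 1
    qs = qpos
    while i >= 0 and j >= 0:
        cur += match if (q[i] == s[j] and q[i] < 4) else mismatch
        if cur > best:
            best = cur
            qs = i
        if best - cur > x_drop:
            break
        i -= 1
        j -= 1
    return best, qs, qe


@njit(cache=True)
def _kmer_codes(codes, w):
    """Positions and packed integer values of all ACGT-only w-mers."""
    n = len(codes) - w + 1
    out_pos = np.empty(max(n, 0), dtype=np.int64)
    out_val = np.empty(max(n, 0), dtype=np.int64)
    k = 0
    for p in range(max(n, 0)):
        val = 0
        ok = True
        for t in range(w):
            c = codes[p + t]
            if c >= 4:
                ok = False
                break
            val = val * 4 + c
        if ok:
            out_pos[k] = p
            out_val[k] = val
            k += 1
    return out_pos[:k], out_val[:k]


# ---------------------------------------------------------------------------
# Seed index and alignment driver
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact word-size lookup over a collection of subject sequences."""

    def __init__(self, subjects: list[tuple[str, str, str]], params: AlignParams):
        """subjects: list of (subject_id, gene_id, sequence)."""
        if not subjects:
            raise ValueError("cannot index an empty subject collection")
        self.params = params
        self.subject_ids = [s[0] for s in subjects]
        self.gene_ids = [s[1] for s in subjects]
        self.codes = [encode(s[2]) for s in subjects]
        self.lengths = [len(s[2]) for s in subjects]
        table: dict[int, list[tuple[int, int]]] = {}
        for idx, codes in enumerate(self.codes):
            pos, val = _kmer_codes(codes, params.word_size)
            for p, v in zip(pos.tolist(), val.tolist()):
                table.setdefault(v, []).append((idx, p))
        self._table = table

    def n_kmers(self, subject_id: str) -> int:
        idx = self.subject_ids.index(subject_id)
        pos, _ = _kmer_codes(self.codes[idx], self.params.word_size)
        return len(pos)

    def lookup(self, val: int) -> list[tuple[int, int]]:
        return self._table.get(val, [])


def index_subjects(subjects: list[tuple[str, str, str]], params: AlignParams | None = None) -> SeedIndex:
    return SeedIndex(subjects, params or AlignParams())


def _cluster_diagonals(seeds: list[tuple[int, int]], max_gap: int) -> list[list[tuple[int, int]]]:
    """Group (qpos, spos) seeds into runs of nearby diagonals."""
    seeds = sorted(seeds, key=lambda t: (t[1] - t[0], t[1]))
    clusters: list[list[tuple[int, int]]] = []
    last_d = None
    for qpos, spos in seeds:
        d = spos - qpos
        if last_d is None or d - last_d > max_gap:
            clusters.append([])
        clusters[-1].append((qpos, spos))
        last_d = d
    return clusters


def local_align(query: str, index: SeedIndex, params: AlignParams | None = None, query_id: str = "query") -> list[Hsp]:
    """All HSPs of ``query`` against the indexed subjects, best first.

    Per (subject, strand), seeds are clustered by diagonal, each cluster
    is scored by ungapped x-drop extension, then refined by gapped DP on
    a subject window spanning the cluster; overlapping HSPs on the same
    subject and strand are collapsed to the highest-scoring one.
    """
    params = params or index.params
    w = params.word_size
    qlen = len(query)
    if qlen < w:
        return []
    hsps: list[Hsp] = []
    for strand, qseq in (("plus", query), ("minus", revcomp(query))):
        qcodes = encode(qseq)
        pos, val = _kmer_codes(qcodes, w)
        per_subject: dict[int, list[tuple[int, int]]] = {}
        for p, v in zip(pos.tolist(), val.tolist()):
            for sidx, spos in index.lookup(v):
                per_subject.setdefault(sidx, []).append((p, spos))
        for sidx, seeds in per_subject.items():
            scodes = index.codes[sidx]
            slen = index.lengths[sidx]
            for cluster in _cluster_diagonals(seeds, params.max_diag_gap):
                ug_best = -1
                for qpos, spos in cluster:
                    ug, _, _ = _ungapped_xdrop(
                        qcodes, scodes, qpos, spos, w,
                        params.match, params.mismatch, params.x_drop,
                    )
                    if ug > ug_best:
                        ug_best = ug
                if ug_best < params.min_ungapped_score:
                    continue
                d_lo = min(s - q for q, s in cluster)
                d_hi = max(s - q for q, s in cluster)
                s_lo = max(0, d_lo - params.window_pad)
                s_hi = min(slen, d_hi + qlen + params.window_pad)
                score, qs, qe, ss, se, ident, alen = _sw_traceback(
                    qcodes, scodes[s_lo:s_hi],
                    params.match, params.mismatch, params.gap_open, params.gap_extend,
                )
                if score <= 0 or qe <= qs:
                    continue
                ss += s_lo
                se += s_lo
                if strand == "minus":
                    qs, qe = qlen - qe, qlen - qs
                hsps.append(
                    Hsp(
                        query_id=query_id,
                        subject_id=index.subject_ids[sidx],
                        subject_gene_id=index.gene_ids[sidx],
                        strand=strand,
                        query_start=qs,
                        query_end=qe,
                        subject_start=ss,
                        subject_end=se,
                        alignment_length=alen,
                        identities=ident,
                        score=int(score),
                        query_length=qlen,
                    )
                )
    # collapse overlapping HSPs per (subject, strand), keep best
    hsps.sort(key=lambda h: (-h.score, h.subject_id, h.strand, h.subject_start))
    kept: list[Hsp] = []
    for h in hsps:
        clash = False
        for k in kept:
            if (
                k.subject_id == h.subject_id
                and k.strand == h.strand
                and h.subject_start < k.subject_end
                and k.subject_start < h.subject_end
            ):
                clash = True
                break
        if not clash:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

MAX_ORACLE_LEN = 2000


def sw_oracle(query: str, subject: str, params: AlignParams | None = None) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Exhaustive plus-strand Smith-Waterman: (score, q interval, s interval).

    Quadratic; guarded to sequences of <= 2,000 bases.  The minus strand
    is the caller's business (pass a reverse-complemented query).  A zero
    score reports empty intervals.
    """
    params = params or AlignParams()
    if len(query) > MAX_ORACLE_LEN or len(subject) > MAX_ORACLE_LEN:
        raise ValueError(f"sw_oracle limited to {MAX_ORACLE_LEN}-base sequences")
    q = encode(query)
    s = encode(subject)
    best, bi, bj = _sw_full(q, s, params.match, params.mismatch, params.gap_open, params.gap_extend)
    if best <= 0:
        return 0, (0, 0), (0, 0)
    # locate the start by aligning the reversed prefixes ending at (bi, bj)
    rbest, ri, rj = _sw_full(
        q[:bi][::-1].copy(), s[:bj][::-1].copy(),
        params.match, params.mismatch, params.gap_open, params.gap_extend,
    )
    return int(best), (bi - ri, bi), (bj - rj, bj)


# ---------------------------------------------------------------------------
# Optional NCBI blastn adapter (cross-validation only)
# ---------------------------------------------------------------------------

class AdapterUnavailableError(RuntimeError):
    """An external tool adapter was requested but its binary is missing."""


def blastn_adapter(
    queries: list[tuple[str, str]],
    subjects: list[tuple[str, str, str]],
    params: AlignParams | None = None,
) -> list[Hsp]:
    """Run NCBI blastn (-word_size, outfmt 6) and parse HSPs.

    For cross-validating assignment behaviour against the real tool;
    never used by the pipeline itself.  queries: (id, seq); subjects:
    (subject_id, gene_id, seq).
    """
    params = params or AlignParams()
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise AdapterUnavailableError("blastn/makeblastdb not found on PATH")
    gene_of = {sid: gid for sid, gid, _ in subjects}
    qlen = dict(queries)
    with tempfile.TemporaryDirectory() as td:
        qf = Path(td, "q.fasta")
        sf = Path(td, "s.fasta")
        qf.write_text("".join(f">{i}\n{s}\n" for i, s in queries))
        sf.write_text("".join(f">{sid}\n{seq}\n" for sid, _, seq in subjects))
        subprocess.run(
            ["makeblastdb", "-in", str(sf), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        out = subprocess.run(
            [
                "blastn", "-task", "blastn", "-query", str(qf), "-db", str(sf),
                "-word_size", str(params.word_size),
                "-reward", str(params.match), "-penalty", str(params.mismatch),
                "-gapopen", str(params.gap_open), "-gapextend", str(params.gap_extend),
                "-dust", "no", "-soft_masking", "false", "-evalue", "1000",
                "-outfmt", "6 qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue score",
            ],
            check=True, capture_output=True, text=True,
        )
    hsps = []
    for line in out.stdout.splitlines():
        f = line.split("\t")
        qid, sid = f[0], f[1]
        length = int(f[3])
        qs, qe = int(f[6]) - 1, int(f[7])
        ss, se = int(f[8]), int(f[9])
        strand = "plus" if ss < se else "minus"
        if strand == "minus":
            ss, se = se, ss
        hsps.append(
            Hsp(
                query_id=qid, subject_id=sid, subject_gene_id=gene_of[sid],
                strand=strand, query_start=qs, query_end=qe,
                subject_start=ss - 1, subject_end=se,
                alignment_length=length,
                identities=round(float(f[2]) * length / 100.0),
                score=int(f[11]),
                query_length=len(qlen[qid]),
            )
        )
    return hsps
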