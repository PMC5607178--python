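"""Evaluation layer: rr, sr, gene typology, NIG, completeness, contiguity.

For simulated data every read's true gene is known, so assignment can
be scored per gene: the recovery rate rr is the fraction of a gene's
simulated reads assigned back to it, and the specificity rate sr is
the fraction of the reads assigned to a gene that truly came from it
(undefined when the gene received no reads).  The (rr, sr) pair places
each gene into one of five categories: perfect (1, 1), recipient
(1, <1), donor (<1, 1), mixed (<1, <1) and undetectable (0, N.A.).

Assembly quality per gene g is measured against the length L_g of its
longest reference transcript: completeness Cp_g is the fraction of
[0, L_g) covered by the union of all aligned contigs' HSP intervals,
and contiguity Ct_g is the fraction covered by the longest contig
alone, so Ct_g <= Cp_g always.  NIG is the number of genes with at
least one validated contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import Hsp
from .assemble import Contig
from .seqio import GeneCatalog

CATEGORIES = ("perfect", "recipient", "donor", "mixed", "undetectable")


@dataclass(frozen=True)
class GeneEvaluation:
    gene_id: str
    gene_length: int
    n_simulated: int
    n_correct: int
    n_assigned: int
    rr: float
    sr: float | None
    category: str


def _correct_and_assigned(
    truth: pd.DataFrame, assignments: pd.DataFrame, gene_id: str, tie_policy: str
) -> tuple[int, int]:
    """(n_correct, n_assigned) for one gene under a tie policy."""
    origin = dict(zip(truth["read_id"], truth["origin_gene_id"]))
    n_correct = n_assigned = 0
    for row in assignments.itertuples(index=False):
        genes = str(row.gene_ids).split(";")
        multigene = len(genes) > 1
        if multigene and tie_policy == "exclude":
            continue
        if gene_id in genes:
            n_assigned += 1
            if origin.get(row.read_id) == gene_id:
                n_correct += 1
    return n_correct, n_assigned


def recovery_rate(truth: pd.DataFrame, assignments: pd.DataFrame, gene_id: str, tie_policy: str = "exclude") -> float:
    """Fraction of the gene's simulated reads assigned back to it."""
    n_simulated = int((truth["origin_gene_id"] == gene_id).sum())
    if n_simulated == 0:
        raise ValueError(f"gene {gene_id!r} has no simulated reads in the truth table")
    n_correct, _ = _correct_and_assigned(truth, assignments, gene_id, tie_policy)
    return n_correct / n_simulated


def specificity_rate(truth: pd.DataFrame, assignments: pd.DataFrame, gene_id: str, tie_policy: str = "exclude") -> float | None:
    """Fraction of reads assigned to the gene that truly came from it.

    None (reported as "NA") when the gene received no reads.
    """
    n_correct, n_assigned = _correct_and_assigned(truth, assignments, gene_id, tie_policy)
    if n_assigned == 0:
        return None
    return n_correct / n_assigned


def classify_gene(rr: float, sr: float | None) -> str:
    """Place a gene in the five-way typology from its (rr, sr) pair."""
    if not (0.0 <= rr <= 1.0):
        raise ValueError("rr must lie in [0, 1]")
    if rr == 0.0:
        if sr is None:
            return "undetectable"
        if sr > 0.0:
            raise ValueError("impossible state: rr = 0 with sr > 0")
        return "mixed"  # received only foreign reads
    if sr is None:
        raise ValueError("impossible state: rr > 0 with sr undefined")
    if rr == 1.0:
        return "perfect" if sr == 1.0 else "recipient"
    return "donor" if sr == 1.0 else "mixed"


def evaluate_genes(
    truth: pd.DataFrame,
    assignments: pd.DataFrame,
    catalog: GeneCatalog,
    tie_policy: str = "exclude",
) -> list[GeneEvaluation]:
    """Per-gene rr/sr/category for every gene in the truth table."""
    sim_counts = truth["origin_gene_id"].value_counts().to_dict()
    origin = dict(zip(truth["read_id"], truth["origin_gene_id"]))
    correct: dict[str, int] = {}
    assigned: dict[str, int] = {}
    for row in assignments.itertuples(index=False):
        genes = str(row.gene_ids).split(";")
        if len(genes) > 1 and tie_policy == "exclude":
            continue
        for g in genes:
            assigned[g] = assigned.get(g, 0) + 1
            if origin.get(row.read_id) == g:
                correct[g] = correct.get(g, 0) + 1
    evals = []
    for gene_id in sorted(sim_counts):
        n_sim = int(sim_counts[gene_id])
        n_cor = correct.get(gene_id, 0)
        n_ass = assigned.get(gene_id, 0)
        rr = n_cor / n_sim
        sr = (n_cor / n_ass) if n_ass > 0 else None
        evals.append(
            GeneEvaluation(
                gene_id=gene_id,
                gene_length=catalog.length_of(gene_id) if gene_id in catalog.entries else 0,
                n_simulated=n_sim,
                n_correct=n_cor,
                n_assigned=n_ass,
                rr=rr,
                sr=sr,
                category=classify_gene(rr, sr),
            )
        )
    return evals


def evaluations_table(evals: list[GeneEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.gene_id, e.gene_length, e.n_simulated, e.n_correct, e.n_assigned, e.rr, e.sr, e.category)
            for e in evals
        ],
        columns=["gene_id", "gene_length", "n_simulated", "n_correct", "n_assigned", "rr", "sr", "category"],
    )


# ---------------------------------------------------------------------------
# Interval coverage metrics (Cp / Ct)
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]], Lg: int) -> int:
    """Total length of the union of half-open intervals clipped to [0, Lg)."""
    clipped = sorted((max(0, s), min(Lg, e)) for s, e in intervals if min(Lg, e) > max(0, s))
    total = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def completeness(contig_hsps: list[Hsp], Lg: int) -> float | None:
    """Fraction of the reference transcript covered by all contigs' HSPs.

    None when there are no HSPs (gene excluded from the Cp distribution).
    """
    if not contig_hsps:
        return None
    return _union_length([(h.subject_start, h.subject_end) for h in contig_hsps], Lg) / Lg


def contiguity(
    hsps_by_contig: dict[str, list[Hsp]],
    contig_lengths: dict[str, int],
    Lg: int,
) -> float | None:
    """Fraction of the reference transcript covered by the longest contig.

    The longest contig is chosen by sequence length, ties broken by the
    lexicographically smallest contig id.  None when no contig aligned.
    """
    candidates = [c for c, hs in hsps_by_contig.items() if hs]
    if not candidates:
        return None
    longest = min(candidates, key=lambda c: (-contig_lengths[c], c))
    ivals = [(h.subject_start, h.subject_end) for h in hsps_by_contig[longest]]
    return _union_length(ivals, Lg) / Lg


def count_identified_genes(per_gene_contigs: dict[str, list[Contig]]) -> int:
    """NIG: genes with at least one validated contig."""
    return sum(1 for contigs in per_gene_contigs.values() if contigs)


def evaluate_assembly(per_gene_contigs: dict[str, list[Contig]], catalog: GeneCatalog) -> pd.DataFrame:
    """Per-gene Cp/Ct table over validated contigs.

    Uses the HSP subject intervals stored at validation time; genes with
    no contig are absent from the table (Cp and Ct are undefined).
    """
    rows = []
    for gene_id in sorted(per_gene_contigs):
        contigs = per_gene_contigs[gene_id]
        if not contigs:
            continue
        Lg = catalog.length_of(gene_id)
        all_hsps = [h for c in contigs for h in c.hsps.get(gene_id, [])]
        by_contig = {c.contig_id: c.hsps.get(gene_id, []) for c in contigs}
        lengths = {c.contig_id: len(c.sequence) for c in contigs}
        cp = completeness(all_hsps, Lg)
        ct = contiguity(by_contig, lengths, Lg)
        rows.append((gene_id, Lg, len(contigs), cp, ct))
    return pd.DataFrame(rows, columns=["gene_id", "gene_length", "n_contigs", "Cp", "Ct"])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

DEFAULT_BINS = list(range(0, 10_001, 500)) + [math.inf]


def summarize(evals: list[GeneEvaluation], bins: list[float] | None = None) -> pd.DataFrame:
    """Category counts and proportions by gene-length bin.

    One row per (length bin, category) with n genes and the within-bin
    proportion; proportions sum to 1 in every populated bin.
    """
    bins = bins or DEFAULT_BINS
    lengths = np.array([e.gene_length for e in evals], dtype=float)
    cats = [e.category for e in evals]
    idx = np.digitize(lengths, bins[1:-1], right=True)
    rows = []
    for b in sorted(set(idx.tolist())):
        members = [cats[i] for i in range(len(cats)) if idx[i] == b]
        lo = bins[b]
        hi = bins[b + 1] if b + 1 < len(bins) else math.inf
        for cat in CATEGORIES:
            n = members.count(cat)
            rows.append((lo, hi, cat, n, n / len(members)))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "category", "n_genes", "proportion"])


def overall_proportions(evals: list[GeneEvaluation]) -> dict[str, float]:
    n = len(evals)
    return {cat: sum(1 for e in evals if e.category == cat) / n for cat in CATEGORIES}
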