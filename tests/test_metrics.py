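"""rr/sr, gene typology, completeness/contiguity interval arithmetic."""

from __future__ import annotations


import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txguide as tg
from txguide.align import Hsp
from txguide.metrics import _union_length, overall_proportions


def tables(n_sim: int, n_correct: int, n_foreign: int, gene: str = "g1"):
    """Truth/assignment tables: n_sim reads from gene, n_correct assigned
    back, n_foreign reads from other genes assigned to it."""
    truth_rows = [(f"own{i}", gene) for i in range(n_sim)]
    truth_rows += [(f"for{i}", "other") for i in range(n_foreign)]
    asg_rows = [(f"own{i}", gene, "own") for i in range(n_correct)]
    asg_rows += [(f"for{i}", gene, "other") for i in range(n_foreign)]
    truth = pd.DataFrame(truth_rows, columns=["read_id", "origin_gene_id"])
    asg = pd.DataFrame(asg_rows, columns=["read_id", "gene_ids", "origin_tag"])
    asg["origin_gene_id"] = [gene if t == "own" else "other" for t in asg.origin_tag]
    return truth, asg.drop(columns="origin_tag")


def interval_hsp(start: int, end: int, contig: str = "c1", Lg: int = 1000) -> Hsp:
    return Hsp(
        query_id=contig, subject_id="ref", subject_gene_id="g1", strand="plus",
        query_start=0, query_end=end - start, subject_start=start, subject_end=end,
        alignment_length=end - start, identities=end - start, score=2 * (end - start),
        query_length=end - start,
    )


class TestRates:
    def test_recovery_rate_worked_example(self):
        truth, asg = tables(100, 80, 0)
        assert tg.recovery_rate(truth, asg, "g1") == pytest.approx(0.8)

    def test_specificity_rate_worked_example(self):
        truth, asg = tables(100, 80, 70)
        assert round(tg.specificity_rate(truth, asg, "g1"), 2) == 0.53

    def test_rr_extremes(self):
        truth, asg = tables(50, 0, 0)
        assert tg.recovery_rate(truth, asg, "g1") == 0.0
        truth, asg = tables(50, 50, 0)
        assert tg.recovery_rate(truth, asg, "g1") == 1.0

    def test_sr_undefined_with_no_assigned_reads(self):
        truth, asg = tables(50, 0, 0)
        assert tg.specificity_rate(truth, asg, "g1") is None

    def test_sr_one_with_only_own_reads(self):
        truth, asg = tables(50, 30, 0)
        assert tg.specificity_rate(truth, asg, "g1") == 1.0

    def test_unknown_gene_errors(self):
        truth, asg = tables(10, 5, 0)
        with pytest.raises(ValueError):
            tg.recovery_rate(truth, asg, "nope")

    def test_multigene_reads_excluded_by_default_counted_when_duplicated(self):
        truth = pd.DataFrame({"read_id": ["r1", "r2"], "origin_gene_id": ["g1", "g1"]})
        asg = pd.DataFrame(
            {"read_id": ["r1", "r2"], "gene_ids": ["g1", "g1;g2"], "origin_gene_id": ["g1", "g1"]}
        )
        assert tg.recovery_rate(truth, asg, "g1") == 0.5
        assert tg.recovery_rate(truth, asg, "g1", tie_policy="duplicate") == 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "rr,sr,expected",
        [
            (1.0, 1.0, "perfect"),
            (1.0, 0.9, "recipient"),
            (0.8, 1.0, "donor"),
            (0.8, 0.9, "mixed"),
            (0.0, None, "undetectable"),
            (0.0, 0.0, "mixed"),  # only foreign reads captured
        ],
    )
    def test_five_way_typology(self, rr, sr, expected):
        assert tg.classify_gene(rr, sr) == expected

    def test_impossible_states_error(self):
        with pytest.raises(ValueError):
            tg.classify_gene(0.0, 0.5)
        with pytest.raises(ValueError):
            tg.classify_gene(0.5, None)

    def test_categories_partition_every_gene(self, small_catalog, small_db, small_dataset):
        reads, truth = small_dataset
        table, _, _ = tg.assign_dataset(reads, small_db)
        evals = tg.evaluate_genes(truth, table, small_catalog)
        assert len(evals) == len(truth.origin_gene_id.unique())
        assert all(e.category in tg.metrics.CATEGORIES for e in evals)
        assert sum(overall_proportions(evals).values()) == pytest.approx(1.0)


class TestCompleteness:
    def test_overlapping_intervals_union(self):
        hsps = [interval_hsp(0, 500), interval_hsp(400, 800, "c2")]
        assert tg.completeness(hsps, 1000) == pytest.approx(0.8)

    def test_full_cover_is_one(self):
        assert tg.completeness([interval_hsp(0, 1000)], 1000) == 1.0

    def test_duplicate_interval_idempotent(self):
        hsps = [interval_hsp(0, 100), interval_hsp(0, 100, "c2")]
        assert tg.completeness(hsps, 1000) == pytest.approx(0.1)

    def test_no_contigs_undefined(self):
        assert tg.completeness([], 1000) is None


class TestContiguity:
    def test_longest_contig_coverage(self):
        by_contig = {"c1": [interval_hsp(0, 600, "c1")], "c2": [interval_hsp(0, 200, "c2")]}
        lengths = {"c1": 600, "c2": 200}
        assert tg.contiguity(by_contig, lengths, 1000) == pytest.approx(0.6)

    def test_full_span_is_one(self):
        assert tg.contiguity({"c1": [interval_hsp(0, 1000)]}, {"c1": 1000}, 1000) == 1.0

    def test_length_tie_breaks_on_contig_id(self):
        by_contig = {"cB": [interval_hsp(0, 300, "cB")], "cA": [interval_hsp(500, 800, "cA")]}
        lengths = {"cA": 300, "cB": 300}
        assert tg.contiguity(by_contig, lengths, 1000) == pytest.approx(0.3)  # cA wins

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ivals=st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 300)), min_size=1, max_size=12
        )
    )
    def test_ct_le_cp_le_one(self, ivals):
        hsps = [interval_hsp(s, min(1000, s + l), f"c{i}") for i, (s, l) in enumerate(ivals)]
        by_contig = {h.query_id: [h] for h in hsps}
        lengths = {h.query_id: h.query_length for h in hsps}
        cp = tg.completeness(hsps, 1000)
        ct = tg.contiguity(by_contig, lengths, 1000)
        assert 0 < ct <= cp <= 1

    def test_union_length_clips_to_reference(self):
        assert _union_length([(-10, 50), (990, 2000)], 1000) == 60


class TestSummaries:
    def test_count_identified_genes(self):
        contigs = {"a": [object()], "b": [object()], "c": [object()], "d": [], "e": []}
        assert tg.count_identified_genes(contigs) == 3
        assert tg.count_identified_genes({}) == 0

    def test_summary_proportions_sum_to_one_per_bin(self, small_catalog, small_db, small_dataset):
        reads, truth = small_dataset
        table, _, _ = tg.assign_dataset(reads, small_db)
        evals = tg.evaluate_genes(truth, table, small_catalog)
        summary = tg.summarize(evals)
        per_bin = summary.groupby("bin_lo").proportion.sum()
        assert all(abs(v - 1.0) < 1e-9 for v in per_bin)
        assert summary.n_genes.sum() == len(evals)

    def test_all_perfect_catalog_summarises_to_100_percent(self, small_catalog, small_db, small_dataset):
        reads, truth = small_dataset
        table, _, _ = tg.assign_dataset(reads, small_db)
        evals = tg.evaluate_genes(truth, table, small_catalog)
        summary = tg.summarize(evals)
        perfect = summary[summary.category == "perfect"]
        assert (perfect[perfect.n_genes > 0].proportion == 1.0).all()
        assert summary[summary.category != "perfect"].n_genes.sum() == 0
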