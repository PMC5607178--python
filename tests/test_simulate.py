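"""Read tiling, divergence injection, dataset determinism, catalog screening."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txguide as tg
from txguide.simulate import gene_rng

from conftest import random_dna


def transcript(seq: str, gene: str = "geneA") -> tg.TranscriptRecord:
    return tg.TranscriptRecord(gene, f"{gene}.t1", seq)


class TestTileReads:
    def test_counts_and_span_evenly_spaced(self):
        rng = np.random.default_rng(0)
        tr = transcript(random_dna(rng, 300))
        cfg = tg.SimConfig(read_length=100, coverage=10, seed=0)
        reads = tg.tile_reads(tr, cfg, gene_rng(0, tr.gene_id))
        assert len(reads) == 30  # ceil(10 * 300 / 100)
        starts = [int(r.read_id.rsplit("_p", 1)[1]) for r in reads]
        assert min(starts) == 0 and max(starts) == 200
        depth = np.zeros(300)
        for s in starts:
            depth[s : s + 100] += 1
        assert abs(depth.mean() - 10) < 0.5

    def test_read_length_equal_to_transcript(self):
        tr = transcript("ACGT" * 25)  # L = 100
        cfg = tg.SimConfig(read_length=100, coverage=10, seed=0)
        reads = tg.tile_reads(tr, cfg, gene_rng(0, tr.gene_id))
        assert len(reads) == 10
        assert all(r.sequence == tr.sequence for r in reads)

    def test_short_transcript_yields_whole_transcript_reads(self):
        tr = transcript("ACGTACGTAC" * 5)  # L = 50
        cfg = tg.SimConfig(read_length=100, coverage=10, seed=0)
        reads = tg.tile_reads(tr, cfg, gene_rng(0, tr.gene_id))
        assert len(reads) == 10  # ceil(10 * 50 / 50)
        assert all(r.sequence == tr.sequence for r in reads)

    def test_reads_carry_origin_and_constant_quality(self):
        tr = transcript("ACGT" * 30)
        reads = tg.tile_reads(tr, tg.SimConfig(seed=0), gene_rng(0, "geneA"))
        assert all(r.origin_gene_id == "geneA" for r in reads)
        assert all(set(r.qualities) == {40} for r in reads)


class TestInjectDivergence:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 500)
        assert tg.inject_divergence(seq, 0.0, np.random.default_rng(1)) == seq

    def test_full_divergence_replaces_every_base(self):
        out = tg.inject_divergence("AAAA", 1.0, np.random.default_rng(1))
        assert len(out) == 4 and "A" not in out

    def test_rate_matches_binomial_expectation(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 10_000)
        out = tg.inject_divergence(seq, 0.15, np.random.default_rng(3))
        d = sum(1 for a, b in zip(seq, out) if a != b)
        sd = np.sqrt(10_000 * 0.15 * 0.85)
        assert abs(d - 1500) <= 3 * sd

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=200),
        div=st.floats(0, 1),
        seed=st.integers(0, 2**20),
    )
    def test_length_preserved_and_n_untouched(self, seq, div, seed):
        out = tg.inject_divergence(seq, div, np.random.default_rng(seed))
        assert len(out) == len(seq)
        for a, b in zip(seq, out):
            if a == "N":
                assert b == "N"


class TestSimulateDataset:
    def test_byte_identical_under_fixed_seed(self, small_catalog, tmp_path):
        cfg = tg.SimConfig(read_length=100, divergence=0.05, coverage=10, seed=3)
        paths = []
        for i in (1, 2):
            fq, tt = tmp_path / f"{i}.fastq", tmp_path / f"{i}.tsv"
            tg.simulate_dataset(small_catalog, cfg, fq, tt)
            paths.append((fq, tt))
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()

    def test_read_count_formula(self):
        cat = tg.random_catalog(5, gene_length=1000, seed=4)
        reads, truth = tg.simulate_reads(cat, tg.SimConfig(read_length=100, coverage=10, seed=4))
        assert len(reads) == 5 * 100  # 5 * ceil(10 * 1000 / 100)
        assert len(truth) == len(reads)

    def test_zero_divergence_reads_are_substrings(self, small_catalog, small_dataset):
        reads, truth = small_dataset
        starts = dict(zip(truth.read_id, truth.start))
        for r in reads[:100]:
            source = small_catalog.entries[r.origin_gene_id].sequence
            s = starts[r.read_id]
            assert source[s : s + len(r)] == r.sequence

    def test_truth_table_complete_and_unique(self, small_dataset):
        reads, truth = small_dataset
        assert sorted(truth.read_id) == sorted(r.read_id for r in reads)
        assert truth.read_id.is_unique

    def test_coverage_conservation(self, small_catalog, small_dataset):
        reads, truth = small_dataset
        by_gene: dict[str, int] = {}
        for r in reads:
            by_gene[r.origin_gene_id] = by_gene.get(r.origin_gene_id, 0) + len(r)
        for gene_id, total in by_gene.items():
            assert total / small_catalog.length_of(gene_id) >= 10

    def test_incremental_stability_per_gene_streams(self):
        cat5 = tg.random_catalog(5, gene_length=300, seed=5)
        sub = tg.GeneCatalog(
            {g: cat5.entries[g] for g in list(cat5.gene_ids())[:2]}, "synthetic"
        )
        cfg = tg.SimConfig(read_length=100, divergence=0.1, coverage=5, seed=5)
        full, _ = tg.simulate_reads(cat5, cfg)
        part, _ = tg.simulate_reads(sub, cfg)
        full_by_id = {r.read_id: r.sequence for r in full}
        for r in part:
            assert full_by_id[r.read_id] == r.sequence


class TestRandomCatalog:
    def test_genes_share_no_9mer_on_either_strand(self):
        cat = tg.random_catalog(8, gene_length=300, seed=6)
        from txguide.align import revcomp

        kmer_owner: dict[str, str] = {}
        for gene_id in cat.gene_ids():
            seq = cat.entries[gene_id].sequence
            for strand_seq in (seq, revcomp(seq)):
                for i in range(len(strand_seq) - 8):
                    k = min(strand_seq[i : i + 9], revcomp(strand_seq[i : i + 9]))
                    owner = kmer_owner.setdefault(k, gene_id)
                    assert owner == gene_id

    def test_planted_paralogs_share_kmers(self):
        cat = tg.random_catalog(4, gene_length=300, seed=6, paralog_pairs=1)
        assert "g0000_par" in cat.entries
        a = cat.entries["g0000"].sequence
        b = cat.entries["g0000_par"].sequence
        shared = set(a[i : i + 9] for i in range(len(a) - 8)) & set(
            b[i : i + 9] for i in range(len(b) - 8)
        )
        assert shared

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tg.SimConfig(divergence=1.5)
        with pytest.raises(ValueError):
            tg.SimConfig(coverage=0)
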