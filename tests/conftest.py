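"""Shared fixtures: synthetic catalogs, simulated datasets, reference dbs.

Heavy objects (the 50-gene study catalog and its divergence sweep) are
session-scoped so the acceptance-level tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import txguide as tg

STUDY_SEED = 7  # fixed seed for the synthetic study conditions


@pytest.fixture(scope="session")
def small_catalog() -> tg.GeneCatalog:
    """10 seed-disjoint genes of 400 bases: quick unit-test substrate."""
    return tg.random_catalog(10, gene_length=400, seed=11)


@pytest.fixture(scope="session")
def small_db(small_catalog) -> tg.ReferenceDb:
    return tg.ReferenceDb.build([("reference", small_catalog)])


@pytest.fixture(scope="session")
def small_dataset(small_catalog):
    """Reads at 0% divergence, 10X, 100 bp from the small catalog."""
    cfg = tg.SimConfig(read_length=100, divergence=0.0, coverage=10, seed=STUDY_SEED)
    reads, truth = tg.simulate_reads(small_catalog, cfg)
    return reads, truth


@pytest.fixture(scope="session")
def study_catalog() -> tg.GeneCatalog:
    """The synthetic analogue of the study's screened gene set:
    50 random 1,000-base genes sharing no 9-mer on either strand."""
    return tg.random_catalog(50, gene_length=1000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_db(study_catalog) -> tg.ReferenceDb:
    return tg.ReferenceDb.build([("reference", study_catalog)])


@pytest.fixture(scope="session")
def divergence_sweep(study_catalog, study_db):
    """Assignment evaluation at the four study divergence levels.

    100-base reads, 10X coverage, divergence 0/5/15/30%; returns
    {divergence: (gene evaluations, assignment summary)}.
    """
    out = {}
    for div in (0.0, 0.05, 0.15, 0.30):
        cfg = tg.SimConfig(read_length=100, divergence=div, coverage=10, seed=STUDY_SEED)
        reads, truth = tg.simulate_reads(study_catalog, cfg)
        table, _, summary = tg.assign_dataset(reads, study_db)
        evals = tg.evaluate_genes(truth, table, study_catalog)
        out[div] = (evals, summary)
    return out


def make_read(read_id: str, sequence: str, phred: int = 40, **kw) -> tg.ReadRecord:
    return tg.ReadRecord(read_id, sequence, [phred] * len(sequence), **kw)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))
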