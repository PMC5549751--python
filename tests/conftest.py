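"""Shared fixtures: a hand-built toy genome/annotation with known overlap
structure, and a small simulated multi-level study with one planted outlier
replicate."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mlseq import core_io

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mlseq.core_io import AlignmentSet
from mlseq.synth_data import OutlierSpec, SimulationConfig, simulate_reads


def make_alignment(placements, k=8):
    """Hand-built AlignmentSet; placements: (seq, start, strand, count) on chr1."""
    rows = [(s, "chr1", st, st + k, strand, c, 1) for s, st, strand, c in placements]
    rec = pd.DataFrame(rows, columns=core_io._RECORD_COLUMNS)
    counts = {s: c for s, _, _, c in placements}
    return AlignmentSet(rec, counts, k)

TOY_GFF = """##gff-version 3
chr1\ttest\tgene\t6\t35\t.\t+\t.\tID=G1
chr1\ttest\tfive_prime_UTR\t6\t10\t.\t+\t.\tID=G1.u5;Parent=G1
chr1\ttest\texon\t6\t20\t.\t+\t.\tID=G1.e1;Parent=G1
chr1\ttest\tintron\t21\t25\t.\t+\t.\tID=G1.i1;Parent=G1
chr1\ttest\texon\t26\t35\t.\t+\t.\tID=G1.e2;Parent=G1
chr1\ttest\tCDS\t11\t20\t.\t+\t.\tID=G1.c1;Parent=G1
chr1\ttest\tCDS\t26\t30\t.\t+\t.\tID=G1.c2;Parent=G1
chr1\ttest\tthree_prime_UTR\t31\t35\t.\t+\t.\tID=G1.u3;Parent=G1
chr1\ttest\tgene\t41\t56\t.\t-\t.\tID=G2
chr1\ttest\texon\t41\t56\t.\t-\t.\tID=G2.e1;Parent=G2
chr1\ttest\tCDS\t43\t54\t.\t-\t.\tID=G2.c1;Parent=G2
"""


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    return {"chr1": seq}


@pytest.fixture(scope="session")
def toy_ann(tmp_path_factory, toy_genome):
    path = tmp_path_factory.mktemp("toy") / "toy.gff3"
    path.write_text(TOY_GFF)
    return core_io.load_annotation(path, chrom_sizes={"chr1": 60})


@pytest.fixture(scope="session")
def study():
    """Small nested study: 2 body parts x 2 treatments x 3 replicates, one
    outlier replicate (HT_plus_r3) with perturbed duplicate structure."""
    cfg = SimulationConfig(
        n_genes=20, depth=6000, outlier=OutlierSpec(), seed=11, depth_jitter=0.05
    )
    return simulate_reads(cfg)


@pytest.fixture(scope="session")
def study_ann(tmp_path_factory, study):
    path = tmp_path_factory.mktemp("study") / "ann.gff3"
    path.write_text(study.gff)
    sizes = {c: len(s) for c, s in study.genome.items()}
    return core_io.load_annotation(path, chrom_sizes=sizes)


@pytest.fixture(scope="session")
def study_alignments(study):
    return {
        s: core_io.exact_match(rs, study.genome, name=s)
        for s, rs in study.readsets.items()
    }
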