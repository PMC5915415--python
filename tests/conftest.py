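from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apsflow import pipeline as pl
from apsflow.models import GeneModel


@pytest.fixture(scope="session")
def clean_demo(tmp_path_factory):
    """Full demo run under exact-recovery conditions: zero terminus
    jitter, no internal-priming artifacts, depth far above the cutoff."""
    outdir = tmp_path_factory.mktemp("clean_demo")
    study, reads, result = pl.demo(
        seed=11, outdir=outdir, jitter_sd=0.0, ars_artifact_rate=0.0
    )
    return study, reads, result


@pytest.fixture(scope="session")
def artifact_demo(tmp_path_factory):
    """Demo run with planted internal-priming artifact sites."""
    outdir = tmp_path_factory.mktemp("artifact_demo")
    study, reads, result = pl.demo(
        seed=12, outdir=outdir, jitter_sd=0.0, ars_artifact_rate=0.05
    )
    return study, reads, result


def _match_truth_to_called(study, result) -> pd.DataFrame:
    """Join the truth table to called sites and annotations on exact
    (chrom, position, strand)."""
    truth = study.truth.set_index(["chrom", "position", "strand"])
    sites = result.sites.set_index(["chrom", "position", "strand"])
    joined = truth.join(sites, how="inner", rsuffix="_called")
    annotations = result.annotations.set_index("site_id")
    return joined.join(annotations, on="site_id_called", rsuffix="_ann")


@pytest.fixture(scope="session")
def truth_vs_called():
    return _match_truth_to_called


# ---------------------------------------------------------------------------
# hand-built class-code fixture
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def class_code_fixture():
    """Hand-annotated gene models plus site spans covering every class
    code, including the 9/10/11-bp intron-penetration and the
    1999/2000/2001-bp downstream boundaries.

    Returns (genes, cases) where each case is
    (span_start, span_end_inclusive, strand, expected_gene, expected_code).
    """
    gene_plus = GeneModel(
        gene_id="GA",
        symbol="GA",
        biotype="protein_coding",
        chrom="chr1",
        strand="+",
        transcripts={"GA.t1": [(1000, 1300), (1500, 1800), (2100, 2400)]},
    )
    gene_minus_x = GeneModel(
        gene_id="GB",
        symbol="GB",
        biotype="lncRNA",
        chrom="chr1",
        strand="-",
        transcripts={"GB.t1": [(6000, 6500)]},
    )
    gene_minus = GeneModel(
        gene_id="GC",
        symbol="GC",
        biotype="protein_coding",
        chrom="chr1",
        strand="-",
        transcripts={"GC.t1": [(12000, 12300), (12600, 12900)]},
    )
    genes = [gene_plus, gene_minus_x, gene_minus]
    cases = [
        # span fully inside exon 2 of the + gene
        (1600, 1610, "+", "GA", "c"),
        # starts in exon 1, ends 10 / 9 / 11 bp into intron 1
        (1290, 1309, "+", "GA", "e"),
        (1290, 1308, "+", "GA", "o"),
        (1290, 1310, "+", "GA", "e"),
        # completed inside intron 1
        (1350, 1360, "+", "GA", "i"),
        # crosses the intron/exon junction with only 5 bp of intron
        (1495, 1505, "+", "GA", "o"),
        # downstream distances 1999 / 2000 / 2001 from the transcript end
        (4398, 4400, "+", "GA", "p"),
        (4399, 4401, "+", "GA", "p"),
        (4400, 4402, "+", None, "u"),
        # plus-strand site inside the exon of the minus-strand gene
        (6200, 6210, "+", "GB", "x"),
        # intergenic
        (9000, 9010, "+", None, "u"),
        # minus-strand gene: exon-confined, exon-to-intron (11 bp), and
        # downstream 1500 bp (3' end of a minus gene is its start)
        (12100, 12110, "-", "GC", "c"),
        (12290, 12310, "-", "GC", "e"),
        (10498, 10500, "-", "GC", "p"),
    ]
    return genes, cases


@pytest.fixture()
def de_count_simulator():
    """Direct NB count-matrix simulator for the 2-vs-2 design (no read
    generation), for differential-test calibration checks."""

    def simulate(
        rng: np.random.Generator,
        n_features: int = 5000,
        de_fraction: float = 0.1,
        log2fc: float = 2.0,
        dispersion: float = 0.05,
        depth: float = 100.0,
    ):
        n_de = int(n_features * de_fraction)
        true = np.zeros(n_features)
        true[: n_de // 2] = log2fc
        true[n_de // 2 : n_de] = -log2fc
        half = 2.0 ** (true / 2.0)
        mu = np.column_stack(
            [depth * half, depth * half, depth / half, depth / half]
        )
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        frame = pd.DataFrame(counts, columns=["KO_1", "KO_2", "WT_1", "WT_2"])
        return frame, true

    return simulate


@pytest.fixture()
def conditions_2v2():
    return {"KO_1": "KO", "KO_2": "KO", "WT_1": "WT", "WT_2": "WT"}
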