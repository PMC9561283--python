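"""Shared fixtures: the worked two-exon transcript and small simulations.

TX1 is a plus-strand coding transcript with exons 101-200 and 301-400 and a
CDS spanning genomic 151-350; its region layout (5'UTR, CDS, intron, CDS,
3'UTR) exercises every region type.  The minus-strand mirror reflects all
coordinates through 501 so the intervals land on the same numbers, which
makes strand-symmetry checks easy to read.
"""

import numpy as np
import pytest

from geotx.annotation import GenomicInterval, TranscriptModel
from geotx.synthetic import SimulationConfig, simulate_annotation


@pytest.fixture
def tx1() -> TranscriptModel:
    return TranscriptModel(
        tx_id="TX1", gene_id="G1", chrom="c1", strand="+",
        exons=[GenomicInterval("c1", 101, 200, "+"),
               GenomicInterval("c1", 301, 400, "+")],
        cds=(151, 350),
    )


@pytest.fixture
def tx1_minus() -> TranscriptModel:
    """TX1 reflected through coordinate 501 onto the minus strand."""
    return TranscriptModel(
        tx_id="TX1m", gene_id="G1m", chrom="c1", strand="-",
        exons=[GenomicInterval("c1", 301, 400, "-"),
               GenomicInterval("c1", 101, 200, "-")],
        cds=(151, 350),
    )


def mirror_pos(gpos: int) -> int:
    """Genomic position of the mirrored site on the minus-strand copy."""
    return 501 - gpos


@pytest.fixture
def tx1_short() -> TranscriptModel:
    """Single-exon non-coding isoform overlapping TX1's first exon."""
    return TranscriptModel(
        tx_id="TX1-short", gene_id="G1", chrom="c1", strand="+",
        exons=[GenomicInterval("c1", 101, 200, "+")],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene simulation shared across tests (read-only)."""
    cfg = SimulationConfig(n_genes=40)
    return cfg, simulate_annotation(cfg, seed=11)


@pytest.fixture(scope="session")
def random_exonic_sites(small_sim):
    """(tx, genomic position) pairs drawn uniformly over exonic space."""
    _, sim = small_sim
    rng = np.random.default_rng(5)
    pairs = []
    for tx in sim.models[:60]:
        for _ in range(5):
            spos = int(rng.integers(1, tx.spliced_length + 1))
            from geotx.annotation import map_to_genome

            pairs.append((tx, map_to_genome(tx, spos, "spliced")))
    return pairs
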