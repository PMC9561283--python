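"""Geographic encoders: exact examples, invariants and strand symmetry."""

import numpy as np
import pytest

from geotx.annotation import GenomicInterval, TranscriptModel, map_coordinate
from geotx.encoders import (
    build_bag,
    build_read_bag,
    decode_chunkTX,
    encode_chunkTX,
    encode_gridTX,
    encode_landmarkTX,
    encode_onehot_region,
    encode_onehot_seq,
    region_flag_array,
    truncate_to_read,
    ChunkMatrix,
)
from geotx.synthetic import SimulationConfig, simulate_annotation

from conftest import mirror_pos


class TestLandmarkTX:
    def test_worked_example(self, tx1):
        lv = encode_landmarkTX(tx1, 160)
        assert tuple(lv.to_array()) == (59, 40, 9, 190, 59, 240)
        assert lv.n_features == 6

    def test_utr5_site_has_negative_cds_distance(self, tx1):
        assert encode_landmarkTX(tx1, 120).d_cds5 == -31

    def test_utr3_site_has_negative_cds3_distance(self, tx1):
        assert encode_landmarkTX(tx1, 360).d_cds3 == 350 - 360

    def test_strand_mirror_identical(self, tx1, tx1_minus):
        for g in (120, 160, 199, 310, 390):
            a = encode_landmarkTX(tx1, g).to_array()
            b = encode_landmarkTX(tx1_minus, mirror_pos(g)).to_array()
            assert np.array_equal(a, b)

    def test_spliced_frame(self, tx1):
        lv = encode_landmarkTX(tx1, 301, frame="spliced")
        # spliced pos 101; exon2 spans spliced 101-200; CDS spliced 51-150
        assert (lv.d_exon5, lv.d_exon3) == (0, 99)
        assert (lv.d_cds5, lv.d_cds3) == (50, 49)
        assert (lv.d_tx5, lv.d_tx3) == (100, 99)

    def test_exon_additivity_on_simulated_sites(self, random_exonic_sites):
        for tx, gpos in random_exonic_sites:
            lv = encode_landmarkTX(tx, gpos)
            exon = tx.containing_exon(gpos)
            assert lv.d_exon5 + lv.d_exon3 + 1 == exon.width
            assert lv.d_tx5 + lv.d_tx3 + 1 == tx.tx_span.width

    def test_noncoding_policy(self, tx1_short):
        lv = encode_landmarkTX(tx1_short, 150)
        assert (lv.d_cds5, lv.d_cds3) == (0, 0)
        assert lv.has_cds is False

    def test_intronic_site_rejected_by_default(self, tx1):
        with pytest.raises(ValueError):
            encode_landmarkTX(tx1, 250)
        lv = encode_landmarkTX(tx1, 250, allow_intronic=True)
        assert lv.d_exon5 == 250 - 201


class TestGridTX:
    def test_three_fragments_worked_example(self, tx1):
        g = encode_gridTX(tx1, 160, n_grids=3)
        lw = np.log(101)
        expected = np.array([
            [1.0, 0.0, 0.5, 0.5, 0.0, lw, 1.0],
            [0.0, 1.0, 0.0, 0.0, 0.0, lw, 0.0],
            [1.0, 0.0, 0.5, 0.0, 0.5, lw, 0.0],
        ])
        assert np.allclose(g.matrix, expected)

    def test_single_fragment_is_whole_transcript_composition(self, tx1):
        g = encode_gridTX(tx1, 160, n_grids=1)
        row = g.matrix[0]
        assert row[0] == pytest.approx(200 / 300)  # exon fraction
        assert row[1] == pytest.approx(100 / 300)
        assert row[6] == 1.0

    def test_row_normalization_invariant(self, small_sim):
        _, sim = small_sim
        for tx in sim.models[:20]:
            site = tx.exons[0].start
            g = encode_gridTX(tx, site, n_grids=17)
            assert np.allclose(g.matrix[:, 0] + g.matrix[:, 1], 1.0)
            assert np.all(
                g.matrix[:, 2] + g.matrix[:, 3] + g.matrix[:, 4]
                <= g.matrix[:, 0] + 1e-12
            )
            assert g.matrix[:, 6].sum() >= 1

    def test_width_one_limit_equals_onehot(self, tx1):
        L = tx1.tx_span.width
        g = encode_gridTX(tx1, 160, n_grids=L)
        flags = region_flag_array(tx1)
        assert np.array_equal(g.matrix[:, :5], flags)

    def test_too_many_grids_suggests_onehot(self, tx1):
        with pytest.raises(ValueError, match="one-hot"):
            encode_gridTX(tx1, 160, n_grids=10_000)


class TestChunkTX:
    def test_seven_chunk_worked_example(self, tx1):
        c = encode_chunkTX(tx1, 160, n_chunks=7)
        # rows: pad, utr5 w50, cds w9, TARGET cds w1, cds w40, intron w100,
        # cds w50 (the 3'UTR run is trimmed)
        widths = np.round(np.expm1(c.matrix[:, 5])).astype(int)
        assert list(widths) == [0, 50, 9, 1, 40, 100, 50]
        assert list(c.matrix[:, 6]) == [0, 0, 0, 1, 0, 0, 0]
        assert c.matrix[1, 3] == 1  # utr5 flag
        assert c.matrix[5, 1] == 1  # intron flag

    def test_default_35_chunks_has_245_entries(self, tx1):
        c = encode_chunkTX(tx1, 160, n_chunks=35)
        assert c.n_features == 245
        populated = np.flatnonzero(c.matrix.any(axis=1))
        assert len(populated) == 7
        assert c.matrix[17, 6] == 1.0  # first target row centered

    def test_single_run_transcript(self):
        tx = TranscriptModel("T", "G", "c1", "+",
                             [GenomicInterval("c1", 10, 19, "+")])
        c = encode_chunkTX(tx, 15, n_chunks=3)
        assert c.matrix[1, 6] == 1.0
        assert np.round(np.expm1(c.matrix[1, 5])) == 1

    def test_even_chunk_count_rejected(self, tx1):
        with pytest.raises(ValueError, match="odd"):
            encode_chunkTX(tx1, 160, n_chunks=6)

    def test_target_area_spanning_runs(self, tx1):
        area = GenomicInterval("c1", 190, 310, "+")
        c = encode_chunkTX(tx1, area, n_chunks=35)
        target_rows = np.flatnonzero(c.matrix[:, 6])
        assert len(target_rows) == 3  # exon tail, intron, exon head
        assert target_rows[0] == 17

    def test_whole_transcript_variant_has_six_columns(self, tx1):
        c = encode_chunkTX(tx1, 160, n_chunks=35, include_target=False)
        assert c.matrix.shape == (35, 6)
        assert np.flatnonzero(c.matrix.any(axis=1)).tolist() == [0, 1, 2, 3, 4]

    def test_strand_mirror_identical(self, tx1, tx1_minus):
        a = encode_chunkTX(tx1, 160, 35).matrix
        b = encode_chunkTX(tx1_minus, mirror_pos(160), 35).matrix
        assert np.array_equal(a, b)


class TestDecodeChunkTX:
    def test_round_trip_worked_example(self, tx1):
        layout = decode_chunkTX(encode_chunkTX(tx1, 160, 35))
        widths = [w for _, w, _ in layout.runs]
        assert widths == [50, 9, 1, 40, 100, 50, 50]
        assert [t for _, _, t in layout.runs] == [False, False, True, False,
                                                  False, False, False]
        assert layout.maybe_truncated is False

    def test_all_zero_matrix_decodes_empty(self):
        m = ChunkMatrix(matrix=np.zeros((35, 7)), n_chunks=35, tx_id="x",
                        target=(0, 0), row_intervals=[None] * 35)
        assert decode_chunkTX(m).runs == ()

    def test_lossless_on_seeded_transcripts(self, small_sim):
        """decode(encode(.)) recovers the exact split-run layout."""
        from geotx.encoders import _split_runs_on_target

        _, sim = small_sim
        rng = np.random.default_rng(9)
        checked = 0
        for tx in sim.models:
            spos = int(rng.integers(1, tx.spliced_length + 1))
            from geotx.annotation import map_to_genome

            gpos = map_to_genome(tx, spos, "spliced")
            layout, t_idx = _split_runs_on_target(tx, gpos)
            if t_idx > 17 or len(layout) - t_idx > 18:
                continue
            decoded = decode_chunkTX(encode_chunkTX(tx, gpos, 35))
            expected = tuple(
                (flags, iv.width, is_t) for flags, iv, is_t in layout
            )
            assert decoded.runs == expected
            checked += 1
        assert checked >= 30

    def test_trimmed_matrix_flagged(self, small_sim):
        _, sim = small_sim
        tx = max(sim.models, key=lambda t: len(t.exons))
        gpos = tx.exons[0].start
        c = encode_chunkTX(tx, gpos, n_chunks=5)
        assert decode_chunkTX(c).maybe_truncated is True


class TestOneHot:
    def test_region_window_all_cds(self, tx1):
        m = encode_onehot_region(tx1, 160, window=5)
        assert m.shape == (5, 5)
        assert np.array_equal(m, np.tile([1, 0, 1, 0, 0], (5, 1)))

    @pytest.mark.parametrize("window,entries", [(101, 505), (251, 1255)])
    def test_entry_counts(self, tx1, window, entries):
        assert encode_onehot_region(tx1, 160, window=window).size == entries

    def test_out_of_span_rows_zero(self, tx1):
        m = encode_onehot_region(tx1, 101, window=11)
        assert np.all(m[:5] == 0)  # positions 96..100 precede the span
        assert np.all(m[5:] != 0).sum() or m[5:].sum() > 0

    def test_sequence_onehot_and_revcomp(self):
        genome = {"c1": "ACGTACGTACGT"}
        site = GenomicInterval("c1", 6, 6, "+")  # C
        m = encode_onehot_seq(genome, site, window=3)
        # window ACG -> rows A, C, G
        assert np.array_equal(
            m, np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]])
        )
        site_m = GenomicInterval("c1", 6, 6, "-")
        mm = encode_onehot_seq(genome, site_m, window=3)
        # revcomp of ACG is CGU -> rows C, G, U
        assert np.array_equal(
            mm, np.array([[0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        )

    def test_out_of_chromosome_rows_zero(self):
        genome = {"c1": "ACGT"}
        m = encode_onehot_seq(genome, GenomicInterval("c1", 1, 1, "+"),
                              window=5)
        assert np.all(m[:2] == 0)
        assert m[2, 0] == 1  # the A itself


class TestTruncateToRead:
    def test_full_read_is_identity(self, tx1):
        c = encode_chunkTX(tx1, 160, 35)
        t = truncate_to_read(c, GenomicInterval("c1", 101, 400, "+"), tx1)
        assert np.array_equal(t.matrix, c.matrix)
        assert t.target_covered

    def test_partial_read_crops_widths(self, tx1):
        c = encode_chunkTX(tx1, 160, 35)
        t = truncate_to_read(c, GenomicInterval("c1", 151, 250, "+"), tx1)
        widths = np.round(np.expm1(t.matrix[:, 5])).astype(int)
        populated = widths[np.flatnonzero(t.matrix.any(axis=1))]
        # utr5 zeroed; intron cropped 100 -> 50; 3' CDS and UTR gone
        assert list(populated) == [9, 1, 40, 50]
        assert t.target_covered

    def test_read_missing_target_flags_encoding(self, tx1):
        c = encode_chunkTX(tx1, 160, 35)
        t = truncate_to_read(c, GenomicInterval("c1", 351, 400, "+"), tx1)
        assert not t.target_covered
        assert np.all(t.matrix[:, 6] == 0)

    def test_disjoint_read_raises(self, tx1):
        with pytest.raises(ValueError):
            truncate_to_read(encode_chunkTX(tx1, 160, 35),
                             GenomicInterval("c1", 900, 999, "+"), tx1)


class TestBags:
    def test_isoform_bag_of_two(self, tx1, tx1_short):
        site = GenomicInterval("c1", 160, 160, "+")
        bag = build_bag(site, [tx1, tx1_short])
        assert len(bag) == 2
        assert bag.meta["has_cds"] == {"TX1": True, "TX1-short": False}

    def test_empty_isoform_list_raises(self):
        site = GenomicInterval("c1", 160, 160, "+")
        with pytest.raises(ValueError, match="160"):
            build_bag(site, [])

    def test_read_bag_pads_to_twenty(self, tx1):
        site = GenomicInterval("c1", 160, 160, "+")
        reads = [GenomicInterval("c1", 110, 390, "+")] * 7
        bag = build_read_bag(site, tx1, reads)
        assert len(bag) == 20
        ids = [tid for tid, _ in bag.members]
        assert ids.count("pad") == 13
        pad_members = [m for tid, m in bag.members if tid == "pad"]
        assert all(np.all(m.matrix == 0) for m in pad_members)

    def test_read_downsampling_is_seeded(self, tx1):
        site = GenomicInterval("c1", 160, 160, "+")
        rng = np.random.default_rng(1)
        reads = [
            GenomicInterval("c1", int(a), int(a) + 120, "+")
            for a in rng.integers(101, 260, size=50)
        ]
        b1 = build_read_bag(site, tx1, reads, seed=3)
        b2 = build_read_bag(site, tx1, reads, seed=3)
        for (_, m1), (_, m2) in zip(b1.members, b2.members):
            assert np.array_equal(m1.matrix, m2.matrix)


def test_all_encoders_strand_invariant_on_simulated_mirrors():
    """Mirror every transcript of a tiny simulation; encodings must match."""
    cfg = SimulationConfig(n_genes=6)
    sim = simulate_annotation(cfg, seed=21)
    rng = np.random.default_rng(2)
    for tx in sim.models[:8]:
        span = tx.tx_span
        M = span.start + span.end  # reflect through the span
        flip = {"+": "-", "-": "+"}[tx.strand]
        mirror = TranscriptModel(
            tx.tx_id + "m", tx.gene_id, tx.chrom, flip,
            [GenomicInterval(tx.chrom, M - e.end, M - e.start, flip)
             for e in tx.exons],
            cds=None if tx.cds is None else (M - tx.cds[1], M - tx.cds[0]),
        )
        spos = int(rng.integers(1, tx.spliced_length + 1))
        from geotx.annotation import map_to_genome

        g = map_to_genome(tx, spos, "spliced")
        gm = M - g
        assert np.array_equal(encode_landmarkTX(tx, g).to_array(),
                              encode_landmarkTX(mirror, gm).to_array())
        assert np.allclose(encode_gridTX(tx, g, 11).matrix,
                           encode_gridTX(mirror, gm, 11).matrix)
        assert np.array_equal(encode_chunkTX(tx, g, 35).matrix,
                              encode_chunkTX(mirror, gm, 35).matrix)
        assert np.array_equal(encode_onehot_region(tx, g, 21),
                              encode_onehot_region(mirror, gm, 21))
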