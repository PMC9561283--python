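"""Geographic encoders for single sites (or intervals) on one isoform.

Four encodings of a target ribonucleotide against a transcript:

* ``landmarkTX`` — six signed/unsigned distances to the 5' and 3' boundaries
  of the containing exon, the CDS, and the whole transcript.  Distances to
  the CDS boundaries go negative when the site sits in a UTR, which lets a
  downstream model read off "how far outside the CDS" directly.
* ``gridTX`` — the transcript split into G near-equal fragments; each row
  carries the region-type composition of a fragment, its log-width and a
  target indicator.
* ``chunkTX`` — maximal region runs, with the run containing the target
  split into left/target/right, the (first) target row centered, zero
  padding on the short side and trimming on the long side.  Lossless for
  transcripts whose post-split run count fits into the C rows.
* one-hot region / sequence matrices over a fixed window, the conventional
  baseline the condensed encodings are compared against.

All encoders work in transcript orientation, so a transcript and its
minus-strand mirror produce identical matrices for mirrored sites.
Matrix width columns store log(width + 1) so that zero-pad rows stay zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .annotation import (
    GenomicInterval,
    TranscriptModel,
    decompose_regions,
    map_coordinate,
)

__all__ = [
    "LandmarkVector",
    "GridMatrix",
    "ChunkMatrix",
    "DecodedLayout",
    "IsoformBag",
    "encode_landmarkTX",
    "encode_gridTX",
    "encode_chunkTX",
    "decode_chunkTX",
    "encode_onehot_region",
    "encode_onehot_seq",
    "truncate_to_read",
    "build_bag",
    "build_read_bag",
    "CHUNK_COLUMNS",
    "REGION_COLUMNS",
]

REGION_COLUMNS = ("exon", "intron", "cds", "utr5", "utr3")
CHUNK_COLUMNS = REGION_COLUMNS + ("log_width", "target")

Target = Union[int, GenomicInterval]


def _target_bounds(target: Target) -> tuple[int, int]:
    if isinstance(target, GenomicInterval):
        return target.start, target.end
    return int(target), int(target)


@dataclass(frozen=True)
class LandmarkVector:
    """Distances (nt) from the target to six transcript landmarks.

    Boundary nucleotides have distance 0, so region width = d5 + d3 + 1.
    ``d_cds5``/``d_cds3`` are negative when the site lies 5' of the CDS
    start / 3' of the CDS end respectively; for non-coding transcripts both
    are 0 and ``has_cds`` is False.
    """

    d_exon5: int
    d_exon3: int
    d_cds5: int
    d_cds3: int
    d_tx5: int
    d_tx3: int
    has_cds: bool = True

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.d_exon5, self.d_exon3, self.d_cds5, self.d_cds3,
             self.d_tx5, self.d_tx3],
            dtype=np.float64,
        )

    @property
    def n_features(self) -> int:
        return 6


@dataclass
class GridMatrix:
    """G x 7 fragment-composition matrix with grid parameters attached."""

    matrix: np.ndarray
    n_grids: int
    log_policy: str = "log1p"
    columns: tuple[str, ...] = CHUNK_COLUMNS

    @property
    def n_features(self) -> int:
        return int(self.matrix.size)


@dataclass
class ChunkMatrix:
    """C x 7 run-level matrix; pad rows are all-zero, target rows centered.

    ``row_intervals`` keeps the genomic interval behind every populated row
    so read-span truncation can crop widths without re-deriving the layout.
    ``target_covered`` is flipped to False by :func:`truncate_to_read` when
    the read does not span the target.
    """

    matrix: np.ndarray
    n_chunks: int
    tx_id: str
    target: tuple[int, int]
    row_intervals: list[Optional[GenomicInterval]] = field(default_factory=list)
    target_covered: bool = True
    columns: tuple[str, ...] = CHUNK_COLUMNS

    @property
    def n_features(self) -> int:
        return int(self.matrix.size)


@dataclass
class IsoformBag:
    """One site's encodings across isoforms (or reads) for attention MIL."""

    site: GenomicInterval
    members: list[tuple[str, object]]
    sequence: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"bag for site {self.site} has no members")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# frame helpers


def _frame_length(tx: TranscriptModel, frame: str) -> int:
    return tx.tx_span.width if frame == "unspliced" else tx.spliced_length


def _frame_pos(tx: TranscriptModel, gpos: int, frame: str) -> Optional[int]:
    return map_coordinate(tx, gpos, "unspliced" if frame == "unspliced" else "spliced")


def _run_frame_interval(tx: TranscriptModel, iv: GenomicInterval) -> tuple[int, int]:
    """Unspliced-frame [start, end] (1-based, 5'->3') of a genomic interval."""
    span = tx.tx_span
    if tx.strand == "+":
        return iv.start - span.start + 1, iv.end - span.start + 1
    return span.end - iv.end + 1, span.end - iv.start + 1


def region_flag_array(tx: TranscriptModel) -> np.ndarray:
    """(L, 5) per-nucleotide region flags over the unspliced span, 5'->3'."""
    L = tx.tx_span.width
    out = np.zeros((L, 5), dtype=np.float64)
    for run in decompose_regions(tx):
        a, b = _run_frame_interval(tx, run.interval)
        out[a - 1 : b] = run.flags
    return out


# ---------------------------------------------------------------------------
# landmarkTX


def encode_landmarkTX(
    tx: TranscriptModel,
    site: int,
    frame: Literal["unspliced", "spliced"] = "unspliced",
    allow_intronic: bool = False,
) -> LandmarkVector:
    """Six landmark distances of an exonic site, measured in the given frame.

    CDS distances follow the subtraction convention pos(site) - pos(CDS
    start) and pos(CDS end) - pos(site), which yields the negative signs for
    UTR sites on either strand automatically (positions are counted from the
    transcript 5' end).
    """
    exon = tx.containing_exon(site)
    if exon is None:
        if not (allow_intronic and frame == "unspliced" and tx.tx_span.contains(site)):
            raise ValueError(
                f"site {site} is not exonic on {tx.tx_id}"
                + ("" if tx.tx_span.contains(site) else " (outside span)")
            )
        # intronic site (opt-in): use the containing intron run's boundaries
        exon = next(
            r.interval
            for r in decompose_regions(tx)
            if r.intron and r.interval.contains(site)
        )
    pos = _frame_pos(tx, site, frame)
    assert pos is not None
    L = _frame_length(tx, frame)
    e5 = _frame_pos(tx, exon.start if tx.strand == "+" else exon.end, frame)
    e3 = _frame_pos(tx, exon.end if tx.strand == "+" else exon.start, frame)
    d_exon5, d_exon3 = pos - e5, e3 - pos
    if tx.has_cds:
        c5 = _frame_pos(tx, tx.cds_start, frame)
        c3 = _frame_pos(tx, tx.cds_end, frame)
        d_cds5, d_cds3 = pos - c5, c3 - pos
        has_cds = True
    else:
        d_cds5 = d_cds3 = 0
        has_cds = False
    return LandmarkVector(
        d_exon5=int(d_exon5),
        d_exon3=int(d_exon3),
        d_cds5=int(d_cds5),
        d_cds3=int(d_cds3),
        d_tx5=int(pos - 1),
        d_tx3=int(L - pos),
        has_cds=has_cds,
    )


# ---------------------------------------------------------------------------
# gridTX


def encode_gridTX(
    tx: TranscriptModel,
    target: Target,
    n_grids: int = 80,
    log_policy: str = "log1p",
) -> GridMatrix:
    """Equal-width fragment composition over the unspliced span.

    The span of length L is split into ``n_grids`` fragments whose widths
    differ by at most one (the first L mod G fragments, counted from the 5'
    end, take the extra nucleotide).
    """
    L = tx.tx_span.width
    G = int(n_grids)
    if G < 1:
        raise ValueError("n_grids must be >= 1")
    if G > L:
        raise ValueError(
            f"n_grids={G} exceeds transcript span {L}; use the one-hot region "
            "encoding for single-nucleotide resolution"
        )
    lo, hi = _target_bounds(target)
    t5 = _frame_pos(tx, lo, "unspliced")
    t3 = _frame_pos(tx, hi, "unspliced")
    if t5 is None or t3 is None:
        raise ValueError(f"target {target} outside span of {tx.tx_id}")
    t5, t3 = min(t5, t3), max(t5, t3)
    flags = region_flag_array(tx)
    base, extra = divmod(L, G)
    mat = np.zeros((G, 7), dtype=np.float64)
    start = 1
    for g in range(G):
        w = base + (1 if g < extra else 0)
        end = start + w - 1
        frag = flags[start - 1 : end]
        mat[g, :5] = frag.sum(axis=0) / w
        mat[g, 5] = np.log1p(w) if log_policy == "log1p" else np.log(w)
        if start <= t3 and end >= t5:
            mat[g, 6] = 1.0
        start = end + 1
    return GridMatrix(matrix=mat, n_grids=G, log_policy=log_policy)


# ---------------------------------------------------------------------------
# chunkTX


def _split_runs_on_target(
    tx: TranscriptModel, target: Target
) -> tuple[list[tuple[tuple[int, ...], GenomicInterval, bool]], int]:
    """Run layout (flags, interval, is_target) 5'->3' with the target split out.

    Returns the list and the index of the first target row.
    """
    lo, hi = _target_bounds(target)
    if not tx.tx_span.contains(lo) or not tx.tx_span.contains(hi):
        raise ValueError(f"target {target} outside span of {tx.tx_id}")
    out: list[tuple[tuple[int, ...], GenomicInterval, bool]] = []
    first_target = -1
    for run in decompose_regions(tx):
        iv = run.interval
        if iv.end < lo or iv.start > hi:
            out.append((run.flags, iv, False))
            continue
        a, b = max(iv.start, lo), min(iv.end, hi)
        # order the up-to-three pieces 5'->3' in transcript orientation
        left = (iv.start, a - 1) if a > iv.start else None
        mid = (a, b)
        right = (b + 1, iv.end) if b < iv.end else None
        pieces = [left, mid, right] if tx.strand == "+" else [right, mid, left]
        for piece in pieces:
            if piece is None:
                continue
            is_target = piece == mid
            piv = GenomicInterval(tx.chrom, piece[0], piece[1], tx.strand)
            if is_target and first_target < 0:
                first_target = len(out)
            out.append((run.flags, piv, is_target))
    # mark contiguity: runs fully inside the target between split pieces are
    # already flagged via mid pieces, nothing more to do
    if first_target < 0:
        raise AssertionError("target not found in runs")
    return out, first_target


def encode_chunkTX(
    tx: TranscriptModel,
    target: Target,
    n_chunks: int = 35,
    include_target: bool = True,
) -> ChunkMatrix:
    """Run-level encoding with the (first) target row centered.

    With the default 35 chunks and 7 columns the matrix carries exactly 245
    scalar entries regardless of transcript complexity.  Setting
    ``include_target=False`` yields the whole-transcript variant: no target
    split, 6 columns, runs placed from the 5' end.
    """
    C = int(n_chunks)
    if C < 1:
        raise ValueError("n_chunks must be >= 1")
    if include_target and C % 2 == 0:
        raise ValueError("n_chunks must be odd so the target row can be centered")

    if not include_target:
        runs = decompose_regions(tx)
        mat = np.zeros((C, 6), dtype=np.float64)
        intervals: list[Optional[GenomicInterval]] = [None] * C
        for i, run in enumerate(runs[:C]):
            mat[i, :5] = run.flags
            mat[i, 5] = np.log1p(run.width)
            intervals[i] = run.interval
        return ChunkMatrix(
            matrix=mat, n_chunks=C, tx_id=tx.tx_id,
            target=(-1, -1), row_intervals=intervals,
            columns=REGION_COLUMNS + ("log_width",),
        )

    layout, t_idx = _split_runs_on_target(tx, target)
    center = (C - 1) // 2
    mat = np.zeros((C, 7), dtype=np.float64)
    intervals = [None] * C
    for i, (flags, iv, is_target) in enumerate(layout):
        row = center + (i - t_idx)
        if row < 0 or row >= C:
            continue  # trimmed
        mat[row, :5] = flags
        mat[row, 5] = np.log1p(iv.width)
        mat[row, 6] = 1.0 if is_target else 0.0
        intervals[row] = iv
    lo, hi = _target_bounds(target)
    return ChunkMatrix(
        matrix=mat, n_chunks=C, tx_id=tx.tx_id,
        target=(lo, hi), row_intervals=intervals,
    )


@dataclass(frozen=True)
class DecodedLayout:
    """Region layout recovered from a chunk matrix.

    ``runs`` holds (flags, width, is_target) 5'->3'.  ``maybe_truncated`` is
    set when populated rows reach the matrix edge, i.e. the encoder may have
    trimmed additional runs.
    """

    runs: tuple[tuple[tuple[int, ...], int, bool], ...]
    maybe_truncated: bool = False


def decode_chunkTX(m: ChunkMatrix) -> DecodedLayout:
    """Invert :func:`encode_chunkTX`: recover flags and widths of every run.

    Exact whenever the transcript's post-split run count fits into the
    matrix (no trimming); widths are recovered by inverting the log1p.
    """
    mat = m.matrix
    populated = np.flatnonzero(mat[:, :6].any(axis=1))
    if populated.size == 0:
        return DecodedLayout(runs=())
    runs = []
    has_target_col = mat.shape[1] >= 7
    for r in populated:
        flags = tuple(int(round(v)) for v in mat[r, :5])
        width = int(round(np.expm1(mat[r, 5])))
        is_target = bool(round(mat[r, 6])) if has_target_col else False
        runs.append((flags, width, is_target))
    edge = populated[0] == 0 or populated[-1] == mat.shape[0] - 1
    return DecodedLayout(runs=tuple(runs), maybe_truncated=bool(edge))


def truncate_to_read(
    m: ChunkMatrix, read_span: GenomicInterval, tx: TranscriptModel
) -> ChunkMatrix:
    """Crop a chunk encoding to the part of the transcript a read covers.

    Rows outside the read are zeroed, boundary rows get their width reduced
    to the overlap, and row positions are preserved.  If the read misses the
    target, the returned matrix has an all-zero target column and
    ``target_covered=False`` instead of raising.
    """
    span = tx.tx_span
    if read_span.end < span.start or read_span.start > span.end:
        raise ValueError(f"read {read_span} does not intersect {tx.tx_id}")
    mat = m.matrix.copy()
    intervals: list[Optional[GenomicInterval]] = []
    covered = False
    for row, iv in enumerate(m.row_intervals):
        if iv is None:
            intervals.append(None)
            continue
        a, b = max(iv.start, read_span.start), min(iv.end, read_span.end)
        if a > b:
            mat[row] = 0.0
            intervals.append(None)
            continue
        new_iv = GenomicInterval(iv.chrom, a, b, iv.strand)
        mat[row, 5] = np.log1p(new_iv.width)
        intervals.append(new_iv)
        if mat.shape[1] >= 7 and mat[row, 6] > 0:
            covered = True
    if not covered and mat.shape[1] >= 7:
        mat[:, 6] = 0.0
    return ChunkMatrix(
        matrix=mat, n_chunks=m.n_chunks, tx_id=m.tx_id, target=m.target,
        row_intervals=intervals, target_covered=covered, columns=m.columns,
    )


# ---------------------------------------------------------------------------
# one-hot encodings


def encode_onehot_region(
    tx: TranscriptModel, site: int, window: int = 251
) -> np.ndarray:
    """(W, 5) region-type indicators over a window centered on the site.

    The window runs in the unspliced frame; rows falling outside the
    transcript span are all-zero.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    pos = _frame_pos(tx, site, "unspliced")
    if pos is None:
        raise ValueError(f"site {site} outside span of {tx.tx_id}")
    flags = region_flag_array(tx)
    L = flags.shape[0]
    h = window // 2
    out = np.zeros((window, 5), dtype=np.float64)
    for i, p in enumerate(range(pos - h, pos + h + 1)):
        if 1 <= p <= L:
            out[i] = flags[p - 1]
    return out


_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def fetch_window(genome, chrom: str, pos: int, window: int, strand: str) -> str:
    """Window of genomic sequence centered on pos, reverse-complemented on -.

    ``genome`` may be a plain dict of chromosome strings or a pyfaidx.Fasta.
    Out-of-range flanks are filled with N.
    """
    h = window // 2
    seq_obj = genome[chrom]
    chrom_len = len(seq_obj)
    lo, hi = pos - h, pos + h
    a, b = max(lo, 1), min(hi, chrom_len)
    core = str(seq_obj[a - 1 : b]).upper()
    seq = "N" * (a - lo) + core + "N" * (hi - b)
    if strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq.replace("T", "U")


def encode_onehot_seq(genome, site: GenomicInterval, window: int = 101) -> np.ndarray:
    """(W, 4) A/C/G/U one-hot of the sequence window around a site.

    N (or out-of-chromosome) rows are all-zero; minus-strand sites are
    reverse-complemented so row 0 is the 5'-most nucleotide.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    seq = fetch_window(genome, site.chrom, site.start, window, site.strand)
    return onehot_sequence(seq)


def onehot_sequence(seq: str) -> np.ndarray:
    """A/C/G/U one-hot of an RNA/DNA string; unknown letters give zero rows."""
    lookup = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for i, ch in enumerate(seq.upper()):
        j = lookup.get(ch)
        if j is not None:
            out[i, j] = 1.0
    return out


# ---------------------------------------------------------------------------
# bag assembly


def build_bag(
    site: GenomicInterval,
    isoforms: Sequence[TranscriptModel],
    encoder: str = "chunk",
    n_chunks: int = 35,
    n_grids: int = 80,
    window: int = 251,
    sequence: Optional[np.ndarray] = None,
) -> IsoformBag:
    """Encode one site against every overlapping isoform.

    The per-member encoder is chunkTX by default; landmark/grid/onehot are
    available through ``encoder``.  Raises when no isoform is supplied (the
    caller decides the skip policy).
    """
    if not isoforms:
        raise ValueError(f"no isoforms supplied for site {site}")
    members: list[tuple[str, object]] = []
    has_cds = {}
    for tx in isoforms:
        if encoder == "chunk":
            enc: object = encode_chunkTX(tx, site, n_chunks=n_chunks)
        elif encoder == "landmark":
            enc = encode_landmarkTX(tx, site.start)
        elif encoder == "grid":
            enc = encode_gridTX(tx, site, n_grids=n_grids)
        elif encoder == "onehot":
            enc = encode_onehot_region(tx, site.start, window=window)
        else:
            raise ValueError(f"unknown encoder {encoder!r}")
        members.append((tx.tx_id, enc))
        has_cds[tx.tx_id] = tx.has_cds
    return IsoformBag(site=site, members=members, sequence=sequence,
                      meta={"has_cds": has_cds})


def build_read_bag(
    site: GenomicInterval,
    tx: TranscriptModel,
    read_spans: Sequence[GenomicInterval],
    bag_size: int = 20,
    n_chunks: int = 35,
    seed: int = 0,
) -> IsoformBag:
    """Fixed-size bag of read-truncated chunk encodings for one site.

    More reads than ``bag_size`` are down-sampled with a seeded RNG; fewer
    are padded with all-zero members (no minimum-coverage threshold), so the
    bag always has exactly ``bag_size`` members.  Pad members carry the id
    ``"pad"`` and must be masked out of attention and Noisy-OR pooling.
    """
    if not read_spans:
        raise ValueError(f"no reads supplied for site {site}")
    base = encode_chunkTX(tx, site, n_chunks=n_chunks)
    spans = list(read_spans)
    if len(spans) > bag_size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(spans), size=bag_size, replace=False)
        spans = [spans[i] for i in sorted(idx)]
    members: list[tuple[str, object]] = []
    for i, rs in enumerate(spans):
        members.append((f"read{i}", truncate_to_read(base, rs, tx)))
    n_pad = bag_size - len(spans)
    pad_mat = np.zeros_like(base.matrix)
    for _ in range(n_pad):
        members.append(
            ("pad", ChunkMatrix(matrix=pad_mat.copy(), n_chunks=base.n_chunks,
                                tx_id=tx.tx_id, target=base.target,
                                row_intervals=[None] * base.n_chunks,
                                target_covered=False))
        )
    return IsoformBag(site=site, members=members,
                      meta={"n_real": len(spans), "n_pad": n_pad})
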