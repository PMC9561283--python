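"""Transcript annotation model and genome<->transcript coordinate services.

The package works in the GTF dialect internally: coordinates are 1-based and
inclusive, exons of a transcript are disjoint, and strand is ``+`` or ``-``.
Every transcript is decomposed into maximal runs of five region types (exon,
intron, CDS, 5'UTR, 3'UTR); all downstream geographic encoders are built on
top of that decomposition and on the spliced/unspliced coordinate maps
defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

Strand = Literal["+", "-"]

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "RegionRun",
    "ParseResult",
    "parse_annotation",
    "decompose_regions",
    "map_coordinate",
    "map_to_genome",
    "TranscriptIndex",
    "overlapping_isoforms",
    "select_isoform",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class TranscriptModel:
    """One isoform: ordered exons, optional CDS span, derived region runs.

    ``exons`` are stored 5'->3' in transcript orientation (i.e. in reversed
    genomic order on the minus strand).  ``cds`` holds the genomic low/high
    coordinates of the first and last coding nucleotide; which of the two is
    the start codon side depends on the strand.
    """

    tx_id: str
    gene_id: str
    chrom: str
    strand: Strand
    exons: list[GenomicInterval]
    cds: Optional[tuple[int, int]] = None  # (genomic low, genomic high)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.tx_id} has no exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end >= b.start:
                raise ValueError(f"transcript {self.tx_id}: exons overlap")
        # normalize to transcript orientation
        self.exons = genomic if self.strand == "+" else genomic[::-1]
        if self.cds is not None:
            lo, hi = min(self.cds), max(self.cds)
            self.cds = (lo, hi)
            if not (self.is_exonic(lo) and self.is_exonic(hi)):
                raise ValueError(
                    f"transcript {self.tx_id}: CDS endpoints outside exonic space"
                )

    @property
    def tx_span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(e.width for e in self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds is not None

    @property
    def cds_start(self) -> Optional[int]:
        """Genomic coordinate of the first coding nucleotide (strand-aware)."""
        if self.cds is None:
            return None
        return self.cds[0] if self.strand == "+" else self.cds[1]

    @property
    def cds_end(self) -> Optional[int]:
        """Genomic coordinate of the last coding nucleotide (strand-aware)."""
        if self.cds is None:
            return None
        return self.cds[1] if self.strand == "+" else self.cds[0]

    def is_exonic(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)

    def containing_exon(self, pos: int) -> Optional[GenomicInterval]:
        for e in self.exons:
            if e.contains(pos):
                return e
        return None

    @property
    def last_exon(self) -> GenomicInterval:
        """The 3'-terminal exon in transcript orientation."""
        return self.exons[-1]


@dataclass(frozen=True)
class RegionRun:
    """A maximal run of nucleotides sharing one region-flag vector."""

    interval: GenomicInterval
    exon: int
    intron: int
    cds: int
    utr5: int
    utr3: int

    def __post_init__(self) -> None:
        if self.exon + self.intron != 1:
            raise ValueError("exactly one of exon/intron must be set")
        if self.cds + self.utr5 + self.utr3 > 1:
            raise ValueError("at most one of cds/utr5/utr3 may be set")
        if self.intron and (self.cds or self.utr5 or self.utr3):
            raise ValueError("intronic runs carry no cds/utr flags")

    @property
    def flags(self) -> tuple[int, int, int, int, int]:
        return (self.exon, self.intron, self.cds, self.utr5, self.utr3)

    @property
    def width(self) -> int:
        return self.interval.width


def _classify(tx: TranscriptModel, pos: int) -> tuple[int, int, int, int, int]:
    """Region-flag vector (exon, intron, cds, utr5, utr3) of one nucleotide."""
    if not tx.is_exonic(pos):
        return (0, 1, 0, 0, 0)
    if tx.cds is None:
        return (1, 0, 0, 0, 0)
    lo, hi = tx.cds
    if lo <= pos <= hi:
        return (1, 0, 1, 0, 0)
    five_prime_side = pos < lo if tx.strand == "+" else pos > hi
    if five_prime_side:
        return (1, 0, 0, 1, 0)
    return (1, 0, 0, 0, 1)


def decompose_regions(tx: TranscriptModel) -> list[RegionRun]:
    """Tile the transcript span with maximal region runs, ordered 5'->3'.

    The runs have no gaps or overlaps; their widths sum to the span width.
    """
    span = tx.tx_span
    cuts = {span.start, span.end + 1}
    for e in tx.exons:
        cuts.add(e.start)
        cuts.add(e.end + 1)
    if tx.cds is not None:
        lo, hi = tx.cds
        cuts.add(lo)
        cuts.add(hi + 1)
    edges = sorted(c for c in cuts if span.start <= c <= span.end + 1)
    segments: list[tuple[int, int, tuple[int, int, int, int, int]]] = []
    for a, b in zip(edges, edges[1:]):
        segments.append((a, b - 1, _classify(tx, a)))
    # merge adjacent segments with identical flags (maximality)
    merged: list[list] = []
    for a, b, flags in segments:
        if merged and merged[-1][2] == flags and merged[-1][1] + 1 == a:
            merged[-1][1] = b
        else:
            merged.append([a, b, flags])
    if tx.strand == "-":
        merged = merged[::-1]
    runs = [
        RegionRun(GenomicInterval(tx.chrom, a, b, tx.strand), *flags)
        for a, b, flags in merged
    ]
    return runs


def map_coordinate(
    tx: TranscriptModel, gpos: int, space: Literal["spliced", "unspliced"] = "spliced"
) -> Optional[int]:
    """Genomic position -> 1-based transcript position, or None if unmapped.

    ``unspliced`` counts nucleotides from the transcript 5' end along the
    primary (intron-containing) transcript; ``spliced`` counts along the
    mature transcript and returns None for intronic positions.
    """
    span = tx.tx_span
    if not span.contains(gpos):
        return None
    if space == "unspliced":
        return gpos - span.start + 1 if tx.strand == "+" else span.end - gpos + 1
    offset = 0
    for e in tx.exons:
        if e.contains(gpos):
            within = gpos - e.start if tx.strand == "+" else e.end - gpos
            return offset + within + 1
        offset += e.width
    return None


def map_to_genome(
    tx: TranscriptModel, tpos: int, space: Literal["spliced", "unspliced"] = "spliced"
) -> int:
    """Inverse of :func:`map_coordinate`; round-trips exactly."""
    if tpos < 1:
        raise ValueError(f"transcript position must be >= 1, got {tpos}")
    span = tx.tx_span
    if space == "unspliced":
        if tpos > span.width:
            raise ValueError(f"position {tpos} beyond unspliced length {span.width}")
        return span.start + tpos - 1 if tx.strand == "+" else span.end - tpos + 1
    if tpos > tx.spliced_length:
        raise ValueError(f"position {tpos} beyond spliced length {tx.spliced_length}")
    remaining = tpos - 1
    for e in tx.exons:
        if remaining < e.width:
            return e.start + remaining if tx.strand == "+" else e.end - remaining
        remaining -= e.width
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# annotation ingest


@dataclass
class ParseResult:
    """Parsed transcripts plus bookkeeping about rejected/ignored records."""

    transcripts: list[TranscriptModel] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)
    warnings: int = 0

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, i):
        return self.transcripts[i]

    def by_id(self) -> dict[str, TranscriptModel]:
        return {t.tx_id: t for t in self.transcripts}


def _record_ids(feature) -> tuple[Optional[str], Optional[str]]:
    attrs = feature.attributes
    tx = attrs.get("transcript_id", [None])[0]
    if tx is None:
        parents = attrs.get("Parent", [])
        if parents:
            tx = parents[0].split(":")[-1]
    gene = attrs.get("gene_id", [None])[0]
    if gene is None:
        gene = attrs.get("gene", [None])[0]
    return tx, gene


def parse_annotation(path: str) -> ParseResult:
    """Read a GTF/GFF3 file into :class:`TranscriptModel` objects.

    Exon features are grouped by ``transcript_id`` (or GFF3 ``Parent``); CDS
    features are optional and, when present, define the coding span from
    which the UTRs are inferred.  Transcripts without exon records, or with
    CDS endpoints outside their exonic space, are rejected and reported.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    genes: dict[str, str] = {}
    seen_other = 0
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype not in ("exon", "cds"):
            seen_other += 1
            continue
        tx_id, gene_id = _record_ids(feat)
        if tx_id is None:
            continue
        genes.setdefault(tx_id, gene_id or tx_id)
        (exons if ftype == "exon" else cds).setdefault(tx_id, []).append(feat)

    result = ParseResult()
    for tx_id in sorted(set(exons) | set(cds)):
        if tx_id not in exons:
            result.rejected[tx_id] = "no exon records"
            continue
        feats = exons[tx_id]
        chrom = feats[0].seqid
        strand = feats[0].strand
        if strand not in ("+", "-"):
            result.rejected[tx_id] = f"invalid strand {strand!r}"
            continue
        intervals = [
            GenomicInterval(chrom, f.start, f.end, strand) for f in feats
        ]
        cds_pair = None
        if tx_id in cds:
            outside = [
                f for f in cds[tx_id]
                if not any(e.start <= f.start and f.end <= e.end
                           for e in intervals)
            ]
            if outside:
                f = outside[0]
                result.rejected[tx_id] = (
                    f"CDS record {f.start}-{f.end} outside exonic space"
                )
                continue
            lo = min(f.start for f in cds[tx_id])
            hi = max(f.end for f in cds[tx_id])
            cds_pair = (lo, hi)
        try:
            model = TranscriptModel(
                tx_id=tx_id,
                gene_id=genes[tx_id],
                chrom=chrom,
                strand=strand,  # type: ignore[arg-type]
                exons=intervals,
                cds=cds_pair,
            )
        except ValueError as exc:
            result.rejected[tx_id] = str(exc)
            continue
        result.transcripts.append(model)
    if not result.transcripts and (seen_other or result.rejected):
        result.warnings += 1
    logger.info(
        "parsed %d transcripts (%d rejected, %d non-exon/CDS records ignored)",
        len(result.transcripts),
        len(result.rejected),
        seen_other,
    )
    return result


# ---------------------------------------------------------------------------
# isoform lookup and selection


class TranscriptIndex:
    """Interval index of transcripts keyed by (chrom, strand).

    ``normalize_chrom=True`` strips a leading ``chr`` prefix on both the
    indexed transcripts and the queries; default is exact chromosome-name
    matching to avoid silent misjoins.
    """

    def __init__(
        self, models: Iterable[TranscriptModel], normalize_chrom: bool = False
    ) -> None:
        self.normalize_chrom = normalize_chrom
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._models: list[TranscriptModel] = list(models)
        for tx in self._models:
            span = tx.tx_span
            key = (self._norm(tx.chrom), tx.strand)
            self._trees.setdefault(key, IntervalTree()).addi(
                span.start, span.end + 1, tx
            )

    def _norm(self, chrom: str) -> str:
        return chrom.removeprefix("chr") if self.normalize_chrom else chrom

    def query(
        self, site: GenomicInterval, mode: Literal["mature", "primary"] = "mature"
    ) -> list[TranscriptModel]:
        key = (self._norm(site.chrom), site.strand)
        tree = self._trees.get(key)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(site.start, site.end + 1):
            tx: TranscriptModel = iv.data
            if not tx.tx_span.contains_interval(site):
                continue
            if mode == "mature":
                if all(tx.is_exonic(p) for p in range(site.start, site.end + 1)):
                    hits.append(tx)
            else:
                hits.append(tx)
        return sorted(hits, key=lambda t: t.tx_id)


def overlapping_isoforms(
    site: GenomicInterval,
    models: Iterable[TranscriptModel] | TranscriptIndex,
    mode: Literal["mature", "primary"] = "mature",
) -> list[TranscriptModel]:
    """Isoforms containing the site in exonic (mature) or span (primary) space."""
    index = models if isinstance(models, TranscriptIndex) else TranscriptIndex(models)
    return index.query(site, mode)


def select_isoform(
    isoforms: Sequence[TranscriptModel],
    policy: Literal["longest", "random"] = "longest",
    seed: int = 0,
) -> TranscriptModel:
    """Pick one isoform: maximal spliced length (ties by tx_id) or seeded draw."""
    if not isoforms:
        raise ValueError("cannot select an isoform from an empty list")
    ordered = sorted(isoforms, key=lambda t: t.tx_id)
    if policy == "longest":
        return sorted(ordered, key=lambda t: (-t.spliced_length, t.tx_id))[0]
    if policy == "random":
        rng = np.random.default_rng(seed)
        return ordered[int(rng.integers(len(ordered)))]
    raise ValueError(f"unknown policy {policy!r}")
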