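"""Synthetic annotation, genome, sites, technique sets and read bags.

The generator emulates the statistical structure the analyses in this
package assume: multi-isoform genes with exon/intron/CDS/UTR architecture,
DRACH-motif candidate sites on mature transcripts, and methylated sites
planted with the geographic preferences reported for m6A — enrichment in
long exons, in the 3'-terminal exon and near the stop codon — plus a mild
extended-sequence-context preference.  Labels are drawn from a logistic
model on those features, so the planted effect sizes are known exactly and
parameter recovery can be tested.

Everything is driven by a single seed: the same seed reproduces the GTF
text, the genome FASTA, the planted sites and the read bags byte for byte.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .annotation import (
    GenomicInterval,
    TranscriptModel,
    TranscriptIndex,
    map_coordinate,
    map_to_genome,
)
from .consistency import TechniqueSet
from .encoders import (
    build_read_bag,
    encode_chunkTX,
    encode_onehot_seq,
)

__all__ = [
    "SimulationConfig",
    "SimulatedAnnotation",
    "PlantedSite",
    "simulate_annotation",
    "scan_drach",
    "spliced_sequence",
    "plant_sites",
    "assemble_dataset",
    "simulate_technique_sets",
    "simulate_read_bags",
]

# DRACH: D=[AGU] R=[AG] A C H=[ACU]; T accepted as U on disk
_DRACH_RE = re.compile(r"(?=([AGTU][AG]AC[ACTU]))", re.IGNORECASE)

# extended-context preference beyond the DRACH core, relative to the A at 0:
# a small fixed position weight table (favourable letters and their weights)
SEQ_CONTEXT_WEIGHTS: dict[int, dict[str, float]] = {
    -3: {"A": 0.3},
    -2: {"G": 0.6},
    -1: {"G": 1.0},
    2: {"U": 0.5, "T": 0.5},
    3: {"A": 0.4},
}
# centering constants so the planted sequence score has roughly zero mean
# and unit scale over random DRACH candidates
_SEQ_SCORE_CENTER = 1.05
_SEQ_SCORE_SCALE = 0.65


@dataclass
class SimulationConfig:
    """Generator parameters; defaults define the package's study conditions.

    Effect sizes (`beta_*`) enter a logistic model for the per-candidate
    methylation probability:

        eta = beta0 + beta_last_exon * 1[last exon]
              + beta_log_exon_width * (log w_exon - log 150)
              + beta_stop * exp(-d_stop / tau)
              + beta_seq * seq_context_score

    ``negative_ratio`` is negatives per positive (1.0 for balanced training
    sets, 10.0 for imbalanced independent test sets);
    ``upsample_positives`` replicates positives (10x for the imbalanced
    training recipe).
    """

    n_genes: int = 150
    isoform_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.10, 0.05)
    exon_count_mean: float = 2.5  # n_exons = 2 + Poisson(mean), capped
    max_exons: int = 10
    exon_len_log_mean: float = math.log(150.0)
    exon_len_log_sd: float = 0.7
    exon_len_range: tuple[int, int] = (30, 1500)
    intron_len_log_mean: float = math.log(300.0)
    intron_len_log_sd: float = 0.7
    intron_len_range: tuple[int, int] = (60, 2500)
    intergenic_gap: tuple[int, int] = (200, 800)
    min_cds_len: int = 60
    beta0: float = -3.4
    beta_last_exon: float = 2.0
    beta_log_exon_width: float = 2.0
    beta_stop: float = 4.0
    tau: float = 200.0
    beta_seq: float = 0.9
    negative_ratio: float = 1.0
    upsample_positives: int = 1
    chrom_name: str = "chr1"

    def geography_free(self) -> "SimulationConfig":
        """Same conditions with all geographic effects switched off."""
        return replace(self, beta_last_exon=0.0, beta_log_exon_width=0.0,
                       beta_stop=0.0)


@dataclass
class SimulatedAnnotation:
    """Generated transcript models together with their on-disk forms."""

    models: list[TranscriptModel]
    genome: dict[str, str]
    gtf_text: str
    fasta_text: str

    def index(self) -> TranscriptIndex:
        return TranscriptIndex(self.models)

    def by_id(self) -> dict[str, TranscriptModel]:
        return {t.tx_id: t for t in self.models}


@dataclass
class PlantedSite:
    """One DRACH candidate with its planted label and generating isoform."""

    site: GenomicInterval
    label: int
    tx_id: str  # carrier isoform on which the geography was evaluated
    motif: str
    eta: float
    features: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.site.chrom, self.site.start, self.site.strand)


# ---------------------------------------------------------------------------
# annotation + genome


def _sample_lengths(rng, n, log_mean, log_sd, lo, hi) -> np.ndarray:
    vals = np.exp(rng.normal(log_mean, log_sd, size=n))
    return np.clip(np.round(vals), lo, hi).astype(int)


def _gene_isoforms(
    rng: np.random.Generator,
    gene_idx: int,
    cfg: SimulationConfig,
    cursor: int,
) -> tuple[list[TranscriptModel], int]:
    """Build one gene: a primary isoform plus derived variants."""
    gene_id = f"G{gene_idx:04d}"
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(min(2 + rng.poisson(cfg.exon_count_mean), cfg.max_exons))
    exon_lens = _sample_lengths(rng, n_exons, cfg.exon_len_log_mean,
                                cfg.exon_len_log_sd, *cfg.exon_len_range)
    intron_lens = _sample_lengths(rng, max(n_exons - 1, 0),
                                  cfg.intron_len_log_mean,
                                  cfg.intron_len_log_sd, *cfg.intron_len_range)
    start = cursor
    exons = []
    pos = start
    for i, w in enumerate(exon_lens):
        exons.append(GenomicInterval(cfg.chrom_name, pos, pos + int(w) - 1, strand))
        pos += int(w)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    gene_end = pos - 1

    primary = TranscriptModel(
        tx_id=f"{gene_id}.T1", gene_id=gene_id, chrom=cfg.chrom_name,
        strand=strand, exons=exons,
    )
    # CDS placement in spliced coordinates: leave a 5'UTR and a 3'UTR
    L = primary.spliced_length
    max_u5 = max(min(300, L // 4), 10)
    max_u3 = max(min(1500, L // 2), 20)
    for _ in range(20):
        u5 = int(rng.integers(10, max_u5 + 1))
        u3 = int(rng.integers(20, max_u3 + 1))
        if L - u5 - u3 >= cfg.min_cds_len:
            break
    else:
        u5, u3 = 10, 20
    cds_pair = None
    if L - u5 - u3 >= cfg.min_cds_len:
        g1 = map_to_genome(primary, u5 + 1, "spliced")
        g2 = map_to_genome(primary, L - u3, "spliced")
        cds_pair = (min(g1, g2), max(g1, g2))
    primary = TranscriptModel(
        tx_id=f"{gene_id}.T1", gene_id=gene_id, chrom=cfg.chrom_name,
        strand=strand, exons=exons, cds=cds_pair,
    )

    isoforms = [primary]
    n_iso = 1 + int(rng.choice(len(cfg.isoform_probs), p=cfg.isoform_probs))
    k = 2
    attempts = 0
    while len(isoforms) < n_iso and attempts < 10 * n_iso:
        attempts += 1
        if n_exons < 2:
            break
        kind = rng.choice(["skip", "short3", "short5"])
        genomic = sorted(exons, key=lambda e: e.start)
        if kind == "skip" and n_exons >= 3:
            drop = int(rng.integers(1, n_exons - 1))
            new_exons = [e for i, e in enumerate(genomic) if i != drop]
        elif kind == "short3":
            # drop the 3'-terminal exon (transcript orientation)
            new_exons = genomic[:-1] if strand == "+" else genomic[1:]
        elif kind == "short5":
            new_exons = genomic[1:] if strand == "+" else genomic[:-1]
        else:
            continue
        if not new_exons:
            continue
        trial = TranscriptModel(
            tx_id=f"{gene_id}.T{k}", gene_id=gene_id, chrom=cfg.chrom_name,
            strand=strand, exons=list(new_exons),
        )
        v_cds = None
        if cds_pair is not None and trial.is_exonic(cds_pair[0]) \
                and trial.is_exonic(cds_pair[1]):
            v_cds = cds_pair
        trial = TranscriptModel(
            tx_id=f"{gene_id}.T{k}", gene_id=gene_id, chrom=cfg.chrom_name,
            strand=strand, exons=list(new_exons), cds=v_cds,
        )
        if any(set((e.start, e.end) for e in t.exons)
               == set((e.start, e.end) for e in trial.exons) for t in isoforms):
            continue
        isoforms.append(trial)
        k += 1
    next_cursor = gene_end + 1 + int(rng.integers(*cfg.intergenic_gap))
    return isoforms, next_cursor


def _gtf_text(models: Sequence[TranscriptModel]) -> str:
    lines = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in models:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        g_lo = min(t.tx_span.start for t in txs)
        g_hi = max(t.tx_span.end for t in txs)
        chrom, strand = txs[0].chrom, txs[0].strand
        attrs = f'gene_id "{gene_id}";'
        lines.append(
            f"{chrom}\tsim\tgene\t{g_lo}\t{g_hi}\t.\t{strand}\t.\t{attrs}"
        )
        for tx in sorted(txs, key=lambda t: t.tx_id):
            span = tx.tx_span
            a = f'gene_id "{gene_id}"; transcript_id "{tx.tx_id}";'
            lines.append(
                f"{chrom}\tsim\ttranscript\t{span.start}\t{span.end}\t.\t{strand}\t.\t{a}"
            )
            for e in sorted(tx.exons, key=lambda e: e.start):
                lines.append(
                    f"{chrom}\tsim\texon\t{e.start}\t{e.end}\t.\t{strand}\t.\t{a}"
                )
            if tx.cds is not None:
                lo, hi = tx.cds
                for e in sorted(tx.exons, key=lambda e: e.start):
                    a2, b2 = max(e.start, lo), min(e.end, hi)
                    if a2 <= b2:
                        lines.append(
                            f"{chrom}\tsim\tCDS\t{a2}\t{b2}\t.\t{strand}\t0\t{a}"
                        )
    return "\n".join(lines) + "\n"


def _fasta_text(genome: dict[str, str], width: int = 70) -> str:
    parts = []
    for chrom in sorted(genome):
        parts.append(f">{chrom}")
        seq = genome[chrom]
        parts.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(parts) + "\n"


def simulate_annotation(
    config: Optional[SimulationConfig] = None, seed: int = 0
) -> SimulatedAnnotation:
    """Generate genes, isoforms and a matching random genome.

    The emitted GTF re-parses to the in-memory models exactly; isoforms of a
    gene always share at least one exon with the primary isoform.
    """
    cfg = config or SimulationConfig()
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    models: list[TranscriptModel] = []
    cursor = 1 + int(rng.integers(*cfg.intergenic_gap))
    for g in range(1, cfg.n_genes + 1):
        isoforms, cursor = _gene_isoforms(rng, g, cfg, cursor)
        models.extend(isoforms)
    chrom_len = cursor + int(rng.integers(*cfg.intergenic_gap))
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.integers(0, 4, size=chrom_len)])
    genome = {cfg.chrom_name: seq}
    return SimulatedAnnotation(
        models=models, genome=genome,
        gtf_text=_gtf_text(models), fasta_text=_fasta_text(genome),
    )


# ---------------------------------------------------------------------------
# DRACH scanning and site planting


def scan_drach(sequence_or_tx, genome: Optional[dict] = None) -> list[int]:
    """Positions of the A of every DRACH match (overlaps included).

    For a string, 1-based string positions are returned.  For a
    :class:`TranscriptModel` (with ``genome``), the scan runs over the
    mature (spliced) sequence and genomic positions of the A are returned.
    """
    if isinstance(sequence_or_tx, TranscriptModel):
        if genome is None:
            raise ValueError("scanning a transcript requires the genome")
        tx = sequence_or_tx
        seq = spliced_sequence(tx, genome)
        return [map_to_genome(tx, p, "spliced") for p in scan_drach(seq)]
    seq = str(sequence_or_tx)
    return [m.start() + 3 for m in _DRACH_RE.finditer(seq)]


def spliced_sequence(tx: TranscriptModel, genome: dict) -> str:
    """Mature transcript sequence 5'->3' (uppercase, T alphabet)."""
    chrom = genome[tx.chrom]
    parts = []
    for e in tx.exons:
        s = str(chrom[e.start - 1 : e.end]).upper()
        if tx.strand == "-":
            s = s.translate(str.maketrans("ACGTUN", "TGCAAN"))[::-1]
        parts.append(s)
    return "".join(parts)


def seq_context_score(context: str, center: int) -> float:
    """Standardized extended-context score of a candidate A.

    ``context`` is the spliced sequence, ``center`` the 0-based index of the
    A.  Raw score sums the fixed position weights; the result is centered
    and scaled by constants chosen for roughly zero mean / unit scale over
    random DRACH candidates.
    """
    raw = 0.0
    n = len(context)
    for off, table in SEQ_CONTEXT_WEIGHTS.items():
        i = center + off
        if 0 <= i < n:
            raw += table.get(context[i].upper(), 0.0)
    return (raw - _SEQ_SCORE_CENTER) / _SEQ_SCORE_SCALE


def _candidate_features(
    tx: TranscriptModel, spos: int, seq: str, cfg: SimulationConfig
) -> tuple[int, dict]:
    gpos = map_to_genome(tx, spos, "spliced")
    exon = tx.containing_exon(gpos)
    assert exon is not None
    is_last = int(exon == tx.last_exon)
    log_w = math.log(exon.width)
    if tx.has_cds:
        stop_spliced = map_coordinate(tx, tx.cds_end, "spliced")
        d_stop = abs(spos - stop_spliced)
        stop_term = math.exp(-d_stop / cfg.tau)
    else:
        d_stop = None
        stop_term = 0.0
    s_seq = seq_context_score(seq, spos - 1)
    feats = {
        "last_exon": is_last,
        "log_exon_width": log_w,
        "stop_term": stop_term,
        "d_stop": d_stop,
        "seq_score": s_seq,
    }
    return gpos, feats


def _eta(feats: dict, cfg: SimulationConfig) -> float:
    return (
        cfg.beta0
        + cfg.beta_last_exon * feats["last_exon"]
        + cfg.beta_log_exon_width * (feats["log_exon_width"] - math.log(150.0))
        + cfg.beta_stop * feats["stop_term"]
        + cfg.beta_seq * feats["seq_score"]
    )


def plant_sites(
    sim: SimulatedAnnotation,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    max_positives: Optional[int] = None,
) -> list[PlantedSite]:
    """Label DRACH candidates with the logistic geography model.

    One carrier isoform per gene is drawn uniformly; candidates are the
    DRACH As on its mature sequence, and each gets a Bernoulli label with
    probability sigmoid(eta) evaluated on the carrier's geography.
    Negatives are then sampled from the label-0 candidates of the same
    transcripts at ``negative_ratio`` negatives per positive; positives may
    be replicated ``upsample_positives`` times for imbalanced-training
    recipes.  Raises when the candidate pool cannot support the ratio.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in sim.models:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    positives: list[PlantedSite] = []
    negatives: list[PlantedSite] = []
    for gene_id in sorted(by_gene):
        isoforms = sorted(by_gene[gene_id], key=lambda t: t.tx_id)
        carrier = isoforms[int(rng.integers(len(isoforms)))]
        seq = spliced_sequence(carrier, sim.genome)
        for spos in scan_drach(seq):
            gpos, feats = _candidate_features(carrier, spos, seq, cfg)
            eta = _eta(feats, cfg)
            p = 1.0 / (1.0 + math.exp(-eta))
            label = int(rng.random() < p)
            site = PlantedSite(
                site=GenomicInterval(carrier.chrom, gpos, gpos, carrier.strand),
                label=label, tx_id=carrier.tx_id,
                motif=seq[spos - 3 : spos + 2], eta=eta, features=feats,
            )
            (positives if label else negatives).append(site)

    if max_positives is not None and len(positives) > max_positives:
        idx = rng.choice(len(positives), size=max_positives, replace=False)
        positives = [positives[i] for i in sorted(idx)]
    n_neg = int(round(cfg.negative_ratio * len(positives)))
    if len(negatives) < n_neg:
        raise ValueError(
            f"candidate pool too small: need {n_neg} negatives, "
            f"have {len(negatives)} (positives: {len(positives)})"
        )
    idx = rng.choice(len(negatives), size=n_neg, replace=False)
    negatives = [negatives[i] for i in sorted(idx)]
    out = positives * max(cfg.upsample_positives, 1) + negatives
    return out


# ---------------------------------------------------------------------------
# dataset assembly for the model zoo


def assemble_dataset(
    sim: SimulatedAnnotation,
    sites: Sequence[PlantedSite],
    n_chunks: int = 35,
    seq_window: int = 101,
    policy: str = "longest",
) -> dict:
    """Encode planted sites into the arrays/bags the models consume.

    ``geo`` holds the chunkTX matrix of the policy-selected overlapping
    isoform (mature-mode overlap, longest by default, as in conventional
    isoform-ambiguous training); ``bags`` holds one entry per site with the
    encodings of all overlapping isoforms, the shared one-hot sequence
    window, and the index of the generating (carrier) isoform when it is
    among the members.
    """
    index = sim.index()
    geo_list, seq_list, y_list, bags = [], [], [], []
    carrier_idx = []
    kept_sites = []
    for ps in sites:
        isoforms = index.query(ps.site, "mature")
        if not isoforms:
            continue
        isoforms = sorted(isoforms, key=lambda t: t.tx_id)
        chosen = sorted(isoforms, key=lambda t: (-t.spliced_length, t.tx_id))[0]
        geo_list.append(encode_chunkTX(chosen, ps.site.start, n_chunks).matrix)
        seq = encode_onehot_seq(sim.genome, ps.site, seq_window)
        seq_list.append(seq)
        y_list.append(ps.label)
        member_geo = np.stack(
            [encode_chunkTX(t, ps.site.start, n_chunks).matrix for t in isoforms]
        )
        ids = [t.tx_id for t in isoforms]
        c_idx = ids.index(ps.tx_id) if ps.tx_id in ids else -1
        carrier_idx.append(c_idx)
        bags.append({
            "geo": member_geo, "seq": seq, "tx_ids": ids,
            "mask": np.ones(len(ids), bool), "carrier_idx": c_idx,
        })
        kept_sites.append(ps)
    return {
        "geo": np.stack(geo_list),
        "seq": np.stack(seq_list),
        "y": np.asarray(y_list, dtype=np.float64),
        "bags": bags,
        "carrier_idx": np.asarray(carrier_idx),
        "sites": kept_sites,
    }


# ---------------------------------------------------------------------------
# technique sets and read bags


def simulate_technique_sets(
    truth: Sequence[Union[PlantedSite, tuple]],
    n_techniques: int = 3,
    sensitivity: float = 0.8,
    fp_rate: float = 0.0,
    universe: Optional[Sequence[tuple]] = None,
    seed: int = 0,
) -> list[TechniqueSet]:
    """Noisy technique-specific site sets from a shared ground truth.

    Each technique keeps each true site with probability ``sensitivity``
    and, when a universe is given, adds each non-true universe site with
    probability ``fp_rate``.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= fp_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth_keys = [
        t.key if isinstance(t, PlantedSite) else tuple(t) for t in truth
    ]
    uni = [tuple(u) for u in universe] if universe is not None else []
    noise_pool = [u for u in uni if u not in set(truth_keys)]
    sets = []
    for i in range(n_techniques):
        kept = [s for s in truth_keys if rng.random() < sensitivity]
        if noise_pool and fp_rate > 0:
            kept += [u for u in noise_pool if rng.random() < fp_rate]
        sets.append(TechniqueSet(f"tech{i+1}", kept))
    return sets


def simulate_read_bags(
    sites: Sequence[PlantedSite],
    models: dict[str, TranscriptModel],
    mean_reads: float = 15.0,
    stoichiometry: float = 0.5,
    bag_size: int = 20,
    read_len_mean: float = 600.0,
    read_len_sd: float = 150.0,
    seed: int = 0,
    n_chunks: int = 35,
) -> dict:
    """Read-level bags for the Noisy-OR site model.

    Per site, reads-per-site ~ 1 + Poisson(mean - 1); each read span covers
    the site with a random offset and is clipped to the transcript span.
    Per-read modification labels are Bernoulli(stoichiometry) for positive
    sites and 0 for negatives.  Bags are built with the 20-read contract:
    seeded down-sampling above ``bag_size``, zero padding below.
    """
    rng = np.random.default_rng(seed)
    bags, y = [], []
    for ps in sites:
        tx = models[ps.tx_id]
        span = tx.tx_span
        n_reads = 1 + int(rng.poisson(max(mean_reads - 1.0, 0.0)))
        spans = []
        read_labels = []
        for _ in range(n_reads):
            L = int(np.clip(rng.normal(read_len_mean, read_len_sd), 150, None))
            off = int(rng.integers(0, L))
            a = max(span.start, ps.site.start - off)
            b = min(span.end, a + L - 1)
            spans.append(GenomicInterval(tx.chrom, a, b, tx.strand))
            read_labels.append(
                int(ps.label and rng.random() < stoichiometry)
            )
        if len(spans) > bag_size:
            # down-sample spans and labels together so they stay aligned
            keep = sorted(rng.choice(len(spans), size=bag_size, replace=False))
            spans = [spans[i] for i in keep]
            read_labels = [read_labels[i] for i in keep]
        bag = build_read_bag(ps.site, tx, spans, bag_size=bag_size,
                             n_chunks=n_chunks, seed=int(rng.integers(2**31)))
        geo = np.stack([m.matrix for _, m in bag.members])
        mask = np.array([tid != "pad" for tid, _ in bag.members])
        bags.append({
            "geo": geo, "mask": mask, "read_labels": read_labels,
            "site": ps.site, "tx_id": ps.tx_id,
        })
        y.append(ps.label)
    return {"bags": bags, "y": np.asarray(y, dtype=np.float64)}
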