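# geotx

**Sub-molecular geographic encoding of RNA transcripts for
modification-site prediction.**

Where a ribonucleotide sits on its transcript — which exon, how wide that
exon is, how far from the stop codon, inside which of 5'UTR / CDS / intron
/ 3'UTR — carries information about RNA modifications such as m6A that the
primary sequence does not: m6A is enriched in long exons, 3'-terminal exons
and near stop codons.  `geotx` is a library (plus a thin `geotx` CLI) for
researchers who build site-level models of the epitranscriptome.  It
provides:

* **Four geographic encoders** of a site against one isoform:
  * `landmarkTX` — six distances to the 5'/3' boundaries of the containing
    exon, the CDS and the transcript, with d(CDS) < 0 in the UTRs
    (6 features);
  * `gridTX` — G near-equal fragments × (region composition, log width,
    target flag) (G×7 features);
  * `chunkTX` — maximal region runs split at the target and centered on it;
    lossless and only 35×7 = 245 features at the default size;
  * the conventional one-hot region / sequence windows (101×5 = 505 or
    251×5 = 1255 features) as the baseline.
* **Annotation machinery**: GTF/GFF3 ingest, exon/intron/CDS/UTR run
  decomposition, spliced/unspliced genome↔transcript coordinate maps,
  isoform overlap queries and longest/random isoform selection.
* **Models** (on a built-in seeded NumPy autodiff stack — no deep-learning
  framework needed): geography-only CNN, sequence-only CNN, the fused
  geography+sequence model, isoform-aware gated-attention MIL whose
  attention weights point at the isoform carrying the signal, a nested MIL
  for peak-level labels (50-nt instances, stride 10), and read-level
  scoring with Noisy-OR aggregation and the 20-read bag contract.
* **Cross-technique consistency**: the min-normalized overlap score
  s(A,B) = |A∩B| / min(|A|,|B|), full pairwise matrices, and a permutation
  FDR for "how many techniques must support a site".
* **A synthetic-data generator** producing multi-isoform genes, DRACH
  candidates, and methylation planted by a logistic geography model — so
  the whole pipeline is testable end to end without downloads.

## Worked example

```python
from geotx import (GenomicInterval, TranscriptModel,
                   encode_landmarkTX, encode_chunkTX, decode_chunkTX)

tx = TranscriptModel(
    tx_id="TX1", gene_id="G1", chrom="c1", strand="+",
    exons=[GenomicInterval("c1", 101, 200, "+"),
           GenomicInterval("c1", 301, 400, "+")],
    cds=(151, 350),
)
print(encode_landmarkTX(tx, 160).to_array())
# [ 59.  40.   9. 190.  59. 240.]
```

The six numbers are the distances from site 160 to the exon 5'/3' ends
(59, 40 — so the exon is 59+40+1 = 100 nt wide), to the CDS start/end
(9, 190), and to the transcript ends (59, 240).  A 5'UTR site would get a
negative CDS-start distance.  `encode_chunkTX(tx, 160)` packs the same
transcript's full region layout into 245 numbers, and
`decode_chunkTX` recovers the exact layout — the encoding is lossless.

Running the narrative scripts in `examples/` prints, among other things:

```text
$ python examples/synthetic_benchmark.py      # ~1 minute, 220 genes
geography-only CNN AUC : 0.738
sequence-only CNN AUC  : 0.548
fused (geo+seq)   AUC  : 0.770
fused - sequence gap with geography planted : +0.222
fused - sequence gap, geography-free labels : -0.019

$ python examples/isoform_attention.py
positive test bags where the top attention weight falls on the
signal-carrying isoform: 96.5% (n=85)

$ python examples/technique_consistency.py
Mean over the 36 technique pairs: 17.69%
```

Geography alone predicts planted methylation far above chance, fusing it
with sequence helps exactly when the labels depend on geography, the MIL
attention identifies the carrier isoform under single-witness conditions,
and nine published m6A profiling techniques agree on average on only
17.69% of their housekeeping-gene sites.  At the package's full default
scale (700 genes, 4000 sites; `geotx.experiments.run_synthetic_benchmark`)
the geography-only CNN reaches AUC 0.805.

## Command line

```bash
geotx simulate --genes 150 --seed 1 --out sim/
geotx encode --annotation sim/annotation.gtf --sites sim/sites.bed \
             --genome sim/genome.fa --encoder chunk --out enc.h5
geotx train --kind geo_cnn --data enc.h5 --folds 10 --seed 1
geotx consistency --sets a.bed --sets b.bed --universe drach.bed --kmin 4
geotx eval --scores scores.tsv
```

Every run writes a provenance record (config, versions, seed) beside its
outputs.

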