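# Methods

## The problem

N6-methyladenosine (m6A) and related RNA modifications form at specific
positions of specific transcripts, and where a ribonucleotide sits relative
to the functional sub-regions of its transcript — exons, introns, the CDS
and the UTRs — carries information about whether it is modified that the
primary sequence does not.  m6A in particular is enriched in long exons, in
3'-terminal exons and near the stop codon.  This package implements
"geographic" encodings of that positional context, the coordinate machinery
they need, model architectures that consume them (including isoform-aware
and read-level multiple-instance variants), a cross-technique consistency
analysis, and a synthetic-data generator that makes all of it testable
without external datasets.

## Coordinate conventions

Internal coordinates are 1-based inclusive (the GTF dialect); BED input is
0-based half-open and converted at the I/O boundary.  Every transcript is
decomposed into maximal runs of five region flags (exon, intron, CDS,
5'UTR, 3'UTR) satisfying exon+intron=1 and cds+utr5+utr3 <= exon.  UTRs are
inferred as exonic space minus the CDS span; the stop codon is taken as the
annotation writes it, with no +/-3 adjustment — annotation dialects differ
on whether the stop codon is inside the CDS, and second-guessing the file
invites silent off-by-threes.  Transcripts without CDS are legal; their
CDS-dependent landmark distances are reported as 0 with a `has_cds` flag in
bag metadata, keeping the landmark vector at its documented six entries.
Chromosome names match exactly by default (a `normalize_chrom` toggle
strips the `chr` prefix) to avoid silent misjoins.  Two coordinate frames
are supported everywhere: *unspliced* (primary transcript, introns
included; the default for all encoders, since the matrix encoders display
introns and the landmark distances are genomic-subtraction style) and
*spliced* (mature transcript).

## The encoders

**landmarkTX** gives six distances from the site to the 5' and 3'
boundaries of its exon, the CDS, and the transcript.  A boundary nucleotide
has distance 0, so width = d5 + d3 + 1; the choice fixes an off-by-one the
distance idea leaves open, and is the plain subtraction pos(site) -
pos(boundary).  CDS distances are computed as pos(site) - pos(CDS start)
and pos(CDS end) - pos(site) *in transcript orientation*, which makes them
negative exactly when the site is in the 5'UTR or 3'UTR on either strand —
no separate sign rule per strand is needed.

**gridTX** splits the unspliced span of length L into G near-equal
fragments (widths differ by at most 1; the 5'-most L mod G fragments take
the extra nucleotide) and reports per fragment the fractional composition
of the five region flags, log(width+1), and a target indicator for every
fragment overlapping the target.  With G = L it degenerates exactly to the
one-hot region encoding; that limit is enforced by tests.

**chunkTX** works at run level: the run containing the target is split into
left / target / right pieces, the (first) target row is placed at the
center row (C+1)/2, the short side is zero-padded and the long side
trimmed.  Columns are the five binary flags, log(width+1), and the target
indicator — 7 columns, so the default C=35 yields 245 scalars.  As long as
no trimming occurs the encoding is lossless: `decode_chunkTX` recovers the
exact split-run layout, inverting the width column with round(expm1).
Decoding flags a *possible* truncation whenever populated rows touch the
matrix edge; a side that exactly fills its 17 rows is therefore flagged
conservatively even though it decoded completely.  A whole-transcript
variant (no target split, 6 columns) is available for applications that
encode a transcript rather than a site.  A target interval overlapping
several runs marks every overlapped fragment as target and centers on the
first.

Width columns store the natural log of (width+1): the +1 keeps zero-pad
rows identically zero, which the decoders and the padding masks rely on.
landmarkTX distances stay raw (they are consumed by tree models, which do
not care about monotone transforms).

**Read truncation.**  For long-read data, the chunk encoding is cropped to
the span a read actually covers: rows outside the read are zeroed, boundary
rows get the overlap width, row positions are preserved.  A read that
misses the target yields an all-zero target column and a `target_covered`
flag rather than an error, so low-coverage sites stay in the data.

All encoders operate in transcript orientation, so a transcript and its
reverse-complement mirror produce identical encodings for mirrored sites;
this strand invariance is property-tested.

## Models

All model kinds share a two-layer convolutional geographic branch (64 then
32 filters, kernels 5 and 3, one max-pool, one dropout at 0.2) and train
with Adam on binary cross-entropy, mini-batch 128 for 20 epochs when input
shapes are fixed, and one bag at a time for one epoch when bags are ragged
(isoform, instance and read bags).  The sequence branch is a stack of three
convolutional blocks over the one-hot A/C/G/U window — a simplified
reference branch in the spirit of published sequence-only predictors;
bit-faithful reproduction of any published network is a non-goal.  The
fused model concatenates the two branch features before dense layers.

The isoform-MIL model encodes each overlapping isoform with the shared
geographic branch, broadcasts the site's sequence feature to every member,
and pools members with gated attention: query_i = tanh(V h_i) *
sigmoid(U h_i), score_i = w . query_i, weights = softmax over the bag,
pooled = sum_i weight_i h_i.  Attention hidden size defaults to 128 and the
post-pool dense layer to 64; both are config-overridable since the
published values live only in supplementary material.  Zero-pad members are
excluded by masking their scores to -inf before the softmax; removing a
zero-weight member changes the pooled vector only at machine precision.
The nested (peak-level) variant first cuts the peak sequence into 50-nt
instances at stride 10 (the trailing partial window is dropped), pools the
instances with a first attention layer, and then runs the isoform MIL.
The read-level model scores each read-truncated encoding and aggregates
with Noisy-OR, 1 - prod(1 - p_i), pads masked out; training backpropagates
through the Noisy-OR in log space.

There is no deep-learning framework dependency: the layers run on a small
reverse-mode autodiff engine over NumPy arrays written for this package
(`geotx.nn`), float64 throughout, gradient-checked against numerical
differentiation in the test suite.  One config seed determines parameter
initialization, mini-batch shuffling and dropout masks, so a run is exactly
reproducible.

## Consistency and permutation FDR

Agreement between two techniques' site sets is the min-normalized overlap
s(A,B) = |A n B| / min(|A|,|B|), reported as a percentage with two decimals
for display and full precision internally.  Site identity is (chrom, pos,
strand) at single-nucleotide resolution with no fuzzy window.  The package
ships the published nine-technique comparison counts on housekeeping genes
as an input table; recomputing all 36 pairwise scores from the diagonal
(set sizes) and upper triangle (intersection counts) reproduces every
published percentage and their mean of 17.69%.

The permutation null for multi-technique support re-places each
technique's sites uniformly at random (without replacement) over the
candidate-motif universe, independently across techniques and preserving
per-technique counts — the simplest exchangeable null consistent with a
motif-restricted permutation analysis.  Whether per-gene counts should
also be preserved is not determinable from the available description; the
global-count null is the declared choice.  FDR(k) is the mean permuted
count of sites with support >= k divided by the observed count, capped at
1, undefined (missing) where the observed count is zero.  Default 1000
permutations, seeded.

## Synthetic data: what it emulates, and what it does not

The generator builds multi-isoform genes (1-5 isoforms; variants skip an
internal exon or truncate a terminal exon, always sharing exons with the
primary), exon and intron lengths lognormal around 150 and 300 nt (introns
scaled down from mammalian scale to keep desk-size genomes), a CDS placed
to leave both UTRs, and a uniform-random genome (T alphabet on disk, U in
model space).  The emitted GTF/FASTA re-parse to the in-memory models
byte-exactly, and everything is reproducible from one seed.

Candidate sites are the DRACH motifs (D=[AGU], R=[AG], H=[ACU]) of one
uniformly drawn carrier isoform per gene.  Labels come from a logistic
model,

    eta = beta0 + beta_last * 1[last exon]
          + beta_logw * (log w_exon - log 150)
          + beta_stop * exp(-d_stop / tau)      (tau = 200 nt)
          + beta_seq * seq_context_score,

with the sequence score a fixed position-weight preference for an extended
GGACU-like context, standardized to roughly zero mean and unit scale over
random DRACH candidates.  Negatives are drawn from the remaining DRACH
candidates of the same transcripts at a configurable ratio (1:1 default,
1:10 for imbalanced test sets, with optional 10x positive up-sampling for
imbalanced training).

Effect sizes are the one genuinely free design choice.  They were fixed
once by matching the *oracle* discriminability — the AUC of the true
planted linear predictor on the balanced n=4000 dataset — to the regime
real m6A data exhibits (geography-only oracle 0.84, full oracle 0.88,
sitting above trained-model performance as a Bayes ceiling should); the
defaults are beta0=-3.4, beta_last=2.0, beta_logw=2.0, beta_stop=4.0,
beta_seq=0.9.  The intercept controls only the base positive rate (0.37
among candidates) and was chosen so the default 1:1 ratio is always
feasible.  `geography_free()` zeroes the three geographic effects, leaving
sequence as the only signal — the negative control for the fusion benefit.

What the generator does *not* emulate: real sequence composition and motif
statistics (the genome is uniform random), expression levels, antibody or
protocol biases, peak-calling artifacts, crosslinking-induced motif
preferences, or Nanopore signal characteristics.  Passing benchmarks on
this data therefore show that the encoders expose planted geographic
signal and that the models can read it — not that any particular AUC will
transfer to real data.

## The benchmark and its numbers

`run_synthetic_benchmark` (700 genes, 2000 positives, 1:1, 75/25
stratified split, all model defaults, one seed end to end) trains the
geography-only CNN, the sequence-only CNN, the fused model and the
isoform-MIL model on the default conditions, and the sequence-only and
fused models again on the geography-free conditions.  The problem size was
chosen to keep the full run at a few CPU-minutes.  The package's checks
assert the qualitative pattern: geography-only AUC >= 0.75, a fusion
benefit of >= 0.03 AUC over sequence-only when geography is planted, and
<= 0.01 when it is not.

**Attention recovery needs single-carrier conditions.**  On the default
conditions the carrier isoform is drawn uniformly and sibling isoforms
share most of their geography, so the carrier is fundamentally
unidentifiable in most bags: even the generative-truth oracle (argmax of
the per-isoform planted eta) coincides with the carrier in only ~53% of
multi-isoform bags.  No attention mechanism can beat the data's own
identifiability, so the recovery experiment (`run_attention_recovery`)
constructs the classic MIL structure from the same generator: positive
bags are sites whose top-eta isoform clears the runner-up by at least one
logit (a unique witness), negative bags are sites unfavorable on every
isoform.  Under those conditions the trained attention places its maximum
weight on the witness isoform in >90% of positive test bags.  A related
caveat observed during development: when positive and negative bags are
*both* allowed to contain favorable-looking members, gated attention can
converge to an inverted (min-attending) solution that predicts equally
well but is uninterpretable — a known degeneracy of attention-MIL worth
remembering when applying the model to data without witness structure.

## Numerical and degenerate-input choices

Ties in longest-isoform selection break lexicographically by transcript
id; random selection sorts by id before the seeded draw so the result does
not depend on input order.  Even chunk counts are rejected rather than
tie-broken.  Grid counts exceeding the span raise with a pointer to the
one-hot encoder.  AUC/AP are reported missing (NaN) for single-class
inputs; cross-validation refuses folds that lose a class.  Stability
choices: BCE is computed from logits via softplus; softmax subtracts the
row max; the Noisy-OR loss works in log space with a 1e-12 floor.
Probabilities at exactly 0 or 1 are legal inputs to `noisy_or`.

## Known limitations

Trans-spliced and circular transcripts are out of scope, as are genome
liftover and annotation retrieval.  The NumPy training stack is
single-threaded desk-scale — minutes for thousands of sites, not hours for
millions — and the published real-data performance tables are explicitly
not reproduced here (external data, GPU-scale training).  The permutation
FDR assumes technique independence under the null; correlated technical
biases between related techniques would inflate observed support without
inflating the null.
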