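# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic study does and does not
emulate, and the known limitations.

## The synthetic study

Every analysis is exercised on data from `trnareg.simulate`, which
plants a known regulatory structure and returns it as ground truth.
The default design mirrors a stem-cell differentiation study: one
pluripotent reference cell type plus three differentiated types, two
replicates each.

**Gene set.** Genes carry GtRNAdb-style names
(`tRNA-<Isotype>-<Anticodon>-<iso#>-<copy#>`); anticodon families are
drawn from the 61 sense codons. Classes are apportioned by the
largest-remainder method (ties by class order), so requested
proportions are hit exactly. Gene bodies (73 nt) contain A-box and
B-box promoter kernels (consensus `TGGCGCAGTGG` at body columns 8–18
and `GGTTCGAATCC` at 53–63) degraded by 0/1/3 point mutations for
housekeeping/repressed/inactive genes — promoter quality decays with
activity. 5′ flanks (200 bp, uniform background) receive class motifs
with probability `motif_effect`: housekeeping gets the GC-rich 10-mer
`GCGGCGGCGC` plus an `AAAAAA` run, inactive gets a `TTTTTTT` run (a Pol
III terminator-like signal), repressed gets a single motif from the
{GC, polyA} mixture at half rate. Motif positions are uniform-random
without overlap and are recorded in the ground truth for attribution
checks. A `duplicate_copy_rate` fraction of loci (default 10 %) are
exact extra copies of a same-class gene — identical body and flank —
to exercise multimapping logic; copy numbers increment within the
isodecoder, matching GtRNAdb naming.

**Counts.** Transcript counts are negative binomial with
Var = μ + φμ² (Poisson at φ = 0). Base abundances are lognormal
(median 50, σ = 0.8); each family designates one or two major
isodecoders at 20× the base scale, so majors dominate their family's
pool already in the reference type, as in real tRNA repertoires. In
differentiated types majors move by a uniform 1.2–4× factor and minors
are divided by a uniform 10–70× factor. Libraries are scaled to
`mean_depth` with lognormal(0, 0.1) per-sample jitter to exercise
normalisation; with fixed sequencing depth, count ratios are
compositional, which is precisely why the analyses normalise by RLE.
The distributional form is an assumption for testability, not a claim
about real tRNA-seq data.

**ChIP.** Input counts are Poisson(50 × jitter); IP counts multiply the
background by an 8× enrichment wherever the planted design says the
gene is bound (housekeeping: all types; repressed: reference only;
inactive: never). Duplicate-copy groups share a multimapped read pool
(odds 0.6 of a read being ambiguous) split equally across members;
singletons get a 2 % multimap rate. The multimap table covers the
reference cell type's IP libraries, the ones the exclusion filter is
defined on.

**Transcriptome.** Coding sequences start with ATG, end with a stop,
have length ≡ 0 mod 3 and no ambiguous bases; codons are drawn from a
Dirichlet-skewed global bias. TPM columns are Dirichlet draws scaled to
10⁶. No coupling between codon usage and tRNA abundance is planted, so
the supply–demand correlation on synthetic data is a null (~0); the
codon-usage machinery is verified by exact hand-computed oracles
instead.

What the generator does *not* emulate: read-level artefacts (no FASTQ,
alignment or fragment-size models), tRNA modification-induced
misincorporation, chromatin context, mappability structure beyond the
duplicate groups, and any real covariation between the transcriptome
and the tRNA pool. Passing tests therefore demonstrate that the
statistics recover a planted structure under their own model
assumptions — not performance on real libraries.

## Repertoire statistics

Proportions are per-sample count fractions; detection requires ≥ 0.005 %
of tRNA-mapped reads in at least one cell type, averaging replicates
per cell type first (a flag switches to per-replicate testing, since
either reading of "in all cell populations" is defensible). The
major-isodecoder count uses the greedy prefix over descending
proportions, which is provably optimal for a cumulative-mass criterion;
ties break by descending proportion then lexical id. RLE size factors
are the median over all-nonzero features of count/geometric-mean,
rescaled so the factors' product is 1. Buffering is summarised
descriptively — log2 fold changes of RLE-normalised per-cell-type
means with pseudocount 0.5, at the transcript and the anticodon level —
rather than by a count-model Wald test; the inferential machinery adds
nothing to the planted-truth comparison and would drag in a fitted
dispersion model.

## Codon usage and wobble mapping

Codon frequencies exclude the start AUG (counted separately, since
initiator Met uses a dedicated tRNA) and the stop codon; internal stops
are an error. Usage is TPM-weighted and column-normalised over the 61
sense codons, making it invariant to TPM rescaling. The wobble table
ships as an editable TSV (`trnareg/data/wobble_rules.tsv`): per codon,
the Watson–Crick cognate anticodon and fallback donors in priority
order (G34 reads codons ending U as well as C; U34 reads G as well as
A; A34, read as inosine after editing, covers U/C/A). Duplication
applies only when the cognate family is absent from the input —
whether abundance-based overrides were also intended is unknowable from
the description, and absence is the conservative reading. Stop-codon
recoding (selenocysteine UGA) is ignored. The coefficient of variation
per codon is computed on per-cell-type mean usage (replicates averaged
first), with sample standard deviation (ddof 1).

## Occupancy classification

The per-feature Poisson enrichment test is a deliberately simplified
stand-in for a genome-wide peak caller operating at tRNA features: the
decision rule (FDR-adjusted Poisson upper-tail p ≤ 0.05) is preserved
while the machinery is fully specified. Two numerical choices matter:

* **λ floor.** λ is the scaled input count floored at the scaled
  sample-mean input (and at `pseudo_lambda` = 1). Treating the raw,
  noisy per-feature input count as a known Poisson rate is
  anticonservative — a low input draw manufactures significance — and
  empirically inflated the null false-discovery proportion to ~0.8.
  The floor is the per-feature analogue of a peak caller's
  max-of-local-and-global background λ, restores calibration
  (P(any false discovery) ≈ 0 at α = 0.05 over 100 null tables) and
  costs no power at realistic enrichment.
* **Depth scaling.** The default scale is the IP/input ratio of total
  assigned reads. On a table containing *only* tRNA features, most of
  which are truly bound, that ratio absorbs the signal itself and
  deflates apparent enrichment (composition bias). The
  `scale_method="background"` option instead starts from a low
  quantile of per-gene IP/input ratios and iteratively re-estimates the
  scale as the median ratio over genes not currently called enriched;
  the analyses use it because at least a third of features is unbound
  in every cell type. On genome-wide data the default is appropriate.

Peak assignment uses the summit when present (narrowPeak field 10),
else the midpoint; distance to a gene interval is 0 inside and the
base gap outside, with hits within 125 bp and the nearest gene winning
ties (a flag allows multi-assignment, for the unstated case of two
genes within the window). Consensus is the strict intersection across
replicates, generalised to all replicates when more than two exist.
Classification is set algebra over consensus sets and is a partition by
construction. Normalised signal divides counts by a pure composition
factor (RLE factor / library size, geometric mean 1) times the
per-million library size; dividing by the raw RLE factor *times*
library size would correct depth twice.

## Motif analysis

PWMs use pseudocount 0.01 per cell; columns gapped in > 50 % of
sequences are dropped before building (flag to disable), and remaining
gapped sequences are excluded. Scanning scores are log2 odds against a
flat background, thresholded on the relative score
(score − min)/(max − min) ≥ 0.9, so the threshold is invariant to PWM
information content. The density map is an *unnormalised* separable
Gaussian kernel sum (σ = 1 grid unit in the position and
sequence-index directions) on a 1-bp grid; each hit's kernel is
renormalised within the grid so total mass equals the number of hits
despite boundary truncation. Per-sequence maxima, not integrals, are
compared across classes, which is why an unnormalised convention is
appropriate.

## tRNet

The full architecture: conv(128 × 20) → eight dilated convs
(128 × 10, dilations 2, 4, …, 256) → global max pool → dense(32) →
head; ReLU after every convolution; same padding (even widths pad one
extra on the right) so the convolutional stack preserves sequence
length — required for global max pooling to see all positions.
Trainable parameters: 1,326,339 (multiclass) / 1,326,273 (binary);
receptive field 20 + 9·(2+4+…+256) = 4,610 bp ≥ 200. The dilation
schedule starts at 2 and doubles ("doubled at each layer" does not fix
the start; the start is configurable).

Two implementation choices matter for trainability and are part of the
architecture here:

* **Residual skips.** Each dilated convolution sits inside a skip
  connection (y = x + ReLU(conv(x))), the standard wiring of the
  network family this architecture derives from. Without skips the
  stack memorises a few hundred training sequences through its random
  deep features before the first layer learns any motif, and held-out
  accuracy stays near chance.
* **Branch down-scaling.** Residual-branch weights are initialised at
  0.05× their He scale (`residual_init_scale`), so optimisation starts
  near the shallow single-convolution model and grows effective depth
  during training. This removed the remaining seed-to-seed
  generalisation variance on planted-motif data.

Training: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7), cross-entropy, batch
32, learning rate 0.00025 by default. The early-stopping contract —
stratified 80/20 split, patience 10 on validation loss, best-validation
weights restored — is implemented and is the default. The desk-scale
experiments instead use `early_stopping=False`: train on the full
training split for a fixed epoch budget and keep the final weights.
With only a few hundred sequences, a validation holdout both starves
training and stops it prematurely, because validation cross-entropy
rises from growing overconfidence while discrimination (accuracy,
AUROC) is still improving; the fixed schedule raised held-out macro
AUROC from ~0.85–0.90 to 0.92–0.98 across seeds. All randomness flows
through seeded generators; training is bit-reproducible on one
platform (float32 parameters, single-threaded determinism of the
underlying BLAS within one build).

Transfer learning follows the three-phase protocol: (1) binary
housekeeping-vs-inactive training on those two classes only — the most
sequence-distinct pair; (2) all layers frozen, head replaced by a 3-way
softmax, trained on all classes (99 trainable parameters); (3) last
convolution unfrozen, trained again. Every phase reuses the same
optimisation settings (the protocol description does not say
otherwise). Weight snapshots per phase make the freezing contract
checkable bit-for-bit. On clean planted-motif data at 600 genes, direct
training is near ceiling and transfer trails it by ~0.03–0.05 macro
AUROC: the binary task never needs to distinguish "one motif" from
"both motifs", so the frozen hidden layer lacks exactly the feature the
repressed class requires, and only the last convolution and head can
compensate. At the 360-gene comparison scale, where direct training is
itself harder, the two protocols are equivalent (mean macro-AUROC gap
< 0.01 over five seeds).

### Desk-scale configuration

Architecture checks use the full network (parameters are counted, not
trained). Training experiments use `trnareg.presets.desk_spec()` —
conv(64 × 20), one residual dilated conv (64 × 9, dilation 32,
receptive field 276 bp), dense(32) — trained with
`desk_train_config()`: Adam at 0.004, batch 16, fixed 50 epochs
(40 for the transfer comparison, 30 for binary pre-training used in
attribution). Problem sizes: 600 genes for class recovery, 360 for the
paired transfer/direct comparison and attribution studies. These sizes
and widths are the package's desk-scale study design; the layer
pattern, activations, pooling and heads are identical to the full
network.

## Attribution

Baselines are exact dinucleotide-preserving shuffles via the
Eulerian-path construction (random last-edge tree into the terminal
base, remaining edges permuted), so attributions cannot reflect
composition. Contribution scores are expected gradients: for each
baseline, midpoint-rule integrated gradients of the chosen task *logit*
(attributing the pre-softmax logit avoids the saturation of softmax
probabilities; a flag is not provided — compose with `predict_proba`
if probability attribution is wanted). The per-baseline mean path
gradient is projected difference-from-reference (subtract each
position's gradient at the baseline's base), giving hypothetical
scores whose one-hot masking yields final scores satisfying
completeness exactly in the integral limit. The default 512
interpolation steps keep the completeness gap below 1e-3 of |f(x)| for
float32 models — at 256 steps the ReLU-kink quadrature error can
marginally exceed that tolerance (verified to be quadrature, not
precision: unchanged under float64 weights).

Seqlet extraction is a simple high-contribution-window report, not a
clustering: 15-bp sliding-window sums of |final| scores receive
add-one empirical p-values against the same statistic computed on the
shuffled baselines (each attributed against the remaining ones), BH
correction at FDR 0.01, overlapping significant windows merged keeping
the maximum, ± 5 bp context added. A known limitation: for repeat-like
motifs (GC runs, polyT), dinucleotide shuffling reassembles similar
runs in the baselines, so the empirical null is conservative and
end-to-end seqlet power on the planted motifs is low; the extraction
logic is validated on controlled contribution matrices, and the
planted-motif signal is demonstrated on the contribution scores
directly (motif positions carry more |contribution| than background in
≥ 90 % of housekeeping flanks).

## Degenerate inputs and tie-breaks

Zero-total count columns, all-zero families, zero-depth libraries,
zero-variance correlation inputs, single-gene chromosomes and
missing-class training sets raise errors naming the offending item;
lone genes on a chromosome report missing distances rather than a
value. Equal-proportion ties in the major-isodecoder prefix break
lexically; equal-distance peak assignments break to the first gene in
coordinate order.
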