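# trnareg

Analyses of human tRNA gene regulation at desk scale: how RNA
polymerase III occupancy, intragenic promoter elements and 5′ flanking
sequence together determine which tRNA genes are active in which cell
type, and how unequal isodecoder usage buffers the anticodon pools that
translation actually sees.

The package is organised as an analysis project. All computation lives
in the library under `src/trnareg`; the numbered scripts under
`analysis/` drive the study end to end on seeded synthetic data and
write their tables under `results/`. It is aimed at computational
biologists working on tRNA biology or Pol III regulation who want the
statistical machinery of such a study as tested, reusable functions.

## What it computes

**Repertoire and buffering** (`trnareg.repertoire`). Transcript-level
tRNA counts become proportions of tRNA-mapped reads; features below
0.005 % in every cell type are undetected. For an anticodon family with
proportions $p_{(1)} \ge p_{(2)} \ge \dots$, the number of *major
isodecoders* is the smallest $k$ with $\sum_{i \le k} p_{(i)} \ge 0.9$.
Buffering is quantified by comparing $\log_2$ fold changes
(RLE-normalised, pseudocount 0.5, differentiated vs pluripotent
reference) at the transcript level against the anticodon level: because
minor isodecoders swing 10–70× while majors move only 1.2–4×, anticodon
pools change far less than individual transcripts.

**Codon supply vs demand** (`trnareg.codon_usage`). Proportional codon
usage per sample is $u_c = \sum_t f_{t,c}\,\mathrm{TPM}_{t}$ over the
61 sense codons, normalised to 1 (start AUG counted separately).
Anticodon-family read proportions are mapped onto codons through
Watson–Crick pairing, with wobble duplication (G34 → codons ending
C/U, U34 → A/G, A34-as-inosine → U/C/A) where the cognate family is
absent; supply–demand agreement is summarised by Pearson *r*.

**Occupancy classification** (`trnareg.occupancy`). Genes with ≥ 25 %
multimapped reads and ≥ 50 total reads in every reference IP library
are excluded. Per-feature enrichment is a Poisson upper-tail test of
the IP count against λ = scaled input (floored at the scaled mean
input), Benjamini–Hochberg corrected within each sample at FDR 0.05.
Replicate hit sets intersect into per-cell-type consensus sets, and
genes are classified: **housekeeping** = bound in every cell type,
**inactive** = bound in none, **repressed** = the union minus the
housekeeping set. Peak BED/narrowPeak files can be used instead, with
summits assigned to tRNA genes within 125 bp.

**Promoter motifs** (`trnareg.motifs`). A-box and B-box sequences
(alignment columns 9–21 and 75–85) become pseudocounted position weight
matrices; scanning reports windows whose relative log-odds score
reaches 90 % of the attainable range; motif density over a sequence set
is a 2D binned Gaussian kernel sum (bandwidth 1 bp) whose per-sequence
maximum separates activity classes.

**tRNet** (`trnareg.trnet`, on the numpy engine in `trnareg.nn`). A
BPNet-style dilated convolutional network maps a one-hot 200-bp 5′
flank to the three activity classes: a width-20 convolution with 128
filters, eight residual dilated convolutions (width 10, dilation
doubling, 128 filters), ReLU throughout, global max pooling, a 32-unit
hidden layer and a softmax head — 1,326,339 trainable parameters with a
4,610-bp receptive field. Training uses Adam, cross-entropy and
(optionally) early stopping; transfer learning pre-trains a binary
housekeeping-vs-inactive model, freezes it, swaps the head for a 3-way
softmax, then unfreezes the last convolution. Evaluation reports
stratified 5-fold accuracy and one-vs-rest AUROC per class with the
macro average.

**Attribution** (`trnareg.attribution`). Expected-gradients
contribution scores of a task logit against ten dinucleotide-preserving
(Eulerian-path) shuffles of each input, with the completeness identity
$\sum \text{final} \approx f(x) - \overline{f(b)}$; hypothetical scores
are the difference-from-reference projections, and final scores are
hypothetical × one-hot. Seqlets are 15-bp windows of summed |final|
scores significant at FDR 0.01 against an empirical null from the
shuffled baselines.

**Synthetic data** (`trnareg.simulate`) generates the whole study from
one seed: a multicopy gene set with GtRNAdb-style names and planted
A-/B-box kernels, class-specific flank motifs (GC-rich 10-mer + polyA
run for housekeeping, polyT run for inactive, a half-rate mixture for
repressed), negative-binomial transcript counts with major-isodecoder
buffering, Poisson ChIP counts following the planted activity design,
and a structurally valid coding transcriptome with TPMs.

## Worked example

```
python analysis/01_simulate.py
python analysis/02_repertoire.py
python analysis/04_occupancy.py
python analysis/06_trnet.py
```

prints, for the default 600-gene study (seed 0):

```
detected 538/540 transcripts (threshold 0.005% of tRNA-mapped reads); 2 undetected
median major isodecoders per family: {'CM': 1.0, 'NPC': 1.0, 'iPSC': 6.0, 'neuron': 1.5}
max |log2FC| transcript level: 7.50; anticodon level: 2.18 (buffered: True)
multimap filter: kept 480, excluded 120 genes
class sizes: {'housekeeping': 160, 'inactive': 160, 'repressed': 160}; ground-truth recovery 1.000
direct training: test accuracy 0.892, AUROC hk=0.975 rep=0.965 inact=1.000 macro=0.980
transfer learning: test accuracy 0.742, macro AUROC 0.964; trainable parameters per phase {'binary': 44225, 'frozen': 99, 'finetune': 37027}
```

Reading these: anticodon pools move ≤ 2.2 log2 units while individual
transcripts move 7.5 — the buffering signature; every
multimapping-clean gene is assigned its true activity class from the
ChIP counts; and the flank-sequence classifier separates all three
classes, with fewer major isodecoders needed outside the pluripotent
reference because minor isodecoders collapse there.

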