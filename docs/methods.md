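# Methods

## Target maps

DNA-DNA contacts arrive as 4DN `.pairs` text (1-based positions, converted
to 0-based half-open exactly once at parse time). Reads are binned at
2048 bp (a position equal to a bin edge belongs to the following bin), then:

1. **ICE balancing** — iterative correction until unmasked row sums agree
   within `tol` (default 1e-5, 200 iterations max). Bins are masked when
   their log marginal deviates from the median by > 5 MADs or they have
   < 2 nonzero entries. Weights are scaled so unmasked rows of the balanced
   matrix sum to 1; a doubly-stochastic input therefore has unit weights.
   Non-convergence returns a flag rather than raising.
2. **Adaptive coarse-graining** — entries whose raw support is below
   `min_count` (default 8) are replaced by the mean balanced value of the
   smallest aligned dyadic block (2×2, 4×4, …) whose summed raw support
   reaches `min_count`; entries with no coverage at any scale stay masked.
   This is a deliberate simplification of multi-scale smoothing: the
   contract downstream steps need is "fill low-coverage entries from
   coarser scales", which dyadic block averaging provides with an exactly
   testable definition.
3. **Observed/expected** — per window (not genome-wide, since targets are
   per-window): each entry is divided by the mean balanced value at its
   diagonal offset over unmasked entries. Offsets with zero or undefined
   expectation come back masked.
4. **Finalize** — natural log, clip to (−2, 2), linear interpolation of
   masked bins along rows and columns (averaged, then symmetrized),
   Gaussian smoothing (σ = 1 bin, truncated at 2σ; σ is configurable since
   no canonical value exists), and a final re-clip. The clip is applied
   both before interpolation and after smoothing: smoothing of clipped
   values can only move them inward, so the final clip is a guard that
   keeps the output invariant (symmetric, finite, within [−2, 2])
   unconditionally true. Whether clipping should precede or follow
   smoothing is genuinely open; this order is documented rather than
   guessed, and the alternative only differs in rare saturated windows.

Windows are 2²⁰ bp (512 bins) by default; any power-of-two multiple of the
bin size works, and the desk-scale experiments use 2¹⁵–2¹⁷ bp. Explicit
split files (chrom/start/end/split TSV) are accepted so a published
train/valid/test partition can be loaded verbatim.

## caRNA features

iMARGI-style `.pairs` records carry the RNA end as side 1 and the DNA end
as side 2. Records with MAPQ ≤ 30 on either end are dropped (a record with
MAPQ 31 is the first retained). Feature channels, all natural-log scaled:

* **nascent** — RNA-end read count per bin, log1p;
* **trans groups (8)** — DNA-end read counts of contacts that are
  inter-chromosomal or span > 2²⁰ bp, excluding self-interactions of genes
  longer than 2²⁰ bp, split by the RNA-end's gene group. When a position
  overlaps several genes the priority is snRNA > snoRNA > other small RNA >
  misc_RNA > lncRNA > protein-coding > other (small-RNA annotations beat
  their host genes, matching how nested small RNAs are annotated inside
  hosts); intergenic positions are `unannotated`. The priority table is
  configurable.
* **ATAC / RNA-seq** — bedGraph signal per bin scaled by
  `iMARGI library size / track total`, then log1p.

log1p rather than log is used everywhere because raw counts include zeros;
it is finite at 0 and asymptotically log(x).

Per-gene **trans-located proportions** attribute each RNA-end read to the
smallest (highest-priority) overlapping gene, which implements host-gene
subtraction for nested genes; the trans numerator applies the same filters
as the feature channels. Genes with zero nascent reads are flagged
undefined (None), never reported as 0 — and a proportion can in principle
exceed 1 only through host/nested bookkeeping asymmetries, which are
flagged rather than clipped.

## The predictor

Trunk: `log2(bin_bp)` = 11 convolution blocks (conv → batch norm → ReLU →
max-pool 2) take one-hot DNA (N → uniform 0.25) from 1-bp to 2048-bp
resolution. The first kernel is 15 bp (21 in the motif experiments, so a
19-bp motif fits inside one receptive field); later kernels are 3 bp;
trunk width defaults to 8 channels. Feature channels are concatenated to
the per-bin embedding, projected by a 1×1 conv (16 channels), passed
through residual dilated 1D convolutions (dilations 1, 2, 4), averaged to
2D (`P_ij = (u_i + u_j)/2`, exchange-symmetric by construction), refined by
residual dilated 2D convolutions (dilations 1, 2) and reduced to one value
per pair. The output is explicitly symmetrized, so exchange symmetry is
exact, not approximate.

Loss: `1 − Pearson r` over the upper triangle at diagonal offset 2,
averaged over the batch; a zero-variance target yields loss 1 with zero
gradient and a warning. Because the objective is scale-free, an affine
output calibration (gain/bias) is fitted on the training windows after
training, by least squares; it does not change Pearson but puts MSE and
map values on the target scale. Optimizer: Adam (lr 0.01, batch 4). Each
variant trains `n_replicates` = 5 times with distinct seeds; the selected
replicate has the best mean rank over (validation MSE ascending, validation
Pearson descending). Batch-norm statistics are frozen at inference and
there is no dropout, so inference is bit-deterministic. These training
hyperparameters are package defaults, config-exposed, not claims about any
published configuration.

The whole network and its backprop are numpy (im2col + GEMM convolutions,
channels-last layout); gradients are verified against finite differences in
float64 in the test suite.

## Attribution

Contribution scores use **expected gradients**: integrated gradients
(midpoint rule, 8 steps) averaged over a background set, which satisfies
the completeness property per background and reduces to
`w·(x − x̄_bg)` exactly for a linear model (asserted at 1e-4 relative).
The background scheme: validation/test examples use 20 randomly selected
training examples; the training set is halved and each half uses examples
from the other. The attributed scalar is the mean predicted contact value
of the window — the simplest linear summary consistent with its downstream
use; any other linear map summary can be supplied. Scores are normalized
per feature by the maximum absolute value over the evaluated split
(per-window mode available), preserving sign, so every feature attains ±1
somewhere.

Extreme regions take the top/bottom 1 % or 5 % of a feature's scores over
bins with positive input value only; ties break by genomic order.
Enrichment is log₂(observed/expected) overlap against annotation bins,
with the eligible-bin set as the universe. Differential caRNA-vs-ATAC bins
require fold change > 5 **and** |normalized score| > 0.25; an ATAC score of
exactly 0 gives infinite fold change (the magnitude gate still applies).
High-confidence RNA-DNA interactions use a hypergeometric upper tail
(`P[X ≥ k]`, margins = gene total and bin total, population = all
contacts) with Benjamini-Hochberg correction over all pairs with k ≥ 1
(zero-count pairs have p = 1 and would only dilute the correction);
q ≤ 0.05 is retained. Candidate RNAs are ranked by the count of retained
interactions landing in extreme regions, ratio as tiebreak (both are
reported; the composite ranking is a documented package choice).

## In-silico perturbations

* **CTCF insertion** — k ∈ 1..4 forward motifs upstream and k
  reverse-complement motifs downstream of a random locus (0.15–0.85 of the
  sequence), 500 bp apart, replacing bases in place (length preserved).
  The motif is the 19-bp CTCF consensus; PWM sampling is not implemented.
  Response = mean predicted contact and local diamond insulation at the
  locus, aggregated over sequences, with two-sided Mann-Whitney tests
  between consecutive k.
* **caRNA elevation** — one channel's raw-scale signal at selected
  boundary bins is multiplied by e^0.5, e^1, e^1.5, e^2
  (`log1p(fold·expm1(x))`), all else untouched; response = Δ insulation
  strength at those boundaries and Δ mean contact vs the unperturbed
  prediction. Fold 1 gives exactly zero delta.
* **R-loop scan** — best local alignment (match +2, mismatch −1, gap open
  −2, extend −0.5; scoring configurable and deliberately conservative since
  the decision thresholds are scoring-insensitive) of the RNA against both
  DNA strands; identity = matched bases / RNA length (the stricter of the
  two readings of "RNA sequence matching"; aligned-span identity is an
  option), max run = longest gap-free perfect match along the alignment
  path. Candidate ⇔ identity > 0.80 and run > 10 bp. The reported strand
  maximizes (candidacy, alignment score). Landmark fractions overlap
  candidate DNA intervals with boundaries/anchors at 5000-bp resolution.

## Synthetic data

The generator plants *recoverable* structure: expected contact maps follow
`(d+1)^-γ` distance decay (γ = 1) attenuated by `exp(−3·strength)` across
each planted boundary, with Gaussian loop bumps; DNA-DNA reads are sampled
from that law (log-uniform distances, rejection across boundaries).
RNA-DNA reads draw a gene by expression, then go cis (exponential
distances, ≤ 2²⁰ bp) with probability `cis_fraction` (default 0.6) or
trans to a genome-wide bin with open bins up-weighted ×4; 15 % of reads
get MAPQ ≤ 30 so the filter is exercised. Gene annotations cover all eight
RNA groups including a snoRNA nested in a protein-coding host. Planted
homologies copy a gene subsequence to a distant locus with mutations
spaced to realize a stated identity and longest perfect run.

For model experiments, `make_model_dataset` builds windows whose targets
are the *expected* (noise-free) maps of per-window planted boundaries and
writes `log1p(strength × 300)` into one caRNA channel at boundary bins
(other channels are |N(0, 0.05)| noise); with `motif_boundaries=True`
strengths are quantized to k/4 and marked by k convergent CTCF motif pairs
in the sequence. What passing these tests shows: the architecture can
extract boundary structure from features or motifs and responds causally
to perturbations of either. What they do not show: performance on real
Micro-C/iMARGI data, where noise, mapping artifacts, distal regulation and
feature collinearity (e.g. caRNA ∼ accessibility) are all harder; the
published full-genome correlations are not reproducible at desk scale and
are not claimed.

Desk-scale problem sizes (chosen once, as package defaults): overfit run —
20 windows of 2¹⁷ bp; feature-vs-sequence contrast — 20 train + 8
validation windows of 2¹⁶ bp, 5 replicates, 20 epochs; CTCF experiment —
100 train + 10 validation windows of 2¹⁵ bp, 25 epochs, 30 probe
sequences; trans-recovery — 10⁵ reads on a 2×2¹⁷-bp genome.

## Known limitations

* ICE and coarse-graining are re-implementations with simplified masking;
  they satisfy the documented contracts but do not bit-match any external
  tool.
* SCC stratum weights follow the variance-stabilized rank-variance
  weighting in spirit; an equal-weight mode exists and the two agree
  closely on distance-normalized maps.
* The aligner-based R-loop scan reports the single best local alignment
  per strand; a pair whose candidacy hinges on a suboptimal alignment
  would be missed (not observed on constructed fixtures).
* Sequence-level (nucleotide) attribution and in-silico DNA mutagenesis
  beyond motif insertion are out of scope.
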