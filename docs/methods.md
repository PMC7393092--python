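# Methods

## Problem setting

Genome-wide association studies report loci, not causal variants: linkage
disequilibrium spreads an association signal over many neutral SNPs, and in
noncoding regions there is no reading frame to point at the functional base.
`epifine` implements a functional fine-mapping strategy that treats each
associated locus as a *bag* of candidate SNPs and asks which members carry a
regulatory-annotation signature that recurs across independently associated
loci. The pipeline has five stages: association-block construction from
summary statistics, binary feature-map annotation, a weakly supervised
two-layer network scored per SNP, a random-forest importance read-out, and
promoter/enhancer gene mapping of the candidate calls.

## Association blocks

SNPs with association p > 5e-4 are discarded. Lead SNPs are chosen greedily:
the smallest-p remaining SNP becomes a lead and all SNPs on the same
chromosome within 1 Mb of it are removed, so selected leads are always more
than 1 Mb apart. Each block then collects the most significant remaining
SNPs within ±1 Mb of its lead, capped at 30 members including the lead. The
flanking radius is not dictated by the construction itself; we reuse the
1 Mb clumping radius and expose it as a parameter. A SNP eligible for two
blocks is assigned to the lead with the smaller p-value (ties: nearer lead,
then lower position), which makes block membership deterministic and
independent of input order. All p-value ties are broken by (chromosome,
position) ascending for reproducibility.

Each true-case block carries an uncertainty weight reflecting confidence in
its positive label, a step function of the block's minimum p-value:
10 below 5e-8, then 8 / 6 / 4 / 2 on successive decades up to 5e-4.
Boundaries use strict `<` on the stronger side, so a minimum of exactly
5e-8 receives weight 8. Control blocks always receive weight 2.

Blocks are partitioned by chromosome: 1–10 train, 11–14 test, 15–22
validation. Blocks on unlisted chromosomes (e.g. X) are dropped with a
warning by default.

## Feature maps

Annotation arrives as positional BED tracks (DHS, histone marks, TFBS;
0-based half-open) or gene-set tracks matched through SNP-to-gene mapping.
A SNP is a 1-bp point: its 1-based position is converted to the 0-based
coordinate pos−1 before interval overlap. The block tensor is
blocks × 30 SNP slots × features, binary, with an explicit presence mask;
members are ordered by position and unused slots are masked and
zero-filled. Features absent (no carrying SNP) in strictly more than 95%
of true-case blocks are removed before training; the filter is computed on
true cases only and controls inherit the surviving feature axis.

Control (false-case) blocks are built by shuffling annotations inside true
blocks, ten controls per true block, sources sampled uniformly with
replacement. The default mode permutes each feature column independently
across the block's unmasked slots: per-feature within-block counts are
conserved exactly while SNP-level feature co-occurrence — the signal the
classifier is meant to detect — is destroyed. Whole-row permutation is
available as an alternative mode; it preserves SNP vectors and is a much
weaker null, useful only for diagnostics.

## Network and loss

Layer 1 applies K = 50 filters of length M (the surviving feature count) to
each SNP vector with a bias and ReLU — a 1-D convolution with stride 1 over
the SNP axis, so each SNP is scored without regard to its neighbors. Layer
2 combines the K activations with a single weight vector, a bias, and a
sigmoid, giving a per-SNP score in (0, 1). Max-pooling over the block's
unmasked slots yields the block score: the multiple-instance assumption
that one functional SNP makes the block positive. Masked padding slots are
excluded from the pool and from autoencoder pretraining.

The loss is an uncertainty-weighted cross-entropy plus an elastic net:

    LOSS = NLL + λ₁‖w‖₁ + λ₂‖w‖₂²
    NLL  = −(1/B) Σₘ Wₘ [Yₘ log fₘ + (1−Yₘ) log(1−fₘ)]

with natural logarithms, B the mini-batch size (default 100), Wₘ the block
weight and fₘ the max-pooled block score, clamped to [1e-7, 1−1e-7] inside
the logs. Penalties cover both layers' weight vectors, never biases.
Gradients are computed analytically (backpropagation routes each block's
gradient through its max slot only; the L1 term contributes sign(w)) and
are verified against central finite differences in the test suite.

First-layer filters are initialized by a tied-weight denoising autoencoder
on all unmasked SNP vectors of the training split: inputs are corrupted by
independent zeroing at rate 0.2, hidden and reconstruction activations are
sigmoids, and the objective is elementwise cross-entropy against the clean
vector — the standard choice for binary data. Fifty pretraining epochs are
used; on the bundled benchmark both omitting pretraining and pretraining
four times longer give uniformly worse optima, so the short-pretraining
default is load-bearing, not cosmetic.

## Optimization and model selection

Training is mini-batch gradient descent with momentum 0.9 and learning
rate 0.01; true and control blocks are mixed uniformly at random each epoch
(seeded). Validation loss (chromosomes 15–22) is monitored every epoch;
a run stops after 50 epochs without improvement (cap 1000) and rewinds to
its best epoch. Because the weighted MIL objective has a strong memorization
basin — the network can fit the few positive training bags by keying on
idiosyncratic background features — three design choices matter:

* **Elastic net**: λ₁ = 0.02, λ₂ = 1e-3. Sparsity makes one shared causal
  pattern cheaper than many memorized ones. With λ's near zero the model
  reaches training AUC 1.0 but chance-level validation AUC.
* **Nonnegative combiner initialization**: combiner weights start
  half-normal, so with ReLU activations the initial per-SNP score increases
  with filter-match strength and max-pooling selects pattern-rich SNPs from
  the first epoch. This raised the fraction of successful optimization runs
  from ~15% to ~67% on the benchmark.
* **Restarts**: `train` launches 5 runs from seeds derived from the config
  seed and keeps the one with the lowest validation loss. Successful and
  memorized runs are cleanly separated by validation loss (≈0.7 vs ≈1.2+),
  so the selection is unambiguous. Mini-batches themselves are also
  necessary: full-batch gradients stall on a plateau in every trial.

A `random_search` helper draws hyperparameter combinations from a
user-supplied grid and scores them the same way, on the validation
chromosomes only; the test chromosomes are touched exactly once, for the
final report.

Evaluation reports block-level AUC (rank probability that a true block
outscores a control; ties count ½) and F1 at the fixed 0.5 threshold with
true cases positive.

## Importance and enrichment

SNPs are labeled positive when their prediction score exceeds 0.5, and a
random forest (100 trees, 10 features per split) is trained to reproduce
those labels from the binary vectors; Gini importance (mean impurity
decrease) ranks features. Repressive marks H3K9me3/H3K27me3 are excluded
before fitting — open-chromatin logic does not apply to them. Per-feature
permutation p-values refit the forest on label-permuted data (default
1,000 permutations); p = (#permuted importances ≥ observed)/n, with ties
counted against significance. Category over-representation among
significant features uses the hypergeometric upper tail
P(X ≥ k) with pmf P(X = k) = C(K,k)·C(N−K,n−k)/C(N,n), and a binomial
upper tail at background rate K/N is reported alongside; the output names
both columns so the reader knows which was used. A per-SNP binomial
annotation test is provided for feature-map displays; its background
fraction defaults to the category's share of surviving features.

## Candidate prioritization

SNPs with score strictly greater than 0.5 become candidates. Gene mapping
uses the 3 kb window strictly upstream of the TSS as the promoter — on the
+ strand positions [tss−3000, tss), mirrored on the − strand — plus
enhancer intervals linked to genes in an input BED; there is deliberately
no nearest-gene fallback, and a SNP keeps all its gene mappings. Blocks
containing a genome-wide-significant tag-SNP (p < 5e-8) are flagged, and
the package reports the comparison between genes reached from candidate
SNPs in flagged blocks and genes reached from the tag-SNPs themselves.

## Synthetic benchmark

The generator emulates the statistical structure the classifier assumes
and nothing more. Blocks of 30 SNPs spaced 1 kb apart are laid out on
chromosomes 1–22 round-robin, ≥ 2 Mb apart within a chromosome so clumping
recovers them exactly. Each block's minimum p-value is drawn log-uniformly
inside a weight tier sampled from a configurable mixture (default uniform
over the five tiers) and assigned to the lead; other members draw
log-uniformly between that minimum and the 5e-4 retention bound. Every
feature vector is Bernoulli(0.05) background except one causal SNP per
causal block, whose 20 designated causal features are Bernoulli(0.7).
Tracks are rendered as 1-bp BED intervals that realize the vectors
exactly — simpler than simulating peak geometry and sufficient for
contract testing. One gene per block (TSS 1.5 kb downstream of the lead)
and an enhancer interval over each causal SNP let the gene-mapping stage
run end to end.

The default benchmark is 25 blocks, 200 features, 20 causal features, 20
causal blocks, seed 17; with 10× controls this gives 275 bags. The five
non-causal blocks are interleaved deterministically (the last block of
every five) so each chromosome split contains causal signal; a random
placement can leave the 4-block test split dominated by non-causal blocks,
which measures split luck rather than recovery. On this benchmark the
trained model reaches held-out block AUC 1.0, causal-SNP recall ≥ 0.95 at
score > 0.5, a non-causal positive rate ≤ 0.01 inside true blocks, and all
20 causal features inside the top-20 Gini ranks, stable across config
seeds.

What the generator does **not** emulate: linkage disequilibrium (feature
vectors are independent across SNPs), realistic peak widths and track
correlations, allele frequencies, overlapping loci, or pathway-track
structure. Passing the benchmark therefore demonstrates that the
implementation recovers a planted co-occurrence signal under the model's
own assumptions — not that the method succeeds on real GWAS data.

## Numerical and degenerate-input choices

Scores are clamped to [1e-7, 1−1e-7] inside logarithms only; emitted
scores are raw sigmoids. Blocks with zero unmasked slots are rejected.
Evaluation requires both classes. The feature filter rejects thresholds
outside (0, 1]. Summary-statistics parsing is strict: non-numeric or
out-of-range p-values and duplicated (chromosome, position) pairs raise
errors naming the file line rather than being silently dropped. Problem
sizes in the shipped tests (25-block benchmark, 100-permutation importance,
100 random clumping instances) were chosen so the full suite exercises
every stage end to end in about a minute on one CPU core.

## Known limitations

The optimizer is plain momentum SGD; adaptive methods were not explored.
Restart selection multiplies training cost by the restart count. The
hypergeometric and binomial tails delegate to scipy; only the surrounding
logic is original. Score calibration is out of scope: 0.5 is a ranking
threshold, not a probability statement. LD-aware credible sets, eQTL
integration, and tissue-expression enrichment are downstream analyses the
package intentionally does not perform.
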