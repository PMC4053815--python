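# Methods

## Observation model

The observation unit is the per-library CAGE tag cluster: tags from one
library whose mapped coordinates overlap by at least 1 bp (strictly, under
0-based half-open coordinates; abutting tags stay separate), with the
quantile-normalized counts summed into x > 0. Working per library rather
than on pooled tags preserves promoters active in a single tissue, at the
cost of duplicate calls for broadly active promoters; duplicates are merged
at the catalogue stage, where a promoter's libraries of expression are
accumulated before the tissue-specificity test.

Quantile normalization maps each library's counts rank-wise onto the
reference library's empirical quantile function (linear interpolation
between the knots p = (k − 1/2)/m; ties receive the mean of the tied
reference quantiles). The reference defaults to the library of median
total tag count — a deterministic stand-in for picking one library at
random — and can be set explicitly or drawn with a seeded generator.

x is modeled with inverse-Gaussian components rather than Poisson or
negative binomial: after quantile normalization the observations are
continuous, and the IG right tail accommodates the orders-of-magnitude
spread of highly expressed promoters. The density, weighted MLE
(μ = Σwx/Σw, 1/λ = Σw(1/x − 1/μ)/Σw) and all mixture arithmetic are
computed in log space; posteriors are never NaN even when both densities
underflow.

## Semi-supervised EM

Each candidate carries a fixed per-example prior (belief) π_i1 from its
sequence features; sampled background regions are exact negatives whose
responsibility is pinned to the background component. EM alternates
responsibilities γ_i1 = π_i1 f1 / (π_i1 f1 + π_i2 f0) with weighted IG
MLEs per component, stopping at a relative log-likelihood change below
1e-6 or 500 iterations; the log-likelihood is monotone by construction and
asserted in tests. Component collapse (responsibility mass < 1e-8) raises;
a non-positive λ MLE is floored at 1e-6 with a warning. Ties at the
classification cutoff resolve to background (fewer false promoters).

Initialization splits the unlabeled observations at the threshold that
maximizes the between-class variance of log counts (Otsu's criterion) and
seeds each component with its side's closed-form MLE. A median split was
tried first and discarded: background-like observations outnumber
promoter-like ones roughly five to one, so the median falls inside the
background mode, both components initialize on noise, and EM then settles
in a degenerate optimum in which the "promoter" component absorbs the
noise bulk. The variance-maximizing split is equally deterministic and
scale-free but lands in the gap between the two modes.

Background regions with no overlapping tags are floored at x = 0.5 — half
the smallest possible normalized single-tag count — rather than a value
far below the count scale. A detached floor spike inflates Σ(1/x) for the
background component, collapses its λ, and leaves the noise mode to be
claimed by the promoter component; a floor adjacent to the noise mode
keeps the background component on the data it is meant to absorb.

### Counts-only baseline

`prior_mode="flat"` runs the comparison model that uses tag counts alone.
It is implemented as the standard mixture with a single global mixing
proportion re-estimated in each M-step (fixed negatives contributing zero
promoter responsibility), not as fixed 0.5 beliefs: with fixed per-example
0.5 priors the promoter component pays no mixing-proportion penalty for
claiming arbitrarily many low-count observations, and the fit is
structurally degenerate. With a global proportion (π1 ≈ 0.1–0.2 on
realistic data) low-count observations face π1 f1 vs (1 − π1) f0 and stay
in the background component, which is the behavior a counts-only
classifier should have.

## The belief (prior) model

Features of the 1 kb window centered on the representative TSS (the
highest-count member tag's 5' end):

- **CpG** = (CG/L) / ((C+G)/2L)², observed/expected CG dinucleotides; ≈ 1
  for random sequence, ≈ 2 for a pure CpG island; 0 when the window has no
  C or G.
- **cons** = mean per-base conservation probability, missing bases
  counting 0 (unaligned), clipped to [0, 1].
- **TATA** = TRAP expected occupancy of a TATA-box position frequency
  matrix, summed over both strands and all offsets: per offset,
  p = R0 e^(−E) / (1 + R0 e^(−E)) with mismatch energy
  E = (1/λ_TRAP) Σ_j ln(c_max,j / c_j), pseudocount 1 per matrix cell,
  λ_TRAP = 0.7 and ln R0 = 0.584 w − 5.66 (the published defaults of the
  TRAP method). Ambiguous bases contribute the column-average penalty. Any
  JASPAR-format matrix can be supplied; the synthetic fixture ships a
  synthetic TATAAA-consensus matrix (it is not a JASPAR export).
- **proximity** = (W − d)/W with W = 50 kb and d the strand-aware distance
  from the TSS to the precursor 5' end, clipped to [0, 1]. The functional
  form is a package choice (bounded, monotone, dimensionless) and is
  pluggable; d < 0 warns and returns 1.

β is fit by IRLS with an L2 penalty on the (internally standardized)
non-intercept coefficients; coefficients and standard errors are reported
on the original scale. `fit_beta`'s default penalty is 1e-4, appropriate
for hundreds-to-thousands of examples. The pipeline's default is 0.5: its
positive set is typically ~10 literature-known promoters against ~100
sampled background regions, which is linearly separable, and a near-zero
penalty then drives |β| into the hundreds and saturates beliefs at exactly
0 or 1, letting the prior override the tag evidence entirely. The pipeline
additionally clips beliefs to [0.02, 0.98]: a belief about an unlabeled
region is never a hard label, so the count likelihood can always override
it. No β values are hard-coded; they are fit from user-supplied labelled
examples or given in the config.

## Candidate construction and catalogue rules

Clusters are assigned to every precursor within 50 kb downstream
(strand-aware) of the representative TSS. Clusters overlapping the TSS of
a transcript that is not a host-gene transcript of an assigned miRNA are
discarded; clusters containing tags that overlap host-gene exons are
discarded unless the cluster lies in the host-TSS ± 100 bp window (the
first exon necessarily begins at the TSS, so host promoters would
otherwise be unreachable). Categories, in precedence order: host_gene
(overlaps host TSS ± 100 bp), intronic (contained in any intron of the
host gene — the same or a different intron as the miRNA), intergenic
(serves an intergenic miRNA), hybrid (intergenic space upstream of an
intragenic miRNA only).

Redundancy removal is cd-hit-like without the external binary: same-locus
calls are merged first (libraries accumulated, tag counts summed), then
sequences are clustered greedily longest-first, joining a cluster when
ungapped sliding identity to the representative is ≥ 0.8 (an 8-mer word
filter skips hopeless pairs); the highest-count member is the
representative. Tissue specificity: expressed in fewer than
ceil(4L/33) libraries of L total, the 33-library rule scaled.

## Validation procedures

PolII: each candidate's 1 kb window is intersected with peak intervals;
promoter calls (p > c) with/without overlap are TP/FP, non-calls
without/with overlap are TN/FN; ROC and precision-recall rows are emitted
across a cutoff grid. RNA-seq: the putative primary transcript runs from
the called TSS to 70 bp past the mature miRNA; per library, its
"continuous coverage" is the longest gap-free covered run divided by the
region length (a transcript needs contiguous support; a flag switches to
the plain covered fraction, coverageBed's semantics, since either reading
is defensible). Each transcript's per-library coverage vector is compared
to the coverage of random background regions — intergenic background for
intergenic pri-miRNAs, intronic for intragenic ones — by a two-sample
Kolmogorov–Smirnov test; p-values are Benjamini–Hochberg adjusted, and a
transcript is present iff fold enrichment ≥ 2 over the background mean and
adjusted P < 0.1. Precision is the fraction present; false negatives are
not estimated (that would require full transcriptome assembly).

## Synthetic study conditions

The default fixture plants a known truth at desk scale: 2 chromosomes ×
1 Mb (chromosome 2 entirely minus-strand), 10 four-exon genes, 20 miRNAs
(10 intergenic, 10 in second introns), 4 CAGE libraries, 30 promoters.
Twenty-four promoters are broadly expressed with per-library cluster
totals ~ IG(μ, 30), μ cycling over 20/40/80/160 — promoter expression
spans orders of magnitude, and a single shared intensity would make the
fitted promoter component unrealistically tight. Six intronic promoters
are weak and library-specific, ~ IG(3.5, 150) in one library: a handful of
tags, above single-tag noise but below any counts-only decision boundary —
exactly the regime the belief prior exists to rescue, and therefore the
regime the benchmark must probe. Background noise tags are scattered
uniformly with counts ~ IG(1.2, 4) rounded to integers (mostly singletons,
light tail). CpG-island sequence (GC 0.7 with injected CG dinucleotides)
marks intergenic and host promoters, a TATAAA box 30 bp upstream marks
intronic ones, and all planted TSSs get an elevated conservation plateau
(0.75–0.95 vs 0–0.15 baseline). Ten promoters are exported as
"literature-known" positives for fitting β. PolII peaks are planted at
± 400 bp of every true TSS and RNA-seq reads tile every true primary
transcript, so the validation procedures have a known answer.

What the fixture does not emulate: multi-mapping and re-capping artifacts,
realistic chromatin-driven tag-position dispersion, 33 distinct tissues,
overlapping gene architectures, and genome-scale background diversity.
Passing the planted-truth benchmark therefore demonstrates the machinery —
normalization, clustering, filtering, the belief-prior mixture and the
validations — under controlled conditions; it does not measure performance
on real FANTOM-scale data.

## Numerical choices and limitations

EM tolerance 1e-6 (relative), max 500 iterations; IRLS tolerance 1e-10,
max 100; all densities in log space; the classification tie at p = c goes
to background; model state (components, mixing, trajectory, β) serializes
to JSON and can be reused via `--model`, skipping EM. Known limitations:
the two-component likelihood surface is multimodal and the deterministic
initialization, while robust in testing, is not a global-optimum
guarantee; the dedup identity is ungapped and approximates cd-hit rather
than reproducing it; coordinates are assumed to be on one assembly
(remapping happens upstream).
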