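# Methods

`perturbome` reimplements, as a tested pipeline, the statistical analyses
used to study how a bacterial transcriptome reorganizes under three kinds
of perturbation — genome reduction (a wild-type versus a reduced genome),
environmental stress (threonine or chloramphenicol at growth-reducing
concentrations), and experimental evolution — together with the extraction
of growth fitness from microplate OD600 curves. Raw sequencing data are
out of scope; a synthetic generator with explicit ground truth stands in
for them, so every stage is validated by parameter recovery rather than by
re-deriving published tables.

## Growth fitness

Pointwise rates between consecutive OD600 readings are
μ_i = ln(C_{i+1}/C_i)/(t_{i+1}−t_i) (natural log, h⁻¹). The growth rate of
a well is the mean of three consecutive μ_i chosen by the
largest-mean/smallest-variance rule; the growth fitness of a condition is
the mean over biological replicates.

The two criteria of the window rule can disagree, so the implementation is
lexicographic with a noise-aware tie band: the primary criterion is the
largest window mean; all windows whose mean lies within
max(1% of the maximum, the median within-window rate SD) of the maximum
compete on smallest variance; remaining ties go to the earliest window.
The noise-scaled band matters: with a long exponential phase the maximum
of many noisy window means overshoots the true rate by roughly two
standard errors (about +10% at μ = 0.2 h⁻¹ with 1% OD noise and 30-min
sampling), while the variance criterion inside the band is unbiased. With
this rule, logistic curves with 1% multiplicative noise give rates within
5% of the generating μ over 0.2–1.0 h⁻¹.

Non-positive OD readings are rejected (instrument artifacts), not floored.
Wells that never grow are reported as "no growth" rather than μ = 0.
The stressor-concentration pick returns the smallest tested concentration
whose relative rate decrease reaches the target (default 30%), plus a
linear interpolation of the rate–concentration segment crossing the
threshold as a refined estimate.

## Expression matrices

FPKM = count · 10⁹ / (gene length in bp · sample total counts). Expression
is log10(FPKM + pseudocount); the pseudocount defaults to the smallest
nonzero FPKM of the dataset (configurable) because zero counts are
otherwise undefined on the log scale. Global normalization adds a
per-sample constant on the log scale so all sample means equal the grand
mean; it is idempotent and equivalent to a multiplicative rescaling of
linear FPKM. Cross-genome analyses are restricted to the genes common to
all genomes, preserving reference-genome order. Sample ordination uses
1 − Spearman correlation with Ward (ward.D2) agglomeration — scipy's
`linkage(..., "ward")` on the precomputed condensed matrix applies exactly
the ward.D2 update — and centered, unscaled PCA.

## Chromosomal periodicity

Per-gene expression (replicate means) is placed at the gene midpoint on
the circular chromosome, and the spatial profile is the mean expression in
a 100-kb span centered on every 1-kb position, with circular wrap-around
(the chromosome has no ends; a linear smoother would create artifacts at
the arbitrary origin). Spans containing no gene are filled by linear
interpolation on the circle. The smoothing is a moving average; note that
it attenuates a cosine of frequency f by sinc(f·w/L) (w = 100 kb), about
3% for six cycles on a 4.6-Mb genome.

The periodogram of the mean-removed profile is taken at integer
frequencies j = 1..⌈n/2⌉−1 cycles per chromosome, normalized so the total
power equals n times the profile variance (Parseval; exact for odd n).
The zero frequency is excluded because the mean is removed; the Nyquist
ordinate of even-length profiles is excluded because its null distribution
differs from the other ordinates' and would bias the g-test.

Fisher's g = max(power)/sum(power) over n ordinates, with the exact null
p-value Σ_{k=1..⌊1/g⌋} (−1)^{k−1} C(n,k)(1−kg)^{n−1}. Terms are evaluated
in log space; because the series alternates, partial terms can dwarf the
result for large n with weak peaks, in which case the sum is recomputed in
exact rational arithmetic (`fractions.Fraction`), which is slower but
immune to cancellation. The dominant period is summarized by least squares
of A·cos(2πx/λ + φ) + c at the max-peak wavelength, solved in the
linearized cos/sin basis (a global optimum, no iteration).

## Transcriptome epistasis

Per-gene changes Δ are differences of replicate-mean log10 expression
between a perturbed condition and the shared reference. The simultaneous
change under two perturbations is regressed through the origin on the sum
of the single changes; α = Σxy/Σx². The model has no intercept term, so
through-origin is the default; an intercept mode exists for sensitivity
analysis. α is invariant to the log base and to swapping the two single
profiles. Classification uses a band of ±0.05 around 1 (the additivity
reference): below, negative epistasis (the perturbations cancel); above,
positive.

Because the regressor x carries measurement noise, α̂ is attenuated by
S²ₓ/(S²ₓ+σ²ₓ) — an errors-in-variables effect that does not vanish with
more genes. At the generator's default signal scale (effect SD 1.0 log10
unit, 40% of genes affected, 3 replicates) the attenuation is below 3% and
recovery is within ±0.05 of the generating coefficient over α ∈ 0.4–1.3.

## Rank Product differential expression

For an nA-vs-nB contrast, each of the K = nA·nB one-vs-one cross-replicate
comparisons ranks genes by log fold change (rank 1 = most extreme; average
ranks on ties), separately for up- and down-regulation. RP is the
geometric mean of the K ranks, accumulated in log space. Significance uses
the rank-permutation null: random within-comparison rank assignments, with
p = (#null ≤ observed + 1)/(N+1) over the pooled null (never exactly
zero), or exhaustive enumeration of the per-gene null (the product of K
independent uniform ranks, n^K states) for small problems. The proportion
of false predictions is pfp = p·n/rank, made monotone by a step-up pass.
DEGs are genes whose direction (the smaller RP side) has pfp at or below
the threshold (default 0.05).

Known limitation: replicate values recur across the K comparisons, so
observed null RPs are overdispersed relative to the independent-rank null
and the test is mildly anticonservative — planted-signal recovery is
excellent in the called direction, but a small excess of opposite-direction
calls can appear when the true signal is strongly one-sided (the signal
genes squeeze the null genes' rank range). A per-gene Welch t-test with
Benjamini–Hochberg adjustment is included as a labeled substitute route;
it is not a count-model method and the Rank Product branch is primary.

## Functional enrichment

One-sided binomial over-representation: for a gene set of size n and a
category of size m in a universe of M genes, p = P[X ≥ x], X ~ Bin(n, m/M),
Bonferroni-corrected over the categories tested together (for module ×
contrast tables, over modules × contrasts). Categories are intersected
with the analysis universe first, then size-filtered — regulons need at
least 11 members and gene categories at least 31, reading "more than
10/30" strictly; both floors are configurable since the source counts are
ambiguous. Under-representation is out of scope.

## Co-expression modules

Unsigned weighted network: adjacency a_ij = |cor(i,j)|^β (Pearson across
samples; β = 12 by default, selectable by the scale-free topology fit —
smallest power whose signed R² of log10 density p(k) on log10 k over
equal-occupancy connectivity bins reaches 0.9). Topological overlap
TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), l_ij = Σ_{u≠i,j} a_iu a_uj.

Modules are branches of the average-linkage tree on 1 − TOM. The published
hybrid dynamic tree cut is replaced by a documented simplified adaptive
cut: over the grid of merge heights (capped at 99% of the tree height so a
structureless network collapsing only at the top yields no module), the
static cut maximizing the number of clusters of at least
`min_module_size` (default 50) wins, ties going to the largest such
height; undersized clusters become module 0. Behavior is validated by
block-recovery ARI against planted truth, not by label identity with any
particular tool.

A module eigengene is the first principal component of the module's
per-gene z-scored expression, scaled to unit variance and sign-aligned to
the module mean profile. Modules whose eigengene dissimilarity
(1 − Pearson r) is below 0.25 are merged iteratively, closest pair first,
recomputing eigengenes after each merge (idempotent once converged).
Module–trait association is the Pearson correlation of each eigengene with
the per-sample growth rate (condition-level means), flagged at p < 0.01.
Modules are then classified from the module × contrast DEG-enrichment
table: *conserved* (no contrast enriched), *epistatic* (enriched in the
single stress contrast but in neither stress-containing dual contrast —
the signature of the enrichment vanishing under dual perturbation), and
*responsive* (any other enrichment pattern).

## Synthetic data

Log10 expression = baseline (2.0, i.e. FPKM 100)
+ amp·cos(2π·n_periods·x/L + φ) at the gene midpoint x
+ condition effects + module contributions + N(0, noise_sd).

* Conditions cross genome (N0/N28) × stress (none/Thr/Cm) × evolution
  (anc/evo) with a configurable replicate count (default 3).
* Single-perturbation effects are sparse Gaussians (default: 40% of genes
  affected, SD 1.0 log10 units — strong perturbations on the scale of the
  study's log-unit expression changes); a condition combining two or more
  perturbations gets alpha_true · (sum of its single effects), the
  generative reading of the epistasis model.
* Modules: each module's genes add loading · factor(sample), loadings
  uniform on [0.5, 1]·strength. The growth-linked module's factor is the
  standardized condition growth rate (monotone by construction); all other
  factors are residualized against the growth-rate trait so that "not
  growth-linked" is exact ground truth at the sample level, not merely an
  expectation — otherwise a planted-truth test of exclusive trait
  association would be corrupted by sampling correlation.
* Deterministic condition growth rates: 0.7 h⁻¹ baseline, ×0.75 for
  genome reduction, ×0.70 per stressor (echoing the ~30% target decrease),
  ×1.15 for evolved strains.
* Counts are one multinomial draw per sample with expectation
  ∝ gene length × linear expression; growth curves are lag/logistic with
  multiplicative log-normal noise, OD 0.01 inoculum, 30-min sampling over
  48 h.

What the generator does **not** emulate: operon structure and the actual
deleted regions of the reduced genome, count overdispersion beyond
multinomial sampling, strand effects, and batch structure. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated statistical model, not robustness to every property of real
RNA-seq data.

## Problem sizes and numerical choices

Recovery tests run at the study's scale where the claim depends on it
(4,000 genes on 4.6 Mb for periodicity; 3,000 genes for slope recovery;
11 modules over 3,399 genes for network recovery; 10,000 null draws for
g-test calibration) and at reduced scale for unit oracles (5–10 genes,
where exhaustive enumeration is feasible). Degenerate inputs raise
explicit errors rather than propagating NaN: non-positive OD, constant
profiles, constant genes/samples, empty intersections, all-zero samples.
Eigengene sign, PCA component sign, leaf order, and window ties all have
deterministic documented conventions; every stochastic routine takes a
seed and equal seeds give byte-identical outputs.
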