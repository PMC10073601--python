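# perturbome

Analysis pipeline for bacterial growth fitness and transcriptome
reorganization under three kinds of perturbation: genomic (a reduced
genome versus the wild type), environmental (a stressor at a
growth-reducing concentration), and evolutionary (experimental evolution).
It is written for microbial systems-biology work of the kind where a
wild-type *E. coli* strain and a genome-reduced derivative are profiled by
RNA-seq across stress and evolution conditions, and the question is how
much of the combined response is explained by the single responses.

The package implements, as a library of sklearn-style estimators plus a
thin CLI:

* **Growth fitness** — pointwise rates μ_i = ln(C_{i+1}/C_i)/(t_{i+1}−t_i)
  from OD600 time series, the steadiest 3-point exponential-phase window,
  replicate-mean growth fitness, dose–response concentration picks, and
  Welch comparisons.
* **Expression matrices** — FPKM from counts, log10 transform with global
  per-sample mean normalization, common-gene restriction, Spearman/ward.D2
  sample clustering and unscaled PCA.
* **Chromosomal periodicity** — spatial expression profile along the
  circular chromosome (1-kb sliding windows, 100-kb circular smoothing),
  periodogram at integer cycles per chromosome, Fisher's exact g-test
  (g = max/sum of periodogram ordinates), and a least-squares cosine fit
  at the dominant wavelength.
* **Transcriptome epistasis** — per-gene changes ΔG, ΔS, ΔE against a
  shared reference; through-origin regression of a simultaneous change
  (ΔGS, ΔGE, ΔES) on the corresponding additive change, ΔGS = α(ΔG+ΔS);
  α < 1 is negative epistasis (the perturbations cancel), α = 1 additivity,
  α > 1 positive epistasis.
* **Rank Product differential expression** — geometric-mean fold-change
  ranks over all cross-replicate comparisons, permutation (or exhaustive)
  significance, proportion-of-false-predictions thresholds, direction
  calls, and DEG-set Venn overlaps; a Welch+BH substitute route.
* **Functional enrichment** — one-sided binomial over-representation of
  regulons / gene categories / modules with Bonferroni correction and
  size filters.
* **Co-expression modules** — unsigned weighted network (|cor|^β,
  default β = 12), topological overlap matrix, adaptive tree-cut module
  detection (min size 50), eigengene merging at dissimilarity 0.25,
  module–growth-rate correlation, and conserved / responsive / epistatic
  module classification.
* **Synthetic data** — a ground-truth-known generator (circular genome,
  six-period spatial cosine, sparse perturbation effects with a built-in
  epistasis coefficient, planted co-expression modules with one
  growth-linked module, multinomial counts, logistic growth curves) used
  by the whole test suite in place of deposited sequencing data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import perturbome as pb

design = pb.SyntheticDesign(n_genes=4000, genome_length=4_600_000,
                            alpha_true=0.6, noise_sd=0.1, seed=1)
expr, truth = pb.generate_expression(design)

# chromosomal periodicity of the reference condition
cols = truth.design_table.index[
    truth.design_table["condition"] == pb.BASELINE_CONDITION]
prof = pb.spatial_profile(expr[cols].mean(axis=1),
                          truth.annotation["midpoint"].to_numpy(),
                          design.genome_length)
res = pb.analyze_periodicity(prof)
print(f"max peak: {res.max_peak_frequency} cycles "
      f"(wavelength {res.wavelength/1e6:.2f} Mb), "
      f"g = {res.g_statistic:.3f}, p = {res.p_value:.3g}")

# transcriptome epistasis of genome reduction x threonine stress
d = lambda to: pb.delta_profile(expr, truth.design_table,
                                pb.BASELINE_CONDITION, to)
slope = pb.epistasis_slope(d("N28-Thr-anc"), d("N28-none-anc"),
                           d("N0-Thr-anc"))
print(f"alpha = {slope.alpha:.3f} ({slope.classification}) "
      f"over {slope.n_genes} genes")

# growth fitness from noisy logistic curves
curves = pb.generate_growth_curves(0.7, lag_h=1.5, capacity=1.0,
                                   noise_sd=0.01, seed=1, n_replicates=3)
print(f"growth fitness = {pb.growth_fitness(curves):.3f} per hour")
```

Output:

```
max peak: 6 cycles (wavelength 0.77 Mb), g = 0.999, p = 0
alpha = 0.593 (negative) over 4000 genes
growth fitness = 0.688 per hour
```

The six-cycle spatial pattern planted by the generator dominates the
periodogram (g near 1; the exact p underflows double precision), the
epistasis slope recovers the generating coefficient 0.6 and is classified
as negative epistasis, and the windowed growth rate lands within a few
percent of the generating 0.7 h⁻¹ despite lag, saturation, and 1% noise.

A CLI mirrors the main stages, e.g.
`perturbome growth --curves curves.csv --out results/` or
`perturbome epistasis --expr expr.tsv --design design.tsv ...`; run
`perturbome --help` for the command list.

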