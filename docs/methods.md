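# Methods

## Model

A K-order epistasis model with marginal effects (eME model) is a map from
the 3^K combination genotypes g (minor-allele counts 0/1/2 at each of K
biallelic loci) to penetrances P(D | g), written per cell as an arithmetic
formula F(α, f) in two scalars: the baseline penetrance α (risk of the
reference genotype) and the relative penetrance f (the multiplier or step
through which minor alleles raise risk). Cells are stored in base-3 order
with the first locus most significant; labels are letter pairs per locus
(AA/Aa/aa, BB/Bb/bb, ...).

Population quantities assume Hardy-Weinberg equilibrium at each locus —
genotype frequencies ((1−m)², 2m(1−m), m²) at MAF m — and linkage
equilibrium across loci, so a combination genotype's frequency is the
product of its per-locus frequencies. Prevalence is the
frequency-weighted mean penetrance; heritability is the between-genotype
variance of penetrance divided by the phenotype's Bernoulli variance
P(D)(1 − P(D)). Both are exact sums over the 3^K cells, not Monte Carlo
estimates.

### Solving for f

The user fixes α, the locus MAFs and one population target (prevalence or
heritability); f is the unknown. Both solvers work on the *raw* expression
values, i.e. before any rescaling, because that is the function the target
equations define; the solved table is rescaled afterwards if needed and its
achieved prevalence/heritability recomputed and written to the output model
file, so any drift introduced by rescaling is visible rather than silent.

- *Prevalence:* raw prevalence is evaluated on [0, f_hi], f_hi doubling
  from 2 until the target is crossed (cap 2^40, else a no-solution error).
  A 257-point grid locates the first sign change — for non-monotone user
  models the smallest root is returned with a warning — and Brent's method
  refines it to |Δf| ≤ 1e-12.
- *Heritability:* h²(f) is scanned on a multiplicative grid (factor 1.05
  per step) starting at f = 1 and moving upward. f = 1 is the null point of
  the multiplicative and threshold families (the table is constant there,
  h² = 0); the additive family x·(1+s·y) is constant at f = 0 instead, so
  when h²(1) already exceeds the target the scan runs downward. Scanning
  away from the null point selects the risk-increasing solution when a
  protective (f < 1) solution with equal h² also exists. The scan stops
  where the raw prevalence leaves (0, 1), beyond which the h² equation is
  undefined. The first crossing is refined by Brent's method; multiple
  crossings trigger a warning.

Round-trip accuracy (forward summary, then inversion) is better than 1e-8
in f throughout the valid-penetrance domain, i.e. wherever the forward
table needs no rescaling. Outside that domain the forward raw summary is
not a probability, so round-trip tests condition their random draws on raw
cells ≤ 1.

### Rescaling

If any solved cell exceeds 1, every cell is divided by 1 + M (M the maximum
cell), mapping the table into [0, 1) monotonically. An alternative mode
divides by M, pinning the top cell to exactly 1; both are exposed through
`normalize_mode` because published penetrance tables exist in both
conventions, and the default is the 1 + M form. The choice only matters
when a requested target forces some cell past 1.

### Expression safety

Model files are CSV rows `genotype,expression`. Expressions are parsed into
an AST and validated against an allowlist (numbers, `x`, `y`, `+ − * / ^`,
unary minus, parentheses) before compilation, so a model file cannot
execute code. Division by zero evaluates to infinity and is then rejected
by the finite-and-non-negative cell check, which names the offending cell.

## Resampling generator

The sampling pool is built from a genotype matrix (codes 1/2/3, labels
0/1): control rows only, restricted to a uniformly random subset of the
requested number of SNP columns, kept in original column order. Per-column
MAFs are (Σ(code−1))/2n, folded onto [0, 0.5] with a flip flag when the
coded allele is in fact the major one.

Each simulated sample draws its own segment plan: fragment lengths uniform
on [len_min, len_max] (defaults 10 and 30 SNPs), last fragment truncated.
Each fragment is copied from one donor row drawn uniformly with
replacement. Consequences used as test oracles:

- every simulated genotype at column j is an actual pool genotype at j
  (closure), hence E[simulated MAF] = pool MAF per column;
- LD is preserved exactly within a fragment, and attenuates across
  fragment boundaries roughly at scale len_max.

Redrawing the plan per sample (rather than sharing one plan) improves donor
mixing; `shared_breakpoints=True` restores the shared-plan variant. Both
readings are defensible interpretations of segment-based resampling, so
both are available.

Model loci are pool columns MAF-matched to the user's targets: candidates
within ±w of each target, w starting at 0.01 and growing by 0.01 until K
distinct columns can be claimed (fewest-candidates targets claim first,
uniformly at random among unclaimed candidates). The penetrance table is
then solved with the *achieved* pool MAFs of the matched columns, not the
requested targets, so the population equations refer to the data actually
generated.

## Labeling and assembly

A sample's label is Bernoulli with probability equal to its penetrance cell
at the model loci — α already encodes the background (not-affected) risk,
so no separate background rate exists. Balanced datasets are assembled by
rejection: candidate rows are generated and labeled in batches, cases and
controls are kept until their quotas fill, and generation aborts with a
quota error after 1000×(n_cases+n_controls) candidates (reachable only with
pathological tables, e.g. a near-zero case probability). Unbalanced
datasets label exactly n_total rows once.

Replicate datasets use independent, individually reproducible random
streams derived from the user seed through `numpy` `SeedSequence` spawn
keys; pool construction and locus matching have their own streams, so e.g.
replicate 3 can be regenerated without replaying replicates 1-2.

## Synthetic pools

`synth_pool` fabricates a sampling pool for testing and self-contained use:
true per-SNP MAFs from a uniform law (default 0.05-0.5) or an explicit
vector, genotypes drawn independently per sample from Hardy-Weinberg
proportions, labels assigned by a control fraction independent of genotype
(a null background). Optional LD: columns are grouped into fixed-size
blocks sharing a true MAF; per sample each block draws a latent genotype
and every column copies it with probability equal to the requested
within-block correlation, drawing independently otherwise. This block-copy
construction makes within-block correlation exactly tunable and trivially
verifiable, which is what the resampler's LD-preservation tests need; it
does not emulate recombination-driven LD decay, haplotype structure,
population stratification or genotyping error, so tests passing on these
pools demonstrate the simulator's mechanics, not robustness to every
property of real panels. `hwe_check` provides the matching diagnostic: a
per-column 1-df chi-square against Hardy-Weinberg expectations at the
estimated MAF, with monomorphic columns skipped.

## Numerical and scale choices

- Root refinement uses Brent's method at xtol 1e-12 with an objective check
  at 1e-10; combination-genotype frequencies are exact outer products, and
  vectorized prevalence/heritability agree with naive enumeration to 1e-12
  (tested to K = 4).
- MAF = 0 is accepted in table computations (mass collapses onto the
  all-common cell); the simulation configuration requires model-locus MAFs
  in (0, 0.5] since a monomorphic model locus carries no signal.
- α = 0 yields an all-zero table and is rejected wherever a target must be
  solved; targets of exactly 0 or 1 are rejected.
- Validation scales: the MAF-preservation experiment runs at 1000 pool
  controls × 1000 SNPs with 5000 simulated samples; label-fidelity checks
  use a 4000-control pool and 50,000 unbalanced samples (a pool this size
  keeps the pool's own Hardy-Weinberg sampling noise well below the
  binomial tolerance of the check); the embedded-signal check uses balanced
  2000/2000 datasets of 1000 SNPs over five seeds. These sizes make the
  binomial error bars decisive while a full run stays in the tens of
  seconds.

## Known limitations

- Only eME models are supported: every cell formula is anchored on α, and
  models with no marginal effects (eNME) cannot be targeted by solving a
  single f. Constructing eNME tables is a different optimization problem
  and out of scope.
- One epistasis model per dataset; no gene-environment terms, covariates or
  quantitative phenotypes.
- The resampler preserves the pool's LD only up to the fragment scale;
  long-range LD is broken by design.
- Output is plain delimited text plus JSON sidecars; no PLINK/VCF/BGEN
  export.
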