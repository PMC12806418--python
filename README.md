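# epistasim

Simulation of case-control SNP datasets with embedded **high-order epistasis
models**, for benchmarking epistasis-detection methods in genome-wide
association studies.

Most epistasis simulators either stop at two-locus models or depend on an
external tool to produce the genotype matrix. `epistasim` does both jobs
itself:

1. **Penetrance-table solving.** A K-order epistasis model with marginal
   effects assigns each of the 3^K combination genotypes a penetrance
   P(D | g) written as a formula F(α, f) in the baseline penetrance α and the
   relative penetrance f. With Hardy-Weinberg genotype frequencies
   q = ((1−m)², 2m(1−m), m²) at each locus (MAF m) and linkage equilibrium
   between loci, the model induces a population prevalence

       P(D) = Σᵢ P(D|gᵢ) P(gᵢ)

   and heritability

       h² = Σᵢ (P(D|gᵢ) − P(D))² P(gᵢ) / (P(D)(1 − P(D))).

   Given α, the locus MAFs and a target P(D) *or* h², the solver recovers f
   by bracketed bisection; if any solved cell exceeds 1 the table is rescaled
   by S(p) = p/(1+M) (M = maximum cell) and the achieved P(D) and h² are
   recomputed and reported.

2. **Fragment resampling.** Simulated genotype rows are spliced from
   column-aligned fragments of real (or synthetic) control samples: the SNP
   axis is cut into segments of random length (default uniform on [10, 30]
   SNPs) and each segment is copied from a random donor. Every simulated
   genotype is a genuine pool genotype at the same column, so minor-allele
   frequencies are preserved and linkage disequilibrium survives within
   fragments.

3. **Label generation.** The K model loci are chosen from pool columns whose
   MAFs match user targets (a ±0.01 window, widened in 0.01 steps until K
   distinct columns qualify). Each simulated sample becomes a case with
   probability equal to its combination genotype's penetrance — the signal
   enters only through labels, never by rewriting genotypes. Output is
   sample-balanced (exact case/control quotas by rejection sampling) or
   unbalanced (natural proportions).

Three canonical model families are built in, parameterized by the total
minor-allele count s of a combination genotype: **additive** x·(1+s·y),
**multiplicative** x·y^s, and **threshold** (x unless every locus carries a
minor allele, else x·y). Arbitrary models are read from a CSV of
`genotype,expression` rows (e.g. `AaBb,x*y^2`) evaluated by a restricted
arithmetic interpreter.

## Worked example

Build a synthetic 1000-sample sampling pool (genotypes in Hardy-Weinberg
proportions, true MAFs uniform on 0.05–0.5), then simulate a balanced
1000/1000 dataset of 1000 SNPs with a two-locus threshold model solved for
prevalence 0.155 at baseline penetrance 0.084:

```sh
epistasim make-fixture --samples 1000 --snps 1200 --seed 5 --out pool.csv
epistasim simulate --sampling pool.csv \
    --model-type threshold --order 2 --alpha 0.084 \
    --prevalence 0.155 --mafs 0.4,0.45 \
    --cases 1000 --controls 1000 --snps 1000 --seed 11 --out sim
```

which prints

```
wrote 1 dataset(s) to sim (f=2.87551, achieved prevalence=0.155, h2=0.0469139)
```

meaning the solver found relative penetrance f ≈ 2.876: carriers of minor
alleles at *both* model loci have penetrance 0.084 × 2.876 ≈ 0.242 versus
the 0.084 baseline, which averages to the requested population prevalence
0.155 over the genotype frequencies at the two matched loci (whose actual
pool MAFs, here 0.403 and 0.4525, are the ones used — see
`sim/model.csv`). The implied heritability of the model is h² ≈ 0.047.
`sim/dataset_1.csv` holds the 2000 labeled samples (codes 1/2/3, final
`label` column) and `sim/dataset_1.csv.meta.json` records the model loci
(columns 761 and 733), the full penetrance table and a config echo.

To solve a table only, without generating data:

```sh
epistasim table --model-type threshold --order 2 --alpha 0.084 \
    --prevalence 0.154875 --mafs 0.5,0.5
```

```
f = 2.5
achieved prevalence   = 0.154875
achieved heritability = 0.029849661192432177
AABB    0.084
...
AaBb    0.21
```

The same pipeline is available as a library — `epistasim.canonical_spec`,
`solve_f_given_prevalence`, `build_table`, `synth_pool`, `build_pool`,
`generate_rows`, `run_simulation` — see the module docstrings.

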