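# popim

Population-genomic inference for a nested three-population system:
window-based diversity and differentiation statistics, joint
site-frequency-spectrum (SFS) demographic inference under
isolation-with-migration (IM) models, and f3 introgression tests — with a
structured-coalescent simulator that generates the synthetic datasets the
pipeline is validated on.

The package is aimed at population geneticists studying very recently
diverged taxa (semispecies, incipient species) from whole-genome
resequencing data.  The motivating system is a trio of *Drosophila*
semispecies with a nested splitting order (WN, (EA, EB)): a
Western-Northern lineage diverging first and two Eastern lineages
splitting more recently, sampled as 9/12/7 sequenced diploids.

## What it computes

**Window statistics** (10 kb non-overlapping windows): nucleotide
diversity per population

&nbsp;&nbsp;π = Σ_sites 2p(1−p)·n/(n−1) / denominator,

absolute divergence Dxy = Σ p₁(1−p₂) + p₂(1−p₁), and Weir–Cockerham
F_ST as a ratio of sums of the per-site variance components a
(among-population), b (among-individual), c (within-individual).  Plus
shared/private SNP partitioning and Mann–Whitney X-vs-autosome
comparisons.

**Demographic inference**: the joint 3-D SFS of polarized, fully
genotyped sites is fit by Poisson composite likelihood to two nested
models — isolation with no migration and isolation with symmetric
migration — under the (WN, (EA, EB)) topology.  Parameters are the
relative sizes ν_WN, ν_E, ν_EA, ν_EB, split times T1 > T2 (units of
2·N_ref generations), symmetric migration rates M = 4·N_ref·m, and the
mutation scale θ = 4·N_ref·μ·L (optimized analytically).  The expected
SFS is computed by a Monte-Carlo coalescent engine: branch lengths of
simulated genealogies are accumulated into SFS cells, so cell
expectation = (θ/2) × mean length.  Models are compared by a
likelihood-ratio test (flagged as anti-conservative for composite
likelihoods), parameter uncertainty by parametric bootstrap, and
estimates are converted to individuals and years via N_ref = θ̂/(4μL)
and years = T·2·N_ref/g (defaults μ = 5.8×10⁻⁹, g = 10 generations per
year).

**Introgression**: f3(C; A, B) = mean[(c−a)(c−b) − c(1−c)/(n_C−1)] over
SNPs, for every target choice, with weighted block-jackknife standard
errors; a significantly negative f3 indicates the target is admixed
between the two sources.

## Worked example

```sh
popim all --out-dir demo --seed 7 --n-loci 100 --n-bootstrap 5
```

simulates a 100-locus dataset under the default model (9/12/7 diploids,
10 kb loci), filters and polarizes it, and runs the full analysis.  The
log prints the per-stage site bookkeeping:

```
INFO popim: simulate: 100 loci, 40453 segregating sites
INFO popim: read: 40453 sites, 28 samples
INFO popim: filter: retained 40441 sites
INFO popim: polarize: 37244 of 40441 sites (92.1%)
INFO popim: sfs: total mass 21061
INFO popim: fit no_migration: loglik=79159.50 theta=3196.14
INFO popim: fit symmetric_migration: loglik=80283.77 theta=3159.16
INFO popim: f3(EA; WN, EB) = 0.005369 (Z = 3.11)
INFO popim: f3(EB; WN, EA) = 0.00616 (Z = 4.15)
INFO popim: f3(WN; EA, EB) = 0.03569 (Z = 8.79)
```

Reading these numbers: 12 of 40,453 sites fail the ≥5-genotyped-per-
population filter at a 2% missing rate with these sample sizes; 92.1%
of sites have two concordant outgroup alleles and are polarized; 21,061
polarized sites have complete genotypes in all 28 individuals and enter
the joint SFS.  The symmetric-migration model improves the composite
log-likelihood by ~1,124 units (LRT statistic 2,249 on 3 df), detecting
the low simulated migration (M = 0.1) — the output flags that
composite-likelihood LRTs are anti-conservative.  All three f3
statistics are positive with positive Z — no sign of admixture, as
expected for tree-like data.  `demo/` contains the window-statistics,
SFS, fit, bootstrap and f3 tables listed in `manifest.json`, every TSV
carrying a seed-stamped provenance header.

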