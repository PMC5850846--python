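# Methods

## The demographic model

The pipeline targets a trio of very recently diverged populations with a
nested splitting order (WN, (EA, EB)).  Backwards in time, the model has
three epochs on the coalescent time scale (units of 2·N_ref
generations, N_ref the ancestral reference size):

* `[0, T2)` — three demes WN, EA, EB with relative sizes ν_WN, ν_EA,
  ν_EB; symmetric migration between each pair at rates M_WN_EA, M_WN_EB,
  M_EA_EB.
* `[T2, T1)` — EA and EB have merged into an Eastern deme E of size ν_E;
  WN and E optionally exchange migrants at M_WN_E (0 by default — the
  epoch-wise rates of the middle epoch are not identifiable from the
  data sizes this pipeline targets, so the parameter exists but is not
  fit unless requested).
* `[T1, ∞)` — a single ancestral deme of size 1 (defining N_ref).

Within a deme of size ν each lineage pair coalesces at rate 1/ν; a
lineage migrates between demes a and b at rate M_ab/2 per unit time.
M is therefore on the 4·N_ref·m scale (m the per-generation migration
probability), the convention of ms-style coalescent simulators; the
unit conversion in `scale_parameters` uses m = M/(4·N_ref) accordingly.
T1 > T2 is enforced structurally by fitting f = T2/T1 ∈ (0, 1).

Mutation is infinite-sites: given a genealogy, mutations fall as a
Poisson process at rate θ_site/2 per unit branch length per site, at
distinct uniform positions within a locus.  Loci are unlinked and have
no intra-locus recombination, mirroring ms-style multi-locus data.

## The expected-SFS engine

Instead of a Wright–Fisher diffusion solver, the expected joint SFS
under a parameter vector is computed by Monte Carlo: simulate
`n_genealogies` genealogies for the full sample configuration, and for
every branch add its length to the SFS cell indexed by the branch's
descendant counts per population.  The expected count of cell (i, j, k)
is then (θ/2) × mean accumulated length; spectra are returned per unit
θ.  This estimator is unbiased, exact in distribution as the genealogy
count grows, directly testable against coalescent theory (E[ξ_i] = θ/i
under panmixia, E[Dxy] = θ_site(1+T) under isolation), and shares its
event engine with the data simulator, so a single implementation is
validated once.  Event times are sampled exactly (exponential
competing-risks sampling, no Euler discretization).  The inner loop is
JIT-compiled with numba; a pure-Python fallback keeps the package
importable without it.

## Likelihood, optimization and model comparison

The data SFS D is compared to the per-unit-θ model spectrum m̃ by
Poisson composite likelihood over unmasked cells (the two invariant
corners are always masked):

  θ̂ = ΣD / Σm̃,  ℓ = Σ [D·ln(θ̂·m̃) − θ̂·m̃],

dropping the log D! constant.  Cells where the Monte-Carlo model mass
is zero but data were observed contribute through a configurable floor
(default 10⁻⁶) in place of m̃ — a smooth penalty rather than −∞, since
such cells are usually Monte-Carlo zeros, not structural zeros.

Optimization is derivative-free Nelder–Mead over log10-transformed
sizes, times and migration rates (f via a logistic transform), with
box bounds ν ∈ [10⁻³, 10³], T1 ∈ [10⁻⁴, 5], M ∈ [0, 20] enforced by
clipping plus a quadratic penalty.  The migration lower bound maps to
exactly M = 0, so the no-migration model is nested *inside* the
symmetric-migration search space; fitting the alternative seeded at the
null optimum can therefore never end below the null likelihood (the
seeded point is kept as a candidate), which makes the LRT's nesting
inequality structural rather than hoped-for.

Monte-Carlo likelihoods need two things to be optimizable: common
random numbers (one fixed genealogy seed per optimization, so the
surface is deterministic) and noise control.  A single-stage simplex
search at ~10³ genealogies reliably stalls on the residual surface
roughness, so fitting has three stages.  (1) Coarse: several seeded
random starts with a wide initial simplex at `n_genealogies` (default
10³).  (2) Polish: Nelder-Mead restarts from the best point at ~10× the
genealogy count with a shrinking simplex.  (3) Response-surface
refinement: a simplex still overfits the surface's own noise (its
argmin sits a few hundred log-likelihood units below the smooth
optimum at realistic data sizes), so each refinement round samples
~2.5× as many points as quadratic coefficients in a box around the
incumbent, fits a full quadratic by least squares — averaging the
noise over all points instead of reacting to single evaluations — and
jumps to its minimizer.  Because the quadratic can extrapolate wildly
along weakly identified ridges, each jump is guarded: the candidate
must beat the incumbent in a paired comparison on fresh genealogy
seeds (judging on the polish surface itself would always favor its own
argmin).  The refinement stage is where the final accuracy comes from;
the earlier stages only need to land within the refinement radius.

The LRT statistic 2(ℓ_alt − ℓ_null) is clamped at zero and referred to
a χ² with df = number of freed migration rates (3 by default).  Because
sites are not independent, composite-likelihood LRTs are
anti-conservative; the result object carries that caveat rather than
attempting an adjustment.

Parametric bootstrap: datasets are re-simulated at the MLE (finite loci
with Poisson mutation counts per SFS cell) and re-analyzed with the
same fitting procedure as the original estimate — not hot-started at
the MLE, because hot-started refits under-disperse and their percentile
CIs then miss both the optimizer's own variability and its bias.  95%
CIs are the 2.5/97.5 percentiles of the replicate estimates; replicates
without a finite likelihood are excluded and counted, >20% failures
aborts.

Real-unit conversion: N_ref = θ̂/(4μL), N_i = ν_i·N_ref, years =
T·2·N_ref/g, m = M/(4·N_ref); defaults μ = 5.8×10⁻⁹ per site per
generation and g = 10 generations per year, the standard values for
temperate *Drosophila*.  X-linked spectra are fit with the same
machinery and no ¾-N_e correction; X/autosome discrepancies are
reported, not reconciled.

## The synthetic-data generator

`simdata` emulates the resequencing data the pipeline is built for:
9/12/7 diploids (WN/EA/EB), per-site θ = 0.006 so that within-population
diversity θ·ν falls in the 0.004–0.008 range typical of these flies,
T1 = 0.27 and T2 = 0.068 (a ≈4:1 ratio of split times), ν = (1.2, 1.0,
1.3, 0.6) for (WN, E, EA, EB), pairwise migration M = 0.1, 2% missing
genotypes, and two outgroup species at 0.039 and 0.043 expected
substitutions per site whose alleles are the true ancestral state
flipped independently with probability 1−e^(−d).  The VCF's REF allele
is the allele carried by the first simulated chromosome (a "reference
strain"), so REF is sometimes the derived state and downstream
polarization is genuinely exercised.

What it does *not* emulate: linked selection, recombination within
loci, inversions, sequencing/genotyping error beyond missingness,
reference bias, and varying callability.  Passing tests therefore
validate the estimators and inference machinery under the stated
neutral model, not robustness to those real-data complications.

## Numerical and design choices

* π/Dxy window denominator: window length in bp (all positions assumed
  callable) unless a callable-sites mask is supplied; a per-analyzed-
  site column is reported alongside, since published tools differ.
* Negative per-window FST values are reported as computed, not clamped.
* Per-site frequencies use genotyped chromosomes only; half-missing
  genotypes count as missing; no imputation anywhere.
* Sites whose shared outgroup allele matches neither VCF allele are
  dropped at polarization (a third allele violates infinite sites).
* SFS missing-data rule is site omission (complete genotypes only);
  hypergeometric projection exists as an option but is off by default.
* Folding merges complementary cells, halving self-complementary ones.
* f3 is unnormalized by default (normalization by target heterozygosity
  is a flag); jackknife blocks are counted in SNPs (default 500)
  because synthetic loci are unlinked, with the weighted delete-one
  scheme handling an unequal trailing block.
* Determinism: every random path (simulation, fitting, bootstrap) is
  driven by explicit seeds; identical seeds give bit-identical outputs.

## Validation scales

Test and validation problem sizes are chosen as the smallest that leave
the checks statistically sharp: coalescent-theory checks use 2,000–20,000
loci; the cross-simulator comparison uses 40,000 loci at θ_locus = 0.1
(≈0.3 segregating sites per genealogy) so that site counts are nearly
independent and a two-sample chi-square homogeneity test against an
independent coalescent simulator is valid — at larger θ_locus,
within-genealogy correlation overdisperses cell counts and the test
rejects even for identical simulators.  Parameter-recovery experiments
run at 6/6/6 diploids and 5,000 × 1 kb loci; bootstrap-coverage
experiments at 3/3/3 diploids with 20 runs × 20 replicates.

## Known limitations

* The composite likelihood ignores linkage between sites within a
  locus; θ̂ and the LRT are the quantities most affected.
* ν_E (the Eastern ancestral size) is informed only by the short
  [T2, T1) epoch and is the least identifiable parameter; it can be
  tied to ν_EA by configuration.
* The Monte-Carlo expected SFS makes the likelihood surface piecewise
  constant at very fine scales; parameter differences below ~1% are not
  resolvable at default genealogy counts.
* Only three-population nested topologies are supported; no growth,
  bottlenecks, asymmetric migration or founder-event models.
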