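"""Synthetic-data generator for the nested three-population divergence model.

Emulates a three-semispecies short-read resequencing dataset: diploid
genotypes for populations WN, EA and EB sampled from a structured
coalescent with splits (WN, (EA, EB)), low symmetric migration,
infinite-sites mutation, missing genotype calls, and two concordant
outgroup species used downstream for ancestral-state polarization.

Defaults describe the emulated study conditions: 9/12/7 diploids,
per-site theta 0.006 (per-site diversity in the 0.004-0.008 range),
split times T1 = 0.27 and T2 = 0.068 (units of 2*N_ref generations),
relative sizes nu = (1.2, 1.0, 1.3, 0.6) for (WN, E, EA, EB), pairwise
migration 0.1 on the 4*N_ref*m scale, and outgroup branch divergences of
0.039 and 0.043 expected substitutions per site.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from . import _coalescent

_BASES = np.array(["A", "C", "G", "T"])

POPULATIONS = ("WN", "EA", "EB")


@dataclass
class DemographicParams:
    """Scaled parameters of the nested isolation-with-migration model.

    Sizes ``nu_*`` are relative to the ancestral reference size N_ref;
    times are in units of 2*N_ref generations with ``T1 > T2 >= 0``
    (T1 = WN/Eastern split, T2 = EA/EB split); migration parameters are
    symmetric rates on the 4*N_ref*m scale (a lineage migrates at M/2 per
    unit time); ``theta`` is 4*N_ref*mu*L for the analyzed length L.
    """

    nu_WN: float = 1.2
    nu_E: float = 1.0
    nu_EA: float = 1.3
    nu_EB: float = 0.6
    T1: float = 0.27
    T2: float = 0.068
    M_WN_EA: float = 0.1
    M_WN_EB: float = 0.1
    M_EA_EB: float = 0.1
    M_WN_E: float = 0.0
    theta: float = 1.0

    def validate(self):
        for name in ("nu_WN", "nu_E", "nu_EA", "nu_EB"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not (np.isfinite(self.T1) and np.isfinite(self.T2)):
            raise ValueError("split times must be finite")
        if not (self.T1 >= self.T2 >= 0):
            raise ValueError(f"need T1 >= T2 >= 0, got T1={self.T1}, T2={self.T2}")
        for name in ("M_WN_EA", "M_WN_EB", "M_EA_EB", "M_WN_E"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        return self

    def replace(self, **kw):
        return dataclasses.replace(self, **kw)


@dataclass
class SimConfig:
    """Sampling and mutation configuration for one synthetic dataset."""

    n_diploids: tuple = (9, 12, 7)  # (WN, EA, EB)
    n_loci: int = 500
    locus_length: int = 10_000
    theta_site: float = 0.006
    seed: int = 2024
    missing_rate: float = 0.02
    outgroup_divergence: tuple = (0.039, 0.043)

    def validate(self):
        if any(n < 1 for n in self.n_diploids) or len(self.n_diploids) != 3:
            raise ValueError("need three positive diploid sample sizes")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be >= 1")
        if self.theta_site <= 0:
            raise ValueError("theta_site must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        return self

    @property
    def n_chrom(self):
        return tuple(2 * n for n in self.n_diploids)


@dataclass
class HaplotypeSet:
    """Simulated haplotypes: one entry per locus.

    ``positions[l]`` are strictly increasing 1-based site positions within
    locus ``l``; ``haplotypes[l]`` is a (chromosomes x sites) 0/1 array
    (0 = ancestral); ``pop_of_chrom`` labels each chromosome row.
    """

    positions: list = field(default_factory=list)
    haplotypes: list = field(default_factory=list)
    pop_of_chrom: np.ndarray = None
    config: SimConfig = None
    params: DemographicParams = None

    @property
    def n_loci(self):
        return len(self.positions)

    def total_segregating(self):
        return sum(len(p) for p in self.positions)


def simulate_im_haplotypes(params: DemographicParams, config: SimConfig) -> HaplotypeSet:
    """Simulate independent non-recombining loci under the structured coalescent.

    Each locus gets one genealogy (exact exponential event times) and a
    Poisson number of infinite-sites mutations at rate theta_site/2 per
    unit branch length per site, placed uniformly on branches, with
    distinct uniform positions within the locus.
    """
    params.validate()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chrom
    ntot = sum(n_chrom)
    pop_of_chrom = np.repeat(POPULATIONS, n_chrom)
    theta_locus = config.theta_site * config.locus_length

    positions, haplotypes = [], []
    for _ in range(config.n_loci):
        branches = _coalescent.simulate_genealogy(rng, n_chrom, params)
        lengths = np.array([b[1] for b in branches])
        total_len = lengths.sum()
        n_mut = rng.poisson(theta_locus / 2.0 * total_len)
        if n_mut > config.locus_length:
            raise ValueError(
                "more mutations than sites in locus; increase locus_length "
                "or decrease theta_site")
        pos = np.sort(rng.choice(config.locus_length, size=n_mut, replace=False)) + 1
        hap = np.zeros((ntot, n_mut), dtype=np.int8)
        if n_mut:
            which = rng.choice(len(branches), size=n_mut, p=lengths / total_len)
            for s, b in enumerate(which):
                hap[branches[b][0], s] = 1
        positions.append(pos)
        haplotypes.append(hap)
    return HaplotypeSet(positions, haplotypes, pop_of_chrom, config, params)


def derived_count_matrix(haps: HaplotypeSet):
    """Per-site derived-allele counts per population, across all loci.

    Returns an (n_sites x 3) integer array in (WN, EA, EB) column order —
    the direct route from simulated haplotypes to a joint SFS.
    """
    masks = [haps.pop_of_chrom == p for p in POPULATIONS]
    blocks = [
        np.column_stack([hap[m].sum(axis=0) for m in masks])
        for hap in haps.haplotypes if hap.shape[1]
    ]
    if not blocks:
        return np.zeros((0, 3), dtype=int)
    return np.concatenate(blocks, axis=0)


def _sample_names(config):
    names = []
    for pop, n in zip(POPULATIONS, config.n_diploids):
        names.extend(f"{pop}_{i + 1}" for i in range(n))
    return names


def write_synthetic_vcf(haps: HaplotypeSet, config: SimConfig, out_dir,
                        prefix="sim", class_of_locus=None):
    """Write the dataset as VCF v4.2 plus sidecar TSVs.

    Chromosomes are paired sequentially into diploid individuals within
    each population; each locus becomes one contig (``locus_0001`` ...).
    The reference allele is the allele carried by chromosome 0 (emulating
    a sequenced reference strain, so REF is sometimes the derived state);
    the ancestral base is written as INFO AA and, with independent
    divergence-dependent flip errors, as a two-outgroup sidecar TSV.
    Missing genotypes are injected at ``config.missing_rate``.

    ``class_of_locus`` optionally maps locus index -> (muller, class) for
    the chromosome-class map; default labels every locus Muller B /
    autosome.  Returns a dict of written paths.
    """
    if any(n % 2 for n in haps.config.n_chrom):
        raise ValueError("odd chromosome count cannot be paired into diploids")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = _sample_names(config)
    p_flip = [1.0 - np.exp(-d) for d in config.outgroup_divergence]

    paths = {
        "vcf": os.path.join(out_dir, f"{prefix}.vcf"),
        "popmap": os.path.join(out_dir, f"{prefix}.popmap.tsv"),
        "outgroups": os.path.join(out_dir, f"{prefix}.outgroups.tsv"),
        "classmap": os.path.join(out_dir, f"{prefix}.classmap.tsv"),
        "truth": os.path.join(out_dir, f"{prefix}.truth.tsv"),
    }

    with open(paths["vcf"], "w") as vcf, \
            open(paths["outgroups"], "w") as ogf, \
            open(paths["truth"], "w") as truthf:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write(f"##source=popim-simdata seed={config.seed}\n")
        vcf.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for l in range(haps.n_loci):
            vcf.write(f"##contig=<ID=locus_{l + 1:04d},length={config.locus_length}>\n")
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples) + "\n")
        ogf.write(f"# popim-simdata seed={config.seed}\n")
        ogf.write("contig\tpos\toutgroup1_allele\toutgroup2_allele\n")
        truthf.write(f"# popim-simdata seed={config.seed}\n")
        truthf.write("contig\tpos\tancestral\tderived\n")

        for l in range(haps.n_loci):
            contig = f"locus_{l + 1:04d}"
            hap = haps.haplotypes[l]
            for s, pos in enumerate(haps.positions[l]):
                anc, der = rng.choice(4, size=2, replace=False)
                anc_base, der_base = _BASES[anc], _BASES[der]
                alleles = hap[:, s]
                # reference strain = chromosome 0
                ref_is_anc = alleles[0] == 0
                ref_base = anc_base if ref_is_anc else der_base
                alt_base = der_base if ref_is_anc else anc_base
                gt_alt = alleles if ref_is_anc else 1 - alleles
                gts = []
                for i in range(0, len(gt_alt), 2):
                    if rng.random() < config.missing_rate:
                        gts.append("./.")
                    else:
                        gts.append(f"{gt_alt[i]}/{gt_alt[i + 1]}")
                vcf.write(f"{contig}\t{pos}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t"
                          f"AA={anc_base}\tGT\t" + "\t".join(gts) + "\n")
                og = []
                for p in p_flip:
                    if rng.random() < p:
                        others = [b for b in "ACGT" if b != anc_base]
                        og.append(others[int(rng.integers(3))])
                    else:
                        og.append(anc_base)
                ogf.write(f"{contig}\t{pos}\t{og[0]}\t{og[1]}\n")
                truthf.write(f"{contig}\t{pos}\t{anc_base}\t{der_base}\n")

    with open(paths["popmap"], "w") as f:
        f.write(f"# popim-simdata seed={config.seed}\n")
        for pop, n in zip(POPULATIONS, config.n_diploids):
            for i in range(n):
                f.write(f"{pop}_{i + 1}\t{pop}\n")

    with open(paths["classmap"], "w") as f:
        f.write(f"# popim-simdata seed={config.seed}\n")
        f.write("scaffold\tmuller\tclass\n")
        for l in range(haps.n_loci):
            muller, cls = ("B", "autosome")
            if class_of_locus is not None and l in class_of_locus:
                muller, cls = class_of_locus[l]
            f.write(f"locus_{l + 1:04d}\t{muller}\t{cls}\n")

    return paths
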