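"""f3 three-population introgression tests with block-jackknife errors.

f3(C; A, B) averages (c-a)(c-b) over SNPs, minus the finite-sample
correction c(1-c)/(n_C - 1) for the target's sampling heterozygosity.  A
significantly negative value indicates the target C is admixed between
sources related to A and B.  Standard errors come from a weighted
delete-one-block jackknife over consecutive SNP blocks (block size in
SNPs by default, since synthetic loci are unlinked; bp-based blocking is
available for real data).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix, PopulationMap

DEFAULT_BLOCK_SIZE = 500


@dataclass
class F3Result:
    target: str
    source_a: str
    source_b: str
    f3: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    block_size: int


def f3_per_snp_terms(a, b, c, n_c, normalize=False):
    """Per-SNP f3 terms (c-a)(c-b) - c(1-c)/(n_c - 1).

    ``a, b, c`` are sample alt-allele frequencies, ``n_c`` genotyped
    chromosome counts in the target.  SNPs with n_c < 2 are dropped.
    With ``normalize=True`` terms are divided by the target's unbiased
    heterozygosity estimate 2c(1-c)n_c/(n_c-1) averaged over kept SNPs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    ok = n_c >= 2
    a, b, c, n_c = a[ok], b[ok], c[ok], n_c[ok]
    terms = (c - a) * (c - b) - c * (1 - c) / (n_c - 1)
    if normalize:
        het = 2 * c * (1 - c) * n_c / (n_c - 1)
        denom = het.mean()
        if denom <= 0:
            raise ValueError("target heterozygosity is zero; cannot normalize")
        terms = terms / denom
    return terms, int((~ok).sum())


def f3_statistic(a, b, c, n_c, normalize=False):
    """Point estimate of f3(C; A, B); see :func:`f3_per_snp_terms`."""
    terms, _ = f3_per_snp_terms(a, b, c, n_c, normalize=normalize)
    if terms.size == 0:
        raise ValueError("no usable SNPs")
    return float(terms.mean())


def bp_block_ids(chroms, positions, block_size_bp=100_000):
    """Per-SNP block labels for physical (bp) jackknife blocking: one
    block per ``block_size_bp`` stretch of each scaffold."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=int)
    return np.array([f"{c}:{p // block_size_bp}"
                     for c, p in zip(chroms, positions)])


def block_jackknife_z(per_snp_terms, block_size_snps: int = DEFAULT_BLOCK_SIZE,
                      block_ids=None):
    """Weighted delete-one-block jackknife.

    Blocks are consecutive runs of ``block_size_snps`` SNPs, or, when
    ``block_ids`` is given (e.g. from :func:`bp_block_ids`), groups of
    SNPs sharing a label.  Returns (estimate, SE, Z).  SE = 0 (all
    blocks identical) yields Z = NaN, reported as such rather than
    inflated.
    """
    terms = np.asarray(per_snp_terms, dtype=float)
    n = terms.size
    if block_ids is not None:
        ids = np.asarray(block_ids)
        if ids.size != n:
            raise ValueError("block_ids length must match terms")
        uniq, inv = np.unique(ids, return_inverse=True)
        n_blocks = uniq.size
        if n_blocks < 2:
            raise ValueError("need at least 2 blocks of SNPs")
        sizes = np.bincount(inv).astype(float)
        block_sums = np.bincount(inv, weights=terms)
        total = terms.sum()
        est = total / n
        loo = (total - block_sums) / (n - sizes)
    else:
        n_blocks = n // block_size_snps
        if n_blocks < 2:
            raise ValueError("need at least 2 full blocks of SNPs")
        edges = [i * block_size_snps for i in range(n_blocks)] + [n]
        sizes = np.diff(edges).astype(float)
        total = terms.sum()
        est = total / n
        loo = np.array([(total - terms[edges[i]:edges[i + 1]].sum())
                        / (n - sizes[i]) for i in range(n_blocks)])
    # weighted delete-one jackknife (handles an unequal trailing block)
    h = n / sizes
    jk_mean = float(n_blocks * est - np.sum((1 - sizes / n) * loo))
    pseudo = h * est - (h - 1) * loo
    var = np.sum((pseudo - jk_mean) ** 2 / (h - 1)) / n_blocks
    se = float(np.sqrt(var))
    z = jk_mean / se if se > 0 else float("nan")
    return jk_mean, se, z


def population_frequencies(gm: GenotypeMatrix, popmap: PopulationMap):
    """Per-site alt-allele frequency and genotyped chromosome count per
    population, as {pop: (freq array, n_chrom array)}."""
    out = {}
    for pop in popmap.populations:
        idx = popmap.indices(pop, gm.samples)
        g = gm.gt[:, idx]
        called = g != MISSING
        n_chr = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_chr > 0, alt / np.maximum(n_chr, 1), np.nan)
        out[pop] = (p, n_chr)
    return out


def all_trees_f3(gm: GenotypeMatrix, popmap: PopulationMap,
                 block_size_snps: int = DEFAULT_BLOCK_SIZE,
                 normalize=False):
    """f3 for every choice of target among the three populations.

    Sites lacking genotypes in any of the three populations are skipped.
    Returns a list of :class:`F3Result` sorted by Z (most negative first).
    """
    pops = popmap.populations
    if len(pops) != 3:
        raise ValueError("exactly three populations required")
    freqs = population_frequencies(gm, popmap)
    results = []
    for target in pops:
        src = [p for p in pops if p != target]
        c, n_c = freqs[target]
        a, n_a = freqs[src[0]]
        b, n_b = freqs[src[1]]
        ok = (n_a >= 1) & (n_b >= 1) & (n_c >= 2)
        terms, _ = f3_per_snp_terms(a[ok], b[ok], c[ok], n_c[ok],
                                    normalize=normalize)
        est, se, z = block_jackknife_z(terms, block_size_snps)
        results.append(F3Result(target, src[0], src[1], est, se, z,
                                int(terms.size), terms.size // block_size_snps,
                                block_size_snps))
    results.sort(key=lambda r: (np.isnan(r.z), r.z))
    return results


def f3_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.target, r.source_a, r.source_b, r.f3, r.se, r.z, r.n_snps,
          r.n_blocks) for r in results],
        columns=["target", "sourceA", "sourceB", "f3", "SE", "Z", "n_snps",
                 "n_blocks"])
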