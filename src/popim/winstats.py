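"""Non-overlapping window statistics: per-population nucleotide diversity,
pairwise absolute divergence (Dxy) and Weir-Cockerham FST, plus
shared/private SNP partitioning and an X-vs-autosome rank-sum comparison.

Per-site quantities use genotyped chromosomes only (no imputation).  The
window denominator is the number of callable positions in the window —
the full window length unless a callable-sites mask is supplied — and a
"per analyzed site" column is reported alongside, since tools differ in
which denominator they print.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .variants import MISSING, GenotypeMatrix, PopulationMap

DEFAULT_WINDOW_SIZE = 10_000


def make_windows(scaffold_lengths: dict, window_size: int = DEFAULT_WINDOW_SIZE):
    """Consecutive [k*w, (k+1)*w) windows per scaffold; trailing partial
    windows (< w bp) are dropped and windows never span scaffolds."""
    if window_size <= 0:
        raise ValueError("window size must be positive")
    windows = []
    for scaf, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for scaffold {scaf!r}")
        for start in range(0, int(length) - window_size + 1, window_size):
            windows.append((scaf, start, start + window_size))
    return windows


def read_callable_mask(bed_path):
    """Read a callable-sites mask from BED (0-based half-open intervals)."""
    df = pd.read_csv(bed_path, sep="\t", comment="#", header=None,
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must have end > start")
    return df


def callable_length(mask: pd.DataFrame, window):
    """Number of callable bp a mask leaves inside a window — the pi/Dxy
    denominator when a mask is supplied."""
    scaf, start, end = window
    sub = mask[mask["chrom"] == scaf]
    overlap = (np.minimum(sub["end"], end)
               - np.maximum(sub["start"], start)).clip(lower=0)
    return int(overlap.sum())


def _window_rows(gm: GenotypeMatrix, window):
    scaf, start, end = window
    s = gm.sites
    mask = (s["chrom"] == scaf).to_numpy() & \
        (s["pos0"].to_numpy() >= start) & (s["pos0"].to_numpy() < end)
    return np.flatnonzero(mask)


def _pop_freqs(gt_block, idx):
    """(alt frequency, genotyped chromosomes, het proportion, diploid n) per site."""
    g = gt_block[:, idx]
    called = g != MISSING
    n_dip = called.sum(axis=1)
    n_chr = 2 * n_dip
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chr > 0, alt / np.maximum(n_chr, 1), np.nan)
        het = np.where(n_dip > 0,
                       (np.where(called, g, 0) == 1).sum(axis=1) / np.maximum(n_dip, 1),
                       np.nan)
    return p, n_chr, het, n_dip


def window_pi(gm: GenotypeMatrix, popmap: PopulationMap, window,
              denominator=None):
    """Per-population nucleotide diversity for one window.

    Per site: unbiased heterozygosity 2*p*(1-p)*n/(n-1) over n genotyped
    chromosomes; sites with n < 2 or monomorphic within the population
    contribute 0.  Returns {pop: (pi_per_bp, pi_per_site, n_sites)} where
    the denominator of pi_per_bp is ``denominator`` (window length by
    default).
    """
    scaf, start, end = window
    denom = (end - start) if denominator is None else denominator
    rows = _window_rows(gm, window)
    out = {}
    for pop in popmap.populations:
        idx = popmap.indices(pop, gm.samples)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} has no samples")
        p, n, _, _ = _pop_freqs(gm.gt[rows], idx)
        ok = n >= 2
        per_site = np.where(ok, 2.0 * p * (1 - p) * n / np.maximum(n - 1, 1), 0.0)
        total = float(np.nansum(per_site))
        n_sites = int(ok.sum())
        out[pop] = (total / denom, total / n_sites if n_sites else 0.0, n_sites)
    return out


def window_dxy(gm: GenotypeMatrix, popmap: PopulationMap, window, pair,
               denominator=None):
    """Absolute divergence for one population pair in one window.

    Per site: p1*(1-p2) + p2*(1-p1); sites lacking genotypes in either
    population are skipped.  Returns (dxy_per_bp, dxy_per_site, n_sites).
    """
    scaf, start, end = window
    denom = (end - start) if denominator is None else denominator
    rows = _window_rows(gm, window)
    i1 = popmap.indices(pair[0], gm.samples)
    i2 = popmap.indices(pair[1], gm.samples)
    if i1.size == 0 or i2.size == 0:
        raise ValueError(f"empty population in pair {pair}")
    p1, n1, _, _ = _pop_freqs(gm.gt[rows], i1)
    p2, n2, _, _ = _pop_freqs(gm.gt[rows], i2)
    ok = (n1 >= 1) & (n2 >= 1)
    per_site = np.where(ok, p1 * (1 - p2) + p2 * (1 - p1), 0.0)
    total = float(np.nansum(per_site))
    n_sites = int(ok.sum())
    return total / denom, total / n_sites if n_sites else 0.0, n_sites


def fst_components(gt_block, idx1, idx2):
    """Weir-Cockerham per-site variance components (a, b, c) for two
    populations, from diploid genotype calls.

    Sites where n_c = 0 or fewer than one diploid per population, or that
    are monomorphic across both populations, yield NaN components and are
    skipped by the ratio-of-sums combination.
    """
    r = 2.0
    p1, _, h1, n1 = _pop_freqs(gt_block, idx1)
    p2, _, h2, n2 = _pop_freqs(gt_block, idx2)
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    bad = (nbar <= 1) | (nc <= 0) | ~np.isfinite(a + b + c)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def window_fst_wc(gm: GenotypeMatrix, popmap: PopulationMap, window, pair):
    """Ratio-of-sums Weir-Cockerham FST for one window.

    Returns (fst, sum_a, sum_abc).  FST is NaN when every usable site is
    monomorphic across the pair (sum_abc = 0), and is reported as computed
    (possibly negative).
    """
    rows = _window_rows(gm, window)
    i1 = popmap.indices(pair[0], gm.samples)
    i2 = popmap.indices(pair[1], gm.samples)
    a, b, c = fst_components(gm.gt[rows], i1, i2)
    sum_a = float(np.nansum(a))
    sum_abc = float(np.nansum(a + b + c))
    fst = sum_a / sum_abc if sum_abc != 0 else float("nan")
    return fst, sum_a, sum_abc


def windowed_statistics(gm: GenotypeMatrix, popmap: PopulationMap, windows,
                        pairs=None):
    """One WindowStatRecord row per window: site count, per-population pi
    and per-pair Dxy/FST with their component sums, per-bp and per-site."""
    if pairs is None:
        pairs = list(itertools.combinations(popmap.populations, 2))
    recs = []
    for window in windows:
        scaf, start, end = window
        rec = {"scaffold": scaf, "start": start, "end": end,
               "n_sites": len(_window_rows(gm, window))}
        for pop, (per_bp, per_site, _) in window_pi(gm, popmap, window).items():
            rec[f"pi_{pop}"] = per_bp
            rec[f"pi_persite_{pop}"] = per_site
        for pair in pairs:
            tag = f"{pair[0]}_{pair[1]}"
            per_bp, per_site, _ = window_dxy(gm, popmap, window, pair)
            rec[f"dxy_{tag}"] = per_bp
            rec[f"dxy_persite_{tag}"] = per_site
            fst, sa, sabc = window_fst_wc(gm, popmap, window, pair)
            rec[f"fst_{tag}"] = fst
            rec[f"fst_sum_a_{tag}"] = sa
            rec[f"fst_sum_abc_{tag}"] = sabc
        recs.append(rec)
    return pd.DataFrame(recs)


def classify_shared_private(gm: GenotypeMatrix, popmap: PopulationMap):
    """Label each site by the set of populations carrying its alt allele.

    Labels are ``private_<P>``, ``shared_<P>_<Q>`` or ``shared_all``;
    sites where the alt allele is absent from every population (possible
    after subsetting) are labelled ``inconsistent`` and counted
    separately.  Returns (labels array, counts dict).
    """
    present = []
    for pop in popmap.populations:
        idx = popmap.indices(pop, gm.samples)
        g = gm.gt[:, idx]
        present.append(np.where(g != MISSING, g, 0).sum(axis=1) > 0)
    present = np.column_stack(present)
    pops = popmap.populations
    labels = np.empty(gm.n_sites, dtype=object)
    for i in range(gm.n_sites):
        which = [pops[j] for j in range(len(pops)) if present[i, j]]
        if len(which) == 0:
            labels[i] = "inconsistent"
        elif len(which) == len(pops):
            labels[i] = "shared_all"
        elif len(which) == 1:
            labels[i] = f"private_{which[0]}"
        else:
            labels[i] = "shared_" + "_".join(which)
    counts = pd.Series(labels).value_counts().to_dict()
    return labels, counts


def rank_sum_compare(values_x, values_autosome):
    """Mann-Whitney U (tie-corrected normal approximation), two-sided.

    Returns (U, p).  If all values in both groups are identical the test
    is degenerate and p = 1 by convention.
    """
    x = np.asarray(values_x, dtype=float)
    a = np.asarray(values_autosome, dtype=float)
    if x.size == 0 or a.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([x, a])).size == 1:
        return x.size * a.size / 2.0, 1.0
    res = stats.mannwhitneyu(x, a, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)
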