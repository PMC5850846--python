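"""Joint three-population site-frequency spectrum: construction from
polarized sites, marginalization, folding, and a text serialization
compatible with the flattened fs layout used by SFS-based inference tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import PolarizedSites, PopulationMap


@dataclass
class JointSFS:
    """Count array indexed by derived-allele count in each population.

    ``data[i, j, k]`` = number of sites with derived counts (i, j, k);
    shape is (2*n1+1, 2*n2+1, 2*n3+1) for diploid sample sizes n1..n3.
    ``mask`` (True = excluded from likelihoods) covers at least the two
    invariant corners.
    """

    data: np.ndarray
    pops: tuple
    folded: bool = False
    mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = default_mask(self.data.shape)
        self.pops = tuple(self.pops)

    @property
    def sample_sizes(self):
        """Chromosome counts per population."""
        return tuple(s - 1 for s in self.data.shape)

    def total(self):
        """Total unmasked mass (number of contributing sites)."""
        return float(self.data[~self.mask].sum())

    def copy(self):
        return JointSFS(self.data.copy(), self.pops, self.folded,
                        self.mask.copy())


def default_mask(shape):
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(0 for _ in shape)] = True
    mask[tuple(s - 1 for s in shape)] = True
    return mask


def build_joint_sfs(ps: PolarizedSites, popmap: PopulationMap,
                    neutral_mask=None) -> JointSFS:
    """Histogram polarized sites into the joint SFS.

    Only sites with complete genotypes in every individual contribute
    (missing data handled by site omission).  ``neutral_mask`` optionally
    restricts to a pre-labelled site subset, given as a set of
    (scaffold, 1-based position) pairs or a boolean array over sites.
    """
    pops = popmap.populations
    sizes = popmap.sizes(ps.gm.samples)
    shape = tuple(2 * sizes[p] + 1 for p in pops)

    complete = np.ones(ps.n_sites, dtype=bool)
    for p in pops:
        complete &= ps.called_chroms[p].to_numpy() == 2 * sizes[p]
    if neutral_mask is not None:
        if isinstance(neutral_mask, np.ndarray):
            complete &= neutral_mask
        else:
            keys = list(zip(ps.gm.sites["chrom"], ps.gm.sites["pos"]))
            complete &= np.array([k in neutral_mask for k in keys])

    counts = np.column_stack([ps.derived[p].to_numpy() for p in pops])[complete]
    for dim, (p, c) in enumerate(zip(pops, counts.T)):
        if c.size and (c.min() < 0 or c.max() >= shape[dim]):
            raise ValueError(f"derived count out of range for population {p}")
    data = np.zeros(shape)
    np.add.at(data, tuple(counts.T), 1.0)
    return JointSFS(data, pops)


def marginalize_sfs(jsfs: JointSFS, population) -> np.ndarray:
    """1-D SFS of one population: sum over the other axes (mass conserved,
    mask ignored — marginals are a bookkeeping view of all sites)."""
    if population not in jsfs.pops:
        raise KeyError(f"unknown population {population!r}")
    axis = jsfs.pops.index(population)
    other = tuple(i for i in range(jsfs.data.ndim) if i != axis)
    return jsfs.data.sum(axis=other)


def fold_sfs(jsfs: JointSFS) -> JointSFS:
    """Fold onto minor-allele configurations.

    Cell (i, j, k) is merged with its complement (2n1-i, 2n2-j, 2n3-k);
    cells whose total derived count exceeds half the total sample size are
    zeroed and masked, and self-complementary cells (total exactly half)
    are halved-and-merged.  Mass is conserved.
    """
    if jsfs.folded:
        raise ValueError("spectrum is already folded")
    n = jsfs.sample_sizes
    total_n = sum(n)
    idx = np.indices(jsfs.data.shape)
    tot_derived = sum(idx)
    rev = jsfs.data[tuple(slice(None, None, -1) for _ in n)]
    folded = np.where(tot_derived * 2 < total_n, jsfs.data + rev, 0.0)
    folded = np.where(tot_derived * 2 == total_n, (jsfs.data + rev) / 2.0, folded)
    mask = jsfs.mask | (tot_derived * 2 > total_n)
    return JointSFS(folded, jsfs.pops, folded=True, mask=mask)


def project_sfs(jsfs: JointSFS, new_sizes) -> JointSFS:
    """Hypergeometric projection to smaller chromosome sample sizes.

    Each cell's mass is redistributed over the smaller configuration
    according to sampling without replacement; an alternative to site
    omission for missing data (off by default in the pipeline, which
    follows the omission rule).  Mass is conserved.
    """
    from scipy.stats import hypergeom

    old = jsfs.sample_sizes
    new = tuple(int(n) for n in new_sizes)
    if any(n > o for n, o in zip(new, old)):
        raise ValueError("projection targets must not exceed current sizes")
    data = jsfs.data
    for axis, (o, n) in enumerate(zip(old, new)):
        if n == o:
            continue
        # P[j derived in subsample of n | i derived among o]
        proj = np.array([[hypergeom.pmf(j, o, i, n) for j in range(n + 1)]
                         for i in range(o + 1)])
        data = np.tensordot(data, proj, axes=([axis], [0]))
        data = np.moveaxis(data, -1, axis)
    return JointSFS(data, jsfs.pops, jsfs.folded)


def write_sfs(jsfs: JointSFS, path):
    """Serialize: dims + folding token, row-major counts, 0/1 mask."""
    with open(path, "w") as f:
        dims = " ".join(str(s) for s in jsfs.data.shape)
        token = "folded" if jsfs.folded else "unfolded"
        f.write(f"{dims} {token} pops={','.join(jsfs.pops)}\n")
        f.write(" ".join(repr(float(x)) for x in jsfs.data.ravel()) + "\n")
        f.write(" ".join(str(int(m)) for m in jsfs.mask.ravel()) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as f:
        header = f.readline().split()
        data = np.array([float(x) for x in f.readline().split()])
        mask = np.array([bool(int(x)) for x in f.readline().split()])
    shape = tuple(int(x) for x in header[: len(header) - 2])
    folded = header[-2] == "folded"
    pops = tuple(header[-1].split("=", 1)[1].split(","))
    return JointSFS(data.reshape(shape), pops, folded, mask.reshape(shape))
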