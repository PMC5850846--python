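"""VCF ingestion, study site filters, outgroup polarization and
chromosome-class partitioning.

Filters follow the study design: keep biallelic SNPs with at least
``min_genotyped_per_pop`` (default 5) genotyped individuals in every
population; assign ancestral states only where two outgroup species carry
the same allele and that allele is one of the site's two alleles; drop
scaffolds whose chromosome class is ``excluded`` (the Muller C analogue)
from all downstream analyses.

Coordinates are 1-based inclusive in all external files (VCF convention);
a 0-based ``pos0`` column is added at ingestion for window arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
_VALID_BASES = frozenset("ACGT")


class PopulationMap:
    """Ordered individual -> population assignment."""

    def __init__(self, sample_to_pop: dict):
        self.sample_to_pop = dict(sample_to_pop)
        seen = []
        for p in self.sample_to_pop.values():
            if p not in seen:
                seen.append(p)
        self.populations = tuple(seen)

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["sample", "population"], dtype=str)
        return cls(dict(zip(df["sample"], df["population"])))

    def samples(self, population):
        return [s for s, p in self.sample_to_pop.items() if p == population]

    def indices(self, population, sample_order):
        members = set(self.samples(population))
        return np.array([i for i, s in enumerate(sample_order) if s in members],
                        dtype=int)

    def sizes(self, sample_order):
        return {p: len(self.indices(p, sample_order)) for p in self.populations}

    def __len__(self):
        return len(self.sample_to_pop)


@dataclass
class GenotypeMatrix:
    """Sites x individuals diploid genotypes (alt-allele counts, -1 missing)."""

    sites: pd.DataFrame  # chrom, pos (1-based), pos0, ref, alt, aa, biallelic_snp
    gt: np.ndarray       # int8, shape (n_sites, n_individuals)
    samples: list

    @property
    def n_sites(self):
        return self.gt.shape[0]

    @property
    def n_individuals(self):
        return self.gt.shape[1]

    def take(self, row_idx):
        return GenotypeMatrix(
            self.sites.iloc[row_idx].reset_index(drop=True),
            self.gt[row_idx], list(self.samples))


@dataclass
class FilterReport:
    rows: list = field(default_factory=list)  # (filter, sites_removed)
    retained: int = 0

    def to_frame(self):
        df = pd.DataFrame(self.rows, columns=["filter", "sites_removed"])
        return pd.concat(
            [df, pd.DataFrame([("retained", self.retained)], columns=df.columns)],
            ignore_index=True)


@dataclass
class PolarizedSites:
    """Polarized subset of a GenotypeMatrix with per-population derived counts."""

    gm: GenotypeMatrix            # polarized sites only; sites has 'ancestral'
    derived: pd.DataFrame         # per-pop derived-allele counts, one column per pop
    called_chroms: pd.DataFrame   # per-pop genotyped chromosome counts
    fraction_polarized: float

    @property
    def n_sites(self):
        return self.gm.n_sites


class ChromosomeClassMap:
    """scaffold -> {X, autosome, excluded} with a Muller label."""

    CLASSES = ("X", "autosome", "excluded")

    def __init__(self, table: pd.DataFrame):
        bad = set(table["class"]) - set(self.CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome classes: {sorted(bad)}")
        self.table = table.set_index("scaffold")

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        df.columns = ["scaffold", "muller", "class"]
        return cls(df)

    def class_of(self, scaffold):
        try:
            return self.table.loc[scaffold, "class"]
        except KeyError:
            raise KeyError(f"scaffold {scaffold!r} missing from chromosome-class map")


def read_genotypes(vcf_path, popmap_path):
    """Read a VCF and its population map into a GenotypeMatrix.

    Multi-allelic and non-SNP records are kept but flagged
    (``biallelic_snp=False``) so the site filter can report them; phasing
    is ignored and half-missing genotypes are coded missing.
    """
    from cyvcf2 import VCF

    popmap = PopulationMap.from_tsv(popmap_path)
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    missing_from_map = [s for s in samples if s not in popmap.sample_to_pop]
    if missing_from_map:
        raise ValueError(f"VCF samples absent from population map: {missing_from_map}")

    recs, gts = [], []
    for v in vcf:
        alts = v.ALT
        snp = (len(alts) == 1 and len(v.REF) == 1 and len(alts[0]) == 1
               and v.REF in _VALID_BASES and alts[0] in _VALID_BASES)
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:  # half-missing counts as missing
                row[i] = MISSING
            else:
                row[i] = min(a, 1) + min(b, 1)
        aa = v.INFO.get("AA")
        recs.append((v.CHROM, v.POS, v.POS - 1, v.REF,
                     alts[0] if alts else ".", aa, snp))
        gts.append(row)

    sites = pd.DataFrame(
        recs, columns=["chrom", "pos", "pos0", "ref", "alt", "aa", "biallelic_snp"])
    gt = np.vstack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8)
    dup = sites.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ValueError("duplicate positions within a scaffold")
    return GenotypeMatrix(sites, gt, samples), popmap


def apply_site_filters(gm: GenotypeMatrix, popmap: PopulationMap,
                       min_genotyped_per_pop: int = 5):
    """Biallelic-SNP and per-population genotyping-completeness filters.

    Retains sites that are biallelic SNPs and have at least
    ``min_genotyped_per_pop`` non-missing individuals in every population.
    Returns (filtered GenotypeMatrix, FilterReport).  Idempotent.
    """
    sizes = popmap.sizes(gm.samples)
    short = {p: n for p, n in sizes.items() if n < min_genotyped_per_pop}
    if short:
        raise ValueError(
            f"filter unsatisfiable: populations smaller than threshold "
            f"{min_genotyped_per_pop}: {short}")

    biallelic = gm.sites["biallelic_snp"].to_numpy()
    ok_counts = np.ones(gm.n_sites, dtype=bool)
    for pop in popmap.populations:
        idx = popmap.indices(pop, gm.samples)
        n_called = (gm.gt[:, idx] != MISSING).sum(axis=1)
        ok_counts &= n_called >= min_genotyped_per_pop

    report = FilterReport()
    report.rows.append(("not_biallelic_snp", int((~biallelic).sum())))
    report.rows.append(
        ("min_genotyped_per_pop", int((biallelic & ~ok_counts).sum())))
    keep = biallelic & ok_counts
    report.retained = int(keep.sum())
    return gm.take(np.flatnonzero(keep)), report


def polarize_sites(gm: GenotypeMatrix, popmap: PopulationMap,
                   outgroups_path=None) -> PolarizedSites:
    """Assign ancestral states by two-outgroup agreement.

    A site is polarized iff both outgroup alleles are present (A/C/G/T),
    identical, and equal to the site's ref or alt; the shared allele
    becomes the ancestral state.  Sites where the shared outgroup allele
    matches neither site allele are dropped (keeps infinite-sites
    consistency).  With ``outgroups_path=None`` the VCF AA tag is used as
    a single pre-agreed outgroup call.
    """
    if outgroups_path is not None:
        og = pd.read_csv(outgroups_path, sep="\t", comment="#", dtype={"pos": int})
        og.columns = ["contig", "pos", "og1", "og2"]
        alleles = og[["og1", "og2"]].astype(str)
        bad = set(alleles.values.ravel()) - _VALID_BASES - {".", "N", "nan"}
        if bad:
            raise ValueError(f"invalid outgroup alleles: {sorted(bad)}")
        lookup = {(c, p): (a1, a2) for c, p, a1, a2
                  in zip(og["contig"], og["pos"], og["og1"], og["og2"])}
        og_pairs = [lookup.get((c, p), (".", "."))
                    for c, p in zip(gm.sites["chrom"], gm.sites["pos"])]
    else:
        og_pairs = [(a, a) if isinstance(a, str) else (".", ".")
                    for a in gm.sites["aa"]]

    ref = gm.sites["ref"].to_numpy()
    alt = gm.sites["alt"].to_numpy()
    anc = np.full(gm.n_sites, "", dtype=object)
    keep = np.zeros(gm.n_sites, dtype=bool)
    for i, (a1, a2) in enumerate(og_pairs):
        if a1 in _VALID_BASES and a1 == a2 and a1 in (ref[i], alt[i]):
            keep[i] = True
            anc[i] = a1

    sub = gm.take(np.flatnonzero(keep))
    sub.sites = sub.sites.assign(ancestral=anc[keep])
    anc_is_ref = (sub.sites["ancestral"] == sub.sites["ref"]).to_numpy()

    derived, called = {}, {}
    for pop in popmap.populations:
        idx = popmap.indices(pop, sub.samples)
        g = sub.gt[:, idx]
        called_chrom = 2 * (g != MISSING).sum(axis=1)
        alt_count = np.where(g != MISSING, g, 0).sum(axis=1)
        derived[pop] = np.where(anc_is_ref, alt_count, called_chrom - alt_count)
        called[pop] = called_chrom

    frac = keep.sum() / gm.n_sites if gm.n_sites else float("nan")
    return PolarizedSites(sub, pd.DataFrame(derived), pd.DataFrame(called),
                          float(frac))


def partition_by_class(gm: GenotypeMatrix, classmap: ChromosomeClassMap):
    """Split a GenotypeMatrix into X and autosome partitions.

    Scaffolds classed ``excluded`` are dropped everywhere; an unclassified
    scaffold is an error, not a silent drop.
    """
    classes = np.array([classmap.class_of(c) for c in gm.sites["chrom"]])
    out = {cls: gm.take(np.flatnonzero(classes == cls))
           for cls in ("X", "autosome")}
    if gm.n_sites and all(p.n_sites == 0 for p in out.values()):
        warnings.warn("all scaffolds excluded: both partitions are empty")
    return out
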