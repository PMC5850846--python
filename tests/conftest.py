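"""Shared fixtures: hand-built toy VCF datasets with known site tallies."""

import numpy as np
import pytest

POPS = ("WN", "EA", "EB")
POP_SIZES = {"WN": 9, "EA": 12, "EB": 7}


def sample_names():
    names = []
    for pop in POPS:
        names.extend(f"{pop}_{i + 1}" for i in range(POP_SIZES[pop]))
    return names


def write_vcf(path, records, samples):
    """records: (chrom, pos, ref, alt, aa, [gt strings per sample])."""
    contigs = []
    for chrom, *_ in records:
        if chrom not in contigs:
            contigs.append(chrom)
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write('##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n')
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        for c in contigs:
            f.write(f"##contig=<ID={c},length=20000>\n")
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, aa, gts in records:
            info = f"AA={aa}" if aa else "."
            f.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t"
                    + "\t".join(gts) + "\n")


def write_popmap(path, samples):
    with open(path, "w") as f:
        for s in samples:
            f.write(f"{s}\t{s.split('_')[0]}\n")


def gts_for(n_het_per_pop=None, missing=None, hom_alt=None):
    """Genotype strings for the 9/12/7 panel: ``n_het_per_pop`` maps pop ->
    number of leading 0/1 individuals; ``missing`` / ``hom_alt`` map pop ->
    number of trailing ./. or 1/1 individuals."""
    n_het_per_pop = n_het_per_pop or {}
    missing = missing or {}
    hom_alt = hom_alt or {}
    gts = []
    for pop in POPS:
        n = POP_SIZES[pop]
        row = ["0/0"] * n
        for i in range(n_het_per_pop.get(pop, 0)):
            row[i] = "0/1"
        for i in range(hom_alt.get(pop, 0)):
            row[n_het_per_pop.get(pop, 0) + i] = "1/1"
        for i in range(missing.get(pop, 0)):
            row[n - 1 - i] = "./."
        gts.append(row)
    return [g for row in gts for g in row]


@pytest.fixture(scope="session")
def toy_records():
    """11 records on scafA: 10 biallelic SNPs of which 3 fail the
    5-per-population rule, plus one multi-allelic record.

    Hand tally: retained after filters = 7 (pos 100, 400, 500, 700, 800,
    900, 1100); polarized = 5 (400 dropped: discordant outgroups; 500
    dropped: shared outgroup allele matches neither site allele); with
    complete genotypes = 4 (pos 800 has a missing EA call).
    """
    return [
        ("scafA", 100, "A", "G", "A", gts_for({"WN": 2, "EA": 1, "EB": 1})),
        ("scafA", 200, "A", "G", "A", gts_for({"EB": 1}, missing={"EB": 3})),
        ("scafA", 300, "A", "G,T", "A", gts_for({"WN": 1})),
        ("scafA", 400, "A", "G", None, gts_for({"EA": 2})),
        ("scafA", 500, "A", "G", "C", gts_for({"WN": 1, "EB": 2})),
        ("scafA", 600, "A", "G", "A", gts_for({"WN": 1}, missing={"WN": 5})),
        ("scafA", 700, "A", "G", "G", gts_for({"WN": 3}, hom_alt={"EB": 7})),
        ("scafA", 800, "A", "G", "A", gts_for({"EA": 4}, missing={"EA": 1})),
        ("scafA", 900, "A", "G", "A", gts_for({"WN": 1, "EA": 1, "EB": 1})),
        ("scafA", 1000, "A", "G", "A", gts_for({"EA": 2}, missing={"EA": 8})),
        ("scafA", 1100, "A", "G", "A", gts_for(hom_alt={"WN": 9})),
    ]


@pytest.fixture(scope="session")
def toy_outgroups():
    """Outgroup alleles keyed to toy_records: 400 discordant, 500 shared
    but matching neither site allele, 700 ancestral = alt; rest = ref."""
    rows = {100: ("A", "A"), 200: ("A", "A"), 300: ("A", "A"),
            400: ("A", "T"), 500: ("C", "C"), 600: ("A", "A"),
            700: ("G", "G"), 800: ("A", "A"), 900: ("A", "A"),
            1000: ("A", "A"), 1100: ("A", "A")}
    return [("scafA", pos, a1, a2) for pos, (a1, a2) in sorted(rows.items())]


@pytest.fixture()
def toy_dataset(tmp_path, toy_records, toy_outgroups):
    samples = sample_names()
    vcf = tmp_path / "toy.vcf"
    popmap = tmp_path / "toy.popmap.tsv"
    og = tmp_path / "toy.outgroups.tsv"
    write_vcf(vcf, toy_records, samples)
    write_popmap(popmap, samples)
    with open(og, "w") as f:
        f.write("contig\tpos\toutgroup1_allele\toutgroup2_allele\n")
        for row in toy_outgroups:
            f.write("\t".join(str(x) for x in row) + "\n")
    return {"vcf": str(vcf), "popmap": str(popmap), "outgroups": str(og)}


@pytest.fixture()
def class_dataset(tmp_path):
    """Three scaffolds labelled X / autosome / excluded, 4 sites each."""
    samples = sample_names()
    records = []
    for chrom in ("scafX", "scafA", "scafC"):
        for i in range(4):
            records.append((chrom, 100 * (i + 1), "A", "G", "A",
                            gts_for({"WN": 1})))
    vcf = tmp_path / "cls.vcf"
    popmap = tmp_path / "cls.popmap.tsv"
    cmap = tmp_path / "cls.classmap.tsv"
    write_vcf(vcf, records, samples)
    write_popmap(popmap, samples)
    with open(cmap, "w") as f:
        f.write("scaffold\tmuller\tclass\n")
        f.write("scafX\tA\tX\nscafA\tB\tautosome\nscafC\tC\texcluded\n")
    return {"vcf": str(vcf), "popmap": str(popmap), "classmap": str(cmap)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
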