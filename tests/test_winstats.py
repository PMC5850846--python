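"""Window statistics against brute-force pair enumeration and an
independently coded Weir-Cockerham implementation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from popim.variants import MISSING, GenotypeMatrix, PopulationMap
from popim.winstats import (classify_shared_private, fst_components,
                            make_windows, rank_sum_compare, window_dxy,
                            window_fst_wc, window_pi, windowed_statistics)


def matrix_from_genotypes(gt, pops_per_sample):
    """Build a GenotypeMatrix + PopulationMap from an int array whose sites
    sit at positions 1..n on scaffold 's'."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape
    samples = [f"i{j}" for j in range(n_ind)]
    sites = pd.DataFrame({
        "chrom": ["s"] * n_sites, "pos": np.arange(1, n_sites + 1),
        "pos0": np.arange(n_sites), "ref": "A", "alt": "G", "aa": "A",
        "biallelic_snp": True})
    gm = GenotypeMatrix(sites, gt, samples)
    popmap = PopulationMap(dict(zip(samples, pops_per_sample)))
    return gm, popmap


def chromosomes(gt_row):
    """Expand diploid genotypes into chromosome alleles (complete data)."""
    out = []
    for g in gt_row:
        out.extend([1, 1] if g == 2 else [1, 0] if g == 1 else [0, 0])
    return out


def brute_force_pi(gt, idx):
    """Mean pairwise difference over all chromosome pairs within a set."""
    total = 0.0
    n_pairs = None
    for row in gt:
        chroms = chromosomes(row[idx])
        pairs = list(itertools.combinations(chroms, 2))
        n_pairs = len(pairs)
        total += sum(a != b for a, b in pairs) / n_pairs
    return total


def brute_force_dxy(gt, idx1, idx2):
    total = 0.0
    for row in gt:
        c1 = chromosomes(row[idx1])
        c2 = chromosomes(row[idx2])
        total += np.mean([a != b for a in c1 for b in c2])
    return total


def reference_wc_fst(gt, idx1, idx2):
    """Independent Weir-Cockerham ratio-of-sums implementation (two pops,
    complete diploid genotypes), written directly from the component
    definitions with explicit per-site loops."""
    num = den = 0.0
    for row in gt:
        g1, g2 = row[idx1], row[idx2]
        n1, n2 = len(g1), len(g2)
        r = 2
        p1 = sum(g1) / (2 * n1)
        p2 = sum(g2) / (2 * n2)
        h1 = sum(1 for g in g1 if g == 1) / n1
        h2 = sum(1 for g in g2 if g == 1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        if nc <= 0 or nbar <= 1:
            continue
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


class TestMakeWindows:
    @pytest.mark.parametrize("length,expect", [(25_000, 2), (9_999, 0),
                                               (10_000, 1), (20_000, 2)])
    def test_counts(self, length, expect):
        assert len(make_windows({"s": length})) == expect

    def test_multi_scaffold(self):
        wins = make_windows({"a": 10_000, "b": 20_000, "c": 5_000})
        assert len(wins) == 3
        assert all(end - start == 10_000 for _, start, end in wins)

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            make_windows({"s": 1000}, 0)


class TestPiDxy:
    def test_worked_pi_example(self):
        """One site, 4 chromosomes, alt count 1: per-site 0.5 (3 of 6
        pairs differ), window pi = 0.05 over a 10 bp denominator."""
        gm, popmap = matrix_from_genotypes([[1, 0]], ["P", "P"])
        res = window_pi(gm, popmap, ("s", 0, 10))
        assert res["P"][0] == pytest.approx(0.05)
        assert res["P"][1] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        gm, popmap = matrix_from_genotypes([[2, 2], [0, 0]], ["P", "P"])
        assert window_pi(gm, popmap, ("s", 0, 10))["P"][0] == 0.0

    def test_fixed_difference_dxy(self):
        gm, popmap = matrix_from_genotypes(
            [[0, 0, 2, 2]] * 3, ["P", "P", "Q", "Q"])
        dxy, _, _ = window_dxy(gm, popmap, ("s", 0, 10), ("P", "Q"))
        assert dxy == pytest.approx(0.3)

    def test_worked_dxy_example(self):
        """p1 = 0.5 / p2 = 0 at one site plus a fixed difference: 0.15."""
        gm, popmap = matrix_from_genotypes(
            [[1, 1, 0, 0], [2, 2, 0, 0]], ["P", "P", "Q", "Q"])
        dxy, _, _ = window_dxy(gm, popmap, ("s", 0, 10), ("P", "Q"))
        assert dxy == pytest.approx(0.15)

    def test_brute_force_equivalence(self, rng):
        """pi and Dxy equal brute-force average pairwise difference on
        complete-genotype matrices with <= 8 chromosomes."""
        for _ in range(25):
            n_sites = int(rng.integers(1, 15))
            gt = rng.integers(0, 3, size=(n_sites, 4))
            gm, popmap = matrix_from_genotypes(gt, ["P", "P", "Q", "Q"])
            win = ("s", 0, 50)
            pi = window_pi(gm, popmap, win)
            for pop, idx in (("P", [0, 1]), ("Q", [2, 3])):
                assert pi[pop][0] * 50 == pytest.approx(
                    brute_force_pi(gt, idx), abs=1e-12)
            dxy, _, _ = window_dxy(gm, popmap, win, ("P", "Q"))
            assert dxy * 50 == pytest.approx(
                brute_force_dxy(gt, [0, 1], [2, 3]), abs=1e-12)


class TestFst:
    def test_fixed_difference_is_one(self):
        gt = [[0, 0, 2, 2]] * 2
        gm, popmap = matrix_from_genotypes(gt, ["P", "P", "Q", "Q"])
        fst, sa, sabc = window_fst_wc(gm, popmap, ("s", 0, 10), ("P", "Q"))
        assert fst == pytest.approx(1.0)

    def test_worked_component_example(self):
        """pop1 {0/1,0/1} vs pop2 {0/0,0/0}: a=0.125, b=-0.125, c=0.25,
        FST = 0.5."""
        gt = [[1, 1, 0, 0]]
        gm, popmap = matrix_from_genotypes(gt, ["P", "P", "Q", "Q"])
        a, b, c = fst_components(gm.gt, np.array([0, 1]), np.array([2, 3]))
        assert a[0] == pytest.approx(0.125)
        assert b[0] == pytest.approx(-0.125)
        assert c[0] == pytest.approx(0.25)
        fst, _, _ = window_fst_wc(gm, popmap, ("s", 0, 10), ("P", "Q"))
        assert fst == pytest.approx(0.5)

    def test_matches_independent_implementation(self, rng):
        """200 random two-population matrices agree with the independently
        coded estimator to 1e-12."""
        for _ in range(200):
            n1 = int(rng.integers(1, 4))
            n2 = int(rng.integers(1, 4))
            n_sites = int(rng.integers(1, 21))
            gt = rng.integers(0, 3, size=(n_sites, n1 + n2))
            pops = ["P"] * n1 + ["Q"] * n2
            gm, popmap = matrix_from_genotypes(gt, pops)
            fst, _, _ = window_fst_wc(gm, popmap, ("s", 0, 100), ("P", "Q"))
            ref = reference_wc_fst(gt, list(range(n1)),
                                   list(range(n1, n1 + n2)))
            if np.isnan(ref):
                assert np.isnan(fst)
            else:
                assert fst == pytest.approx(ref, abs=1e-12)

    def test_duplicating_sites_invariant(self, rng):
        gt = rng.integers(0, 3, size=(8, 6))
        pops = ["P"] * 3 + ["Q"] * 3
        gm1, popmap = matrix_from_genotypes(gt, pops)
        gm2, _ = matrix_from_genotypes(np.vstack([gt, gt]), pops)
        f1, _, _ = window_fst_wc(gm1, popmap, ("s", 0, 100), ("P", "Q"))
        f2, _, _ = window_fst_wc(gm2, popmap, ("s", 0, 100), ("P", "Q"))
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_all_monomorphic_undefined(self):
        gm, popmap = matrix_from_genotypes([[0, 0, 0, 0]],
                                           ["P", "P", "Q", "Q"])
        fst, _, _ = window_fst_wc(gm, popmap, ("s", 0, 10), ("P", "Q"))
        assert np.isnan(fst)


class TestSharedPrivate:
    def test_venn_tally(self):
        """12 sites with constructed presence patterns."""
        patterns = [  # (alt in WN, EA, EB)
            (1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1),
            (0, 1, 1), (1, 1, 1), (1, 1, 1), (1, 1, 1)]
        gt = np.array([[p[0], p[1], p[2]] for p in patterns], dtype=np.int8)
        gm, popmap = matrix_from_genotypes(gt, ["WN", "EA", "EB"])
        labels, counts = classify_shared_private(gm, popmap)
        assert counts == {"private_WN": 2, "private_EA": 1, "private_EB": 1,
                          "shared_WN_EA": 2, "shared_WN_EB": 1,
                          "shared_EA_EB": 2, "shared_all": 3}

    def test_absent_everywhere_flagged(self):
        gm, popmap = matrix_from_genotypes([[0, 0, 0]], ["WN", "EA", "EB"])
        labels, counts = classify_shared_private(gm, popmap)
        assert counts == {"inconsistent": 1}


class TestRankSum:
    def test_identical_multisets(self):
        u, p = rank_sum_compare([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation(self):
        u, p = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p < 0.1

    def test_matches_reference_normal_approximation(self, rng):
        """Hand-coded tie-corrected normal approximation as oracle."""
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=30)
        u, p = rank_sum_compare(x, y)
        allv = np.concatenate([x, y])
        ranks = sps.rankdata(allv)
        r1 = ranks[:30].sum()
        n1 = n2 = 30
        u1 = r1 - n1 * (n1 + 1) / 2
        _, tie_counts = np.unique(allv, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts)
        var = n1 * n2 / 12 * ((n1 + n2 + 1)
                              - tie_term / ((n1 + n2) * (n1 + n2 - 1)))
        z = (u1 - n1 * n2 / 2) / np.sqrt(var)
        p_ref = 2 * sps.norm.sf(abs(z))
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_all_identical_degenerate(self):
        _, p = rank_sum_compare([2, 2], [2, 2, 2])
        assert p == 1.0


def test_callable_mask_denominator(tmp_path):
    """A callable-sites BED mask shrinks the pi denominator to the
    callable overlap with the window."""
    from popim.winstats import callable_length, read_callable_mask
    bed = tmp_path / "mask.bed"
    bed.write_text("s\t0\t5\ns\t8\t12\nother\t0\t100\n")
    mask = read_callable_mask(bed)
    assert callable_length(mask, ("s", 0, 10)) == 7  # 5 + 2
    assert callable_length(mask, ("s", 50, 60)) == 0
    gm, popmap = matrix_from_genotypes([[1, 0]], ["P", "P"])
    pi = window_pi(gm, popmap, ("s", 0, 10),
                   denominator=callable_length(mask, ("s", 0, 10)))
    assert pi["P"][0] == pytest.approx(0.5 / 7)


def test_windowed_statistics_table(rng):
    gt = rng.integers(0, 3, size=(30, 6))
    gm, popmap = matrix_from_genotypes(gt, ["P"] * 3 + ["Q"] * 3)
    df = windowed_statistics(gm, popmap, [("s", 0, 20), ("s", 20, 40)])
    assert len(df) == 2
    assert df.loc[0, "n_sites"] == 20 and df.loc[1, "n_sites"] == 10
    assert {"pi_P", "pi_Q", "dxy_P_Q", "fst_P_Q"} <= set(df.columns)
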