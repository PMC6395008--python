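import itertools

import numpy as np
import pandas as pd
import pytest

from homeokit import popstats
from homeokit.popstats import (
    PopstatsError,
    bootstrap_compare,
    classify_degeneracy,
    pi0_pi4,
    window_dxy,
    window_pi,
)
from homeokit.variants import MISSING, HaplotypeAlignment


def _aln(haps, positions=None, scaffold="chr1"):
    haps = np.asarray(haps, dtype=np.int8)
    n, s = haps.shape
    pos = np.asarray(positions) if positions is not None else np.arange(1, s + 1)
    return HaplotypeAlignment(
        [f"h{i}" for i in range(n)],
        np.repeat(scaffold, s), pos, np.repeat("A", s), np.repeat("T", s), haps,
    )


def brute_pi(haps):
    """Sum over sites of mean pairwise differences over complete pairs."""
    total = 0.0
    for j in range(haps.shape[1]):
        col = haps[:, j]
        vals = col[col != MISSING]
        if len(vals) < 2:
            continue
        pairs = list(itertools.combinations(vals, 2))
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total


def brute_dxy(a, b):
    total = 0.0
    for j in range(a.shape[1]):
        xs = a[:, j][a[:, j] != MISSING]
        ys = b[:, j][b[:, j] != MISSING]
        if len(xs) == 0 or len(ys) == 0:
            continue
        total += np.mean([x != y for x in xs for y in ys])
    return total


class TestWindowPi:
    def test_identical_haplotypes_give_zero(self):
        df = window_pi(_aln([[0, 1, 0], [0, 1, 0]]), window_bp=10)
        assert df.value.iloc[0] == 0.0

    def test_single_site_example(self):
        """Alleles (0,0,1,1) in a 100-site window: pi = 2*0.25*(4/3)/100."""
        aln = _aln([[0], [0], [1], [1]], positions=[50])
        df = window_pi(aln, window_bp=100, accessible={("chr1", 0): 100})
        assert df.value.iloc[0] == pytest.approx((2 * 0.25 * 4 / 3) / 100)
        assert df.value.iloc[0] == pytest.approx(0.006667, abs=1e-6)
        # brute force: 4 differing pairs of 6, over 100 sites
        assert df.value.iloc[0] == pytest.approx(brute_pi(aln.haps) / 100)

    def test_single_haplotype_raises(self):
        with pytest.raises(PopstatsError):
            window_pi(_aln([[0, 1]]))

    def test_window_with_no_accessible_sites_is_nan(self):
        aln = _aln([[MISSING, 0], [MISSING, 0]], positions=[5, 15])
        df = window_pi(aln, window_bp=10)
        assert np.isnan(df.value.iloc[0])

    def test_matches_bruteforce_on_random_instances(self, rng):
        """Frequency-formula pi equals mean pairwise differences, any missingness."""
        for _ in range(200):
            n = rng.integers(2, 7)
            s = rng.integers(1, 30)
            haps = rng.integers(0, 2, size=(n, s)).astype(np.int8)
            haps[rng.random((n, s)) < 0.2] = MISSING
            aln = _aln(haps)
            with pytest.warns(UserWarning):
                df = window_pi(aln, window_bp=1_000_000)
            got = df.value.iloc[0] * df.n_accessible.iloc[0]
            if df.n_accessible.iloc[0] == 0:
                assert np.isnan(df.value.iloc[0])
            else:
                assert got == pytest.approx(brute_pi(haps))

    def test_concatenating_windows_is_length_weighted_mean(self):
        aln = _aln([[0, 1, 0, 1], [1, 1, 0, 0]], positions=[2, 4, 12, 14])
        acc = {("chr1", 0): 10, ("chr1", 10): 10}
        df = window_pi(aln, window_bp=10, accessible=acc)
        joint = window_pi(aln, window_bp=20, accessible={("chr1", 0): 20})
        weighted = (df.value * df.n_accessible).sum() / 20
        assert joint.value.iloc[0] == pytest.approx(weighted)


class TestWindowDxy:
    def test_identical_singletons_give_zero(self):
        a = _aln([[0, 1]])
        df = window_dxy(a, a, window_bp=10)
        assert df.value.iloc[0] == 0.0

    def test_three_site_example(self):
        """A={000}, B={011} over 3 accessible sites -> 2/3."""
        a = _aln([[0, 0, 0]])
        b = _aln([[0, 1, 1]])
        with pytest.warns(UserWarning):
            df = window_dxy(a, b, window_bp=10)
        assert df.value.iloc[0] == pytest.approx(2 / 3)

    def test_symmetric_and_matches_bruteforce(self, rng):
        for _ in range(100):
            na, nb, s = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 20)
            A = rng.integers(0, 2, size=(na, s)).astype(np.int8)
            B = rng.integers(0, 2, size=(nb, s)).astype(np.int8)
            A[rng.random((na, s)) < 0.15] = MISSING
            B[rng.random((nb, s)) < 0.15] = MISSING
            with pytest.warns(UserWarning):
                ab = window_dxy(_aln(A), _aln(B), window_bp=1000)
                ba = window_dxy(_aln(B), _aln(A), window_bp=1000)
            assert ab.value.iloc[0] == pytest.approx(ba.value.iloc[0], nan_ok=True)
            got = ab.value.iloc[0] * ab.n_accessible.iloc[0]
            if ab.n_accessible.iloc[0] > 0:
                assert got == pytest.approx(brute_dxy(A, B))

    def test_empty_group_raises(self):
        a = _aln([[0]])
        with pytest.raises(PopstatsError):
            window_dxy(a, _aln(np.zeros((0, 1))), window_bp=10)


def test_dxy_recovers_intersubgenome_divergence(clean_dataset):
    truth, params = clean_dataset["truth"], clean_dataset["params"]
    co, cg = truth.co_alignment(), truth.cg_alignment()
    acc = {
        (s, st): params.scaffold_length()
        for s, st, _ in popstats.tile_windows(co.scaffolds, co.positions, params.scaffold_length())
    }
    df = window_dxy(co, cg, params.scaffold_length(), accessible=acc)
    mean_dxy = (df.value * df.n_accessible).sum() / df.n_accessible.sum()
    # inter-haplotype differences include divergence plus within-panel variation
    assert 0.015 < mean_dxy < 0.045


class TestBootstrap:
    def test_identical_groups_give_p_near_one(self, rng):
        vals = rng.random(20)
        p = bootstrap_compare(vals, vals.copy(), n_boot=2000, seed=1)
        assert p > 0.5

    def test_disjoint_groups_hit_minimum_attainable_p(self):
        a = np.zeros(20)
        b = np.ones(20)
        p = bootstrap_compare(a, b, n_boot=10_000, seed=2)
        assert p == pytest.approx(2 / 10_001)

    def test_requires_two_windows(self):
        with pytest.raises(PopstatsError):
            bootstrap_compare([1.0], [1.0, 2.0])


GFF = """\
##gff-version 3
chr1\ttest\tgene\t1\t9\t.\t+\t.\tID=g1
chr1\ttest\tCDS\t1\t9\t.\t+\t0\tID=g1.c;Parent=g1
chr2\ttest\tgene\t1\t9\t.\t-\t.\tID=g2
chr2\ttest\tCDS\t1\t9\t.\t-\t0\tID=g2.c;Parent=g2
"""


@pytest.fixture()
def toy_genome(tmp_path):
    # chr1 + strand: ATG GGG AAA -> codons ATG, GGG, AAA
    # chr2 - strand: same coding sequence read on the complement
    fasta = tmp_path / "ref.fa"
    fwd = "ATGGGGAAA"
    rev = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    fasta.write_text(f">chr1\n{fwd}\n>chr2\n{rev}\n")
    gff = tmp_path / "genes.gff"
    gff.write_text(GFF)
    return str(fasta), str(gff)


class TestDegeneracy:
    def test_codon_examples_and_strand_symmetry(self, toy_genome):
        fasta, gff = toy_genome
        cm = classify_degeneracy(fasta, gff)
        plus = cm[cm.scaffold == "chr1"].set_index("position")["fold"]
        # ATG: every position 0-fold (Met is a single codon)
        assert plus.loc[1] == "0-fold" and plus.loc[2] == "0-fold" and plus.loc[3] == "0-fold"
        # GGG: third position 4-fold (glycine), first 0-fold
        assert plus.loc[6] == "4-fold" and plus.loc[4] == "0-fold"
        # AAA (Lys): third position is 2-fold -> other
        assert plus.loc[9] == "other"
        minus = cm[cm.scaffold == "chr2"]["fold"]
        assert sorted(minus) == sorted(plus)

    def test_codon_enumeration_against_biopython(self):
        """0-fold/4-fold classes agree with direct translation of all substitutions."""
        from Bio.Data import CodonTable
        from Bio.Seq import Seq

        table = CodonTable.unambiguous_dna_by_id[1]
        for codon in ("ATG", "GGG", "TTA", "TGG", "CGA"):
            for pos in range(3):
                got = popstats._codon_degeneracy(codon, pos, table)
                aa = str(Seq(codon).translate())
                subs = [
                    str(Seq(codon[:pos] + b + codon[pos + 1 :]).translate())
                    for b in "ACGT" if b != codon[pos]
                ]
                n_change = sum(s != aa for s in subs)
                expect = "0-fold" if n_change == 3 else "4-fold" if n_change == 0 else "other"
                assert got == expect

    def test_partial_codon_warns(self, tmp_path):
        fasta = tmp_path / "r.fa"
        fasta.write_text(">c\nATGGG\n")
        gff = tmp_path / "g.gff"
        gff.write_text("##gff-version 3\nc\tt\tCDS\t1\t5\t.\t+\t0\tID=x\n")
        with pytest.warns(UserWarning, match="divisible"):
            classify_degeneracy(str(fasta), str(gff))


class TestPi0Pi4:
    def test_neutral_data_ratio_near_one(self, rng):
        # same mutational process at all sites: expect ratio ~ 1
        n_sites = 600
        haps = (rng.random((8, n_sites)) < rng.random(n_sites) * 0.5).astype(np.int8)
        aln = _aln(haps, positions=np.arange(1, n_sites + 1))
        cm = pd.DataFrame(
            {
                "scaffold": "chr1",
                "position": np.arange(1, n_sites + 1),
                "fold": np.where(np.arange(n_sites) % 2 == 0, "0-fold", "4-fold"),
            }
        )
        p0, p4, ratio = pi0_pi4(aln, cm)
        assert 0.7 < ratio < 1.3

    def test_suppressed_zero_fold_variation_recovers_factor(self, rng):
        n_sites = 1000
        freqs = rng.random(n_sites) * 0.5
        fold = np.where(np.arange(n_sites) % 2 == 0, "0-fold", "4-fold")
        freqs[fold == "0-fold"] *= 0.25  # purifying selection suppresses diversity
        haps = (rng.random((10, n_sites)) < freqs).astype(np.int8)
        aln = _aln(haps, positions=np.arange(1, n_sites + 1))
        cm = pd.DataFrame({"scaffold": "chr1", "position": np.arange(1, n_sites + 1), "fold": fold})
        _, _, ratio = pi0_pi4(aln, cm)
        assert 0.1 < ratio < 0.45

    def test_monomorphic_fourfold_sites_flag_undefined_ratio(self):
        aln = _aln([[0, 1], [0, 0]], positions=[1, 2])
        cm = pd.DataFrame(
            {"scaffold": ["chr1", "chr1"], "position": [1, 2], "fold": ["4-fold", "0-fold"]}
        )
        p0, p4, ratio = pi0_pi4(aln, cm)
        assert p4 == 0.0 and np.isnan(ratio)
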