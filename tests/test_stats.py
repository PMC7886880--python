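import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelmark import (
    GenotypeMatrix,
    allele_frequencies,
    binarize,
    distance_matrix,
    gene_diversity,
    nei_minimum_distance,
    observed_heterozygosity,
    panel_summary,
    pic,
    upgma,
)
from indelmark.stats import debinarize, leaf_depths


def matrix_from(calls, lines, markers):
    return GenotypeMatrix(lines, markers, calls)


class TestAlleleFrequencies:
    def test_monomorphic(self):
        m = matrix_from({(f"L{i}", "m"): {100} for i in range(10)},
                        [f"L{i}" for i in range(10)], ["m"])
        assert allele_frequencies(m, "m") == {100: 1.0}

    def test_even_split_with_copy_counting(self):
        calls = {(f"L{i}", "m"): ({100} if i < 5 else {130}) for i in range(10)}
        m = matrix_from(calls, [f"L{i}" for i in range(10)], ["m"])
        assert allele_frequencies(m, "m") == {100: 0.5, 130: 0.5}

    def test_heterozygote_contributes_one_copy_each(self):
        calls = {("L0", "m"): {100, 130}, ("L1", "m"): {100}}
        m = matrix_from(calls, ["L0", "L1"], ["m"])
        assert allele_frequencies(m, "m") == {100: 0.75, 130: 0.25}

    def test_all_missing_rejected(self):
        m = matrix_from({("L0", "m"): None}, ["L0"], ["m"])
        with pytest.raises(ValueError):
            allele_frequencies(m, "m")


class TestDiversityAndPic:
    def test_closed_forms(self):
        assert gene_diversity({1: 1.0}) == 0.0
        assert gene_diversity({1: 0.5, 2: 0.5}) == pytest.approx(0.5)
        assert gene_diversity({1: 0.88, 2: 0.12}) == pytest.approx(0.2112)
        assert pic({1: 1.0}) == 0.0
        assert pic({1: 0.5, 2: 0.5}) == pytest.approx(0.375)

    def test_biallelic_locus_with_printed_minimum_diversity(self):
        # p+q=1 and 1-p^2-q^2 = 0.22 (the panel's least-diverse marker);
        # its PIC must round to the printed 0.20
        q = min(np.roots([2, -2, 0.22]))
        freqs = {1: 1 - q, 2: q}
        assert gene_diversity(freqs) == pytest.approx(0.22, abs=1e-9)
        assert round(pic(freqs), 2) == 0.20

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_pic_never_exceeds_gene_diversity(self, raw):
        total = sum(raw)
        freqs = {i: v / total for i, v in enumerate(raw)}
        assert pic(freqs) <= gene_diversity(freqs) + 1e-12

    def test_equal_frequencies_attain_diversity_bound(self):
        for k in (2, 3, 5):
            freqs = {i: 1.0 / k for i in range(k)}
            assert gene_diversity(freqs) == pytest.approx(1 - 1 / k)


class TestHeterozygosity:
    def test_fraction_of_two_band_lines(self):
        lines = [f"L{i}" for i in range(48)]
        calls = {(l, "m"): ({100, 130} if i < 10 else {100})
                 for i, l in enumerate(lines)}
        m = matrix_from(calls, lines, ["m"])
        assert observed_heterozygosity(m, "m") == pytest.approx(10 / 48)

    def test_extremes(self):
        m = matrix_from({("L0", "m"): {100}, ("L1", "m"): {130}},
                        ["L0", "L1"], ["m"])
        assert observed_heterozygosity(m, "m") == 0.0
        m2 = matrix_from({("L0", "m"): {100, 130}}, ["L0"], ["m"])
        assert observed_heterozygosity(m2, "m") == 1.0


class TestPanelSummary:
    def test_mean_allele_count_38_biallelic_plus_one_triallelic(self):
        lines = [f"L{i}" for i in range(6)]
        markers = [f"m{i}" for i in range(39)]
        calls = {}
        for mi, marker in enumerate(markers):
            for li, line in enumerate(lines):
                if mi < 38:
                    calls[(line, marker)] = {100} if li % 2 else {130}
                else:
                    calls[(line, marker)] = {100 + 30 * (li % 3)}
        df = panel_summary(matrix_from(calls, lines, markers))
        assert df.loc["m38", "allele_count"] == 3
        assert round(df.loc["mean", "allele_count"], 2) == 2.03

    def test_monomorphic_marker(self):
        df = panel_summary(matrix_from({("L0", "m"): {100}, ("L1", "m"): {100}},
                                       ["L0", "L1"], ["m"]))
        row = df.loc["m"]
        assert row["allele_count"] == 1
        assert row["gene_diversity"] == 0.0 == row["pic"]


class TestNeiMinimumDistance:
    def toy(self):
        lines = ["X", "Y", "Z"]
        markers = ["m1", "m2", "m3", "m4"]
        calls = {
            ("X", "m1"): {100}, ("X", "m2"): {100, 120},
            ("X", "m3"): {150}, ("X", "m4"): {200},
            ("Y", "m1"): {100}, ("Y", "m2"): {120},
            ("Y", "m3"): {160}, ("Y", "m4"): {200, 210},
            ("Z", "m1"): {110}, ("Z", "m2"): {100},
            ("Z", "m3"): {150}, ("Z", "m4"): None,
        }
        return matrix_from(calls, lines, markers)

    def test_hand_computed_toy_values(self):
        m = self.toy()
        assert nei_minimum_distance(m, "X", "Y") == pytest.approx(0.375)
        assert nei_minimum_distance(m, "X", "Z") == pytest.approx(1.25 / 3)
        assert nei_minimum_distance(m, "Y", "Z") == pytest.approx(1.0)

    def test_identical_lines_are_at_zero(self):
        calls = {(l, m): {100} for l in ("A", "B") for m in ("m1", "m2")}
        mat = matrix_from(calls, ["A", "B"], ["m1", "m2"])
        assert nei_minimum_distance(mat, "A", "B") == 0.0

    def test_fully_disjoint_homozygous_lines_are_at_one(self):
        calls = {("A", m): {100} for m in ("m1", "m2", "m3")}
        calls |= {("B", m): {130} for m in ("m1", "m2", "m3")}
        mat = matrix_from(calls, ["A", "B"], ["m1", "m2", "m3"])
        assert nei_minimum_distance(mat, "A", "B") == 1.0

    def test_symmetry_and_inbred_mismatch_limit(self):
        """For homozygous panels the distance is the mismatch proportion."""
        rng = np.random.default_rng(7)
        lines = [f"L{i}" for i in range(6)]
        markers = [f"m{j}" for j in range(20)]
        calls = {
            (l, m): {int(rng.choice([100, 130, 160]))}
            for l in lines for m in markers
        }
        mat = matrix_from(calls, lines, markers)
        for i, x in enumerate(lines):
            for y in lines[i + 1:]:
                d_xy = nei_minimum_distance(mat, x, y)
                assert d_xy == pytest.approx(nei_minimum_distance(mat, y, x))
                mismatch = np.mean(
                    [mat.get(x, m) != mat.get(y, m) for m in markers])
                assert d_xy == pytest.approx(mismatch)

    def test_no_shared_locus_rejected(self):
        calls = {("A", "m1"): {100}, ("A", "m2"): None,
                 ("B", "m1"): None, ("B", "m2"): {100}}
        mat = matrix_from(calls, ["A", "B"], ["m1", "m2"])
        with pytest.raises(ValueError):
            nei_minimum_distance(mat, "A", "B")


def ultrametric_4taxon():
    ids = list("ABCD")
    d = pd.DataFrame(
        [[0.0, 0.2, 0.8, 0.8], [0.2, 0.0, 0.8, 0.8],
         [0.8, 0.8, 0.0, 0.4], [0.8, 0.8, 0.4, 0.0]],
        index=ids, columns=ids)
    return d


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        tree = upgma(d)
        assert leaf_depths(tree) == {"A": 0.4, "B": 0.4}

    def test_recovers_generating_ultrametric_tree(self):
        tree = upgma(ultrametric_4taxon())
        tips = {t.name for t in tree.tips()}
        assert tips == set("ABCD")
        # clades (A,B) and (C,D), merge heights 0.1, 0.2, root 0.4
        lca_ab = tree.lowest_common_ancestor(["A", "B"])
        lca_cd = tree.lowest_common_ancestor(["C", "D"])
        dist = tree.tip_tip_distances()
        assert dist["A", "B"] == pytest.approx(0.2)
        assert dist["C", "D"] == pytest.approx(0.4)
        assert dist["A", "C"] == pytest.approx(0.8)
        assert {t.name for t in lca_ab.tips()} == {"A", "B"}
        assert {t.name for t in lca_cd.tips()} == {"C", "D"}

    def test_output_is_ultrametric_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        n = 8
        ids = [f"L{i}" for i in range(n)]
        raw = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (raw + raw.T) / 2
        np.fill_diagonal(mat, 0.0)
        d = pd.DataFrame(mat, index=ids, columns=ids)
        tree = upgma(d)
        depths = leaf_depths(tree)
        assert max(depths.values()) - min(depths.values()) < 1e-9
        perm = rng.permutation(n)
        d2 = d.iloc[perm, perm]
        tree2 = upgma(d2)
        t1 = tree.tip_tip_distances()
        t2 = tree2.tip_tip_distances()
        for i, x in enumerate(ids):
            for y in ids[i + 1:]:
                assert t1[x, y] == pytest.approx(t2[x, y], abs=1e-9)

    def test_cophenetic_distances_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        n = 10
        ids = [f"L{i}" for i in range(n)]
        raw = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (raw + raw.T) / 2
        np.fill_diagonal(mat, 0.0)
        tree = upgma(pd.DataFrame(mat, index=ids, columns=ids))
        z = linkage(squareform(mat), method="average")
        coph = squareform(cophenet(z))
        ours = tree.tip_tip_distances()
        for i in range(n):
            for j in range(i + 1, n):
                assert ours[ids[i], ids[j]] == pytest.approx(coph[i, j], abs=1e-9)

    def test_nan_rejected(self):
        d = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]],
                         index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            upgma(d)


class TestBinarize:
    def test_biallelic_homozygous_columns_are_complementary(self):
        lines = ["L0", "L1", "L2", "L3"]
        calls = {(l, "m"): ({100} if i % 2 else {130})
                 for i, l in enumerate(lines)}
        b = binarize(matrix_from(calls, lines, ["m"]))
        assert list(b.columns) == ["m_100", "m_130"]
        assert (b["m_100"] + b["m_130"] == 1).all()

    def test_heterozygote_scores_both_bands(self):
        calls = {("L0", "m"): {100, 130}, ("L1", "m"): {100}}
        b = binarize(matrix_from(calls, ["L0", "L1"], ["m"]))
        assert b.loc["L0"].tolist() == [1, 1]
        assert b.loc["L1"].tolist() == [1, 0]

    def test_roundtrip_identity(self):
        lines = ["L0", "L1", "L2"]
        calls = {
            ("L0", "m1"): {100, 130}, ("L0", "m2"): {200},
            ("L1", "m1"): {130}, ("L1", "m2"): {210},
            ("L2", "m1"): {100}, ("L2", "m2"): None,
        }
        mat = matrix_from(calls, lines, ["m1", "m2"])
        assert debinarize(binarize(mat)) == mat


def test_distance_matrix_is_symmetric_zero_diagonal():
    lines = ["A", "B", "C"]
    calls = {(l, m): {100 if (l, m) != ("C", "m2") else 130}
             for l in lines for m in ("m1", "m2")}
    d = distance_matrix(matrix_from(calls, lines, ["m1", "m2"]))
    assert np.allclose(d.values, d.values.T)
    assert np.allclose(np.diag(d.values), 0.0)
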