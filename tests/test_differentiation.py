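"""Pairwise Fst, unbiased Nei distance, the dual-triangle matrix."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caseinpop.differentiation import (
    build_pair_matrix,
    nei_unbiased_distance,
    overall_differentiation,
    pairwise_fst,
    pairwise_result,
)
from caseinpop.genotype_io import GenotypeCounts
from caseinpop.report import round_report

from conftest import PUBLISHED_FST, PUBLISHED_NEI


def gc(n11, n12, n22, label="x"):
    return GenotypeCounts(label, n11, n12, n22)


pair_counts = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
).filter(lambda t: sum(t) > 0)


def generic_gst(freq_vectors):
    """k-allele Gst oracle: works for any number of alleles/populations."""
    k = len(freq_vectors)
    n_alleles = len(freq_vectors[0])
    p_bar = [sum(v[i] for v in freq_vectors) / k for i in range(n_alleles)]
    ht = 1.0 - sum(p * p for p in p_bar)
    hs = sum(1.0 - sum(p * p for p in v) for v in freq_vectors) / k
    return (ht - hs) / ht if ht > 0 else 0.0


class TestPairwiseFst:
    @pytest.mark.parametrize(
        "pair, printed",
        [(("Gyr", "Holstein Friesian"), "0.067"),
         (("Brown Swiss", "Gyr"), "0.059")],
    )
    def test_published_cells(self, pair, printed, breed_counts):
        by_label = {c.label: c for c in breed_counts}
        fst = pairwise_fst(by_label[pair[0]], by_label[pair[1]])
        assert round_report(fst, 3) == printed

    def test_identical_populations(self):
        c = gc(10, 20, 30)
        assert pairwise_fst(c, c) == pytest.approx(0.0, abs=1e-15)

    def test_shared_fixation_defined_as_zero(self):
        assert pairwise_fst(gc(0, 0, 10), gc(0, 0, 20)) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(pair_counts, pair_counts)
    def test_symmetry_bounds_and_generic_oracle(self, a, b):
        ca, cb = gc(*a, label="a"), gc(*b, label="b")
        fst = pairwise_fst(ca, cb)
        assert fst == pairwise_fst(cb, ca)
        assert 0.0 <= fst < 1.0
        # two-term biallelic form equals the generic k-allele Gst
        from caseinpop.locus_stats import allele_frequencies

        pa, pb = allele_frequencies(ca).p, allele_frequencies(cb).p
        oracle = max(generic_gst([[pa, 1 - pa], [pb, 1 - pb]]), 0.0)
        assert fst == pytest.approx(oracle, abs=1e-12)


class TestNeiUnbiasedDistance:
    def test_published_cell(self, breed_counts):
        by_label = {c.label: c for c in breed_counts}
        d = nei_unbiased_distance(by_label["Jersey"], by_label["Holstein Friesian"])
        assert round_report(d, 3) == "0.013"

    def test_near_identical_pair_clamped_to_zero(self, breed_counts):
        """Raw genetic identity slightly exceeds 1 for very close pairs."""
        by_label = {c.label: c for c in breed_counts}
        res = pairwise_result(by_label["Brown Swiss"], by_label["Holstein Friesian"])
        assert res.jxy / math.sqrt(res.ujx * res.ujy) > 1.0
        assert res.nei_unbiased_d == 0.0

    def test_self_distance_vanishes_at_large_n(self):
        # same frequencies, N = 10^6: the small-sample bias term -> 0
        big = gc(90_000, 420_000, 490_000)
        assert nei_unbiased_distance(big, big) < 1e-4

    def test_bias_shrinks_as_samples_grow(self):
        # same allele frequencies (0.3 vs 0.7) at growing N: the distance
        # converges monotonically to the bias-free asymptote (from below,
        # since the correction lowers the within-population homozygosities)
        jx = 0.3**2 + 0.7**2
        jxy = 2 * 0.3 * 0.7
        asymptote = -math.log(jxy / jx)
        gaps = []
        for k in (1, 10, 100):
            a = gc(9 * k, 42 * k, 49 * k, "a")
            b = gc(49 * k, 42 * k, 9 * k, "b")
            gaps.append(abs(nei_unbiased_distance(a, b) - asymptote))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[-1] < 2e-4

    @settings(deadline=None, derandomize=True)
    @given(pair_counts, pair_counts)
    def test_symmetry_and_nonnegativity(self, a, b):
        ca, cb = gc(*a, label="a"), gc(*b, label="b")
        d = nei_unbiased_distance(ca, cb)
        assert d == nei_unbiased_distance(cb, ca)
        assert d >= 0.0


class TestPairMatrix:
    def test_full_published_matrix(self, breed_counts):
        """All ten Fst cells at 3 d.p.; Nei cells within 0.0025 of print."""
        matrix = build_pair_matrix(breed_counts)
        for (a, b), printed in PUBLISHED_FST.items():
            assert round_report(matrix.get_fst(a, b), 3) == round_report(printed, 3), (a, b)
        for (a, b), printed in PUBLISHED_NEI.items():
            assert matrix.get_nei(a, b) == pytest.approx(printed, abs=2.5e-3), (a, b)

    def test_rendered_layout(self, breed_counts):
        text = build_pair_matrix(breed_counts).render()
        lines = text.strip().splitlines()
        assert len(lines) == 6
        gyr_row = lines[3].split("\t")
        assert gyr_row[0] == "Gyr" and gyr_row[3] == "–"
        assert gyr_row[4] == "0.067"  # Fst above the diagonal

    def test_identical_groups(self):
        m = build_pair_matrix([gc(5, 5, 5, "a"), gc(5, 5, 5, "b")])
        assert m.get_fst("a", "b") == pytest.approx(0.0, abs=1e-15)
        assert m.get_nei("a", "b") == pytest.approx(0.0, abs=1e-3)

    def test_three_groups_symmetric_access(self):
        m = build_pair_matrix([gc(9, 42, 49, "a"), gc(25, 50, 25, "b"),
                               gc(49, 42, 9, "c")])
        assert len(m.fst) == 3
        assert m.get_fst("c", "a") == m.get_fst("a", "c")
        assert m.get_nei("c", "a") == m.get_nei("a", "c")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_pair_matrix([gc(1, 1, 1, "a"), gc(2, 2, 2, "a")])


class TestOverallDifferentiation:
    def test_mean_pairwise(self, breed_counts):
        value, tag = overall_differentiation(breed_counts, "mean_pairwise")
        assert tag == "mean_pairwise"
        assert value == pytest.approx(0.0238, abs=2e-4)

    def test_unweighted_gst(self, breed_counts):
        value, tag = overall_differentiation(breed_counts, "unweighted")
        assert value == pytest.approx(0.0344, abs=2e-4)

    def test_size_weighted_below_unweighted_here(self, breed_counts):
        uw, _ = overall_differentiation(breed_counts, "unweighted")
        sw, _ = overall_differentiation(breed_counts, "size_weighted")
        assert 0.0 < sw < uw

    @pytest.mark.parametrize("method", ["unweighted", "size_weighted", "mean_pairwise"])
    def test_identical_groups_give_zero(self, method):
        groups = [gc(10, 20, 10, "a"), gc(10, 20, 10, "b")]
        value, _ = overall_differentiation(groups, method)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_unknown_method_rejected(self, breed_counts):
        with pytest.raises(ValueError):
            overall_differentiation(breed_counts, "magic")
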