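"""Statistic-level checks against independent oracles and hand-derived values."""

import math
from collections import Counter
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatkcan.simulate import CohortSpec, generate_catalog
from gatkcan.stats import (
    StrandDiffSample,
    dnm,
    fisher_strand,
    intermutation_distances,
    quality_by_depth,
    rank_sum_z,
    strand_diff_test,
)
from gatkcan.types import SiteCatalog, StrandCounts


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Probability-mass two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pr(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pr(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return min(sum(pr(x) for x in range(lo, hi + 1) if pr(x) <= p_obs * (1 + 1e-10)), 1.0)


def mann_whitney_u(alt, ref) -> float:
    return sum((1.0 if a > r else 0.5 if a == r else 0.0) for a in alt for r in ref)


def exact_two_sided_p(alt, ref) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = list(alt) + list(ref)
    n_alt = len(alt)
    u_obs = mann_whitney_u(alt, ref)
    us = []
    for idx in combinations(range(len(pooled)), n_alt):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(mann_whitney_u(grp, rest))
    us = np.asarray(us)
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return min(p, 1.0)


class TestQualityByDepth:
    @pytest.mark.parametrize("qual,depth,expected", [(100, 50, 2.0), (0, 10, 0.0), (7.5, 3, 2.5)])
    def test_quotient(self, qual, depth, expected):
        assert quality_by_depth(qual, depth) == pytest.approx(expected)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            quality_by_depth(10, 0)


class TestFisherStrand:
    def test_balanced_table_is_zero(self):
        assert fisher_strand(StrandCounts(10, 10, 10, 10)) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_margin_is_zero(self):
        assert fisher_strand(StrandCounts(0, 0, 10, 10)) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_strand(StrandCounts(0, 0, 0, 0))

    def test_biased_table_matches_enumeration(self):
        phred = fisher_strand(StrandCounts(50, 50, 20, 0))
        p = fisher_two_sided_oracle(50, 50, 20, 0)
        assert phred == pytest.approx(-10 * math.log10(p), abs=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if a + b + c + d == 0:
                continue
            p = fisher_two_sided_oracle(a, b, c, d)
            expect = 500.0 if p <= 0 else min(max(-10 * math.log10(p), 0.0), 500.0)
            assert fisher_strand(StrandCounts(a, b, c, d)) == pytest.approx(expect, abs=1e-9)

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30), c=st.integers(0, 30), d=st.integers(0, 30)
    )
    @settings(max_examples=60, deadline=None)
    def test_row_and_double_swap_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        base = fisher_strand(StrandCounts(a, b, c, d))
        assert 0.0 <= base <= 500.0
        swapped_rows = fisher_strand(StrandCounts(c, d, a, b))
        swapped_both = fisher_strand(StrandCounts(b, a, d, c))
        assert base == pytest.approx(swapped_rows, abs=1e-9)
        assert base == pytest.approx(swapped_both, abs=1e-9)


class TestRankSumZ:
    def test_identical_samples_give_zero(self):
        assert rank_sum_z([1, 2, 3], [1, 2, 3]) == 0.0

    def test_sign_convention_alt_smaller_is_negative(self):
        assert rank_sum_z([5, 6, 7], [1, 2, 3]) < 0

    def test_closed_form_value(self):
        # U_y = 25, mean = 12.5, var = 5*5*11/12, continuity correction 0.5
        expected = (25 - 12.5 - 0.5) / math.sqrt(5 * 5 * 11 / 12)
        assert rank_sum_z([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(expected, abs=1e-9)

    def test_tie_corrected_variance_against_independent_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 8, rng.integers(2, 12)).astype(float)
            y = rng.integers(0, 8, rng.integers(2, 12)).astype(float)
            u = mann_whitney_u(y, x)
            n1, n2 = len(x), len(y)
            n = n1 + n2
            counts = Counter(list(x) + list(y))
            tie = sum(t**3 - t for t in counts.values()) / (n * (n - 1))
            var = n1 * n2 / 12 * ((n + 1) - tie)
            if var <= 0:
                expected = 0.0
            else:
                diff = u - n1 * n2 / 2
                diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
                expected = diff / math.sqrt(var)
            assert rank_sum_z(x, y) == pytest.approx(expected, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_z([], [1.0])


class TestStrandDiffTest:
    def test_identical_samples_give_one(self):
        assert strand_diff_test(StrandDiffSample((1, 2, 3), (1, 2, 3))) == 1.0

    def test_small_sample_exact_value(self):
        # U = 0; each tail has mass 1/C(6,3) = 1/20; two-sided p = 2/20
        assert strand_diff_test(StrandDiffSample((1, 2, 3), (4, 5, 6))) == pytest.approx(0.1)

    def test_exact_path_matches_full_permutation_enumeration(self):
        rng = np.random.default_rng(7)
        for n1 in range(2, 7):
            for n2 in range(2, 7):
                vals = rng.permutation(100)[: n1 + n2].astype(float)
                alt, ref = tuple(vals[:n1]), tuple(vals[n1:])
                got = strand_diff_test(StrandDiffSample(alt, ref))
                assert got == pytest.approx(exact_two_sided_p(alt, ref), abs=1e-12)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        ref = tuple(int(v) for v in rng.integers(-3, 4, 30))
        alt = tuple(v + 10 for v in ref)
        assert strand_diff_test(StrandDiffSample(alt, ref)) < 0.01

    def test_exact_and_normal_paths_agree_at_n8(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = rng.permutation(1000)[:16].astype(float)
            alt, ref = tuple(vals[:8]), tuple(vals[8:])
            exact = strand_diff_test(StrandDiffSample(alt, ref))
            approx = float(
                mannwhitneyu(alt, ref, alternative="two-sided", method="asymptotic").pvalue
            )
            assert exact == pytest.approx(approx, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            strand_diff_test(StrandDiffSample((), (1,)))


@pytest.fixture()
def catalog():
    return SiteCatalog(
        [("chr1", 100, "A", "G", None), ("chr1", 1000, "C", "T", None), ("chr2", 500, "G", "A", None)]
    )


class TestDnm:

    def test_exact_match_is_zero(self, catalog):
        assert dnm("chr1", 100, "A", "G", catalog) == 0.0

    def test_nearest_neighbor_distance(self, catalog):
        assert dnm("chr1", 400, "A", "C", catalog) == 300.0

    def test_absent_chromosome_is_infinite(self, catalog):
        assert dnm("chrX", 123, "A", "C", catalog) == math.inf

    def test_colocated_allele_mismatch_not_zero(self, catalog):
        assert dnm("chr1", 100, "A", "T", catalog) > 0

    def test_binary_search_equals_linear_scan(self):
        catalog = generate_catalog(CohortSpec().genome, 5000, seed=9)
        all_pos = {c: catalog.positions(c) for c in catalog.chromosomes}
        rng = np.random.default_rng(2)
        chroms = catalog.chromosomes
        for _ in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, 50_000_000))
            got = dnm(chrom, pos, "A", "C", catalog)
            brute = float(np.min(np.abs(all_pos[chrom] - pos)))
            if brute == 0:
                brute = 1.0 if not catalog.contains_exact(chrom, pos, "A", "C") else 0.0
            assert got == brute


class TestIntermutationDistances:
    def test_single_chromosome(self):
        imds, median = intermutation_distances({"chr1": [1, 11, 111]})
        assert imds["chr1"].tolist() == [10, 100]
        assert median == 55.0

    def test_single_mutation_gives_empty(self):
        imds, median = intermutation_distances({"chr1": [42]})
        assert imds["chr1"].size == 0
        assert math.isnan(median)

    def test_no_cross_chromosome_distances(self):
        imds, median = intermutation_distances({"chr1": [1, 5], "chr2": [2, 12]})
        assert imds["chr1"].tolist() == [4]
        assert imds["chr2"].tolist() == [10]
        assert median == 7.0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            intermutation_distances({"chr1": [5, 1]})
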