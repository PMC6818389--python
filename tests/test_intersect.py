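"""Exact multi-set intersection distribution against enumeration oracles."""

import math
from collections import Counter
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from drivercall import (
    IntersectionSpec,
    all_subset_intersections,
    expected_intersection,
    intersection_pmf,
    intersection_pvalue,
)


def enumerate_overlap_distribution(n_background, sizes):
    """Brute-force distribution of |∩ A_i| over all subset combinations."""
    universe = range(n_background)
    pools = [list(combinations(universe, n)) for n in sizes]
    counts = Counter()
    total = 0

    def recurse(i, current):
        nonlocal total
        if i == len(pools):
            counts[len(current)] += 1
            total += 1
            return
        for subset in pools[i]:
            recurse(i + 1, current & set(subset))

    for first in pools[0]:
        recurse(1, set(first))
    return {k: v / total for k, v in counts.items()}


class TestIntersectionPmf:
    def test_two_sets_reduce_to_hypergeometric(self):
        pmf = intersection_pmf(20, [10, 10])
        expected = hypergeom.pmf(np.arange(11), 20, 10, 10)
        np.testing.assert_allclose(pmf, expected, atol=1e-12)

    def test_three_sets_match_exhaustive_enumeration(self):
        pmf = intersection_pmf(6, [3, 3, 3])
        oracle = enumerate_overlap_distribution(6, [3, 3, 3])
        for x in range(4):
            assert pmf[x] == pytest.approx(oracle.get(x, 0.0), abs=1e-12)

    def test_full_set_is_absorbing(self):
        with_full = intersection_pmf(8, [8, 4, 3])
        without = intersection_pmf(8, [4, 3])
        np.testing.assert_allclose(with_full, without, atol=1e-12)

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            intersection_pmf(10, [5])

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError, match="set size"):
            intersection_pmf(10, [11, 5])

    @given(
        st.integers(min_value=2, max_value=30),
        st.data(),
    )
    @settings(deadline=None, max_examples=60)
    def test_pmf_sums_to_one(self, n_background, data):
        m = data.draw(st.integers(min_value=2, max_value=4))
        sizes = [
            data.draw(st.integers(min_value=1, max_value=n_background))
            for _ in range(m)
        ]
        pmf = intersection_pmf(n_background, sizes)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)


class TestIntersectionPvalue:
    def test_observed_zero_is_whole_support(self):
        spec = IntersectionSpec(background_size=10, set_sizes=(4, 4), observed=0)
        assert intersection_pvalue(spec) == 1.0

    def test_two_set_case_equals_hypergeometric_survival(self):
        spec = IntersectionSpec(background_size=20, set_sizes=(10, 10), observed=7)
        assert intersection_pvalue(spec) == pytest.approx(
            hypergeom.sf(6, 20, 10, 10), rel=1e-10
        )

    def test_full_overlap_three_sets_matches_enumeration(self):
        spec = IntersectionSpec(background_size=6, set_sizes=(3, 3, 3), observed=3)
        oracle = enumerate_overlap_distribution(6, [3, 3, 3])
        assert intersection_pvalue(spec) == pytest.approx(oracle[3], abs=1e-12)

    def test_pvalue_non_increasing_in_observed(self):
        previous = 1.0
        for observed in range(0, 6):
            spec = IntersectionSpec(
                background_size=30, set_sizes=(8, 10, 12), observed=observed
            )
            p = intersection_pvalue(spec)
            assert p <= previous + 1e-12
            previous = p

    def test_exchangeable_in_set_order(self):
        a = IntersectionSpec(background_size=25, set_sizes=(5, 9, 13), observed=2)
        b = IntersectionSpec(background_size=25, set_sizes=(13, 5, 9), observed=2)
        assert intersection_pvalue(a) == pytest.approx(intersection_pvalue(b), rel=1e-12)

    def test_deep_significance_survives_in_log_space(self):
        # 6 identical sets of 100 genes from a 20000-gene background: the
        # full-overlap p-value is astronomically small but must not hit 0
        # before the -log10 report.
        results = all_subset_intersections(
            {f"s{k}": frozenset(f"G{i}" for i in range(100)) for k in range(6)},
            20000,
        )
        deepest = [r for r in results if r.degree == 6][0]
        assert deepest.observed == 100
        assert deepest.neg_log10_p > 500
        assert 0.0 <= deepest.p_value <= 1.0


class TestExpectedIntersection:
    @pytest.mark.parametrize(
        "n_background, sizes, expected",
        [(20, (10, 10), 5.0), (100, (50, 50, 50), 12.5), (10, (0, 5), 0.0)],
    )
    def test_closed_form(self, n_background, sizes, expected):
        assert expected_intersection(n_background, sizes) == pytest.approx(expected)


class TestAllSubsetIntersections:
    def make_sets(self, m, size, n_background=50, overlap=True):
        if overlap:
            return {
                f"set{k}": frozenset(f"G{i}" for i in range(k, k + size))
                for k in range(m)
            }
        return {
            f"set{k}": frozenset(f"G{k * size + i}" for i in range(size))
            for k in range(m)
        }

    def test_six_sets_emit_57_results(self):
        results = all_subset_intersections(self.make_sets(6, 10), 50)
        assert len(results) == 57  # 2^6 - 6 - 1

    def test_results_ordered_by_degree_then_label(self):
        results = all_subset_intersections(self.make_sets(3, 5), 50)
        labels = [r.subset_label for r in results]
        assert labels == [
            ("set0", "set1"),
            ("set0", "set2"),
            ("set1", "set2"),
            ("set0", "set1", "set2"),
        ]

    def test_identical_sets_hit_the_point_mass_boundary(self):
        genes = frozenset(f"G{i}" for i in range(5))
        results = all_subset_intersections({"a": genes, "b": genes}, 20)
        (res,) = results
        assert res.observed == 5
        assert res.p_value == pytest.approx(hypergeom.pmf(5, 20, 5, 5), rel=1e-10)

    def test_disjoint_sets_give_p_one(self):
        results = all_subset_intersections(self.make_sets(2, 5, overlap=False), 50)
        assert results[0].observed == 0
        assert results[0].p_value == 1.0

    def test_set_exceeding_background_rejected(self):
        sets = {"a": frozenset(f"G{i}" for i in range(30)), "b": frozenset(["G1"])}
        with pytest.raises(ValueError, match="more than the"):
            all_subset_intersections(sets, 20)

    def test_gene_outside_background_membership_rejected(self):
        background = frozenset(f"G{i}" for i in range(10))
        sets = {"a": frozenset(["G1", "ALIEN"]), "b": frozenset(["G2"])}
        with pytest.raises(ValueError, match="absent from the"):
            all_subset_intersections(sets, 10, background=background)

    def test_observed_counts_are_true_intersections(self):
        sets = {
            "a": frozenset(["G1", "G2", "G3"]),
            "b": frozenset(["G2", "G3", "G4"]),
            "c": frozenset(["G3", "G4", "G5"]),
        }
        results = {r.subset_label: r for r in all_subset_intersections(sets, 30)}
        assert results[("a", "b")].observed == 2
        assert results[("a", "b", "c")].observed == 1
        assert results[("a", "b")].expected == pytest.approx(30 * (3 / 30) ** 2)
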