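"""Gene identity, exclusion handling, grouping and the Wilcoxon rank-sum test."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploshare.sharing import (
    enumerate_sharing_pairs,
    exclude_haplotype,
    gene_identity,
    most_widespread_haplotype,
    pair_identities,
    sharing_test,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(a, b):
    """Exhaustive enumeration oracle for the two-sided rank-sum p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = u_stat(a, b)
    idx = range(len(pooled))
    us = []
    for comb in itertools.combinations(idx, n1):
        rest = [i for i in idx if i not in comb]
        us.append(u_stat(pooled[list(comb)], pooled[rest]))
    us = np.array(us)
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


def toy_counts():
    counts = pd.DataFrame(
        {
            "H1": [8, 8, 0, 0],
            "H2": [2, 0, 5, 0],
            "H3": [0, 2, 0, 5],
        },
        index=["A1", "A2", "B1", "B2"],
    )
    coords = pd.DataFrame(
        {
            "species": ["spA", "spA", "spB", "spB"],
            "latitude": [30.0, 30.5, 30.2, 36.0],
            "longitude": [110.0, 110.4, 110.2, 116.0],
        },
        index=["A1", "A2", "B1", "B2"],
    )
    return counts, coords


class TestGeneIdentity:
    def test_identical_compositions(self):
        assert gene_identity([0.5, 0.5, 0], [0.5, 0.5, 0]) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        assert gene_identity([1, 0], [0, 1]) == 0.0

    def test_half_overlap(self):
        # x = {H1:.5, H2:.5}, y = {H1:.5, H3:.5} -> 0.25 / sqrt(0.5 * 0.5) = 0.5
        assert gene_identity([0.5, 0.5, 0], [0.5, 0, 0.5]) == pytest.approx(0.5)

    def test_raw_mode(self):
        assert gene_identity([0.5, 0.5, 0], [0.5, 0, 0.5], mode="raw") == pytest.approx(0.25)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gene_identity([0, 0], [1, 0])


class TestExclusion:
    def test_fixed_population_dropped(self):
        counts = pd.DataFrame({"H1": [4, 2], "H2": [0, 2]}, index=["P1", "P2"])
        out = exclude_haplotype(counts, "H1")
        assert list(out.index) == ["P2"]
        assert out.at["P2", "H2"] == 2

    def test_frequencies_renormalise(self):
        counts = pd.DataFrame({"H1": [2], "H2": [2]}, index=["P1"])
        out = exclude_haplotype(counts, "H1")
        freqs = out.div(out.sum(axis=1), axis=0)
        assert freqs.at["P1", "H2"] == 1.0

    def test_unknown_label_is_noop(self):
        counts = pd.DataFrame({"H1": [2]}, index=["P1"])
        assert exclude_haplotype(counts, "H99").equals(counts)

    def test_exclusion_emptying_a_species_rejected(self):
        counts = pd.DataFrame({"H1": [5, 5], "H2": [0, 3]}, index=["A1", "B1"])
        coords = pd.DataFrame(
            {"species": ["spA", "spB"], "latitude": [30, 31], "longitude": [110, 111]},
            index=["A1", "B1"],
        )
        with pytest.raises(ValueError, match="empties species"):
            sharing_test(counts, coords, exclude="H1")

    def test_most_widespread(self):
        counts, _ = toy_counts()
        assert most_widespread_haplotype(counts) == "H1"


class TestWilcoxon:
    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        # 20 orderings, 2 extreme -> exact two-sided p = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_branch_matches_enumeration(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(0, 1, r.integers(3, 8))
        b = r.normal(0.5, 1, r.integers(3, 8))
        assert wilcoxon_rank_sum(a, b) == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_asymptotic_branch_close_to_enumeration(self):
        """The tie-corrected normal approximation tracks the exact law at n=8."""
        from scipy.stats import mannwhitneyu

        r = np.random.default_rng(3)
        worst = 0.0
        for _ in range(10):
            a, b = r.normal(0, 1, 8), r.normal(0.8, 1, 8)
            asym = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            worst = max(worst, abs(asym - exact_rank_sum_p(a, b)))
        assert worst < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestGrouping:
    def test_groups_partition_heterospecific_pairs(self):
        counts, coords = toy_counts()
        pairs = pair_identities(counts, coords, threshold_km=300)
        # all 4 heterospecific pairs, no conspecific ones
        assert len(pairs) == 4
        assert set(pairs["group"]) <= {"G2", "G3"}
        assert (pairs.loc[pairs["in_g1"], "group"] == "G2").all()  # G1 subset of G2
        assert (pairs.loc[pairs["in_g1"], "J"] > 0).all()

    def test_threshold_monotonicity(self):
        counts, coords = toy_counts()
        n2 = [
            (pair_identities(counts, coords, threshold_km=t)["group"] == "G2").sum()
            for t in (50, 300, 1500)
        ]
        assert n2 == sorted(n2)

    def test_identical_compositions_give_unit_means(self):
        counts = pd.DataFrame({"H1": [3, 3, 3, 3]}, index=["A1", "A2", "B1", "B2"])
        coords = pd.DataFrame(
            {
                "species": ["spA", "spA", "spB", "spB"],
                "latitude": [30.0, 30.5, 30.2, 36.0],
                "longitude": [110.0, 110.4, 110.2, 116.0],
            },
            index=counts.index,
        )
        res, _ = sharing_test(counts, coords)
        r = res["spA-spB"]
        assert r.m1 == r.m2 == r.m3 == 1.0
        assert r.p23 == pytest.approx(1.0)

    def test_pooled_equals_union_of_species_pairs(self):
        counts, coords = toy_counts()
        coords = coords.copy()
        coords.loc["B2", "species"] = "spC"
        res, pairs = sharing_test(counts, coords)
        assert res["all"].n2 + res["all"].n3 == len(pairs)
        assert res["all"].n2 == sum(res[k].n2 for k in res if k != "all")
        assert res["all"].n3 == sum(res[k].n3 for k in res if k != "all")

    def test_exclusion_shrinks_pair_counts(self):
        counts, coords = toy_counts()
        res_all, _ = sharing_test(counts, coords)
        res_ex, _ = sharing_test(counts, coords, exclude="H2")
        assert res_ex["spA-spB"].n2 <= res_all["spA-spB"].n2
        assert res_ex["spA-spB"].n1 <= res_all["spA-spB"].n1

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(threshold=st.floats(min_value=10, max_value=2000))
    def test_every_near_pair_in_exactly_one_group(self, threshold):
        counts, coords = toy_counts()
        pairs = pair_identities(counts, coords, threshold_km=threshold)
        assert ((pairs["group"] == "G2") ^ (pairs["group"] == "G3")).all()


class TestEnumerateSharingPairs:
    def test_no_sharing_is_empty(self):
        counts = pd.DataFrame({"H1": [3, 0], "H2": [0, 3]}, index=["A1", "B1"])
        coords = pd.DataFrame(
            {"species": ["spA", "spB"], "latitude": [30, 30.5], "longitude": [110, 110]},
            index=["A1", "B1"],
        )
        assert enumerate_sharing_pairs(counts, coords).empty

    def test_single_shared_label_reported(self):
        counts = pd.DataFrame({"H5": [2, 3], "H6": [1, 0]}, index=["A1", "B1"])
        coords = pd.DataFrame(
            {"species": ["spA", "spB"], "latitude": [30, 30.9], "longitude": [110, 110]},
            index=["A1", "B1"],
        )
        out = enumerate_sharing_pairs(counts, coords)
        assert len(out) == 1
        assert out.at[0, "shared_haplotypes"] == "H5"
        assert out.at[0, "distance_km"] < 300

    def test_excluded_label_not_counted_as_sharing(self):
        counts = pd.DataFrame({"H1": [2, 3], "H2": [1, 0]}, index=["A1", "B1"])
        coords = pd.DataFrame(
            {"species": ["spA", "spB"], "latitude": [30, 30.5], "longitude": [110, 110]},
            index=["A1", "B1"],
        )
        assert enumerate_sharing_pairs(counts, coords, exclude="H1").empty
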