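import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longmicro.diversity import (
    DissimilarityMatrix,
    bray_curtis,
    bray_curtis_matrix,
    classify_dominance,
    permanova,
    shannon,
    stability_windows,
    target_taxon_fractions,
)
from longmicro.io import SampleRecord


def _rec(sample, subject, age, centre="Finland"):
    return SampleRecord(
        sample_id=sample, subject_id=subject, age_days=age, centre=centre,
        breastfeeding=True, weaned_age_days=400, antibiotic_courses=[],
        delivery_mode="vaginal", outcome="control", pair_id=None, reads=10**7,
    )


class TestShannon:
    def test_single_species_zero(self):
        assert shannon([100.0]) == 0.0

    def test_uniform_four_species(self):
        assert shannon([25, 25, 25, 25]) == pytest.approx(np.log(4), abs=1e-12)

    def test_hand_summation(self):
        # -sum p ln p for p = (0.5, 0.25, 0.25) = 1.5 ln 2
        assert shannon([50, 25, 25]) == pytest.approx(1.5 * np.log(2), abs=1e-12)

    def test_all_zero_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(shannon([0.0, 0.0]))

    def test_scale_invariance(self):
        x = np.array([3.0, 1.0, 6.0])
        assert shannon(x) == pytest.approx(shannon(10 * x), abs=1e-12)


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis([10, 5, 0], [10, 5, 0]) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([10, 0], [0, 7]) == 1.0

    def test_direct_formula(self):
        assert bray_curtis([50, 50, 0], [25, 25, 50]) == pytest.approx(0.5)

    def test_both_zero_missing(self):
        assert np.isnan(bray_curtis([0, 0], [0, 0]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_minsum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, size=8)
        y = rng.uniform(0, 10, size=8)
        oracle = 1 - 2 * sum(min(a, b) for a, b in zip(x, y)) / (x.sum() + y.sum())
        assert bray_curtis(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_matrix_matches_scalar_op(self, tiny_cohort):
        _, _, tax, _, _ = tiny_cohort
        dm = bray_curtis_matrix(tax)
        v = tax.data.to_numpy()
        for i, j in [(0, 1), (2, 10), (5, 30)]:
            assert dm.data[i, j] == pytest.approx(bray_curtis(v[i], v[j]), abs=1e-12)


class TestDominance:
    def test_clear_majority(self):
        fr = {"A": 0.62, "B": 0.1, "C": 0.0, "D": 0.0}
        assert classify_dominance(fr, taxa=("A", "B", "C", "D")) == "A"

    def test_below_half_is_mixed(self):
        fr = {"A": 0.45, "B": 0.3, "C": 0.1, "D": 0.0}
        assert classify_dominance(fr, taxa=("A", "B", "C", "D")) == "mixed"

    def test_exactly_half_is_mixed(self):
        # the dominance definition is strictly greater than 0.5
        fr = {"A": 0.5, "B": 0.2, "C": 0.1, "D": 0.1}
        assert classify_dominance(fr, taxa=("A", "B", "C", "D")) == "mixed"

    def test_phylum_target_aggregates_member_species(self):
        row = pd.Series(
            {"Escherichia_coli": 30.0, "Klebsiella_pneumoniae": 25.0,
             "Enterobacter_cloacae": 5.0, "Bifidobacterium_longum": 20.0}
        )
        fr = target_taxon_fractions(row)
        assert fr["Proteobacteria"] == pytest.approx(0.6)
        assert classify_dominance(row) == "Proteobacteria"


class TestStabilityWindows:
    def _dm(self, n):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.2, 0.8, size=(n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        return DissimilarityMatrix([f"s{i}" for i in range(n)], d)

    def test_single_subject_only_within_subject_pairs(self):
        recs = [_rec(f"s{i}", "S1", 100 + 10 * i) for i in range(4)]
        sw = stability_windows(self._dm(4), recs, n_boot=50, seed=0)
        w = sw[sw.window_start_days == 60]
        got = dict(zip(w["stratum"], w["n_pairs"]))
        assert got["within_subject"] == 6
        assert got["within_centre"] == 0 and got["between_centre"] == 0

    def test_far_apart_samples_never_cowindowed(self):
        recs = [_rec("s0", "S1", 100), _rec("s1", "S1", 200)]
        sw = stability_windows(self._dm(2), recs, n_boot=50, seed=0)
        assert sw["n_pairs"].sum() == 0

    def test_pair_count_conservation(self, midsize_cohort):
        _, records, tax, _, _ = midsize_cohort
        dm = bray_curtis_matrix(tax)
        sw = stability_windows(dm, records, n_boot=10, seed=0)
        ages = {r.sample_id: r.age_days for r in records}
        a = np.array([ages[s] for s in dm.ids])
        for start, grp in sw.groupby("window_start_days"):
            inside = (a >= start) & (a < start + 90)
            n = int(inside.sum())
            assert grp["n_pairs"].sum() == n * (n - 1) // 2

    def test_ci_brackets_median_and_small_strata_get_nan(self):
        recs = [_rec(f"s{i}", f"S{i}", 100, centre="Finland") for i in range(8)]
        sw = stability_windows(self._dm(8), recs, n_boot=200, seed=1)
        w = sw[(sw.window_start_days == 60) & (sw.stratum == "within_centre")].iloc[0]
        assert w["ci99_low"] <= w["median_bc"] <= w["ci99_high"]
        ws = sw[(sw.window_start_days == 60) & (sw.stratum == "within_subject")].iloc[0]
        assert ws["n_pairs"] == 0 and np.isnan(ws["median_bc"])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            stability_windows(self._dm(2), [_rec("s0", "S1", 1), _rec("s1", "S1", 2)],
                              window_days=0)


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        # two groups, within-group distance 0, between-group distance 1:
        # Gower closed form on the 4-sample toy gives R^2 = 1
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float
        )
        dm = DissimilarityMatrix(list("abcd"), d)
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_group_rejected(self):
        d = np.array([[0, 1], [1, 0]], float)
        with pytest.raises(ValueError):
            permanova(DissimilarityMatrix(["a", "b"], d), ["g", "g"])

    def test_constant_distances_give_p_one(self):
        n = 6
        d = np.ones((n, n)) - np.eye(n)
        dm = DissimilarityMatrix([f"s{i}" for i in range(n)], d)
        res = permanova(dm, ["a", "a", "a", "b", "b", "b"], n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_zero_total_ss_returns_missing(self):
        d = np.zeros((4, 4))
        dm = DissimilarityMatrix(list("abcd"), d)
        res = permanova(dm, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert np.isnan(res.r_squared)

    def test_r2_terms_partition_total(self, tiny_cohort):
        _, records, tax, _, _ = tiny_cohort
        dm = bray_curtis_matrix(tax)
        groups = np.array([s.split("_")[0] for s in dm.ids])
        res = permanova(dm, groups, n_perm=9, seed=0)
        # R^2 + residual fraction = 1 by construction of the partition
        resid = 1 - res.r_squared
        assert 0 <= res.r_squared <= 1 and resid >= 0

    def test_strata_restrict_permutations(self):
        # permuting within strata that coincide with groups leaves the
        # statistic invariant, so p = 1
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 0.9, size=(8, 8))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        dm = DissimilarityMatrix([f"s{i}" for i in range(8)], d)
        g = ["a"] * 4 + ["b"] * 4
        res = permanova(dm, g, n_perm=49, seed=0, strata=g)
        assert res.p_value == 1.0


def test_dissimilarity_matrix_validation():
    with pytest.raises(ValueError):
        DissimilarityMatrix(["a", "b"], np.array([[0, 0.5], [0.4, 0]]))
    with pytest.raises(ValueError):
        DissimilarityMatrix(["a", "b"], np.array([[0.1, 0.5], [0.5, 0.1]]))
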