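"""Identification-table statistics: filtering, counts, CVs, ranks, sets, tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from monodigest.identification import (
    cv_per_protein,
    exclusive_intersections,
    filter_confident,
    intersections_to_frame,
    ks_rank_uniformity,
    load_table,
    proportion_quantified,
    rank_abundance,
    summarize_counts,
    two_sample_ks,
    two_sample_t,
    wilcoxon_rank_sum,
)


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["protein", "peptide", "condition", "replicate", "abundance", "q_value"]
    )


@pytest.fixture
def small_table():
    rows = []
    for rep in (1, 2, 3):
        rows += [
            ("A", "PEPTIDEA", "c1", rep, 80 + 10 * rep, 0.001),
            ("B", "PEPTIDEB", "c1", rep, 10.0, 0.001),
        ]
    # peptide C only quantified in replicates 1-2
    rows += [("C", "PEPTIDEC", "c1", 1, 5.0, 0.001), ("C", "PEPTIDEC", "c1", 2, 5.0, 0.001)]
    return make_table(rows)


class TestFilterAndCounts:
    def test_threshold_strictly_less(self):
        t = make_table([("A", "p", "c", 1, 1.0, 0.001), ("B", "q", "c", 1, 1.0, 0.02)])
        out = filter_confident(t, 0.01)
        assert list(out["protein"]) == ["A"]

    def test_all_pass_is_identity(self):
        t = make_table([("A", "p", "c", 1, 1.0, 0.001)])
        assert filter_confident(t, 0.5).equals(t)

    def test_bad_threshold_rejected(self):
        t = make_table([("A", "p", "c", 1, 1.0, 0.001)])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                filter_confident(t, bad)

    def test_random_mixture_matches_recount(self):
        rng = np.random.default_rng(0)
        q = rng.random(500)
        t = make_table([("P%d" % i, "pep%d" % i, "c", 1, 1.0, qi) for i, qi in enumerate(q)])
        assert len(filter_confident(t, 0.01)) == int((q < 0.01).sum())

    def test_distinct_counts_per_replicate(self):
        t = make_table(
            [
                ("A", "p1", "c", 1, 1.0, 0.0),
                ("A", "p2", "c", 1, 1.0, 0.0),
                ("B", "p3", "c", 1, 1.0, 0.0),
            ]
        )
        s = summarize_counts(t)
        assert s.loc[0, "mean_proteins"] == 2
        assert s.loc[0, "mean_peptides"] == 3

    def test_replicate_mean(self):
        rows = [("A", "p1", "c", 1, 1.0, 0.0), ("B", "p2", "c", 1, 1.0, 0.0)]
        rows += [(f"P{i}", f"x{i}", "c", 2, 1.0, 0.0) for i in range(4)]
        s = summarize_counts(make_table(rows))
        assert s.loc[0, "mean_proteins"] == 3.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_counts(make_table([]))


class TestCV:
    def test_known_cv(self, small_table):
        cv = cv_per_protein(small_table, "c1")
        a = cv.set_index("protein")["cv_pct"]
        assert a["A"] == pytest.approx(10.0)  # (90,100,110): mean 100, sample sd 10
        assert a["B"] == pytest.approx(0.0)

    def test_scale_invariance(self, small_table):
        scaled = small_table.assign(abundance=small_table["abundance"] * 1e4)
        a = cv_per_protein(small_table, "c1").set_index("protein")["cv_pct"]
        b = cv_per_protein(scaled, "c1").set_index("protein")["cv_pct"]
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_min_replicates_omits(self, small_table):
        cv3 = cv_per_protein(small_table, "c1", min_replicates=3)
        assert "C" not in set(cv3["protein"])
        cv2 = cv_per_protein(small_table, "c1", min_replicates=2)
        assert "C" in set(cv2["protein"])

    def test_peptide_level_exposed(self, small_table):
        cv = cv_per_protein(small_table, "c1", level="peptide")
        assert set(cv.columns) >= {"protein", "peptide", "cv_pct"}

    def test_missing_condition_rejected(self, small_table):
        with pytest.raises(ValueError):
            cv_per_protein(small_table, "nope")


def test_exact_cv_values():
    t = make_table([("A", "p", "c", r, a, 0.0) for r, a in enumerate((90, 100, 110), 1)])
    cv = cv_per_protein(t, "c")
    assert cv.loc[0, "cv_pct"] == pytest.approx(10.0)


class TestProportionQuantified:
    def test_two_of_three_complete(self, small_table):
        assert proportion_quantified(small_table, "c1") == pytest.approx(2 / 3)

    def test_all_complete(self):
        t = make_table([("A", "p", "c", r, 1.0, 0.0) for r in (1, 2)])
        assert proportion_quantified(t, "c") == 1.0

    def test_random_missingness_matches_recount(self):
        rng = np.random.default_rng(1)
        rows = []
        complete = 0
        for i in range(200):
            present = rng.random(3) < 0.7
            if present.all():
                complete += 1
            for r, keep in enumerate(present, 1):
                if keep:
                    rows.append((f"P{i}", f"pep{i}", "c", r, 1.0, 0.0))
        t = make_table(rows)
        n_entities = t.groupby(["protein", "peptide"]).ngroups
        assert proportion_quantified(t, "c") == pytest.approx(complete / n_entities)


class TestRankAbundance:
    def test_descending_order(self):
        t = make_table([("A", "p", "c", 1, 100.0, 0.0), ("B", "q", "c", 1, 10.0, 0.0)])
        rk = rank_abundance(t, "c")
        assert list(rk["protein"]) == ["A", "B"]
        assert list(rk["rank"]) == [1, 2]

    def test_tie_break_lexicographic(self):
        t = make_table([("Z", "p", "c", 1, 5.0, 0.0), ("A", "q", "c", 1, 5.0, 0.0)])
        rk = rank_abundance(t, "c")
        assert list(rk["protein"]) == ["A", "Z"]

    def test_matches_numpy_sort(self):
        rng = np.random.default_rng(3)
        vals = 10 ** rng.normal(6, 1, size=50)
        t = make_table([(f"P{i:02d}", f"p{i}", "c", 1, v, 0.0) for i, v in enumerate(vals)])
        rk = rank_abundance(t, "c")
        expected = [f"P{i:02d}" for i in np.argsort(-vals, kind="stable")]
        assert list(rk["protein"]) == expected


class TestExclusiveIntersections:
    def test_worked_example(self):
        counts = exclusive_intersections({"X": {"a", "b"}, "Y": {"b", "c"}})
        assert counts == {
            frozenset({"X"}): 1,
            frozenset({"Y"}): 1,
            frozenset({"X", "Y"}): 1,
        }

    def test_disjoint_sets(self):
        counts = exclusive_intersections({"X": {"a"}, "Y": {"b"}, "Z": {"c"}})
        assert all(len(sig) == 1 for sig in counts)

    def test_counts_sum_to_union_random(self):
        rng = np.random.default_rng(4)
        universe = [f"p{i}" for i in range(300)]
        sets = {
            name: set(rng.choice(universe, size=100, replace=False)) for name in "ABC"
        }
        counts = exclusive_intersections(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))
        # brute-force membership classification
        for sig, n in counts.items():
            members = [
                e
                for e in set().union(*sets.values())
                if {k for k, s in sets.items() if e in s} == set(sig)
            ]
            assert len(members) == n

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            exclusive_intersections({"X": {"a"}})

    def test_matrix_frame(self):
        counts = exclusive_intersections({"X": {"a", "b"}, "Y": {"b"}})
        df = intersections_to_frame(counts, ["X", "Y"])
        assert set(df.columns) == {"X", "Y", "count"}
        assert df["count"].sum() == 2


class TestKSUniformity:
    def test_single_middle_rank(self):
        # rank 50 of 99 maps to u = 0.5 exactly; for n=1, D >= 0.5 always
        res = ks_rank_uniformity([50], 99)
        assert res.statistic == pytest.approx(0.5)
        assert res.p_value == pytest.approx(1.0)

    def test_top_decile_concentration(self):
        """Ranks jammed into the top decile: D near 0.9, p tiny; agrees with a
        Monte-Carlo uniform null."""
        ranks = list(range(1, 31))  # top 30 of 300
        res = ks_rank_uniformity(ranks, 300)
        assert res.statistic >= 0.85
        rng = np.random.default_rng(5)
        null_d = []
        for _ in range(2000):
            u = np.sort(rng.random(30))
            grid = np.arange(1, 31) / 30
            d = max(np.abs(grid - u).max(), np.abs(u - (np.arange(30) / 30)).max())
            null_d.append(d)
        mc_p = float(np.mean(np.array(null_d) >= res.statistic))
        assert res.p_value < 1e-6 and mc_p < 0.005

    def test_rank_bounds_enforced(self):
        with pytest.raises(ValueError):
            ks_rank_uniformity([0], 10)
        with pytest.raises(ValueError):
            ks_rank_uniformity([], 10)


class TestTwoSampleKS:
    def test_identical_samples(self):
        res = two_sample_ks([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_supports(self):
        res = two_sample_ks([1, 2, 3], [101, 102, 103])
        assert res.statistic == 1.0

    def test_matches_permutation_oracle_small_n(self):
        """Exact-mode p agrees with full permutation enumeration (n<=8)."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(loc=0.8, size=6)
            res = two_sample_ks(a, b)
            pooled = np.concatenate([a, b])
            count = 0
            total = 0
            for idx in itertools.combinations(range(11), 5):
                mask = np.zeros(11, bool)
                mask[list(idx)] = True
                aa, bb = np.sort(pooled[mask]), np.sort(pooled[~mask])
                # D statistic of the relabelled split
                grid = np.sort(pooled)
                cdf_a = np.searchsorted(aa, grid, side="right") / 5
                cdf_b = np.searchsorted(bb, grid, side="right") / 6
                d = np.abs(cdf_a - cdf_b).max()
                total += 1
                if d >= res.statistic - 1e-12:
                    count += 1
            assert res.p_value == pytest.approx(count / total, rel=0.10)


class TestWilcoxon:
    def test_worked_exact_case(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method.startswith("exact")

    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(7)
        a = 10 ** rng.normal(5, 0.3, 60)
        b = 10 ** rng.normal(6, 0.3, 60)
        res = wilcoxon_rank_sum(a, b)
        assert res.p_value < 1e-3

    def test_exact_agrees_with_enumeration(self):
        """Exact p equals label-permutation enumeration of U."""
        rng = np.random.default_rng(8)
        a = rng.normal(size=4)
        b = rng.normal(loc=0.5, size=5)
        res = wilcoxon_rank_sum(a, b)
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        n1, n2 = 4, 5
        mean_u = n1 * n2 / 2
        obs_u = res.statistic
        count = total = 0
        for idx in itertools.combinations(range(9), n1):
            r1 = ranks[list(idx)].sum()
            u = r1 - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total)


class TestWelchT:
    def test_identical_samples(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_statistic_monotone_in_shift(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=20)
        t_prev = 0.0
        for shift in (0.5, 1.0, 2.0):
            res = two_sample_t(base, base + shift)
            assert abs(res.statistic) > abs(t_prev)
            t_prev = res.statistic

    def test_zero_variance_both_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


def test_load_table_with_column_map(tmp_path):
    p = tmp_path / "ids.csv"
    p.write_text(
        "Accession,Sequence,Cond,Rep,Intensity,q\nA,PEP,c1,1,100.0,0.001\n"
    )
    df = load_table(
        p,
        column_map={
            "protein": "Accession",
            "peptide": "Sequence",
            "condition": "Cond",
            "replicate": "Rep",
            "abundance": "Intensity",
            "q_value": "q",
        },
    )
    assert list(df["protein"]) == ["A"]


def test_load_table_missing_columns_rejected(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("protein\tpeptide\nA\tPEP\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_table(p)
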