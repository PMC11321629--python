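"""Fisher exact enrichment, Bonferroni adjustment, frequency and correlation reports."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact, rankdata

import diseasemap as dm


def enumeration_p(a, b, c, d, sided):
    """Exhaustive hypergeometric oracle over all tables with fixed margins."""
    n = a + b + c + d
    row = a + b
    col = a + c
    denom = math.comb(n, col)

    def table_prob(x):
        return math.comb(row, x) * math.comb(n - row, col - x) / denom

    lo = max(0, row + col - n)
    hi = min(row, col)
    if sided == "one-greater":
        return sum(table_prob(x) for x in range(a, hi + 1))
    p_obs = table_prob(a)
    return min(1.0, sum(
        table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= p_obs * (1 + 1e-7)
    ))


class TestFisherP:
    def test_worked_example(self):
        # 20 diseases, cluster of 5; feature in 4 cluster diseases and 1 outside
        p = dm.fisher_p(4, 1, 1, 14, sided="one-greater")
        assert p == pytest.approx(76 / 15504)

    def test_feature_in_every_disease(self):
        assert dm.fisher_p(5, 15, 0, 0, sided="one-greater") == pytest.approx(1.0)

    @pytest.mark.parametrize("sided", ["one-greater", "two"])
    def test_matches_enumeration_oracle_small_tables(self, sided):
        for n in range(2, 10):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        assert dm.fisher_p(a, b, c, d, sided) == pytest.approx(
                            enumeration_p(a, b, c, d, sided), abs=1e-12
                        )

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            table = [[a, b], [c, d]]
            assert dm.fisher_p(a, b, c, d, "one-greater") == pytest.approx(
                fisher_exact(table, alternative="greater")[1], abs=1e-10
            )
            assert dm.fisher_p(a, b, c, d, "two") == pytest.approx(
                fisher_exact(table, alternative="two-sided")[1], abs=1e-10
            )

    def test_monotone_in_enrichment(self):
        # shifting one association into the cluster at fixed margins lowers p
        p_weak = dm.fisher_p(3, 2, 2, 13, "one-greater")
        p_strong = dm.fisher_p(4, 1, 1, 14, "one-greater")
        assert p_strong < p_weak

    def test_two_sided_at_least_smaller_tail(self):
        # the minimum-likelihood two-sided p contains the tail in the
        # direction of the observed effect
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 10, size=4)
            directed = min(
                dm.fisher_p(a, b, c, d, "one-greater"),
                dm.fisher_p(b, a, d, c, "one-greater"),  # the "less" tail
            )
            assert dm.fisher_p(a, b, c, d, "two") >= directed - 1e-12


class TestBonferroni:
    def test_paper_style_multiplier(self):
        # p * clusters * features, capped at 1
        assert dm.bonferroni_adjust(1e-6, 71, 21020) == 1.0
        adj = dm.bonferroni_adjust(1e-10, 71, 21020)
        assert adj == pytest.approx(1.49242e-4, rel=1e-4)
        assert adj < 0.05

    def test_zero_stays_zero(self):
        assert dm.bonferroni_adjust(0.0, 71, 21020) == 0.0

    def test_order_preserving(self):
        ps = np.array([1e-9, 1e-6, 1e-3, 0.5])
        adj = dm.bonferroni_adjust(ps, 10, 100)
        assert (np.diff(adj) >= 0).all()

    def test_invalid_multipliers(self):
        with pytest.raises(dm.FormatError):
            dm.bonferroni_adjust(0.1, 0, 10)


def _toy_incidence():
    # 6 diseases, 3 features; d0-d2 share f0 heavily
    vals = np.array(
        [[1, 1, 0], [1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1], [0, 0, 1]],
        dtype=np.uint8,
    )
    return dm.IncidenceMatrix(
        [f"d{i}" for i in range(6)], ["f0", "f1", "f2"], vals, name="toy"
    )


class TestOneVsAll:
    def test_counts_and_pvalues(self):
        inc = _toy_incidence()
        assign = dm.ClusterAssignment(inc.disease_ids, [1, 1, 1, 2, 2, 2], 2)
        records = dm.fisher_one_vs_all(inc, assign, 1)
        by_feat = {r.feature_id: r for r in records}
        r = by_feat["f0"]
        assert (r.a, r.b, r.c, r.d) == (3, 0, 0, 3)
        assert r.p_nominal == pytest.approx(enumeration_p(3, 0, 0, 3, "one-greater"))
        assert r.a + r.b + r.c + r.d == inc.n_diseases
        assert r.p_adjusted == pytest.approx(min(1.0, r.p_nominal * 2 * 3))
        assert r.haldane  # zero cells present -> corrected odds ratio flagged

    def test_all_clusters_frame(self):
        inc = _toy_incidence()
        assign = dm.ClusterAssignment(inc.disease_ids, [1, 1, 1, 2, 2, 2], 2)
        frame = dm.enrich_all_clusters(inc, assign)
        assert len(frame) == 6  # 3 features x 2 clusters
        assert (frame["p_adjusted"] >= frame["p_nominal"] - 1e-15).all()


class TestPairwiseAndGroup:
    def test_equal_rates_not_enriched(self):
        vals = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.uint8)
        inc = dm.IncidenceMatrix(["a", "b", "c", "d"], ["f0", "f1"], vals)
        recs = dm.fisher_pairwise(inc, ["a", "b"], ["c", "d"])
        assert all(r.p_nominal >= 0.5 for r in recs)

    def test_skewed_table_matches_oracle(self):
        # cluster A: 6/8 associated, cluster B: 1/9 associated
        rows = [[1]] * 6 + [[0]] * 2 + [[1]] + [[0]] * 8
        ids = [f"d{i:02d}" for i in range(17)]
        inc = dm.IncidenceMatrix(ids, ["f0"], np.array(rows, dtype=np.uint8))
        a_ids, b_ids = ids[:8], ids[8:]
        (rec,) = dm.fisher_pairwise(inc, a_ids, b_ids)
        assert (rec.a, rec.b, rec.c, rec.d) == (6, 1, 2, 8)
        assert rec.p_nominal == pytest.approx(enumeration_p(6, 1, 2, 8, "one-greater"))

    def test_swapped_tails_cover_distribution(self):
        rows = [[1]] * 6 + [[0]] * 2 + [[1]] + [[0]] * 8
        ids = [f"d{i:02d}" for i in range(17)]
        inc = dm.IncidenceMatrix(ids, ["f0"], np.array(rows, dtype=np.uint8))
        (p_ab,) = [r.p_nominal for r in dm.fisher_pairwise(inc, ids[:8], ids[8:])]
        (p_ba,) = [r.p_nominal for r in dm.fisher_pairwise(inc, ids[8:], ids[:8])]
        assert p_ab + p_ba >= 1.0  # both tails include the observed table

    def test_symmetric_group_table_p_one(self):
        vals = np.array([[1], [0], [1], [0]], dtype=np.uint8)
        inc = dm.IncidenceMatrix(["a", "b", "c", "d"], ["f0"], vals)
        (rec,) = dm.fisher_group_vs_group(inc, ["a", "b"], ["c", "d"])
        assert rec.p_nominal == pytest.approx(1.0)
        assert rec.sided == "two"

    def test_overlapping_groups_rejected(self):
        inc = _toy_incidence()
        with pytest.raises(dm.FormatError, match="disjoint"):
            dm.fisher_pairwise(inc, ["d0", "d1"], ["d1", "d2"])


class TestFeatureFrequency:
    def test_toy_counting(self):
        t = dm.AssociationTable(
            "toy", frozenset({("d1", "g1"), ("d2", "g1"), ("d1", "g2")}), "gene"
        )
        freq = dm.feature_frequency(t)
        assert freq["feature_id"].tolist() == ["g1", "g2"]
        assert freq["n_diseases_linked"].tolist() == [2, 1]
        assert freq["rank"].tolist() == [1, 2]

    def test_ties_ordered_by_feature_id(self):
        t = dm.AssociationTable(
            "toy", frozenset({("d1", "gB"), ("d2", "gA")}), "gene"
        )
        assert dm.feature_frequency(t)["feature_id"].tolist() == ["gA", "gB"]

    def test_top_n_larger_than_feature_count(self):
        t = dm.AssociationTable("toy", frozenset({("d1", "g1")}), "gene")
        assert len(dm.feature_frequency(t, top_n=100)) == 1


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.array([1, 2, 3, 4, 5.0])
        assert dm.spearman_report(x, x ** 3)[0] == pytest.approx(1.0)
        assert dm.spearman_report(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 3.0, 1.0, 4.0, 4.0, 7.0, 6.0, 6.0])
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert dm.spearman_report(x, y)[0] == pytest.approx(oracle, abs=1e-12)

    def test_series_aligned_on_index_intersection(self):
        import pandas as pd

        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=["w", "x", "y", "z"])
        b = pd.Series([8.0, 4.0, 3.0, 2.0], index=["x", "y", "z", "q"])
        rho, _ = dm.spearman_report(a, b)
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(dm.FormatError):
            dm.spearman_report([1, 2], [2, 1])
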