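"""Reader-study statistics against independent oracles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from angiosynth.reader_stats import (
    TURING_DESIGN,
    RatingTable,
    TuringResponses,
    compare_groups,
    fleiss_kappa,
    load_ratings_csv,
    load_turing_csv,
    make_turing_design_fixture,
    pairwise_kappa,
    summarize_ratings,
    turing_confusion,
    wilcoxon_signed_rank,
)


class TestTuringConfusion:
    def _resp(self, truth, judged):
        n = len(truth)
        return TuringResponses(
            item_id=list(range(n)),
            stratum=["s"] * n,
            truth=np.array(truth),
            judgments=pd.DataFrame({"rater_1": judged}),
        )

    def test_perfect_discrimination(self):
        truth = ["real"] * 5 + ["generated"] * 5
        r = turing_confusion(self._resp(truth, truth), "rater_1")
        assert r["accuracy"] == 1.0

    def test_worked_2x2(self):
        truth = ["real"] * 10 + ["generated"] * 10
        judged = (["real"] * 8 + ["generated"] * 2) + (["real"] * 4 + ["generated"] * 6)
        r = turing_confusion(self._resp(truth, judged), "rater_1")
        assert r["accuracy"] == pytest.approx(0.7)
        assert r["sensitivity"] == pytest.approx(0.8)
        assert r["recall_generated"] == pytest.approx(0.6)
        assert sum(r["counts"].values()) == 20

    def test_coinflip_accuracy_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        truth = rng.choice(["real", "generated"], size=n)
        judged = rng.choice(["real", "generated"], size=n)
        r = turing_confusion(self._resp(truth, judged), "rater_1")
        assert r["accuracy"] == pytest.approx(0.5, abs=0.02)

    def test_unknown_rater(self):
        with pytest.raises(ValueError):
            turing_confusion(self._resp(["real", "generated"], ["real", "real"]), "rater_9")


class TestTuringDesign:
    def test_design_sums_to_200(self):
        assert sum(TURING_DESIGN.values()) == 200

    def test_fixture_loader_roundtrip(self, tmp_path):
        df = make_turing_design_fixture(seed=0, n_raters=5)
        path = tmp_path / "turing.csv"
        df.to_csv(path, index=False)
        resp = load_turing_csv(path)
        assert resp.n_items == 200
        assert len(resp.raters) == 5
        counts = pd.Series(resp.stratum).value_counts().to_dict()
        assert counts == TURING_DESIGN


class TestFleissKappa:
    def test_perfect_agreement(self):
        ratings = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_null_monte_carlo(self):
        rng = np.random.default_rng(1)
        ratings = rng.integers(0, 2, size=(2000, 5))
        assert fleiss_kappa(ratings) == pytest.approx(0.0, abs=0.02)

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(2)
        for _ in range(10):
            ratings = rng.integers(0, 3, size=(12, 4))
            table, _ = aggregate_raters(ratings)
            assert fleiss_kappa(ratings) == pytest.approx(sm_fleiss(table), abs=1e-12)

    def test_small_table_bruteforce(self):
        # direct evaluation of the formula on a worked 4x3 table
        ratings = np.array([[0, 0, 1], [1, 1, 1], [0, 1, 1], [0, 0, 0]])
        n_i, n_r = 4, 3
        counts = np.array([[2, 1], [0, 3], [1, 2], [3, 0]], dtype=float)
        p_bar = np.mean(((counts**2).sum(axis=1) - n_r) / (n_r * (n_r - 1)))
        p_cat = counts.sum(axis=0) / (n_i * n_r)
        expected = (p_bar - (p_cat**2).sum()) / (1 - (p_cat**2).sum())
        assert fleiss_kappa(ratings) == pytest.approx(expected, abs=1e-12)

    def test_single_category_sentinel(self):
        assert np.isnan(fleiss_kappa(np.zeros((5, 3), dtype=int)))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.zeros((1, 5), dtype=int))


class TestPairwiseKappa:
    def test_identical_lists(self):
        a = [1, 3, 5, 2, 4]
        assert pairwise_kappa(a, a) == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 6, size=5000)
        b = rng.integers(1, 6, size=5000)
        assert pairwise_kappa(a, b) == pytest.approx(0.0, abs=0.03)

    @pytest.mark.parametrize("weighting", ["none", "linear", "quadratic"])
    def test_against_sklearn_oracle(self, weighting):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(4)
        sk_w = {"none": None, "linear": "linear", "quadratic": "quadratic"}[weighting]
        for _ in range(10):
            a = rng.integers(1, 6, size=40)
            b = np.clip(a + rng.integers(-1, 2, size=40), 1, 5)
            labels = np.arange(min(a.min(), b.min()), max(a.max(), b.max()) + 1)
            expected = cohen_kappa_score(a, b, labels=labels, weights=sk_w)
            assert pairwise_kappa(a, b, weighting) == pytest.approx(expected, abs=1e-10)

    def test_worked_3x3_bruteforce(self):
        a = np.array([1, 1, 2, 2, 3, 3, 1, 2, 3])
        b = np.array([1, 2, 2, 2, 3, 1, 1, 2, 3])
        # unweighted: po and pe by hand
        po = np.mean(a == b)
        pe = sum(np.mean(a == k) * np.mean(b == k) for k in (1, 2, 3))
        expected = (po - pe) / (1 - pe)
        assert pairwise_kappa(a, b, "none") == pytest.approx(expected, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            pairwise_kappa([1], [1])
        with pytest.raises(ValueError):
            pairwise_kappa([1, 2], [1, 2], weighting="cubic")


def _bruteforce_wilcoxon(x, y):
    """Independent enumeration oracle for the two-sided exact p-value."""
    from scipy.stats import rankdata

    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return w_obs, count / 2**n


class TestWilcoxon:
    def test_all_zero_differences_sentinel(self):
        w, p = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert np.isnan(w) and np.isnan(p)

    def test_n5_all_positive_distinct(self):
        x = [10.0, 20.0, 30.0, 40.0, 50.0]
        y = [9.0, 17.0, 26.0, 35.0, 44.0]
        w, p = wilcoxon_signed_rank(x, y)
        assert w == 15.0
        assert p == pytest.approx(2 / 32)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.normal(size=n)
        y = x + rng.normal(size=n) * 0.8
        w, p = wilcoxon_signed_rank(x, y)
        w_b, p_b = _bruteforce_wilcoxon(x, y)
        assert w == pytest.approx(w_b)
        assert p == pytest.approx(p_b, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            _, p = wilcoxon_signed_rank(x, y)
            ref = scipy_wilcoxon(x, y, method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        _, p1 = wilcoxon_signed_rank(x, y)
        _, p2 = wilcoxon_signed_rank(y, x)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(13)
        x = rng.normal(0.3, 1, size=60)
        y = rng.normal(0, 1, size=60)
        _, p = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestCompareGroups:
    def test_chi_square_proportional_table(self):
        stat, p = compare_groups([[10, 20], [20, 40]], method="chi_square")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_kruskal_identical_groups(self):
        stat, _ = compare_groups([[1, 2, 3], [1, 2, 3]], method="kruskal_wallis")
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_mann_whitney_complete_separation(self):
        stat, _ = compare_groups([1, 2, 3], [4, 5, 6], method="mann_whitney")
        assert stat == 0.0

    def test_paired_t_runs(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.1, 2.2, 2.9], method="paired_t")
        assert np.isfinite(stat) and 0 <= p <= 1

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            compare_groups([1], [2], method="anova")


class TestRatings:
    def _table(self, real_scores, gen_scores, stratum="2D-IA"):
        rows = []
        for i, (r, g) in enumerate(zip(real_scores, gen_scores)):
            rows.append({"item_id": i, "stratum": stratum, "arm": "real",
                         "rater_1": r[0], "rater_2": r[1]})
            rows.append({"item_id": i, "stratum": stratum, "arm": "generated",
                         "rater_1": g[0], "rater_2": g[1]})
        return RatingTable(pd.DataFrame(rows))

    def test_all_fives(self):
        t = self._table([(5, 5)] * 4, [(5, 5)] * 4)
        rep = summarize_ratings(t)
        assert rep["overall"]["real"]["mean"] == 5.0
        assert rep["overall"]["real"]["sd"] == 0.0

    def test_sample_sd_closed_form(self):
        scores = np.array([5, 5, 4, 5], dtype=float)
        t = self._table([(5, 5), (4, 5)], [(5, 5), (4, 5)])
        rep = summarize_ratings(t)
        assert rep["overall"]["real"]["mean"] == pytest.approx(scores.mean())
        assert rep["overall"]["real"]["sd"] == pytest.approx(np.std(scores, ddof=1))

    def test_identical_arms_sentinel(self):
        t = self._table([(5, 4), (3, 4), (5, 5)], [(5, 4), (3, 4), (5, 5)])
        rep = summarize_ratings(t)
        assert np.isnan(rep["overall"]["wilcoxon_p"])

    def test_pairing_must_be_bijection(self):
        rows = [
            {"item_id": 0, "stratum": "s", "arm": "real", "rater_1": 5},
            {"item_id": 1, "stratum": "s", "arm": "generated", "rater_1": 4},
        ]
        with pytest.raises(ValueError, match="bijection"):
            RatingTable(pd.DataFrame(rows))

    def test_score_range_validated(self):
        rows = [
            {"item_id": 0, "stratum": "s", "arm": "real", "rater_1": 6},
            {"item_id": 0, "stratum": "s", "arm": "generated", "rater_1": 4},
        ]
        with pytest.raises(ValueError, match="1..5"):
            RatingTable(pd.DataFrame(rows))

    def test_ratings_csv_roundtrip(self, tmp_path):
        t = self._table([(5, 4), (4, 4)], [(5, 5), (3, 4)])
        path = tmp_path / "ratings.csv"
        t.table.to_csv(path, index=False)
        loaded = load_ratings_csv(path)
        assert loaded.raters == ["rater_1", "rater_2"]
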