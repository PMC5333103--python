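"""LOOCV protocol, PR curves, TPR@k, rank ratios and pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netprio import (GeneNetwork, DiseaseGeneSet, DataError,
                     SyntheticScenario, generate_scenario,
                     all_pairs_raw_distance, adjust_distance,
                     disease_weights, prioritize_disease,
                     loocv, loocv_pr, pr_curve, tpr_at_k, rank_ratio,
                     pooled_pr, convert_loocv_scores,
                     compare_raw_vs_adjusted,
                     mean_pairwise_disease_distance)


class TestLoocv:
    def test_minimum_k_two_folds(self, path_network):
        dm = all_pairs_raw_distance(path_network)
        adm = adjust_distance(dm)
        res = loocv(adm, DiseaseGeneSet("d", frozenset(["g1", "g3"])))
        assert res.k == 2
        pos = res.table[res.table["label"] == 1]
        assert len(pos) == 2 and pos["rank"].notna().all()

    def test_k_below_two_rejected(self, path_network):
        dm = all_pairs_raw_distance(path_network)
        adm = adjust_distance(dm)
        with pytest.raises(DataError):
            loocv(adm, DiseaseGeneSet("d", frozenset(["g1"])))

    def test_every_gene_scored_exactly_once(self, planted):
        _, ds, _, adm = planted
        res = loocv(adm, ds)
        assert len(res.table) == adm.n
        assert res.table["gene"].is_unique
        assert res.table["label"].sum() == res.k

    def test_held_out_scores_differ_from_full_set_scores(self, planted):
        _, ds, _, adm = planted
        res = loocv(adm, ds)
        full = disease_weights(adm, ds)
        pos = res.table[res.table["label"] == 1]
        for _, row in pos.head(3).iterrows():
            assert row["score"] != pytest.approx(
                full.weight_of(row["gene"]), rel=1e-12)

    def test_remove_then_readd_reproduces_full_weights(self, planted):
        _, ds, _, adm = planted
        g = sorted(ds.genes)[0]
        rebuilt = DiseaseGeneSet(ds.disease_id,
                                 ds.without(g).genes | {g})
        w1 = disease_weights(adm, ds).weights
        w2 = disease_weights(adm, rebuilt).weights
        np.testing.assert_array_equal(w1, w2)

    def test_planted_module_recovered(self, planted):
        _, ds, _, adm = planted
        res = loocv(adm, ds)
        pos = res.table[res.table["label"] == 1]
        assert pos["rank_ratio"].median() < 0.5
        # and far better than a permuted-label control
        rng = np.random.default_rng(0)
        scores = res.table["score"].to_numpy()
        labels = res.table["label"].to_numpy()
        null_auc = np.mean([pr_curve(scores, rng.permutation(labels)).auc
                            for _ in range(20)])
        assert loocv_pr(res).auc > 5 * null_auc


class TestPrCurve:
    def test_perfect_separation(self):
        scores = np.r_[np.linspace(2, 3, 5), np.linspace(0, 1, 20)]
        labels = np.r_[np.ones(5), np.zeros(20)].astype(int)
        c = pr_curve(scores, labels)
        assert c.auc == pytest.approx(1.0)
        assert c.fmax == pytest.approx(1.0)

    def test_hand_enumerated_four_thresholds(self):
        # pos 0.9, neg 0.8, pos 0.7, neg 0.1
        c = pr_curve([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        np.testing.assert_allclose(c.recall, [0.5, 0.5, 1.0, 1.0])
        np.testing.assert_allclose(c.precision, [1.0, 0.5, 2 / 3, 0.5])
        assert c.fmax == pytest.approx(0.8)

    def test_tied_scores_collapse_to_one_threshold(self):
        c = pr_curve([0.9, 0.9, 0.1], [1, 0, 0])
        assert len(c.thresholds) == 2
        np.testing.assert_allclose(c.precision, [0.5, 1 / 3])

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            pr_curve([1.0, 0.5], [1, 1])

    def test_recall_nondecreasing_and_bounds(self, planted):
        _, ds, _, adm = planted
        c = loocv_pr(loocv(adm, ds))
        assert np.all(np.diff(c.recall) >= 0)
        assert 0 <= c.auc <= 1 and 0 <= c.fmax <= 1

    def test_fmax_attained_on_curve(self, planted):
        _, ds, _, adm = planted
        c = loocv_pr(loocv(adm, ds))
        f1 = 2 * c.precision * c.recall / (c.precision + c.recall)
        assert c.fmax == pytest.approx(np.nanmax(f1))

    def test_plot_returns_axes(self):
        import matplotlib
        matplotlib.use("Agg")
        c = pr_curve([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        ax = c.plot(label="toy")
        assert ax.get_xlabel() == "recall"

    def test_matches_sklearn_points(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.3).astype(int)
        c = pr_curve(scores, labels)
        p_sk, r_sk, t_sk = sklearn.precision_recall_curve(labels, scores)
        # sklearn orders ascending thresholds and appends a (1, 0) anchor
        ours = {(round(r, 10), round(p, 10))
                for r, p in zip(c.recall, c.precision)}
        theirs = {(round(r, 10), round(p, 10))
                  for r, p in zip(r_sk[:-1], p_sk[:-1])}
        assert theirs <= ours


class TestTprAtK:
    def make_result(self, scores, labels):
        from netprio.evaluate import LoocvResult
        n = len(scores)
        table = pd.DataFrame({
            "gene": [f"g{i:03d}" for i in range(n)],
            "score": scores, "label": labels,
            "rank": np.nan, "rank_ratio": np.nan,
        })
        return LoocvResult("d", table, n, int(np.sum(labels)))

    def test_all_positives_on_top(self):
        res = self.make_result([5, 4, 3, 2, 1], [1, 1, 0, 0, 0])
        out = tpr_at_k(res, ks=[2])
        assert out["tpr"].iloc[0] == 1.0

    def test_no_positives_in_top_k(self):
        res = self.make_result([5, 4, 3, 2, 1], [0, 0, 0, 1, 1])
        assert tpr_at_k(res, ks=[2])["tpr"].iloc[0] == 0.0

    def test_whole_list_gives_prevalence(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(40) < 0.25).astype(int)
        res = self.make_result(rng.normal(size=40), labels)
        out = tpr_at_k(res, ks=[40])
        assert out["tpr"].iloc[0] == pytest.approx(labels.mean())

    def test_recall_mode_divides_by_k_disease(self):
        res = self.make_result([5, 4, 3, 2, 1], [1, 0, 1, 0, 0])
        prec = tpr_at_k(res, ks=[1], mode="precision")["tpr"].iloc[0]
        rec = tpr_at_k(res, ks=[1], mode="recall")["tpr"].iloc[0]
        assert prec == 1.0 and rec == 0.5

    def test_k_out_of_range_rejected(self):
        res = self.make_result([1, 2], [0, 1])
        with pytest.raises(DataError):
            tpr_at_k(res, ks=[3])


class TestRankRatio:
    def ranking(self, n, unranked=0):
        return pd.DataFrame({
            "rank": np.arange(1, n + unranked + 1),
            "gene": [f"g{i:03d}" for i in range(n + unranked)],
            "unranked": [False] * n + [True] * unranked,
        })

    def test_first_of_hundred(self):
        assert rank_ratio(self.ranking(100), "g000") == pytest.approx(0.01)

    def test_last_is_one(self):
        assert rank_ratio(self.ranking(50), "g049") == pytest.approx(1.0)

    def test_absent_gene_rejected(self):
        with pytest.raises(DataError):
            rank_ratio(self.ranking(10), "nope")

    def test_uniform_random_placement_centers_at_half(self):
        rng = np.random.default_rng(8)
        n = 101
        medians = [np.median(rng.integers(1, n + 1, size=51)) / n
                   for _ in range(200)]
        assert np.mean(medians) == pytest.approx(0.5, abs=0.03)


class TestPooling:
    def labeled(self, seed, skill):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(10), np.zeros(90)].astype(int)
        scores = rng.normal(size=100) + skill * labels
        return scores, labels

    def test_duplicated_disease_preserves_auc(self):
        s, l = self.labeled(1, 3.0)
        single = pr_curve(s, l).auc
        assert pooled_pr([(s, l), (s, l)]).auc == pytest.approx(single)

    def test_pooling_perfect_and_random_lies_between(self):
        sp, lp = self.labeled(2, 100.0)   # effectively perfect
        sr, lr = self.labeled(3, 0.0)
        a_perfect = pr_curve(sp, lp).auc
        a_random = pr_curve(sr, lr).auc
        pooled = pooled_pr([(sp, lp), (sr, lr)]).auc
        assert a_random < pooled < a_perfect

    def test_positive_count_conserved(self):
        s1, l1 = self.labeled(4, 1.0)
        s2, l2 = self.labeled(5, 1.0)
        c = pooled_pr([(s1, l1), (s2, l2)])
        assert c.recall[-1] == 1.0
        # weakest threshold admits all: precision = pooled prevalence
        assert c.precision[-1] == pytest.approx((l1.sum() + l2.sum()) / 200)

    def test_single_disease_rejected(self):
        s, l = self.labeled(6, 1.0)
        with pytest.raises(DataError):
            pooled_pr([(s, l)])

    def test_converted_scores_are_stepwise_precisions(self, planted):
        _, ds, _, adm = planted
        res = loocv(adm, ds)
        conv = convert_loocv_scores(res)
        s = conv["score"].to_numpy()
        lab = conv["label"].to_numpy()
        for i in range(0, len(conv), 61):
            mask = s >= s[i]
            assert conv["converted"].iloc[i] == pytest.approx(
                lab[mask].sum() / mask.sum())


class TestCompareRawVsAdjusted:
    def test_hub_fixture_adjustment_not_worse(self, hub_world):
        net, ds, hub, _, _ = hub_world
        out = compare_raw_vs_adjusted(net, [ds])
        row = out.iloc[0]
        assert row["fmax_adjusted"] >= row["fmax_raw"]
        assert row["stratum"] == "<=10"

    def test_scattered_module_reported_without_assertion(self, planted):
        net, _, dm, _ = planted
        rng = np.random.default_rng(9)
        scattered = DiseaseGeneSet(
            "scattered", frozenset(rng.choice(dm.genes, 15, replace=False)))
        out = compare_raw_vs_adjusted(net, [scattered])
        assert np.isfinite(out["fmax_adjusted"]).all()

    def test_mean_pairwise_distance_brute_force(self, planted):
        _, ds, dm, _ = planted
        got = mean_pairwise_disease_distance(dm, ds)
        idx = [dm.index_of(g) for g in sorted(ds.genes)]
        pairs = [(i, j) for a, i in enumerate(idx) for j in idx[a + 1:]]
        expected = np.mean([dm.values[i, j] for i, j in pairs])
        assert got == pytest.approx(expected, rel=1e-12)


class TestParameterRecovery:
    def test_module_beats_degree_matched_control(self):
        """Planted module LOOCV outranks a degree-matched random gene set."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            net, sets = generate_scenario(SyntheticScenario(seed=seed))
            dm = all_pairs_raw_distance(net)
            adm = adjust_distance(dm)
            ds = sets[0]
            deg = net.degrees()
            rng = np.random.default_rng(seed + 1000)
            pool = [g for g in adm.genes if g not in ds.genes]
            pool.sort(key=lambda g: deg[g])
            control = set()
            for g in sorted(ds.genes):
                ranked = sorted((abs(deg[c] - deg[g]), c) for c in pool
                                if c not in control)
                # nearest-degree candidates; pick one at random among top 5
                cands = [c for _, c in ranked[:5]]
                control.add(cands[rng.integers(len(cands))])
            ctrl = DiseaseGeneSet("control", frozenset(control))
            rr_mod = loocv(adm, ds).table.query("label == 1")["rank_ratio"].mean()
            rr_ctl = loocv(adm, ctrl).table.query("label == 1")["rank_ratio"].mean()
            wins += rr_mod < rr_ctl
        p = stats.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
        assert p < 0.05
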