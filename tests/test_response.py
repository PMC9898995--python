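import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ddcpredict.clustering import DdcModel
from ddcpredict.diffexpr import DEGResult
from ddcpredict.io import ExpressionMatrix
from ddcpredict.response import (
    ClusterResponseModel,
    ResponseCohort,
    auc_ci_delong,
    classification_metrics,
    lasso_cv,
    rank_selected_genes,
    response_deg_overlap,
    roc_auc,
    smote,
    split_train_test,
)
from ddcpredict.synthetic import simulate_network, simulate_response_cohort


def _cohort(n_resp=80, n_non=29, n_genes=6, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    n = n_resp + n_non
    samples = [f"s{i}" for i in range(n)]
    labels = {s: ("responder" if i < n_resp else "non-responder")
              for i, s in enumerate(samples)}
    data = pd.DataFrame(rng.normal(7, 1, size=(n_genes, n)), index=genes, columns=samples)
    return ResponseCohort(ExpressionMatrix("coh", "panel", data, labels))


class TestSplit:
    def test_stratification_arithmetic(self):
        cohort = _cohort(80, 29)
        train, test = split_train_test(cohort, ratio=0.8, seed=0)
        lab = cohort.matrix.labels
        n_resp_train = sum(lab[s] == "responder" for s in train)
        n_non_train = sum(lab[s] == "non-responder" for s in train)
        assert abs(n_resp_train - 64) <= 1
        assert abs(n_non_train - 23) <= 1
        assert len(train) + len(test) == 109
        assert not set(train) & set(test)

    def test_deterministic(self):
        cohort = _cohort()
        assert split_train_test(cohort, seed=5) == split_train_test(cohort, seed=5)

    def test_minimum_class_size_enforced(self):
        cohort = _cohort(10, 4)
        with pytest.raises(ValueError):
            split_train_test(cohort)


class TestSmote:
    def test_synthetic_points_on_segment(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0], [6.0, 4.0], [7.0, 5.0]])
        y = np.array([1, 1, 0, 0, 0])
        bx, by = smote(x, y, k=1, seed=0)
        new = bx[len(x):]
        assert len(new) == 1
        t = new[0, 0]
        assert 0.0 <= t <= 1.0
        assert new[0, 1] == pytest.approx(t)  # on the segment (0,0)-(1,1)

    def test_balanced_input_unchanged(self):
        x = np.arange(8.0).reshape(4, 2)
        y = np.array([0, 0, 1, 1])
        bx, by = smote(x, y, k=1, seed=0)
        assert np.array_equal(bx, x) and np.array_equal(by, y)

    def test_output_balanced_at_study_imbalance(self):
        # 2.76:1 at n = 94 -> 69 majority / 25 minority
        rng = np.random.default_rng(0)
        x = rng.normal(size=(94, 5))
        y = np.array([1] * 69 + [0] * 25)
        bx, by = smote(x, y, k=5, seed=1)
        counts = np.bincount(by)
        assert abs(counts[0] - counts[1]) <= 1

    def test_convex_hull_property(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 3))
        y = np.array([1] * 24 + [0] * 6)
        bx, _ = smote(x, y, k=3, seed=3)
        minority = x[y == 0]
        new = bx[30:]
        assert new.min() >= minority.min() - 1e-12
        assert new.max() <= minority.max() + 1e-12

    def test_small_minority_handled(self):
        x = np.arange(20.0).reshape(10, 2)
        y = np.array([1] * 7 + [0] * 3)
        with pytest.warns(UserWarning):
            bx, by = smote(x, y, k=5, seed=0)
        assert np.bincount(by)[0] == 7
        with pytest.raises(ValueError):
            smote(x, np.array([1] * 9 + [0]), k=5)


class TestRocAuc:
    def test_hand_examples(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.9, 0.3, 0.8, 0.4], [1, 1, 0, 0]) == 0.5
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 9)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            s = rng.integers(0, 4, size=n).astype(float)  # many ties
            pos = s[y == 1]
            neg = s[y == 0]
            brute = np.mean([
                1.0 if a > b else 0.5 if a == b else 0.0
                for a, b in itertools.product(pos, neg)
            ])
            assert roc_auc(s, y) == pytest.approx(brute)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=100)
        y = (rng.random(100) < 0.4).astype(int)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDelongCi:
    def test_perfect_separation_degenerate_interval(self):
        with pytest.warns(UserWarning):
            lo, hi = auc_ci_delong([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (lo, hi) == (1.0, 1.0)

    def test_sign_reversal_symmetry(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        lo, hi = auc_ci_delong(s, y)
        lo2, hi2 = auc_ci_delong(-s, y)
        assert lo2 == pytest.approx(1 - hi, abs=1e-12)
        assert hi2 == pytest.approx(1 - lo, abs=1e-12)

    def test_null_coverage(self):
        rng = np.random.default_rng(3)
        covered = 0
        reps = 300
        for _ in range(reps):
            s = rng.normal(size=100)
            y = np.array([1] * 50 + [0] * 50)
            lo, hi = auc_ci_delong(s, y)
            covered += lo <= 0.5 <= hi
        assert 0.91 <= covered / reps <= 0.985


class TestClassificationMetrics:
    def test_hand_confusion(self):
        pred = [1] * 6 + [0] * 22
        truth = [1] * 5 + [0] + [1] * 2 + [0] * 20
        m = classification_metrics(pred, truth)
        assert (m.tp, m.fp, m.fn, m.tn) == (5, 1, 2, 20)
        assert m.precision == pytest.approx(0.833, abs=1e-3)
        assert m.recall == pytest.approx(0.714, abs=1e-3)
        assert m.f1 == pytest.approx(0.769, abs=1e-3)

    def test_perfect_and_inverted(self):
        y = [1, 0, 1, 0]
        perfect = classification_metrics(y, y)
        assert (perfect.accuracy, perfect.precision, perfect.recall, perfect.f1) == (1, 1, 1, 1)
        inverted = classification_metrics([0, 1, 0, 1], y)
        assert inverted.recall == 0.0

    def test_no_predicted_positives_warns(self):
        with pytest.warns(UserWarning):
            m = classification_metrics([0, 0, 0], [1, 0, 1])
        assert np.isnan(m.precision)


class TestLassoCv:
    def test_path_head_is_null_model(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 10))
        y = (rng.random(60) < 0.4).astype(int)
        fit = lasso_cv(x, y, [f"g{i}" for i in range(10)], folds=5, seed=0)
        # refit at the path head: all-zero coefficients, intercept = log-odds
        from ddcpredict.response import _path_fits
        z = (x - fit.feature_mean) / fit.feature_sd
        head = next(iter(_path_fits(z, y, fit.lambda_path[:1])))
        assert np.allclose(head.coef_, 0.0)
        expected = np.log(y.mean() / (1 - y.mean()))
        assert head.intercept_[0] == pytest.approx(expected, abs=1e-3)

    def test_planted_coefficients_recovered(self):
        rng = np.random.default_rng(1)
        recovered, false_pos = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p = 200, 60
            x = rng.normal(size=(n, p))
            beta = np.zeros(p)
            planted = [3, 11, 25, 40, 55]
            beta[planted] = [2, -2, 2, -2, 2]
            prob = 1 / (1 + np.exp(-(x @ beta)))
            y = (rng.random(n) < prob).astype(int)
            fit = lasso_cv(x, y, [f"g{i}" for i in range(p)], folds=10, seed=seed)
            sel = {int(g[1:]) for g in fit.selected_genes}
            recovered.append(len(sel & set(planted)))
            false_pos.append(len(sel - set(planted)))
        assert np.mean([r >= 4 for r in recovered]) >= 0.8
        # signs of recovered planted coefficients match the truth
        for g, c in fit.coefficients.items():
            i = int(g[1:])
            if i in planted:
                assert np.sign(c) == np.sign(beta[i])

    def test_selected_exactly_nonzero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 15))
        y = (rng.random(80) < 0.5).astype(int)
        fit = lasso_cv(x, y, [f"g{i}" for i in range(15)], folds=5, seed=2)
        assert set(fit.selected_genes) == set(fit.coefficients)

    def test_insufficient_class_count_rejected(self):
        x = np.zeros((12, 3))
        y = np.array([1] * 9 + [0] * 3)
        with pytest.raises(ValueError):
            lasso_cv(x, y, ["a", "b", "c"], folds=5)


class TestRankSelectedGenes:
    def test_star_center_ranks_first(self):
        g, _ = simulate_network(node_names=[f"n{i}" for i in range(8)],
                                planted_on=[], background_p=0.0, seed=0)
        g.add_edges_from([("hub", f"n{i}") for i in range(8)])
        table = rank_selected_genes(g, ["hub"] + [f"n{i}" for i in range(8)], k=3)
        t = table.table
        assert t["degree"].idxmax() == "hub"
        assert bool(t.at["hub", "in_top_degree"])

    def test_high_rank_response_deg_flagged(self):
        import networkx as nx
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(6)})
        degs = [DEGResult("v0", 1.5, 3, 0.001, 0.01, "up")]
        table = rank_selected_genes(g, list(g.nodes), k=3, response_degs=degs)
        assert table.flagged == ["v0"]

    def test_no_deg_flag_warns(self):
        import networkx as nx
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(4)})
        with pytest.warns(UserWarning):
            table = rank_selected_genes(g, list(g.nodes), k=2, response_degs=[])
        assert table.flagged == []

    def test_empty_subgraph_rejected(self):
        import networkx as nx
        g = nx.empty_graph(5)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(5)})
        with pytest.raises(ValueError):
            rank_selected_genes(g, ["v0", "v1"])


class TestResponseDegOverlap:
    def _ddc(self, assignment):
        k = max(assignment.values())
        return DdcModel(k=k, assignment=assignment, centroids=np.empty(0),
                        total_wss=0.0, wss_curve={}, chosen_k=k, seed=0)

    def _deg(self, gene, logfc, direction):
        return DEGResult(gene, logfc, 0, 0.01, 0.01, direction)

    def test_counting_and_direction(self):
        ddc = self._ddc({"a": 6, "b": 6, "c": 6, "d": 2})
        degs = [self._deg("a", 1.5, "up"), self._deg("b", 2.0, "up"),
                self._deg("c", -1.2, "down"), self._deg("d", 1.1, "up")]
        overlap = response_deg_overlap(degs, ddc, logfc_threshold=1.0)
        frac, frac_up = overlap[6]
        assert frac == pytest.approx(0.75)
        assert frac_up == pytest.approx(2 / 3)
        assert overlap[2][0] == pytest.approx(0.25)

    def test_threshold_excludes_small_effects(self):
        ddc = self._ddc({"a": 1, "b": 1})
        degs = [self._deg("a", 0.9, "up"), self._deg("b", 1.0, "up")]
        overlap = response_deg_overlap(degs, ddc, logfc_threshold=1.0)
        assert overlap[1][0] == pytest.approx(1.0)  # only b counts, all in cluster 1

    def test_no_passing_deg_warns_with_zeros(self):
        ddc = self._ddc({"a": 1})
        with pytest.warns(UserWarning):
            overlap = response_deg_overlap([self._deg("a", 0.5, "up")], ddc)
        assert overlap[1] == (0.0, 0.0)


class TestPerClusterPipeline:
    def test_null_cohort_auc_near_half(self):
        aucs = []
        for seed in range(3):
            cohort_m, truth = simulate_response_cohort(
                n_patients=150, coef_scale=0.0, n_panel_genes=60, n_blocks=3,
                block_rhos=(0.5, 0.0, -0.5), predictive_block=2, seed=seed,
            )
            assignment = {g: b for b, gl in truth.planted_blocks.items() for g in gl}
            res = ClusterResponseModel.from_dataframe(
                cohort_m.data, cohort_m.labels, assignment
            ).fit(seed=seed)
            aucs.extend(r.auc_test for r in res.reports)
        assert 0.5 - 0.2 <= np.mean(aucs) <= 0.5 + 0.2

    def test_deterministic_rerun(self):
        cohort_m, truth = simulate_response_cohort(
            n_patients=120, n_panel_genes=40, n_blocks=2,
            block_rhos=(0.4, -0.4), predictive_block=1, n_predictive=3, seed=4,
        )
        assignment = {g: b for b, gl in truth.planted_blocks.items() for g in gl}
        model = ClusterResponseModel.from_dataframe(cohort_m.data, cohort_m.labels, assignment)
        a = model.fit(seed=1)
        b = model.fit(seed=1)
        assert [r.to_dict() for r in a.reports] == [r.to_dict() for r in b.reports]

    def test_summary_mentions_best_cluster(self):
        cohort_m, truth = simulate_response_cohort(
            n_patients=120, n_panel_genes=40, n_blocks=2,
            block_rhos=(0.4, -0.4), predictive_block=1, n_predictive=3, seed=4,
        )
        assignment = {g: b for b, gl in truth.planted_blocks.items() for g in gl}
        res = ClusterResponseModel.from_dataframe(
            cohort_m.data, cohort_m.labels, assignment
        ).fit(seed=1)
        text = res.summary()
        assert "Best cluster" in text and "auc_test" in text
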