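import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import separable_records
from ffproteo.cohort import CohortConfig, SampleRecord, simulate_cohort
from ffproteo.forest import (ForestParams, ProteinScoreTable, _mdi_array,
                             accumulate_scores, audit_forest,
                             balanced_accuracy, class_weights,
                             evaluate_final_classifier, gini_impurity,
                             grouped_kfold, mdi_importances, rfecv_run,
                             select_outlier_proteins, train_forest)


class TestGini:
    def test_pure_set_is_zero(self):
        assert gini_impurity({"pcos": 10, "control": 0}) == 0.0

    def test_balanced_is_half(self):
        assert gini_impurity({"pcos": 5, "control": 5}) == 0.5

    def test_quarter_three_quarters(self):
        assert gini_impurity({"pcos": 1, "control": 3}) == pytest.approx(0.375)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity({"pcos": 0.0, "control": 0.0})

    @given(st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_label_swap(self, a, b):
        if a + b == 0:
            return
        g = gini_impurity({"pcos": a, "control": b})
        assert 0.0 <= g <= 0.5
        assert g == pytest.approx(gini_impurity({"pcos": b, "control": a}))
        if a == 0 or b == 0:
            assert g == 0.0


class TestClassWeights:
    def test_balanced_all_equal(self):
        w = class_weights(["pcos", "pcos", "control", "control"])
        assert np.allclose(w, w[0])

    def test_imbalanced_ratio(self):
        w = class_weights(["pcos"] + ["control"] * 4)
        assert w[0] / w[1] == pytest.approx(4.0)

    def test_study_fluid_counts_ratio(self):
        labels = ["pcos"] * 112 + ["control"] * 110
        w = class_weights(labels)
        assert w[0] / w[-1] == pytest.approx(110 / 112)

    def test_per_class_totals_equal_one(self):
        w = class_weights(["pcos"] * 3 + ["control"] * 7)
        assert np.sum(w[:3]) == pytest.approx(1.0)
        assert np.sum(w[3:]) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(["pcos", "pcos"])


def _records_for_patients(n_patients, fluids_each=1, repeats=2):
    records = []
    for i in range(n_patients):
        group = "pcos" if i % 2 == 0 else "control"
        for f in range(fluids_each):
            for r in range(1, repeats + 1):
                records.append(SampleRecord(f"P{i}", group, f"F{i}_{f}", r))
    return records


class TestGroupedKFold:
    def test_one_patient_per_fold(self):
        records = _records_for_patients(20)
        folds = grouped_kfold(records, n_folds=20, seed=0)
        counts = {}
        for p, f in folds.fold_of_patient.items():
            counts[f] = counts.get(f, 0) + 1
        assert sorted(counts) == list(range(1, 21))
        assert all(c == 1 for c in counts.values())

    def test_74_patients_20_folds(self):
        records = _records_for_patients(74)
        folds = grouped_kfold(records, n_folds=20, seed=1)
        sizes = sorted(
            list(folds.fold_of_patient.values()).count(f)
            for f in range(1, 21))
        assert sizes.count(3) == 6 and sizes.count(4) == 14

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(_records_for_patients(5), n_folds=20, seed=0)

    def test_rows_of_patient_share_fold_and_partition(self):
        records = _records_for_patients(25, fluids_each=2, repeats=3)
        folds = grouped_kfold(records, n_folds=10, seed=3)
        all_test = []
        for train_idx, test_idx in folds.iter_splits(records):
            test_patients = {records[i].patient_id for i in test_idx}
            train_patients = {records[i].patient_id for i in train_idx}
            assert not test_patients & train_patients
            all_test.extend(test_idx)
        assert sorted(all_test) == list(range(len(records)))

    def test_deterministic_under_seed(self):
        records = _records_for_patients(30)
        a = grouped_kfold(records, 5, seed=7)
        b = grouped_kfold(records, 5, seed=7)
        assert a.fold_of_patient == b.fold_of_patient


class TestBalancedAccuracy:
    def test_perfect(self):
        assert balanced_accuracy(["pcos", "control"], ["pcos", "control"]) == 1.0

    def test_constant_prediction(self):
        assert balanced_accuracy(["pcos", "control"], ["pcos", "pcos"]) == 0.5

    def test_mean_of_recalls(self):
        y_true = ["p", "p", "p", "p", "c", "c"]
        y_pred = ["p", "p", "c", "c", "c", "c"]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(["p", "p"], ["p", "c"])


class TestTrainForest:
    def test_separable_in_sample(self):
        X, y, _ = separable_records(60)
        model = train_forest(X, y, class_weights(y), ForestParams(seed=0))
        assert balanced_accuracy(y, model.predict(X)) == 1.0

    def test_single_class_predicts_it_everywhere(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = np.array(["pcos"] * 40)
        model = train_forest(X, y, np.ones(40), ForestParams(seed=0))
        assert set(model.predict(X)) == {"pcos"}

    def test_too_few_rows_gives_single_leaves(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))  # 40 < 2 * 30
        y = np.array(["pcos"] * 25 + ["control"] * 15)
        model = train_forest(X, y, np.ones(40), ForestParams(seed=0))
        for tree in model.trees:
            assert tree.node_count == 1
        # weighted majority everywhere
        assert set(model.predict(rng.normal(size=(10, 3)))) == {"pcos"}

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError):
            train_forest(np.zeros((4, 2)), ["pcos"] * 3, np.ones(4),
                         ForestParams())

    def test_deterministic_under_seed(self):
        X, y, _ = separable_records(40)
        a = train_forest(X, y, class_weights(y), ForestParams(seed=5))
        b = train_forest(X, y, class_weights(y), ForestParams(seed=5))
        assert np.array_equal(_mdi_array(a), _mdi_array(b))

    def test_structural_audit_default_params(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 10))
        y = np.where(X[:, 0] + rng.normal(scale=0.5, size=200) > 0,
                     "pcos", "control")
        model = train_forest(X, y, class_weights(y), ForestParams(seed=1))
        for audit in audit_forest(model):
            assert audit["depth"] <= 3
            assert audit["min_leaf_rows"] >= 30


def brute_force_mdi(model, X, y, weights):
    """Oracle: route rows through stored splits, recompute impurities from the
    labels, and accumulate weighted impurity decreases."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    w = np.asarray(weights, dtype=float)
    w = w * (n / w.sum())
    p = len(model.feature_ids)
    total = np.zeros(p)
    for tree in model.trees:
        imp = np.zeros(p)

        def node_gini(mask):
            ww = {c: w[mask & (y == c)].sum() for c in np.unique(y)}
            return gini_impurity(ww), sum(ww.values())

        def walk(node, mask):
            left, right = tree.children_left[node], tree.children_right[node]
            if left == -1:
                return
            feat, thr = tree.feature[node], tree.threshold[node]
            lmask = mask & (X[:, feat] <= thr)
            rmask = mask & (X[:, feat] > thr)
            g, wt = node_gini(mask)
            gl, wl = node_gini(lmask)
            gr, wr = node_gini(rmask)
            imp[feat] += (wt * g - wl * gl - wr * gr) / w.sum()
            walk(left, lmask)
            walk(right, rmask)

        walk(0, np.ones(n, dtype=bool))
        total += imp
    total /= len(model.trees)
    s = total.sum()
    return total / s if s > 0 else total


class TestMDI:
    def test_single_leaf_forest_all_zero(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        y = np.array(["pcos"] * 6 + ["control"] * 4)
        model = train_forest(X, y, np.ones(10), ForestParams(seed=0))
        assert all(v == 0 for v in mdi_importances(model).values())

    def test_only_split_feature_gets_full_importance(self):
        X, y, _ = separable_records(60)
        X = np.column_stack([X[:, 0], np.zeros(len(y))])  # feature 1 constant
        model = train_forest(X, y, class_weights(y),
                             ForestParams(seed=0, features_per_split=2))
        imp = mdi_importances(model)
        assert imp["0"] == pytest.approx(1.0)
        assert imp["1"] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 5))
        y = np.where(X[:, 1] - 0.5 * X[:, 3]
                     + rng.normal(scale=0.7, size=150) > 0, "pcos", "control")
        w = class_weights(y)
        model = train_forest(
            X, y, w, ForestParams(n_trees=5, min_samples_leaf=10,
                                  bootstrap_rows=False, seed=4))
        reported = np.array([mdi_importances(model)[str(j)] for j in range(5)])
        oracle = brute_force_mdi(model, X, y, w)
        assert np.allclose(reported, oracle, atol=1e-10)


def _signal_dataset(effect=1.0, n_per_group=40, n_noise=10, seed=0):
    cfg = CohortConfig(n_pcos_patients=n_per_group,
                       n_control_patients=n_per_group,
                       n_proteins=n_noise + 5,
                       effects=tuple((j, effect) for j in range(5)),
                       patient_sd=0.1, fluid_sd=0.08, repeat_sd=0.12,
                       seed=seed)
    return simulate_cohort(cfg)


class TestRfecv:
    def test_constant_feature_eliminated_first(self):
        X, y, records = separable_records(60)
        X = np.column_stack([X[:, 0], np.full(len(y), 3.0)])
        params = ForestParams(min_samples_leaf=5, seed=0)
        res = rfecv_run(X, y, records, params, n_folds=5,
                        feature_ids=["signal", "constant"])
        assert res.per_protein_cycle_score["constant"] == 0
        assert res.per_protein_cycle_score["signal"] == 1
        assert res.optimal_feature_count in (1, 2)

    def test_informative_features_retained(self):
        hits = 0
        for seed in range(10):
            d = _signal_dataset(effect=1.0, n_per_group=20, n_noise=25,
                                seed=seed)
            params = ForestParams(min_samples_leaf=20, seed=seed)
            res = rfecv_run(d.intensities, d.labels, d.rows, params,
                            n_folds=5, step=0.3,
                            feature_ids=d.protein_ids)
            scores = res.per_protein_cycle_score
            top5 = sorted(scores, key=lambda k: -scores[k])[:5]
            if set(top5) == set(d.protein_ids[:5]):
                hits += 1
        assert hits >= 9

    def test_all_noise_accuracy_near_half(self):
        accs = []
        for seed in range(10):
            cfg = CohortConfig(n_pcos_patients=15, n_control_patients=15,
                               n_proteins=8, seed=seed)
            d = simulate_cohort(cfg)
            res = rfecv_run(d.intensities, d.labels, d.rows,
                            ForestParams(seed=seed), n_folds=5, step=0.5,
                            feature_ids=d.protein_ids)
            accs.append(np.mean(list(res.mean_accuracy_by_count.values())))
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_deterministic(self):
        d = _signal_dataset(n_per_group=15, n_noise=6, seed=3)
        params = ForestParams(seed=11)
        a = rfecv_run(d.intensities, d.labels, d.rows, params, n_folds=5,
                      step=0.5, feature_ids=d.protein_ids)
        b = rfecv_run(d.intensities, d.labels, d.rows, params, n_folds=5,
                      step=0.5, feature_ids=d.protein_ids)
        assert a.per_protein_cycle_score == b.per_protein_cycle_score
        assert a.optimal_feature_count == b.optimal_feature_count


class TestAccumulateScores:
    def test_single_cycle_equals_rfecv(self):
        d = _signal_dataset(n_per_group=15, n_noise=6, seed=2)
        params = ForestParams()
        table = accumulate_scores(d.intensities, d.labels, d.rows, params,
                                  n_folds=5, n_cycles=1, step=0.5,
                                  feature_ids=d.protein_ids, seed=21)
        tie_ss, cycle_ss = np.random.SeedSequence(21).spawn(2)
        tie_rank = np.random.default_rng(tie_ss).permutation(
            d.intensities.shape[1])
        res = rfecv_run(d.intensities, d.labels, d.rows,
                        ForestParams(seed=int(cycle_ss.generate_state(1)[0])),
                        n_folds=5, step=0.5, feature_ids=d.protein_ids,
                        tie_rank=tie_rank)
        assert table.score == {k: float(v)
                               for k, v in res.per_protein_cycle_score.items()}

    def test_same_master_seed_identical(self):
        d = _signal_dataset(n_per_group=15, n_noise=6, seed=2)
        kw = dict(n_folds=5, n_cycles=2, step=0.5,
                  feature_ids=d.protein_ids, seed=8)
        a = accumulate_scores(d.intensities, d.labels, d.rows,
                              ForestParams(), **kw)
        b = accumulate_scores(d.intensities, d.labels, d.rows,
                              ForestParams(), **kw)
        assert a.score == b.score

    def test_scores_nonnegative_and_bounded(self):
        d = _signal_dataset(n_per_group=15, n_noise=6, seed=4)
        table = accumulate_scores(d.intensities, d.labels, d.rows,
                                  ForestParams(), n_folds=5, n_cycles=2,
                                  step=1, feature_ids=d.protein_ids, seed=0)
        p = len(d.protein_ids)
        assert all(0 <= v <= 2 * (p - 1) for v in table.score.values())


class TestSelectOutliers:
    def test_all_equal_empty(self):
        table = ProteinScoreTable(score={f"p{i}": 6.0 for i in range(10)})
        assert select_outlier_proteins(table) == set()

    def test_four_extremes_selected(self):
        score = {f"bg{i}": 6.0 + (i % 3) for i in range(480)}
        score.update({f"hit{i}": 330.0 for i in range(4)})
        table = ProteinScoreTable(score=score)
        assert select_outlier_proteins(table) == {f"hit{i}" for i in range(4)}
        assert table.selected["hit0"] and not table.selected["bg0"]

    def test_table2_like_distribution_selects_about_20(self):
        # background: median 6, IQR 9.5; outliers mimic the reported scores
        bg = np.clip(np.linspace(-3.5, 15.5, 464), 0, None)
        outliers = [330, 330, 330, 330, 324, 301, 210, 178, 146, 128, 93, 83,
                    59, 55, 51, 49, 48, 46, 44, 44]
        score = {f"bg{i}": float(v) for i, v in enumerate(bg)}
        score.update({f"hit{i}": float(v) for i, v in enumerate(outliers)})
        table = ProteinScoreTable(score=score)
        selected = select_outlier_proteins(table)
        assert {f"hit{i}" for i in range(20)} <= selected
        assert len(selected) <= 30

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError):
            select_outlier_proteins(ProteinScoreTable(score={"a": 1.0}))


class TestFinalClassifier:
    def test_separable_protein_high_accuracy(self):
        X, y, records = separable_records(60)
        acc = evaluate_final_classifier(X[:, :1], y, records,
                                        ForestParams(seed=0), n_folds=5)
        assert acc >= 0.95

    def test_noise_proteins_near_half(self):
        accs = []
        for seed in range(10):
            cfg = CohortConfig(n_pcos_patients=20, n_control_patients=20,
                               n_proteins=5, seed=seed)
            d = simulate_cohort(cfg)
            accs.append(evaluate_final_classifier(
                d.intensities, d.labels, d.rows, ForestParams(seed=seed),
                n_folds=8))
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_label_permutation_near_half(self):
        accs = []
        for seed in range(8):
            d = _signal_dataset(effect=1.0, n_per_group=25, n_noise=5,
                                seed=seed)
            rng = np.random.default_rng(seed)
            # permute group labels at the patient level
            patients = sorted({r.patient_id for r in d.rows})
            perm = dict(zip(patients,
                            rng.permutation([("pcos" if p.startswith("P")
                                              else "control")
                                             for p in patients])))
            y = np.array([perm[r.patient_id] for r in d.rows])
            accs.append(evaluate_final_classifier(
                d.intensities, y, d.rows, ForestParams(seed=seed), n_folds=8))
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_signal_monotonicity(self):
        effects = [0.0, 0.3, 0.6, 1.0]
        means = []
        for effect in effects:
            accs = []
            for seed in range(5):
                if effect == 0:
                    cfg = CohortConfig(n_pcos_patients=30,
                                       n_control_patients=30, n_proteins=5,
                                       patient_sd=0.1, fluid_sd=0.08,
                                       repeat_sd=0.12, seed=seed)
                else:
                    cfg = CohortConfig(n_pcos_patients=30,
                                       n_control_patients=30, n_proteins=5,
                                       effects=tuple((j, effect)
                                                     for j in range(3)),
                                       patient_sd=0.1, fluid_sd=0.08,
                                       repeat_sd=0.12, seed=seed)
                d = simulate_cohort(cfg)
                accs.append(evaluate_final_classifier(
                    d.intensities, d.labels, d.rows, ForestParams(seed=seed),
                    n_folds=10))
            means.append(np.mean(accs))
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 0.05
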