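"""Model grid, repeated stratified CV, selection, metrics and benchmark."""

import numpy as np
import pandas as pd
import pytest

from glucopheno.classify import (
    CVProtocol,
    CVResult,
    FeatureSetSpec,
    ModelSpec,
    benchmark_feature_sets,
    build_model_grid,
    compare_auroc,
    default_feature_sets,
    evaluate_on_test,
    make_estimator,
    repeated_stratified_cv,
    select_model,
)


class _FixedScores:
    """Stub classifier emitting preset margins (for metric arithmetic)."""

    def __init__(self, scores, threshold=0.5):
        self.scores = np.asarray(scores, float)
        self.threshold = threshold

    def decision_function(self, X):
        return self.scores

    def predict(self, X):
        return (self.scores >= self.threshold).astype(int)


class TestModelGrid:
    def test_grid_has_20_models_and_4_architectures(self):
        grid = build_model_grid(seed=0)
        assert len(grid) == 20
        assert len({m.architecture for m in grid}) == 4
        for arch in ("LR-L1", "SVM-linear", "SVM-RBF", "RF"):
            assert sum(m.architecture == arch for m in grid) == 5

    def test_same_seed_same_grid(self):
        assert build_model_grid(3) == build_model_grid(3)

    def test_every_spec_builds_a_classifier(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        for spec in build_model_grid(0):
            est = make_estimator(spec, FeatureSetSpec("Demographics"))
            # pipelines need DataFrame columns for the demographic set
            df = pd.DataFrame(X, columns=["age", "sex", "bmi"])
            est.fit(df, y)
            assert set(est.predict(df)) <= {0, 1}


class TestFeatureSets:
    def test_nine_sets_all_include_demographics(self):
        sets = default_feature_sets()
        assert len(sets) == 9
        for s in sets:
            assert set(("age", "sex", "bmi", "ethnicity",
                        "family_history")) <= set(s.columns)

    def test_curve_sets_add_curve_columns(self):
        by_name = {s.name: s for s in default_feature_sets()}
        assert len(by_name["Demographics+OGTT_G_Features"].columns) == 5 + 16
        assert by_name["Demographics+OGTT_G_ReducedRep"].curve_representation == "reduced"


class TestRepeatedCV:
    def test_separable_data_reaches_auroc_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame({"x": y * 10.0 + rng.normal(0, 0.1, 60),
                          "z": rng.normal(size=60)})
        spec = ModelSpec("SVM-linear", 1.0, 0)
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        est = Pipeline([("s", StandardScaler()), ("clf", spec.make())])
        res = repeated_stratified_cv(X, y, [(spec, est)], k=5, repeats=2, seed=0)
        assert res[spec.name].mean("auroc") == pytest.approx(1.0)

    def test_permuted_labels_centre_at_half(self):
        """Label-free features score at chance, averaged over permutations
        (any one permutation keeps a chance in-sample association)."""
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(200, 5)),
                         columns=list("abcde"))
        spec = ModelSpec("LR-L1", 1.0, 0)
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        means = []
        for p in range(5):
            y = rng.permutation(np.repeat([0, 1], 100))
            est = Pipeline([("s", StandardScaler()), ("clf", spec.make())])
            res = repeated_stratified_cv(X, y, [(spec, est)], k=5, repeats=2,
                                         seed=p)
            means.append(res[spec.name].mean("auroc"))
        assert abs(np.mean(means) - 0.5) <= 0.05

    def test_class_smaller_than_k_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="stratification"):
            repeated_stratified_cv(X, y, [], k=5)


class TestSelection:
    def _result(self, arch, hyper, auroc, f1=0.5, sens=0.5):
        rec = pd.DataFrame({"auroc": [auroc] * 4, "f1": [f1] * 4,
                            "sensitivity": [sens] * 4})
        return CVResult(ModelSpec(arch, hyper, 0), rec)

    def test_single_model_returned(self):
        r = self._result("RF", 100, 0.8)
        assert select_model({r.model.name: r}) is r

    def test_highest_auroc_wins(self):
        a = self._result("RF", 100, 0.9)
        b = self._result("RF", 200, 0.8)
        assert select_model({"a": a, "b": b}).model == a.model

    def test_f1_then_sensitivity_criterion(self):
        a = self._result("RF", 100, 0.7, f1=0.8, sens=0.8)
        b = self._result("RF", 200, 0.9, f1=0.8, sens=0.7)
        chosen = select_model({"a": a, "b": b}, criterion="f1_sensitivity")
        assert chosen.model == a.model

    def test_tie_goes_to_simpler_model(self):
        a = self._result("RF", 50, 0.85)
        b = self._result("RF", 800, 0.85)
        assert select_model({"b": b, "a": a}).model.hyperparameter == 50

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_model({})


class TestEvaluation:
    def test_hand_counted_auroc(self):
        """y=[1,1,0,0], scores=[0.9,0.6,0.7,0.1]: 3 of 4 pairs concordant."""
        m = _FixedScores([0.9, 0.6, 0.7, 0.1])
        out = evaluate_on_test(m, np.zeros((4, 1)), [1, 1, 0, 0])
        assert out["auroc"] == pytest.approx(0.75)

    def test_perfect_scores_all_metrics_one(self):
        m = _FixedScores([0.9, 0.8, 0.2, 0.1])
        out = evaluate_on_test(m, np.zeros((4, 1)), [1, 1, 0, 0])
        for v in out.values():
            assert v == pytest.approx(1.0)

    def test_all_positive_predictions(self):
        m = _FixedScores([0.9, 0.9, 0.9, 0.9])
        out = evaluate_on_test(m, np.zeros((4, 1)), [1, 1, 0, 0])
        assert out["sensitivity"] == 1.0 and out["specificity"] == 0.0

    def test_single_class_test_set_auroc_undefined(self):
        m = _FixedScores([0.9, 0.8, 0.7])
        out = evaluate_on_test(m, np.zeros((3, 1)), [1, 1, 1])
        assert np.isnan(out["auroc"]) and out["sensitivity"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_auroc_equals_brute_force_pair_count(self, seed):
        """auROC must equal the concordant-pair fraction (ties count 1/2),
        enumerated by brute force on <=12-sample instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        y = np.zeros(n, int)
        y[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if y.sum() == 0 or y.sum() == n:
            y[0] = 1 - y[0]
        scores = np.round(rng.random(n), 1)  # coarse grid to provoke ties
        conc = total = 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                total += 1
                conc += 1.0 if scores[i] > scores[j] else 0.5 if scores[i] == scores[j] else 0.0
        out = evaluate_on_test(_FixedScores(scores), np.zeros((n, 1)), y)
        assert out["auroc"] == pytest.approx(conc / total)


class TestCompareAuroc:
    def test_identical_samples_adjusted_p_is_one(self):
        a = np.linspace(0.4, 0.9, 50)
        _, _, adj = compare_auroc(a, a, n_comparisons=8)
        assert adj == 1.0

    def test_separated_samples_tiny_p(self):
        a = np.linspace(0.8, 0.9, 50)
        b = np.linspace(0.1, 0.2, 50)
        _, p, _ = compare_auroc(a, b)
        assert p < 1e-15

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(20), rng.random(20)
        _, _, adj = compare_auroc(a, b, n_comparisons=10**6)
        assert adj <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_auroc([], [0.5])


class TestBenchmark:
    def test_full_table_shape_and_leakage_guard(self, small_table):
        """9 feature sets x 4 phenotypes -> 36 rows, with a small model grid
        and protocol so the structure (not the power) is under test."""
        protocol = CVProtocol(k=3, repeats=1, seed=0,
                              c_grid=(1.0,), tree_grid=(50,))
        table = benchmark_feature_sets(small_table, protocol=protocol)
        assert len(table) == 36
        assert set(table["phenotype"]) == {"muscle_ir", "beta_cell",
                                           "incretin", "hepatic_ir"}
        assert set(table["feature_set"]) == {s.name for s in default_feature_sets()}
        assert table["cv_auroc"].between(0, 1).all()

    def test_missing_columns_reported_per_feature_set(self, small_table):
        protocol = CVProtocol(k=3, repeats=1, seed=0,
                              c_grid=(1.0,), tree_grid=(50,))
        data = small_table.drop(columns=["prs"])
        table = benchmark_feature_sets(
            data, ["muscle_ir"],
            default_feature_sets(["Demographics", "Demographics+PRS"]),
            protocol,
        )
        bad = table[table["feature_set"] == "Demographics+PRS"]
        assert "error" in bad.columns and bad["error"].notna().all()
        good = table[table["feature_set"] == "Demographics"]
        assert good["cv_auroc"].notna().all()
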