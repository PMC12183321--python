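"""Repeated cross-validated benchmark of subphenotype classifiers.

The protocol: four classifier architectures (L1 logistic regression with
the SAGA solver, linear- and RBF-kernel SVMs, random forest), each swept
over five hyperparameter values (20 models total), evaluated by k-fold
stratified cross-validation with per-repeat reshuffling, and compared
across nine feature sets that all include basic demographics.  Curve-shape
feature sets either append the 14 engineered OGTT features or project
curves through a PCA basis refitted inside every training fold (no leakage
into validation folds).

Class-score conventions: decision-function margins for the SVMs, predicted
class-1 probability for the logistic and forest models.  Every pipeline
standardizes features before the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .curves import CANONICAL_GRID
from .features import FEATURE_NAMES, CurveFeaturizer
from .reduced import ReducedRepresentation

__all__ = [
    "DEMOGRAPHIC_COLUMNS",
    "CURVE_COLUMNS",
    "PHENOTYPE_LABELS",
    "ModelSpec",
    "build_model_grid",
    "FeatureSetSpec",
    "default_feature_sets",
    "CVProtocol",
    "CVResult",
    "repeated_stratified_cv",
    "select_model",
    "evaluate_on_test",
    "benchmark_feature_sets",
    "compare_auroc",
]

DEMOGRAPHIC_COLUMNS = ("age", "sex", "bmi", "ethnicity", "family_history")

#: wide-format column names of the 16 canonical glucose samples
CURVE_COLUMNS = tuple(
    f"g_{'m' if t < 0 else ''}{abs(int(t))}" for t in CANONICAL_GRID
)

#: binary label column per prediction task
PHENOTYPE_LABELS = {
    "muscle_ir": "muscle_ir",
    "beta_cell": "beta_dysfunction",
    "incretin": "incretin_dysfunction",
    "hepatic_ir": "hepatic_ir_flag",
}

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_TREE_GRID = (50, 100, 200, 400, 800)


@dataclass(frozen=True)
class ModelSpec:
    """One architecture + hyperparameter combination."""

    architecture: str  # "LR-L1" | "SVM-linear" | "SVM-RBF" | "RF"
    hyperparameter: float
    seed: int = 0

    @property
    def name(self) -> str:
        h = self.hyperparameter
        h_str = f"{h:g}"
        return f"{self.architecture}(C={h_str})" if self.architecture != "RF" else f"RF(n={int(h)})"

    @property
    def complexity(self) -> float:
        """Tie-break key: smaller penalty inverse / fewer trees first."""
        return float(self.hyperparameter)

    def make(self):
        """Fresh classifier for this spec (unscaled; wrap in a pipeline)."""
        if self.architecture == "LR-L1":
            import sklearn

            kwargs = dict(solver="saga", max_iter=10_000,
                          C=self.hyperparameter, random_state=self.seed)
            if sklearn.__version__ >= "1.8":
                kwargs["l1_ratio"] = 1.0  # pure L1 under the new API
            else:
                kwargs["penalty"] = "l1"
            return LogisticRegression(**kwargs)
        if self.architecture == "SVM-linear":
            return SVC(kernel="linear", C=self.hyperparameter,
                       random_state=self.seed)
        if self.architecture == "SVM-RBF":
            return SVC(kernel="rbf", C=self.hyperparameter,
                       random_state=self.seed)
        if self.architecture == "RF":
            return RandomForestClassifier(
                n_estimators=int(self.hyperparameter), random_state=self.seed
            )
        raise ValueError(f"unknown architecture {self.architecture!r}")


def build_model_grid(
    seed: int = 0,
    c_grid: tuple = DEFAULT_C_GRID,
    tree_grid: tuple = DEFAULT_TREE_GRID,
) -> list[ModelSpec]:
    """The 4 x 5 = 20 model grid, deterministically seeded."""
    grid: list[ModelSpec] = []
    for arch in ("LR-L1", "SVM-linear", "SVM-RBF"):
        grid.extend(ModelSpec(arch, c, seed) for c in c_grid)
    grid.extend(ModelSpec("RF", n, seed) for n in tree_grid)
    return grid


@dataclass(frozen=True)
class FeatureSetSpec:
    """Named feature set; demographics are part of every set."""

    name: str
    extra_columns: tuple = ()
    curve_representation: str | None = None  # None | "features" | "reduced"

    @property
    def columns(self) -> tuple:
        cols = DEMOGRAPHIC_COLUMNS + self.extra_columns
        if self.curve_representation is not None:
            cols = cols + CURVE_COLUMNS
        return cols


def default_feature_sets(include: "list[str] | None" = None) -> list[FeatureSetSpec]:
    """The nine benchmark feature sets (optionally a named subset)."""
    sets = [
        FeatureSetSpec("Demographics"),
        FeatureSetSpec("Demographics+PRS", ("prs",)),
        FeatureSetSpec("Demographics+Lab", ("hba1c", "fpg")),
        FeatureSetSpec("Demographics+Incretins", ("gip_2h", "glp1_2h")),
        FeatureSetSpec("Demographics+HOMA-B", ("homa_b",)),
        FeatureSetSpec("Demographics+HOMA-IR", ("homa_ir",)),
        FeatureSetSpec("Demographics+Matsuda", ("matsuda",)),
        FeatureSetSpec("Demographics+OGTT_G_Features", (),
                       curve_representation="features"),
        FeatureSetSpec("Demographics+OGTT_G_ReducedRep", (),
                       curve_representation="reduced"),
    ]
    if include is not None:
        by_name = {s.name: s for s in sets}
        return [by_name[n] for n in include]
    return sets


def make_estimator(
    spec: ModelSpec,
    feature_set: FeatureSetSpec,
    smoothing_parameter: float = 0.35,
) -> Pipeline:
    """Full pipeline for one model on one feature set.

    Curve columns are mapped through the chosen representation (engineered
    features or fold-fitted PCA projection); everything is standardized
    before the classifier.
    """
    steps = []
    if feature_set.curve_representation == "reduced":
        rep = ReducedRepresentation(smoothing_parameter=smoothing_parameter)
        steps.append(
            ("columns", ColumnTransformer(
                [("curve", rep, list(CURVE_COLUMNS))], remainder="passthrough"
            ))
        )
    elif feature_set.curve_representation == "features":
        steps.append(
            ("columns", ColumnTransformer(
                [("curve", CurveFeaturizer(), list(CURVE_COLUMNS))],
                remainder="passthrough",
            ))
        )
    steps.append(("scale", StandardScaler()))
    steps.append(("clf", spec.make()))
    return Pipeline(steps)


def _scores(model, X) -> np.ndarray:
    clf = model[-1] if isinstance(model, Pipeline) else model
    if hasattr(clf, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _fold_metrics(model, X_val, y_val) -> dict:
    y_val = np.asarray(y_val)
    scores = _scores(model, X_val)
    pred = model.predict(X_val)
    tp = int(np.sum((pred == 1) & (y_val == 1)))
    tn = int(np.sum((pred == 0) & (y_val == 0)))
    fp = int(np.sum((pred == 1) & (y_val == 0)))
    fn = int(np.sum((pred == 0) & (y_val == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec_ = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    acc = (tp + tn) / y_val.size
    auroc = (
        roc_auc_score(y_val, scores)
        if np.unique(y_val).size == 2
        else float("nan")
    )
    return {
        "auroc": auroc, "sensitivity": sens, "specificity": spec_,
        "precision": prec, "f1": f1, "accuracy": acc,
    }


METRIC_NAMES = ("auroc", "sensitivity", "specificity", "precision", "f1",
                "accuracy")


@dataclass
class CVResult:
    """Per-fold metric distributions of one model across all repeats."""

    model: ModelSpec
    records: pd.DataFrame  # one row per (repeat, fold), columns METRIC_NAMES

    def mean(self, metric: str = "auroc") -> float:
        return float(np.nanmean(self.records[metric]))

    def std(self, metric: str = "auroc") -> float:
        return float(np.nanstd(self.records[metric], ddof=1))

    def summary(self) -> pd.Series:
        return self.records[list(METRIC_NAMES)].mean()


@dataclass(frozen=True)
class CVProtocol:
    """Cross-validation and split settings of the benchmark."""

    k: int = 5
    repeats: int = 100
    seed: int = 0
    test_size: float = 0.2
    selection: str = "auroc"
    smoothing_parameter: float = 0.35
    c_grid: tuple = DEFAULT_C_GRID
    tree_grid: tuple = DEFAULT_TREE_GRID


def repeated_stratified_cv(
    X: pd.DataFrame,
    y,
    models: "list[tuple[ModelSpec, object]]",
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Shuffled, stratified k-fold CV repeated ``repeats`` times.

    ``models`` is a list of (spec, unfitted estimator) pairs; estimators are
    cloned per fold, so any fold-internal preprocessing (PCA basis and
    scaler included) is refitted on the training folds only.
    """
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary labels required")
    if counts.min() < k:
        raise ValueError(
            f"stratification impossible: a class has {counts.min()} < k={k} members"
        )
    rows: dict[str, list[dict]] = {spec.name: [] for spec, _ in models}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + rep)
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            X_tr = X.iloc[tr] if hasattr(X, "iloc") else X[tr]
            X_va = X.iloc[va] if hasattr(X, "iloc") else X[va]
            for spec, est in models:
                fitted = clone(est).fit(X_tr, y[tr])
                m = _fold_metrics(fitted, X_va, y[va])
                m.update(repeat=rep, fold=fold)
                rows[spec.name].append(m)
    return {
        spec.name: CVResult(spec, pd.DataFrame(rows[spec.name]))
        for spec, _ in models
    }


def select_model(results: dict[str, CVResult], criterion: str = "auroc") -> CVResult:
    """Pick the winning model from CV distributions.

    'auroc': highest mean CV auROC.  'f1_sensitivity': lexicographic
    (mean F1, mean sensitivity).  Ties go to the simpler model (smaller
    C / fewer trees, in grid order).
    """
    if not results:
        raise ValueError("no model results to select from")
    ordered = sorted(results.values(), key=lambda r: r.model.complexity)
    if criterion == "auroc":
        key = lambda r: (r.mean("auroc"),)
    elif criterion == "f1_sensitivity":
        key = lambda r: (r.mean("f1"), r.mean("sensitivity"))
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    return max(ordered, key=key)


def evaluate_on_test(model, X_test, y_test, threshold: float = 0.5) -> dict:
    """Held-out metrics of a fitted model.

    auROC uses continuous scores and is NaN (with the other metrics still
    returned) when the test set has a single class.  ``threshold`` applies
    to probability scores; margin-only models predict by margin sign.
    """
    y_test = np.asarray(y_test).astype(int)
    if y_test.size == 0:
        raise ValueError("empty test set")
    clf = model[-1] if isinstance(model, Pipeline) else model
    if hasattr(clf, "predict_proba") and threshold != 0.5:
        proba = model.predict_proba(X_test)[:, 1]
        pred = (proba >= threshold).astype(int)
        scores = proba
    else:
        pred = model.predict(X_test)
        scores = _scores(model, X_test)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec_ = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    return {
        "auroc": roc_auc_score(y_test, scores)
        if np.unique(y_test).size == 2 else float("nan"),
        "sensitivity": sens,
        "specificity": spec_,
        "precision": prec,
        "f1": 2 * prec * sens / (prec + sens) if prec + sens else 0.0,
        "accuracy": (tp + tn) / y_test.size,
    }


def benchmark_feature_sets(
    data: pd.DataFrame,
    phenotypes: "list[str] | None" = None,
    feature_sets: "list[FeatureSetSpec] | None" = None,
    protocol: CVProtocol = CVProtocol(),
    detailed: bool = False,
):
    """Grid + CV + selection + held-out evaluation per phenotype x feature set.

    ``data`` holds one row per participant with feature columns and the
    binary label columns of ``PHENOTYPE_LABELS``.  Returns a tidy benchmark
    table (one row per cell) and, when ``detailed``, the per-model CV
    results keyed by (phenotype, feature set).
    """
    phenotypes = phenotypes or list(PHENOTYPE_LABELS)
    feature_sets = feature_sets or default_feature_sets()
    grid = build_model_grid(protocol.seed, protocol.c_grid, protocol.tree_grid)
    rows, details = [], {}
    for pheno in phenotypes:
        label_col = PHENOTYPE_LABELS[pheno]
        if label_col not in data.columns:
            raise KeyError(f"label column {label_col!r} absent")
        y = data[label_col].astype(int).to_numpy()
        for fs in feature_sets:
            missing = [c for c in fs.columns if c not in data.columns]
            if missing:
                rows.append({"phenotype": pheno, "feature_set": fs.name,
                             "error": f"missing columns {missing}"})
                continue
            X = data.loc[:, list(fs.columns)]
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=protocol.test_size, stratify=y,
                random_state=protocol.seed,
            )
            models = [
                (spec, make_estimator(spec, fs, protocol.smoothing_parameter))
                for spec in grid
            ]
            results = repeated_stratified_cv(
                X_tr, y_tr, models, k=protocol.k, repeats=protocol.repeats,
                seed=protocol.seed,
            )
            best = select_model(results, protocol.selection)
            est = make_estimator(best.model, fs, protocol.smoothing_parameter)
            est.fit(X_tr, y_tr)
            test_metrics = evaluate_on_test(est, X_te, y_te)
            row = {"phenotype": pheno, "feature_set": fs.name,
                   "classifier": best.model.name,
                   "cv_auroc": best.mean("auroc"),
                   "cv_auroc_sd": best.std("auroc")}
            row.update(test_metrics)
            rows.append(row)
            if detailed:
                details[(pheno, fs.name)] = results
    table = pd.DataFrame(rows)
    return (table, details) if detailed else table


def compare_auroc(dist_a, dist_b, n_comparisons: int = 1) -> tuple[float, float, float]:
    """Wilcoxon rank-sum on two auROC distributions with Bonferroni.

    Returns (statistic, raw two-sided p, adjusted p = min(1, p * n)).
    """
    a, b = np.asarray(dist_a, float), np.asarray(dist_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("auROC samples must be nonempty")
    stat, p = stats.ranksums(a, b)
    return float(stat), float(p), float(min(1.0, p * n_comparisons))
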