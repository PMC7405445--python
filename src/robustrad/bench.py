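"""Selector x model benchmarking at multiple OS class boundaries.

Survival is dichotomized at clinically motivated boundaries (304.2, 365,
425.8 and 540 days by default; a case exactly at the boundary counts as a
long survivor).  Every combination of the 13 selectors and 12 model
families is evaluated by stratified 10-fold cross-validation in which
imputation, standardization and feature selection are fitted on the
training folds only, so selection can never see test labels.  The best
combination per boundary (by mean AUC) is then refitted on the full
training cohort and applied once to an unseen second cohort; the per-metric
decrease is the transfer drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import FeatureID, FeatureTable, FormatError
from .select import BINARY_ONLY, SELECTOR_METHODS, SelectorSpec, select_features

DEFAULT_BOUNDARY_DAYS = (304.2, 365.0, 425.8, 540.0)


@dataclass(frozen=True)
class OSBoundary:
    days: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("boundary must be positive")
        if not self.label:
            object.__setattr__(self, "label", f"{self.days:g}d")


def default_boundaries() -> list[OSBoundary]:
    return [OSBoundary(d) for d in DEFAULT_BOUNDARY_DAYS]


def binarize_os(os_days: np.ndarray, boundary: OSBoundary) -> np.ndarray:
    """1 = long survivor (OS >= boundary, ties inclusive), 0 = short."""
    return (np.asarray(os_days, dtype=float) >= boundary.days).astype(int)


METRIC_NAMES = (
    "auc", "balanced_accuracy", "accuracy", "sensitivity", "specificity",
    "f1", "precision",
)


@dataclass
class MetricsRecord:
    auc: float
    balanced_accuracy: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def mean(cls, records: list["MetricsRecord"]) -> "MetricsRecord":
        return cls(**{
            m: float(np.nanmean([getattr(r, m) for r in records]))
            for m in METRIC_NAMES
        })


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with tie correction."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        warnings.warn("one-class fold: AUC undefined", stacklevel=2)
        return float("nan")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def classification_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsRecord:
    """AUC from the continuous scores; confusion-table metrics at the
    probability threshold (0.5 by default)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    return MetricsRecord(
        auc=auc_score(y, s),
        balanced_accuracy=float(np.nanmean([sens, spec])),
        accuracy=(tp + tn) / len(y),
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        precision=prec,
    )


# --------------------------------------------------------------------------
# model registry
# --------------------------------------------------------------------------

def _make_model(model_id: str, seed: int):
    registry = {
        "knn": lambda: KNeighborsClassifier(),
        "svc_linear": lambda: SVC(kernel="linear", probability=True, random_state=seed),
        "svc_rbf": lambda: SVC(kernel="rbf", probability=True, random_state=seed),
        "gaussian_process": lambda: GaussianProcessClassifier(random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "mlp": lambda: MLPClassifier(max_iter=500, random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "naive_bayes": lambda: GaussianNB(),
        "qda": lambda: QuadraticDiscriminantAnalysis(),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "logistic": lambda: LogisticRegression(max_iter=1000, random_state=seed),
    }
    if model_id not in registry:
        raise KeyError(f"unknown model {model_id!r}; registry: {sorted(registry)}")
    return registry[model_id]()


MODEL_IDS = (
    "knn", "svc_linear", "svc_rbf", "gaussian_process", "decision_tree",
    "random_forest", "mlp", "adaboost", "naive_bayes", "qda",
    "gradient_boosting", "logistic",
)


def grid_size(n_classes: int = 2) -> int:
    """Number of selector x model combinations (t-score is binary-only)."""
    selectors = [
        s for s in SELECTOR_METHODS if n_classes == 2 or s not in BINARY_ONLY
    ]
    return len(selectors) * len(MODEL_IDS)


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Candidate-feature restriction applied before selection.

    ``sequence`` keeps T1c- and FLAIR-derived features (plus the
    sequence-free ones); ``handpicked`` keeps the intensity-free families —
    shape, enhancement geometry, centroids — and age.
    """

    kind: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("none", "sequence", "handpicked"):
            raise ValueError(f"unknown prior {self.kind!r}")

    def apply(self, feature_ids: list[FeatureID]) -> list[FeatureID]:
        if self.kind == "none":
            return list(feature_ids)
        if self.kind == "sequence":
            return [f for f in feature_ids if f.sequence in ("T1c", "FLAIR", "none")]
        return [
            f for f in feature_ids
            if f.family in ("shape", "geometry", "centroid", "clinical")
        ]


# --------------------------------------------------------------------------
# cross-validation harness
# --------------------------------------------------------------------------

class _Pipeline:
    """Median imputation + standardization + selection + model, all fitted
    on training data only."""

    def __init__(self, selector: SelectorSpec, model_id: str, seed: int):
        self.selector = selector
        self.model_id = model_id
        self.seed = seed

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_Pipeline":
        self.medians_ = np.nanmedian(x, axis=0)
        self.medians_ = np.nan_to_num(self.medians_, nan=0.0)
        xi = np.where(np.isfinite(x), x, self.medians_)
        self.mu_ = xi.mean(axis=0)
        self.sd_ = xi.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        xs = (xi - self.mu_) / self.sd_
        k = min(self.selector.k, xs.shape[1])
        spec = replace(self.selector, k=k, seed=self.seed)
        self.support_ = select_features(xs, y, spec)
        self.model_ = _make_model(self.model_id, self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(xs[:, self.support_], y)
        return self

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        xi = np.where(np.isfinite(x), x, self.medians_)
        xs = (xi - self.mu_) / self.sd_
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            proba = self.model_.predict_proba(xs[:, self.support_])
        positive = list(self.model_.classes_).index(1)
        return proba[:, positive]


@dataclass
class BenchmarkResult:
    boundary: OSBoundary
    selector: SelectorSpec
    model_id: str
    split_metrics: list[MetricsRecord]
    mean_metrics: MetricsRecord
    seed: int


def cross_validate(
    table: FeatureTable,
    y: np.ndarray,
    selector: SelectorSpec,
    model_id: str,
    seed: int,
    boundary: OSBoundary | None = None,
    n_splits: int = 10,
) -> BenchmarkResult:
    """Leakage-free stratified k-fold CV of one selector x model combo."""
    x = table.values
    y = np.asarray(y)
    min_class = int(np.bincount(y).min())
    if min_class < n_splits:
        warnings.warn(
            f"minority class has {min_class} cases; reducing folds", stacklevel=2
        )
        n_splits = max(2, min_class)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    records = []
    for train, test in skf.split(x, y):
        pipe = _Pipeline(selector, model_id, seed).fit(x[train], y[train])
        scores = pipe.predict_scores(x[test])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records.append(classification_metrics(y[test], scores))
    return BenchmarkResult(
        boundary=boundary or OSBoundary(365.0),
        selector=selector,
        model_id=model_id,
        split_metrics=records,
        mean_metrics=MetricsRecord.mean(records),
        seed=seed,
    )


@dataclass(frozen=True)
class Combo:
    selector: SelectorSpec
    model_id: str


def run_benchmark_grid(
    table: FeatureTable,
    os_days: np.ndarray,
    boundaries: list[OSBoundary] | None = None,
    selectors: tuple[str, ...] = SELECTOR_METHODS,
    models: tuple[str, ...] = MODEL_IDS,
    prior: PriorSpec = PriorSpec("none"),
    seed: int = 0,
    selector_k: int = 10,
    n_splits: int = 10,
) -> tuple[pd.DataFrame, dict[str, tuple[Combo, BenchmarkResult]]]:
    """Evaluate every selector x model combination at every boundary.

    Returns a tidy result table and, per boundary label, the best combo by
    mean AUC (ties: balanced accuracy, then lexicographic combo name).
    """
    boundaries = boundaries or default_boundaries()
    candidate = prior.apply(table.feature_ids)
    if not candidate:
        raise FormatError("prior restriction left no candidate features")
    sub = table.subset(candidate)

    rows = []
    best: dict[str, tuple[Combo, BenchmarkResult]] = {}
    for boundary in boundaries:
        y = binarize_os(os_days, boundary)
        if len(np.unique(y)) < 2:
            warnings.warn(f"boundary {boundary.label}: single class, skipped", stacklevel=2)
            continue
        ranked = []
        for sel in selectors:
            if sel in BINARY_ONLY and len(np.unique(y)) != 2:
                continue
            spec = SelectorSpec(method=sel, k=selector_k)
            for model_id in models:
                res = cross_validate(
                    sub, y, spec, model_id, seed, boundary=boundary, n_splits=n_splits
                )
                m = res.mean_metrics
                rows.append({
                    "boundary": boundary.label,
                    "selector": sel,
                    "model": model_id,
                    **m.as_dict(),
                })
                ranked.append((
                    -np.nan_to_num(m.auc), -np.nan_to_num(m.balanced_accuracy),
                    sel, model_id, res,
                ))
        ranked.sort(key=lambda r: r[:4])
        _, _, sel, model_id, res = ranked[0]
        best[boundary.label] = (Combo(res.selector, model_id), res)
    return pd.DataFrame(rows), best


# --------------------------------------------------------------------------
# transfer evaluation
# --------------------------------------------------------------------------

@dataclass
class TransferResult:
    boundary: OSBoundary
    combo: Combo
    single: MetricsRecord  # training-cohort CV mean
    multi: MetricsRecord  # held-out second-cohort evaluation
    drop: dict[str, float]


def performance_drop(single: MetricsRecord, multi: MetricsRecord) -> dict[str, float]:
    """Per-metric decrease from training-CV performance to transfer
    performance: drop = single - multi."""
    return {
        m: float(getattr(single, m) - getattr(multi, m)) for m in METRIC_NAMES
    }


def transfer_evaluate(
    train_table: FeatureTable,
    train_os: np.ndarray,
    test_table: FeatureTable,
    test_os: np.ndarray,
    combo: Combo,
    boundary: OSBoundary,
    seed: int = 0,
    n_splits: int = 10,
) -> TransferResult:
    """Refit the full pipeline on the training cohort, evaluate once on the
    second cohort, and report the per-metric drop against the training CV.

    Test features missing from the training table are dropped; training
    features missing from the test table are imputed with training medians.
    """
    shared = [f for f in train_table.feature_ids if f in set(test_table.feature_ids)]
    if not shared:
        raise FormatError("disjoint feature spaces between cohorts")
    train_ids = train_table.feature_ids
    missing = [f for f in train_ids if f not in set(shared)]
    if missing:
        warnings.warn(
            f"{len(missing)} training features absent from the test cohort; "
            "imputed with training medians", stacklevel=2
        )

    y_train = binarize_os(train_os, boundary)
    y_test = binarize_os(test_os, boundary)
    cv = cross_validate(
        train_table, y_train, combo.selector, combo.model_id, seed,
        boundary=boundary, n_splits=n_splits,
    )

    x_train = train_table.values
    pipe = _Pipeline(combo.selector, combo.model_id, seed).fit(x_train, y_train)
    test_df = test_table.df.reindex(columns=train_table.df.columns)
    scores = pipe.predict_scores(test_df.to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        multi = classification_metrics(y_test, scores)
    return TransferResult(
        boundary=boundary,
        combo=combo,
        single=cv.mean_metrics,
        multi=multi,
        drop=performance_drop(cv.mean_metrics, multi),
    )


def drop_report(results: dict[str, list[TransferResult]]) -> pd.DataFrame:
    """Summary table: per feature-set mean drop per metric across
    boundaries, plus per-boundary detail rows."""
    rows = []
    for feature_set, transfers in results.items():
        for tr in transfers:
            for metric in METRIC_NAMES:
                rows.append({
                    "feature_set": feature_set,
                    "boundary": tr.boundary.label,
                    "metric": metric,
                    "single": getattr(tr.single, metric),
                    "multi": getattr(tr.multi, metric),
                    "drop": tr.drop[metric],
                })
        for metric in METRIC_NAMES:
            drops = [tr.drop[metric] for tr in transfers]
            rows.append({
                "feature_set": feature_set,
                "boundary": "mean",
                "metric": metric,
                "single": float("nan"),
                "multi": float("nan"),
                "drop": float(np.nanmean(drops)),
            })
    return pd.DataFrame(rows)
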